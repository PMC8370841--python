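gene	star_allele	rsid	required_state	activity	function
CYP2C19	*2	rs4244285	variant	0.0	no_function
CYP2C19	*3	rs4986893	variant	0.0	no_function
CYP2C19	*4	rs28399504	variant	0.0	no_function
CYP2C19	*5	rs56337013	variant	0.0	no_function
CYP2C19	*6	rs72552267	variant	0.0	no_function
CYP2C19	*7	rs72558186	variant	0.0	no_function
CYP2C19	*8	rs41291556	variant	0.0	no_function
CYP2C19	*17	rs12248560	variant	1.25	increased_function
CYP2D6	*2	rs16947	variant	1.0	normal_function
CYP2D6	*3	rs35742686	variant	0.0	no_function
CYP2D6	*4	rs3892097	variant	0.0	no_function
CYP2D6	*6	rs5030655	variant	0.0	no_function
CYP2D6	*7	rs5030867	variant	0.0	no_function
CYP2D6	*8	rs5030865	variant	0.0	no_function
CYP2D6	*9	rs5030656	variant	0.5	decreased_function
CYP2D6	*10	rs1065852	variant	0.25	decreased_function
CYP2D6	*11	rs5030863	variant	0.0	no_function
CYP2D6	*12	rs5030862	variant	0.0	no_function
CYP2D6	*17	rs28371706	variant	0.5	decreased_function
CYP2D6	*29	rs59421388	variant	0.5	decreased_function
CYP2D6	*41	rs28371725	variant	0.5	decreased_function
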