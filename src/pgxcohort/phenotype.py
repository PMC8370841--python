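"""Star-allele diplotype calling and metabolizer phenotyping.

CYP2D6 and CYP2C19 genotypes are translated to star-allele diplotypes
via a packaged, editable translation table of publicly documented
single-site allele definitions restricted to the panel's rsIDs. Each
allele carries an activity value; the diplotype activity score (the sum
of the two allele activities, scaled by copy number for CYP2D6) maps to
the poor / intermediate / normal / ultrarapid spectrum with the widely
used activity-score cutoffs:

    poor            activity == 0
    intermediate    0 < activity < 1.25
    normal          1.25 <= activity <= 2.25
    ultrarapid      activity > 2.25

Unphased heterozygous calls at two variant-defining sites are assigned
in trans (one allele each), the conservative clinical reading that
maximizes detected non-functionality.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .panel import (
    GenotypeClass,
    PanelDefinition,
    PatientGenotype,
    load_default_panel,
)

logger = logging.getLogger(__name__)

PHENOTYPED_GENES = ("CYP2D6", "CYP2C19")

# Activity-score cutoffs (per-gene configurable through AlleleTranslationTable).
POOR_MAX = 0.0
INTERMEDIATE_MAX = 1.25  # exclusive upper bound of the intermediate band
NORMAL_MAX = 2.25

CYP2C19_UM_TRIGGER_RSID = "rs12248560"  # *17 promoter variant


class MetabolizerPhenotype(str, Enum):
    POOR = "poor"
    INTERMEDIATE = "intermediate"
    NORMAL = "normal"
    ULTRARAPID = "ultrarapid"
    INDETERMINATE = "indeterminate"


class ProfileType(str, Enum):
    PHARMACOKINETIC = "pharmacokinetic"
    PHARMACODYNAMIC = "pharmacodynamic"
    BOTH = "both"
    NONE = "none"


@dataclass(frozen=True)
class StarAllele:
    """A named haplotype defined by required genotype states at one or
    more panel sites, with a numeric activity value."""

    gene: str
    name: str
    defining_sites: tuple[str, ...]  # rsIDs whose variant state defines the allele
    activity: float
    function: str = ""

    def __post_init__(self) -> None:
        if self.activity < 0:
            raise ValueError(f"{self.gene} {self.name}: negative activity")

    @property
    def number(self) -> int:
        digits = "".join(c for c in self.name if c.isdigit())
        return int(digits) if digits else 0


@dataclass
class AlleleTranslationTable:
    """Per-gene star-allele definitions. Every gene implicitly has a
    default *1 allele with activity 1.0 that applies when no defining
    variant is present."""

    alleles: dict[str, list[StarAllele]]  # gene -> alleles

    def for_gene(self, gene: str) -> list[StarAllele]:
        return self.alleles.get(gene, [])

    def rsids(self) -> frozenset[str]:
        return frozenset(
            r for alleles in self.alleles.values() for a in alleles for r in a.defining_sites
        )


def load_default_translation_table() -> AlleleTranslationTable:
    text = resources.files("pgxcohort.data").joinpath("allele_definitions.tsv").read_text()
    return parse_translation_table(text.splitlines())


def parse_translation_table(lines) -> AlleleTranslationTable:
    reader = csv.DictReader(lines, delimiter="\t")
    grouped: dict[tuple[str, str], dict] = {}
    for row in reader:
        key = (row["gene"], row["star_allele"])
        rec = grouped.setdefault(
            key, {"sites": [], "activity": float(row["activity"]), "function": row["function"]}
        )
        rec["sites"].append(row["rsid"])
    alleles: dict[str, list[StarAllele]] = {}
    for (gene, name), rec in grouped.items():
        alleles.setdefault(gene, []).append(
            StarAllele(
                gene=gene,
                name=name,
                defining_sites=tuple(rec["sites"]),
                activity=rec["activity"],
                function=rec["function"],
            )
        )
    return AlleleTranslationTable(alleles=alleles)


def load_translation_table(path: Union[str, Path]) -> AlleleTranslationTable:
    with open(path) as fh:
        return parse_translation_table(fh)


class IndeterminateGenotype(Exception):
    """All sites for a gene are no_call; no diplotype can be assigned."""


_DOSE = {
    GenotypeClass.REF_HOMOZYGOUS: 0,
    GenotypeClass.HETEROZYGOUS: 1,
    GenotypeClass.VARIANT_HOMOZYGOUS: 2,
    GenotypeClass.NO_CALL: 0,
}


def call_diplotype(
    gene: str,
    genotype: PatientGenotype,
    table: Optional[AlleleTranslationTable] = None,
    panel: Optional[PanelDefinition] = None,
) -> tuple[tuple[str, str], float]:
    """Assign a star-allele diplotype and activity score for one gene.

    Alleles are matched greedily in priority order (more defining sites
    first, then lower allele number); each matched allele consumes one
    variant dose at each of its defining sites. Remaining haplotype
    slots default to *1 (activity 1.0). For CYP2D6 the summed activity
    is scaled by copy_number / 2 when a copy number other than 2 is
    declared.

    Raises :class:`IndeterminateGenotype` when every panel site of the
    gene is no_call.
    """
    table = table or load_default_translation_table()
    panel = panel or load_default_panel()
    sites = panel.sites_for_gene(gene)
    if not sites:
        raise ValueError(f"gene {gene} has no panel sites")
    if all(genotype.genotype_class(r) is GenotypeClass.NO_CALL for r in sites):
        raise IndeterminateGenotype(gene)

    doses = {r: _DOSE[genotype.genotype_class(r)] for r in sites}
    candidates = sorted(
        table.for_gene(gene), key=lambda a: (-len(a.defining_sites), a.number)
    )
    assigned: list[StarAllele] = []
    for allele in candidates:
        if len(assigned) == 2:
            break
        if not all(r in doses for r in allele.defining_sites):
            continue
        copies = min(doses[r] for r in allele.defining_sites)
        copies = min(copies, 2 - len(assigned))
        for _ in range(copies):
            assigned.append(allele)
            for r in allele.defining_sites:
                doses[r] -= 1

    default = StarAllele(gene=gene, name="*1", defining_sites=(), activity=1.0,
                         function="normal_function")
    while len(assigned) < 2:
        assigned.append(default)
    assigned.sort(key=lambda a: a.number)
    activity = sum(a.activity for a in assigned)
    if gene == "CYP2D6" and genotype.cyp2d6_copy_number != 2:
        activity *= genotype.cyp2d6_copy_number / 2.0
    return (assigned[0].name, assigned[1].name), activity


def phenotype_from_activity(
    gene: str,
    activity: float,
    copy_number: Optional[int] = None,
    rs12248560_state: GenotypeClass = GenotypeClass.REF_HOMOZYGOUS,
) -> MetabolizerPhenotype:
    """Map an activity score to the metabolizer spectrum.

    CYP2C19 ultrarapid is additionally triggered by homozygosity for the
    *17 promoter variant (rs12248560). CYP2D6 ultrarapid requires a
    declared copy number above 2: a SNP-only panel cannot observe the
    gene duplications that define CYP2D6 UM.
    """
    if activity < 0:
        raise ValueError("activity must be non-negative")
    if gene == "CYP2C19" and rs12248560_state is GenotypeClass.VARIANT_HOMOZYGOUS:
        return MetabolizerPhenotype.ULTRARAPID
    if activity == POOR_MAX:
        return MetabolizerPhenotype.POOR
    if activity < INTERMEDIATE_MAX:
        return MetabolizerPhenotype.INTERMEDIATE
    if activity <= NORMAL_MAX:
        return MetabolizerPhenotype.NORMAL
    if gene == "CYP2D6" and (copy_number is None or copy_number <= 2):
        # activity > 2.25 without a duplication cannot happen with the
        # packaged table; guard anyway and stay at normal.
        logger.warning("CYP2D6 activity %.2f without copy_number > 2; not calling UM", activity)
        return MetabolizerPhenotype.NORMAL
    return MetabolizerPhenotype.ULTRARAPID


def call_phenotype(
    gene: str,
    genotype: PatientGenotype,
    table: Optional[AlleleTranslationTable] = None,
    panel: Optional[PanelDefinition] = None,
) -> MetabolizerPhenotype:
    """Diplotype + activity-threshold phenotype call for one gene;
    indeterminate when the gene is entirely no_call."""
    try:
        _, activity = call_diplotype(gene, genotype, table, panel)
    except IndeterminateGenotype:
        return MetabolizerPhenotype.INDETERMINATE
    return phenotype_from_activity(
        gene,
        activity,
        copy_number=genotype.cyp2d6_copy_number if gene == "CYP2D6" else None,
        rs12248560_state=genotype.genotype_class(CYP2C19_UM_TRIGGER_RSID)
        if gene == "CYP2C19"
        else GenotypeClass.REF_HOMOZYGOUS,
    )


def count_pd_variants(
    genotype: PatientGenotype, panel: Optional[PanelDefinition] = None
) -> int:
    """Number of distinct pharmacodynamic panel sites (receptor,
    transporter, other-PD categories) carrying at least one variant
    allele. Zygosity-insensitive; each rsID counted once even when it
    is annotated under several genes; no_call contributes 0."""
    panel = panel or load_default_panel()
    count = 0
    for rsid in panel.rsids:
        if not panel.is_pd_site(rsid):
            continue
        if genotype.genotype_class(rsid) in (
            GenotypeClass.HETEROZYGOUS,
            GenotypeClass.VARIANT_HOMOZYGOUS,
        ):
            count += 1
    return count


@dataclass(frozen=True)
class PhenotypeProfile:
    """Per-patient phenotyping summary feeding the genetic score."""

    patient_id: str
    cyp2d6: MetabolizerPhenotype
    cyp2c19: MetabolizerPhenotype
    pd_variant_count: int
    profile_type: ProfileType

    def __post_init__(self) -> None:
        if self.pd_variant_count < 0:
            raise ValueError("pd_variant_count must be >= 0")


def _effective(p: MetabolizerPhenotype) -> MetabolizerPhenotype:
    """Indeterminate is treated as normal for profile typing so missing
    data cannot inflate risk (logged by callers)."""
    return MetabolizerPhenotype.NORMAL if p is MetabolizerPhenotype.INDETERMINATE else p


def classify_profile_type(
    cyp2d6: MetabolizerPhenotype,
    cyp2c19: MetabolizerPhenotype,
    pd_variant_count: int,
) -> ProfileType:
    pk_abnormal = any(
        _effective(p) is not MetabolizerPhenotype.NORMAL for p in (cyp2d6, cyp2c19)
    )
    pd_present = pd_variant_count > 0
    if pk_abnormal and pd_present:
        return ProfileType.BOTH
    if pk_abnormal:
        return ProfileType.PHARMACOKINETIC
    if pd_present:
        return ProfileType.PHARMACODYNAMIC
    return ProfileType.NONE


def build_profile(
    genotype: PatientGenotype,
    panel: Optional[PanelDefinition] = None,
    table: Optional[AlleleTranslationTable] = None,
) -> PhenotypeProfile:
    """Assemble the per-patient phenotype profile from diplotype calls
    and the PD variant tally."""
    panel = panel or load_default_panel()
    table = table or load_default_translation_table()
    cyp2d6 = call_phenotype("CYP2D6", genotype, table, panel)
    cyp2c19 = call_phenotype("CYP2C19", genotype, table, panel)
    for gene, pheno in (("CYP2D6", cyp2d6), ("CYP2C19", cyp2c19)):
        if pheno is MetabolizerPhenotype.INDETERMINATE:
            logger.warning(
                "patient %s: %s indeterminate, treated as normal for profiling",
                genotype.patient_id,
                gene,
            )
    pd_count = count_pd_variants(genotype, panel)
    return PhenotypeProfile(
        patient_id=genotype.patient_id,
        cyp2d6=cyp2d6,
        cyp2c19=cyp2c19,
        pd_variant_count=pd_count,
        profile_type=classify_profile_type(cyp2d6, cyp2c19, pd_count),
    )
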