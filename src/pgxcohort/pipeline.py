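"""End-to-end orchestration: ingest → phenotype → score → statistics → report.

The pipeline runs either on real input files (genotype table or VCF +
questionnaire CSV + demographics CSV) or in simulate mode on a
generated cohort. Patients lacking a baseline questionnaire are
excluded from statistics (logged) but retained in phenotype outputs;
the paired Wilcoxon runs only on the follow-up-complete subset;
Spearman runs on both the full cohort and the follow-up subset.

Report files are byte-identical across reruns with identical config and
seeds: provenance carries a config hash and component versions, not
wall-clock timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from ._version import __version__ as _pkg_version
from .panel import PANEL_VERSION, load_default_panel, parse_genotype_table, parse_vcf
from .phenotype import (
    MetabolizerPhenotype,
    PhenotypeProfile,
    build_profile,
    classify_profile_type,
    load_default_translation_table,
)
from .scoring import (
    MoodCategory,
    MoodSublevel,
    Timepoint,
    mood_points,
    side_effect_points,
)
from .simulate import GeneratorConfig, SyntheticCohort, generate_cohort, generate_genotype_mode
from .stats import (
    DEFAULT_HIGH_EFFECTIVENESS_THRESHOLD,
    DEFAULT_N_BOOT,
    DEFAULT_ROC_SEED,
    CohortSummary,
    DegenerateInputError,
    RocResult,
    SpearmanResult,
    WilcoxonResult,
    dichotomize_effectiveness,
    roc_bootstrap_smoothed,
    spearman_correlation,
    summarize_cohort,
    wilcoxon_paired,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline run configuration: exactly one of the real-input paths
    (``input_dir`` or explicit files) or ``simulate`` must be active."""

    input_dir: Optional[Union[str, Path]] = None
    genotype_table: Optional[Union[str, Path]] = None
    vcf: Optional[Union[str, Path]] = None
    questionnaires: Optional[Union[str, Path]] = None
    demographics: Optional[Union[str, Path]] = None
    profiles: Optional[Union[str, Path]] = None
    simulate: Optional[GeneratorConfig] = None
    simulate_genotype_mode: bool = False

    effect_size_convention: str = "total_observations"
    dichotomization_threshold: float = DEFAULT_HIGH_EFFECTIVENESS_THRESHOLD
    roc_on_full_cohort: bool = True
    n_boot: int = DEFAULT_N_BOOT
    roc_seed: int = DEFAULT_ROC_SEED

    def validate(self) -> None:
        has_real = any(
            x is not None
            for x in (self.input_dir, self.genotype_table, self.vcf, self.profiles)
        )
        if has_real == (self.simulate is not None):
            raise ValueError("exactly one of real-input mode or simulate mode must be active")


@dataclass
class AnalysisReport:
    summary_full: CohortSummary
    summary_followup: Optional[CohortSummary]
    wilcoxon: Optional[WilcoxonResult]
    spearman_full: Optional[SpearmanResult]
    spearman_followup: Optional[SpearmanResult]
    roc: Optional[RocResult]
    n_input: int
    n_analyzed: int
    n_excluded_no_baseline: int
    provenance: dict = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame, repr=False)

    def to_dict(self) -> dict:
        def conv(obj):
            if obj is None:
                return None
            d = dataclasses.asdict(obj)
            for k, v in list(d.items()):
                if isinstance(v, tuple):
                    d[k] = list(v)
                elif isinstance(v, dict):
                    d[k] = v
            return d

        roc = None
        if self.roc is not None:
            roc = conv(self.roc)

        return {
            "cohort": {
                "n_input": self.n_input,
                "n_analyzed": self.n_analyzed,
                "n_excluded_no_baseline": self.n_excluded_no_baseline,
            },
            "summary_full": conv(self.summary_full),
            "summary_followup": conv(self.summary_followup),
            "wilcoxon": conv(self.wilcoxon),
            "spearman_full": conv(self.spearman_full),
            "spearman_followup": conv(self.spearman_followup),
            "roc": roc,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _read_questionnaires(path: Union[str, Path]) -> pd.DataFrame:
    q = pd.read_csv(path, dtype={"patient_id": str}, keep_default_na=False)
    required = {"patient_id", "timepoint", "mood_category", "mood_sublevel", "side_effects"}
    missing = required - set(q.columns)
    if missing:
        raise ValueError(f"{path}: missing questionnaire column(s) {sorted(missing)}")
    totals = []
    for _, row in q.iterrows():
        cat = MoodCategory(row["mood_category"])
        sub = MoodSublevel(row["mood_sublevel"]) if row["mood_sublevel"] else None
        mp = mood_points(cat, sub)
        sep = side_effect_points(str(row["side_effects"]).split(";"))
        totals.append(mp + sep)
    q = q.assign(total=totals)
    return q


def _profiles_from_frame(frame: pd.DataFrame) -> list[PhenotypeProfile]:
    profiles = []
    for _, row in frame.iterrows():
        d6 = MetabolizerPhenotype(row["cyp2d6_phenotype"])
        c19 = MetabolizerPhenotype(row["cyp2c19_phenotype"])
        count = int(row["pd_variant_count"])
        profiles.append(
            PhenotypeProfile(
                patient_id=str(row["patient_id"]),
                cyp2d6=d6,
                cyp2c19=c19,
                pd_variant_count=count,
                profile_type=classify_profile_type(d6, c19, count),
            )
        )
    return profiles


def _load_real_inputs(config: RunConfig) -> pd.DataFrame:
    """Assemble the per-patient analysis table from input files."""
    from .scoring import genetic_mutation_score

    if config.input_dir is not None:
        d = Path(config.input_dir)
        if config.genotype_table is None and (d / "genotypes.csv").exists():
            config.genotype_table = d / "genotypes.csv"
        if config.profiles is None and (d / "profiles.csv").exists():
            config.profiles = d / "profiles.csv"
        if config.questionnaires is None:
            config.questionnaires = d / "questionnaires.csv"
        if config.demographics is None and (d / "demographics.csv").exists():
            config.demographics = d / "demographics.csv"

    if config.questionnaires is None or not Path(config.questionnaires).exists():
        raise FileNotFoundError(
            f"questionnaire file not found: {config.questionnaires}"
        )

    panel = load_default_panel()
    table = load_default_translation_table()
    if config.genotype_table is not None or config.vcf is not None:
        if config.genotype_table is not None:
            genotypes = parse_genotype_table(config.genotype_table, panel)
        else:
            genotypes = parse_vcf(config.vcf, panel)
        profiles = [build_profile(g, panel, table) for g in genotypes]
    elif config.profiles is not None:
        profiles = _profiles_from_frame(pd.read_csv(config.profiles, dtype={"patient_id": str}))
    else:
        raise ValueError("no genotype, VCF or profile input given")

    rows = []
    for pr in profiles:
        score = genetic_mutation_score(pr)
        rows.append(
            {
                "patient_id": pr.patient_id,
                "cyp2d6_phenotype": pr.cyp2d6.value,
                "cyp2c19_phenotype": pr.cyp2c19.value,
                "pd_variant_count": pr.pd_variant_count,
                "profile_type": pr.profile_type.value,
                "genetic_total": score.total,
            }
        )
    frame = pd.DataFrame(rows)

    quest = _read_questionnaires(config.questionnaires)
    for tp, col in ((Timepoint.BASELINE.value, "baseline_total"),
                    (Timepoint.FOLLOWUP.value, "followup_total")):
        sub = quest[quest["timepoint"] == tp][["patient_id", "total"]]
        sub = sub.rename(columns={"total": col})
        frame = frame.merge(sub, on="patient_id", how="left")

    if config.demographics is not None and Path(config.demographics).exists():
        demo = pd.read_csv(config.demographics, dtype={"patient_id": str})
        frame = frame.merge(demo, on="patient_id", how="left")
    return frame


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        if isinstance(o, Path):
            return str(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> AnalysisReport:
    """Execute the full analysis and return the report."""
    config.validate()

    if config.simulate is not None:
        cohort: SyntheticCohort = (
            generate_genotype_mode(config.simulate)
            if config.simulate_genotype_mode
            else generate_cohort(config.simulate)
        )
        frame = cohort.to_frame()
    else:
        frame = _load_real_inputs(config)

    n_input = len(frame)
    has_baseline = frame["baseline_total"].notna() if "baseline_total" in frame else pd.Series(False, index=frame.index)
    n_excluded = int((~has_baseline).sum())
    if n_excluded:
        logger.info("excluding %d patients without baseline questionnaire", n_excluded)
    analyzed = frame[has_baseline].reset_index(drop=True)
    n_analyzed = len(analyzed)

    summary_full = summarize_cohort(analyzed)
    followup = analyzed[analyzed["followup_total"].notna()].reset_index(drop=True)
    summary_followup = summarize_cohort(followup) if len(followup) else None

    wilcoxon = None
    if len(followup) >= 5:
        try:
            wilcoxon = wilcoxon_paired(
                followup["baseline_total"],
                followup["followup_total"],
                effect_size_convention=config.effect_size_convention,
            )
        except DegenerateInputError as exc:
            logger.warning("Wilcoxon not computed: %s", exc)
    else:
        logger.warning("Wilcoxon not computed: %d follow-up pairs", len(followup))

    def _spearman(sub: pd.DataFrame) -> Optional[SpearmanResult]:
        if len(sub) < 4:
            return None
        try:
            return spearman_correlation(sub["genetic_total"], sub["baseline_total"])
        except DegenerateInputError as exc:
            logger.warning("Spearman not computed: %s", exc)
            return None

    spearman_full = _spearman(analyzed)
    spearman_followup = _spearman(followup)

    roc = None
    roc_frame = analyzed if config.roc_on_full_cohort else followup
    if len(roc_frame):
        labels = dichotomize_effectiveness(
            roc_frame["baseline_total"], config.dichotomization_threshold
        )
        try:
            roc = roc_bootstrap_smoothed(
                roc_frame["genetic_total"], labels,
                n_boot=config.n_boot, seed=config.roc_seed,
            )
        except DegenerateInputError as exc:
            logger.warning("ROC not computed: %s", exc)

    provenance = {
        "package_version": _pkg_version,
        "panel_version": PANEL_VERSION,
        "config_hash": _config_hash(config),
        "roc_seed": config.roc_seed,
        "simulate_seed": config.simulate.seed if config.simulate else None,
        "effect_size_convention": config.effect_size_convention,
        "dichotomization_threshold": config.dichotomization_threshold,
    }
    return AnalysisReport(
        summary_full=summary_full,
        summary_followup=summary_followup,
        wilcoxon=wilcoxon,
        spearman_full=spearman_full,
        spearman_followup=spearman_followup,
        roc=roc,
        n_input=n_input,
        n_analyzed=n_analyzed,
        n_excluded_no_baseline=n_excluded,
        provenance=provenance,
        table=analyzed,
    )


def write_report(report: AnalysisReport, out_dir: Union[str, Path]) -> dict:
    """Serialize a report: ``report.json``, ``table2.csv`` (descriptive
    summary), ``scores.csv`` and ``profiles.csv``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "report": out / "report.json",
        "table2": out / "table2.csv",
        "scores": out / "scores.csv",
        "profiles": out / "profiles.csv",
    }
    paths["report"].write_text(report.to_json())
    report.summary_full.to_frame().to_csv(paths["table2"], index=False)
    score_cols = [
        c
        for c in ("patient_id", "genetic_total", "baseline_total", "followup_total")
        if c in report.table.columns
    ]
    report.table[score_cols].to_csv(paths["scores"], index=False)
    prof_cols = [
        c
        for c in (
            "patient_id",
            "cyp2d6_phenotype",
            "cyp2c19_phenotype",
            "pd_variant_count",
            "profile_type",
        )
        if c in report.table.columns
    ]
    report.table[prof_cols].to_csv(paths["profiles"], index=False)
    return {k: str(v) for k, v in paths.items()}
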