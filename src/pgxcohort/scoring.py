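"""Composite clinical scores.

Two bespoke rule-based scores drive the cohort analysis:

* **Genetic mutation score (0-15).** Each of CYP2D6 and CYP2C19
  contributes 5 points for an extreme metabolizer phenotype (poor or
  ultrarapid), 2 for intermediate, 0 for normal; a patient extreme in
  both scores 10. One point is added per pharmacodynamic variant site
  (receptor, transporter, other PD genes), capped at 5.

* **Treatment effectiveness score (1-10, higher = worse).** Mood toward
  regular work tasks on a 1-5 scale ("I feel good" = 1, "I force myself
  to do work" = 2-3, "I am unable to work" = 4-5) plus the number of
  distinct reported medication side effects capped at 5. The scale's
  printed anchor is "0 (Good) to 10 (Worst)"; because mood is 1-5 the
  attainable minimum is 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Optional

from .phenotype import MetabolizerPhenotype, PhenotypeProfile

logger = logging.getLogger(__name__)

PD_POINT_CAP = 5
EXTREME_POINTS = 5
INTERMEDIATE_POINTS = 2
NORMAL_POINTS = 0


class Timepoint(str, Enum):
    BASELINE = "baseline"
    FOLLOWUP = "followup"


class MoodCategory(str, Enum):
    FEEL_GOOD = "feel_good"        # "I feel good"
    FORCE_MYSELF = "force_myself"  # "I force myself to do work"
    UNABLE = "unable"              # "I am unable to work"


class MoodSublevel(str, Enum):
    LOW = "low"
    HIGH = "high"


@dataclass(frozen=True)
class GeneticMutationScore:
    pk_points_2d6: int
    pk_points_2c19: int
    pd_points: int

    def __post_init__(self) -> None:
        valid = {NORMAL_POINTS, INTERMEDIATE_POINTS, EXTREME_POINTS}
        if self.pk_points_2d6 not in valid or self.pk_points_2c19 not in valid:
            raise ValueError("per-gene PK points must be 0, 2 or 5")
        if not 0 <= self.pd_points <= PD_POINT_CAP:
            raise ValueError("pd_points must be in [0, 5]")

    @property
    def total(self) -> int:
        return self.pk_points_2d6 + self.pk_points_2c19 + self.pd_points


@dataclass(frozen=True)
class EffectivenessScore:
    mood_points: int
    side_effect_points: int
    timepoint: Timepoint

    def __post_init__(self) -> None:
        if not 1 <= self.mood_points <= 5:
            raise ValueError("mood_points must be in [1, 5]")
        if not 0 <= self.side_effect_points <= 5:
            raise ValueError("side_effect_points must be in [0, 5]")

    @property
    def total(self) -> int:
        return self.mood_points + self.side_effect_points


@dataclass(frozen=True)
class ScoreRecord:
    patient_id: str
    genetic: GeneticMutationScore
    baseline: EffectivenessScore
    followup: Optional[EffectivenessScore] = None


def pk_phenotype_points(phenotype: MetabolizerPhenotype) -> int:
    """Per-gene pharmacokinetic score contribution: 5 for an extreme
    (poor or ultrarapid) metabolizer, 2 for intermediate, 0 for normal.
    Indeterminate contributes 0 with a warning — missing data must not
    raise risk scores."""
    if phenotype in (MetabolizerPhenotype.POOR, MetabolizerPhenotype.ULTRARAPID):
        return EXTREME_POINTS
    if phenotype is MetabolizerPhenotype.INTERMEDIATE:
        return INTERMEDIATE_POINTS
    if phenotype is MetabolizerPhenotype.NORMAL:
        return NORMAL_POINTS
    if phenotype is MetabolizerPhenotype.INDETERMINATE:
        logger.warning("indeterminate phenotype scored as 0 PK points")
        return NORMAL_POINTS
    raise ValueError(f"unknown phenotype {phenotype!r}")


def genetic_mutation_score(profile: PhenotypeProfile) -> GeneticMutationScore:
    """Score a phenotype profile on the 0-15 genetic mutation scale."""
    return GeneticMutationScore(
        pk_points_2d6=pk_phenotype_points(profile.cyp2d6),
        pk_points_2c19=pk_phenotype_points(profile.cyp2c19),
        pd_points=min(profile.pd_variant_count, PD_POINT_CAP),
    )


def mood_points(
    category: MoodCategory, sublevel: Optional[MoodSublevel] = None
) -> int:
    """Map the questionnaire mood answer to its 1-5 point value. The
    middle and upper bands span two integers each, so they require an
    explicit severity sublevel."""
    if category is MoodCategory.FEEL_GOOD:
        return 1
    if category is MoodCategory.FORCE_MYSELF:
        if sublevel is None:
            raise ValueError("force_myself requires a sublevel (low/high)")
        return 2 if sublevel is MoodSublevel.LOW else 3
    if category is MoodCategory.UNABLE:
        if sublevel is None:
            raise ValueError("unable requires a sublevel (low/high)")
        return 4 if sublevel is MoodSublevel.LOW else 5
    raise ValueError(f"unknown mood category {category!r}")


def side_effect_points(side_effects: Iterable[str]) -> int:
    """Count distinct reported side effects (case-insensitive,
    whitespace-trimmed), capped at 5."""
    distinct = {s.strip().lower() for s in side_effects if s and s.strip()}
    return min(len(distinct), PD_POINT_CAP)


def effectiveness_score(
    mood_pts: int, side_effect_pts: int, timepoint: Timepoint = Timepoint.BASELINE
) -> EffectivenessScore:
    """Combine mood and side-effect points into the 1-10 treatment
    effectiveness score (component validation in the dataclass)."""
    return EffectivenessScore(
        mood_points=mood_pts,
        side_effect_points=side_effect_pts,
        timepoint=timepoint,
    )


def points_to_components(total: int) -> tuple[int, int]:
    """Split an integer effectiveness total in [1, 10] into a valid
    (mood, side-effect) component pair, favouring an even split."""
    if not 1 <= total <= 10:
        raise ValueError("effectiveness total must be in [1, 10]")
    mood = min(5, max(1, total - 5, round(total / 2)))
    return mood, total - mood
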