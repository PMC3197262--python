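"""Three-point grading of lumen-visibility measurements.

Each of the three measured categories maps onto a 1/2/3 (poor /
intermediate / good) score by fixed thresholds; the three scores sum to an
overall score of 3-9, classified poor (3-4), intermediate (5-7) or good
(8-9).  Boundary values belong to the intermediate band in every category
(e.g. a relative signal intensity of exactly 40% or 60% scores 2, a
homogeneity ratio of exactly 0.10 scores 2).

Grading operates on the rounded values as reported (integer percents, two
decimals for homogeneity), so regrading a published measurement table is
exact integer/decimal arithmetic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .metrics import MeasurementResult

__all__ = [
    "GradingThresholds",
    "GradeReport",
    "grade_signal_intensity",
    "grade_lumen_narrowing",
    "grade_homogeneity",
    "overall_grade",
    "grade_measurement",
    "grade_table",
]

CLASSES = ("poor", "intermediate", "good")


@dataclass(frozen=True)
class GradingThresholds:
    si_poor_below: float = 40.0  # % relative signal intensity
    si_good_above: float = 60.0
    vis_poor_below: float = 40.0  # % minimal visible lumen diameter
    vis_good_above: float = 70.0
    hom_poor_at_or_above: float = 0.4  # SD/mean
    hom_good_below: float = 0.1
    overall_poor_max: int = 4
    overall_good_min: int = 8

    def __post_init__(self) -> None:
        if not (self.si_poor_below < self.si_good_above):
            raise ValueError("si thresholds out of order")
        if not (self.vis_poor_below < self.vis_good_above):
            raise ValueError("vis thresholds out of order")
        if not (self.hom_good_below < self.hom_poor_at_or_above):
            raise ValueError("homogeneity thresholds out of order")
        if not (self.overall_poor_max < self.overall_good_min):
            raise ValueError("overall thresholds out of order")


DEFAULT_THRESHOLDS = GradingThresholds()


@dataclass
class GradeReport:
    stent_id: int
    name: str
    score_si: int
    score_vis: int
    score_hom: int
    overall_score: int
    overall_class: str


def grade_signal_intensity(
    si_percent: float, thresholds: GradingThresholds = DEFAULT_THRESHOLDS
) -> int:
    """1 if below 40%, 2 for 40-60% inclusive, 3 above 60%."""
    if si_percent < 0:
        raise ValueError("si_percent must be >= 0")
    if si_percent < thresholds.si_poor_below:
        return 1
    return 2 if si_percent <= thresholds.si_good_above else 3

def grade_lumen_narrowing(
    vis_min_percent: float, thresholds: GradingThresholds = DEFAULT_THRESHOLDS
) -> int:
    """1 if below 40%, 2 for 40-70% inclusive, 3 above 70%."""
    if vis_min_percent < 0:
        raise ValueError("vis_min_percent must be >= 0")
    if vis_min_percent > 100:
        warnings.warn(
            f"visible lumen {vis_min_percent}% exceeds 100%; clamping", stacklevel=2
        )
        vis_min_percent = 100.0
    if vis_min_percent < thresholds.vis_poor_below:
        return 1
    return 2 if vis_min_percent <= thresholds.vis_good_above else 3

def grade_homogeneity(
    sd_over_mean: float, thresholds: GradingThresholds = DEFAULT_THRESHOLDS
) -> int:
    """1 if SD/mean >= 0.4, 2 for [0.1, 0.4), 3 below 0.1."""
    if sd_over_mean < 0:
        raise ValueError("sd_over_mean must be >= 0")
    if sd_over_mean >= thresholds.hom_poor_at_or_above:
        return 1
    return 3 if sd_over_mean < thresholds.hom_good_below else 2


def classify_overall(
    overall_score: int, thresholds: GradingThresholds = DEFAULT_THRESHOLDS
) -> str:
    if overall_score <= thresholds.overall_poor_max:
        return "poor"
    return "good" if overall_score >= thresholds.overall_good_min else "intermediate"


def overall_grade(
    score_si: int,
    score_vis: int,
    score_hom: int,
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[int, str]:
    """Sum the category scores and classify: 3-4 poor, 5-7 intermediate, 8-9 good."""
    for s in (score_si, score_vis, score_hom):
        if s not in (1, 2, 3):
            raise ValueError(f"category scores must be in {{1, 2, 3}}, got {s}")
    total = score_si + score_vis + score_hom
    return total, classify_overall(total, thresholds)


def grade_measurement(
    m: MeasurementResult, thresholds: GradingThresholds = DEFAULT_THRESHOLDS
) -> GradeReport:
    s_si = grade_signal_intensity(m.si_percent, thresholds)
    s_vis = grade_lumen_narrowing(m.vis_min_percent, thresholds)
    s_hom = grade_homogeneity(m.sd_over_mean, thresholds)
    total, cls = overall_grade(s_si, s_vis, s_hom, thresholds)
    return GradeReport(m.stent_id, m.name, s_si, s_vis, s_hom, total, cls)


def grade_table(
    measurements: list[MeasurementResult],
    thresholds: GradingThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[GradeReport], dict[str, dict[str, int]]]:
    """Grade a measurement collection and tally the class counts.

    Returns per-stent reports ordered by stent id plus counts of
    good/intermediate/poor per category and for the overall class.
    """
    ids = [m.stent_id for m in measurements]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate stent ids in measurement table")
    reports = [
        grade_measurement(m, thresholds)
        for m in sorted(measurements, key=lambda m: m.stent_id)
    ]
    score_to_class = {1: "poor", 2: "intermediate", 3: "good"}
    counts = {
        cat: {c: 0 for c in CLASSES} for cat in ("si", "vis", "hom", "overall")
    }
    for r in reports:
        counts["si"][score_to_class[r.score_si]] += 1
        counts["vis"][score_to_class[r.score_vis]] += 1
        counts["hom"][score_to_class[r.score_hom]] += 1
        counts["overall"][r.overall_class] += 1
    return reports, counts
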