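"""Clinical endpoint computation and outcome labels.

ADHD-RS conventions used here (documented in the methods note): each of
the 18 items (9 inattention, 9 hyperactivity/impulsivity) is rated 0–3;
a scale *score* is the count of its items rated ≥ 2 (symptom present),
which keeps the ≥6 child / ≥5 adult inclusion cut-offs and baseline
totals around 12 coherent; *remission* is judged on the endpoint mean of
the 18 raw item ratings (≤ 1.00, boundary inclusive). Endpoints use the
outtake assessment when present, otherwise the last available one
(last observation carried forward, LOCF).

Labels: R25 / R50 — ≥25% / ≥50% reduction on either scale score;
remission — endpoint item mean ≤ 1.00; drop-out (DO) — ≤ 20 sessions and
not a responder (R25), excluded from analysis sets; non-responder (NR) —
> 20 sessions and not R25.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as spstats

N_ITEMS = 18
ATT_SLICE = slice(0, 9)
HYP_SLICE = slice(9, 18)
SYMPTOM_RATING = 2  # item counts toward the scale score when rated >= 2
DO_SESSION_CUTOFF = 20
REMISSION_ITEM_MEAN = 1.00


@dataclass
class SubjectRecord:
    """Clinical scores over assessments for one subject.

    ``adhd_items`` is (n_assessments x 18) with ratings 0–3; rows follow
    ``assessment_sessions`` (0 = intake; the last entry is outtake when
    complete). Missing later assessments are simply absent rows.
    """

    subject_id: str
    age: float
    sex: str  # "female" | "male"
    adhd_items: np.ndarray
    assessment_sessions: list[int]
    sessions_taken: int
    psqi_total: float = float("nan")
    hsdq: dict[str, float] = field(default_factory=dict)  # subscales incl. "sbd"
    protocol: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.adhd_items = np.asarray(self.adhd_items, dtype=float)
        if self.adhd_items.ndim != 2 or self.adhd_items.shape[1] != N_ITEMS:
            raise ValueError("adhd_items must be n_assessments x 18")
        if self.adhd_items.shape[0] != len(self.assessment_sessions):
            raise ValueError("assessment rows and session indices disagree")
        if list(self.assessment_sessions) != sorted(self.assessment_sessions):
            raise ValueError("assessments must be time-ordered")
        if np.nanmin(self.adhd_items) < 0 or np.nanmax(self.adhd_items) > 3:
            raise ValueError("item ratings must lie in [0, 3]")


def scale_score(items: np.ndarray, scale: slice) -> float:
    """Symptom-count scale score: number of items rated ≥ 2."""
    return float(np.sum(np.asarray(items)[scale] >= SYMPTOM_RATING))


@dataclass
class OutcomeLabel:
    endpoint_source: str  # "post" | "LOCF" | "baseline-only"
    att_reduction_pct: float
    hyp_reduction_pct: float
    item_mean: float
    remission: bool
    r50: bool
    r25: bool
    nr: bool
    do: bool

    @property
    def responder(self) -> bool:
        return self.r25

    @property
    def excluded(self) -> bool:
        return self.do


def apply_locf(record: SubjectRecord) -> tuple[np.ndarray, str]:
    """Endpoint item ratings and their source.

    Outtake when the subject completed assessments; otherwise the last
    available assessment (LOCF); intake-only subjects are flagged.
    """
    if record.adhd_items.shape[0] == 0:
        raise ValueError("record has no assessments")
    items = record.adhd_items[-1]
    if record.adhd_items.shape[0] == 1:
        return items, "baseline-only"
    complete = record.meta.get("outtake_present")
    if complete is None:
        # heuristic: the final row is outtake when its session index is
        # the subject's final session count
        complete = record.assessment_sessions[-1] >= record.sessions_taken
    return items, ("post" if complete else "LOCF")


def _reduction_pct(pre: float, post: float) -> float:
    if pre <= 0:
        return float("nan")  # undefined; caller flags
    return 100.0 * (pre - post) / pre


def classify_outcome(
    record: SubjectRecord,
    do_session_cutoff: int = DO_SESSION_CUTOFF,
    remission_item_mean: float = REMISSION_ITEM_MEAN,
) -> OutcomeLabel:
    """R25/R50/remission/DO/NR labels from baseline and LOCF endpoint."""
    baseline = record.adhd_items[0]
    endpoint, source = apply_locf(record)
    att_red = _reduction_pct(scale_score(baseline, ATT_SLICE), scale_score(endpoint, ATT_SLICE))
    hyp_red = _reduction_pct(scale_score(baseline, HYP_SLICE), scale_score(endpoint, HYP_SLICE))
    finite = [v for v in (att_red, hyp_red) if np.isfinite(v)]
    best = max(finite) if finite else float("nan")
    r25 = bool(best >= 25.0) if np.isfinite(best) else False
    r50 = bool(best >= 50.0) if np.isfinite(best) else False
    item_mean = float(np.mean(endpoint))
    remission = item_mean <= remission_item_mean
    do = record.sessions_taken <= do_session_cutoff and not r25
    nr = record.sessions_taken > do_session_cutoff and not r25
    return OutcomeLabel(
        endpoint_source=source,
        att_reduction_pct=att_red,
        hyp_reduction_pct=hyp_red,
        item_mean=item_mean,
        remission=remission,
        r50=r50,
        r25=r25,
        nr=nr,
        do=do,
    )


def cohens_d(m1: float, s1: float, m2: float, s2: float) -> float:
    """Cohen's d with the pooled-SD denominator √((s1² + s2²)/2)."""
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be non-negative")
    denom = np.sqrt((s1**2 + s2**2) / 2.0)
    if denom == 0:
        raise ValueError("both standard deviations are zero; d undefined")
    return float((m1 - m2) / denom)


def cohens_d_groups(x1: np.ndarray, x2: np.ndarray) -> float:
    """Cohen's d between two samples (same pooled-SD form, ddof=1)."""
    x1, x2 = np.asarray(x1, float), np.asarray(x2, float)
    return cohens_d(x1.mean(), x1.std(ddof=1), x2.mean(), x2.std(ddof=1))


def pooled_rate(counts: list[tuple[int, int]]) -> float:
    """Pooled event percentage Σevents / Σn × 100, rounded to 1 dp."""
    ev = sum(e for e, _ in counts)
    n = sum(n for _, n in counts)
    if n <= 0 or any(ni <= 0 for _, ni in counts):
        raise ValueError("group sizes must be positive")
    return round(100.0 * ev / n, 1)


@dataclass
class StatResult:
    """One inferential statistic with its reference distribution facts."""

    statistic: float
    p: float
    df: float | tuple | None = None
    name: str = ""
    extra: dict = field(default_factory=dict)


def chisq_2x2(table: np.ndarray) -> StatResult:
    """Pearson chi-square on a 2x2 table, df = 1, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, dof, _ = spstats.chi2_contingency(table, correction=False)
    return StatResult(statistic=float(chi2), p=float(p), df=float(dof), name="chi2")
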