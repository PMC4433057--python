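"""Reliability and agreement statistics of the examination study.

The analysis layer mirrors the study's data analysis: the comparator per
(subject, rater, angle) is the mean of the five examination repetitions;
repeatability is the mean within-repetition standard deviation; inter-rater
reliability is the two-way mixed, average-measures intraclass correlation
ICC(3,k) with ICC ≥ 0.8 read as acceptable; inter-rater agreement uses
Bland–Altman mean differences and 95% limits of agreement with |MDiff| < 5°
read as an acceptable systematic difference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .catalog import Catalog

__all__ = [
    "ICC_ACCEPTABLE",
    "MDIFF_ACCEPTABLE_DEG",
    "LOA_MULTIPLIER",
    "RatingTable",
    "ICCResult",
    "BlandAltmanResult",
    "rep_mean_sd",
    "build_rating_table",
    "repeatability_table",
    "icc_3k",
    "bland_altman",
    "agreement_panel",
    "validity_flags",
]

ICC_ACCEPTABLE = 0.8
MDIFF_ACCEPTABLE_DEG = 5.0
LOA_MULTIPLIER = 1.96  # 95% limits of agreement


def rep_mean_sd(values) -> tuple[float, float]:
    """Sample mean and SD (n−1 denominator) of one subject's repetitions."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("at least two repetitions are required for a within-repetition SD")
    return float(v.mean()), float(v.std(ddof=1))


@dataclass
class RatingTable:
    """Subjects × raters matrix of per-subject repetition means for one
    examination angle; rows with any missing cell are dropped and counted."""

    angle_id: str
    source: str  # 'measurement' | 'examiner'
    values: np.ndarray  # (n_subjects, n_raters)
    subject_ids: list
    rater_ids: list
    n_dropped: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError("a rating table needs at least 2 subjects and 2 raters")
        if np.isnan(self.values).any():
            raise ValueError("rating table must not contain missing cells")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


def build_rating_table(
    sheet: pd.DataFrame, angle_id: str, source: str, value_col: str
) -> RatingTable:
    """Pivot a long sheet (subject, rater, angle_id, rep, value) into the
    subjects × raters matrix of repetition means for one angle."""
    sub = sheet[sheet["angle_id"] == angle_id]
    if sub.empty:
        raise KeyError(f"sheet holds no rows for angle {angle_id!r}")
    means = (
        sub.groupby(["subject", "rater"])[value_col].mean().unstack("rater")
    )
    complete = means.dropna(axis=0, how="any")
    return RatingTable(
        angle_id=angle_id,
        source=source,
        values=complete.to_numpy(),
        subject_ids=list(complete.index),
        rater_ids=list(complete.columns),
        n_dropped=len(means) - len(complete),
    )


def repeatability_table(
    sheets: dict[str, tuple[pd.DataFrame, str]], catalog: Catalog | None = None
) -> pd.DataFrame:
    """Mean within-repetition SD per examination family and source.

    ``sheets`` maps a source name to ``(long sheet, value column)``.  The SD
    is computed per (subject, rater, angle) over the repetitions and averaged
    over subjects, raters and — when a catalog is given — the left/right
    members of the examination family, mirroring the published layout.
    Returns a tidy frame ``family (or angle_id), source, mean_sd_deg``.
    """
    rows = []
    for source, (sheet, col) in sheets.items():
        sds = sheet.groupby(["subject", "rater", "angle_id"])[col].std(ddof=1)
        if sds.isna().any():
            raise ValueError("every (subject, rater, angle) needs >= 2 repetitions")
        per_angle = sds.groupby("angle_id").mean()
        if catalog is None:
            for aid, val in per_angle.items():
                rows.append((aid, source, float(val)))
        else:
            fam = pd.Series(
                {aid: catalog.lookup(aid).family for aid in per_angle.index}
            )
            per_family = per_angle.groupby(fam).mean()
            for family, val in per_family.items():
                rows.append((family, source, float(val)))
    key = "angle_id" if catalog is None else "family"
    return pd.DataFrame(rows, columns=[key, "source", "mean_sd_deg"])


@dataclass
class ICCResult:
    angle_id: str
    source: str
    icc_3k: float
    bms: float  # between-subject mean square
    jms: float  # between-rater mean square
    ems: float  # residual mean square
    n: int
    k: int
    acceptable: bool
    undefined: bool = False


def icc_3k(table: RatingTable) -> ICCResult:
    """Two-way mixed, average-measures intraclass correlation.

    From the two-way ANOVA of the n × k matrix: ICC(3,k) = (BMS − EMS)/BMS
    where BMS is the between-subject and EMS the residual mean square.
    Negative estimates are reported as computed; with zero between-subject
    variance the coefficient is undefined and returned as NaN with a flag.
    """
    x = table.values
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    bms = k * float(((row_means - grand) ** 2).sum()) / (n - 1)
    jms = n * float(((col_means - grand) ** 2).sum()) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ems = float((resid**2).sum()) / ((n - 1) * (k - 1))
    if bms <= 0:
        return ICCResult(
            table.angle_id, table.source, float("nan"), bms, jms, ems, n, k,
            acceptable=False, undefined=True,
        )
    icc = (bms - ems) / bms
    return ICCResult(
        table.angle_id, table.source, float(icc), bms, jms, ems, n, k,
        acceptable=bool(icc >= ICC_ACCEPTABLE),
    )


@dataclass
class BlandAltmanResult:
    angle_id: str
    rater_pair: tuple
    mdiff: float  # mean of (a − b)
    sd_diff: float  # SD of differences, n−1
    loa_low: float
    loa_high: float
    points: pd.DataFrame = field(repr=False)  # subject, mean_deg, diff_deg
    mdiff_acceptable: bool = False


def _bland_altman_from_columns(
    angle_id: str, pair: tuple, a: np.ndarray, b: np.ndarray, subjects
) -> BlandAltmanResult:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diffs = a - b
    means = 0.5 * (a + b)
    mdiff = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0
    points = pd.DataFrame({"subject": subjects, "mean_deg": means, "diff_deg": diffs})
    return BlandAltmanResult(
        angle_id=angle_id,
        rater_pair=pair,
        mdiff=mdiff,
        sd_diff=sd,
        loa_low=mdiff - LOA_MULTIPLIER * sd,
        loa_high=mdiff + LOA_MULTIPLIER * sd,
        points=points,
        mdiff_acceptable=bool(abs(mdiff) < MDIFF_ACCEPTABLE_DEG),
    )


def bland_altman(table: RatingTable, pair: tuple) -> BlandAltmanResult:
    """Bland–Altman agreement of two raters of one table.

    The difference direction is first-listed minus second-listed; limits of
    agreement are MDiff ± 1.96·SD of the per-subject differences; the
    acceptance flag applies the strict |MDiff| < 5° rule.
    """
    try:
        ia = table.rater_ids.index(pair[0])
        ib = table.rater_ids.index(pair[1])
    except ValueError as exc:
        raise KeyError(f"rater pair {pair!r} not present in table {table.angle_id}") from exc
    return _bland_altman_from_columns(
        table.angle_id, tuple(pair), table.values[:, ia], table.values[:, ib], table.subject_ids
    )


def agreement_panel(
    measurement: RatingTable, examiner: RatingTable
) -> list[BlandAltmanResult]:
    """The study's 3×3 agreement panel (general in k).

    Row 1: each examiner against their own measurement result (examiner −
    measurement); row 2: every pair of measurement results; row 3: every pair
    of examiner ratings.  For k raters that is k + C(k,2) + C(k,2)
    comparisons (9 for k = 3), in this order.
    """
    if measurement.k != examiner.k:
        raise ValueError("measurement and examiner tables must share the rater set")
    if list(measurement.subject_ids) != list(examiner.subject_ids):
        common = [s for s in measurement.subject_ids if s in set(examiner.subject_ids)]
        if len(common) < 2:
            raise ValueError("measurement and examiner tables share fewer than 2 subjects")
        mi = [list(measurement.subject_ids).index(s) for s in common]
        ei = [list(examiner.subject_ids).index(s) for s in common]
        m_vals, e_vals, subjects = measurement.values[mi], examiner.values[ei], common
    else:
        m_vals, e_vals, subjects = measurement.values, examiner.values, list(measurement.subject_ids)
    aid = measurement.angle_id
    panel: list[BlandAltmanResult] = []
    k = measurement.k
    for i in range(k):
        panel.append(
            _bland_altman_from_columns(
                aid,
                (f"Ex{i + 1}", f"Meas{i + 1}"),
                e_vals[:, i],
                m_vals[:, i],
                subjects,
            )
        )
    for i, j in itertools.combinations(range(k), 2):
        panel.append(
            _bland_altman_from_columns(
                aid, (f"Meas{i + 1}", f"Meas{j + 1}"), m_vals[:, i], m_vals[:, j], subjects
            )
        )
    for i, j in itertools.combinations(range(k), 2):
        panel.append(
            _bland_altman_from_columns(
                aid, (f"Ex{i + 1}", f"Ex{j + 1}"), e_vals[:, i], e_vals[:, j], subjects
            )
        )
    return panel


def _flag(mean: float, lo: float, hi: float) -> str:
    if mean < lo:
        return "below"
    if mean > hi:
        return "above"
    return "within"


def validity_flags(means: dict[str, float] | pd.Series, catalog: Catalog) -> pd.DataFrame:
    """Compare per-angle cohort means against both literature reference
    ranges; boundaries are inclusive ('within')."""
    rows = []
    for aid, mean in dict(means).items():
        exam = catalog.lookup(aid)
        rows.append(
            (
                aid,
                float(mean),
                _flag(mean, *exam.ref_range_1),
                _flag(mean, *exam.ref_range_2),
            )
        )
    return pd.DataFrame(rows, columns=["angle_id", "mean_deg", "flag_ref1", "flag_ref2"])
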