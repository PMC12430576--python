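"""Fiber-quality phenotype summaries, normality screening, and extreme-bulk construction.

In a bulked-segregant design the two DNA pools are built from families at the
tails of the phenotype distribution.  This module summarises per-family fiber
length (mm, upper-half mean length) and fiber strength (cN/tex), screens the
population for approximate normality (the quantitative-trait premise), and
assigns families to the superior (HC1) and inferior (HC2) bulks by strict
threshold rules on both traits jointly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: canonical phenotype table columns
LENGTH_COL = "fiber_length_mm"
STRENGTH_COL = "fiber_strength_cN_tex"
FAMILY_COL = "family_id"


@dataclass(frozen=True)
class TraitSummary:
    """Descriptive statistics for one trait across the population.

    ``skewness`` and ``excess_kurtosis`` are the adjusted Fisher-Pearson
    estimators with sample-size bias correction (the convention of mainstream
    statistics packages such as SPSS); they are ``None`` (and
    ``moments_defined`` is False) when the sample is constant or too small
    for the correction terms.
    """

    n: int
    mean: float
    sd: float
    cv_percent: float
    skewness: float | None
    excess_kurtosis: float | None
    maximum: float
    minimum: float
    value_range: float
    moments_defined: bool


@dataclass(frozen=True)
class BulkRule:
    """Threshold rules for bulk membership; strict inequalities, both traits.

    A family joins the superior bulk iff length > ``length_gt`` AND
    strength > ``strength_gt``; the inferior bulk iff length < ``length_lt``
    AND strength < ``strength_lt``.  The high thresholds must exceed the low
    ones so the two rules can never both hold.
    """

    length_gt: float
    strength_gt: float
    length_lt: float
    strength_lt: float

    def __post_init__(self) -> None:
        if not (self.length_gt > self.length_lt and self.strength_gt > self.strength_lt):
            raise ValueError(
                "bulk rules overlap: high thresholds must exceed low thresholds"
            )

    @classmethod
    def study_default(cls) -> "BulkRule":
        """Thresholds used to build the 20-family HC1 and 12-family HC2 pools."""
        return cls(length_gt=30.5, strength_gt=31.0, length_lt=29.5, strength_lt=30.0)


@dataclass(frozen=True)
class BulkAssignment:
    """Partition of the families into HC1 (superior), HC2 (inferior), rest."""

    high_ids: tuple[str, ...]
    low_ids: tuple[str, ...]
    unassigned_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if set(self.high_ids) & set(self.low_ids):
            raise ValueError("a family cannot belong to both bulks")


def summarize_trait(values) -> TraitSummary:
    """Descriptive statistics for one trait (mean, sd, CV%, shape, extremes).

    Parameters
    ----------
    values : array-like of float
        Per-family trait values; at least two finite values required.

    Notes
    -----
    sd is the sample standard deviation (n-1 denominator); CV% = 100*sd/mean.
    A constant sample yields sd = CV = 0 with shape moments flagged undefined
    rather than NaN.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if x.size < 2:
        raise ValueError(f"need at least 2 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("trait values must be finite")

    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    maximum = float(np.max(x))
    minimum = float(np.min(x))

    skew = float(stats.skew(x, bias=False)) if sd > 0 and x.size >= 3 else None
    kurt = (
        float(stats.kurtosis(x, fisher=True, bias=False))
        if sd > 0 and x.size >= 4
        else None
    )
    defined = skew is not None and kurt is not None

    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    return TraitSummary(
        n=int(x.size),
        mean=mean,
        sd=sd,
        cv_percent=cv,
        skewness=skew,
        excess_kurtosis=kurt,
        maximum=maximum,
        minimum=minimum,
        value_range=maximum - minimum,
        moments_defined=defined,
    )


def normality_screen(summary: TraitSummary) -> tuple[bool, list[str]]:
    """Heuristic normality screen: pass iff |skewness| < 1 and |kurtosis| < 1.

    This is the breeder's rule of thumb for declaring a trait approximately
    normal (hence quantitative), not a formal test.  Strict inequalities; a
    degenerate (constant) sample fails with reason ``"degenerate"``.
    """
    if not summary.moments_defined:
        return False, ["degenerate"]
    reasons = []
    if not abs(summary.skewness) < 1.0:
        reasons.append(f"|skewness| = {abs(summary.skewness):.3g} not < 1")
    if not abs(summary.excess_kurtosis) < 1.0:
        reasons.append(f"|kurtosis| = {abs(summary.excess_kurtosis):.3g} not < 1")
    return (not reasons), reasons


def select_bulks(table: pd.DataFrame, rule: BulkRule) -> BulkAssignment:
    """Assign families to extreme bulks by strict threshold rules on both traits.

    HC1 collects rows with length > ``rule.length_gt`` and strength >
    ``rule.strength_gt``; HC2 those with length < ``rule.length_lt`` and
    strength < ``rule.strength_lt``.  Everything else (including boundary
    values) is unassigned.  Emits a warning if either bulk is empty, since the
    downstream association scan needs both pools.
    """
    if table.empty:
        warnings.warn("empty phenotype table: both bulks are empty", stacklevel=2)
        return BulkAssignment((), (), ())
    fl = table[LENGTH_COL].to_numpy(float)
    fs = table[STRENGTH_COL].to_numpy(float)
    ids = table[FAMILY_COL].astype(str).to_numpy()
    hi = (fl > rule.length_gt) & (fs > rule.strength_gt)
    lo = (fl < rule.length_lt) & (fs < rule.strength_lt)
    rest = ~(hi | lo)
    if not hi.any():
        warnings.warn("superior bulk (HC1) is empty under the given rule", stacklevel=2)
    if not lo.any():
        warnings.warn("inferior bulk (HC2) is empty under the given rule", stacklevel=2)
    return BulkAssignment(tuple(ids[hi]), tuple(ids[lo]), tuple(ids[rest]))


def select_extreme_by_rank(
    table: pd.DataFrame, n_high: int, n_low: int
) -> BulkAssignment:
    """Fixed-size extreme bulks by rank on the combined standardized score.

    Families are scored by the sum of the z-scores of the two traits, then the
    top ``n_high`` form HC1 and the bottom ``n_low`` form HC2 (the sorted-list
    picking practitioners use when they want bulks of an exact size).  The two
    sets never overlap provided ``n_high + n_low <= len(table)``.
    """
    if n_high < 1 or n_low < 1:
        raise ValueError("bulk sizes must be >= 1")
    if n_high + n_low > len(table):
        raise ValueError("bulks larger than the population")
    score = np.zeros(len(table))
    for col in (LENGTH_COL, STRENGTH_COL):
        x = table[col].to_numpy(float)
        sd = x.std()
        score += (x - x.mean()) / (sd if sd > 0 else 1.0)
    order = np.argsort(score, kind="stable")
    ids = table[FAMILY_COL].astype(str).to_numpy()
    low = tuple(ids[order[:n_low]])
    high = tuple(ids[order[-n_high:]])
    rest = tuple(ids[order[n_low : len(table) - n_high]])
    return BulkAssignment(high, low, rest)


def summary_frame(summaries: dict[str, TraitSummary]) -> pd.DataFrame:
    """Tabulate trait summaries, one row per trait, in report column order."""
    rows = []
    for trait, s in summaries.items():
        rows.append(
            {
                "trait": trait,
                "mean": s.mean,
                "sd": s.sd,
                "cv_percent": s.cv_percent,
                "skewness": s.skewness if s.moments_defined else float("nan"),
                "kurtosis": s.excess_kurtosis if s.moments_defined else float("nan"),
                "maximum": s.maximum,
                "minimum": s.minimum,
                "range": s.value_range,
                "n": s.n,
            }
        )
    return pd.DataFrame(rows)


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype TSV with columns family_id, fiber_length_mm, fiber_strength_cN_tex."""
    df = pd.read_csv(path, sep="\t", dtype={FAMILY_COL: str})
    missing = {FAMILY_COL, LENGTH_COL, STRENGTH_COL} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df[FAMILY_COL].duplicated().any():
        raise ValueError("family_id values must be unique")
    return df


def write_phenotypes(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
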