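"""Test-retest repeatability statistics for paired measurements.

Two paired designs are supported: scan-rescan (repeat acquisition within one
visit, isolating technique error) and interval scans (repeat after weeks,
adding physiological variability).  For each measured quantity the layer
computes the Bland-Altman bias and limits of agreement, the within-subject
coefficient of variation by the root-mean-square method for duplicate
measurements (within-subject SD = |x1 - x2| / sqrt(2)), the group CoV as the
RMS of per-subject CoVs, and a Mann-Whitney comparison of CoV distributions
between the two designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "RepeatabilitySummary",
    "subject_cov",
    "group_cov",
    "bland_altman",
    "paired_mean_difference",
    "mann_whitney_u",
    "summarize_pairs",
    "load_paired_measurements",
    "bland_altman_plot",
]


@dataclass
class PairedMeasurements:
    """Same-quantity measurements from two occasions, paired by subject."""

    subject_ids: Sequence[str]
    x1: np.ndarray
    x2: np.ndarray
    quantity: str = ""
    occasions: tuple[str, str] = ("scan1", "scan2")

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float)
        self.x2 = np.asarray(self.x2, dtype=float)
        if not (len(self.subject_ids) == len(self.x1) == len(self.x2)):
            raise ValueError("subject_ids, x1 and x2 must have equal length")
        if len(self.x1) < 2:
            raise ValueError("at least 2 paired measurements are required")
        if np.any(~np.isfinite(self.x1)) or np.any(~np.isfinite(self.x2)):
            raise ValueError("missing or non-finite pairs are not allowed")

    @property
    def differences(self) -> np.ndarray:
        return self.x2 - self.x1

    @property
    def means(self) -> np.ndarray:
        return (self.x1 + self.x2) / 2.0

    def swapped(self) -> "PairedMeasurements":
        return PairedMeasurements(
            self.subject_ids, self.x2.copy(), self.x1.copy(), self.quantity,
            (self.occasions[1], self.occasions[0]),
        )


@dataclass
class RepeatabilitySummary:
    """Bias, limits of agreement, and CoV summaries for one quantity."""

    quantity: str
    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    per_subject_cov: np.ndarray = field(default_factory=lambda: np.array([]))
    group_cov: float = float("nan")


def subject_cov(x1: float, x2: float) -> float:
    """Within-subject CoV (%) of a duplicate measurement, RMS method.

    The within-subject SD of two measurements is |x1 - x2| / sqrt(2); the
    CoV divides it by the pair mean.  Undefined (error) for non-positive
    means.  Scale-invariant: rescaling both measurements leaves it unchanged.
    """
    mean = (x1 + x2) / 2.0
    if mean <= 0:
        raise ValueError("subject CoV is undefined for a non-positive pair mean")
    sd = abs(x1 - x2) / np.sqrt(2.0)
    return 100.0 * sd / mean


def group_cov(per_subject_covs: Sequence[float]) -> float:
    """Group CoV (%): root mean square of the per-subject CoVs."""
    c = np.asarray(per_subject_covs, dtype=float)
    if c.size == 0:
        raise ValueError("need at least one per-subject CoV")
    return float(np.sqrt(np.mean(c**2)))


def bland_altman(pairs: PairedMeasurements) -> RepeatabilitySummary:
    """Bias (mean of x2 - x1) and 95% limits of agreement.

    LoA = bias +/- 1.96 x SD of the differences (sample SD, n-1 denominator).
    The (mean, difference) points for plotting are available from the input
    via ``pairs.means`` / ``pairs.differences``.
    """
    d = pairs.differences
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return RepeatabilitySummary(
        quantity=pairs.quantity,
        n=len(d),
        bias=bias,
        sd_diff=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


def paired_mean_difference(
    pairs: PairedMeasurements,
    interval: str = "loa",
) -> tuple[float, float, float]:
    """Observed mean difference with a 95% interval.

    ``interval="loa"`` (default) returns the observed-difference interval
    bias +/- 1.96 SD(d), the construction matching the spread of individual
    differences; ``interval="ci"`` returns the confidence interval of the
    mean, bias +/- 1.96 SD(d)/sqrt(n).
    """
    s = bland_altman(pairs)
    if interval == "loa":
        return s.bias, s.loa_lower, s.loa_upper
    if interval == "ci":
        half = 1.96 * s.sd_diff / np.sqrt(s.n)
        return s.bias, s.bias - half, s.bias + half
    raise ValueError("interval must be 'loa' or 'ci'")


#: exact-enumeration limits for the U null distribution
_EXACT_MIN_N = 8
_EXACT_TOTAL = 20


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U statistic (for group_a) and two-sided p value.

    Uses the exact null distribution when ``min(n) <= 8``, ``n_a + n_b <=
    20`` and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity corrections.  The thresholds are
    fixed so results are reproducible across sample sizes.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = len(np.unique(pooled)) == len(pooled)
    exact = (
        min(a.size, b.size) <= _EXACT_MIN_N
        and a.size + b.size <= _EXACT_TOTAL
        and tie_free
    )
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def cov_per_subject(pairs: PairedMeasurements) -> np.ndarray:
    return np.array([subject_cov(a, b) for a, b in zip(pairs.x1, pairs.x2)])


def summarize_pairs(pairs: PairedMeasurements) -> RepeatabilitySummary:
    """Full repeatability summary: Bland-Altman fields plus CoVs."""
    s = bland_altman(pairs)
    covs = cov_per_subject(pairs)
    s.per_subject_cov = covs
    s.group_cov = group_cov(covs)
    return s


def summarize_designs(
    rescan: dict[str, PairedMeasurements],
    interval: dict[str, PairedMeasurements],
) -> pd.DataFrame:
    """Side-by-side summary of the two designs per quantity.

    One row per quantity: observed mean difference with its 95% interval and
    group CoV for each design, plus the Mann-Whitney p value comparing the
    per-subject CoV distributions between designs.
    """
    rows = []
    for q in rescan:
        sr = summarize_pairs(rescan[q])
        row = {
            "quantity": q,
            "rescan_mean_diff": sr.bias,
            "rescan_int_lower": sr.loa_lower,
            "rescan_int_upper": sr.loa_upper,
            "rescan_cov_pct": sr.group_cov,
        }
        if q in interval:
            si = summarize_pairs(interval[q])
            _, p = mann_whitney_u(sr.per_subject_cov, si.per_subject_cov)
            row.update(
                interval_mean_diff=si.bias,
                interval_int_lower=si.loa_lower,
                interval_int_upper=si.loa_upper,
                interval_cov_pct=si.group_cov,
                p_cov_between_designs=p,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def load_paired_measurements(path) -> dict[str, PairedMeasurements]:
    """Read long-format CSV (subject_id, occasion, quantity, value).

    Each quantity must have exactly two occasions per subject; subjects with
    missing pairs are dropped with a warning.
    """
    import warnings

    df = pd.read_csv(path)
    required = {"subject_id", "occasion", "quantity", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required)}")
    out = {}
    for q, grp in df.groupby("quantity"):
        occ = sorted(grp["occasion"].unique())
        if len(occ) != 2:
            raise ValueError(f"quantity {q!r} has {len(occ)} occasions; need 2")
        wide = grp.pivot_table(
            index="subject_id", columns="occasion", values="value"
        )
        complete = wide.dropna()
        if len(complete) < len(wide):
            warnings.warn(
                f"quantity {q!r}: dropped {len(wide) - len(complete)} subjects "
                "with missing pairs",
                stacklevel=2,
            )
        out[q] = PairedMeasurements(
            list(complete.index),
            complete[occ[0]].to_numpy(),
            complete[occ[1]].to_numpy(),
            quantity=str(q),
            occasions=(str(occ[0]), str(occ[1])),
        )
    return out


def bland_altman_plot(pairs: PairedMeasurements, ax=None):
    """Scatter of (pair mean, difference) with bias and LoA lines."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    s = bland_altman(pairs)
    ax.scatter(pairs.means, pairs.differences, s=18)
    ax.axhline(s.bias, color="k")
    for y in (s.loa_lower, s.loa_upper):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel(f"mean of occasions ({pairs.quantity})")
    ax.set_ylabel("difference (occasion 2 - occasion 1)")
    return ax
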