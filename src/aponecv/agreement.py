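"""Manual-vs-automated agreement statistics (intraclass correlation).

The automated counts are validated against manual counts of the same
fields by the intraclass correlation coefficient in its two-way
random-effects, absolute-agreement, average-measures form — ICC(A,k) in
McGraw & Wong's taxonomy, ICC(2,k) in Shrout & Fleiss's.  The two-way
layout (images x raters) is decomposed into row, column and error mean
squares; absolute agreement keeps the rater (column) variance in the
denominator, so a systematic counting bias lowers the coefficient where
a consistency-type ICC would not notice it.

    ICC(A,k) = (MSR - MSE) / (MSR + (MSC - MSE) / n)

95% confidence bounds use the F-based formulas of McGraw & Wong
(single-measure bounds mapped to average measures by Spearman-Brown);
the p-value comes from F = MSR/MSE with (n-1) and (n-1)(k-1) degrees of
freedom.

A paired manual/automated count table for six fields of HeLa cells
(three untreated controls, three after photodynamic treatment) ships
with the package and is reproduced by :func:`reproduce_validation`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PairedCounts",
    "AgreementResult",
    "icc_two_way",
    "difference_column",
    "load_validation_counts",
    "reproduce_validation",
    "round_half_up",
]

MEASURES = ("apoptotic", "necrotic", "viable")


@dataclass(frozen=True)
class PairedCounts:
    """Per-image counts from two raters (manual and automated)."""

    labels: tuple[str, ...]
    rater_a: tuple[int, ...]
    rater_b: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.rater_a) == len(self.rater_b)):
            raise ValueError("labels and both rater series must align")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 paired observations")
        if min(min(self.rater_a), min(self.rater_b)) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class AgreementResult:
    icc: float
    ci_low: float
    ci_high: float
    p_value: float
    model: str
    mean_squares: tuple[float, float, float]  # (MSR, MSC, MSE)


def round_half_up(x: float, decimals: int) -> float:
    """Decimal rounding with ties away from zero (0.0005 -> 0.001)."""
    factor = 10 ** decimals
    return float(np.floor(abs(x) * factor + 0.5) / factor * np.sign(x))


def _mean_squares(Y: np.ndarray) -> tuple[float, float, float]:
    """Row, column and error mean squares of a two-way layout."""
    n, k = Y.shape
    grand = Y.mean()
    ss_rows = k * ((Y.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((Y.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((Y - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return (ss_rows / (n - 1), ss_cols / (k - 1),
            ss_err / ((n - 1) * (k - 1)))


def icc_two_way(data: PairedCounts, alpha: float = 0.05) -> AgreementResult:
    """ICC, two-way random effects, absolute agreement, average of 2 raters.

    A table with zero total variance (both raters constant and equal) has
    agreement by construction; the ICC is defined as 1.0 with a degenerate
    [1, 1] confidence interval in that case.
    """
    Y = np.column_stack([data.rater_a, data.rater_b]).astype(float)
    n, k = Y.shape
    msr, msc, mse = _mean_squares(Y)

    denom = msr + (msc - mse) / n
    if denom <= 0:  # zero total variance
        return AgreementResult(icc=1.0, ci_low=1.0, ci_high=1.0,
                               p_value=np.nan,
                               model="two-way random, absolute agreement, "
                                     f"average of {k} raters",
                               mean_squares=(msr, msc, mse))
    icc_k = (msr - mse) / denom

    df1 = n - 1
    df2 = (n - 1) * (k - 1)
    if mse > 0:
        f_stat = msr / mse
        p = float(stats.f.sf(f_stat, df1, df2))
    else:
        p = 0.0

    # McGraw & Wong F-based bounds for the single-measure ICC(A,1),
    # Spearman-Brown-stepped up to average measures.
    icc_1 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse > 0 and not np.isclose(icc_1, 1.0):
        fj = msc / mse
        a = k * icc_1 * fj + n * (1 + (k - 1) * icc_1) - k * icc_1
        v = df2 * a ** 2 / (df1 * k ** 2 * icc_1 ** 2 * fj ** 2
                            + (n * (1 + (k - 1) * icc_1) - k * icc_1) ** 2)
        f_u = stats.f.ppf(1 - alpha / 2, df1, v)
        f_l = stats.f.ppf(1 - alpha / 2, v, df1)
        l1 = (n * (msr - f_u * mse)
              / (f_u * (k * msc + (k * n - k - n) * mse) + n * msr))
        u1 = (n * (f_l * msr - mse)
              / (k * msc + (k * n - k - n) * mse + n * f_l * msr))
        ci_low = l1 * k / (1 + l1 * (k - 1))
        ci_high = u1 * k / (1 + u1 * (k - 1))
    else:
        ci_low = ci_high = 1.0

    return AgreementResult(icc=float(icc_k), ci_low=float(ci_low),
                           ci_high=float(min(ci_high, 1.0)), p_value=p,
                           model="two-way random, absolute agreement, "
                                 f"average of {k} raters",
                           mean_squares=(msr, msc, mse))


def difference_column(data: PairedCounts) -> tuple[int, ...]:
    """Per-image absolute manual-vs-automated differences (the DIF column)."""
    return tuple(abs(a - b) for a, b in zip(data.rater_a, data.rater_b))


def load_validation_counts() -> dict[str, PairedCounts]:
    """The packaged six-image manual/automated validation table.

    Returns one :class:`PairedCounts` per measure (apoptotic, necrotic,
    viable), images ordered controls first, then treated samples.
    """
    with resources.files("aponecv.data").joinpath(
            "validation_counts.csv").open() as fh:
        df = pd.read_csv(fh)
    out: dict[str, PairedCounts] = {}
    for measure in MEASURES:
        sub = df[df["measure"] == measure].sort_values(
            ["condition", "image"])  # control < treatment, images 1..3
        labels = tuple(f"{c}-{i}" for c, i in zip(sub["condition"], sub["image"]))
        out[measure] = PairedCounts(labels=labels,
                                    rater_a=tuple(int(v) for v in sub["manual"]),
                                    rater_b=tuple(int(v) for v in sub["automated"]))
    return out


def reproduce_validation() -> dict[str, AgreementResult]:
    """ICC per measure on the packaged validation counts."""
    return {measure: icc_two_way(data)
            for measure, data in load_validation_counts().items()}
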