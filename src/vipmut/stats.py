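"""Correlation, inverse-polynomial regression and Fisher-z significance.

Two correlation measures are used between per-motif vIP values X and
normalized SBS frequencies Y:

* the Pearson linear coefficient r, and
* a non-linear coefficient: fit f(X) = a + b/X + c/X^2 + d/X^3 by least
  squares (linear in a..d) and take r_nonlinear = Pearson(f(X), Y).

Significance is assessed with the Fisher z-transformation z = atanh(r):
the statistic z * sqrt(n-3) is compared against the standard normal
(two-sided).  Differences between two correlations (the 5'-3' asymmetry
of Table-5 type) use the standard two-sample z statistic on the same
scale.  P-values are raw; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .frequencies import NormalizedFrequencyTable
from .vip_tables import StackVIPTable, motif_vip

__all__ = [
    "CorrelationResult",
    "NonlinearFit",
    "RegressionLine",
    "AsymmetryResult",
    "StatConfig",
    "pearson",
    "nonlinear_r",
    "slope",
    "fisher_z_pvalue",
    "fisher_z_confint",
    "correlation_difference_test",
    "vip_frequency_analysis",
    "asymmetry_analysis",
]


@dataclass(frozen=True)
class StatConfig:
    alpha: float = 0.05
    sidedness: str = "two-sided"

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0,1)")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    p: float
    method: str = "linear"
    exact: bool = False  # |r|=1 -> p reported as exactly 0


def _check_xy(x, y, min_n: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} points, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant variable")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a Fisher-z two-sided p-value."""
    x, y = _check_xy(x, y, 3)
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-15:
        return CorrelationResult(r=float(np.sign(r)), n=x.size, p=0.0, exact=True)
    p = fisher_z_pvalue(r, x.size) if x.size >= 4 else float("nan")
    return CorrelationResult(r=r, n=x.size, p=p)


@dataclass(frozen=True)
class NonlinearFit:
    a: float
    b: float
    c: float
    d: float
    r_nonlinear: float
    n: int

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return self.a + self.b / x + self.c / x**2 + self.d / x**3


def nonlinear_r(x: Sequence[float], y: Sequence[float]) -> NonlinearFit:
    """Least-squares fit of y = a + b/x + c/x^2 + d/x^3 and its r.

    The problem is linear in (a,b,c,d); the inverse-power basis columns
    are standardized before solving to control conditioning and the
    coefficients are back-transformed.  Duplicated x (rank-deficient
    basis) falls back to the minimum-norm solution.
    """
    x, y = _check_xy(x, y, 4)
    if np.any(x <= 0):
        raise ValueError("nonlinear fit requires strictly positive x")
    cols = [np.ones_like(x), 1.0 / x, 1.0 / x**2, 1.0 / x**3]
    basis = np.column_stack(cols)
    mu = basis.mean(axis=0)
    sd = basis.std(axis=0)
    sd[0] = 1.0  # intercept column untouched
    sd[sd == 0] = 1.0
    scaled = (basis - mu) / sd
    scaled[:, 0] = 1.0
    coef_s, _, rank, _ = np.linalg.lstsq(scaled, y, rcond=None)
    if rank < 4:
        import warnings

        warnings.warn("rank-deficient inverse-power basis; minimum-norm solution used")
    coef = np.zeros(4)
    coef[1:] = coef_s[1:] / sd[1:]
    coef[0] = coef_s[0] - float(np.dot(coef[1:], mu[1:]))
    fitted = basis @ coef
    if np.ptp(fitted) == 0:
        raise ValueError("nonlinear correlation undefined: fitted values constant")
    r = float(np.corrcoef(fitted, y)[0, 1])
    return NonlinearFit(*(float(c) for c in coef), r_nonlinear=min(1.0, r), n=x.size)


@dataclass(frozen=True)
class RegressionLine:
    slope: float
    intercept: float


def slope(x: Sequence[float], y: Sequence[float]) -> RegressionLine:
    """Ordinary least-squares regression line of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ValueError("slope undefined for constant x")
    res = sps.linregress(x, y)
    return RegressionLine(slope=float(res.slope), intercept=float(res.intercept))


def fisher_z_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for H0: rho=0 via z = atanh(r), stat = z*sqrt(n-3)."""
    if n < 4:
        raise ValueError("Fisher z test needs n >= 4")
    if abs(r) >= 1:
        return 0.0
    stat = np.arctanh(r) * np.sqrt(n - 3)
    return float(2.0 * sps.norm.sf(abs(stat)))


def fisher_z_confint(r: float, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Fisher-z confidence interval for a correlation coefficient."""
    if n < 4:
        raise ValueError("Fisher z interval needs n >= 4")
    z = np.arctanh(r)
    half = sps.norm.ppf(1 - alpha / 2) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlation_difference_test(
    r1: float, n1: int, r2: float, n2: int
) -> tuple[float, float]:
    """Two-sided z-test for the difference of two correlations.

    statistic = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
    """
    for r, n in ((r1, n1), (r2, n2)):
        if n < 4:
            raise ValueError("Fisher z test needs n >= 4")
        if abs(r) >= 1:
            raise ValueError("correlation difference undefined at |r| = 1")
    stat = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(stat), float(2.0 * sps.norm.sf(abs(stat)))


@dataclass(frozen=True)
class AsymmetryResult:
    """Difference of vIP-frequency correlations between 5'- and 3'-flank motifs."""

    region: str
    length: int
    r_forward: float  # X first: XN, XNN, XNNN (3' flank)
    r_reverse: float  # X last: NX, NNX, NNNX (5' flank)
    n: int
    p: float

    @property
    def diff(self) -> float:
        return self.r_forward - self.r_reverse


# ---------------------------------------------------------------------------
# table-level drivers


def _motif_xy(
    stack_table: StackVIPTable,
    table: NormalizedFrequencyTable,
    subset_base: str | None,
) -> tuple[np.ndarray, np.ndarray, int]:
    x_index = table.spec.x_index
    xs, ys = [], []
    for motif, ratio in table.ratios.items():
        if subset_base is not None and motif[x_index] != subset_base:
            continue
        xs.append(motif_vip(stack_table, motif))
        ys.append(ratio)
    return np.asarray(xs), np.asarray(ys), len(xs)


def vip_frequency_analysis(
    stack_table: StackVIPTable,
    freq_tables: Mapping[tuple[str, str], NormalizedFrequencyTable],
    subsets: Sequence[str | None] = (None, "G", "C", "A", "T"),
) -> pd.DataFrame:
    """Correlation matrix of vIP vs normalized frequency per region/pattern.

    ``freq_tables`` maps (region_or_group_label, pattern) to a
    NormalizedFrequencyTable.  For each table and each subset (All, or a
    fixed wild-type base at the X position) the linear r and its Fisher-z
    p, the non-linear r, and the regression slope are reported.  Rows
    with fewer than 4 usable motifs are emitted with computable=False.
    """
    rows = []
    for (label, pattern), table in freq_tables.items():
        for subset in subsets:
            x, y, n = _motif_xy(stack_table, table, subset)
            row = dict(
                region=label,
                pattern=pattern,
                subset="All" if subset is None else subset,
                n=n,
                r_linear=np.nan,
                p_linear=np.nan,
                r_nonlinear=np.nan,
                slope=np.nan,
                intercept=np.nan,
                computable=False,
            )
            if n >= 4 and np.ptp(x) > 0 and np.ptp(y) > 0:
                lin = pearson(x, y)
                line = slope(x, y)
                row.update(
                    r_linear=lin.r, p_linear=lin.p,
                    slope=line.slope, intercept=line.intercept,
                    computable=True,
                )
                try:
                    row["r_nonlinear"] = nonlinear_r(x, y).r_nonlinear
                except ValueError:
                    pass
            rows.append(row)
    return pd.DataFrame(rows)


ASYMMETRY_PAIRS = (("XN", "NX"), ("XNN", "NNX"), ("XNNN", "NNNX"))


def asymmetry_analysis(
    stack_table: StackVIPTable,
    freq_tables: Mapping[tuple[str, str], NormalizedFrequencyTable],
) -> list[AsymmetryResult]:
    """5'-3' asymmetry: r(XN..N) - r(N..NX) per region and motif length.

    ``freq_tables`` must contain both orientations for each region.  The
    p-value is a two-sample Fisher-z test on the correlation difference;
    both correlations share the same motif count n.
    """
    labels = sorted({label for (label, _pattern) in freq_tables})
    out: list[AsymmetryResult] = []
    for label in labels:
        for fwd, rev in ASYMMETRY_PAIRS:
            if (label, fwd) not in freq_tables or (label, rev) not in freq_tables:
                continue
            xf, yf, nf = _motif_xy(stack_table, freq_tables[(label, fwd)], None)
            xr, yr, nr = _motif_xy(stack_table, freq_tables[(label, rev)], None)
            rf = pearson(xf, yf)
            rr = pearson(xr, yr)
            _, p = correlation_difference_test(rf.r, nf, rr.r, nr)
            out.append(
                AsymmetryResult(
                    region=label, length=len(fwd),
                    r_forward=rf.r, r_reverse=rr.r, n=nf, p=p,
                )
            )
    return out
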