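"""Clone-by-glomerulus innervation matrix analytics.

Single-neuron clones chart which glomeruli one interneuron innervates in one
animal; stacking many clones gives a binary clones x glomeruli matrix. This
module provides the co-innervation correlation matrix with significance, the
Ward clustering leaf order used for heatmap display, per-glomerulus
innervation frequency (optionally against glomerular volume), and the
coupon-collector sample-size calculation that motivates how many clones to
induce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import t as t_dist

from .model import InputError

logger = logging.getLogger(__name__)

EULER_GAMMA = 0.5772156649015329


@dataclass
class InnervationMatrix:
    """Binary clones x glomeruli matrix."""

    values: pd.DataFrame  # index = clone ids, columns = glomerulus names

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise InputError("innervation matrix must be binary")
        if self.values.columns.duplicated().any():
            raise InputError("duplicate glomerulus names in innervation matrix")

    @property
    def n_clones(self) -> int:
        return len(self.values)

    @property
    def glomeruli(self) -> list[str]:
        return list(self.values.columns)

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t")

    @classmethod
    def from_csv(cls, path: str | Path) -> "InnervationMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class CorrelationResult:
    r: pd.DataFrame          # G x G Pearson matrix (NaN where undefined)
    p: pd.DataFrame          # two-sided p-values from the t transform
    n: int                   # rows used
    constant_columns: list[str]

    def pair(self, a: str, b: str) -> tuple[float, float]:
        return float(self.r.at[a, b]), float(self.p.at[a, b])


def pearson_p_value(r: float, n: int) -> float:
    """Two-sided p for product-moment r via t = r sqrt((n-2)/(1-r^2))."""
    if n < 3:
        raise InputError("p-value requires n >= 3")
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * t_dist.sf(abs(t), df=n - 2))


def innervation_correlations(matrix: InnervationMatrix,
                             holm: bool = False) -> CorrelationResult:
    """Pairwise Pearson correlation of glomerulus columns with p-values.

    Product-moment r per column pair; two-sided p from the t distribution
    with n-2 degrees of freedom. Constant columns yield undefined (NaN)
    entries, flagged rather than zero-filled. No multiplicity correction by
    default; ``holm=True`` applies a Holm step-down adjustment across the
    upper-triangle p-values.
    """
    df = matrix.values
    n = len(df)
    if n < 3:
        raise InputError("innervation_correlations requires at least 3 clones")
    cols = list(df.columns)
    x = df.to_numpy(float)
    sd = x.std(axis=0)
    constant = [c for c, s in zip(cols, sd) if s == 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[np.isin(cols, constant), :] = np.nan
    r[:, np.isin(cols, constant)] = np.nan
    np.fill_diagonal(r, [np.nan if c in constant else 1.0 for c in cols])

    p = np.full_like(r, np.nan)
    iu, ju = np.triu_indices(len(cols), k=1)
    for i, j in zip(iu, ju):
        if not np.isnan(r[i, j]):
            p[i, j] = p[j, i] = pearson_p_value(r[i, j], n)
    np.fill_diagonal(p, [np.nan if c in constant else 1.0 for c in cols])

    if holm:
        flat = [(i, j) for i, j in zip(iu, ju) if not np.isnan(p[i, j])]
        pvals = np.array([p[i, j] for i, j in flat])
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, k in enumerate(order):
            running = max(running, (m - rank) * pvals[k])
            adj[k] = min(running, 1.0)
        for (i, j), v in zip(flat, adj):
            p[i, j] = p[j, i] = v

    rdf = pd.DataFrame(r, index=cols, columns=cols)
    pdf = pd.DataFrame(p, index=cols, columns=cols)
    return CorrelationResult(rdf, pdf, n, constant)


def ward_order(matrix: InnervationMatrix, axis: str = "rows") -> list:
    """Leaf order from Ward (ward.D2-equivalent) clustering on Euclidean distance.

    ``axis`` selects ``"rows"`` (clones) or ``"columns"`` (glomeruli). A single
    item returns the identity order.
    """
    if axis == "rows":
        data = matrix.values.to_numpy(float)
        labels = list(matrix.values.index)
    elif axis == "columns":
        data = matrix.values.to_numpy(float).T
        labels = list(matrix.values.columns)
    else:
        raise InputError(f"axis must be rows or columns, got {axis!r}")
    if len(labels) < 2:
        return labels
    z = linkage(data, method="ward")
    return [labels[i] for i in leaves_list(z)]


def innervation_frequency(matrix: InnervationMatrix,
                          volumes: dict[str, float] | None = None):
    """Per-glomerulus innervation frequency, optionally vs glomerular volume.

    Frequency is the column mean. With ``volumes`` given (keyed by glomerulus
    name), also returns Pearson r and p between frequency and volume;
    glomeruli lacking a volume are excluded and logged.
    """
    freq = matrix.values.mean(axis=0)
    if volumes is None:
        return freq
    common = [g for g in freq.index if g in volumes]
    missing = sorted(set(freq.index) - set(common))
    if missing:
        logger.info("innervation_frequency: no volume for %s; excluded", missing)
    if len(common) < 3:
        raise InputError("frequency-volume correlation requires >= 3 glomeruli")
    f = freq[common].to_numpy()
    v = np.array([volumes[g] for g in common])
    if f.std() == 0 or v.std() == 0:
        return freq, float("nan"), float("nan")
    r = float(np.corrcoef(f, v)[0, 1])
    return freq, r, pearson_p_value(r, len(common))


@dataclass
class CouponCollectorResult:
    n_types: int
    expectation: float            # n * H_n
    quantile: float | None        # q requested, None in expectation mode
    sample_size: int | None       # min t with P(all collected by t) >= q
    asymptotic: float | None = None  # n (ln n + gamma + 1/(2n))


def coupon_probability(n_types: int, t: int) -> float:
    """P(all n types seen in t uniform draws), by inclusion-exclusion."""
    if t < n_types:
        return 0.0
    total = 0.0
    for k in range(n_types + 1):
        total += (-1) ** k * comb(n_types, k) * ((n_types - k) / n_types) ** t
    return float(min(max(total, 0.0), 1.0))


def coupon_collector(n_types: float, mode: str = "expectation",
                     q: float = 0.95) -> CouponCollectorResult:
    """Coupon-collector sampling design for ``n_types`` equally likely types.

    ``mode="expectation"`` returns E[T] = n * H_n (exact, for integer n) and
    the asymptotic form n (ln n + gamma + 1/(2n)), which is also defined for
    non-integer type counts (e.g. a mean cell count). ``mode="quantile"``
    additionally returns the smallest t with P(all collected by t) >= q.
    """
    if n_types < 1:
        raise InputError("n_types must be >= 1")
    asym = float(n_types * (np.log(n_types) + EULER_GAMMA + 1.0 / (2.0 * n_types)))
    n_int = int(round(n_types))
    harmonic = sum(1.0 / i for i in range(1, n_int + 1))
    expectation = n_int * harmonic
    if mode == "expectation":
        return CouponCollectorResult(n_int, expectation, None, None, asym)
    if mode != "quantile":
        raise InputError(f"mode must be expectation or quantile, got {mode!r}")
    if not (0.0 < q < 1.0):
        raise InputError(f"q must lie in (0, 1), got {q}")
    t = n_int
    while coupon_probability(n_int, t) < q:
        t += 1
    return CouponCollectorResult(n_int, expectation, q, t, asym)


def simulate_coupon_collector(n_types: int, n_runs: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo draws of T (draws needed to collect all types).

    Samples each run as the sum of the stage-wise geometric waiting times
    (the wait for the k-th new type is Geometric((n - k + 1)/n)), which is
    exact in distribution and independent of the closed-form expectation and
    the inclusion-exclusion probabilities it cross-checks.
    """
    total = np.zeros(n_runs, dtype=np.int64)
    for k in range(n_types):
        total += rng.geometric((n_types - k) / n_types, size=n_runs)
    return total
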