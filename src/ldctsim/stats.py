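"""Nonparametric statistics for the phantom and reader analyses.

Exact sign test, Mann-Whitney U (exact by enumeration for small samples,
normal approximation with tie correction otherwise) and unweighted Cohen's
kappa with the conventional agreement bands.  All three are implemented from
first principles so that the package's test suite can check them against
brute-force enumeration and against independent library implementations.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

__all__ = [
    "TestResult",
    "KappaResult",
    "sign_test",
    "mann_whitney",
    "cohen_kappa",
    "kappa_band",
    "EXACT_THRESHOLD",
]

#: Combined sample size up to which the Mann-Whitney p-value is computed by
#: exhaustive enumeration of group assignments.
EXACT_THRESHOLD = 12


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its two-sided p-value."""

    statistic: float
    p_value: float
    n_effective: int
    method_note: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        """Significance at the conventional 0.05 level."""
        return self.p_value <= 0.05


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its qualitative agreement band."""

    kappa: float
    band: str

    @property
    def defined(self) -> bool:
        return math.isfinite(self.kappa)


def _binom_pmf(n: int, k: int) -> float:
    return math.comb(n, k) * 0.5**n


def sign_test(a, b) -> TestResult:
    """Exact two-sided sign test on paired samples.

    Tied pairs are dropped; the p-value is the doubled smaller binomial tail
    (capped at 1) on the sign counts under the fair-coin null.  With all
    pairs tied the test is vacuous and p = 1 is returned with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("sign test requires two equal-length 1-D samples")
    diff = a - b
    n_pos = int(np.sum(diff > 0))
    n_neg = int(np.sum(diff < 0))
    n = n_pos + n_neg
    if n == 0:
        warnings.warn("all pairs tied; sign test is vacuous", stacklevel=2)
        return TestResult(0.0, 1.0, 0, "exact binomial; all pairs tied")
    k = min(n_pos, n_neg)
    tail = sum(_binom_pmf(n, i) for i in range(k + 1))
    p = min(1.0, 2.0 * tail)
    return TestResult(
        float(n_pos), p, n, f"exact binomial on {n} untied pairs ({n_pos}+ / {n_neg}-)"
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x from midranks of the pooled data."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For combined samples of at most ``EXACT_THRESHOLD`` observations the
    p-value is exact: every assignment of the pooled values into groups of
    the observed sizes is enumerated and the fraction with |U - n1*n2/2| at
    least as extreme as observed is reported (with midranks, so ties are
    handled consistently).  Larger samples use the normal approximation with
    the tie-corrected variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u_obs = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= EXACT_THRESHOLD:
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        total = 0
        extreme = 0
        d_obs = abs(u_obs - mu) - 1e-12
        for comb in itertools.combinations(idx, n1):
            rest = [i for i in idx if i not in comb]
            u = _u_statistic(pooled[list(comb)], pooled[rest])
            total += 1
            if abs(u - mu) >= d_obs:
                extreme += 1
        p = extreme / total
        note = f"exact enumeration of C({n1 + n2},{n1}) assignments"
    else:
        pooled = np.concatenate([x, y])
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
        var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var_u <= 0:
            warnings.warn("all observations tied; U test is vacuous", stacklevel=2)
            return TestResult(u_obs, 1.0, n, "normal approximation; all tied")
        z = (u_obs - mu) / math.sqrt(var_u)
        p = float(2.0 * norm.sf(abs(z)))
        note = "normal approximation with tie correction"
    return TestResult(float(u_obs), min(1.0, p), n1 + n2, note)


#: Agreement bands on the conventional kappa scale (upper edges, labels).
KAPPA_BANDS = (
    (0.0, "no agreement"),
    (0.2, "slight"),
    (0.4, "fair"),
    (0.6, "moderate"),
    (0.8, "substantial"),
    (1.0, "almost perfect"),
)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement label for a kappa value."""
    if not math.isfinite(kappa):
        return "undefined"
    if kappa <= 0.0:
        return "no agreement"
    for upper, label in KAPPA_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return label
    return "almost perfect"


def cohen_kappa(r1, r2) -> KappaResult:
    """Unweighted Cohen's kappa between two raters.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the raters' marginal category frequencies.  When both
    raters use a single identical category p_e = 1 and kappa is undefined
    (returned as NaN with band "undefined").
    """
    r1 = np.asarray(r1)
    r2 = np.asarray(r2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size == 0:
        raise ValueError("ratings must be two equal-length non-empty 1-D sequences")
    cats = np.union1d(r1, r2)
    i1 = np.searchsorted(cats, r1)
    i2 = np.searchsorted(cats, r2)
    k = len(cats)
    table = np.zeros((k, k))
    np.add.at(table, (i1, i2), 1)
    n = table.sum()
    p_o = np.trace(table) / n
    p_e = float(np.sum(table.sum(axis=1) * table.sum(axis=0)) / n**2)
    if p_e >= 1.0 - 1e-12:
        warnings.warn(
            "both raters used a single category; kappa undefined", stacklevel=2
        )
        return KappaResult(float("nan"), "undefined")
    kap = float((p_o - p_e) / (1.0 - p_e))
    return KappaResult(kap, kappa_band(kap))
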