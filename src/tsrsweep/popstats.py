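"""Population-genetic summary statistics and small tests.

Watterson's theta, nucleotide diversity pi, the diploid effective-size
estimator ``Ne = theta_W / (4 mu)``, and the continuity-corrected (Yates)
chi-squared test used for the shared-haplotype comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable2x2",
    "harmonic_number",
    "watterson_theta",
    "ne_from_theta",
    "nucleotide_diversity",
    "segregating_sites",
    "chi2_yates",
    "chi2_uncorrected",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 table of non-negative integer counts, rows = groups, cols = outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("table total must be > 0")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def marginals(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def harmonic_number(n: int) -> float:
    """a_n = sum_{i=1}^{n} 1/i (Watterson's correction factor uses a_{n-1})."""
    if n < 0:
        raise ValueError("n must be >= 0")
    return float(np.sum(1.0 / np.arange(1, n + 1)))


def watterson_theta(S: int, n: int, L: int = 1) -> float:
    """Watterson's estimator per site: ``theta_W = S / (a_{n-1} * L)``.

    Parameters
    ----------
    S : number of segregating sites
    n : number of sequences sampled
    L : number of sites surveyed
    """
    if n < 2:
        raise ValueError("need at least 2 sequences")
    if L < 1:
        raise ValueError("L must be >= 1")
    if S < 0:
        raise ValueError("S must be >= 0")
    return S / (harmonic_number(n - 1) * L)


def ne_from_theta(theta: float, mu: float) -> float:
    """Diploid effective population size ``Ne = theta / (4 mu)``."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    if theta < 0:
        raise ValueError("theta must be >= 0")
    return theta / (4.0 * mu)


def _as_matrix(sample) -> np.ndarray:
    mat = np.asarray(sample)
    if mat.ndim != 2:
        raise ValueError("sample must be a 2-D (n_sequences, L) matrix")
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    return mat


def segregating_sites(sample) -> int:
    """Number of polymorphic columns in an (n_sequences, L) allele matrix."""
    mat = _as_matrix(sample)
    return int(np.sum(np.any(mat != mat[0], axis=0)))


def nucleotide_diversity(sample) -> float:
    """Average pairwise difference per site over all sequence pairs.

    ``sample`` is an (n_sequences, L) matrix of allele states (any hashable
    dtype; columns are compared for inequality).
    """
    mat = _as_matrix(sample)
    n, L = mat.shape
    diff = 0.0
    # column-wise: sum over unordered pairs of mismatch indicators
    for col in range(L):
        _, counts = np.unique(mat[:, col], return_counts=True)
        same = np.sum(counts * (counts - 1)) / 2.0
        diff += n * (n - 1) / 2.0 - same
    return diff / (n * (n - 1) / 2.0) / L


def chi2_yates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Continuity-corrected (Yates) chi-squared test of independence.

    ``chi2 = N (|ad - bc| - N/2)^2 / [(a+b)(c+d)(a+c)(b+d)]``, clamped to 0
    when ``|ad - bc| <= N/2``; p is the upper tail of chi-squared with 1 df.
    """
    if any(m == 0 for m in table.marginals):
        raise ValueError("all marginals must be positive")
    n = table.total
    cross = abs(table.a * table.d - table.b * table.c)
    adj = max(cross - n / 2.0, 0.0)
    denom = np.prod([float(m) for m in table.marginals])
    statistic = n * adj * adj / denom
    p = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return float(statistic), p


def chi2_uncorrected(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-squared without continuity correction (exposed for
    comparison; the corrected form is the default elsewhere)."""
    if any(m == 0 for m in table.marginals):
        raise ValueError("all marginals must be positive")
    n = table.total
    cross = table.a * table.d - table.b * table.c
    denom = np.prod([float(m) for m in table.marginals])
    statistic = n * float(cross) ** 2 / denom
    p = float(stats.chi2.sf(statistic, df=1)) if statistic > 0 else 1.0
    return float(statistic), p
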