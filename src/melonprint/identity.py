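"""Pairwise fingerprint comparison between varieties.

Two varieties are compared locus by locus: a locus contributes a difference
iff both genotypes are observed and their unordered allele pairs differ.
Loci with a missing call in either variety are excluded from the pair's
compared-locus count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .genotypes import GenotypeMatrix


@dataclass
class DifferenceMatrix:
    """Per-pair differing-marker counts plus per-pair compared-locus counts."""

    varieties: list[str]
    differences: np.ndarray  # (n, n) int, symmetric, zero diagonal
    compared: np.ndarray  # (n, n) int, symmetric
    n_loci: int  # total panel size (fixed denominator)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.differences, index=self.varieties, columns=self.varieties
        )

    def pair_values(self) -> np.ndarray:
        """Strict upper triangle of the difference counts, row-major."""
        iu = np.triu_indices(len(self.varieties), k=1)
        return self.differences[iu]


def pairwise_differences(matrix: GenotypeMatrix) -> DifferenceMatrix:
    """Count differing markers (and compared loci) for every variety pair."""
    n = matrix.n_varieties
    if n < 2:
        raise ValueError("need at least 2 varieties")
    gid = matrix.genotype_ids()  # (n, m), -1 missing
    obs = gid >= 0
    diffs = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n - 1):
        both = obs[i] & obs[i + 1 :]
        ndiff = (both & (gid[i] != gid[i + 1 :])).sum(axis=1)
        ncomp = both.sum(axis=1)
        diffs[i, i + 1 :] = ndiff
        comp[i, i + 1 :] = ncomp
    diffs += diffs.T
    comp += comp.T
    np.fill_diagonal(comp, matrix.n_loci)
    return DifferenceMatrix(list(matrix.varieties), diffs, comp, matrix.n_loci)


def difference_distribution(
    dm: DifferenceMatrix, n_loci: int | None = None, bin_width: float = 10.0
) -> pd.DataFrame:
    """Histogram of per-pair percent difference over fixed-width bins.

    Percentage = differences / total panel loci x 100 (fixed denominator).
    Bins are half-open [lo, hi); the last bin is closed so 100% is counted.
    """
    total = n_loci if n_loci is not None else dm.n_loci
    pct = dm.pair_values() / total * 100.0
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(pct, bins=edges)  # numpy closes the last bin
    return pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "n_pairs": counts,
        }
    )


def marker_system_concordance(
    dm_ssr: DifferenceMatrix, dm_snp: DifferenceMatrix
) -> tuple[float, float, float]:
    """OLS of per-pair SNP differences on SSR differences: (slope, intercept, R^2)."""
    if dm_ssr.varieties != dm_snp.varieties:
        raise ValueError("difference matrices cover different variety sets")
    x = dm_ssr.pair_values().astype(float)
    y = dm_snp.pair_values().astype(float)
    if np.ptp(y) == 0 or np.ptp(x) == 0:
        # degenerate: a constant axis carries no linear signal
        slope = 0.0
        intercept = float(np.mean(y))
        return slope, intercept, 0.0
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def unresolved_pairs(
    dm: DifferenceMatrix, min_differences: int = 1
) -> list[tuple[str, str]]:
    """Variety pairs whose difference count falls below the resolution threshold."""
    n = len(dm.varieties)
    out = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            if dm.differences[i, j] < min_differences:
                out.append((dm.varieties[i], dm.varieties[j]))
    return out
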