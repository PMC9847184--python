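"""Minimal discriminating marker-set selection.

Variety certification asks for the smallest marker subset under which
(nearly) every variety has a unique multilocus genotype.  A marker resolves
a variety pair iff both genotypes are observed and differ; a pair with a
missing call at a marker is conservatively NOT resolved by it.  Finding the
smallest such subset is a set-cover problem; the greedy heuristic is the
workhorse, with exhaustive enumeration as a small-instance oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix, locus_stats


@dataclass
class CoreSetResult:
    selected: list[str]
    resolution_curve: list[dict] = field(repr=False)  # per step: rates after adding
    unresolved_pairs: list[tuple[str, str]] = field(default_factory=list)
    pair_rate: float = 0.0
    variety_rate: float = 0.0


def _pair_resolution_masks(matrix: GenotypeMatrix) -> np.ndarray:
    """Boolean (m, n_pairs): marker j resolves pair p (both observed, unequal)."""
    gid = matrix.genotype_ids()  # (n, m)
    n = matrix.n_varieties
    iu, ju = np.triu_indices(n, k=1)
    gi, gj = gid[iu], gid[ju]  # (n_pairs, m)
    return ((gi >= 0) & (gj >= 0) & (gi != gj)).T.copy()


def _rates(resolved: np.ndarray, n: int) -> tuple[float, float]:
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = resolved.size
    pair_rate = resolved.mean() if n_pairs else 1.0
    ok = np.ones(n, dtype=bool)
    bad = ~resolved
    ok[iu[bad]] = False
    ok[ju[bad]] = False
    return float(pair_rate), float(ok.mean())


def resolution_rate(matrix: GenotypeMatrix, subset: list[str]) -> tuple[float, float]:
    """(pair_rate, variety_rate) achieved by a marker subset.

    pair_rate: resolved pairs / all pairs.  variety_rate: fraction of
    varieties distinguishable from every other variety.
    """
    n = matrix.n_varieties
    if not subset:
        return 0.0, 0.0
    masks = _pair_resolution_masks(matrix)
    idx = [matrix.panel.index_of(m) for m in subset]
    resolved = masks[idx].any(axis=0)
    return _rates(resolved, n)


def greedy_core_set(
    matrix: GenotypeMatrix,
    *,
    stop_k: int | None = None,
    target_variety_rate: float | None = None,
    target_pair_rate: float | None = None,
) -> CoreSetResult:
    """Greedy forward selection of the marker resolving most unresolved pairs.

    Stops when no marker resolves any remaining pair, or when ``stop_k``
    markers are selected, or when a target rate is reached.  Ties between
    equally-resolving markers are broken by higher PIC, then lower missing
    rate, then panel order, making the selection deterministic.
    """
    n = matrix.n_varieties
    if n < 2:
        raise ValueError("need at least 2 varieties")
    masks = _pair_resolution_masks(matrix)  # (m, n_pairs)
    stats = locus_stats(matrix)
    pic_v = stats["pic"].fillna(0.0).to_numpy()
    miss_v = stats["missing_rate"].to_numpy()
    m = masks.shape[0]
    resolved = np.zeros(masks.shape[1], dtype=bool)
    selected: list[str] = []
    curve: list[dict] = []
    available = np.ones(m, dtype=bool)
    while True:
        gains = (masks & ~resolved).sum(axis=1)
        gains[~available] = 0
        best_gain = gains.max() if m else 0
        if best_gain == 0:
            break
        cand = np.flatnonzero(gains == best_gain)
        # tie-break: higher PIC, lower missing rate, panel order
        order = sorted(cand, key=lambda j: (-pic_v[j], miss_v[j], j))
        j = order[0]
        available[j] = False
        resolved |= masks[j]
        selected.append(matrix.panel.marker_ids[j])
        pr, vr = _rates(resolved, n)
        curve.append(
            {"n_markers": len(selected), "pair_rate": pr, "variety_rate": vr}
        )
        if stop_k is not None and len(selected) >= stop_k:
            break
        if target_variety_rate is not None and vr >= target_variety_rate:
            break
        if target_pair_rate is not None and pr >= target_pair_rate:
            break
    pr, vr = _rates(resolved, n) if selected else (0.0, 0.0)
    iu, ju = np.triu_indices(n, k=1)
    bad = ~resolved
    unresolved = [(matrix.varieties[i], matrix.varieties[j]) for i, j in zip(iu[bad], ju[bad])]
    return CoreSetResult(selected, curve, unresolved, pr, vr)


def exhaustive_core_set(matrix: GenotypeMatrix, max_panel: int = 15) -> list[str]:
    """Smallest marker subset resolving every resolvable pair, by enumeration.

    Subsets are enumerated in increasing size, lexicographic order within a
    size, so ties break to the lexicographically first subset of marker
    indices.  Intended as a verification oracle; refuses panels beyond
    ``max_panel`` markers.
    """
    from itertools import combinations

    m = matrix.n_loci
    if m > max_panel:
        raise ValueError(f"exhaustive search capped at {max_panel} markers")
    masks = _pair_resolution_masks(matrix)
    resolvable = masks.any(axis=0)
    ids = matrix.panel.marker_ids
    if not resolvable.any():
        return []
    for size in range(1, m + 1):
        for combo in combinations(range(m), size):
            covered = masks[list(combo)].any(axis=0)
            if np.array_equal(covered, resolvable):
                return [ids[j] for j in combo]
    return list(ids)
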