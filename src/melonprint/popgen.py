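"""Population-genetic analyses on variety fingerprints.

Implements Bruvo's microsatellite distance, neighbor-joining tree building,
a three-level analysis of molecular variance (among populations / among
individuals within populations / within individuals), multi-allelic
Weir-Cockerham Fst, and membership-threshold population labelling.

All analyses are diploid-only; missing genotypes are skipped locus-wise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import SSR, GenotypeMatrix

ADMIXED = "admixed"


# ---------------------------------------------------------------------------
# Bruvo distance
# ---------------------------------------------------------------------------

def _bruvo_step(x: float, y: float) -> float:
    return 1.0 - 2.0 ** (-abs(x - y))


def bruvo_locus_distance(g1, g2) -> float:
    """Bruvo distance between two diploid SSR genotypes in repeat units.

    Per allele pair d(x, y) = 1 - 2^(-|x - y|); the locus distance is the
    minimum over the two perfect matchings of the mean per-pair distance.
    """
    (a1, a2), (b1, b2) = g1, g2
    m1 = (_bruvo_step(a1, b1) + _bruvo_step(a2, b2)) / 2.0
    m2 = (_bruvo_step(a1, b2) + _bruvo_step(a2, b1)) / 2.0
    return min(m1, m2)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def bruvo_matrix(matrix: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-locus Bruvo distance between every variety pair.

    SSR loci use repeat-number separation.  SNP loci contribute through the
    same formula with alleles treated as unit-separated states, so a shared
    allele pair costs 0, one differing allele 0.5x2^0... i.e. per best
    pairing each mismatching allele adds 0.5.  Loci missing in either variety
    are excluded from that pair's mean.
    """
    n = matrix.n_varieties
    m = matrix.n_loci
    # per-locus allele values: SSR -> repeat number; SNP -> allele code where
    # any two distinct codes are "one step" apart
    is_ssr = np.array([mk.type == SSR for mk in matrix.panel])
    vals = np.full((n, m, 2), np.nan)
    for j in range(m):
        table = matrix.allele_tables[j]
        for i in range(n):
            a, b = matrix.codes[i, j]
            if a < 0:
                continue
            if is_ssr[j]:
                vals[i, j, 0] = float(table[a])
                vals[i, j, 1] = float(table[b])
            else:
                vals[i, j, 0] = float(a)
                vals[i, j, 1] = float(b)
    out = np.zeros((n, n))

    def step(delta: np.ndarray, ssr_mask: np.ndarray) -> np.ndarray:
        d = 1.0 - 2.0 ** (-np.abs(delta))
        # SNP states: any difference is a single step
        snp = ~ssr_mask
        d[snp] = np.where(np.abs(delta[snp]) > 0, 0.5, 0.0)
        return d

    for i in range(n - 1):
        a1, a2 = vals[i, :, 0], vals[i, :, 1]
        b1, b2 = vals[i + 1 :, :, 0], vals[i + 1 :, :, 1]
        ssr_mask = np.broadcast_to(is_ssr, b1.shape)
        m1 = (step(a1 - b1, ssr_mask) + step(a2 - b2, ssr_mask)) / 2.0
        m2 = (step(a1 - b2, ssr_mask) + step(a2 - b1, ssr_mask)) / 2.0
        loc = np.minimum(m1, m2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(loc, axis=1)
        mean = np.nan_to_num(mean)
        out[i, i + 1 :] = mean
    out += out.T
    return DistanceMatrix(list(matrix.varieties), out)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list = field(default_factory=list)  # (TreeNode, branch_length)

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name or ""
        inner = ",".join(f"{c._nwk()}:{bl:.10g}" for c, bl in self.children)
        return f"({inner})" + (self.name or "")

    def leaf_names(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaf_names())
        return out

    def leaf_distances(self) -> pd.DataFrame:
        """Patristic (path-length) distances between all leaf pairs."""
        names = self.leaf_names()
        d = pd.DataFrame(0.0, index=names, columns=names)

        # distance via recursive merge: for each internal node, leaves in
        # different child subtrees are connected through it
        def collect(node: TreeNode, depth: float) -> dict[str, float]:
            if not node.children:
                return {node.name: depth}
            subs = [collect(c, bl) for c, bl in node.children]
            for x in range(len(subs)):
                for y in range(x + 1, len(subs)):
                    for la, da in subs[x].items():
                        for lb, db in subs[y].items():
                            d.loc[la, lb] = d.loc[lb, la] = da + db
            merged: dict[str, float] = {}
            for s in subs:
                for k, v in s.items():
                    merged[k] = v + depth
            return merged

        collect(self, 0.0)
        return d


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining with deterministic tie-breaks.

    The pair minimizing the Q criterion is joined; ties go to the smallest
    (i, j) node-creation-index pair.  Negative branch lengths are clamped to
    zero with the deficit moved to the sister branch.  Returns the unrooted
    tree as a trifurcating root node.
    """
    n0 = len(dm.labels)
    if n0 < 2:
        raise ValueError("need at least 2 taxa")
    if n0 == 2:
        d = float(dm.values[0, 1])
        root = TreeNode()
        root.children = [
            (TreeNode(dm.labels[0]), d / 2.0),
            (TreeNode(dm.labels[1]), d / 2.0),
        ]
        return root
    D = dm.values.astype(float).copy()
    nodes = [TreeNode(lbl) for lbl in dm.labels]
    order = list(range(n0))  # creation indices of active nodes
    active = list(range(n0))  # positions into D rows

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return li, max(lj, 0.0)

    next_index = n0
    while len(active) > 3:
        r = len(active)
        sub = D[np.ix_(active, active)]
        sums = sub.sum(axis=1)
        q = (r - 2) * sub - sums[:, None] - sums[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(np.isclose(q, qmin, rtol=0, atol=1e-12))
        cand = [(a, b) for a, b in cand if a < b]
        # deterministic: smallest creation-index pair
        a, b = min(cand, key=lambda ab: (order[ab[0]], order[ab[1]]))
        i, j = active[a], active[b]
        dij = D[i, j]
        li = dij / 2.0 + (sums[a] - sums[b]) / (2.0 * (r - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode()
        parent.children = [(nodes[i], li), (nodes[j], lj)]
        # distances from new node to the rest
        new_row = np.zeros(D.shape[0] + 1)
        for c_pos, k in enumerate(active):
            if k in (i, j):
                continue
            new_row[k] = (D[i, k] + D[j, k] - dij) / 2.0
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = new_row[:-1]
        D[:-1, -1] = new_row[:-1]
        nodes.append(parent)
        pos_new = D.shape[0] - 1
        keep = [p for p in active if p not in (i, j)]
        ords = [order[active.index(p)] for p in keep]
        active = keep + [pos_new]
        order = ords + [next_index]
        next_index += 1
    root = TreeNode()
    if len(active) == 3:
        i, j, k = active
        dij, dik, djk = D[i, j], D[i, k], D[j, k]
        li = (dij + dik - djk) / 2.0
        lj = (dij + djk - dik) / 2.0
        lk = (dik + djk - dij) / 2.0
        branches = [[nodes[i], li], [nodes[j], lj], [nodes[k], lk]]
        # clamp negatives, deficit to the longest sibling
        for b in branches:
            if b[1] < 0:
                longest = max(branches, key=lambda x: x[1])
                longest[1] += b[1]
                b[1] = 0.0
        root.children = [(nd, max(bl, 0.0)) for nd, bl in branches]
    else:  # 2 remain (n0 == 3 handled above; defensive)
        i, j = active
        root.children = [(nodes[i], D[i, j] / 2.0), (nodes[j], D[i, j] / 2.0)]
    return root


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    table: pd.DataFrame  # rows: among_populations, among_individuals, within_individuals, total
    components: dict
    phi: dict
    negative_components: list[str]

    @property
    def percentages(self) -> dict:
        return dict(zip(self.table.index[:-1], self.table["percentage"][:-1]))


def _clean_labels(matrix: GenotypeMatrix, labels) -> tuple[list[int], list[str]]:
    if isinstance(labels, dict):
        lab = [labels.get(v) for v in matrix.varieties]
    else:
        lab = list(labels)
    idx, kept = [], []
    for i, l in enumerate(lab):
        if l is None or l == ADMIXED:
            continue
        idx.append(i)
        kept.append(str(l))
    # drop singleton populations
    counts = pd.Series(kept).value_counts()
    single = set(counts.index[counts < 2])
    if single:
        warnings.warn(f"excluding singleton populations: {sorted(single)}")
        pairs = [(i, l) for i, l in zip(idx, kept) if l not in single]
        idx = [i for i, _ in pairs]
        kept = [l for _, l in pairs]
    return idx, kept


def amova(matrix: GenotypeMatrix, labels) -> AmovaResult:
    """Three-level AMOVA from allele-mismatch distances, locus by locus.

    Strata: among populations / among individuals within populations /
    within individuals.  Sums of squared distances use the standard
    squared-deviation identities for a 0/1 allele mismatch metric; variance
    components come from the mean squares and the unbalanced-design
    coefficient n_c computed on allele counts.
    """
    idx, labs = _clean_labels(matrix, labels)
    pops = sorted(set(labs))
    k = len(pops)
    if k < 2:
        raise ValueError("AMOVA needs >= 2 populations of size >= 2")
    n = len(idx)
    pop_of = np.array([pops.index(l) for l in labs])
    ssd_ap = ssd_ai = ssd_wi = 0.0
    for j in range(matrix.n_loci):
        codes = matrix.codes[idx, j, :]  # (n, 2)
        obs = codes[:, 0] >= 0
        if obs.sum() < 2:
            continue
        a = codes[obs]
        po = pop_of[obs]
        # within individuals
        wi = 0.5 * np.sum(a[:, 0] != a[:, 1])
        # pooled and per-pop allele counts
        alleles = a.ravel()
        pool_counts = np.bincount(alleles)
        N = alleles.size
        ssd_t_loc = (N * N - np.sum(pool_counts.astype(float) ** 2)) / (2.0 * N)
        wp = 0.0
        for p in range(k):
            al = a[po == p].ravel()
            if al.size == 0:
                continue
            c = np.bincount(al)
            wp += (al.size**2 - np.sum(c.astype(float) ** 2)) / (2.0 * al.size)
        ssd_wi += wi
        ssd_ai += wp - wi
        ssd_ap += ssd_t_loc - wp
    df_ap = k - 1
    df_ai = n - k
    df_wi = n
    ms_ap = ssd_ap / df_ap
    ms_ai = ssd_ai / df_ai if df_ai else float("nan")
    ms_wi = ssd_wi / df_wi
    pop_sizes = np.bincount(pop_of, minlength=k)
    allele_sizes = 2.0 * pop_sizes
    n_tot = allele_sizes.sum()
    n_c = (n_tot - np.sum(allele_sizes**2) / n_tot) / (k - 1)
    sigma_wi = ms_wi
    sigma_ai = (ms_ai - ms_wi) / 2.0
    sigma_ap = (ms_ap - ms_ai) / n_c
    comps = {
        "among_populations": sigma_ap,
        "among_individuals": sigma_ai,
        "within_individuals": sigma_wi,
    }
    negative = [kk for kk, v in comps.items() if v < 0]
    total = sum(comps.values())
    pct = {kk: 100.0 * v / total for kk, v in comps.items()}
    def _ratio(num: float, den: float) -> float:
        return num / den if den else float("nan")

    phi = {
        "Phi_ST": _ratio(sigma_ap, total),
        "Phi_IS": _ratio(sigma_ai, sigma_ai + sigma_wi),
        "Phi_IT": _ratio(sigma_ap + sigma_ai, total),
    }
    table = pd.DataFrame(
        {
            "df": [df_ap, df_ai, df_wi, df_ap + df_ai + df_wi],
            "sum_sq": [ssd_ap, ssd_ai, ssd_wi, ssd_ap + ssd_ai + ssd_wi],
            "mean_sq": [ms_ap, ms_ai, ms_wi, float("nan")],
            "variance_component": [sigma_ap, sigma_ai, sigma_wi, total],
            "percentage": [
                pct["among_populations"],
                pct["among_individuals"],
                pct["within_individuals"],
                100.0,
            ],
        },
        index=[
            "among_populations",
            "among_individuals_within_populations",
            "within_individuals",
            "total",
        ],
    )
    return AmovaResult(table, comps, phi, negative)


# ---------------------------------------------------------------------------
# Weir-Cockerham Fst
# ---------------------------------------------------------------------------

def _wc_components(matrix: GenotypeMatrix, idx_by_pop: list[np.ndarray]):
    """Per-locus, per-allele Weir-Cockerham a, b, c sums over two or more pops."""
    r = len(idx_by_pop)
    A = B = C = 0.0
    for j in range(matrix.n_loci):
        table_len = len(matrix.allele_tables[j])
        if table_len < 2:
            continue
        ns, ps, hs = [], [], []
        for idx in idx_by_pop:
            codes = matrix.codes[idx, j, :]
            obs = codes[:, 0] >= 0
            a = codes[obs]
            ni = a.shape[0]
            if ni == 0:
                ns.append(0)
                ps.append(np.zeros(table_len))
                hs.append(np.zeros(table_len))
                continue
            counts = np.bincount(a.ravel(), minlength=table_len).astype(float)
            freq = counts / (2 * ni)
            # h_i(A): proportion of individuals heterozygous for allele A
            het_mask = a[:, 0] != a[:, 1]
            het = np.zeros(table_len)
            for x, y in a[het_mask]:
                het[x] += 1
                het[y] += 1
            het /= ni
            ns.append(ni)
            ps.append(freq)
            hs.append(het)
        ns_arr = np.array(ns, dtype=float)
        if np.sum(ns_arr > 0) < 2 or np.any(ns_arr < 1):
            continue
        nbar = ns_arr.mean()
        if nbar <= 1:
            continue
        nc = (r * nbar - np.sum(ns_arr**2) / (r * nbar)) / (r - 1)
        P = np.vstack(ps)  # (r, n_alleles)
        H = np.vstack(hs)
        pbar = np.sum(ns_arr[:, None] * P, axis=0) / (r * nbar)
        s2 = np.sum(ns_arr[:, None] * (P - pbar[None, :]) ** 2, axis=0) / (
            (r - 1) * nbar
        )
        hbar = np.sum(ns_arr[:, None] * H, axis=0) / (r * nbar)
        a_c = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        b_c = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c_c = hbar / 2.0
        A += a_c.sum()
        B += b_c.sum()
        C += c_c.sum()
    return A, B, C


def wc_theta(matrix: GenotypeMatrix, labels, pop_a: str, pop_b: str) -> float:
    """Multi-allelic Weir-Cockerham theta between two populations
    (ratio-of-sums over loci and alleles)."""
    if isinstance(labels, dict):
        lab = [labels.get(v) for v in matrix.varieties]
    else:
        lab = list(labels)
    ia = np.array([i for i, l in enumerate(lab) if l == pop_a])
    ib = np.array([i for i, l in enumerate(lab) if l == pop_b])
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each population needs >= 2 samples")
    A, B, C = _wc_components(matrix, [ia, ib])
    denom = A + B + C
    return float(A / denom) if denom else 0.0


def pairwise_fst(matrix: GenotypeMatrix, labels) -> pd.DataFrame:
    """Pairwise Weir-Cockerham theta between all labelled populations."""
    idx, labs = _clean_labels(matrix, labels)
    lab_aligned = [None] * matrix.n_varieties
    for i, l in zip(idx, labs):
        lab_aligned[i] = l
    pops = sorted(set(labs))
    out = pd.DataFrame(0.0, index=pops, columns=pops)
    for x in range(len(pops)):
        for y in range(x + 1, len(pops)):
            t = wc_theta(matrix, lab_aligned, pops[x], pops[y])
            out.iloc[x, y] = out.iloc[y, x] = t
    return out


# ---------------------------------------------------------------------------
# Membership classification
# ---------------------------------------------------------------------------

def classify_membership(q: pd.DataFrame, threshold: float = 0.7) -> pd.Series:
    """Assign each variety its argmax population if membership >= threshold,
    else "admixed".  Rows of ``q`` must sum to 1 (+-0.01)."""
    sums = q.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=0.01):
        bad = q.index[~np.isclose(sums, 1.0, atol=0.01)].tolist()
        raise ValueError(f"Q rows do not sum to 1: {bad[:5]}")
    best = q.idxmax(axis=1)
    best_val = q.max(axis=1)
    labels = best.where(best_val >= threshold, ADMIXED)
    labels.name = "population"
    return labels
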