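"""Bruvo distance, neighbor joining, AMOVA, Fst and membership labelling."""

import numpy as np
import pandas as pd
import pytest

from melonprint import (
    DistanceMatrix,
    amova,
    bruvo_locus_distance,
    bruvo_matrix,
    classify_membership,
    nj_tree,
    pairwise_fst,
    wc_theta,
)
from melonprint.simulate import SimConfig, simulate_frequencies, simulate_genotypes

from conftest import make_matrix, random_matrix


class TestBruvoLocus:
    def test_identical_genotypes(self):
        assert bruvo_locus_distance((10, 10), (10, 10)) == 0.0

    def test_single_repeat_shift(self):
        assert bruvo_locus_distance((10, 10), (11, 11)) == pytest.approx(0.5)

    def test_matching_minimization(self):
        # matchings: {(10,11),(12,12)} -> (0.5+0)/2 = 0.25
        #            {(10,12),(12,11)} -> (0.75+0.5)/2 = 0.625
        assert bruvo_locus_distance((10, 12), (11, 12)) == pytest.approx(0.25)

    def test_symmetry_bounds_translation_invariance(self):
        rng = np.random.default_rng(30)
        for _ in range(200):
            g1 = tuple(sorted(rng.integers(5, 30, size=2).tolist()))
            g2 = tuple(sorted(rng.integers(5, 30, size=2).tolist()))
            d = bruvo_locus_distance(g1, g2)
            assert d == pytest.approx(bruvo_locus_distance(g2, g1))
            assert 0.0 <= d <= 1.0
            if g1 == g2:
                assert d == 0.0
            shift = int(rng.integers(1, 10))
            g1s = tuple(a + shift for a in g1)
            g2s = tuple(a + shift for a in g2)
            assert bruvo_locus_distance(g1s, g2s) == pytest.approx(d)


class TestBruvoMatrix:
    def test_identical_matrices_zero(self):
        rows = [[(10, 12), (8, 8)], [(10, 12), (8, 8)]]
        dm = bruvo_matrix(make_matrix(rows))
        assert np.allclose(dm.values, 0.0)

    def test_single_locus_equals_locus_distance(self):
        m = make_matrix([[(10, 12)], [(11, 12)]])
        dm = bruvo_matrix(m)
        assert dm.values[0, 1] == pytest.approx(bruvo_locus_distance((10, 12), (11, 12)))

    def test_snp_loci_contribute_mismatch_distance(self):
        m = make_matrix([[("A", "A")], [("A", "T")]])
        assert bruvo_matrix(m).values[0, 1] == pytest.approx(0.25)
        m2 = make_matrix([[("A", "A")], [("T", "T")]])
        assert bruvo_matrix(m2).values[0, 1] == pytest.approx(0.5)

    def test_fixture_matches_per_locus_averaging_oracle(self):
        rng = np.random.default_rng(31)
        m = random_matrix(rng, 5, 8, missing=0.2)
        dm = bruvo_matrix(m)
        for a in range(5):
            for b in range(a + 1, 5):
                dists = []
                for j in range(m.n_loci):
                    ga, gb = m.cell(a, j), m.cell(b, j)
                    if ga is None or gb is None:
                        continue
                    dists.append(bruvo_locus_distance(ga, gb))
                expect = float(np.mean(dists)) if dists else 0.0
                assert dm.values[a, b] == pytest.approx(expect)
        assert np.allclose(dm.values, dm.values.T)
        assert np.all(dm.values <= 1.0 + 1e-12)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def random_additive_tree(rng, n_leaves):
    """Random unrooted binary tree with positive edge lengths; returns
    (leaf names, path-length distance matrix)."""
    # adjacency: node -> list of (node, length)
    adj = {}

    def connect(a, b, w):
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))

    def el():
        return float(rng.uniform(0.5, 2.0))

    leaves = [f"L{i}" for i in range(n_leaves)]
    internal = 0
    connect(leaves[0], "I0", el())
    connect(leaves[1], "I0", el())
    connect(leaves[2], "I0", el())
    edges = [(leaves[0], "I0"), (leaves[1], "I0"), (leaves[2], "I0")]
    for leaf in leaves[3:]:
        a, b = edges[rng.integers(0, len(edges))]
        w = dict(adj[a])[b]
        internal += 1
        mid = f"I{internal}"
        adj[a] = [(x, ww) for x, ww in adj[a] if x != b]
        adj[b] = [(x, ww) for x, ww in adj[b] if x != a]
        split = float(rng.uniform(0.2, 0.8)) * w
        connect(a, mid, split)
        connect(b, mid, w - split)
        connect(leaf, mid, el())
        edges.remove((a, b))
        edges.extend([(a, mid), (b, mid), (leaf, mid)])

    def dists_from(src):
        out = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u]:
                if v not in out:
                    out[v] = out[u] + w
                    stack.append(v)
        return out

    D = np.zeros((n_leaves, n_leaves))
    for i, a in enumerate(leaves):
        da = dists_from(a)
        for j, b in enumerate(leaves):
            D[i, j] = da[b]
    return leaves, D


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 5.0, 9.0], [5.0, 0.0, 8.0], [9.0, 8.0, 0.0]])
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {c.name: bl for c, bl in tree.children}
        assert lengths["a"] == pytest.approx((5 + 9 - 8) / 2)
        assert lengths["b"] == pytest.approx((5 + 8 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 8 - 5) / 2)

    def test_recovers_additive_trees_exactly(self):
        rng = np.random.default_rng(32)
        for _ in range(50):
            leaves, D = random_additive_tree(rng, 6)
            tree = nj_tree(DistanceMatrix(leaves, D))
            got = tree.leaf_distances().loc[leaves, leaves].to_numpy()
            assert np.allclose(got, D, atol=1e-9)

    def test_identical_taxa_form_zero_length_cherry(self):
        D = np.array(
            [
                [0.0, 0.0, 4.0, 4.0],
                [0.0, 0.0, 4.0, 4.0],
                [4.0, 4.0, 0.0, 2.0],
                [4.0, 4.0, 2.0, 0.0],
            ]
        )
        tree = nj_tree(DistanceMatrix(["a", "b", "c", "d"], D))
        pat = tree.leaf_distances()
        assert pat.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_no_negative_branch_lengths(self):
        rng = np.random.default_rng(33)
        m = random_matrix(rng, 7, 10, missing=0.1)
        tree = nj_tree(bruvo_matrix(m))

        def walk(node):
            for c, bl in node.children:
                assert bl >= 0.0
                walk(c)

        walk(tree)

    def test_newick_round_trips_through_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(34)
        leaves, D = random_additive_tree(rng, 6)
        tree = nj_tree(DistanceMatrix(leaves, D))
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in dt.taxon_namespace}
        for i, a in enumerate(leaves):
            for j, b in enumerate(leaves):
                if i < j:
                    assert pdm.patristic_distance(taxa[a], taxa[b]) == pytest.approx(
                        D[i, j], abs=1e-6
                    )


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova_oracle(matrix, labels):
    """Explicit sums-of-squares AMOVA from pairwise allele mismatches."""
    lab = list(labels)
    keep = [i for i, l in enumerate(lab) if l is not None and l != "admixed"]
    pops = sorted({lab[i] for i in keep})
    k = len(pops)
    n = len(keep)

    def d2(x, y):
        return 0.0 if x == y else 1.0

    ssd_t = ssd_wp = ssd_wi = 0.0
    for j in range(matrix.n_loci):
        cells = {i: matrix.cell(i, j) for i in keep}
        obs = {i: c for i, c in cells.items() if c is not None}
        if len(obs) < 2:
            continue
        alleles = [(i, a) for i, c in obs.items() for a in c]
        N = len(alleles)
        tot = sum(
            d2(alleles[x][1], alleles[y][1])
            for x in range(N)
            for y in range(x + 1, N)
        )
        ssd_t += tot / N
        for p in pops:
            al = [a for i, a in alleles if lab[i] == p]
            Np = len(al)
            if Np == 0:
                continue
            s = sum(
                d2(al[x], al[y]) for x in range(Np) for y in range(x + 1, Np)
            )
            ssd_wp += s / Np
        for i, (a, b) in obs.items():
            ssd_wi += 0.5 * d2(a, b)
    ssd_ap = ssd_t - ssd_wp
    ssd_ai = ssd_wp - ssd_wi
    df_ap, df_ai, df_wi = k - 1, n - k, n
    ms_ap, ms_ai, ms_wi = ssd_ap / df_ap, ssd_ai / df_ai, ssd_wi / df_wi
    sizes = np.array([sum(1 for i in keep if lab[i] == p) for p in pops], dtype=float)
    a_sizes = 2 * sizes
    n_tot = a_sizes.sum()
    n_c = (n_tot - np.sum(a_sizes**2) / n_tot) / (k - 1)
    s_wi = ms_wi
    s_ai = (ms_ai - ms_wi) / 2
    s_ap = (ms_ap - ms_ai) / n_c
    return {
        "ssd": (ssd_ap, ssd_ai, ssd_wi),
        "components": (s_ap, s_ai, s_wi),
    }


class TestAmova:
    @pytest.fixture()
    def fixture12(self):
        rng = np.random.default_rng(40)
        rows = []
        for _ in range(6):  # popA: alleles mostly 1/2
            rows.append([tuple(sorted(rng.integers(1, 3, size=2).tolist())) for _ in range(4)])
        for _ in range(6):  # popB: alleles mostly 3/4
            rows.append([tuple(sorted(rng.integers(3, 5, size=2).tolist())) for _ in range(4)])
        labels = ["A"] * 6 + ["B"] * 6
        return make_matrix(rows), labels

    def test_matches_explicit_sums_of_squares_oracle(self, fixture12):
        matrix, labels = fixture12
        res = amova(matrix, labels)
        oracle = amova_oracle(matrix, labels)
        got_ssd = tuple(res.table["sum_sq"][:3])
        assert got_ssd == pytest.approx(oracle["ssd"])
        assert tuple(res.table["variance_component"][:3]) == pytest.approx(
            oracle["components"]
        )

    def test_percentages_sum_to_100(self, fixture12):
        matrix, labels = fixture12
        res = amova(matrix, labels)
        assert res.table["percentage"][:3].sum() == pytest.approx(100.0, abs=0.1)
        assert res.table.loc["total", "df"] == res.table["df"][:3].sum()

    def test_fixed_homozygous_populations_are_all_among_population(self):
        rows = [[(1, 1), (5, 5)]] * 4 + [[(2, 2), (6, 6)]] * 4
        labels = ["A"] * 4 + ["B"] * 4
        res = amova(make_matrix(rows), labels)
        assert res.table.loc["among_populations", "percentage"] == pytest.approx(100.0)
        assert res.phi["Phi_ST"] == pytest.approx(1.0)

    def test_single_population_rejected(self):
        m = random_matrix(np.random.default_rng(41), 6, 3)
        with pytest.raises(ValueError):
            amova(m, ["A"] * 6)

    def test_singleton_population_excluded_with_warning(self):
        rows = [[(1, 1)]] * 4 + [[(2, 2)]] * 4 + [[(3, 3)]]
        labels = ["A"] * 4 + ["B"] * 4 + ["C"]
        with pytest.warns(UserWarning, match="singleton"):
            res = amova(make_matrix(rows), labels)
        assert res.table.loc["among_populations", "df"] == 1

    def test_random_labels_on_structureless_data_give_near_zero(self):
        rng = np.random.default_rng(42)
        m = random_matrix(rng, 60, 30, missing=0.0)
        vals = []
        for _ in range(5):
            labels = list(rng.permutation(["A"] * 30 + ["B"] * 30))
            vals.append(amova(m, labels).table.loc["among_populations", "percentage"])
        assert abs(np.mean(vals)) < 5.0


# ---------------------------------------------------------------------------
# Fst
# ---------------------------------------------------------------------------

def _bn_panel(F, n_per_pop, n_loci, seed):
    cfg = SimConfig(
        n_pop1=n_per_pop,
        n_pop2=n_per_pop,
        n_admixed=0,
        n_ssr=0,
        n_snp=n_loci,
        fst=F,
        selfing=0.0,
        n_diagnostic=0,
        snp_missing_max=0.0,
        snp_freq_clip=0.0,
        snp_min_pooled_maf=0.0,
        seed=seed,
    )
    rng = cfg.rng()
    freqs = simulate_frequencies(cfg, rng)
    return simulate_genotypes(freqs, cfg, rng)


class TestFst:
    def test_identical_frequencies_near_zero(self):
        data = _bn_panel(F=1e-6, n_per_pop=200, n_loci=100, seed=50)
        t = wc_theta(data.matrix, data.labels, "pop1", "pop2")
        assert abs(t) < 0.02

    def test_alternatively_fixed_populations_give_one(self):
        rows = [[("A", "A"), ("C", "C")]] * 5 + [[("T", "T"), ("G", "G")]] * 5
        m = make_matrix(rows)
        t = wc_theta(m, ["p1"] * 5 + ["p2"] * 5, "p1", "p2")
        assert t == pytest.approx(1.0)

    @pytest.mark.parametrize("F", [0.1, 0.3, 0.55])
    def test_balding_nichols_parameter_recovery(self, F):
        data = _bn_panel(F=F, n_per_pop=200, n_loci=200, seed=int(F * 100))
        t = wc_theta(data.matrix, data.labels, "pop1", "pop2")
        assert t == pytest.approx(F, abs=0.05)

    def test_pairwise_table_symmetric_zero_diagonal(self, panel_sim, pure_labels):
        tbl = pairwise_fst(panel_sim.matrix, pure_labels)
        assert np.allclose(tbl.values, tbl.values.T)
        assert np.allclose(np.diag(tbl.values), 0.0)
        assert tbl.loc["pop1", "pop2"] > 0.3  # strongly diverged subspecies


# ---------------------------------------------------------------------------
# Membership classification
# ---------------------------------------------------------------------------

class TestMembership:
    def test_clear_assignment(self):
        q = pd.DataFrame({"p1": [0.95], "p2": [0.05]}, index=["v1"])
        assert classify_membership(q).loc["v1"] == "p1"

    def test_below_threshold_is_admixed(self):
        q = pd.DataFrame({"p1": [0.6], "p2": [0.4]}, index=["v1"])
        assert classify_membership(q).loc["v1"] == "admixed"

    def test_boundary_exactly_070_is_assigned(self):
        q = pd.DataFrame({"p1": [0.7], "p2": [0.3]}, index=["v1"])
        assert classify_membership(q).loc["v1"] == "p1"

    def test_rows_must_sum_to_one(self):
        q = pd.DataFrame({"p1": [0.7], "p2": [0.2]}, index=["v1"])
        with pytest.raises(ValueError):
            classify_membership(q)

    def test_synthetic_q_matrix_recovers_generating_labels(self, panel_sim):
        got = classify_membership(panel_sim.q)
        assert list(got) == panel_sim.labels
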