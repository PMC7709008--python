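import itertools
import math

import numpy as np
import pandas as pd
import pytest

import kaspop as kp
from kaspop.distances import DistanceMatrix
from kaspop.genotypes import HOM_REF, HET, HOM_ALT, MISSING
from conftest import make_matrix


def simple_panel(locus_ids, ref="G", alt="C"):
    return pd.DataFrame(
        {"locus_id": locus_ids, "reference_allele": ref, "alternate_allele": alt}
    )


class TestPseudoSequences:
    def test_iupac_encoding_at_gc_locus(self):
        m = make_matrix([[HOM_REF], [HET], [HOM_ALT]])
        seqs = kp.encode_pseudosequences(m, simple_panel(m.locus_ids))
        assert [seqs[s] for s in m.sample_ids] == ["G", "S", "C"]

    def test_all_missing_sample_is_all_n(self):
        m = make_matrix([[MISSING, MISSING]])
        seqs = kp.encode_pseudosequences(m, simple_panel(m.locus_ids))
        assert seqs["s0"] == "NN"

    def test_subset_conserves_length(self, small_matrix):
        panel = simple_panel(small_matrix.locus_ids)
        subset = small_matrix.locus_ids[::3]
        seqs = kp.encode_pseudosequences(small_matrix, panel, subset)
        assert all(len(s) == len(subset) for s in seqs.values())

    def test_locus_absent_from_panel_raises(self, small_matrix):
        panel = simple_panel(small_matrix.locus_ids[:-1])
        with pytest.raises(KeyError):
            kp.encode_pseudosequences(small_matrix, panel)


def uniform_composition_pair(p_mismatch_sites=2, matched_per_base=22):
    """Sequence pair with uniform base composition whose mismatching
    sites cover all six unordered base pairs equally."""
    a, b = [], []
    for base in "ACGT":
        a += [base] * matched_per_base
        b += [base] * matched_per_base
    for x, y in itertools.combinations("ACGT", 2):
        for _ in range(p_mismatch_sites // 2):
            a += [x, y]
            b += [y, x]
    return "".join(a), "".join(b)


class TestTajimaNei:
    def test_identical_sequences_zero(self):
        assert kp.tajima_nei_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_reduces_to_jukes_cantor_at_uniform_composition(self):
        seq_a, seq_b = uniform_composition_pair()
        n = len(seq_a)
        p = 12 / n
        jc = -0.75 * math.log(1 - 4 * p / 3)
        d = kp.tajima_nei_distance(seq_a, seq_b)
        assert d == pytest.approx(jc, rel=1e-12)

    def test_n_and_ambiguity_columns_excluded_pairwise(self):
        base = kp.tajima_nei_distance("AACCGGTT", "AACCGGTA")
        with_n = kp.tajima_nei_distance("AACCGGTTN", "AACCGGTAC")
        with_iupac = kp.tajima_nei_distance("AACCGGTTR", "AACCGGTAC")
        assert with_n == pytest.approx(base)
        assert with_iupac == pytest.approx(base)

    def test_symmetry_and_zero_iff_identical(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), 60))
            b = "".join(rng.choice(list("ACGT"), 60))
            dab = kp.tajima_nei_distance(a, b)
            dba = kp.tajima_nei_distance(b, a)
            if not (np.isnan(dab) and np.isnan(dba)):
                assert dab == dba
                assert (dab == 0) == (a == b)

    def test_no_comparable_sites_flagged(self):
        assert np.isnan(kp.tajima_nei_distance("NNN", "ACG"))

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            kp.tajima_nei_distance("ACG", "AC")


class TestEaed:
    def test_identical_clones_give_zero(self):
        calls = np.tile([HOM_REF, HET, HOM_ALT, HOM_REF, HET], (4, 1))
        m = make_matrix(calls)
        result = kp.eaed(m, simple_panel(m.locus_ids))
        assert result.loc["A1", "EAED1"] == 0.0

    def test_maf_classes_partition_loci(self, small_matrix):
        freqs = kp.allele_frequencies(small_matrix)
        low = (freqs["maf"] < 0.3).sum()
        high = (freqs["maf"] >= 0.3).sum()
        assert low + high == small_matrix.n_loci

    def test_single_sample_accession_not_computable(self):
        calls = np.array([[HOM_REF], [HOM_ALT], [HET]])
        m = make_matrix(calls, accessions=["A1", "A1", "A2"])
        result = kp.eaed(m, simple_panel(m.locus_ids))
        assert np.isnan(result.loc["A2", "EAED1"])

    def test_high_missing_samples_excluded(self):
        calls = np.full((4, 30), HET)
        calls[0, :10] = MISSING  # 33% missing -> excluded
        m = make_matrix(calls)
        result = kp.eaed(m, simple_panel(m.locus_ids))
        assert result.loc["A1", "n_retained"] == 3

    def test_divergence_tracks_simulated_diversity(self):
        means = []
        for maf_lo, maf_hi in [(0.05, 0.15), (0.35, 0.5)]:
            spec = kp.SimGenotypeSpec(
                3, 10, 80, ancestral_maf_range=(maf_lo, maf_hi), seed=31
            )
            m = kp.simulate_genotype_matrix(spec)
            res = kp.eaed(m, simple_panel(m.locus_ids))
            means.append(res["EAED1"].mean())
        assert means[1] > means[0]


def random_additive_tree(rng, n_leaves):
    """Random binary tree as (children, branch length) plus the exact
    leaf-to-leaf path-length matrix (the additive oracle)."""
    import skbio

    nodes = [skbio.TreeNode(name=f"t{i}", length=None) for i in range(n_leaves)]
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), 2, replace=False))
        a, b = nodes[j], nodes[i]
        parent = skbio.TreeNode(children=[nodes.pop(j), nodes.pop(i)])
        parent.children[0].length = float(rng.uniform(0.1, 1.0))
        parent.children[1].length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    root = skbio.TreeNode(children=nodes)
    for child in root.children:
        if child.length is None:
            child.length = float(rng.uniform(0.1, 1.0))
    ids = [f"t{i}" for i in range(n_leaves)]
    tipd = root.tip_tip_distances()
    order = [list(tipd.ids).index(i) for i in ids]
    return root, DistanceMatrix(ids=ids, values=tipd.data[np.ix_(order, order)])


class TestNeighborJoining:
    def test_two_taxa_single_edge(self):
        dm = DistanceMatrix(ids=["a", "b"], values=np.array([[0.0, 0.4], [0.4, 0.0]]))
        tree, newick, flags = kp.neighbor_joining(dm)
        d = tree.tip_tip_distances()
        assert d[("a", "b")] == pytest.approx(0.4)

    def test_four_taxon_split_matches_four_point_oracle(self):
        # additive matrix from ((A,B),(C,D)) with internal edge 0.5
        #   A-B: 3, C-D: 7, cross pairs via internal edge
        br = {"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0}
        ids = list(br)
        vals = np.zeros((4, 4))
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i == j:
                    continue
                d = br[x] + br[y]
                same = {x, y} in ({"A", "B"}, {"C", "D"})
                vals[i, j] = d if same else d + 0.5
        dm = DistanceMatrix(ids=ids, values=vals)
        # four-point oracle: the true split minimizes the pair-sum
        sums = {
            frozenset(("A", "B")): vals[0, 1] + vals[2, 3],
            frozenset(("A", "C")): vals[0, 2] + vals[1, 3],
            frozenset(("A", "D")): vals[0, 3] + vals[1, 2],
        }
        assert min(sums, key=sums.get) == frozenset(("A", "B"))
        tree, _, _ = kp.neighbor_joining(dm)
        tipd = tree.tip_tip_distances()
        for i, x in enumerate(ids):
            for j, y in enumerate(ids):
                if i < j:
                    assert tipd[(x, y)] == pytest.approx(vals[i, j], abs=1e-9)

    @pytest.mark.parametrize("n_leaves", [5, 8, 12])
    def test_additive_matrices_recovered_exactly(self, n_leaves):
        rng = np.random.default_rng(n_leaves)
        for _ in range(5):
            _, dm = random_additive_tree(rng, n_leaves)
            tree, _, _ = kp.neighbor_joining(dm)
            tipd = tree.tip_tip_distances()
            order = [list(tipd.ids).index(i) for i in dm.ids]
            got = tipd.data[np.ix_(order, order)]
            assert np.allclose(got, dm.values, atol=1e-8)

    def test_ultrametric_topology_recovered(self):
        # balanced ultrametric tree ((a:1,b:1):1,(c:1,d:1):1)
        vals = np.array(
            [[0, 2, 4, 4], [2, 0, 4, 4], [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float
        )
        dm = DistanceMatrix(ids=["a", "b", "c", "d"], values=vals)
        tree, _, _ = kp.neighbor_joining(dm)
        tipd = tree.tip_tip_distances()
        assert tipd[("a", "b")] == pytest.approx(2.0)
        assert tipd[("c", "d")] == pytest.approx(2.0)
        assert tipd[("a", "c")] == pytest.approx(4.0)

    def test_undefined_entries_rejected_with_pairs_listed(self):
        vals = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        dm = DistanceMatrix(ids=["a", "b", "c"], values=vals)
        with pytest.raises(ValueError, match="a.*b"):
            kp.neighbor_joining(dm)

    def test_newick_labels_sanitized(self):
        dm = DistanceMatrix(
            ids=["tip one", "tip two"], values=np.array([[0, 1.0], [1.0, 0]])
        )
        _, newick, _ = kp.neighbor_joining(dm)
        assert "tip_one" in newick and " " not in newick


class TestPcoa:
    def test_points_on_a_line_load_one_axis(self):
        x = np.array([0.0, 1.0, 2.5, 4.0])
        vals = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix(ids=list("abcd"), values=vals)
        res = kp.pcoa(dm, n_axes=3)
        assert res.pct_variance[0] == pytest.approx(100.0, abs=1e-8)
        assert res.coordinates.shape[1] == 1  # truncated to positive spectrum

    def test_euclidean_configuration_recovered(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(7, 2))
        vals = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        dm = DistanceMatrix(ids=[f"p{i}" for i in range(7)], values=vals)
        res = kp.pcoa(dm, n_axes=2)
        got = res.coordinates.to_numpy()
        rec = np.linalg.norm(got[:, None] - got[None, :], axis=-1)
        assert np.allclose(rec, vals, atol=1e-8)
        # squared-Euclidean origin: spectrum non-negative up to tolerance
        assert res.eigenvalues.min() > -1e-8 * max(1.0, res.eigenvalues.max())

    def test_id_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 3))
        vals = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        ids = [f"p{i}" for i in range(6)]
        res = kp.pcoa(DistanceMatrix(ids=ids, values=vals), n_axes=2)
        perm = [3, 1, 5, 0, 2, 4]
        res_p = kp.pcoa(
            DistanceMatrix(
                ids=[ids[i] for i in perm], values=vals[np.ix_(perm, perm)]
            ),
            n_axes=2,
        )
        a = res.coordinates.loc[ids].to_numpy()
        b = res_p.coordinates.loc[ids].to_numpy()
        # same configuration up to axis sign
        for k in range(a.shape[1]):
            assert np.allclose(a[:, k], b[:, k], atol=1e-8) or np.allclose(
                a[:, k], -b[:, k], atol=1e-8
            )


class TestEvannoDeltaK:
    def test_linear_mean_lnp_gives_zero(self):
        table = pd.DataFrame(
            {"K": range(1, 8), "mean_lnP": np.linspace(-100, -40, 7), "sd_lnP": 1.0}
        )
        profile = kp.evanno_delta_k(table)
        assert np.allclose(profile["delta_K"], 0.0, atol=1e-9)

    def test_planted_elbow_is_argmax(self):
        for elbow in (3, 5, 9):
            table = kp.simulate_loglik_table(15, elbow, seed=elbow)
            assert kp.evanno_delta_k(table).attrs["optimal_k"] == elbow

    def test_two_rows_rejected(self):
        table = pd.DataFrame({"K": [1, 2], "mean_lnP": [-10, -5], "sd_lnP": [1, 1]})
        with pytest.raises(ValueError):
            kp.evanno_delta_k(table)

    def test_zero_sd_excluded_with_warning(self):
        table = pd.DataFrame(
            {"K": [1, 2, 3, 4], "mean_lnP": [-10, -4, -3.5, -3.4], "sd_lnP": [1, 0, 1, 1]}
        )
        with pytest.warns(UserWarning):
            profile = kp.evanno_delta_k(table)
        assert np.isnan(profile.loc[profile["K"] == 2, "delta_K"]).all()
        assert profile.attrs["optimal_k"] == 3
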