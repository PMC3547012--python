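import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mtsnip.io import LabelledAlignment, SampleRecord
from mtsnip.profile import (
    ChangeCounts,
    DistanceMatrix,
    Tree,
    bin_changes,
    build_nj_tree,
    calibrate_rates,
    count_changes,
    make_profile,
    pairwise_distance_matrix,
)
from mtsnip.simulate import SimConfig, _coalescent_tree, simulate_alignment

from conftest import make_alignment, random_sequences


# ---------------------------------------------------------------------------
# independent oracles


def brute_force_p_distance(seq_a: str, seq_b: str, mode: str) -> float:
    mism = comp = 0
    for a, b in zip(seq_a, seq_b):
        if a == "N" or b == "N":
            continue
        if mode == "pairwise_deletion" and (a == "-" or b == "-"):
            continue
        comp += 1
        mism += a != b
    return mism / comp


def brute_force_min_changes(root: Tree, tip_state: dict[str, int]) -> int:
    """Exhaustive minimum-mutation enumeration over all ancestral labellings.

    States are 0..4 (A, C, G, T, gap); a tip with state 5 (N) is free and
    enumerated like an internal node.
    """
    internals = [n for n in root.postorder() if not n.is_leaf]
    free_tips = [n for n in root.postorder() if n.is_leaf and tip_state[n.name] == 5]
    dims = internals + free_tips
    idx = {id(n): i for i, n in enumerate(dims)}
    grids = np.stack(
        np.meshgrid(*([np.arange(5)] * len(dims)), indexing="ij"), axis=-1
    ).reshape(-1, len(dims))
    cost = np.zeros(len(grids), dtype=int)
    for n in internals:
        for c in n.children:
            a = grids[:, idx[id(n)]]
            if c.is_leaf and id(c) not in idx:
                cost += a != tip_state[c.name]
            else:
                cost += a != grids[:, idx[id(c)]]
    return int(cost.min())


SYM = "ACGT-N"


# ---------------------------------------------------------------------------
# p-distance


class TestPairwiseDistance:
    def test_identical_pair_is_zero(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGT"})
        dm = pairwise_distance_matrix(aln)
        assert dm[("a", "b")] == 0.0

    def test_single_mismatch(self):
        aln = make_alignment({"a": "ACGT", "b": "ACGA"})
        dm = pairwise_distance_matrix(aln)
        assert dm[("a", "b")] == pytest.approx(0.25)

    @pytest.mark.parametrize("mode", ["pairwise_deletion", "gap_fifth"])
    def test_matches_brute_force(self, rng, mode):
        seqs = dict(zip("abcde", random_sequences(rng, 5, 100, "ACGT-N")))
        aln = make_alignment(seqs)
        dm = pairwise_distance_matrix(aln, mode=mode)
        ids = list(seqs)
        for i, x in enumerate(ids):
            for y in ids[i + 1 :]:
                expected = brute_force_p_distance(seqs[x], seqs[y], mode)
                assert dm[(x, y)] == pytest.approx(expected)

    def test_symmetry_and_zero_diagonal(self, rng):
        seqs = dict(zip("abcd", random_sequences(rng, 4, 60, "ACGT")))
        dm = pairwise_distance_matrix(make_alignment(seqs))
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_no_comparable_sites_errors(self):
        aln = make_alignment({"a": "A---", "b": "-CGT", "c": "ACGT"})
        with pytest.raises(ValueError, match="'a'.*'b'"):
            pairwise_distance_matrix(aln)


# ---------------------------------------------------------------------------
# neighbour joining


def _siblings(root: Tree, x: str, y: str) -> bool:
    for node in root.postorder():
        names = {c.name for c in node.children if c.is_leaf}
        if {x, y} <= names:
            return True
    return False


class TestNJ:
    def test_three_taxa_closed_form(self):
        D = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = build_nj_tree(DistanceMatrix(ids=["a", "b", "c"], values=D))
        lengths = {c.name: c.branch_length for c in tree.children}
        assert lengths["a"] == pytest.approx(0.5 * (0.3 + 0.5 - 0.6))
        assert lengths["b"] == pytest.approx(0.5 * (0.3 + 0.6 - 0.5))
        assert lengths["c"] == pytest.approx(0.5 * (0.5 + 0.6 - 0.3))

    def test_four_taxa_additive_recovery(self):
        # generated by the tree ((A:1,B:2):1,(C:3,D:4))
        ids = ["A", "B", "C", "D"]
        D = np.array(
            [
                [0.0, 3.0, 5.0, 6.0],
                [3.0, 0.0, 6.0, 7.0],
                [5.0, 6.0, 0.0, 7.0],
                [6.0, 7.0, 7.0, 0.0],
            ]
        )
        tree = build_nj_tree(DistanceMatrix(ids=ids, values=D))
        assert _siblings(tree, "A", "B")
        lengths = {n.name: n.branch_length for n in tree.leaves()}
        assert lengths == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})
        internal = [c for c in tree.children if not c.is_leaf][0]
        assert internal.branch_length == pytest.approx(1.0)

    def test_tie_break_joins_lowest_index_pair(self):
        ids = ["a", "b", "c", "d"]
        D = np.full((4, 4), 2.0)
        np.fill_diagonal(D, 0.0)
        tree = build_nj_tree(DistanceMatrix(ids=ids, values=D))
        assert _siblings(tree, "a", "b")

    def test_rejects_bad_input(self):
        bad = DistanceMatrix(ids=["a", "b", "c"], values=np.array([[0, 1, 1], [2, 0, 1], [1, 1, 0.0]]))
        with pytest.raises(ValueError, match="symmetric"):
            build_nj_tree(bad)
        neg = np.array([[0, -1, 1], [-1, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="negative"):
            build_nj_tree(DistanceMatrix(ids=["a", "b", "c"], values=neg))

    def test_newick_round_trips_through_dendropy(self):
        D = np.array([[0.0, 3.0, 5.0, 6.0], [3.0, 0.0, 6.0, 7.0],
                      [5.0, 6.0, 0.0, 7.0], [6.0, 7.0, 7.0, 0.0]])
        tree = build_nj_tree(DistanceMatrix(ids=list("ABCD"), values=D))
        import dendropy

        parsed = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        assert {t.label for t in parsed.taxon_namespace} == set("ABCD")


# ---------------------------------------------------------------------------
# Fitch change counting


class TestCountChanges:
    def _tree(self, names, seed=0):
        return _coalescent_tree(list(names), np.random.default_rng(seed))

    def test_invariant_column_zero(self):
        aln = make_alignment({n: "AAAA" for n in "abcd"})
        counts = count_changes(aln, self._tree("abcd"))
        assert counts.totals.sum() == 0

    def test_two_state_column_one_transition(self):
        root = Tree()
        left, right = Tree(), Tree()
        for name, parent in (("t1", left), ("t2", left), ("t3", right), ("t4", right)):
            parent.children.append(Tree(name, 1.0))
        left.branch_length = right.branch_length = 1.0
        root.children = [left, right]
        aln = make_alignment({"t1": "A", "t2": "A", "t3": "G", "t4": "G"})
        counts = count_changes(aln, root)
        assert counts.transitions[0] == 1
        assert counts.totals[0] == 1

    def test_transversion_and_indel_classification(self):
        root = self._tree(["a", "b"])
        aln = make_alignment({"a": "AC-", "b": "TCA"})
        counts = count_changes(aln, root)
        assert counts.transversions[0] == 1  # A vs T
        assert counts.totals[1] == 0
        assert counts.insertions[2] + counts.deletions[2] == 1  # gap vs A

    def test_n_tip_is_unconstrained(self):
        root = self._tree("abcd")
        aln = make_alignment({"a": "A", "b": "A", "c": "N", "d": "A"})
        counts = count_changes(aln, root)
        assert counts.totals[0] == 0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            names = [f"t{i}" for i in range(6)]
            root = _coalescent_tree(names, rng)
            cols = rng.integers(0, 5, size=(len(names), 12))
            seqs = {n: "".join(SYM[s] for s in cols[i]) for i, n in enumerate(names)}
            aln = make_alignment(seqs)
            counts = count_changes(aln, root)
            for col in range(12):
                tip_state = {n: int(cols[i, col]) for i, n in enumerate(names)}
                expected = brute_force_min_changes(root, tip_state)
                assert counts.totals[col] == expected

    def test_matches_enumeration_with_n(self, rng):
        names = list("abcd")
        for _ in range(20):
            root = _coalescent_tree(names, rng)
            states = rng.integers(0, 6, size=4)
            aln = make_alignment({n: SYM[s] for n, s in zip(names, states)})
            counts = count_changes(aln, root)
            expected = brute_force_min_changes(root, dict(zip(names, map(int, states))))
            assert counts.totals[0] == expected

    def test_tip_without_sequence_errors(self):
        root = self._tree(["a", "b", "zz"])
        aln = make_alignment({"a": "A", "b": "A"})
        with pytest.raises(ValueError, match="zz"):
            count_changes(aln, root)


# ---------------------------------------------------------------------------
# binning and calibration


def _counts_from_totals(totals) -> ChangeCounts:
    totals = np.asarray(totals, dtype=int)
    zero = np.zeros_like(totals)
    return ChangeCounts(transitions=totals, transversions=zero.copy(),
                        insertions=zero.copy(), deletions=zero.copy())


class TestBinning:
    def test_twelve_columns_two_bins(self):
        bins = bin_changes(_counts_from_totals([1] * 12), width=6)
        assert len(bins) == 2
        assert (bins[0].start_col, bins[0].end_col) == (1, 6)
        assert (bins[1].start_col, bins[1].end_col) == (7, 12)

    def test_change_in_column_seven_lands_in_bin_two(self):
        totals = [0] * 12
        totals[6] = 5
        bins = bin_changes(_counts_from_totals(totals), width=6)
        assert bins[0].value == 0
        assert bins[1].value == 5

    def test_width_one_is_passthrough(self, rng):
        totals = rng.integers(0, 5, size=20)
        bins = bin_changes(_counts_from_totals(totals), width=1)
        assert [b.value for b in bins] == list(map(float, totals))

    @given(
        totals=st.lists(st.integers(min_value=0, max_value=9), min_size=1, max_size=80),
        width=st.integers(min_value=1, max_value=30),
    )
    def test_bin_totals_conserved(self, totals, width):
        bins = bin_changes(_counts_from_totals(totals), width=width)
        assert sum(b.value for b in bins) == sum(totals)
        # bins tile the columns without overlap
        assert bins[0].start_col == 1
        for prev, nxt in zip(bins, bins[1:]):
            assert nxt.start_col == prev.end_col + 1
        assert bins[-1].end_col == len(totals)


class TestCalibration:
    def test_flat_profile_gives_calibration_rate_everywhere(self):
        bins = calibrate_rates(_counts_from_totals([2] * 90), calibration_rate=24.0)
        assert all(b.value == pytest.approx(24.0) for b in bins)

    def test_hot_bin_rate_is_four_times_rest(self):
        totals = [1] * 300
        totals[30:60] = [4] * 30
        bins = calibrate_rates(_counts_from_totals(totals), calibration_rate=6.0)
        assert bins[1].value == pytest.approx(4 * bins[0].value)

    def test_linearity_in_calibration_rate(self, rng):
        totals = rng.integers(0, 6, size=120)
        totals[0] = 1  # ensure nonzero
        one = calibrate_rates(_counts_from_totals(totals), calibration_rate=5.0)
        two = calibrate_rates(_counts_from_totals(totals), calibration_rate=10.0)
        for a, b in zip(one, two):
            assert b.value == pytest.approx(2 * a.value)

    def test_invariant_to_uniform_count_rescaling(self, rng):
        totals = rng.integers(0, 6, size=120)
        totals[3] = 2
        a = calibrate_rates(_counts_from_totals(totals), calibration_rate=7.0)
        b = calibrate_rates(_counts_from_totals(totals * 3), calibration_rate=7.0)
        for x, y in zip(a, b):
            assert y.value == pytest.approx(x.value)

    def test_weighted_mean_equals_calibration(self, rng):
        totals = rng.integers(0, 8, size=97)  # last bin truncated
        totals[5] = 3
        bins = calibrate_rates(_counts_from_totals(totals), calibration_rate=24.0)
        weights = [b.end_col - b.start_col + 1 for b in bins]
        mean = sum(w * b.value for w, b in zip(weights, bins)) / sum(weights)
        assert mean == pytest.approx(24.0, rel=1e-9)

    def test_zero_changes_errors(self):
        with pytest.raises(ValueError, match="calibrate"):
            calibrate_rates(_counts_from_totals([0] * 60), calibration_rate=24.0)


@pytest.mark.slow
def test_planted_window_rate_factor_recovered():
    """Planted 30-col window at 4x rate: max bin / median of others within 30%."""
    ratios = []
    for seed in range(5):
        cfg = SimConfig(
            seed=seed, n_species=1, genealogy="star", background_rate=0.01,
            hot_window=(541, 570), hot_factor=4.0,
        )
        aln, _ = simulate_alignment(cfg)
        profile, _ = make_profile(aln, calibration_rate=6.0)
        values = [b.value for b in profile.rate_bins]
        top = int(np.argmax(values))
        others = values[:top] + values[top + 1 :]
        assert (profile.rate_bins[top].start_col, profile.rate_bins[top].end_col) == (541, 570)
        ratios.append(values[top] / float(np.median(others)))
    assert 4.0 * 0.7 <= np.mean(ratios) <= 4.0 * 1.3
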