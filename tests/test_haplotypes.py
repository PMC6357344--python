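import numpy as np
import pytest

from clonehap import (
    Fragment,
    SpanningForest,
    TruthSet,
    derive_ancestors,
    linearize_tree,
    score,
)
from clonehap.phasing import PhasedTree


def _forest(trees):
    out = []
    for verts, phases in trees:
        out.append(
            PhasedTree(
                seed=verts[0],
                vertices=list(verts),
                edges=[(verts[k], verts[k + 1], 1.0) for k in range(len(verts) - 1)],
                phase=dict(zip(verts, phases)),
            )
        )
    return SpanningForest(trees=out)


class TestLinearizeTree:
    def test_single_tree_single_fragment(self):
        positions = np.arange(5) * 100
        forest = _forest([((0, 1, 2, 3, 4), (1, 0, 1, 0, 1))])
        frags = linearize_tree(forest, positions)
        assert len(frags) == 1
        assert frags[0].n_sites == 5

    def test_forest_of_three_trees(self):
        positions = np.arange(9) * 50
        forest = _forest(
            [((0, 1), (1, 0)), ((3, 4), (0, 0)), ((6, 7, 8), (1, 1, 1))]
        )
        assert len(linearize_tree(forest, positions)) == 3

    def test_singleton_trees_are_not_fragments(self):
        positions = np.arange(3) * 10
        forest = _forest([((0,), (1,)), ((1, 2), (0, 1))])
        frags = linearize_tree(forest, positions)
        assert len(frags) == 1
        assert list(frags[0].sites) == [1, 2]

    def test_sites_sorted_by_reference_position(self):
        positions = np.array([500, 100, 300])
        forest = _forest([((0, 1, 2), (1, 1, 0))])
        frags = linearize_tree(forest, positions)
        assert list(frags[0].sites) == [1, 2, 0]
        assert frags[0].start_pos == 100 and frags[0].end_pos == 500


class TestDeriveAncestors:
    def test_companion_is_complement_on_last_clone(self):
        frag = Fragment(
            sites=np.array([0, 1, 2]),
            states=np.array([1, 0, 1], dtype=np.int8),
            start_pos=0,
            end_pos=200,
        )
        hset = derive_ancestors([frag], np.zeros(3, dtype=int), 1, 3)
        assert list(hset.matrix[0]) == [1, 0, 1]
        assert list(hset.matrix[1]) == [0, 1, 0]

    def test_piecewise_inheritance_formula(self):
        # I=3, one site per originating clone, all B on the last clone's
        # tracked haplotype
        frag = Fragment(
            sites=np.array([0, 1, 2]),
            states=np.array([1, 1, 1], dtype=np.int8),
            start_pos=0,
            end_pos=20,
        )
        sub = np.array([1, 0, 2])
        hset = derive_ancestors([frag], sub, 3, 3)
        m = hset.matrix
        # site 0 (sub=1): present in clones 1 and 2, absent from clone 0
        assert (m[4, 0], m[2, 0], m[0, 0]) == (1, 1, 0)
        assert (m[5, 0], m[3, 0], m[1, 0]) == (0, 0, 0)
        # site 1 (sub=0, founding): B on one haplotype of every clone
        assert (m[4, 1], m[2, 1], m[0, 1]) == (1, 1, 1)
        # site 2 (sub=2): only the last clone carries it
        assert (m[4, 2], m[2, 2], m[0, 2]) == (1, 0, 0)

    def test_reference_state_propagates_unchanged(self):
        # child A at a site forces every ancestor's father chain to A
        frag = Fragment(
            sites=np.array([0, 1]),
            states=np.array([0, 0], dtype=np.int8),
            start_pos=0,
            end_pos=10,
        )
        sub = np.array([0, 2])
        hset = derive_ancestors([frag], sub, 3, 2)
        assert np.all(hset.matrix[[0, 2, 4]] == 0)
        # companion of a founding site is then B in every clone
        assert np.all(hset.matrix[[1, 3, 5], 0] == 1)

    @pytest.mark.parametrize("seed", range(20))
    def test_inheritance_invariant_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        I = int(rng.integers(1, 5))
        sub = rng.integers(0, I, size=n)
        cut = sorted(rng.choice(np.arange(1, n), size=2, replace=False))
        frags = []
        for lo, hi in zip([0, *cut], [*cut, n]):
            if hi - lo >= 2:
                frags.append(
                    Fragment(
                        sites=np.arange(lo, hi),
                        states=rng.integers(0, 2, hi - lo).astype(np.int8),
                        start_pos=lo * 10,
                        end_pos=(hi - 1) * 10,
                    )
                )
        # derive_ancestors asserts the inheritance invariant internally
        hset = derive_ancestors(frags, sub, I, n)
        # and row pairs are heterozygous exactly where sub(j) <= i
        for i in range(I):
            placed = hset.matrix[2 * i] >= 0
            het = hset.matrix[2 * i] != hset.matrix[2 * i + 1]
            assert np.all(het[placed] == (sub[placed] <= i))


def _truth(n, sub, side, I):
    return TruthSet(
        positions=np.arange(n) * 100,
        ref_codes=np.zeros(n, dtype=np.uint8),
        alt_codes=np.ones(n, dtype=np.uint8),
        sub=np.asarray(sub),
        side=np.asarray(side),
        n_subclones=I,
    )


class TestScore:
    def _perfect_recon(self, truth, I):
        # tracked haplotype carries the mutation where side == 0
        states = np.where(truth.side == 0, 1, 0).astype(np.int8)
        frag = Fragment(
            sites=np.arange(truth.n_sites),
            states=states,
            start_pos=0,
            end_pos=int(truth.positions[-1]),
        )
        return derive_ancestors([frag], truth.sub, I, truth.n_sites)

    def test_perfect_reconstruction(self):
        truth = _truth(6, [0, 1, 0, 2, 1, 0], [0, 1, 1, 0, 0, 1], 3)
        hset = self._perfect_recon(truth, 3)
        m = score(hset, truth)
        assert m.recognition_rate == 1.0
        assert m.accuracy_rate == 1.0
        assert m.fragment_count == 1

    def test_global_flip_is_free(self):
        truth = _truth(6, [0, 1, 0, 2, 1, 0], [0, 1, 1, 0, 0, 1], 3)
        hset = self._perfect_recon(truth, 3)
        flipped = derive_ancestors(
            [
                Fragment(
                    sites=hset.fragments[0].sites,
                    states=(1 - hset.fragments[0].states).astype(np.int8),
                    start_pos=0,
                    end_pos=500,
                )
            ],
            truth.sub,
            3,
            truth.n_sites,
        )
        assert score(flipped, truth).accuracy_rate == 1.0

    def test_half_placed_recognition(self):
        truth = _truth(8, [0] * 8, [0] * 8, 1)
        frag = Fragment(
            sites=np.arange(4),
            states=np.ones(4, dtype=np.int8),
            start_pos=0,
            end_pos=300,
        )
        hset = derive_ancestors([frag], truth.sub, 1, 8)
        m = score(hset, truth)
        assert m.recognition_rate == 0.5
        assert m.n_placed == 4

    def test_fragment_span_arithmetic(self):
        truth = _truth(2, [0, 0], [0, 0], 1)
        frag = Fragment(
            sites=np.array([0, 1]),
            states=np.array([1, 0], dtype=np.int8),
            start_pos=100,
            end_pos=10167,
        )
        truth = TruthSet(
            positions=np.array([100, 10167]),
            ref_codes=np.zeros(2, dtype=np.uint8),
            alt_codes=np.ones(2, dtype=np.uint8),
            sub=np.zeros(2, dtype=int),
            side=np.zeros(2, dtype=int),
            n_subclones=1,
        )
        hset = derive_ancestors([frag], truth.sub, 1, 2)
        assert score(hset, truth).longest_length == 10068

    def test_mismatched_site_sets_rejected(self):
        truth = _truth(5, [0] * 5, [0] * 5, 1)
        frag = Fragment(
            sites=np.array([0, 1]),
            states=np.array([1, 0], dtype=np.int8),
            start_pos=0,
            end_pos=100,
        )
        hset = derive_ancestors([frag], np.zeros(3, dtype=int), 1, 3)
        with pytest.raises(ValueError):
            score(hset, truth)

    def test_no_double_placement(self, mixture_run):
        hset = mixture_run.result.haplotype_set
        all_sites = np.concatenate([f.sites for f in hset.fragments])
        assert len(all_sites) == len(np.unique(all_sites))
        m = mixture_run.metrics
        assert m.n_placed == len(all_sites)
        assert m.recognition_rate == pytest.approx(m.n_placed / m.n_sites)
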