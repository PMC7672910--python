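"""Cross-region germline propagation, presence posterior, matrix, tree."""

import math
from itertools import combinations

import numpy as np
import pytest

from pmlseq.model import CopyNumberSegment, Patient, RegionData, VariantCall
from pmlseq.multiregion_clonality import (
    PresenceMatrix,
    build_presence_matrix,
    infer_tree,
    presence_posterior,
    propagate_germline_exclusion,
)


def _v(pos, vaf=0.4, depth=100, **kw):
    return VariantCall(chrom="chr1", pos=pos, ref="A", alt="T", vaf=vaf, depth=depth, **kw)


def _patient(region_variants, segments=None):
    return Patient(
        "P1",
        [
            RegionData(region_id=rid, variants=list(vs), segments=list(segments or []))
            for rid, vs in region_variants.items()
        ],
    )


NEUTRAL = CopyNumberSegment("chr1", 0, 1_000_000, 0.0, n_probes=100, baf=0.5)
LOH = CopyNumberSegment("chr1", 1_000_000, 2_000_000, -0.4, n_probes=100, baf=0.2)


class TestGermlinePropagation:
    def test_high_vaf_in_one_region_removed_from_all(self):
        shared = 5_000
        patient = _patient(
            {
                "A": [_v(shared, vaf=0.95), _v(10)],
                "B": [_v(shared, vaf=0.5)],
                "C": [_v(shared, vaf=0.4)],
            },
            segments=[NEUTRAL, LOH],
        )
        out = propagate_germline_exclusion(patient)
        for region in out.regions:
            assert all(v.pos != shared for v in region.variants)
        assert [v.pos for v in out.region("A").variants] == [10]

    def test_loh_segment_blocks_propagation(self):
        inside_loh = 1_500_000
        patient = _patient(
            {"A": [_v(inside_loh, vaf=0.95)], "B": [_v(inside_loh, vaf=0.5)]},
            segments=[NEUTRAL, LOH],
        )
        out = propagate_germline_exclusion(patient)
        assert len(out.region("A").variants) == 1
        assert len(out.region("B").variants) == 1

    def test_threshold_is_strictly_greater_than(self):
        patient = _patient({"A": [_v(100, vaf=0.9)]}, segments=[NEUTRAL])
        assert len(propagate_germline_exclusion(patient).region("A").variants) == 1

    def test_idempotent(self):
        patient = _patient(
            {"A": [_v(5_000, vaf=0.95), _v(10)], "B": [_v(5_000, vaf=0.5)]},
            segments=[NEUTRAL],
        )
        once = propagate_germline_exclusion(patient)
        twice = propagate_germline_exclusion(once)
        for r1, r2 in zip(once.regions, twice.regions):
            assert [v.key for v in r1.variants] == [v.key for v in r2.variants]


def _direct_posterior(alt, depth, e=0.02, prior=0.5):
    l1 = 1.0 / (depth + 1)
    l0 = math.comb(depth, alt) * e**alt * (1 - e) ** (depth - alt)
    return prior * l1 / (prior * l1 + (1 - prior) * l0)


class TestPresencePosterior:
    @pytest.mark.parametrize(
        "alt,depth",
        [(0, 50), (1, 50), (5, 50), (25, 50), (50, 50), (0, 200), (10, 200), (3, 7)],
    )
    def test_matches_direct_formula_to_twelve_significant_digits(self, alt, depth):
        assert presence_posterior(alt, depth) == pytest.approx(
            _direct_posterior(alt, depth), rel=1e-12
        )

    def test_reference_value_all_reference_reads(self):
        # 0/50 alt reads still leave ~5% presence probability: zero alt
        # reads are unlikely under a uniform VAF but possible at f ~ 0.
        assert presence_posterior(0, 50) == pytest.approx(0.0511, abs=5e-4)

    def test_all_alt_reads_overwhelm_the_error_model(self):
        assert presence_posterior(50, 50) > 0.999

    def test_no_reads_returns_the_prior(self):
        assert presence_posterior(0, 0, prior=0.3) == pytest.approx(0.3)

    def test_monotone_nondecreasing_in_alt_beyond_the_error_mode(self):
        # The error likelihood Binom(alt; depth, e) rises up to its mode at
        # ~depth*e, so the posterior dips there before climbing; beyond the
        # mode it is non-decreasing in alt.
        depth, e = 80, 0.02
        mode = math.ceil(depth * e)
        values = [presence_posterior(a, depth, e=e) for a in range(mode, depth + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))
        # and the zero-alt cell still favors absence at this depth
        assert presence_posterior(0, depth, e=e) < 0.5

    def test_invalid_counts_are_errors(self):
        from pmlseq.model import PmlseqError

        with pytest.raises(PmlseqError):
            presence_posterior(5, 2)
        with pytest.raises(PmlseqError):
            presence_posterior(-1, 10)
        with pytest.raises(PmlseqError):
            presence_posterior(1, 10, e=0.7)


class TestPresenceMatrix:
    def test_matrix_shape_is_mutations_by_regions(self):
        patient = _patient(
            {
                "A": [_v(p) for p in (1, 2, 3, 4, 5)],
                "B": [_v(p) for p in (1, 2)],
                "C": [],
            }
        )
        matrix = build_presence_matrix(patient)
        assert matrix.shape == (5, 3)

    def test_low_depth_cell_is_unknown_regardless_of_alt(self):
        patient = _patient({"A": [_v(1, vaf=1.0, depth=2)]})
        matrix = build_presence_matrix(patient, min_depth=5)
        assert matrix.classification[0, 0] == "unknown"

    def test_ubiquitous_high_vaf_mutation_present_everywhere(self):
        patient = _patient({r: [_v(1, vaf=0.4, depth=100)] for r in "ABC"})
        matrix = build_presence_matrix(patient)
        assert (matrix.classification == "present").all()

    def test_region_without_counts_is_unknown(self):
        patient = _patient({"A": [_v(1)], "B": []})
        matrix = build_presence_matrix(patient)
        assert matrix.classification[0, 1] == "unknown"


def _matrix_from_patterns(regions, patterns, depth=200, present_alt=50, absent_alt=4):
    """Deterministic matrix encoding exact presence patterns."""
    keys = [("chr1", 100 + i, "A", "C") for i in range(len(patterns))]
    variants = {r: [] for r in regions}
    counts = {r: {} for r in regions}
    for key, pattern in zip(keys, patterns):
        for r in regions:
            counts[r][key] = (present_alt if r in pattern else absent_alt, depth)
        for r in pattern:
            variants[r].append(
                VariantCall(chrom=key[0], pos=key[1], ref=key[2], alt=key[3],
                            vaf=present_alt / depth, depth=depth)
            )
    patient = Patient(
        "P", [RegionData(region_id=r, variants=variants[r], counts=counts[r])
              for r in regions]
    )
    return build_presence_matrix(patient)


def _fitch_score(tree, pattern, leaves):
    """Parsimony changes of a binary character on a rooted tree given as
    nested tuples of leaf names."""

    def post(node):
        if isinstance(node, str):
            return ({1} if node in pattern else {0}), 0
        sets, cost = zip(*(post(c) for c in node))
        inter = set.intersection(*sets)
        if inter:
            return inter, sum(cost)
        return set.union(*sets), sum(cost) + 1

    _, changes = post(tree)
    return changes


def _all_rooted_trees(leaves):
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]
    for k in range(1, len(rest) + 1):
        for group in combinations(rest, k):
            remaining = [x for x in rest if x not in group]
            for left in _all_rooted_trees([first, *remaining]):
                for right in _all_rooted_trees(list(group)):
                    yield (left, right)


def _tree_clades(tree, n_leaves):
    out = set()

    def walk(node):
        if isinstance(node, str):
            return frozenset({node})
        regions = frozenset()
        for c in node:
            regions |= walk(c)
        out.add(regions)
        return regions

    walk(tree)
    return {c for c in out if 1 < len(c) < n_leaves}


class TestInferTree:
    def test_worked_three_region_example(self):
        """Trunk of 8 shared mutations, 4 shared by 3B/3C, privates 2/1/3
        -> topology ((3B,3C),3A) with those edge counts."""
        regions = ["3A", "3B", "3C"]
        patterns = (
            [{"3A", "3B", "3C"}] * 8
            + [{"3A"}] * 2
            + [{"3B", "3C"}] * 4
            + [{"3B"}] * 1
            + [{"3C"}] * 3
        )
        tree = infer_tree(_matrix_from_patterns(regions, patterns))
        assert tree.conflict_free and tree.homoplasy_count == 0
        assert tree.clades() == {frozenset({"3B", "3C"})}
        counts = tree.edge_counts()
        assert counts[frozenset({"3A", "3B", "3C"})] == 8
        assert counts[frozenset({"3B", "3C"})] == 4
        assert counts[frozenset({"3A"})] == 2
        assert counts[frozenset({"3B"})] == 1
        assert counts[frozenset({"3C"})] == 3
        assert tree.newick() == "(3A:2,(3B:1,3C:3):4):8;"

    def test_all_shared_gives_trunk_only_tree(self):
        regions = ["A", "B", "C"]
        tree = infer_tree(_matrix_from_patterns(regions, [set(regions)] * 6))
        assert tree.clades() == set()
        assert tree.edge_counts()[frozenset(regions)] == 6

    def test_single_region_star_tree(self):
        tree = infer_tree(_matrix_from_patterns(["A"], [{"A"}] * 3))
        assert tree.root.is_leaf or len(tree.root.children) == 0

    def test_conflict_free_matrix_matches_exhaustive_parsimony_optimum(self):
        rng = np.random.default_rng(42)
        regions = ["A", "B", "C", "D"]
        all_trees = list(_all_rooted_trees(regions))
        for _ in range(30):
            # random binary generating tree, >=1 mutation on every node
            def split(names):
                if len(names) == 1:
                    return [set(names)]
                k = int(rng.integers(1, len(names)))
                perm = [names[i] for i in rng.permutation(len(names))]
                return [set(names)] + split(perm[:k]) + split(perm[k:])

            clades = split(regions)
            patterns = []
            for c in clades:
                patterns.extend([set(c)] * int(rng.integers(1, 4)))
            matrix = _matrix_from_patterns(regions, patterns)
            inferred = infer_tree(matrix)
            assert inferred.conflict_free and inferred.homoplasy_count == 0
            # exhaustive oracle: total Fitch parsimony over all rooted trees
            def score(t):
                return sum(_fitch_score(t, p, regions) for p in patterns)

            best = min(score(t) for t in all_trees)
            optimal_clade_sets = [
                _tree_clades(t, 4) for t in all_trees if score(t) == best
            ]
            assert inferred.clades() in optimal_clade_sets

    def test_conflicting_matrix_reports_homoplasy_deterministically(self):
        regions = ["A", "B", "C", "D"]
        patterns = [{"A", "B"}] * 5 + [{"B", "C"}] * 2 + [{"C", "D"}] * 5
        t1 = infer_tree(_matrix_from_patterns(regions, patterns))
        t2 = infer_tree(_matrix_from_patterns(regions, patterns))
        assert not t1.conflict_free and t1.homoplasy_count > 0
        assert t1.newick() == t2.newick()

    def test_unknown_cells_do_not_define_clades(self):
        regions = ["A", "B", "C"]
        matrix = _matrix_from_patterns(regions, [{"A", "B"}] * 3 + [{"C"}] * 2)
        # make one mutation's C cell unknown (low depth)
        key = matrix.mutations[0]
        for r in matrix.regions:
            pass
        matrix.depth[0, 2] = 2
        matrix.classification[0, 2] = "unknown"
        tree = infer_tree(matrix)
        assert tree.clades() == {frozenset({"A", "B"})}
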