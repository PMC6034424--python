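import itertools
import math

import numpy as np
import pytest

from clonescape import (
    PresenceMatrix,
    cosine_similarity,
    individual_rarefaction,
    overlap_counts,
    plateau_cutoff,
    sample_rarefaction,
    stratified_sample_rarefaction,
)


def exhaustive_individual(counts, n):
    """Enumerate every size-n subset of individuals; average the richness."""
    pool = [i for i, c in enumerate(counts) for _ in range(c)]
    subsets = list(itertools.combinations(range(len(pool)), n))
    total = sum(len({pool[i] for i in sub}) for sub in subsets)
    return total / len(subsets)


def exhaustive_sample(matrix, t):
    """Enumerate every size-t subset of replicate columns."""
    m = np.asarray(matrix, dtype=bool)
    cols = range(m.shape[1])
    subsets = list(itertools.combinations(cols, t))
    total = sum(int(m[:, list(sub)].any(axis=1).sum()) for sub in subsets)
    return total / len(subsets)


def monte_carlo_individual(counts, n, draws, rng):
    pool = np.repeat(np.arange(len(counts)), counts)
    N = len(pool)
    idx = np.argsort(rng.random((draws, N)), axis=1)[:, :n]
    picked = pool[idx]
    picked.sort(axis=1)
    richness = 1 + (np.diff(picked, axis=1) != 0).sum(axis=1)
    return richness.mean(), richness.std(ddof=1) / math.sqrt(draws)


def monte_carlo_sample(matrix, t, draws, rng):
    m = np.asarray(matrix, dtype=bool)
    T = m.shape[1]
    idx = np.argsort(rng.random((draws, T)), axis=1)[:, :t]
    richness = np.array([int(m[:, cols].any(axis=1).sum()) for cols in idx])
    return richness.mean(), richness.std(ddof=1) / math.sqrt(draws)


class TestIndividualRarefaction:
    def test_full_sample_returns_observed_richness(self):
        counts = [4, 2, 1, 1]
        assert individual_rarefaction(counts, 8) == pytest.approx(4.0)

    def test_two_pairs_subsample_two(self):
        # E[S(2)] for counts (2,2): enumeration over C(4,2)=6 subsamples
        assert individual_rarefaction([2, 2], 2) == pytest.approx(2 - 2 / 6)
        assert exhaustive_individual([2, 2], 2) == pytest.approx(2 - 2 / 6)

    def test_zero_subsample(self):
        assert individual_rarefaction([3, 3], 0) == 0.0

    def test_oversized_subsample_rejected(self):
        with pytest.raises(ValueError):
            individual_rarefaction([2, 2], 5)

    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            k = rng.integers(1, 4)
            counts = rng.integers(1, 4, k).tolist()
            total = sum(counts)
            for n in range(total + 1):
                assert individual_rarefaction(counts, n) == pytest.approx(
                    exhaustive_individual(counts, n), abs=1e-12
                )

    def test_curve_concave_non_decreasing(self):
        counts = [10, 5, 3, 1, 1]
        vals = [individual_rarefaction(counts, n) for n in range(21)]
        diffs = np.diff(vals)
        assert np.all(diffs >= -1e-12)
        assert np.all(np.diff(diffs) <= 1e-9)


class TestSampleRarefaction:
    def matrix(self):
        return PresenceMatrix(
            matrix=np.array([[1, 1], [1, 0]], dtype=bool),
            clone_ids=[1, 2],
            replicate_ids=["R1", "R2"],
        )

    def test_all_replicates_returns_row_count(self):
        assert sample_rarefaction(self.matrix(), 2) == pytest.approx(2.0)

    def test_single_replicate_expectation(self):
        # clone 1 present in both replicates, clone 2 in one: E[S(1)] = 1.5
        assert sample_rarefaction(self.matrix(), 1) == pytest.approx(1.5)

    def test_ubiquitous_clone_contributes_one_at_every_t(self):
        m = PresenceMatrix(np.ones((1, 5), dtype=bool), [1], list("abcde"))
        for t in range(1, 6):
            assert sample_rarefaction(m, t) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = rng.random((6, 5)) < 0.5
            m[m.sum(axis=1) == 0, 0] = True
            pm = PresenceMatrix(m, list(range(6)), [f"R{j}" for j in range(5)])
            for t in range(1, 6):
                assert sample_rarefaction(pm, t) == pytest.approx(
                    exhaustive_sample(m, t), abs=1e-12
                )

    def test_matches_monte_carlo_within_three_sigma(self):
        rng = np.random.default_rng(17)
        m = rng.random((12, 6)) < 0.4
        m[m.sum(axis=1) == 0, 0] = True
        pm = PresenceMatrix(m, list(range(12)), [f"R{j}" for j in range(6)])
        for t in (2, 4):
            mean, se = monte_carlo_sample(m, t, 20_000, rng)
            assert abs(sample_rarefaction(pm, t) - mean) <= 3 * se + 1e-9


def build_presence(rows, T):
    m = np.zeros((len(rows), T), dtype=bool)
    for i, k in enumerate(rows):
        m[i, :k] = True
    return PresenceMatrix(m, list(range(len(rows))), [f"R{j}" for j in range(T)])


class TestStratifiedCurves:
    def test_cutoff_one_is_full_matrix_curve(self):
        pm = build_presence([1, 2, 3, 4], 4)
        (curve,) = stratified_sample_rarefaction(pm, [1])
        assert curve.values[-1] == pytest.approx(4.0)
        for t, v in zip(curve.sizes, curve.values):
            assert v == pytest.approx(sample_rarefaction(pm, int(t)))

    def test_cutoff_t_restricts_to_ubiquitous_clones(self):
        pm = build_presence([1, 4, 4], 4)
        (curve,) = stratified_sample_rarefaction(pm, [4])
        assert np.allclose(curve.values, 2.0)  # both ubiquitous clones, flat

    def test_cutoff_beyond_max_gives_zero_curve(self):
        pm = build_presence([1, 2], 4)
        (curve,) = stratified_sample_rarefaction(pm, [5])
        assert np.all(curve.values == 0.0)


class TestPlateau:
    def test_flat_tail_plateaus(self):
        pm = build_presence([1, 2, 5, 5, 5], 5)
        curves = stratified_sample_rarefaction(pm, [1, 5])
        assert plateau_cutoff(curves) == 5

    def test_linear_curve_not_plateaued(self):
        from clonescape import RarefactionCurve

        curve = RarefactionCurve(np.arange(1, 6), np.arange(1.0, 6.0), label=1)
        assert plateau_cutoff([curve]) is None

    def test_simulated_many_replicate_repertoire_has_finite_cutoff(self):
        # deep-replicate design: larger strata saturate, the full set does not
        rng = np.random.default_rng(207)
        T = 19
        rows = []
        for _ in range(300):
            # heavy-tailed per-clone detection probability
            p = min(1.0, rng.lognormal(-2.5, 1.5))
            row = rng.random(T) < p
            if row.any():
                rows.append(row)
        pm = PresenceMatrix(np.array(rows), list(range(len(rows))),
                            [f"R{j}" for j in range(T)])
        cutoffs = [1, 2, 3, 4, 5, 6, 10]
        curves = stratified_sample_rarefaction(pm, cutoffs)
        got = plateau_cutoff(curves)
        assert got in cutoffs
        # visual-rule oracle: smallest cutoff whose final increment is <1%
        expected = None
        for c in curves:
            v = c.values
            if v[-1] > 0 and (v[-1] - v[-2]) / v[-1] < 0.01:
                expected = c.label
                break
        assert got == expected is not None


class TestCosine:
    def test_identity(self):
        a = {"c1": 3.0, "c2": 1.0}
        assert cosine_similarity(a, dict(a)) == pytest.approx(1.0)

    def test_disjoint_sets_orthogonal(self):
        assert cosine_similarity({"a": 2.0}, {"b": 5.0}) == pytest.approx(0.0)

    def test_worked_value(self):
        assert cosine_similarity([1, 2], [2, 1]) == pytest.approx(0.8)

    def test_scale_invariance_and_symmetry(self):
        a, b = [1.0, 2.0, 0.0], [3.0, 1.0, 1.0]
        assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
        assert cosine_similarity([10, 20, 0], b) == pytest.approx(
            cosine_similarity(a, b)
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_similarity({"a": 0.0}, {"a": 1.0})


class TestOverlapCounts:
    def test_identical_sets(self):
        s = {"s1": set("abcde"), "s2": set("abcde")}
        summary = overlap_counts(s)
        assert summary.exactly_k[2] == 5
        assert summary.exactly_k[1] == 0

    def test_partial_overlap(self):
        summary = overlap_counts({"s1": {"a", "b", "c"}, "s2": {"b", "c", "d"}})
        assert summary.at_least_k[2] == 2
        assert sorted(summary.shared_clones) == ["b", "c"]

    def test_agrees_with_presence_matrix_row_sums(self, sim_pipeline):
        clones = sim_pipeline["clones"]
        pm = PresenceMatrix.from_clones(clones)
        sets = {
            rep: {c.clone_id for c in clones if rep in c.replicate_presence}
            for rep in pm.replicate_ids
        }
        summary = overlap_counts(sets)
        assert summary.at_least_k[2] == int((pm.row_sums >= 2).sum())
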