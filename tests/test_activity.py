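import math

import numpy as np
import pytest
from scipy.spatial.distance import jensenshannon

from conftest import binary_matrix, chain
from pavd.activity import (
    ActivityDistribution,
    ActivityMatrix,
    PAV,
    activity_distribution,
    compute_activity_matrix,
    compute_pav,
    distance_matrix,
    group_average_distribution,
    js_divergence,
    pavd,
)
from pavd.bdeu import ScoreConfig
from pavd.networks import enumerate_candidates
from pavd.simulate import SyntheticCohortSpec, sample_cohort


def random_distribution(rng, n):
    return rng.dirichlet(np.ones(n))


def random_pav(rng, sample_id, pathway_sizes):
    dists = tuple(
        ActivityDistribution(f"P{i}", tuple(f"c{k}" for k in range(n)),
                             random_distribution(rng, n))
        for i, n in enumerate(pathway_sizes)
    )
    return PAV(sample_id, dists)


class TestJsDivergence:
    def test_identical_distributions_zero(self):
        rng = np.random.default_rng(0)
        for n in (2, 3, 9):
            p = random_distribution(rng, n)
            assert js_divergence(p, p) == 0.0

    def test_disjoint_support_is_one_bit(self):
        assert js_divergence([1, 0], [0, 1]) == pytest.approx(1.0, abs=1e-12)

    def test_half_uniform_vs_point_mass(self):
        assert js_divergence([0.5, 0.5], [1, 0]) == pytest.approx(0.311278, abs=1e-6)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(2, 10))
            p, q = random_distribution(rng, n), random_distribution(rng, n)
            expected = jensenshannon(p, q, base=2) ** 2
            assert js_divergence(p, q) == pytest.approx(expected, abs=1e-9)

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError, match="shape"):
            js_divergence([1, 0], [1, 0, 0])
        with pytest.raises(ValueError, match="sums to"):
            js_divergence([0.7, 0.2], [0.5, 0.5])
        with pytest.raises(ValueError, match="negative"):
            js_divergence([1.5, -0.5], [0.5, 0.5])


class TestPavdMetric:
    def test_identity_and_mismatch(self):
        rng = np.random.default_rng(2)
        x = random_pav(rng, "x", [3, 5])
        assert pavd(x, x) == 0.0
        y = random_pav(rng, "y", [3, 4])
        with pytest.raises(ValueError, match="mismatch"):
            pavd(x, y)

    def test_disjoint_plus_identical_pathways(self):
        d1x = ActivityDistribution("P0", ("a", "b"), np.array([1.0, 0.0]))
        d1y = ActivityDistribution("P0", ("a", "b"), np.array([0.0, 1.0]))
        shared = ActivityDistribution("P1", ("a", "b"), np.array([0.4, 0.6]))
        assert pavd(PAV("x", (d1x, shared)), PAV("y", (d1y, shared))) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_metric_axioms_on_random_pavs(self):
        rng = np.random.default_rng(3)
        sizes = [int(rng.integers(2, 10)) for _ in range(4)]
        pavs = [random_pav(rng, f"s{i}", sizes) for i in range(30)]
        for i in range(100):
            x, y = pavs[i % 30], pavs[(i * 7 + 3) % 30]
            d = pavd(x, y)
            assert d >= 0
            assert pavd(y, x) == pytest.approx(d, abs=1e-12)
        for i in range(100):
            x, y, z = (pavs[(i * 3) % 30], pavs[(i * 5 + 1) % 30], pavs[(i * 11 + 2) % 30])
            assert pavd(x, z) <= pavd(x, y) + pavd(y, z) + 1e-9

    def test_sqrt_js_is_metric_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(2, 9))
            p, q, r = (random_distribution(rng, n) for _ in range(3))
            dpq = math.sqrt(js_divergence(p, q))
            dqr = math.sqrt(js_divergence(q, r))
            dpr = math.sqrt(js_divergence(p, r))
            assert dpr <= dpq + dqr + 1e-9


class TestActivityDistributionComputation:
    def test_distribution_is_normalized_loo_ratios(self):
        # the distribution must equal the softmax of the per-candidate
        # leave-one-out log ratios computed independently (no term caching)
        from pavd.bdeu import loo_log_ratio

        family = enumerate_candidates(chain("P", ("A", "B", "C")))
        rng = np.random.default_rng(5)
        data = binary_matrix({g: rng.integers(2, size=7).tolist() for g in "ABC"})
        for sid in data.sample_ids[:3]:
            ratios = np.array([
                loo_log_ratio(net, data, sid) for net in family.networks()
            ])
            expected = np.exp(ratios) / np.exp(ratios).sum()
            dist = activity_distribution(family, data, sid)
            assert dist.probs == pytest.approx(expected, abs=1e-12)
        # the arithmetic itself: a log-ratio gap of ln 3 between two candidates
        # normalizes to [0.25, 0.75]
        gap = np.exp([0.0, math.log(3)])
        assert (gap / gap.sum()) == pytest.approx([0.25, 0.75], abs=1e-12)

    def test_coupled_sample_in_decoupled_cohort_prefers_normal(self, ab_family):
        # cohort: mostly decoupled A,B; the (1,1)/(0,0)-heavy block favors Normal
        rng = np.random.default_rng(0)
        a = rng.integers(2, size=40).tolist()
        b = rng.integers(2, size=40).tolist()
        a[:1] = [1]; b[:1] = [1]
        data = binary_matrix({"A": a + [1, 1, 0, 0] * 5, "B": b + [1, 1, 0, 0] * 5})
        coupled_ids = data.sample_ids[40:]
        dist = activity_distribution(ab_family, data, coupled_ids[0])
        assert dist.probs[0] > dist.probs[1]

    def test_normalized_and_deterministic(self, ab_family):
        data = binary_matrix({"A": [1, 0, 1, 1], "B": [1, 1, 0, 1]})
        d1 = activity_distribution(ab_family, data, "s1")
        d2 = activity_distribution(ab_family, data, "s1")
        assert d1.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.array_equal(d1.probs, d2.probs)


class TestActivityMatrix:
    def _families_and_data(self):
        fam1 = enumerate_candidates(chain("P1", ("A", "B")))
        fam2 = enumerate_candidates(chain("P2", ("C", "D", "E")))
        rng = np.random.default_rng(6)
        data = binary_matrix({g: rng.integers(2, size=6).tolist() for g in "ABCDE"})
        return [fam1, fam2], data

    def test_matrix_columns_equal_pavs(self):
        families, data = self._families_and_data()
        R = compute_activity_matrix(families, data)
        assert (R.n_pathways, R.n_samples) == (2, 6)
        for sid in data.sample_ids:
            direct = compute_pav(families, data, sid)
            col = R.pav(sid)
            for a, b in zip(direct.distributions, col.distributions):
                assert np.allclose(a.probs, b.probs, atol=1e-12)

    def test_every_cell_normalized(self):
        families, data = self._families_and_data()
        R = compute_activity_matrix(families, data)
        for pid in R.pathway_ids:
            assert np.allclose(R.probs[pid].sum(axis=1), 1.0, atol=1e-9)

    def test_empty_family_list_gives_empty_pav(self):
        _, data = self._families_and_data()
        assert len(compute_pav([], data, "s0")) == 0


class TestDistanceMatrix:
    def test_identical_columns_zero(self):
        R = ActivityMatrix(
            ["P"], ["s0", "s1"], {"P": ("Normal", "e")},
            {"P": np.array([[0.3, 0.7], [0.3, 0.7]])},
        )
        dm = distance_matrix(R)
        assert np.array_equal(dm.values, np.zeros((2, 2)))

    def test_agrees_with_pairwise_pavd_and_symmetry(self):
        families = [enumerate_candidates(chain("P1", ("A", "B", "C")))]
        rng = np.random.default_rng(7)
        data = binary_matrix({g: rng.integers(2, size=5).tolist() for g in "ABC"})
        R = compute_activity_matrix(families, data)
        dm = distance_matrix(R)
        assert np.array_equal(dm.values, dm.values.T)
        for i, si in enumerate(R.sample_ids):
            for j, sj in enumerate(R.sample_ids):
                assert dm.values[i, j] == pytest.approx(
                    pavd(R.pav(si), R.pav(sj)), abs=1e-12
                )

    def test_triangle_inequality_on_all_triples(self):
        rng = np.random.default_rng(8)
        n = 8
        R = ActivityMatrix(
            ["P1", "P2"], [f"s{i}" for i in range(n)],
            {"P1": ("a", "b", "c"), "P2": ("a", "b")},
            {"P1": rng.dirichlet(np.ones(3), n), "P2": rng.dirichlet(np.ones(2), n)},
        )
        V = distance_matrix(R).values
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert V[i, k] <= V[i, j] + V[j, k] + 1e-9


class TestGroupAverage:
    def test_single_member_group_is_identity(self):
        R = ActivityMatrix(
            ["P"], ["s0", "s1"], {"P": ("a", "b")},
            {"P": np.array([[0.2, 0.8], [0.6, 0.4]])},
        )
        avg = group_average_distribution(R, "P", ["s1"])
        assert avg.probs == pytest.approx([0.6, 0.4], abs=1e-12)

    def test_mean_of_point_masses(self):
        R = ActivityMatrix(
            ["P"], ["s0", "s1"], {"P": ("a", "b")},
            {"P": np.array([[1.0, 0.0], [0.0, 1.0]])},
        )
        avg = group_average_distribution(R, "P", ["s0", "s1"])
        assert avg.probs == pytest.approx([0.5, 0.5], abs=1e-12)

    def test_empty_group_rejected(self):
        R = ActivityMatrix(["P"], ["s0"], {"P": ("a", "b")},
                           {"P": np.array([[0.5, 0.5]])})
        with pytest.raises(ValueError, match="empty"):
            group_average_distribution(R, "P", [])


def test_simulation_grounded_attribution(ab_family):
    """A strongly coupled pair in a mostly-decoupled cohort: the samples whose
    mechanism keeps the edge give Normal the majority of probability mass."""
    from pavd.networks import PathwayNetwork

    pathway = PathwayNetwork("p", ("A", "B"), (("A", "B"),))
    spec = SyntheticCohortSpec(
        pathways=[pathway],
        group_mechanisms={"coupled": {}, "decoupled": {"p": ("A", "B")}},
        group_sizes={"coupled": 30, "decoupled": 170},
        beta=0.95,
        seed=12,
    )
    data, labels, _, _ = sample_cohort(spec)
    R = compute_activity_matrix([ab_family], data, ScoreConfig())
    coupled_ids = [s for s in data.sample_ids if labels[s] == "coupled"]
    avg = group_average_distribution(R, "p", coupled_ids)
    assert avg.modal_candidate() == "Normal"
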