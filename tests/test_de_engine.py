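import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, nbinom

from coreresponse import de_engine
from coreresponse.data_io import CountMatrix, build_design
from coreresponse.de_engine import (
    bh_adjust,
    estimate_dispersion,
    exact_nb_test,
    run_all_contrasts,
)
from coreresponse.normalization import tmm_factors, unit_factors
from coreresponse.synthetic_data import simulate_two_group


def _bh_oracle(p):
    """Literal step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    best = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        best = min(best, p[i] * m / (rank + 1))
        q[i] = best
    return np.array(q)


class TestBH:
    def test_worked_examples(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bh_adjust([0.005, 0.1, 0.9]), [0.015, 0.15, 0.9])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_on_random_vectors(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(rng.integers(1, 200))
        assert np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_properties_hold_on_arbitrary_vectors(self, p):
        """q matches the brute-force step-up, never drops below p, stays in
        [0, 1], and preserves the ordering of p-values."""
        p = np.array(p)
        q = bh_adjust(p)
        assert np.allclose(q, _bh_oracle(p), atol=1e-12)
        assert np.all(q >= p - 1e-12) and np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


def _exact_oracle_enumeration(s_a, s_b, n_a, n_b, phi):
    """Exhaustive conditional enumeration over all splits of s = s_a + s_b.

    Group sums are NB with means proportional to replicate numbers and
    dispersion phi/n (phi=0: Poisson, conditionally binomial).
    """
    s = s_a + s_b
    t = np.arange(s + 1)
    m_a = s * n_a / (n_a + n_b)
    m_b = s - m_a
    if phi == 0:
        pr = binom.pmf(t, s, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / phi, n_b / phi
        pa = nbinom.pmf(t, r_a, r_a / (r_a + m_a))
        pb = nbinom.pmf(s - t, r_b, r_b / (r_b + m_b))
        pr = pa * pb
        pr = pr / pr.sum()
    obs = pr[s_a]
    return min(1.0, float(pr[pr <= obs * (1 + 1e-12)].sum()))


class TestExactTest:
    def test_balanced_identical_sums_give_p_one(self):
        libs = np.full(3, 1e6)
        p = exact_nb_test([10, 12, 8], [11, 9, 10], libs, libs, phi=0.1)
        assert p == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        la, lb = np.full(2, 2e6), np.full(4, 2e6)
        p1 = exact_nb_test([40, 45], [10, 12, 9, 8], la, lb, phi=0.05)
        p2 = exact_nb_test([10, 12, 9, 8], [40, 45], lb, la, phi=0.05)
        assert p1 == pytest.approx(p2, rel=1e-9)

    @pytest.mark.parametrize("seed", range(30))
    def test_poisson_limit_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = int(rng.integers(1, 4)), int(rng.integers(1, 5))
        s_a = int(rng.integers(0, 26))
        s_b = int(rng.integers(0, 26 - 0))
        p_fast = de_engine._exact_test_from_sums(s_a, s_b, n_a, n_b, 0.0)
        p_oracle = _exact_oracle_enumeration(s_a, s_b, n_a, n_b, 0.0)
        assert p_fast == pytest.approx(p_oracle, abs=1e-10)

    @pytest.mark.parametrize("phi", [0.05, 0.2, 1.0])
    def test_nb_case_matches_enumeration(self, phi):
        rng = np.random.default_rng(int(phi * 100))
        for _ in range(10):
            s_a, s_b = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            p_fast = de_engine._exact_test_from_sums(s_a, s_b, 3, 9, phi)
            p_oracle = _exact_oracle_enumeration(s_a, s_b, 3, 9, phi)
            assert p_fast == pytest.approx(p_oracle, rel=1e-8, abs=1e-12)

    def test_input_validation(self):
        libs = np.full(2, 1e6)
        with pytest.raises(ValueError, match="non-negative"):
            exact_nb_test([-1, 2], [1, 2], libs, libs, 0.1)
        with pytest.raises(ValueError, match="dispersion"):
            exact_nb_test([1, 2], [1, 2], libs, libs, -0.1)


class TestDispersion:
    def test_poisson_counts_give_near_zero_dispersion(self):
        counts, samples, _ = simulate_two_group(2000, 3, 3, 1e6, phi=0.0, seed=0)
        design = build_design(counts, samples)
        d = estimate_dispersion(counts, design, unit_factors(counts))
        assert np.median(d.phi) <= 0.05

    def test_nb_dispersion_recovered(self):
        counts, samples, _ = simulate_two_group(2000, 3, 9, 1e6, phi=0.2, seed=1)
        design = build_design(counts, samples)
        d = estimate_dispersion(counts, design, unit_factors(counts))
        assert 0.1 <= np.median(d.phi) <= 0.3
        assert 0.1 <= d.phi_median <= 0.3

    def test_constant_counts_give_zero_raw(self):
        counts = CountMatrix(
            ["g0", "g1"],
            ["a1", "a2", "a3"],
            np.array([[7, 7, 7], [100, 100, 100]]),
        )
        from coreresponse.data_io import SampleRecord

        samples = [
            SampleRecord(f"a{i}", "UC", "unchallenged", "none", "none", 12.0, i)
            for i in (1, 2, 3)
        ]
        design = build_design(counts, samples)
        d = estimate_dispersion(counts, design, unit_factors(counts))
        assert np.all(d.phi_raw == 0.0)

    def test_requires_replicates(self):
        counts, samples, _ = simulate_two_group(50, 1, 1, 1e5, phi=0.1, seed=2)
        from coreresponse.data_io import Design

        design = Design(samples=samples, contrasts=[("Tr", 12.0)], control_pool=["UC_r1"])
        with pytest.raises(ValueError, match="replicate"):
            estimate_dispersion(counts, design, unit_factors(counts))


class TestRunAllContrasts:
    def test_flag_semantics_and_direction(self, small_experiment):
        de = small_experiment["de"]
        fdr = 0.05
        assert ((de["q"] < fdr) == de["de"]).all()
        flagged = de[de["de"]]
        assert (
            np.sign(flagged["log2fc"]).replace({1.0: "up", -1.0: "down"})
            == flagged["direction"]
        ).all()
        assert (de.loc[~de["de"], "direction"] == "none").all()
        # q >= p after BH step-up never decreases below the raw p
        assert (de["q"] >= de["p"] - 1e-12).all()

    def test_log2fc_monotone_in_a_single_count(self):
        base = np.array([[50, 60, 55, 50, 52, 48], [500, 480, 510, 505, 495, 500]])
        lfcs = []
        for bump in (0, 40, 80):
            y = base.copy()
            y[0, 0] += bump
            cm = CountMatrix(["g0", "g1"], [f"s{i}" for i in range(6)], y)
            from coreresponse.data_io import SampleRecord

            samples = [
                SampleRecord(f"s{i}", "Tr" if i < 3 else "UC",
                             "live" if i < 3 else "unchallenged",
                             "DAP" if i < 3 else "none",
                             "low" if i < 3 else "none", 12.0, i % 3 + 1)
                for i in range(6)
            ]
            design = build_design(cm, samples)
            disp = estimate_dispersion(cm, design, unit_factors(cm))
            tab = run_all_contrasts(cm, design, unit_factors(cm), disp)
            lfcs.append(float(tab.loc[tab["gene"] == "g0", "log2fc"].iloc[0]))
        assert lfcs[0] < lfcs[1] < lfcs[2]

    def test_null_pvalues_uniform(self):
        """Global null: p-values super-uniform/uniform, almost nothing flagged."""
        counts, samples, _ = simulate_two_group(1500, 3, 9, 1e6, phi=0.2, seed=3)
        design = build_design(counts, samples)
        factors = tmm_factors(counts)
        disp = estimate_dispersion(counts, design, factors)
        tab = run_all_contrasts(counts, design, factors, disp)
        from scipy.stats import kstest

        assert kstest(tab["p"], "uniform").statistic < 0.05
        assert tab["de"].mean() <= 0.01
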