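import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import evometab as em


def brute_force_poisson_binomial(p):
    """Independent oracle: enumerate all 2^n Bernoulli outcomes."""
    n = len(p)
    pmf = np.zeros(n + 1)
    for bits in itertools.product([0, 1], repeat=n):
        pr = 1.0
        for pi, b in zip(p, bits):
            pr *= pi if b else 1.0 - pi
        pmf[sum(bits)] += pr
    return pmf


# -- Poisson binomial / SINIB -----------------------------------------------

def test_pmf_all_zero_probabilities():
    assert em.poisson_binomial_pmf(np.zeros(12)).tolist() == [1.0] + [0.0] * 12


def test_pmf_reduces_to_binomial():
    from math import comb

    pmf = em.poisson_binomial_pmf([0.5] * 12)
    expected = np.array([comb(12, k) / 4096 for k in range(13)])
    np.testing.assert_allclose(pmf, expected, atol=1e-12)


def test_pmf_matches_enumeration_frozen_example():
    pmf = em.poisson_binomial_pmf([0.1, 0.2, 0.3])
    np.testing.assert_allclose(pmf, brute_force_poisson_binomial([0.1, 0.2, 0.3]), atol=1e-15)
    np.testing.assert_allclose(pmf, [0.504, 0.398, 0.092, 0.006], atol=5e-4)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_pmf_matches_enumeration_property(p):
    np.testing.assert_allclose(
        em.poisson_binomial_pmf(p), brute_force_poisson_binomial(p), atol=1e-12
    )


def test_pmf_sums_to_one_and_mean_is_sum_p():
    rng = np.random.default_rng(0)
    p = rng.random(12)
    dist = em.poisson_binomial(p)
    assert dist.pmf.sum() == pytest.approx(1.0, abs=1e-12)
    assert (dist.pmf >= 0).all()
    assert float(np.arange(13) @ dist.pmf) == pytest.approx(dist.mean, abs=1e-9)


def test_probabilities_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        em.poisson_binomial_pmf([0.2, 1.2])


def test_sinib_general_case_matches_enumeration():
    sizes, p = (2, 3), (0.3, 0.6)
    pmf = em.sinib_pmf(sizes, p)
    brute = np.zeros(sum(sizes) + 1)
    for k1 in range(sizes[0] + 1):
        for k2 in range(sizes[1] + 1):
            brute[k1 + k2] += stats.binom.pmf(k1, sizes[0], p[0]) * stats.binom.pmf(
                k2, sizes[1], p[1]
            )
    np.testing.assert_allclose(pmf, brute, atol=1e-12)


def test_sinib_unit_sizes_equal_poisson_binomial():
    p = [0.1, 0.5, 0.9, 0.3]
    np.testing.assert_allclose(
        em.sinib_pmf([1] * 4, p), em.poisson_binomial_pmf(p), atol=1e-12
    )


# -- Spearman pairs ----------------------------------------------------------

def test_identical_and_reversed_profiles():
    vals = np.arange(10.0)
    rows = []
    for li, v in (("A+1", vals), ("A+2", vals), ("A+3", vals[::-1])):
        for i, x in enumerate(v):
            rows.append((f"c{i}", "pos", li, "exponential", 2.0**x, x))
    tiny = pd.DataFrame(rows, columns=["compound", "ion_mode", "line_id", "phase", "fc", "log2fc"])
    pairs = em.spearman_pairs(tiny, "exponential").set_index(["line_a", "line_b"])
    assert pairs.loc[("A+1", "A+2"), "rho"] == pytest.approx(1.0)
    assert pairs.loc[("A+1", "A+3"), "rho"] == pytest.approx(-1.0)


def test_spearman_matches_rank_then_pearson_oracle():
    rng = np.random.default_rng(3)
    rows = []
    vecs = {}
    for li in ["A+1", "A-2", "A-4"]:
        v = rng.normal(size=5)
        vecs[li] = v
        for i, x in enumerate(v):
            rows.append((f"c{i}", "pos", li, "exponential", 2.0**x, x))
    fct = pd.DataFrame(rows, columns=["compound", "ion_mode", "line_id", "phase", "fc", "log2fc"])
    pairs = em.spearman_pairs(fct, "exponential").set_index(["line_a", "line_b"])
    for a, b in itertools.combinations(vecs, 2):
        ra, rb = stats.rankdata(vecs[a]), stats.rankdata(vecs[b])
        oracle = np.corrcoef(ra, rb)[0, 1]
        key = (a, b) if (a, b) in pairs.index else (b, a)
        assert pairs.loc[key, "rho"] == pytest.approx(oracle, abs=1e-12)


def test_constant_profile_recorded_as_nan():
    rows = []
    for li, v in (("A+1", [1.0] * 5), ("A+2", [1, 2, 3, 4, 5])):
        for i, x in enumerate(v):
            rows.append((f"c{i}", "pos", li, "exponential", 2.0**x, float(x)))
    fct = pd.DataFrame(rows, columns=["compound", "ion_mode", "line_id", "phase", "fc", "log2fc"])
    with pytest.warns(UserWarning, match="undefined"):
        pairs = em.spearman_pairs(fct, "exponential")
    assert pairs["rho"].isna().all()


def test_pair_count_is_n_choose_2(noise_fct_factory):
    pairs = em.spearman_pairs(noise_fct_factory(0, n_features=30), "exponential")
    assert len(pairs) == 66


# -- permutation null --------------------------------------------------------

def test_null_mean_near_zero(noise_fct_factory):
    res = em.permutation_null(noise_fct_factory(5), "exponential", n_permutations=300, seed=1)
    sd = res.null_rhos.std() / np.sqrt(res.null_rhos.shape[0])
    assert abs(res.mean_null) < max(3 * sd, 5e-3)


def test_planted_parallelism_detected(noise_fct_factory):
    fct = noise_fct_factory(6, planted_frac=0.25)
    res = em.permutation_null(fct, "exponential", n_permutations=500, seed=2)
    assert res.mean_observed > np.quantile(res.null_rhos.mean(axis=1), 0.999)
    assert res.p_value <= 1e-4
    assert res.p_empirical <= 0.01


def test_permutation_seed_determinism(noise_fct_factory):
    fct = noise_fct_factory(7)
    a = em.permutation_null(fct, "exponential", n_permutations=50, seed=9)
    b = em.permutation_null(fct, "exponential", n_permutations=50, seed=9)
    np.testing.assert_array_equal(a.null_rhos, b.null_rhos)
    assert a.p_value == b.p_value


def test_null_shape_matches_b_and_pairs(noise_fct_factory):
    res = em.permutation_null(noise_fct_factory(8), "exponential", n_permutations=25, seed=0)
    assert res.null_rhos.shape == (25, 66)


# -- phase contrast ----------------------------------------------------------

def _fake_result(rhos, phase):
    pairs = pd.DataFrame(
        {"line_a": "x", "line_b": "y", "rho": np.asarray(rhos, dtype=float)}
    )
    return em.CorrelationNullResult(
        phase=phase,
        pairs=pairs,
        null_rhos=np.zeros((1, len(rhos))),
        t_stat=0.0,
        p_value=1.0,
        p_empirical=1.0,
        mean_observed=float(np.mean(rhos)),
        mean_null=0.0,
    )


def test_phase_contrast_identical_inputs():
    rhos = np.linspace(0.1, 0.6, 66)
    out = em.phase_contrast(_fake_result(rhos, "exponential"), _fake_result(rhos, "stationary"))
    assert out["difference"] == pytest.approx(0.0)
    assert out["p_value"] == pytest.approx(1.0)
    assert "mean_rho_exponential" in out and "mean_rho_stationary" in out


def test_phase_contrast_power_at_gap_030():
    """A 0.3 mean-rho gap over 66 pairs is detected at p<0.001 nearly always."""
    rng = np.random.default_rng(0)
    hits = 0
    n_rep = 40
    for _ in range(n_rep):
        exp = np.clip(rng.normal(0.5, 0.15, 66), -1, 1)
        sta = np.clip(rng.normal(0.2, 0.15, 66), -1, 1)
        out = em.phase_contrast(_fake_result(exp, "exponential"), _fake_result(sta, "stationary"))
        hits += out["p_value"] < 1e-3
    assert hits >= 0.95 * n_rep


# -- within/across phase sample correlations ---------------------------------

def test_within_phase_correlations_exceed_across(default_pipeline):
    imputed = default_pipeline[2]
    res = em.within_across_phase_correlations(imputed)
    assert res["median_within"] > res["median_across"]
    assert res["mannwhitney_p"] < 1e-3


def test_single_phase_flagged():
    pt, _ = em.simulate_peak_table(
        em.SimulationConfig(
            n_compounds=20, phases=("exponential",), parallel_spec=(), censor_quantile=0.0, seed=3
        )
    )
    imputed = em.preprocess(pt, impute_seed=1)
    res = em.within_across_phase_correlations(imputed)
    assert res["single_phase"]
    assert np.isnan(res["median_across"])


def test_no_phase_structure_when_shift_zero():
    pt, _ = em.simulate_peak_table(
        em.SimulationConfig(
            n_compounds=120,
            parallel_spec=(),
            background_effect_sd=0.0,
            phase_shift_sd=0.0,
            censor_quantile=0.0,
            seed=6,
        )
    )
    imputed = em.preprocess(pt, impute_seed=1)
    res = em.within_across_phase_correlations(imputed)
    assert abs(res["median_within"] - res["median_across"]) < 0.05


# -- line probabilities and spectrum ----------------------------------------

def _calls_from_matrix(up_matrix, lines):
    """Build a calls table from a features x lines boolean 'up' matrix."""
    rows = []
    for i, row in enumerate(np.asarray(up_matrix)):
        for j, li in enumerate(lines):
            lfc = 1.5 if row[j] else 0.0
            rows.append((f"c{i}", "pos", li, "exponential", 2.0**lfc, lfc,
                         "up" if row[j] else "none"))
    return pd.DataFrame(
        rows,
        columns=["compound", "ion_mode", "line_id", "phase", "fc", "log2fc", "direction"],
    )


def test_line_probabilities_arithmetic():
    lines = list(em.EVOLVED_LINES)
    mat = np.zeros((300, 12), dtype=bool)
    mat[:30, 0] = True  # 30 of 300 features up in the first line
    calls = _calls_from_matrix(mat, lines)
    p = em.line_probabilities(calls, "exponential", "up", lines=lines)
    assert p.iloc[0] == pytest.approx(0.1)
    assert (p.iloc[1:] == 0).all()


def test_line_probabilities_match_recount(default_pipeline):
    *_, calls = default_pipeline
    p = em.line_probabilities(calls, "stationary", "down")
    sel = calls[calls["phase"] == "stationary"]
    for li in p.index:
        grp = sel[sel["line_id"] == li]
        assert p[li] == pytest.approx((grp["direction"] == "down").mean())


def test_spectrum_no_calls_all_mass_at_zero():
    lines = list(em.EVOLVED_LINES)
    calls = _calls_from_matrix(np.zeros((50, 12), dtype=bool), lines)
    spec = em.parallelism_spectrum(calls, "exponential", "up", lines=lines)
    assert spec.observed[0] == spec.n_features == 50
    assert spec.expected[0] == pytest.approx(50.0)


def test_spectrum_conservation(default_pipeline):
    *_, calls = default_pipeline
    for phase in em.PHASES:
        for direction in ("up", "down"):
            spec = em.parallelism_spectrum(calls, phase, direction)
            assert spec.observed.sum() == spec.n_features
            assert spec.expected.sum() == pytest.approx(spec.n_features, abs=1e-6)


def test_spectrum_counts_exact_k():
    lines = list(em.EVOLVED_LINES)
    mat = np.zeros((40, 12), dtype=bool)
    mat[:7, :5] = True  # 7 features shared up in exactly 5 lines
    calls = _calls_from_matrix(mat, lines)
    spec = em.parallelism_spectrum(calls, "exponential", "up", lines=lines)
    assert spec.observed[5] == 7
    assert spec.observed[0] == 33


def test_cluster_lines_returns_all_lines(noise_fct_factory):
    pairs = em.spearman_pairs(noise_fct_factory(2, n_features=40), "exponential")
    order, linkage = em.cluster_lines(pairs)
    assert sorted(order) == sorted(em.EVOLVED_LINES)
    assert linkage.shape == (11, 4)
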