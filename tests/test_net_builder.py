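"""Network construction: amplitude sampling, calibration, topology, ablation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import integrate, stats

from ssrnet import (
    EXCITATORY,
    LogNormalEpspSpec,
    NetworkSpec,
    ParameterError,
    build_network,
    calibrate_single_epsp,
    epsp_to_conductance,
    remove_strong_synapses,
    sample_epsp_amplitudes,
)
from ssrnet.streams import stream_rng, EPSP_AMPLITUDES


def lognormal_pdf(x, mu, sigma):
    """The printed log-normal density, used as an independent quadrature oracle."""
    return np.exp(-((np.log(x) - mu) ** 2) / (2 * sigma**2)) / (
        np.sqrt(2 * np.pi) * sigma * x
    )


def truncated_mass(lo, hi, spec):
    """Probability mass of the density on [lo, hi], normalized to (0, vmax]."""
    num, _ = integrate.quad(lognormal_pdf, lo, hi, args=(spec.mu, spec.sigma))
    den, _ = integrate.quad(lognormal_pdf, 1e-12, spec.vmax_mv, args=(spec.mu, spec.sigma))
    return num / den


class TestEpspSampling:
    def test_empty_draw(self, epsp_spec, rng):
        assert len(sample_epsp_amplitudes(0, epsp_spec, rng)) == 0

    def test_bounds_and_reproducibility(self, epsp_spec):
        a = sample_epsp_amplitudes(5000, epsp_spec, stream_rng(7, EPSP_AMPLITUDES))
        b = sample_epsp_amplitudes(5000, epsp_spec, stream_rng(7, EPSP_AMPLITUDES))
        c = sample_epsp_amplitudes(5000, epsp_spec, stream_rng(8, EPSP_AMPLITUDES))
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
        assert np.all(a > 0) and np.all(a <= epsp_spec.vmax_mv)

    def test_density_mode_is_0p2_mv(self, epsp_spec):
        """argmax of the density with sigma=1, mu=ln(0.2)+1 sits at 0.2 mV."""
        x = np.linspace(0.01, 2.0, 200000)
        argmax = x[np.argmax(lognormal_pdf(x, epsp_spec.mu, epsp_spec.sigma))]
        assert argmax == pytest.approx(0.2, abs=1e-4)
        assert math.exp(epsp_spec.mu - epsp_spec.sigma**2) == pytest.approx(0.2)

    def test_sample_distribution_ks(self, epsp_spec, rng):
        """KS test of 1e5 samples against the truncated CDF at alpha=0.01."""
        sample = sample_epsp_amplitudes(100_000, epsp_spec, rng)
        res = stats.kstest(sample, epsp_spec.truncated_cdf)
        assert res.pvalue > 0.01

    def test_strong_tail_fraction_matches_quadrature(self, epsp_spec, rng):
        """Fraction above 9 mV agrees with quadrature of the density on (9, 20]."""
        n = 1_000_000
        sample = sample_epsp_amplitudes(n, epsp_spec, rng)
        frac = float((sample > 9.0).mean())
        expected = truncated_mass(9.0, epsp_spec.vmax_mv, epsp_spec)
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(frac - expected) < 3 * se

    def test_invalid_spec_rejected(self):
        with pytest.raises(ParameterError):
            LogNormalEpspSpec(sigma=0.0)
        with pytest.raises(ParameterError):
            LogNormalEpspSpec(mode_mv=-1.0)


class TestConductanceCalibration:
    def test_division_rule(self):
        assert epsp_to_conductance(1.0) == pytest.approx(0.01)
        assert epsp_to_conductance(0.2) == pytest.approx(0.002)
        assert epsp_to_conductance(20.0) == pytest.approx(0.2)
        with pytest.raises(ParameterError):
            epsp_to_conductance(0.0)

    def test_zero_weight_stays_at_rest(self):
        assert calibrate_single_epsp(0.0) == 0.0

    def test_peak_matches_linearized_closed_form(self):
        """For a small conductance the peak depolarization has the closed form
        (V_E - V_L) G (e^{-t*/tau_m} - e^{-t*/tau_s}) / (1/tau_s - 1/tau_m),
        t* = ln(tau_m/tau_s) / (1/tau_s - 1/tau_m)."""
        p = EXCITATORY
        g = 0.002
        k = 1.0 / p.tau_s - 1.0 / p.tau_m
        t_star = math.log(p.tau_m / p.tau_s) / k
        analytic = (
            (p.v_exc - p.v_leak) * g
            * (math.exp(-t_star / p.tau_m) - math.exp(-t_star / p.tau_s)) / k
        )
        peak = calibrate_single_epsp(g, dt=0.001)
        assert peak == pytest.approx(analytic, rel=0.02)
        # nominal 0.2 mV EPSP reproduced within 15 %
        assert peak == pytest.approx(0.2, rel=0.15)

    def test_v_over_100_rule_within_15_percent(self):
        """The V/100 conductance rule matches the ODE peak within 15 % over
        the physiological range [0.1, 10] mV."""
        for v_epsp in [0.1, 0.3, 1.0, 3.0, 10.0]:
            peak = calibrate_single_epsp(epsp_to_conductance(v_epsp), dt=0.01)
            assert abs(peak - v_epsp) / v_epsp <= 0.15

    def test_calibration_curve_monotone_sublinear(self):
        weights = np.linspace(0.001, 0.12, 12)
        peaks = np.array([calibrate_single_epsp(w, dt=0.01) for w in weights])
        assert np.all(np.diff(peaks) > 0)
        # sub-linear near threshold: gain per unit weight decreases
        gains = peaks / weights
        assert gains[-1] < gains[0]


class TestBuildNetwork:
    def test_empty_when_probability_zero(self):
        spec = NetworkSpec(n_total=50, ei_ratio=(40, 10), p_conn_exc=0.0, p_conn_inh=0.0)
        assert len(build_network(spec, seed=0)) == 0

    def test_outgoing_density_matches_probability(self):
        spec = NetworkSpec(n_total=300, ei_ratio=(240, 60))
        table = build_network(spec, seed=1)
        df = table.df
        e_rows = df[df.pre_id < 240]
        n_pairs = 240 * 299
        p_hat = len(e_rows) / n_pairs
        se = math.sqrt(0.1 * 0.9 / n_pairs)
        assert abs(p_hat - 0.1) < 3 * se
        i_rows = df[df.pre_id >= 240]
        n_pairs = 60 * 299
        p_hat = len(i_rows) / n_pairs
        se = math.sqrt(0.5 * 0.5 / n_pairs)
        assert abs(p_hat - 0.5) < 3 * se

    def test_failure_probability_identity(self):
        spec = NetworkSpec(n_total=120, ei_ratio=(100, 20))
        table = build_network(spec, seed=2)
        ee = table.rows("EE")
        np.testing.assert_allclose(
            ee.p_fail * (spec.a_mv + ee.epsp_mv), spec.a_mv, rtol=1e-14
        )
        np.testing.assert_allclose(ee.weight, ee.epsp_mv / 100.0, rtol=1e-14)

    def test_table_invariants(self):
        spec = NetworkSpec(n_total=150, ei_ratio=(120, 30))
        table = build_network(spec, seed=3)
        df = table.df
        assert (df.pre_id != df.post_id).all()
        assert not df.duplicated(["pre_id", "post_id"]).any()
        ee = df.class_pair == "EE"
        assert df.delay_ms[ee].between(1, 3).all()
        assert df.delay_ms[~ee].between(0, 2).all()
        assert (df.p_fail[~ee] == 0).all()
        assert df.epsp_mv[~ee].isna().all()
        # fixed cross-class weights
        assert (df.weight[df.class_pair == "EI"] == spec.g_ei).all()
        assert (df.weight[df.class_pair == "IE"] == spec.g_ie).all()
        assert (df.weight[df.class_pair == "II"] == spec.g_ii).all()

    def test_deterministic_under_stream(self):
        spec = NetworkSpec(n_total=80, ei_ratio=(64, 16))
        a = build_network(spec, seed=9, trial=0)
        b = build_network(spec, seed=9, trial=0)
        c = build_network(spec, seed=9, trial=1)
        assert a.equals(b)
        assert not a.equals(c)

    @given(
        n_e=st.integers(5, 40),
        n_i=st.integers(2, 15),
        p_e=st.floats(0.0, 1.0),
        p_i=st.floats(0.0, 1.0),
        seed=st.integers(0, 1000),
    )
    def test_invariants_hold_for_random_specs(self, n_e, n_i, p_e, p_i, seed):
        spec = NetworkSpec(
            n_total=n_e + n_i, ei_ratio=(n_e, n_i), p_conn_exc=p_e, p_conn_inh=p_i
        )
        table = build_network(spec, seed=seed)
        df = table.df
        assert (df.pre_id != df.post_id).all()
        assert not df.duplicated(["pre_id", "post_id"]).any()
        ee = df.class_pair == "EE"
        assert df.delay_ms[ee].between(1, 3).all()
        assert df.delay_ms[~ee].between(0, 2).all()
        if ee.any():
            np.testing.assert_allclose(
                df.p_fail[ee] * (spec.a_mv + df.epsp_mv[ee]), spec.a_mv, rtol=1e-12
            )

    def test_roundtrip_tsv(self, tmp_path):
        spec = NetworkSpec(n_total=40, ei_ratio=(32, 8))
        table = build_network(spec, seed=4)
        path = tmp_path / "net.tsv"
        table.write_tsv(path)
        back = table.read_tsv(path)
        assert back.n_e == 32 and back.n_i == 8
        np.testing.assert_allclose(back.df.weight, table.df.weight)
        np.testing.assert_array_equal(back.df.pre_id, table.df.pre_id)


class TestRemoveStrong:
    def test_identity_when_no_strong_rows(self):
        spec = NetworkSpec(n_total=40, ei_ratio=(30, 10))
        table = build_network(spec, seed=5)
        # force all amplitudes below threshold
        table.df.loc[table.df.class_pair == "EE", "epsp_mv"] = 0.5
        out = remove_strong_synapses(table, 9.0)
        assert out.equals(table)

    def test_idempotent(self):
        spec = NetworkSpec(n_total=200, ei_ratio=(160, 40))
        table = build_network(spec, seed=6)
        once = remove_strong_synapses(table, 9.0)
        twice = remove_strong_synapses(once, 9.0)
        assert once.equals(twice)
        assert not (once.df.epsp_mv > 9.0).any()
        # non-EE rows untouched
        assert (once.df.class_pair != "EE").sum() == (table.df.class_pair != "EE").sum()

    def test_removed_count_matches_tail_mass(self, epsp_spec):
        """Mean strong synapses per excitatory neuron ~ (N_E-1) p * tail mass."""
        spec = NetworkSpec(n_total=2500, ei_ratio=(2000, 500))
        table = build_network(spec, seed=7)
        removed = len(table) - len(remove_strong_synapses(table, 9.0))
        expected_per_neuron = (
            (spec.n_e - 1) * spec.p_conn_exc
            * truncated_mass(9.0, epsp_spec.vmax_mv, epsp_spec)
        )
        expected = expected_per_neuron * spec.n_e
        se = math.sqrt(expected)  # ~Poisson count of rare tail rows
        assert abs(removed - expected) < 4 * se

    def test_build_with_ablation_flag(self):
        spec = NetworkSpec(n_total=400, ei_ratio=(320, 80), remove_strong=True)
        table = build_network(spec, seed=8)
        assert not (table.df.epsp_mv > 9.0).any()
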