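"""Synthetic cohort generator: label fidelity, reproducibility, and the
flow-to-vibration coupling law."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from vibrouroflow import (CohortSpec, FlowCurve, PatternLabel,
                          REFERENCE_CLASS_COUNTS, classify_pattern,
                          compute_rms_envelope, generate_cohort,
                          simulate_flow_curve, simulate_vibration)
from vibrouroflow.errors import UnsatisfiableSpecError
from vibrouroflow.synthetic import _filter_power_gain


@pytest.mark.parametrize("label", list(PatternLabel))
def test_generated_curves_satisfy_their_own_label(label):
    rng = np.random.default_rng(55)
    for _ in range(5):
        curve = simulate_flow_curve(label, rng)
        assert classify_pattern(curve) == label


def test_fixed_seed_reproduces_curves_exactly():
    a = simulate_flow_curve(PatternLabel.NORMAL, np.random.default_rng(9))
    b = simulate_flow_curve(PatternLabel.NORMAL, np.random.default_rng(9))
    assert a.dt == b.dt
    assert np.array_equal(a.flow, b.flow)


def test_contradictory_overrides_are_unsatisfiable():
    # a normal-class curve cannot have Qmax 5 (the rule demands >= 15)
    with pytest.raises(UnsatisfiableSpecError):
        simulate_flow_curve(PatternLabel.NORMAL, np.random.default_rng(0),
                            params={"qmax": 5.0})


def test_qmax_override_is_honored():
    c = simulate_flow_curve(PatternLabel.NORMAL, np.random.default_rng(1),
                            params={"qmax": 22.0})
    # resampling the template to the curve grid can shave the peak slightly
    assert c.flow.max() == pytest.approx(22.0, rel=0.01)


class TestCohort:
    def test_reference_distribution_counts(self, reference_cohort):
        _, cohort = reference_cohort
        counts = {k: sum(1 for s in cohort if int(s.label) == k)
                  for k in range(6)}
        assert counts == REFERENCE_CLASS_COUNTS
        assert len(cohort) == 76

    def test_single_session_cohort(self):
        cohort = generate_cohort(CohortSpec(class_counts={4: 1}, seed=3))
        assert len(cohort) == 1
        assert cohort[0].label == PatternLabel.SAWTOOTH

    def test_same_seed_is_byte_identical(self, tmp_path):
        from vibrouroflow.io import save_cohort
        spec = CohortSpec(class_counts={0: 1, 3: 1}, seed=12)
        for d in ("a", "b"):
            save_cohort(tmp_path / d, generate_cohort(spec))
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()

    def test_cohort_parameters_within_clinical_ranges(self, reference_cohort):
        """Qmax, voided volume and voiding time all stay inside the
        reference study's printed ranges."""
        _, cohort = reference_cohort
        gp = [s.generator_params for s in cohort]
        assert all(4.0 <= p["qmax"] <= 50.0 for p in gp)
        assert all(50.0 <= p["voided_volume"] <= 690.0 for p in gp)
        assert all(4.0 <= p["voiding_time"] <= 62.0 for p in gp)


class TestVibrationCoupling:
    def test_zero_flow_yields_silence(self):
        spec = CohortSpec(class_counts={0: 1}, noise_snr_db=np.inf)
        flow = FlowCurve(dt=0.05, flow=np.zeros(100))
        v = simulate_vibration(flow, spec, np.random.default_rng(0))
        assert np.all(v.samples == 0)

    def test_constant_flow_envelope_matches_closed_form(self):
        """For constant flow Q the waveform is stationary modulated noise:
        the RMS envelope equals gain*Q (unit-normalized filters) and is
        constant within 5 % when averaged over >= 100 windows."""
        spec = CohortSpec(class_counts={0: 1}, noise_snr_db=np.inf)
        q = 30.0
        flow = np.full(1201, q)  # 60 s at dt = 0.05
        flow[0] = flow[-1] = 0
        v = simulate_vibration(FlowCurve(dt=0.05, flow=flow), spec,
                               np.random.default_rng(8))
        env = compute_rms_envelope(v)
        inside = (env.times > 2.0) & (env.times < 59.0)
        assert inside.sum() >= 100
        expected = spec.vibration.gain * q
        assert env.values[inside].mean() == pytest.approx(expected, rel=0.05)

    def test_doubling_flow_doubles_the_envelope(self):
        spec = CohortSpec(class_counts={0: 1}, noise_snr_db=np.inf)
        flow = np.full(401, 12.0)
        flow[0] = flow[-1] = 0
        v1 = simulate_vibration(FlowCurve(dt=0.05, flow=flow), spec,
                                np.random.default_rng(4))
        v2 = simulate_vibration(FlowCurve(dt=0.05, flow=2 * flow), spec,
                                np.random.default_rng(4))
        m1 = compute_rms_envelope(v1).values.max()
        m2 = compute_rms_envelope(v2).values.max()
        assert m2 == pytest.approx(2 * m1, rel=1e-6)

    def test_unit_power_normalization_of_filters(self):
        from scipy.signal import butter, iirpeak
        b, a = iirpeak(600 / 2000, 5)
        g = _filter_power_gain(b, a)
        assert g > 0
        sos = butter(4, [150 / 2000, 1800 / 2000], btype="bandpass",
                     output="sos")
        assert _filter_power_gain(sos) > 0

    def test_envelope_tracks_flow_rank_order(self, noiseless_cohort):
        """At infinite SNR the RMS envelope is monotonically related to the
        flow curve on every session (Spearman >= 0.95)."""
        _, cohort = noiseless_cohort
        for s in cohort:
            env = compute_rms_envelope(s.vibration)
            pad = s.generator_params["pad_s"]
            q = np.interp(env.times, s.flow.times + pad, s.flow.flow,
                          left=0.0, right=0.0)
            rho = spearmanr(q, env.values).statistic
            assert rho >= 0.95, s.session_id
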