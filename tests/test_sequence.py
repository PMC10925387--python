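"""Signal-simulation checks against closed forms and the EPG oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qmrinet.sequence import (
    IsochromatEnsemble,
    SequenceConfig,
    TissueParams,
    make_flip_schedule,
    signal_jacobian,
    simulate_fisp_epg,
    simulate_fisp_isochromat,
    slice_profile,
)


def one_pulse_seq(angle=np.pi / 2):
    """Single excitation after full recovery (TI >> T1, no inversion)."""
    return SequenceConfig(
        flip_schedule=np.array([angle]), ti=100.0, inversion_efficiency=0.0
    )


class TestFlipSchedule:
    @pytest.mark.parametrize(
        "descriptor, expected",
        [
            ([np.pi / 2], [np.pi / 2]),
            ({"kind": "constant", "length": 3, "angle": 0.0}, [0.0, 0.0, 0.0]),
        ],
    )
    def test_explicit_and_constant(self, descriptor, expected):
        assert np.allclose(make_flip_schedule(descriptor), expected)

    def test_sinusoidal_deterministic_and_bounded(self):
        d = {"kind": "sinusoidal", "length": 100, "max_angle": 1.2}
        a = make_flip_schedule(d)
        b = make_flip_schedule(d)
        assert np.array_equal(a, b)
        assert a.shape == (100,)
        assert a.min() >= 0 and a.max() <= 1.2 + 1e-12

    @pytest.mark.parametrize(
        "bad",
        [[], [4.0], [-0.1], {"kind": "nonsense", "length": 5}],
    )
    def test_rejects_invalid(self, bad):
        with pytest.raises(ValueError):
            make_flip_schedule(bad)


class TestSliceProfile:
    def test_degenerate_single_isochromat(self):
        ens = slice_profile(n_fwhm=1, n_total=1)
        assert ens.n_iso == 1
        assert ens.flip_scale[0] == 1.0

    def test_fwhm_points_are_half_maximum(self):
        ens = slice_profile(n_fwhm=601, n_total=1324)
        assert ens.flip_scale.max() == pytest.approx(1.0, abs=1e-6)
        for p in (-0.5, 0.5):
            i = int(np.argmin(np.abs(ens.positions - p)))
            assert ens.flip_scale[i] == pytest.approx(0.5, abs=1e-3)

    def test_paper_configuration_counts(self):
        ens = slice_profile(n_fwhm=600, n_total=1324)
        assert ens.n_iso == 1324
        inside = (ens.positions >= -0.5) & (ens.positions <= 0.5)
        assert inside.sum() == 600
        # spoiler span across the FWHM sub-population equals the nominal moment
        span = ens.phase_per_tr[inside].max() - ens.phase_per_tr[inside].min()
        assert span == pytest.approx(14.6 * np.pi, rel=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            slice_profile(time_bandwidth=-1.0)
        with pytest.raises(ValueError):
            slice_profile(n_fwhm=10, n_total=5)


class TestIsochromatSimulator:
    def test_zero_m0_and_zero_flips(self, short_seq, uniform_ensemble):
        fp = simulate_fisp_isochromat(
            TissueParams(1.0, 0.08, m0=0.0), short_seq, uniform_ensemble
        )
        assert np.all(fp.signal == 0)
        seq0 = SequenceConfig(flip_schedule=np.zeros(10))
        fp0 = simulate_fisp_isochromat(TissueParams(1.0, 0.08), seq0, uniform_ensemble)
        assert np.allclose(fp0.signal, 0)

    def test_one_pulse_closed_form(self):
        seq = one_pulse_seq()
        tis = TissueParams(1.0, 0.08, m0=2.0 - 1.0j)
        ens = IsochromatEnsemble.uniform_dephasing(1, 0.0)
        fp = simulate_fisp_isochromat(tis, seq, ens)
        assert abs(fp.signal[0]) == pytest.approx(
            abs(tis.m0) * np.exp(-seq.te / tis.t2), rel=1e-12
        )

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        re=st.floats(-3, 3, allow_nan=False),
        im=st.floats(-3, 3, allow_nan=False),
    )
    def test_linearity_in_m0(self, re, im):
        seq = SequenceConfig(flip_schedule=make_flip_schedule({"kind": "sinusoidal", "length": 20}))
        ens = IsochromatEnsemble.uniform_dephasing(16)
        base = simulate_fisp_isochromat(TissueParams(1.0, 0.08), seq, ens).signal
        c = re + 1j * im
        scaled = simulate_fisp_isochromat(TissueParams(1.0, 0.08, m0=c), seq, ens).signal
        assert np.allclose(scaled, c * base, atol=1e-14)

    def test_matches_epg_oracle(self, wm_tissue):
        seq = SequenceConfig(
            flip_schedule=make_flip_schedule({"kind": "sinusoidal", "length": 400})
        )
        ens = IsochromatEnsemble.uniform_dephasing(512)
        s_iso = simulate_fisp_isochromat(wm_tissue, seq, ens).signal
        s_epg = simulate_fisp_epg(wm_tissue, seq).signal
        rel_rms = np.linalg.norm(s_iso - s_epg) / np.linalg.norm(s_epg)
        assert rel_rms < 0.01

    def test_first_readout_monotone_in_recovery(self):
        """After ideal inversion, Mz at the first readout grows with TI/T1."""
        ens = IsochromatEnsemble.uniform_dephasing(1, 0.0)
        vals = []
        for ti in (0.02, 0.2, 0.5, 1.0, 3.0):
            seq = SequenceConfig(flip_schedule=np.array([np.pi / 2]), ti=ti)
            fp = simulate_fisp_isochromat(TissueParams(1.0, 0.08), seq, ens)
            vals.append(fp.signal[0].imag)  # proportional to Mz before the pulse
        assert np.all(np.diff(vals) > 0)


class TestEPG:
    def test_one_pulse_closed_form(self):
        seq = one_pulse_seq()
        fp = simulate_fisp_epg(TissueParams(1.0, 0.08), seq)
        assert abs(fp.signal[0]) == pytest.approx(np.exp(-seq.te / 0.08), rel=1e-12)

    def test_constant_flip_reaches_fisp_steady_state(self):
        """Long constant-flip train converges to the Freeman-Hill SSFP-FID value."""
        alpha, t1, t2, tr, te = np.deg2rad(30.0), 1.0, 0.08, 10e-3, 5e-3
        seq = SequenceConfig(flip_schedule=np.full(3000, alpha))
        s = simulate_fisp_epg(TissueParams(t1, t2), seq).signal
        e1, e2 = np.exp(-tr / t1), np.exp(-tr / t2)
        p = 1 - e1 * np.cos(alpha) - e2**2 * (e1 - np.cos(alpha))
        q = e2 * (1 - e1) * (1 + np.cos(alpha))
        r = (1 - e2**2) / np.sqrt(p**2 - q**2)
        expected = np.tan(alpha / 2) * (1 - (e1 - np.cos(alpha)) * r) * np.exp(-te / t2)
        assert abs(s[-1]) == pytest.approx(expected, rel=1e-6)


class TestJacobian:
    def test_m0_column_is_signal(self, short_seq, uniform_ensemble, wm_tissue):
        jac = signal_jacobian(wm_tissue, short_seq, uniform_ensemble)
        base = simulate_fisp_isochromat(wm_tissue, short_seq, uniform_ensemble).signal
        assert np.allclose(jac[:, 2], base)
        assert np.allclose(jac[:, 3], 1j * base)

    def test_t2_derivative_of_one_pulse_closed_form(self):
        seq = one_pulse_seq()
        tis = TissueParams(1.0, 0.008)
        ens = IsochromatEnsemble.uniform_dephasing(1, 0.0)
        jac = signal_jacobian(tis, seq, ens, params_to_differentiate=("t2",))
        expected = (seq.te / tis.t2**2) * np.exp(-seq.te / tis.t2)
        assert abs(jac[0, 0]) == pytest.approx(expected, rel=1e-6)

    def test_richardson_step_halving(self, short_seq, uniform_ensemble, wm_tissue):
        """Central differences: halving the step shrinks the error ~4x."""
        j_ref = signal_jacobian(wm_tissue, short_seq, uniform_ensemble, rel_step=1e-6)
        j_h = signal_jacobian(wm_tissue, short_seq, uniform_ensemble, rel_step=4e-3)
        j_h2 = signal_jacobian(wm_tissue, short_seq, uniform_ensemble, rel_step=2e-3)
        err_h = np.linalg.norm(j_h[:, :2] - j_ref[:, :2])
        err_h2 = np.linalg.norm(j_h2[:, :2] - j_ref[:, :2])
        assert err_h2 < err_h / 3.0  # O(step^2)

    def test_directional_consistency(self, short_seq, uniform_ensemble, wm_tissue):
        jac = signal_jacobian(wm_tissue, short_seq, uniform_ensemble)
        dt = np.array([1e-5, -2e-6])
        pert = TissueParams(wm_tissue.t1 + dt[0], wm_tissue.t2 + dt[1])
        ds = (
            simulate_fisp_isochromat(pert, short_seq, uniform_ensemble).signal
            - simulate_fisp_isochromat(wm_tissue, short_seq, uniform_ensemble).signal
        )
        assert np.allclose(ds, jac[:, :2] @ dt, atol=1e-9)

    def test_boundary_and_step_errors(self, short_seq, uniform_ensemble):
        with pytest.raises(ValueError):
            signal_jacobian(
                TissueParams(1.0, 1e-9), short_seq, uniform_ensemble, rel_step=1.0,
                params_to_differentiate=("t2",),
            )
        with pytest.raises(ValueError):
            signal_jacobian(
                TissueParams(1.0, 0.08), short_seq, uniform_ensemble, rel_step=0.0,
                params_to_differentiate=("t2",),
            )


def test_sequence_config_validation():
    with pytest.raises(ValueError):
        SequenceConfig(tr=1e-3, te=5e-3)
    with pytest.raises(ValueError):
        SequenceConfig(flip_schedule=np.array([]))
    with pytest.raises(ValueError):
        SequenceConfig(flip_schedule=np.array([3.5]))
    with pytest.warns(UserWarning):
        TissueParams(t1=0.1, t2=0.5)
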