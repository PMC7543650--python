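"""Architecture space, CMC dynamics, and spectral prediction properties."""

import numpy as np
import pytest

from siatdcm import cmc_forward as cmc
from siatdcm.errors import ConfigurationError, StabilityError


class TestModelSpace:
    def test_four_architectures(self, model_space):
        assert sorted(model_space) == [1, 2, 3, 4]
        assert set(model_space[1].forward_edges) == {
            ("EV", "AM"), ("EV", "IN"), ("AM", "IN"),
        }
        assert set(model_space[2].forward_edges) == {
            ("EV", "AM"), ("EV", "IN"), ("IN", "AM"),
        }
        assert set(model_space[3].forward_edges) == {("EV", "AM"), ("AM", "IN")}
        assert set(model_space[4].forward_edges) == {("EV", "IN"), ("IN", "AM")}

    def test_model1_fully_reciprocated(self, model1):
        assert len(model1.forward_edges) == 3
        assert len(model1.backward_edges) == 3

    def test_model3_has_no_direct_ev_in_edge(self, model_space):
        edges = set(model_space[3].forward_edges) | set(
            model_space[3].backward_edges
        )
        assert ("EV", "IN") not in edges
        assert ("IN", "EV") not in edges

    def test_backward_edges_transpose_forward(self, model_space):
        for spec in model_space.values():
            assert {(t, s) for s, t in spec.forward_edges} == set(
                spec.backward_edges
            )

    def test_nonreciprocal_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            cmc.NetworkSpec(
                model_id=9,
                forward_edges=(("EV", "AM"),),
                backward_edges=(("IN", "EV"),),
            )


class TestSpectralPrediction:
    @pytest.mark.parametrize("mid", [1, 2, 3, 4])
    @pytest.mark.parametrize("cond", cmc.CONDITIONS)
    def test_hermitian_positive_semidefinite(self, model_space, freqs, mid, cond):
        spec = model_space[mid]
        S = cmc.predict_csd(
            cmc.CMCParams.prior_mean(spec), spec, freqs, cond
        ).spectra[cond]
        assert np.allclose(S, np.conj(np.swapaxes(S, 1, 2)))
        diag = S[:, np.arange(3), np.arange(3)]
        assert np.all(diag.imag == 0)
        assert np.all(diag.real >= 0)
        mineig = min(np.linalg.eigvalsh(S[f]).min() for f in range(S.shape[0]))
        assert mineig >= -1e-10 * np.abs(S).max()

    def test_disconnected_network_has_no_cross_spectra(self, model1, freqs):
        off = {
            n: -30.0
            for n in cmc.parameter_names(model1)
            if n.startswith(("F:", "B:"))
        }
        p = cmc.CMCParams.prior_mean(model1).updated(off)
        S = cmc.predict_csd(p, model1, freqs, "self_life").spectra["self_life"]
        diag_floor = S[:, np.arange(3), np.arange(3)].real.min()
        for i in range(3):
            for j in range(3):
                if i != j:
                    assert np.all(np.abs(S[:, i, j]) < 1e-8 * diag_floor)

    def test_innovations_amplitude_scales_power_quadratically(self, model1, freqs):
        # doubling the innovations amplitude (x4 power) with negligible
        # channel noise multiplies every auto-spectrum by 4
        base = cmc.CMCParams.prior_mean(model1).with_updates(**{"N:amp": -30.0})
        loud = base.with_updates(**{"U:amp": np.log(4.0)})
        s0 = cmc.predict_csd(base, model1, freqs, "self_life").spectra["self_life"]
        s1 = cmc.predict_csd(loud, model1, freqs, "self_life").spectra["self_life"]
        assert np.allclose(s1, 4.0 * s0, rtol=1e-10)

    def test_forward_strength_increases_coherence(self, model1, freqs):
        cohs = []
        for a in np.linspace(-0.6, 0.6, 7):
            p = cmc.CMCParams.prior_mean(model1).with_updates(
                **{"F:EV->AM:SP-SS": float(a)}
            )
            S = cmc.predict_csd(p, model1, freqs, "self_life").spectra["self_life"]
            coh = np.abs(S[:, 0, 1]) ** 2 / (S[:, 0, 0].real * S[:, 1, 1].real)
            cohs.append(coh.mean())
        assert np.all(np.diff(cohs) > 0)

    def test_out_of_band_frequencies_rejected(self, model1):
        p = cmc.CMCParams.prior_mean(model1)
        with pytest.raises(ConfigurationError):
            cmc.predict_csd(p, model1, np.array([0.5, 2.0]), "self_life")
        with pytest.raises(ConfigurationError):
            cmc.predict_csd(p, model1, np.array([30.0, 80.0]), "self_life")

    def test_unstable_parameters_raise(self, model1, freqs):
        # strong disinhibition of every region destabilizes the linearization
        p = cmc.CMCParams.prior_mean(model1).updated(
            {"G:EV": -4.0, "G:AM": -4.0, "G:IN": -4.0,
             "F:EV->AM:SP-SS": 2.5, "F:EV->IN:SP-SS": 2.5, "F:AM->IN:SP-SS": 2.5,
             "B:AM->EV:DP-SP": 2.5, "B:IN->EV:DP-SP": 2.5, "B:IN->AM:DP-SP": 2.5}
        )
        with pytest.raises(StabilityError):
            cmc.predict_csd(p, model1, freqs, "self_life")


class TestTimeDomain:
    def test_quiescent_without_input(self, model1):
        p = cmc.CMCParams.prior_mean(model1)
        p.bump_amplitude = 0.0
        t, y = cmc.simulate_timeseries(p, model1, duration=0.5, dt=5e-4)
        assert np.max(np.abs(y)) < 1e-12

    def test_null_modulation_makes_conditions_identical(self, model1):
        p = cmc.CMCParams.prior_mean(model1)  # all B = 0
        rng = np.random.default_rng(0)
        innov = cmc.sample_innovations(p, 1000, 5e-4, rng)[0]
        _, y_life = cmc.simulate_timeseries(
            p, model1, 0.5, dt=5e-4, condition="self_life", innovations=innov
        )
        _, y_death = cmc.simulate_timeseries(
            p, model1, 0.5, dt=5e-4, condition="self_death", innovations=innov
        )
        assert np.array_equal(y_life, y_death)

    def test_modulation_changes_self_death_only(self, model1):
        p = cmc.CMCParams.prior_mean(model1).with_updates(**{"Mod:F:EV->AM": -0.5})
        rng = np.random.default_rng(0)
        innov = cmc.sample_innovations(p, 1000, 5e-4, rng)[0]
        _, y_life = cmc.simulate_timeseries(
            p, model1, 0.5, dt=5e-4, condition="self_life", innovations=innov
        )
        _, y_death = cmc.simulate_timeseries(
            p, model1, 0.5, dt=5e-4, condition="self_death", innovations=innov
        )
        assert not np.allclose(y_life, y_death)

    def test_small_signal_linearity_of_evoked_response(self, model1):
        # doubling a small stimulus bump doubles the deflection within 5%
        p = cmc.CMCParams.prior_mean(model1)
        p.bump_amplitude = 0.05
        _, y1 = cmc.simulate_timeseries(p, model1, 0.4, dt=2.5e-4)
        p2 = p.copy()
        p2.bump_amplitude = 0.10
        _, y2 = cmc.simulate_timeseries(p2, model1, 0.4, dt=2.5e-4)
        peak1 = np.max(np.abs(y1))
        peak2 = np.max(np.abs(y2))
        assert peak2 == pytest.approx(2 * peak1, rel=0.05)

    def test_determinism_with_shared_innovations(self, model1):
        p = cmc.CMCParams.prior_mean(model1)
        rng = np.random.default_rng(4)
        innov = cmc.sample_innovations(p, 800, 5e-4, rng)[0]
        _, a = cmc.simulate_timeseries(p, model1, 0.4, dt=5e-4, innovations=innov)
        _, b = cmc.simulate_timeseries(p, model1, 0.4, dt=5e-4, innovations=innov)
        assert np.array_equal(a, b)
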