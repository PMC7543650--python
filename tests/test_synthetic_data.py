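"""Structure, determinism and statistical fidelity of the generators."""

import numpy as np
import pandas as pd
import pytest

from siatdcm import cmc_forward as cmc
from siatdcm import synthetic_data as sd
from siatdcm.behavior_scoring import compute_dscore
from siatdcm.errors import ConfigurationError, SchemaError


class TestBehaviorGenerator:
    def test_run_structure(self):
        cfg = sd.CohortConfig(group="HV", n_subjects=2, d_mean=-0.3, d_sd=0.4, seed=1)
        for table in sd.generate_behavior_cohort(cfg):
            assert table["block_index"].nunique() == 8
            crit = table[table["block_type"] == "critical"]
            assert crit["block_index"].nunique() == 4
            counts = crit["condition"].value_counts()
            assert counts["self_life"] == 56
            assert counts["self_death"] == 56
            assert (table["rt_ms"] > 0).all()

    def test_zero_bias_config_scores_near_zero(self):
        cfg = sd.CohortConfig(group="HV", n_subjects=5, d_mean=0.0, d_sd=0.0, seed=3)
        for table in sd.generate_behavior_cohort(cfg):
            assert abs(compute_dscore(table).D) < 0.15

    def test_empirical_d_matches_configured_target(self):
        # with zero between-subject spread the offset construction pins the
        # empirical D-score of every subject to the configured mean
        cfg = sd.CohortConfig(group="SC", n_subjects=4, d_mean=-0.4, d_sd=0.0, seed=9)
        for table in sd.generate_behavior_cohort(cfg):
            assert compute_dscore(table).D == pytest.approx(-0.4, abs=1e-6)

    def test_seed_determinism(self):
        cfg = sd.CohortConfig(group="HV", n_subjects=3, d_mean=-0.3, d_sd=0.4, seed=11)
        a = sd.generate_behavior_cohort(cfg)
        b = sd.generate_behavior_cohort(cfg)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta, tb)

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            sd.CohortConfig(group="HV", n_subjects=0, d_mean=0, d_sd=0.1)
        with pytest.raises(ConfigurationError):
            sd.CohortConfig(group="HV", n_subjects=2, d_mean=0, d_sd=0.1,
                            rt_base_ms=-5)
        with pytest.raises(ConfigurationError):
            sd.CohortConfig(group="XX", n_subjects=2, d_mean=0, d_sd=0.1)


class TestSubjectParameters:
    def test_zero_noise_hv_equals_beta_mean(self):
        truth = sd.SecondLevelTruth(
            parameters=("F:EV->AM:SP-SS", "B:AM->EV:DP-SP"),
            beta_mean=(-0.3, 0.1),
            beta_group=(0.0, 0.5),
            between_subject_sd=0.0,
        )
        subs = sd.generate_subject_parameters(truth, 3, 2, seed=0)
        for s in subs[:3]:
            assert s.group == "HV"
            assert s.params.get("F:EV->AM:SP-SS") == pytest.approx(-0.3)
            assert s.params.get("B:AM->EV:DP-SP") == pytest.approx(0.1)
        for s in subs[3:]:
            assert s.group == "SC"
            assert s.params.get("B:AM->EV:DP-SP") == pytest.approx(0.6)

    def test_group_difference_monte_carlo(self):
        # SC-minus-HV sample difference concentrates on beta_group
        truth = sd.default_group_truth()
        j = truth.parameters.index("F:EV->IN:SP-SS")
        diffs = []
        for seed in range(200):
            subs = sd.generate_subject_parameters(truth, 21, 4, seed=seed)
            hv = np.mean([s.params.get("F:EV->IN:SP-SS") for s in subs[:21]])
            sc = np.mean([s.params.get("F:EV->IN:SP-SS") for s in subs[21:]])
            diffs.append(sc - hv)
        se = truth.between_subject_sd * np.sqrt(1 / 4 + 1 / 21) / np.sqrt(200)
        assert np.mean(diffs) == pytest.approx(truth.beta_group[j], abs=2 * se)

    def test_null_group_effect_centered_on_zero(self):
        truth = sd.SecondLevelTruth(
            parameters=("F:EV->AM:SP-SS",),
            beta_mean=(-0.3,),
            beta_group=(0.0,),
            between_subject_sd=0.1,
        )
        diffs = []
        for seed in range(100):
            subs = sd.generate_subject_parameters(truth, 10, 10, seed=seed)
            vals = [s.params.get("F:EV->AM:SP-SS") for s in subs]
            diffs.append(np.mean(vals[10:]) - np.mean(vals[:10]))
        assert np.mean(diffs) == pytest.approx(0.0, abs=0.01)

    def test_unknown_parameter_name_listed_in_error(self):
        truth = sd.SecondLevelTruth(
            parameters=("F:EV->XX:SP-SS",), beta_mean=(0.1,), beta_group=(0.0,)
        )
        with pytest.raises(SchemaError, match="F:EV->XX:SP-SS"):
            sd.generate_subject_parameters(truth, 2, 0, seed=0)


class TestCsdGenerator:
    def test_noiseless_passthrough(self, model1, freqs):
        p = cmc.CMCParams.prior_mean(model1)
        ds = sd.generate_csd_dataset([p], spec=model1, freqs=freqs,
                                     noise_level=0.0, seed=0)[0]
        for cond in cmc.CONDITIONS:
            expected = cmc.predict_csd(p, model1, freqs, cond).spectra[cond]
            assert np.array_equal(ds.spectra[cond], expected)

    def test_seed_determinism_and_hermitian(self, model1, freqs):
        p = cmc.CMCParams.prior_mean(model1)
        a = sd.generate_csd_dataset([p], spec=model1, freqs=freqs, seed=5)[0]
        b = sd.generate_csd_dataset([p], spec=model1, freqs=freqs, seed=5)[0]
        for cond in cmc.CONDITIONS:
            assert np.array_equal(a.spectra[cond], b.spectra[cond])
        assert a.is_hermitian()

    def test_negative_noise_rejected(self, model1):
        p = cmc.CMCParams.prior_mean(model1)
        with pytest.raises(ConfigurationError):
            sd.generate_csd_dataset([p], spec=model1, noise_level=-0.1)

    def test_first_level_posteriors_track_truth(self):
        truth = sd.default_group_truth()
        subs = sd.generate_subject_parameters(truth, 5, 0, seed=2)
        posts = sd.generate_first_level_posteriors(
            subs, truth, seed=3, fields=truth.parameters
        )
        for s, p in zip(subs, posts):
            err = np.abs(
                p.Ep - np.array([s.params.get(n) for n in truth.parameters])
            )
            assert np.all(err < 5 * np.sqrt(truth.first_level_posterior_var))
            assert np.allclose(
                np.diag(p.Cp), truth.first_level_posterior_var
            )
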