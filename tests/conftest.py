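import numpy as np
import pytest

from siatdcm import cmc_forward as cmc
from siatdcm import synthetic_data as sd


@pytest.fixture(scope="session")
def model_space():
    return {m.model_id: m for m in cmc.build_model_space()}


@pytest.fixture(scope="session")
def model1(model_space):
    return model_space[1]


@pytest.fixture(scope="session")
def freqs():
    return cmc.default_freqs()


@pytest.fixture(scope="session")
def modulated_dataset(model1, freqs):
    """One synthetic subject generated from Model 1 with a negative trial
    modulation on the forward EV->AM edge, at the default noise level."""
    truth = cmc.CMCParams.prior_mean(model1).with_updates(**{"Mod:F:EV->AM": -0.4451})
    ds = sd.generate_csd_dataset([truth], spec=model1, freqs=freqs,
                                 noise_level=0.1, seed=7)[0]
    return truth, ds


def make_behavior_table(self_life_rts, self_death_rts, subject_id="S1"):
    """Minimal critical-trials-only behavior table."""
    import pandas as pd

    rows = []
    for cond, rts in (("self_life", self_life_rts), ("self_death", self_death_rts)):
        for k, rt in enumerate(rts):
            rows.append(
                {
                    "subject_id": subject_id,
                    "group": "HV",
                    "block_index": 2,
                    "block_type": "critical",
                    "condition": cond,
                    "trial_index": k,
                    "rt_ms": float(rt),
                    "correct": True,
                }
            )
    return pd.DataFrame(rows)
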