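"""Synthetic cohorts: behavior, connectivity parameters and cross-spectra.

Three generators cover the inputs the analysis consumes:

* :func:`generate_behavior_cohort` — trial-level implicit-association task
  runs (8 blocks; 4 critical blocks with 56 self-life and 56 self-death
  trials) whose empirical D-score per subject equals a draw from the
  configured group distribution.
* :func:`generate_subject_parameters` — per-subject connectivity parameter
  sets built from second-level ground truth (group-average effect plus
  HV-vs-SC difference plus between-subject noise).
* :func:`generate_csd_dataset` — per-subject, per-condition cross-spectral
  densities from the CMC forward model plus Hermitian observation noise
  whose magnitude is proportional to the local spectral scale (emulating the
  sampling error of trial-averaged spectral estimates).

Defaults reproduce the cohort structure of the emulated study: 21 healthy
volunteers (HV, mean D -0.297, SD 0.44) and 4 suicide-crisis participants
(SC, mean D -0.083, SD 0.32).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cmc_forward as cmc
from .dcm_inversion import Posterior
from .errors import ConfigurationError, SchemaError

__all__ = [
    "CohortConfig",
    "SecondLevelTruth",
    "SubjectParameters",
    "generate_behavior_cohort",
    "generate_subject_parameters",
    "generate_first_level_posteriors",
    "generate_csd_dataset",
    "default_group_truth",
]

N_CRITICAL_PER_CONDITION = 56
TRIALS_PER_CRITICAL_BLOCK = 28
TRIALS_PER_SINGLE_BLOCK = 24
RT_FLOOR_MS = 50.0
ACCURACY = 0.95

#: |D| beyond which the exact offset construction is clamped (the targeting
#: equation becomes singular as the condition offset dominates total spread)
D_CLAMP = 1.9


@dataclass(frozen=True)
class CohortConfig:
    """Behavioral cohort configuration for one group."""

    group: str
    n_subjects: int
    d_mean: float
    d_sd: float
    rt_base_ms: float = 800.0
    rt_sigma: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.group not in ("HV", "SC"):
            raise ConfigurationError("group must be 'HV' or 'SC'")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.rt_base_ms <= 0 or self.rt_sigma <= 0:
            raise ConfigurationError("rt_base_ms and rt_sigma must be positive")
        if self.d_sd < 0:
            raise ConfigurationError("d_sd must be non-negative")

    @classmethod
    def hv_default(cls, seed: int = 0) -> "CohortConfig":
        return cls(group="HV", n_subjects=21, d_mean=-0.297, d_sd=0.44, seed=seed)

    @classmethod
    def sc_default(cls, seed: int = 0) -> "CohortConfig":
        return cls(group="SC", n_subjects=4, d_mean=-0.083, d_sd=0.32, seed=seed)


def _block_layout():
    """8 blocks: 4 single-category, 4 critical, interleaved."""
    return [
        ("single", "life_death"),
        ("single", "me_notme"),
        ("critical", None),
        ("critical", None),
        ("single", "life_death"),
        ("single", "me_notme"),
        ("critical", None),
        ("critical", None),
    ]


def _subject_run(rng: np.random.Generator, cfg: CohortConfig, subject_id: str):
    true_d = float(
        rng.normal(cfg.d_mean, cfg.d_sd) if cfg.d_sd > 0 else cfg.d_mean
    )
    d = float(np.clip(true_d, -D_CLAMP, D_CLAMP))
    rows = []
    crit_rows = []
    for b, (btype, sub) in enumerate(_block_layout()):
        if btype == "single":
            conds = (
                ["life", "death"] if sub == "life_death" else ["me", "not_me"]
            ) * (TRIALS_PER_SINGLE_BLOCK // 2)
        else:
            conds = ["self_life", "self_death"] * (TRIALS_PER_CRITICAL_BLOCK // 2)
        conds = list(rng.permutation(conds))
        for k, cond in enumerate(conds):
            rt = float(
                np.exp(rng.normal(np.log(cfg.rt_base_ms), cfg.rt_sigma))
            )
            row = {
                "subject_id": subject_id,
                "group": cfg.group,
                "block_index": b,
                "block_type": btype,
                "condition": cond,
                "trial_index": k,
                "rt_ms": rt,
                "correct": bool(rng.random() < ACCURACY),
                "iti_s": float(rng.uniform(1.5, 2.5)),
            }
            rows.append(row)
            if btype == "critical":
                crit_rows.append(row)

    # Inject the condition offset so the empirical D equals the drawn D:
    # realized condition means are pinned to grand_mean +/- delta/2, with
    # delta solving delta^2 = D^2 * SSw / (n - 1 - n D^2 / 4).
    life = [r for r in crit_rows if r["condition"] == "self_life"]
    death = [r for r in crit_rows if r["condition"] == "self_death"]
    rl = np.array([r["rt_ms"] for r in life])
    rd = np.array([r["rt_ms"] for r in death])
    grand = float(np.concatenate([rl, rd]).mean())
    ssw = float(((rl - rl.mean()) ** 2).sum() + ((rd - rd.mean()) ** 2).sum())
    n = rl.size + rd.size
    denom = n - 1 - n * d * d / 4.0
    delta = d * np.sqrt(ssw / denom) if denom > 0 else 0.0
    for r, v in zip(life, rl - rl.mean() + grand + delta / 2.0):
        r["rt_ms"] = max(float(v), RT_FLOOR_MS)
    for r, v in zip(death, rd - rd.mean() + grand - delta / 2.0):
        r["rt_ms"] = max(float(v), RT_FLOOR_MS)
    return pd.DataFrame(rows), true_d


def generate_behavior_cohort(config: CohortConfig):
    """One trial table per subject; returns ``list[pd.DataFrame]``.

    Every run contains 4 critical blocks with exactly 56 self-life and 56
    self-death trials.  RTs are lognormal around ``rt_base_ms``; each
    subject's true D is drawn from Normal(d_mean, d_sd^2) and injected as an
    additive condition offset scaled by the realized within-subject spread,
    so the empirical D-score reproduces the draw.
    """
    rng = np.random.default_rng(config.seed)
    tables = []
    for i in range(config.n_subjects):
        sid = f"{config.group}{i + 1:03d}"
        table, _ = _subject_run(rng, config, sid)
        tables.append(table)
    return tables


# ---------------------------------------------------------------------------
# connectivity parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SecondLevelTruth:
    """Ground-truth second-level effects over named connectivity parameters.

    ``beta_mean`` is the group-average effect and ``beta_group`` the
    SC-minus-HV difference, both in log-scaling units; unnamed parameters are
    implicitly zero.  ``between_subject_sd`` scales iid Gaussian
    between-subject variability and ``first_level_posterior_var`` the
    variance of the synthesized first-level posteriors.
    """

    parameters: tuple
    beta_mean: tuple
    beta_group: tuple
    between_subject_sd: float = 0.1
    first_level_posterior_var: float = 0.05

    def __post_init__(self):
        if not (
            len(self.parameters) == len(self.beta_mean) == len(self.beta_group)
        ):
            raise SchemaError("truth vectors must align with parameter names")
        if self.between_subject_sd < 0 or self.first_level_posterior_var < 0:
            raise ConfigurationError("variances must be non-negative")

    def resolve(self, spec: cmc.NetworkSpec):
        known = set(cmc.parameter_names(spec))
        unresolved = sorted(set(self.parameters) - known)
        if unresolved:
            raise SchemaError(
                f"truth parameters do not resolve against model "
                f"{spec.model_id}: {unresolved}"
            )


def default_group_truth() -> SecondLevelTruth:
    """Built-in effect sizes used as simulation ground truth.

    Group-average effects load on the forward EV->AM pathways and their trial
    modulation (with small sub-threshold effects elsewhere); the group
    difference loads on the forward EV->IN (SP-SS) pathway (reduced in SC)
    and the backward AM->EV (DP-SP) pathway (enhanced in SC).
    """
    rows = [
        # (name, beta_mean, beta_group)
        ("F:EV->AM:SP-SS", -0.3035, 0.0),
        ("F:EV->AM:SP-DP", -0.2287, 0.0),
        ("Mod:F:EV->AM", -0.4451, 0.0),
        ("B:IN->EV:DP-SP", 0.144, 0.0),
        ("B:IN->AM:DP-SP", 0.0695, 0.0),
        ("F:EV->IN:SP-SS", -0.0696, -0.5904),
        ("F:AM->IN:SP-SS", -0.0833, 0.0),
        ("B:AM->EV:DP-SP", 0.0, 0.5477),
    ]
    return SecondLevelTruth(
        parameters=tuple(r[0] for r in rows),
        beta_mean=tuple(r[1] for r in rows),
        beta_group=tuple(r[2] for r in rows),
    )


@dataclass
class SubjectParameters:
    subject_id: str
    group: str  # "HV" or "SC"
    params: cmc.CMCParams

    @property
    def group_indicator(self) -> int:
        return 0 if self.group == "HV" else 1


def generate_subject_parameters(
    truth: SecondLevelTruth,
    n_hv: int,
    n_sc: int,
    seed: int = 0,
    spec: cmc.NetworkSpec | None = None,
):
    """Per-subject CMC parameter sets around the second-level truth.

    Subject i's named parameters are
    ``beta_mean + group_i * beta_group + Normal(0, between_subject_sd^2)``
    elementwise (group_i = 0 for HV, 1 for SC); all other parameters stay at
    their prior mean of zero.
    """
    if n_hv < 0 or n_sc < 0 or n_hv + n_sc == 0:
        raise ConfigurationError("need at least one subject")
    if spec is None:
        spec = cmc.build_model_space()[0]
    truth.resolve(spec)
    rng = np.random.default_rng(seed)
    bm = np.asarray(truth.beta_mean)
    bg = np.asarray(truth.beta_group)
    out = []
    for i in range(n_hv + n_sc):
        group = "HV" if i < n_hv else "SC"
        g = 0 if group == "HV" else 1
        noise = rng.normal(0.0, truth.between_subject_sd, bm.size)
        theta = bm + g * bg + noise
        params = cmc.CMCParams.prior_mean(spec).updated(
            dict(zip(truth.parameters, theta))
        )
        sid = f"{group}{(i if group == 'HV' else i - n_hv) + 1:03d}"
        out.append(SubjectParameters(subject_id=sid, group=group, params=params))
    return out


def generate_first_level_posteriors(
    subjects,
    truth: SecondLevelTruth,
    seed: int = 0,
    fields: tuple | None = None,
):
    """Synthesize first-level posteriors directly from subject parameters.

    Emulates the output of model inversion without running it: the posterior
    mean is the subject's true parameter plus Normal(0,
    first_level_posterior_var) estimation noise, with an isotropic posterior
    covariance of the same variance.  Useful for testing second-level
    inference in isolation.
    """
    rng = np.random.default_rng(seed)
    v = truth.first_level_posterior_var
    posteriors = []
    for s in subjects:
        names = tuple(fields) if fields is not None else tuple(s.params.names)
        theta = np.array([s.params.get(n) for n in names])
        ep = theta + rng.normal(0.0, np.sqrt(v), theta.size)
        posteriors.append(
            Posterior(
                names=names,
                Ep=ep,
                Cp=np.eye(theta.size) * max(v, 1e-12),
                F=0.0,
                subject_id=s.subject_id,
            )
        )
    return posteriors


# ---------------------------------------------------------------------------
# cross-spectral datasets
# ---------------------------------------------------------------------------


def generate_csd_dataset(
    subjects,
    spec: cmc.NetworkSpec | None = None,
    freqs: np.ndarray | None = None,
    noise_level: float = 0.1,
    seed: int = 0,
    wiring: cmc.IntrinsicWiring = cmc.DEFAULT_INTRINSIC,
):
    """Observed cross-spectra for each subject and both trial conditions.

    The observation is the model-predicted CSD plus complex Hermitian noise
    whose standard deviation at entry (i, j) is
    ``noise_level * sqrt(S_ii(f) S_jj(f))`` — the scaling of the sampling
    error of a trial-averaged cross-spectral estimate (noise_level ~ 0.1
    corresponds to averaging roughly 100 trials).  Accepts CMCParams or
    SubjectParameters; returns one CrossSpectra (with both conditions) per
    subject.
    """
    if noise_level < 0:
        raise ConfigurationError("noise_level must be non-negative")
    if spec is None:
        spec = cmc.build_model_space()[0]
    if freqs is None:
        freqs = cmc.default_freqs()
    rng = np.random.default_rng(seed)
    R = spec.n_regions
    out = []
    for s in subjects:
        params = s.params if isinstance(s, SubjectParameters) else s
        spectra = {}
        for cond in cmc.CONDITIONS:
            S = cmc.predict_csd(params, spec, freqs, cond, wiring).spectra[cond]
            if noise_level > 0:
                d = np.sqrt(np.abs(S[:, np.arange(R), np.arange(R)].real))
                sc = noise_level * d[:, :, None] * d[:, None, :]
                z = (
                    rng.standard_normal(S.shape)
                    + 1j * rng.standard_normal(S.shape)
                ) / np.sqrt(2.0)
                noise = sc * z
                noise = 0.5 * (noise + np.conj(np.swapaxes(noise, 1, 2)))
                S = S + noise
            spectra[cond] = S
        out.append(
            cmc.CrossSpectra(freqs=np.asarray(freqs, float), regions=spec.regions,
                             spectra=spectra)
        )
    return out
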