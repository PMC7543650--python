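"""Parametric empirical Bayes (PEB) over first-level posteriors.

Second-level model: each subject's first-level parameter vector theta_i (for
a chosen subset of connectivity parameters) is

    theta_i = (x_i (x) I_m) beta + eps_i,     eps_i ~ N(0, sigma_b^2 I),

where x_i is the subject's row of the between-subject design matrix (column
1 all ones for the group-average effect, column 2 the 0/1 group indicator)
and beta stacks one coefficient vector per covariate.  First-level evidence
enters through each subject's posterior mean and covariance, so uncertain
subjects are automatically down-weighted.  The between-subject variance is
estimated by maximizing the (empirical-Bayes) marginal evidence; posterior
probabilities that individual effects are nonzero come from Bayesian model
reduction (pinning one beta entry to zero and comparing log evidences).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ConfigurationError, CoverageError, SchemaError

__all__ = [
    "build_design_matrix",
    "PEBResult",
    "run_peb",
    "threshold_parameters",
    "compare_model_fits_by_group",
]

#: prior variance of each second-level coefficient (log-scaling units^2);
#: weakly informative relative to the sub-unity effect sizes of interest
BETA_PRIOR_VARIANCE = 1.0

COVARIATES = ("mean", "group")


def build_design_matrix(groups) -> np.ndarray:
    """Two-column design: intercept (average effect) and 0/1 group indicator.

    ``groups`` holds "HV"/"SC" labels or 0/1 indicators, one per subject.
    """
    g = []
    for item in groups:
        if item in ("HV", 0, False):
            g.append(0.0)
        elif item in ("SC", 1, True):
            g.append(1.0)
        else:
            raise SchemaError(f"unrecognized group label {item!r}")
    X = np.column_stack([np.ones(len(g)), np.array(g)])
    return X


@dataclass
class PEBResult:
    parameters: tuple
    covariates: tuple
    Ep: np.ndarray  # (n_covariates, n_parameters)
    Vp: np.ndarray  # posterior variances, same shape
    Pp: np.ndarray  # posterior probability effect is nonzero, same shape
    between_subject_sd: float
    beta_mean: np.ndarray  # full stacked posterior mean
    beta_cov: np.ndarray  # full stacked posterior covariance
    free_energy: float

    def effect(self, covariate: str, parameter: str):
        i = self.covariates.index(covariate)
        j = self.parameters.index(parameter)
        return float(self.Ep[i, j]), float(self.Vp[i, j]), float(self.Pp[i, j])


def _stack_subjects(posteriors, fields):
    means, covs = [], []
    for p in posteriors:
        m, c = p.subset(fields)
        means.append(m)
        covs.append(c)
    return means, covs


def _beta_posterior(means, covs, X, prior_prec, log_sb2):
    """Gaussian posterior over stacked beta at fixed between-subject variance.

    Returns (posterior precision, posterior mean, free energy), where the
    free energy is the exact log marginal likelihood of the Gaussian
    hierarchy (beta integrated out).
    """
    sb2 = np.exp(log_sb2)
    m = means[0].size
    k = X.shape[1]
    Lam = np.diag(np.full(k * m, prior_prec))
    b = np.zeros(k * m)
    quad = 0.0
    logdet = 0.0
    n_total = 0
    for mi, ci, xi in zip(means, covs, X):
        Di = ci + sb2 * np.eye(m)
        Di_inv = np.linalg.inv(Di)
        sign, ld = np.linalg.slogdet(Di)
        logdet += ld
        quad += float(mi @ Di_inv @ mi)
        n_total += m
        # K_i = kron(x_i, I_m); accumulate K^T D^-1 K and K^T D^-1 m
        for a in range(k):
            b[a * m:(a + 1) * m] += xi[a] * (Di_inv @ mi)
            for c in range(k):
                Lam[a * m:(a + 1) * m, c * m:(c + 1) * m] += (
                    xi[a] * xi[c] * Di_inv
                )
    mu = np.linalg.solve(Lam, b)
    sign, ld_post = np.linalg.slogdet(Lam)
    F = (
        -0.5 * (quad - float(b @ mu))
        - 0.5 * logdet
        - 0.5 * n_total * np.log(2 * np.pi)
        + 0.5 * k * m * np.log(prior_prec)
        - 0.5 * ld_post
    )
    return Lam, mu, F


def _reduced_log_evidence(mu, Lam, prior_prec, index, pinned_var=1e-10):
    """Log evidence change when one beta entry's prior shrinks to ~zero.

    For Gaussian prior/posterior pairs the evidence ratio of the reduced
    model (entry pinned at 0) to the full model is a Gaussian integral:
    with posterior N(mu, Lam^-1) and prior precision pi0, the reduced prior
    replaces pi0 with 1/pinned_var on the selected entry.
    """
    n = mu.size
    d_prec = np.zeros(n)
    d_prec[index] = 1.0 / pinned_var - prior_prec
    Lam_r = Lam + np.diag(d_prec)
    sign_r, ld_r = np.linalg.slogdet(Lam_r)
    sign, ld = np.linalg.slogdet(Lam)
    h = Lam @ mu  # natural parameter of the posterior
    mu_r = np.linalg.solve(Lam_r, h)
    dF = 0.5 * (ld - ld_r) + 0.5 * np.log(1.0 / pinned_var) - 0.5 * np.log(
        prior_prec
    )
    dF += 0.5 * float(mu_r @ Lam_r @ mu_r - mu @ h)
    return dF


def run_peb(posteriors, X, fields) -> PEBResult:
    """Fit the second-level model and score each effect's posterior probability.

    ``posteriors`` supply first-level means and covariances; ``X`` is the
    (n_subjects, 2) design matrix; ``fields`` names the parameter subset
    (typically the extrinsic and modulatory connection parameters).
    """
    X = np.asarray(X, dtype=float)
    fields = tuple(fields)
    if X.ndim != 2 or X.shape[0] != len(posteriors):
        raise SchemaError("design matrix rows must match the posterior list")
    if np.linalg.matrix_rank(X) < min(X.shape) and not _degenerate_ok(X):
        raise ConfigurationError("design matrix is rank deficient")
    m = len(fields)
    means, covs = _stack_subjects(posteriors, fields)
    prior_prec = 1.0 / BETA_PRIOR_VARIANCE

    res = optimize.minimize_scalar(
        lambda t: -_beta_posterior(means, covs, X, prior_prec, t)[2],
        bounds=(-10.0, 2.0),
        method="bounded",
        options={"xatol": 1e-3},
    )
    log_sb2 = float(res.x)
    Lam, mu, F = _beta_posterior(means, covs, X, prior_prec, log_sb2)
    cov = np.linalg.inv(Lam)

    k = X.shape[1]
    Ep = mu.reshape(k, m)
    Vp = np.diag(cov).reshape(k, m)
    Pp = np.empty((k, m))
    for a in range(k):
        for j in range(m):
            dF = _reduced_log_evidence(mu, Lam, prior_prec, a * m + j)
            # Pp(effect present) under equal model priors
            Pp[a, j] = 1.0 / (1.0 + np.exp(np.clip(dF, -700, 700)))
    return PEBResult(
        parameters=fields,
        covariates=COVARIATES[:k],
        Ep=Ep,
        Vp=Vp,
        Pp=Pp,
        between_subject_sd=float(np.exp(0.5 * log_sb2)),
        beta_mean=mu,
        beta_cov=cov,
        free_energy=float(F),
    )


def _degenerate_ok(X):
    # an all-zero group column is allowed: the group effect simply shrinks
    # to its prior
    return X.shape[1] == 2 and np.all(X[:, 0] == 1) and np.all(X[:, 1] == 0)


def threshold_parameters(result: PEBResult, pp_threshold: float = 0.95):
    """Parameters exceeding the posterior-probability threshold per covariate,
    sorted by Pp then |Ep| (both descending)."""
    out = {}
    for i, cov in enumerate(result.covariates):
        hits = [
            (result.parameters[j], float(result.Ep[i, j]), float(result.Pp[i, j]))
            for j in range(len(result.parameters))
            if result.Pp[i, j] > pp_threshold
        ]
        hits.sort(key=lambda h: (-h[2], -abs(h[1])))
        out[cov] = hits
    return out


def compare_model_fits_by_group(fit_metrics, groups):
    """Group means and standard errors of the across-region fit correlation.

    Guards against systematically worse fits in one group biasing the
    second-level comparison.  Single-subject groups report an undefined SE
    with a warning.
    """
    fit_metrics = np.asarray(list(fit_metrics), dtype=float)
    groups = list(groups)
    if fit_metrics.size != len(groups):
        raise SchemaError("fit metrics and groups must align")
    out = {}
    for g in dict.fromkeys(groups):  # preserve order
        vals = fit_metrics[[i for i, x in enumerate(groups) if x == g]]
        if vals.size == 0:
            raise CoverageError(f"group {g!r} is empty")
        if vals.size == 1:
            warnings.warn(
                f"group {g!r} has a single subject; SE undefined", stacklevel=2
            )
            se = float("nan")
        else:
            se = float(vals.std(ddof=1) / np.sqrt(vals.size))
        out[g] = {"mean": float(vals.mean()), "se": se, "n": int(vals.size)}
    return out
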