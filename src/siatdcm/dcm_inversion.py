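"""Variational-Laplace inversion of the CMC cross-spectral model.

The observed data feature is the complex cross-spectral density (CSD) over
1-58 Hz for the two trial conditions.  Real and imaginary parts of the
upper-triangular CSD entries are stacked into a real prediction-error vector;
observation noise carries one log-precision component per region.  A
Gauss-Newton scheme with Levenberg-Marquardt damping ascends the Laplace
approximation to the variational free energy F; steps are accepted only when
F increases, so F is non-decreasing over accepted iterations by construction
(and the iteration trace records it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import cmc_forward as cmc
from .errors import (
    ConfigurationError,
    DegenerateInputError,
    SchemaError,
    StabilityError,
)

__all__ = ["PriorSpec", "Posterior", "fit_dcm", "compute_fit_metric"]

_PRIOR_VARIANCE_BY_CLASS = {
    "extrinsic": 1.0 / 16.0,
    "modulatory": 1.0 / 16.0,
    "intrinsic": 1.0 / 64.0,
    "rate": 1.0 / 128.0,
    "drive_amp": 1.0 / 16.0,
    "drive_exp": 1.0 / 64.0,
    "gain": 1.0 / 16.0,
}


def _param_class(name: str) -> str:
    if name.startswith(("F:", "B:")):
        return "extrinsic"
    if name.startswith("Mod:"):
        return "modulatory"
    if name.startswith("G:"):
        return "intrinsic"
    if name.startswith("T:"):
        return "rate"
    if name in ("U:amp", "N:amp"):
        return "drive_amp"
    if name in ("U:exp", "N:exp"):
        return "drive_exp"
    if name.startswith("L:"):
        return "gain"
    raise SchemaError(f"cannot classify parameter {name!r}")


@dataclass
class PriorSpec:
    """Gaussian shrinkage priors over log-scaling parameters.

    Prior means are zero (no scaling); variances are assigned by parameter
    class.  ``hyper_mean``/``hyper_variance`` parameterize the Gaussian
    hyperprior on each region's log observation precision.
    """

    names: tuple
    mean: np.ndarray
    variance: np.ndarray
    hyper_mean: float = 4.0
    hyper_variance: float = 9.0

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.variance = np.asarray(self.variance, dtype=float)
        if np.any(self.variance <= 0):
            raise ConfigurationError("prior variances must be positive")
        if self.mean.shape != (len(self.names),) or self.variance.shape != (
            len(self.names),
        ):
            raise SchemaError("prior vectors do not match parameter names")

    @classmethod
    def default(cls, spec: cmc.NetworkSpec) -> "PriorSpec":
        names = cmc.parameter_names(spec)
        var = np.array([_PRIOR_VARIANCE_BY_CLASS[_param_class(n)] for n in names])
        return cls(names=names, mean=np.zeros(len(names)), variance=var)


@dataclass
class Posterior:
    """First-level posterior density and model evidence for one subject."""

    names: tuple
    Ep: np.ndarray
    Cp: np.ndarray
    F: float
    fit_correlations: dict = field(default_factory=dict)
    trace: list = field(default_factory=list)
    log_precisions: np.ndarray | None = None
    subject_id: str = ""

    def get(self, name: str) -> float:
        return float(self.Ep[self.names.index(name)])

    def variance(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.Cp[i, i])

    def subset(self, fields) -> tuple:
        """(mean, covariance) over the requested parameter names."""
        missing = [f for f in fields if f not in self.names]
        if missing:
            raise SchemaError(f"posterior lacks parameters: {missing}")
        idx = [self.names.index(f) for f in fields]
        return self.Ep[idx], self.Cp[np.ix_(idx, idx)]


# ---------------------------------------------------------------------------
# data featurization
# ---------------------------------------------------------------------------


def _feature_vector(spectra: dict, n_regions: int):
    """Stack both conditions' upper-triangular CSD entries into reals.

    Returns the vector and, per element, the region index used for the
    observation-precision components (off-diagonal (i, j) entries are
    assigned to region i).
    """
    chunks, regions = [], []
    iu, ju = np.triu_indices(n_regions)
    for cond in sorted(spectra):
        s = spectra[cond]  # (F, R, R)
        for i, j in zip(iu, ju):
            if i == j:
                chunks.append(s[:, i, i].real)
                regions.append(np.full(s.shape[0], i))
            else:
                chunks.append(s[:, i, j].real)
                chunks.append(s[:, i, j].imag)
                regions.append(np.full(2 * s.shape[0], i))
    return np.concatenate(chunks), np.concatenate(regions)


def _precision_weights(spectra: dict, n_regions: int) -> np.ndarray:
    """Fixed within-component precision weighting for each data element.

    The sampling error of a cross-spectral estimate S_ij(f) scales with
    sqrt(S_ii(f) S_jj(f)), so each region's precision component carries a
    fixed 1 / (S_ii S_jj) envelope (from the observed diagonal), scaled by a
    single estimated log-precision per region.
    """
    chunks = []
    iu, ju = np.triu_indices(n_regions)
    for cond in sorted(spectra):
        s = spectra[cond]
        d = np.abs(s[:, np.arange(n_regions), np.arange(n_regions)].real)
        floor = 1e-12 * max(float(d.max()), 1e-300)
        d = np.maximum(d, floor)
        for i, j in zip(iu, ju):
            m = d[:, i] * d[:, j]
            if i == j:
                chunks.append(1.0 / m)
            else:
                chunks.append(1.0 / m)
                chunks.append(1.0 / m)
    return np.concatenate(chunks)


def _check_hermitian(observed: cmc.CrossSpectra):
    for cond, s in observed.spectra.items():
        scale = max(float(np.max(np.abs(s))), 1e-30)
        if np.max(np.abs(s - np.conj(np.swapaxes(s, 1, 2)))) > 1e-6 * scale:
            raise SchemaError(f"observed CSD for {cond!r} is not Hermitian")


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def fit_dcm(
    observed: cmc.CrossSpectra,
    spec: cmc.NetworkSpec,
    priors: PriorSpec | None = None,
    max_iter: int = 128,
    tol: float = 0.01,
    converge_count: int = 4,
    restarts: int = 0,
    restart_seed: int = 0,
    wiring: cmc.IntrinsicWiring = cmc.DEFAULT_INTRINSIC,
    subject_id: str = "",
) -> Posterior:
    """Invert the CMC-CSD model for one subject.

    ``observed`` must contain both trial conditions (the trial-modulation
    parameters are only identified by their contrast).  With ``restarts > 0``
    additional seeded initializations are fitted and the highest-F solution
    returned.
    """
    _check_hermitian(observed)
    if set(observed.conditions) != set(cmc.CONDITIONS):
        raise SchemaError(
            f"observed CSD must contain conditions {cmc.CONDITIONS}, "
            f"got {observed.conditions}"
        )
    if priors is None:
        priors = PriorSpec.default(spec)
    if tuple(priors.names) != cmc.parameter_names(spec):
        raise SchemaError("prior parameter ordering does not match the model")

    best = None
    rng = np.random.default_rng(restart_seed)
    for attempt in range(restarts + 1):
        theta0 = priors.mean.copy()
        if attempt > 0:
            theta0 = theta0 + 0.1 * rng.standard_normal(theta0.size)
        try:
            post = _fit_once(
                observed, spec, priors, theta0, max_iter, tol,
                converge_count, wiring, subject_id,
            )
        except StabilityError:
            if attempt == restarts and best is None:
                raise
            continue
        if best is None or post.F > best.F:
            best = post
    return best


def _fit_once(
    observed, spec, priors, theta_init, max_iter, tol, converge_count,
    wiring, subject_id,
):
    freqs = observed.freqs
    R = spec.n_regions
    y, region_of = _feature_vector(observed.spectra, R)
    scale = float(np.sqrt(np.mean(y**2)))
    if scale <= 0:
        raise DegenerateInputError("observed CSD is identically zero")
    y = y / scale
    n_data = y.size
    masks = [region_of == r for r in range(R)]
    n_per = np.array([m.sum() for m in masks], dtype=float)
    q = _precision_weights(
        {c: s / scale for c, s in observed.spectra.items()}, R
    )
    log_q_sum = float(np.sum(np.log(q)))

    names = priors.names
    p0 = priors.mean
    pi0 = 1.0 / priors.variance
    lam0, vlam = priors.hyper_mean, priors.hyper_variance

    def predict(theta):
        params = cmc.CMCParams(names=names, values=theta)
        spectra = {}
        for cond in cmc.CONDITIONS:
            spectra[cond] = cmc.predict_csd(
                params, spec, freqs, cond, wiring
            ).spectra[cond]
        g, _ = _feature_vector(spectra, R)
        return g / scale

    def jacobian(theta, g0):
        h = 1e-4
        J = np.empty((n_data, theta.size))
        for k in range(theta.size):
            tk = theta.copy()
            tk[k] += h
            J[:, k] = (predict(tk) - g0) / h
        return J

    def precision_diag(lam):
        w = np.empty(n_data)
        for r, m in enumerate(masks):
            w[m] = np.exp(lam[r])
        return w * q

    def update_lambdas(lam, e, Jsig_diag):
        # bounded log-precisions keep the Newton update finite when the
        # residual vanishes (noise-free data)
        lam = lam.copy()
        qe2 = q * e**2 + q * Jsig_diag
        for _ in range(4):
            for r, m in enumerate(masks):
                sq = float(qe2[m].sum())
                pi_r = np.exp(lam[r])
                grad = 0.5 * (n_per[r] - pi_r * sq) - (lam[r] - lam0) / vlam
                curv = -0.5 * pi_r * sq - 1.0 / vlam
                lam[r] = float(np.clip(lam[r] - grad / curv, lam0 - 32.0,
                                       lam0 + 32.0))
        return lam

    def free_energy(theta, lam, e, Sigma, logdet_Sigma, Jsig_diag):
        w = precision_diag(lam)
        dtheta = theta - p0
        f = -0.5 * float(e @ (w * e))
        f += 0.5 * (float(n_per @ lam) + log_q_sum) - 0.5 * n_data * np.log(2 * np.pi)
        f += -0.5 * float(dtheta @ (pi0 * dtheta))
        f += 0.5 * (logdet_Sigma + float(np.sum(np.log(pi0))))
        # hyperparameter terms (Laplace over each lambda)
        qe2 = q * e**2 + q * Jsig_diag
        for r, m in enumerate(masks):
            sq = float(qe2[m].sum())
            curv = 0.5 * np.exp(lam[r]) * sq + 1.0 / vlam
            f += -0.5 * (lam[r] - lam0) ** 2 / vlam
            f += 0.5 * (np.log(1.0 / curv) - np.log(vlam))
        return f

    def posterior_cov(J, lam):
        w = precision_diag(lam)
        H = J.T @ (w[:, None] * J) + np.diag(pi0)
        Sigma = np.linalg.inv(H)
        sign, logdet = np.linalg.slogdet(Sigma)
        if sign <= 0:
            raise StabilityError("posterior covariance not positive definite")
        return Sigma, logdet

    theta = theta_init.copy()
    lam = np.full(R, lam0)
    g = predict(theta)
    e = y - g
    J = jacobian(theta, g)
    Sigma, logdet = posterior_cov(J, lam)
    Jsig = np.einsum("ij,jk,ik->i", J, Sigma, J)
    lam = update_lambdas(lam, e, Jsig)
    F = free_energy(theta, lam, e, Sigma, logdet, Jsig)
    trace = [F]

    nu = 1.0 / 64.0
    stall = 0
    for _ in range(max_iter):
        w = precision_diag(lam)
        H = J.T @ (w[:, None] * J) + np.diag(pi0)
        grad = J.T @ (w * e) - pi0 * (theta - p0)
        accepted = False
        for _try in range(8):
            try:
                step = np.linalg.solve(H + nu * np.diag(np.diag(H)), grad)
                cand = theta + step
                g_c = predict(cand)
                e_c = y - g_c
                J_c = jacobian(cand, g_c)
                Sig_c, logdet_c = posterior_cov(J_c, lam)
                Jsig_c = np.einsum("ij,jk,ik->i", J_c, Sig_c, J_c)
                lam_c = update_lambdas(lam, e_c, Jsig_c)
                F_c = free_energy(cand, lam_c, e_c, Sig_c, logdet_c, Jsig_c)
            except (StabilityError, np.linalg.LinAlgError):
                nu = min(nu * 8.0, 1e8)
                continue
            if F_c > F:
                theta, g, e, J = cand, g_c, e_c, J_c
                Sigma, logdet, Jsig = Sig_c, logdet_c, Jsig_c
                lam, F = lam_c, F_c
                nu = max(nu / 8.0, 1e-8)
                accepted = True
                break
            nu = min(nu * 8.0, 1e8)
        if not accepted:
            stall += 1
            if stall >= 2:
                break
            continue
        trace.append(F)
        if len(trace) > converge_count and all(
            trace[-k - 1] - trace[-k - 2] < tol for k in range(converge_count)
        ):
            break

    params = cmc.CMCParams(names=names, values=theta)
    predicted = {
        cond: cmc.predict_csd(params, spec, freqs, cond, wiring).spectra[cond]
        for cond in cmc.CONDITIONS
    }
    pred_cs = cmc.CrossSpectra(freqs=freqs, regions=spec.regions, spectra=predicted)
    fits = compute_fit_metric(pred_cs, observed)
    return Posterior(
        names=tuple(names),
        Ep=theta,
        Cp=Sigma,
        F=float(F),
        fit_correlations=fits,
        trace=trace,
        log_precisions=lam,
        subject_id=subject_id,
    )


def compute_fit_metric(
    predicted: cmc.CrossSpectra, observed: cmc.CrossSpectra
) -> dict:
    """Per-region Pearson correlation between predicted and observed
    auto-spectral magnitudes (stacked across conditions), plus their mean."""
    if predicted.freqs.shape != observed.freqs.shape or not np.allclose(
        predicted.freqs, observed.freqs
    ):
        raise SchemaError("predicted and observed frequency grids differ")
    conds = sorted(set(predicted.conditions) & set(observed.conditions))
    if not conds:
        raise SchemaError("no common conditions between predicted and observed")
    out = {}
    for r, name in enumerate(observed.regions):
        p = np.concatenate(
            [np.abs(predicted.spectra[c][:, r, r]) for c in conds]
        )
        o = np.concatenate(
            [np.abs(observed.spectra[c][:, r, r]) for c in conds]
        )
        if np.ptp(p) == 0 or np.ptp(o) == 0:
            raise DegenerateInputError(
                f"constant auto-spectrum for region {name}; correlation undefined"
            )
        out[name] = float(stats.pearsonr(p, o)[0])
    out["mean"] = float(np.mean([out[r] for r in observed.regions]))
    return out
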