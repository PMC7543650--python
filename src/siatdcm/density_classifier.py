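"""Gaussian density non-overlap classification of cases against controls.

For a selected connectivity parameter, a control density N(m, s^2) is built
from the between-subject mean and variance of the healthy-volunteer (HV)
estimates.  Each case (suicide-crisis, SC) contributes its own conditional
density — the subject's first-level posterior for that parameter.  The
distance measure is the non-overlapping probability mass

    non-overlap(p, q) = 1 - OVL(p, q),      OVL = integral of min(p, q),

computed in closed form from the intersection points of the two Gaussian
densities (and cross-checkable by adaptive quadrature).  Specificity in
controls uses leave-one-out cross-validation at a fixed non-overlap
threshold; per-case "sensitivity" is reported as the continuous non-overlap
percentage (a thresholded binary variant is available via ``binary=True``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .errors import DegenerateInputError, InsufficientDataError

__all__ = [
    "GaussianDensity",
    "ClassifierReport",
    "gaussian_nonoverlap",
    "nonoverlap_numeric",
    "control_density",
    "loocv_specificity",
    "case_sensitivity",
    "mean_sensitivity",
    "classify_parameter",
]


@dataclass(frozen=True)
class GaussianDensity:
    mean: float
    variance: float

    def __post_init__(self):
        if not (self.variance > 0) or not math.isfinite(self.variance):
            raise DegenerateInputError(
                f"Gaussian density requires positive finite variance "
                f"(got {self.variance})"
            )


@dataclass(frozen=True)
class ClassifierReport:
    parameter: str
    per_case_sensitivity: tuple  # percent, one per case
    mean_sensitivity: float  # percent, rounded half away from zero
    specificity: float  # percent
    threshold: float
    flagged_cases: tuple  # case indices above threshold (binary reading)


def _norm(d: GaussianDensity) -> stats.rv_continuous:
    return stats.norm(d.mean, math.sqrt(d.variance))


def gaussian_nonoverlap(d1: GaussianDensity, d2: GaussianDensity) -> float:
    """1 - OVL of two Gaussian densities, in closed form.

    The overlapping coefficient integrates the pointwise minimum of the two
    pdfs.  The minimum switches branches only at points where the densities
    are equal, which solve a quadratic in x; the integral of the minimum is
    then a sum of Gaussian-CDF differences.  For equal variances this reduces
    to OVL = 2*Phi(-|mu1-mu2| / (2*sigma)).
    """
    if (d1.mean, d1.variance) == (d2.mean, d2.variance):
        return 0.0
    # intersection points solve log p1(x) - log p2(x) = a x^2 + b x + c = 0
    a = 0.5 * (1.0 / d2.variance - 1.0 / d1.variance)
    b = d1.mean / d1.variance - d2.mean / d2.variance
    c = (
        0.5 * (d2.mean**2 / d2.variance - d1.mean**2 / d1.variance)
        + 0.5 * math.log(d2.variance / d1.variance)
    )
    # variances equal to machine precision: the quadratic degenerates to a
    # line with a single crossing (the far root is numerical noise)
    if abs(a) <= 1e-12 * (0.5 / d1.variance + 0.5 / d2.variance):
        if b == 0.0:
            return 0.0
        points = [-c / b]
    else:
        disc = b * b - 4 * a * c
        if disc <= 0:
            points = []
        else:
            r = math.sqrt(disc)
            points = sorted([(-b - r) / (2 * a), (-b + r) / (2 * a)])
    n1, n2 = _norm(d1), _norm(d2)
    edges = [-math.inf, *points, math.inf]
    ovl = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        if not hi > lo:
            continue
        mid = _interval_midpoint(lo, hi, d1, d2)
        # branch selection via the quadratic itself (stable in far tails
        # where both log densities are astronomically negative)
        n = n1 if (a * mid + b) * mid + c <= 0 else n2
        ovl += n.cdf(hi) - n.cdf(lo)
    return float(min(1.0, max(0.0, 1.0 - ovl)))


def _interval_midpoint(lo, hi, d1, d2):
    if math.isinf(lo) and math.isinf(hi):
        return 0.5 * (d1.mean + d2.mean)
    if math.isinf(lo):
        return hi - 1.0
    if math.isinf(hi):
        return lo + 1.0
    return 0.5 * (lo + hi)


def nonoverlap_numeric(d1: GaussianDensity, d2: GaussianDensity) -> float:
    """Adaptive-quadrature reference for :func:`gaussian_nonoverlap`.

    The integrand min(pdf1, pdf2) has kinks where the densities cross;
    crossings are located by sign scanning and bisection (independently of
    the closed form's quadratic) and passed to the quadrature as
    subdivision points.
    """
    n1, n2 = _norm(d1), _norm(d2)
    s1, s2 = math.sqrt(d1.variance), math.sqrt(d2.variance)
    lo = min(d1.mean - 12 * s1, d2.mean - 12 * s2)
    hi = max(d1.mean + 12 * s1, d2.mean + 12 * s2)
    from scipy.optimize import brentq

    grid = np.linspace(lo, hi, 4097)
    diff = n1.logpdf(grid) - n2.logpdf(grid)
    kinks = []
    for i in np.nonzero(diff[:-1] * diff[1:] < 0)[0]:
        kinks.append(
            float(
                brentq(
                    lambda x: n1.logpdf(x) - n2.logpdf(x),
                    grid[i], grid[i + 1],
                )
            )
        )
    ovl, _ = integrate.quad(
        lambda x: min(n1.pdf(x), n2.pdf(x)), lo, hi, limit=400,
        points=sorted(kinks) or None,
    )
    return float(1.0 - ovl)


def control_density(hv_estimates) -> GaussianDensity:
    """Control group density from between-subject sample moments (ddof=1)."""
    x = np.asarray(list(hv_estimates), dtype=float)
    if x.size < 3:
        raise InsufficientDataError("control density requires n >= 3")
    var = float(np.var(x, ddof=1))
    if var <= 0:
        raise DegenerateInputError("control estimates have zero variance")
    return GaussianDensity(mean=float(x.mean()), variance=var)


def loocv_specificity(
    hv_estimates,
    hv_posterior_variances,
    threshold: float = 0.95,
) -> float:
    """Leave-one-out specificity (%) in controls.

    Each held-out control contributes its conditional density
    N(estimate, posterior variance), compared against the control density of
    the remaining n-1 subjects; folds whose non-overlap exceeds ``threshold``
    count as false positives.
    """
    x = np.asarray(list(hv_estimates), dtype=float)
    v = np.asarray(list(hv_posterior_variances), dtype=float)
    if x.size != v.size:
        raise InsufficientDataError("estimates and variances must align")
    if x.size < 4:
        raise InsufficientDataError("LOOCV specificity requires n >= 4")
    flags = 0
    for i in range(x.size):
        rest = np.delete(x, i)
        ctrl = control_density(rest)
        held = GaussianDensity(mean=float(x[i]), variance=float(v[i]))
        if gaussian_nonoverlap(ctrl, held) > threshold:
            flags += 1
    return float(100.0 * (x.size - flags) / x.size)


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def mean_sensitivity(per_case_percent) -> int:
    """Aggregate per-case sensitivity percentages into the reported mean.

    Arithmetic mean, rounded half away from zero to an integer percent.
    """
    vals = list(per_case_percent)
    if not vals:
        raise InsufficientDataError("at least one case is required")
    return _round_half_away(float(np.mean(vals)))


def case_sensitivity(
    control: GaussianDensity,
    case_posteriors,
    threshold: float = 0.95,
    binary: bool = False,
):
    """Per-case and mean sensitivity (%) of cases against the control density.

    Default reading: per-case sensitivity is the continuous non-overlap
    percentage between the control density and the case's conditional
    density; the mean is rounded half away from zero to an integer percent.
    With ``binary=True`` per-case values are 100/0 at the threshold.
    """
    cases = list(case_posteriors)
    if not cases:
        raise InsufficientDataError("at least one case is required")
    raw = [100.0 * gaussian_nonoverlap(control, c) for c in cases]
    if binary:
        per_case = [100.0 if r > 100.0 * threshold else 0.0 for r in raw]
    else:
        per_case = raw
    return per_case, mean_sensitivity(per_case)


def classify_parameter(
    parameter: str,
    hv_estimates,
    hv_posterior_variances,
    case_estimates,
    case_posterior_variances,
    threshold: float = 0.95,
    binary: bool = False,
) -> ClassifierReport:
    """Full control-vs-case report for one connectivity parameter."""
    ctrl = control_density(hv_estimates)
    cases = [
        GaussianDensity(mean=float(m), variance=float(v))
        for m, v in zip(case_estimates, case_posterior_variances)
    ]
    per_case, mean = case_sensitivity(ctrl, cases, threshold, binary)
    spec = loocv_specificity(hv_estimates, hv_posterior_variances, threshold)
    flagged = tuple(
        i for i, s in enumerate(
            [100.0 * gaussian_nonoverlap(ctrl, c) for c in cases]
        )
        if s > 100.0 * threshold
    )
    return ClassifierReport(
        parameter=parameter,
        per_case_sensitivity=tuple(per_case),
        mean_sensitivity=float(mean),
        specificity=spec,
        threshold=threshold,
        flagged_cases=flagged,
    )
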