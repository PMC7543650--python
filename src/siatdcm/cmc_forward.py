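"""Canonical-microcircuit (CMC) neural mass forward model for spectral responses.

Each region of interest contains four neuronal populations — spiny stellate
cells (SS), superficial pyramidal cells (SP), inhibitory interneurons (II) and
deep pyramidal cells (DP) — coupled through a fixed intrinsic wiring pattern.
Extrinsic (between-region) connections follow the laminar convention: forward
connections originate in the source's SP population and target SS and DP of
the receiving region; backward connections originate in DP and target SP and
II.  Each population obeys a second-order (convolution) synaptic kernel driven
by sigmoid-transformed presynaptic depolarizations.

The module exposes the four candidate network architectures over left early
visual cortex (EV), amygdala (AM) and insula (IN), a nonlinear time-domain
integrator, and the linearized transfer-function route to predicted complex
cross-spectral densities (CSDs) over the 1-58 Hz band.

All connection strengths are parameterized as log-scaling factors applied to
fixed prior scales, so physical strengths are strictly positive.  Condition
``self_death`` multiplies modulated edges by ``exp(B)`` relative to
``self_life``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, SchemaError, StabilityError

__all__ = [
    "POPULATIONS",
    "IntrinsicWiring",
    "DEFAULT_INTRINSIC",
    "NetworkSpec",
    "CMCParams",
    "CrossSpectra",
    "CONDITIONS",
    "build_model_space",
    "parameter_names",
    "simulate_timeseries",
    "sample_innovations",
    "predict_csd",
    "transfer_functions",
    "system_matrix",
]

POPULATIONS = ("SS", "SP", "II", "DP")
CONDITIONS = ("self_life", "self_death")

#: voltage bound (mV-equivalent) beyond which integration is declared unstable
STATE_BOUND = 500.0

# Prior scales for extrinsic pathways (s^-1 per unit presynaptic firing).
# Forward pathways: source SP -> target SS (primary) and target DP (secondary);
# backward: source DP -> target SP (primary) and target II (secondary).
EXTRINSIC_SCALE = {
    "SP-SS": 1600.0,
    "SP-DP": 800.0,
    "DP-SP": 1600.0,
    "DP-II": 800.0,
}

# Spectral drive constants; log-scaling parameters multiply these.
# g_u(f) = exp(U:amp) * INNOVATIONS_SCALE * (f**-b + INNOVATIONS_FLOOR)
# g_n(f) = exp(N:amp) * CHANNEL_SCALE     * (f**-d + CHANNEL_FLOOR)
INNOVATIONS_SCALE = 1.0
INNOVATIONS_FLOOR = 0.125
CHANNEL_SCALE = 2.5e-4
CHANNEL_FLOOR = 0.25
OBSERVATION_SCALE = 100.0


@dataclass(frozen=True)
class IntrinsicWiring:
    """Signed intrinsic coupling table for one region.

    ``weights[(target, source)]`` is the synaptic drive (s^-1 per unit firing)
    that the source population's sigmoid output exerts on the target
    population's second-order kernel; negative entries are inhibitory.  The
    table is versioned so alternative wirings can be serialized and compared.
    """

    version: str
    weights: dict
    time_constants_ms: dict
    sigmoid_slope: float

    def weight_matrix(self) -> np.ndarray:
        w = np.zeros((4, 4))
        for (tgt, src), val in self.weights.items():
            w[POPULATIONS.index(tgt), POPULATIONS.index(src)] = val
        return w

    def kappas(self) -> np.ndarray:
        """Inverse time constants (s^-1), ordered as POPULATIONS."""
        return np.array(
            [1000.0 / self.time_constants_ms[p] for p in POPULATIONS]
        )


#: Default ten-connection intrinsic pattern.  SS and SP form a fast
#: granular/supragranular loop (gamma-range resonance), II and DP a slower
#: infragranular loop; every population carries an inhibitory self-connection
#: (for SS and SP the recurrent inhibition is absorbed into the SP->SS and
#: self entries).  Magnitudes follow the conventional 200 s^-1 base scale.
DEFAULT_INTRINSIC = IntrinsicWiring(
    version="1.0",
    weights={
        ("SS", "SS"): -800.0,
        ("SS", "SP"): -2400.0,
        ("SP", "SS"): 2400.0,
        ("SP", "SP"): -1600.0,
        ("SP", "II"): -800.0,
        ("II", "SS"): 400.0,
        ("II", "DP"): 400.0,
        ("II", "II"): -800.0,
        ("DP", "II"): -400.0,
        ("DP", "DP"): -200.0,
    },
    time_constants_ms={"SS": 4.0, "SP": 4.0, "II": 16.0, "DP": 28.0},
    sigmoid_slope=2.0 / 3.0,
)


@dataclass(frozen=True)
class NetworkSpec:
    """Directed forward/backward edge structure for one candidate model."""

    model_id: int
    forward_edges: tuple
    backward_edges: tuple
    regions: tuple = ("EV", "AM", "IN")
    coordinates_mm: dict = field(
        default_factory=lambda: {
            "EV": (-2.0, -92.0, -4.0),
            "AM": (-20.0, -10.0, -30.0),
            "IN": (-50.0, 10.0, 2.0),
        }
    )
    input_region: str = "EV"

    def __post_init__(self):
        fwd = set(self.forward_edges)
        bwd = set(self.backward_edges)
        for s, t in fwd | bwd:
            if s == t:
                raise ConfigurationError(f"self-edge {s}->{t} not allowed")
            if s not in self.regions or t not in self.regions:
                raise ConfigurationError(f"edge {s}->{t} uses unknown region")
        if {(t, s) for s, t in fwd} != bwd:
            raise ConfigurationError(
                "backward edges must reciprocate the forward edges"
            )
        if self.input_region not in self.regions:
            raise ConfigurationError("input region must be in the region list")

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def build_model_space() -> list:
    """The four candidate architectures over EV, AM and IN.

    Model 1 is fully connected (EV->AM, EV->IN, AM->IN); Models 2-4 drop or
    reroute one forward pathway.  Every forward edge is reciprocated by a
    backward edge.
    """
    forward = {
        1: (("EV", "AM"), ("EV", "IN"), ("AM", "IN")),
        2: (("EV", "AM"), ("EV", "IN"), ("IN", "AM")),
        3: (("EV", "AM"), ("AM", "IN")),
        4: (("EV", "IN"), ("IN", "AM")),
    }
    specs = []
    for mid, fwd in forward.items():
        bwd = tuple((t, s) for s, t in fwd)
        specs.append(NetworkSpec(model_id=mid, forward_edges=fwd, backward_edges=bwd))
    return specs


def parameter_names(spec: NetworkSpec) -> tuple:
    """Canonical ordered parameter names for a network architecture.

    ``F:src->tgt:SP-SS`` / ``F:src->tgt:SP-DP`` — forward pathway log-scalings;
    ``B:src->tgt:DP-SP`` / ``B:src->tgt:DP-II`` — backward pathway log-scalings;
    ``Mod:F:src->tgt`` / ``Mod:B:src->tgt`` — trial (self-death vs self-life)
    modulation per directed edge; ``G:<region>`` — intrinsic gain; ``T:<pop>``
    — rate-constant log-scaling; ``U:*`` / ``N:*`` — neuronal-innovations and
    channel-noise spectra; ``L:<region>`` — electrode gain.
    """
    names = []
    for s, t in spec.forward_edges:
        names += [f"F:{s}->{t}:SP-SS", f"F:{s}->{t}:SP-DP"]
    for s, t in spec.backward_edges:
        names += [f"B:{s}->{t}:DP-SP", f"B:{s}->{t}:DP-II"]
    for s, t in spec.forward_edges:
        names.append(f"Mod:F:{s}->{t}")
    for s, t in spec.backward_edges:
        names.append(f"Mod:B:{s}->{t}")
    for r in spec.regions:
        names.append(f"G:{r}")
    names += [f"T:{p}" for p in POPULATIONS]
    names += ["U:amp", "U:exp", "N:amp", "N:exp"]
    for r in spec.regions:
        names.append(f"L:{r}")
    return tuple(names)


@dataclass
class CMCParams:
    """Log-scaling parameter set for one subject under one architecture."""

    names: tuple
    values: np.ndarray
    bump_amplitude: float = 1.0
    bump_latency_ms: float = 80.0
    bump_width_ms: float = 16.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise SchemaError("parameter vector length does not match names")
        self._index = {n: i for i, n in enumerate(self.names)}

    @classmethod
    def prior_mean(cls, spec: NetworkSpec) -> "CMCParams":
        names = parameter_names(spec)
        return cls(names=names, values=np.zeros(len(names)))

    def get(self, name: str) -> float:
        try:
            return float(self.values[self._index[name]])
        except KeyError:
            raise SchemaError(f"unknown parameter {name!r}") from None

    def with_updates(self, **by_name) -> "CMCParams":
        return self.updated(by_name)

    def updated(self, by_name: dict) -> "CMCParams":
        unknown = sorted(set(by_name) - set(self._index))
        if unknown:
            raise SchemaError(f"unknown parameters: {unknown}")
        values = self.values.copy()
        for n, v in by_name.items():
            values[self._index[n]] = v
        return replace(self, values=values)

    def copy(self) -> "CMCParams":
        return replace(self, values=self.values.copy())


@dataclass
class CrossSpectra:
    """Complex cross-spectral densities, frequencies x region x region."""

    freqs: np.ndarray
    regions: tuple
    spectra: dict  # condition -> complex ndarray (F, R, R)

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        for cond, s in self.spectra.items():
            s = np.asarray(s, dtype=complex)
            expected = (self.freqs.size, len(self.regions), len(self.regions))
            if s.shape != expected:
                raise SchemaError(
                    f"CSD for {cond!r} has shape {s.shape}, expected {expected}"
                )
            self.spectra[cond] = s

    @property
    def conditions(self) -> tuple:
        return tuple(self.spectra)

    def is_hermitian(self, tol: float = 1e-8) -> bool:
        return all(
            np.allclose(s, np.conj(np.swapaxes(s, 1, 2)), atol=tol * _scale(s))
            for s in self.spectra.values()
        )


def _scale(s: np.ndarray) -> float:
    m = float(np.max(np.abs(s))) if s.size else 1.0
    return m if m > 0 else 1.0


# ---------------------------------------------------------------------------
# parameter unpacking
# ---------------------------------------------------------------------------


def _edge_strengths(params: CMCParams, spec: NetworkSpec, condition: str):
    """Physical forward/backward pathway strengths for one trial condition."""
    if condition not in CONDITIONS:
        raise ConfigurationError(f"condition must be one of {CONDITIONS}")
    fwd, bwd = {}, {}
    for s, t in spec.forward_edges:
        mod = math.exp(params.get(f"Mod:F:{s}->{t}")) if condition == "self_death" else 1.0
        fwd[(s, t)] = (
            EXTRINSIC_SCALE["SP-SS"] * math.exp(params.get(f"F:{s}->{t}:SP-SS")) * mod,
            EXTRINSIC_SCALE["SP-DP"] * math.exp(params.get(f"F:{s}->{t}:SP-DP")) * mod,
        )
    for s, t in spec.backward_edges:
        mod = math.exp(params.get(f"Mod:B:{s}->{t}")) if condition == "self_death" else 1.0
        bwd[(s, t)] = (
            EXTRINSIC_SCALE["DP-SP"] * math.exp(params.get(f"B:{s}->{t}:DP-SP")) * mod,
            EXTRINSIC_SCALE["DP-II"] * math.exp(params.get(f"B:{s}->{t}:DP-II")) * mod,
        )
    return fwd, bwd


def _region_tables(params: CMCParams, spec: NetworkSpec, wiring: IntrinsicWiring):
    """Per-region intrinsic weight matrices and rate constants."""
    base = wiring.weight_matrix()
    kap = wiring.kappas() * np.exp(
        -np.array([params.get(f"T:{p}") for p in POPULATIONS])
    )
    tables = []
    i_sp = POPULATIONS.index("SP")
    for r in spec.regions:
        w = base.copy()
        w[i_sp, i_sp] *= math.exp(params.get(f"G:{r}"))
        tables.append(w)
    return tables, kap


def _sigmoid(v: np.ndarray, rho: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-rho * v)) - 0.5


# ---------------------------------------------------------------------------
# nonlinear time-domain integration
# ---------------------------------------------------------------------------


def sample_innovations(
    params: CMCParams,
    n_samples: int,
    dt: float,
    rng: np.random.Generator,
    n_regions: int = 3,
    n_batch: int = 1,
) -> np.ndarray:
    """Draw neuronal-innovations time series with the parameterized spectrum.

    White Gaussian noise is colored in the frequency domain so that the
    one-sided power spectral density of the output matches the innovations
    spectrum g_u(f) used by :func:`predict_csd` (the DC bin is zeroed).
    Returns an array of shape ``(n_batch, n_regions, n_samples)``.
    """
    a = INNOVATIONS_SCALE * math.exp(params.get("U:amp"))
    b = math.exp(params.get("U:exp"))
    freqs = np.fft.rfftfreq(n_samples, dt)
    amp = np.zeros_like(freqs)
    pos = freqs > 0
    gu = a * (freqs[pos] ** (-b) + INNOVATIONS_FLOOR)
    # unit white noise has E|X_k|^2 = n; one-sided PSD of y is 2 dt |Y_k|^2 / n
    amp[pos] = np.sqrt(gu / (2.0 * dt))
    white = rng.standard_normal((n_batch, n_regions, n_samples))
    spec = np.fft.rfft(white, axis=-1) * amp
    return np.fft.irfft(spec, n=n_samples, axis=-1)


def _rhs_factory(params, spec, wiring, condition):
    """Vectorized CMC right-hand side over a batch of state vectors."""
    R = spec.n_regions
    rho = wiring.sigmoid_slope
    tables, kap = _region_tables(params, spec, wiring)
    w_int = np.stack(tables)  # (R, 4, 4)
    fwd, bwd = _edge_strengths(params, spec, condition)
    ridx = {r: i for i, r in enumerate(spec.regions)}
    i_in = ridx[spec.input_region]
    # extrinsic coupling matrices per (target pop <- source pop)
    a_ss_sp = np.zeros((R, R))  # forward, target SS <- source SP
    a_dp_sp = np.zeros((R, R))  # forward, target DP <- source SP
    a_sp_dp = np.zeros((R, R))  # backward, target SP <- source DP (inhibitory)
    a_ii_dp = np.zeros((R, R))  # backward, target II <- source DP (inhibitory)
    for (s, t), (g1, g2) in fwd.items():
        a_ss_sp[ridx[t], ridx[s]] = g1
        a_dp_sp[ridx[t], ridx[s]] = g2
    for (s, t), (g1, g2) in bwd.items():
        a_sp_dp[ridx[t], ridx[s]] = -g1
        a_ii_dp[ridx[t], ridx[s]] = -g2

    def rhs(v, i, drive_ss):
        """v, i: (batch, R, 4); drive_ss: (batch, R) exogenous input to SS."""
        s = _sigmoid(v, rho)
        u = np.einsum("rpq,brq->brp", w_int, s)
        s_sp, s_dp = s[..., 1], s[..., 3]
        u[..., 0] += s_sp @ a_ss_sp.T + drive_ss
        u[..., 3] += s_sp @ a_dp_sp.T
        u[..., 1] += s_dp @ a_sp_dp.T
        u[..., 2] += s_dp @ a_ii_dp.T
        dv = i
        di = (u - 2.0 * i) * kap - v * kap**2
        return dv, di

    return rhs, i_in


def simulate_timeseries(
    params: CMCParams,
    spec: NetworkSpec,
    duration: float,
    dt: float = 1e-3,
    condition: str = "self_life",
    innovations: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    wiring: IntrinsicWiring = DEFAULT_INTRINSIC,
    return_states: bool = False,
):
    """Integrate the CMC dynamics and return observed per-region traces.

    The observation is the electrode-gain-scaled SP depolarization.  A
    Gaussian bump drives the input region's SS population; optional
    ``innovations`` (shape ``(R, T)`` or ``(batch, R, T)``) add stochastic
    neuronal drive, or are drawn from ``rng`` when provided.  Integration uses
    Heun's method; any state exceeding ``STATE_BOUND`` raises
    :class:`StabilityError`.

    Returns ``(t, y)`` with ``y`` of shape ``(R, T)`` (or ``(batch, R, T)``
    for batched innovations); with ``return_states=True`` the full state
    arrays are appended.
    """
    if dt <= 0 or dt > 1.5e-3:
        raise ConfigurationError("dt must be positive and at most ~1 ms")
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    R = spec.n_regions
    rhs, i_in = _rhs_factory(params, spec, wiring, condition)

    batched = True
    if innovations is None and rng is not None:
        innovations = sample_innovations(params, n, dt, rng, n_regions=R)[0]
    if innovations is None:
        innov = np.zeros((1, R, n))
        batched = False
    else:
        innov = np.asarray(innovations, dtype=float)
        if innov.ndim == 2:
            innov = innov[None]
            batched = False
        if innov.shape[1:] != (R, n):
            raise ConfigurationError(
                f"innovations must have shape (..., {R}, {n})"
            )
    nb = innov.shape[0]

    lat = params.bump_latency_ms / 1000.0
    wid = params.bump_width_ms / 1000.0
    bump = params.bump_amplitude * np.exp(-((t - lat) ** 2) / (2.0 * wid**2))

    v = np.zeros((nb, R, 4))
    i = np.zeros((nb, R, 4))
    i_sp = POPULATIONS.index("SP")
    gains = OBSERVATION_SCALE * np.exp(
        [params.get(f"L:{r}") for r in spec.regions]
    )
    y = np.empty((nb, R, n))
    vs = np.empty((nb, R, 4, n)) if return_states else None

    drive = np.zeros((nb, R))
    for k in range(n):
        drive[:] = innov[:, :, k]
        drive[:, i_in] += bump[k]
        dv1, di1 = rhs(v, i, drive)
        vp = v + dt * dv1
        ip = i + dt * di1
        dv2, di2 = rhs(vp, ip, drive)
        v = v + 0.5 * dt * (dv1 + dv2)
        i = i + 0.5 * dt * (di1 + di2)
        if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > STATE_BOUND:
            raise StabilityError(
                f"state bound exceeded at t={t[k]:.3f}s "
                f"(model {spec.model_id}, condition {condition})"
            )
        y[:, :, k] = v[:, :, i_sp] * gains
        if return_states:
            vs[:, :, :, k] = v

    if not batched:
        y = y[0]
        if return_states:
            vs = vs[0]
    return (t, y, vs) if return_states else (t, y)


# ---------------------------------------------------------------------------
# linearization and spectral prediction
# ---------------------------------------------------------------------------


def system_matrix(
    params: CMCParams,
    spec: NetworkSpec,
    condition: str,
    wiring: IntrinsicWiring = DEFAULT_INTRINSIC,
):
    """Jacobian A, innovations input matrix C and observation matrix L.

    The dynamics are linearized at the quiescent fixed point (zero
    depolarization), which is exact here because the sigmoid output is zero at
    rest and the stochastic drive is zero-mean.  States are ordered
    region-major as ``[v_SS, i_SS, v_SP, i_SP, v_II, i_II, v_DP, i_DP]``.
    """
    R = spec.n_regions
    rho = wiring.sigmoid_slope
    dsig = rho / 4.0  # sigmoid derivative at rest
    tables, kap = _region_tables(params, spec, wiring)
    fwd, bwd = _edge_strengths(params, spec, condition)
    ridx = {r: i for i, r in enumerate(spec.regions)}

    n = 8 * R
    A = np.zeros((n, n))

    def vi(r, p):  # state indices for region r, population p
        base = 8 * r + 2 * POPULATIONS.index(p)
        return base, base + 1

    for r in range(R):
        w = tables[r]
        for pi, p in enumerate(POPULATIONS):
            iv, ii = vi(r, p)
            A[iv, ii] = 1.0
            A[ii, iv] += -kap[pi] ** 2
            A[ii, ii] = -2.0 * kap[pi]
            for qi, q in enumerate(POPULATIONS):
                jv, _ = vi(r, q)
                A[ii, jv] += kap[pi] * w[pi, qi] * dsig

    k = {p: kap[i] for i, p in enumerate(POPULATIONS)}
    for (s, t), (g1, g2) in fwd.items():
        sv, _ = vi(ridx[s], "SP")
        A[vi(ridx[t], "SS")[1], sv] += k["SS"] * g1 * dsig
        A[vi(ridx[t], "DP")[1], sv] += k["DP"] * g2 * dsig
    for (s, t), (g1, g2) in bwd.items():
        sv, _ = vi(ridx[s], "DP")
        A[vi(ridx[t], "SP")[1], sv] += -k["SP"] * g1 * dsig
        A[vi(ridx[t], "II")[1], sv] += -k["II"] * g2 * dsig

    C = np.zeros((n, R))
    for r in range(R):
        C[vi(r, "SS")[1], r] = k["SS"]

    L = np.zeros((R, n))
    for r, name in enumerate(spec.regions):
        L[r, vi(r, "SP")[0]] = OBSERVATION_SCALE * math.exp(params.get(f"L:{name}"))
    return A, C, L


def transfer_functions(
    params: CMCParams,
    spec: NetworkSpec,
    freqs: np.ndarray,
    condition: str,
    wiring: IntrinsicWiring = DEFAULT_INTRINSIC,
) -> np.ndarray:
    """Frequency response H(f) from per-region innovations to observations.

    Returns a complex array of shape ``(F, R, R)``; raises
    :class:`StabilityError` if the linearized dynamics have an eigenvalue with
    positive real part.
    """
    A, C, L = system_matrix(params, spec, condition, wiring)
    lam, V = np.linalg.eig(A)
    if np.max(lam.real) > 1e-9:
        raise StabilityError(
            f"unstable linearization (max Re eig = {np.max(lam.real):.4g}) "
            f"for model {spec.model_id}, condition {condition}"
        )
    LV = L @ V
    VC = np.linalg.solve(V, C.astype(complex))
    iw = 2j * np.pi * np.asarray(freqs, dtype=float)
    resolvent = 1.0 / (iw[:, None] - lam[None, :])  # (F, n)
    return np.einsum("ri,fi,ic->frc", LV, resolvent, VC)


def _drive_spectra(params: CMCParams, freqs: np.ndarray):
    f = np.asarray(freqs, dtype=float)
    gu = (
        INNOVATIONS_SCALE
        * math.exp(params.get("U:amp"))
        * (f ** (-math.exp(params.get("U:exp"))) + INNOVATIONS_FLOOR)
    )
    gn = (
        CHANNEL_SCALE
        * math.exp(params.get("N:amp"))
        * (f ** (-math.exp(params.get("N:exp"))) + CHANNEL_FLOOR)
    )
    return gu, gn


def predict_csd(
    params: CMCParams,
    spec: NetworkSpec,
    freqs: np.ndarray,
    condition: str,
    wiring: IntrinsicWiring = DEFAULT_INTRINSIC,
) -> CrossSpectra:
    """Predicted cross-spectral density for one trial condition.

    CSD(f) = H(f) G_u(f) H(f)* + G_n(f), with G_u the (shared, diagonal)
    neuronal-innovations spectrum and G_n the diagonal channel-noise spectrum.
    Hermitian and positive semidefinite by construction.
    """
    f = np.asarray(freqs, dtype=float)
    if f.size == 0 or f.min() < 1.0 - 1e-9 or f.max() > 58.0 + 1e-9:
        raise ConfigurationError("frequencies must lie within the 1-58 Hz band")
    H = transfer_functions(params, spec, f, condition, wiring)
    gu, gn = _drive_spectra(params, f)
    S = gu[:, None, None] * (H @ np.conj(np.swapaxes(H, 1, 2)))
    S[:, np.arange(spec.n_regions), np.arange(spec.n_regions)] += gn[:, None]
    # enforce exact Hermitian symmetry against round-off
    S = 0.5 * (S + np.conj(np.swapaxes(S, 1, 2)))
    return CrossSpectra(freqs=f, regions=spec.regions, spectra={condition: S})


def default_freqs() -> np.ndarray:
    """The fitted frequency grid: 1-58 Hz at 1 Hz resolution."""
    return np.arange(1.0, 59.0)
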