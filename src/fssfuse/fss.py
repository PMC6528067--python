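"""Functional Source Separation of a steady-state evoked source.

Semi-blind source extraction: a single unmixing vector ``w`` over the
EEG channels is chosen to maximize

    F(w) = sum over phases of  J(w) + lambda * psi(R_stim(w), k)

where ``J`` is the log-cosh negentropy approximation used by fastICA
(non-Gaussianity of the unit-variance projection ``w^T x``), ``R_stim``
is the stimulus-response functional — the mean Hilbert envelope of the
trial-averaged projected source during stimulation minus the mean
envelope during the pre-stimulus baseline — and ``psi`` saturates at 1
once ``R_stim`` reaches the admissibility scale ``k`` (the maximal
``R_stim`` over a plain fastICA decomposition of the same phase).  With
``lambda = 0`` the method reduces to single-component ICA and serves as
the comparison mode.

The functional term is non-differentiable, so the contrast is maximized
by simulated annealing on the unit sphere of channel weights, warm
started at the best fastICA component and jointly over all phases.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import integrate, signal
from scipy.fft import next_fast_len
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from ._fast import mean_logcosh, mean_var
from .preprocess import Recording, epoch

__all__ = [
    "ContrastParams", "PhaseData", "EvokedAverage", "AnnealSchedule",
    "FssResult", "IcaDecomposition", "IcaConvergenceError",
    "g_logcosh", "gauss_reference", "negentropy_J", "evoked_average",
    "r_stim", "saturation_H", "estimate_k", "ica_decompose",
    "contrast_F", "anneal_optimize", "extract_source", "prepare_phases",
    "hilbert_envelope", "run_fss",
]

K_FLOOR = 1e-6  # positive floor for the admissibility scale on null data


class IcaConvergenceError(RuntimeError):
    """fastICA failed to converge after the allowed retries."""


class ZeroVarianceError(ValueError):
    """Projection has zero variance; the unit-variance constraint is undefined."""


# --------------------------------------------------------------------------
# contrast ingredients
# --------------------------------------------------------------------------

def g_logcosh(u, a1: float = 1.0):
    """The fastICA nonlinearity G(u) = log(cosh(a1 u)) / a1 (even, >= 0).

    Evaluated through ``|x| + log1p(e^{-2|x|}) - log 2`` so it is stable
    for arbitrarily large ``|u|``.
    """
    if not 1.0 <= a1 <= 2.0:
        raise ValueError("a1 must lie in [1, 2]")
    x = a1 * np.asarray(u, dtype=float)
    ax = np.abs(x)
    return (ax + np.log1p(np.exp(-2.0 * ax)) - math.log(2.0)) / a1


@lru_cache(maxsize=None)
def gauss_reference(a1: float = 1.0) -> float:
    """E{G(v)} for standard-normal v, by adaptive quadrature."""
    if not 1.0 <= a1 <= 2.0:
        raise ValueError("a1 must lie in [1, 2]")

    def integrand(v):
        return float(g_logcosh(v, a1)) * math.exp(-0.5 * v * v) / math.sqrt(2 * math.pi)

    val, _ = integrate.quad(integrand, 0.0, 12.0, limit=200)
    return 2.0 * val  # integrand is even


@dataclass
class ContrastParams:
    """Weights, windows and per-phase admissibility scales of the contrast.

    lambda_weight balances independence (J) against the functional
    constraint (default 10 for steady-state recovery); t_s..t_e is the
    stimulation integral window, t_b..0 the pre-stimulus baseline, in
    seconds relative to trial onset.
    """

    lambda_weight: float = 10.0
    a1: float = 1.0
    t_s: float = 0.0
    t_e: float = 5.0
    t_b: float = -1.0
    gauss_ref: float = field(init=False)

    def __post_init__(self):
        if not 1.0 <= self.a1 <= 2.0:
            raise ValueError("a1 must lie in [1, 2]")
        if not self.t_b < 0 <= self.t_s < self.t_e:
            raise ValueError("need t_b < 0 <= t_s < t_e")
        self.gauss_ref = gauss_reference(self.a1)


@dataclass
class EvokedAverage:
    """Trial-averaged projected source on the epoch window."""

    values: np.ndarray
    fs: float
    window: tuple[float, float]

    def __post_init__(self):
        expected = int(round((self.window[1] - self.window[0]) * self.fs)) + 1
        if self.values.size != expected:
            raise ValueError(
                f"evoked length {self.values.size} inconsistent with "
                f"window {self.window} at fs={self.fs}"
            )


@dataclass
class PhaseData:
    """One phase's narrowband recording prepared for optimization.

    ``x`` is samples x channels (C-contiguous for fast projections);
    ``mean_epoch`` is the per-channel trial average on the epoch window,
    so the evoked response of any projection is just ``w @ mean_epoch``.
    ``k`` is the admissibility scale, set by :func:`estimate_k` before
    FSS optimization.
    """

    phase_id: str
    x: np.ndarray                 # samples x channels, narrowband
    fs: float
    onsets: np.ndarray            # seconds
    window: tuple[float, float] = (-1.0, 7.0)
    mean_epoch: np.ndarray | None = None   # channels x window samples
    k: float | None = None
    ica: "IcaDecomposition | None" = None

    @classmethod
    def from_recording(cls, rec: Recording, schedule,
                       window: tuple[float, float] = (-1.0, 7.0)) -> "PhaseData":
        """Prepare a narrowband recording + schedule for optimization."""
        onsets = np.asarray(getattr(schedule, "onsets", schedule), dtype=float)
        phase_id = getattr(schedule, "phase_id", "?")
        ep = epoch(rec, onsets, *window)
        return cls(
            phase_id=phase_id,
            x=np.ascontiguousarray(rec.data.T, dtype=np.float32),
            fs=rec.fs,
            onsets=onsets,
            window=window,
            mean_epoch=ep.mean(),
        )

    @property
    def n_channels(self) -> int:
        return self.x.shape[1]

    def project(self, w: np.ndarray) -> np.ndarray:
        return self.x @ np.asarray(w, dtype=self.x.dtype)


def hilbert_envelope(x: np.ndarray, pad: int = 0) -> np.ndarray:
    """Instantaneous amplitude |analytic signal|, mirror-padded against edge bias."""
    x = np.asarray(x, dtype=float)
    if pad > 0:
        pad = min(pad, x.size - 1)
        x = np.concatenate([x[pad:0:-1], x, x[-2:-pad - 2:-1]])
    n = x.size
    nfft = next_fast_len(n)
    env = np.abs(signal.hilbert(x, N=nfft)[:n])
    if pad > 0:
        env = env[pad:n - pad]
    return env


def negentropy_J(w: np.ndarray, phase: PhaseData, params: ContrastParams) -> float:
    """Log-cosh negentropy approximation of the unit-variance projection."""
    u = phase.project(w)
    m, v = mean_var(u)
    if v <= 1e-300:
        raise ZeroVarianceError("projection w^T x has zero variance")
    mg = mean_logcosh(u, m, 1.0 / math.sqrt(v), params.a1)
    return float((mg - params.gauss_ref) ** 2)


def evoked_average(w: np.ndarray, phase: PhaseData,
                   scale: float | None = None) -> EvokedAverage:
    """Trial average of the unit-variance projected source.

    ``scale`` (the projection's standard deviation over the whole
    recording) may be passed in to avoid recomputation; otherwise it is
    derived from the data.
    """
    if phase.mean_epoch is None:
        raise ValueError("phase has no precomputed mean epoch")
    w = np.asarray(w, dtype=float)
    if scale is None:
        _, v = mean_var(phase.project(w))
        if v <= 1e-300:
            raise ZeroVarianceError("projection w^T x has zero variance")
        scale = math.sqrt(v)
    values = (w / scale) @ phase.mean_epoch
    return EvokedAverage(values=values, fs=phase.fs, window=phase.window)


def r_stim(ea: EvokedAverage, params: ContrastParams) -> float:
    """Stimulus-response functional.

    Mean Hilbert envelope of the evoked average over [t_s, t_e] minus the
    mean envelope over the baseline [t_b, 0].  The envelope is computed
    with 1 s mirror padding so transform edge artifacts stay outside the
    integration windows.
    """
    t0, t1 = ea.window
    if t0 > params.t_b or t1 < params.t_e:
        raise ValueError(
            f"epoch window {ea.window} does not cover [{params.t_b}, {params.t_e}]"
        )
    env = hilbert_envelope(ea.values, pad=int(round(ea.fs)))
    fs = ea.fs

    def seg(lo, hi):
        i0 = int(round((lo - t0) * fs))
        i1 = int(round((hi - t0) * fs)) + 1
        return env[i0:i1].mean()

    return float(seg(params.t_s, params.t_e) - seg(params.t_b, 0.0))


def saturation_H(r: float, k: float) -> float:
    """psi(R_stim, k): linear in r below the admissibility scale, 1 above."""
    if k <= 0:
        raise ValueError("admissibility scale k must be positive")
    return r / k if r <= k else 1.0


# --------------------------------------------------------------------------
# fastICA: admissibility scale and warm starts
# --------------------------------------------------------------------------

@dataclass
class IcaDecomposition:
    """Unmixing rows (components x channels) with per-component scores."""

    unmixing: np.ndarray
    r_stims: np.ndarray
    js: np.ndarray
    seed: int
    converged: bool


def ica_decompose(phase: PhaseData, params: ContrastParams | None = None,
                  n_components: int | None = None, seed: int = 0,
                  decim: int = 8, max_iter: int = 200, tol: float = 1e-3,
                  retries: int = 0, strict: bool = False) -> IcaDecomposition:
    """fastICA decomposition of the phase's narrowband data.

    Estimation runs on temporally decimated samples (the narrowband data
    is heavily oversampled at the recording rate, so plain decimation
    loses nothing the mixing estimate needs); component scores are then
    evaluated on the full-resolution data.

    The fixed-point iteration frequently stops at ``max_iter`` on
    narrowband EEG without meeting sklearn's tolerance even though the
    components are perfectly usable, so by default a flagged,
    non-converged decomposition is returned after the reseeded retries;
    ``strict=True`` raises :class:`IcaConvergenceError` instead.
    """
    params = params or ContrastParams()
    xd = phase.x[:: max(1, decim)]
    last_w = None
    converged = False
    used_seed = seed
    for attempt in range(retries + 1):
        used_seed = seed + 101 * attempt
        ica = FastICA(
            n_components=n_components, whiten="unit-variance",
            fun="logcosh", fun_args={"alpha": params.a1},
            max_iter=max_iter, tol=tol, random_state=used_seed,
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always", ConvergenceWarning)
            ica.fit(xd)
        last_w = ica.components_
        if not any(issubclass(c.category, ConvergenceWarning) for c in caught):
            converged = True
            break
    if not converged:
        if strict or last_w is None:
            raise IcaConvergenceError(
                f"fastICA did not converge after {retries + 1} seeded attempts"
            )
        warnings.warn("fastICA stopped at max_iter; using last decomposition",
                      RuntimeWarning)
    r_list, j_list = [], []
    for row in last_w:
        _, v = mean_var(phase.project(row))
        if v <= 1e-300:
            r_list.append(0.0)
            j_list.append(0.0)
            continue
        ea = evoked_average(row, phase, scale=math.sqrt(v))
        r_list.append(r_stim(ea, params))
        j_list.append(negentropy_J(row, phase, params))
    return IcaDecomposition(
        unmixing=last_w, r_stims=np.asarray(r_list), js=np.asarray(j_list),
        seed=used_seed, converged=converged,
    )


def estimate_k(phase: PhaseData, params: ContrastParams | None = None,
               n_components: int | None = None, seed: int = 0, **kwargs) -> float:
    """Admissibility scale: maximal R_stim over a fastICA decomposition.

    Stored on the phase (with the decomposition, reused as annealing warm
    starts).  On null data the maximum can be <= 0; it is then clamped to
    a small positive floor so the saturation term stays defined.
    """
    dec = ica_decompose(phase, params, n_components=n_components, seed=seed, **kwargs)
    phase.ica = dec
    k = float(max(dec.r_stims.max(), K_FLOOR))
    phase.k = k
    return k


def prepare_phases(phases: list[PhaseData], params: ContrastParams | None = None,
                   n_components: int | None = None, seed: int = 0, **kwargs) -> None:
    """Set the admissibility scale (and warm-start components) on every phase."""
    for i, ph in enumerate(phases):
        estimate_k(ph, params, n_components=n_components, seed=seed + i, **kwargs)


# --------------------------------------------------------------------------
# joint contrast and simulated annealing
# --------------------------------------------------------------------------

def _phase_terms(w: np.ndarray, phase: PhaseData, params: ContrastParams,
                 need_h: bool) -> tuple[float, float | None]:
    """(J, R_stim) of one phase for a unit-sphere direction w."""
    u = phase.project(w)
    m, v = mean_var(u)
    if v <= 1e-300:
        raise ZeroVarianceError("projection w^T x has zero variance")
    inv_sd = 1.0 / math.sqrt(v)
    mg = mean_logcosh(u, m, inv_sd, params.a1)
    j = (mg - params.gauss_ref) ** 2
    r = None
    if need_h:
        ea = evoked_average(w, phase, scale=math.sqrt(v))
        r = r_stim(ea, params)
    return float(j), r


def contrast_F(w: np.ndarray, phases: list[PhaseData], params: ContrastParams,
               combine: str = "sum") -> float:
    """Joint contrast: sum over phases of J + lambda * psi(R_stim, k).

    Scale invariant in ``w`` (each term renormalizes the projection to
    unit variance) and even under sign flip.  ``combine='concat'``
    evaluates a single term on the concatenated phases instead, with the
    maximal per-phase k.
    """
    if combine == "concat" and len(phases) > 1:
        phases = [concatenate_phases(phases)]
    lam = params.lambda_weight
    total = 0.0
    for ph in phases:
        need_h = lam != 0.0
        if need_h and ph.k is None:
            raise ValueError(f"phase {ph.phase_id}: k not set (run estimate_k first)")
        j, r = _phase_terms(w, ph, params, need_h)
        total += j
        if need_h:
            total += lam * saturation_H(r, ph.k)
    return float(total)


def concatenate_phases(phases: list[PhaseData]) -> PhaseData:
    """Single pseudo-phase from several phases (shared channel space)."""
    fs = phases[0].fs
    window = phases[0].window
    x = np.vstack([p.x for p in phases])
    onsets, offset = [], 0.0
    for p in phases:
        onsets.append(p.onsets + offset)
        offset += p.x.shape[0] / fs
    weights = np.array([len(p.onsets) for p in phases], dtype=float)
    mean_epoch = sum(wt * p.mean_epoch for wt, p in zip(weights, phases)) / weights.sum()
    ks = [p.k for p in phases if p.k is not None]
    return PhaseData(
        phase_id="+".join(p.phase_id for p in phases),
        x=x, fs=fs, onsets=np.concatenate(onsets), window=window,
        mean_epoch=mean_epoch, k=max(ks) if ks else None,
    )


@dataclass
class AnnealSchedule:
    """Simulated-annealing settings.

    Temperature defaults to auto-calibration (set from the spread of
    contrast changes under initial proposals), cools geometrically to
    ``temp_floor_ratio`` of the start, with ``steps_per_temp`` proposals
    per level; ``restarts`` random restarts follow the warm start, and a
    greedy small-step polish finishes from the best point.
    """

    initial_temp: float | None = None
    cooling: float = 0.85
    steps_per_temp: int = 10
    temp_floor_ratio: float = 1e-2
    step_scale: float = 0.3
    restarts: int = 1
    polish_steps: int = 100
    subsample: int = 2   # temporal stride of the optimizer's objective
    seed: int = 0


@dataclass
class FssResult:
    """Optimum of the joint contrast and its diagnostics."""

    w: np.ndarray
    channel_labels: list[str] | None
    contrast: float
    sources: dict[str, np.ndarray]
    trace: np.ndarray
    phase_diagnostics: dict[str, dict[str, float]]
    mode: str
    no_accept_warning: bool = False

    @property
    def fitted_variance(self) -> float:
        return 1.0


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector cannot be normalized")
    return v / n


def anneal_optimize(phases: list[PhaseData], params: ContrastParams,
                    schedule: AnnealSchedule | None = None,
                    channel_labels: list[str] | None = None,
                    combine: str = "sum") -> FssResult:
    """Maximize the joint contrast over unit-sphere directions.

    Deterministic given the schedule seed.  Warm start: the fastICA
    component (over all phases) with the highest joint contrast, when
    decompositions are available; plus ``restarts`` random restarts.
    """
    schedule = schedule or AnnealSchedule()
    if params.lambda_weight != 0.0:
        for ph in phases:
            if ph.k is None:
                raise ValueError(
                    f"phase {ph.phase_id}: k not set; call prepare_phases first"
                )
    rng = np.random.default_rng(schedule.seed)
    n_ch = phases[0].n_channels
    if any(p.n_channels != n_ch for p in phases):
        raise ValueError("phases disagree on channel count")

    # the optimizer may score proposals on temporally strided samples;
    # reported diagnostics always use the full-resolution data
    opt_phases = _strided_phases(phases, schedule.subsample)

    def objective(w):
        return contrast_F(w, opt_phases, params, combine=combine)

    starts: list[np.ndarray] = []
    candidates = [row for ph in phases if ph.ica is not None
                  for row in ph.ica.unmixing]
    if candidates:
        scores = [objective(_unit(c)) for c in candidates]
        starts.append(_unit(candidates[int(np.argmax(scores))]))
    for _ in range(schedule.restarts):
        starts.append(_unit(rng.standard_normal(n_ch)))

    best_w, best_f = None, -np.inf
    trace: list[float] = []
    accepted_total = 0
    for w0 in starts:
        w = w0.copy()
        f = objective(w)
        if f > best_f:
            best_w, best_f = w.copy(), f
        t0 = schedule.initial_temp
        if t0 is None:
            deltas = []
            for _ in range(12):
                probe = _unit(w + schedule.step_scale * rng.standard_normal(n_ch))
                deltas.append(abs(objective(probe) - f))
            t0 = max(float(np.median(deltas)), 1e-9)
        t = t0
        t_end = t0 * schedule.temp_floor_ratio
        while t > t_end:
            step = schedule.step_scale * max(math.sqrt(t / t0), 0.1)
            for _ in range(schedule.steps_per_temp):
                w_new = _unit(w + step * rng.standard_normal(n_ch))
                f_new = objective(w_new)
                if f_new >= f or rng.random() < math.exp((f_new - f) / t):
                    w, f = w_new, f_new
                    accepted_total += 1
                if f > best_f:
                    best_w, best_f = w.copy(), f
                trace.append(best_f)
            t *= schedule.cooling
    # greedy polish around the optimum
    w, f = best_w.copy(), best_f
    for _ in range(schedule.polish_steps):
        w_new = _unit(w + 0.02 * rng.standard_normal(n_ch))
        f_new = objective(w_new)
        if f_new > f:
            w, f = w_new, f_new
        trace.append(f)
    best_w, best_f = w, f

    best_w = _fix_sign(best_w)
    best_f = contrast_F(best_w, phases, params, combine=combine)
    diagnostics = {}
    sources = {}
    for ph in phases:
        j, r = _phase_terms(best_w, ph, params, need_h=True)
        diagnostics[ph.phase_id] = {
            "J": j,
            "R_stim": r,
            "H": saturation_H(r, ph.k) if ph.k else float("nan"),
            "k": ph.k if ph.k is not None else float("nan"),
        }
        sources[ph.phase_id] = extract_source(best_w, ph)
    mode = "ica" if params.lambda_weight == 0.0 else "fss"
    if accepted_total == 0:
        warnings.warn("simulated annealing accepted no moves", RuntimeWarning)
    return FssResult(
        w=best_w, channel_labels=channel_labels, contrast=best_f,
        sources=sources, trace=np.asarray(trace),
        phase_diagnostics=diagnostics, mode=mode,
        no_accept_warning=(accepted_total == 0),
    )


def _strided_phases(phases: list[PhaseData], stride: int) -> list[PhaseData]:
    if stride <= 1:
        return phases
    out = []
    for ph in phases:
        cp = PhaseData(
            phase_id=ph.phase_id, x=np.ascontiguousarray(ph.x[::stride]),
            fs=ph.fs, onsets=ph.onsets, window=ph.window,
            mean_epoch=ph.mean_epoch, k=ph.k, ica=ph.ica,
        )
        out.append(cp)
    return out


def _fix_sign(w: np.ndarray) -> np.ndarray:
    """Sign convention: the largest-|weight| channel gets a positive weight."""
    return w if w[np.argmax(np.abs(w))] >= 0 else -w


def extract_source(w: np.ndarray, phase: PhaseData) -> np.ndarray:
    """Unit-variance projected source w^T x for one phase."""
    u = phase.project(w)
    m, v = mean_var(u)
    if v <= 1e-300:
        raise ZeroVarianceError("projection w^T x has zero variance")
    return (u - m) / math.sqrt(v)


def run_fss(phases: list[PhaseData], params: ContrastParams | None = None,
            schedule: AnnealSchedule | None = None, mode: str = "fss",
            ica_seed: int = 0, n_components: int | None = None,
            channel_labels: list[str] | None = None,
            combine: str = "sum") -> FssResult:
    """Prepare phases (fastICA k estimation) and run the joint optimization.

    ``mode='ica'`` zeroes the functional weight, giving the
    simulated-annealing ICA comparison on identical data.
    """
    params = params or ContrastParams()
    if mode == "ica":
        params = ContrastParams(
            lambda_weight=0.0, a1=params.a1,
            t_s=params.t_s, t_e=params.t_e, t_b=params.t_b,
        )
    elif mode != "fss":
        raise ValueError("mode must be 'fss' or 'ica'")
    if any(ph.ica is None or ph.k is None for ph in phases):
        prepare_phases(phases, params, n_components=n_components, seed=ica_seed)
    return anneal_optimize(phases, params, schedule,
                           channel_labels=channel_labels, combine=combine)
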