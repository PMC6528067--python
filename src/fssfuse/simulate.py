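"""EEG-fMRI co-simulation with known ground truth.

Generates the three ingredients the fusion pipeline assumes:

1. a steady-state visual evoked potential (ssVEP) source — a 10 Hz
   oscillation phase-locked to trial onsets, gated on for the stimulus
   duration with smooth ramps, and with log-normal trial-to-trial
   amplitude fluctuation;
2. sensor EEG as a linear mixture of that source, an ongoing
   alpha-band distractor and broadband noise sources, projected through
   a fixed topography (occipitally weighted for the ssVEP) plus
   sensor-level white noise;
3. BOLD voxel series in which a subset of voxels follows the
   hemodynamically delayed single-trial ssVEP amplitude and the rest
   are pure noise.

Everything is driven by a single :class:`SimConfig` and a seed, and all
intermediate quantities (sources, mixing matrix, sensor noise, coupled
voxel indices) are retained so downstream estimators can be scored
against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .preprocess import Recording

PHASES = ("HAB", "ACQ", "EXT")

#: 31 scalp sites of the extended 10-20 montage used for simulation.
CHANNELS_31 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "TP9", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "POz", "O1", "Oz", "O2",
]

POSTERIOR_CHANNEL = "Oz"


class ScheduleError(ValueError):
    """Raised for inconsistent trial schedules."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the co-simulation.

    Defaults reproduce the study conditions the pipeline targets:
    31-channel EEG at 250 Hz, 40 trials per phase of a 5.1 s stimulus
    whose contrast reverses every 100 ms (second-harmonic ssVEP at
    10 Hz), inter-trial interval uniform(0, 8) s plus a 3 s fixation
    cross, and BOLD sampled at TR = 1.98 s.
    """

    n_channels: int = 31
    fs: float = 250.0
    ssvep_freq: float = 10.0
    stim_duration: float = 5.1
    reversal_interval: float = 0.1
    n_trials: int = 40
    iti_max: float = 8.0
    fixation_duration: float = 3.0
    ramp_duration: float = 0.1
    trial_amp_sigma: float = 0.4
    alpha_distractor_freq: float = 10.5
    alpha_bandwidth: float = 1.5
    alpha_amp: float = 1.5
    alpha_mod_sigma: float = 1.0
    n_noise_sources: int = 10
    noise_band: tuple[float, float] = (0.5, 30.0)
    snr_sensor: float = 1.0
    # BOLD side
    n_voxels: int = 512
    n_coupled: int = 48
    grid_shape: tuple[int, int, int] = (8, 8, 8)
    coupling: float = 0.5
    coupling_mode: str = "hrf"  # "hrf" | "shift"
    tr: float = 1.98
    hrf_lag: float = 4.0
    bold_ar1: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 2 * 30.0:
            raise ValueError("sampling rate must exceed twice the 30 Hz band edge")
        if not 0 < self.n_coupled < self.n_voxels:
            raise ValueError("need 0 < n_coupled < n_voxels")
        if self.ssvep_freq >= self.fs / 2:
            raise ValueError("ssVEP frequency must be below Nyquist")
        if self.coupling_mode not in ("hrf", "shift"):
            raise ValueError("coupling_mode must be 'hrf' or 'shift'")


@dataclass
class TrialSchedule:
    """Trial onset times for one experimental phase."""

    phase_id: str
    onsets: np.ndarray  # seconds from recording start
    stim_duration: float
    reversal_interval: float

    @property
    def n_trials(self) -> int:
        return len(self.onsets)

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.size == 0:
            raise ScheduleError("schedule has no trials")
        if np.any(np.diff(self.onsets) <= 0):
            raise ScheduleError("onsets must be strictly increasing")

    def span(self) -> float:
        """Seconds from start to the end of the last stimulus."""
        return float(self.onsets[-1] + self.stim_duration)


@dataclass
class GroundTruth:
    """Latent sources and mixing used to build one phase's sensor data."""

    source_matrix: np.ndarray        # sources x samples
    mixing_matrix: np.ndarray        # channels x sources
    ssvep_index: int
    trial_amplitudes: np.ndarray     # per-trial envelope scale, > 0
    ssvep_envelope: np.ndarray       # instantaneous ssVEP amplitude, samples
    fs: float
    sensor_noise: np.ndarray | None = None   # channels x samples, set by mixing
    coupled_voxel_ids: np.ndarray | None = None

    @property
    def ssvep_source(self) -> np.ndarray:
        return self.source_matrix[self.ssvep_index]


@dataclass
class BoldDataset:
    """Voxel-by-scan BOLD matrix on a regular TR grid."""

    series: np.ndarray               # voxels x scans
    tr: float
    mask: np.ndarray                 # boolean per voxel
    scan_onsets: np.ndarray          # seconds
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_scans(self) -> int:
        return self.series.shape[1]

    @property
    def n_voxels(self) -> int:
        return self.series.shape[0]


def phase_seed(config: SimConfig, phase_id: str, stream: str = "") -> np.random.Generator:
    """Deterministic per-phase, per-stream random generator."""
    idx = PHASES.index(phase_id) if phase_id in PHASES else 17
    ss = np.random.SeedSequence([int(config.seed), idx, abs(hash(stream)) % (2**31)])
    return np.random.default_rng(ss)


def make_schedule(config: SimConfig, phase_id: str) -> TrialSchedule:
    """Draw one phase's trial onsets.

    Each trial is preceded by a uniform(0, iti_max) gray-cross interval
    plus a fixed fixation period, so consecutive onsets are separated by
    at least ``stim_duration + fixation_duration``.
    """
    if config.n_trials <= 0:
        raise ScheduleError("n_trials must be positive")
    rng = phase_seed(config, phase_id, "schedule")
    itis = rng.uniform(0.0, config.iti_max, size=config.n_trials) + config.fixation_duration
    onsets = np.empty(config.n_trials)
    t = 0.0
    for i in range(config.n_trials):
        t += itis[i]
        # align to the sample grid so t=0 of every epoch is an exact sample
        onsets[i] = round(t * config.fs) / config.fs
        t = onsets[i] + config.stim_duration
    return TrialSchedule(
        phase_id=phase_id,
        onsets=onsets,
        stim_duration=config.stim_duration,
        reversal_interval=config.reversal_interval,
    )


def recording_duration(schedule: TrialSchedule, post: float = 8.0) -> float:
    """Recording length covering the schedule plus a post-stimulus tail."""
    return schedule.span() + post


def _cosine_gate(t: np.ndarray, onset: float, duration: float, ramp: float) -> np.ndarray:
    """Smooth on/off gate: cosine ramps of length `ramp` inside [onset, onset+duration]."""
    g = np.zeros_like(t)
    rel = t - onset
    inside = (rel >= 0) & (rel <= duration)
    g[inside] = 1.0
    if ramp > 0:
        up = inside & (rel < ramp)
        g[up] = 0.5 * (1 - np.cos(np.pi * rel[up] / ramp))
        down = inside & (rel > duration - ramp)
        g[down] = 0.5 * (1 - np.cos(np.pi * (duration - rel[down]) / ramp))
    return g


def _bandpass_noise(rng, n, fs, lo, hi, order=4):
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_sources(
    schedule: TrialSchedule,
    config: SimConfig,
    duration: float | None = None,
) -> GroundTruth:
    """Build the latent source matrix for one phase.

    Row 0 is the ssVEP: a sinusoid at ``ssvep_freq`` phase-locked to each
    trial onset, gated by a smooth envelope over the stimulus period and
    scaled per trial by a log-normal amplitude. Row 1 is an ongoing
    amplitude-modulated alpha-band distractor; remaining rows are
    broadband (0.5-30 Hz) noise.
    """
    if duration is None:
        duration = recording_duration(schedule)
    if schedule.span() > duration:
        raise ScheduleError(
            f"schedule spans {schedule.span():.1f}s but recording is {duration:.1f}s"
        )
    n = int(round(duration * config.fs))
    t = np.arange(n) / config.fs
    rng = phase_seed(config, schedule.phase_id, "sources")

    # --- ssVEP: phase-locked gated oscillation ------------------------------
    trial_amps = np.exp(rng.normal(0.0, config.trial_amp_sigma, size=schedule.n_trials))
    envelope = np.zeros(n)
    carrier = np.zeros(n)
    for onset, amp in zip(schedule.onsets, trial_amps):
        gate = _cosine_gate(t, onset, schedule.stim_duration, config.ramp_duration)
        envelope += amp * gate
        active = gate > 0
        # phase-locked: oscillation phase referenced to trial onset
        carrier[active] = np.sin(2 * np.pi * config.ssvep_freq * (t[active] - onset))
    ssvep = envelope * carrier

    # --- alpha distractor: amplitude-modulated narrowband noise -------------
    half_bw = config.alpha_bandwidth / 2
    alpha_carrier = _bandpass_noise(
        rng, n, config.fs,
        config.alpha_distractor_freq - half_bw,
        config.alpha_distractor_freq + half_bw,
    )
    slow = _lowpass_noise(rng, n, config.fs, cutoff=0.2)
    mod = np.exp(config.alpha_mod_sigma * slow)
    alpha = alpha_carrier * mod
    alpha *= config.alpha_amp / alpha.std()

    # --- broadband noise sources -------------------------------------------
    noise_rows = [
        _bandpass_noise(rng, n, config.fs, *config.noise_band)
        for _ in range(config.n_noise_sources)
    ]

    sources = np.vstack([ssvep, alpha] + noise_rows)
    return GroundTruth(
        source_matrix=sources,
        mixing_matrix=default_mixing(config, n_sources=sources.shape[0]),
        ssvep_index=0,
        trial_amplitudes=trial_amps,
        ssvep_envelope=envelope,
        fs=config.fs,
    )


def _lowpass_noise(rng, n, fs, cutoff):
    sos = signal.butter(2, cutoff, btype="lowpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


# Topography templates: weight per channel-name prefix, posterior-dominant
# for the ssVEP (largest at Oz), parieto-central for alpha.
_SSVEP_TOPO = {
    "Oz": 1.0, "O1": 0.8, "O2": 0.8, "POz": 0.85,
    "P7": 0.45, "P3": 0.5, "Pz": 0.6, "P4": 0.5, "P8": 0.45,
    "CP1": 0.25, "CP2": 0.25, "CP5": 0.2, "CP6": 0.2, "TP9": 0.15, "TP10": 0.15,
}
_ALPHA_TOPO = {
    "Pz": 1.0, "P3": 0.9, "P4": 0.9, "POz": 0.75, "P7": 0.6, "P8": 0.6,
    "CP1": 0.6, "CP2": 0.6, "CP5": 0.45, "CP6": 0.45,
    "Cz": 0.4, "C3": 0.3, "C4": 0.3, "Oz": 0.4, "O1": 0.35, "O2": 0.35,
}


def default_mixing(config: SimConfig, n_sources: int) -> np.ndarray:
    """Channels x sources forward mixing with fixed physiological topographies."""
    labels = channel_labels(config.n_channels)
    a = np.zeros((config.n_channels, n_sources))
    for i, lab in enumerate(labels):
        a[i, 0] = _SSVEP_TOPO.get(lab, 0.08)
        a[i, 1] = _ALPHA_TOPO.get(lab, 0.1)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 999]))
    for j in range(2, n_sources):
        col = rng.standard_normal(config.n_channels)
        # smooth random topography, moderate norm so noise sources are diffuse
        a[:, j] = 0.35 * col / np.linalg.norm(col)
    return a


def channel_labels(n_channels: int) -> list[str]:
    if n_channels == len(CHANNELS_31):
        return list(CHANNELS_31)
    return [f"CH{i:02d}" for i in range(n_channels)]


def mix_to_sensors(
    truth: GroundTruth,
    config: SimConfig,
    schedule: TrialSchedule | None = None,
    mixing: np.ndarray | None = None,
) -> Recording:
    """Project sources to the sensor array and add white sensor noise.

    ``snr_sensor`` is the RMS ratio of the mixed signal to the added
    sensor noise (per recording, broadband); the noise realization is
    stored on ``truth.sensor_noise`` so the mixture is exactly
    reconstructable.
    """
    a = truth.mixing_matrix if mixing is None else mixing
    if a.shape[1] != truth.source_matrix.shape[0]:
        raise ValueError(
            f"mixing has {a.shape[1]} source columns, "
            f"but {truth.source_matrix.shape[0]} sources given"
        )
    if mixing is not None:
        truth.mixing_matrix = a
    clean = a @ truth.source_matrix
    phase_id = schedule.phase_id if schedule is not None else "HAB"
    rng = phase_seed(config, phase_id, "sensor-noise")
    if config.snr_sensor > 0 and np.isfinite(config.snr_sensor):
        noise_sd = np.sqrt(np.mean(clean**2)) / config.snr_sensor
    else:
        noise_sd = 0.0
    noise = noise_sd * rng.standard_normal(clean.shape)
    truth.sensor_noise = noise
    events = []
    if schedule is not None:
        events = [(int(round(o * config.fs)), schedule.phase_id) for o in schedule.onsets]
    return Recording(
        data=clean + noise,
        fs=config.fs,
        channel_labels=channel_labels(a.shape[0]),
        events=events,
    )


def double_gamma_hrf(tr_grid: np.ndarray, peak: float = 6.0, undershoot: float = 16.0,
                     ratio: float = 1 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response on the given time grid."""
    from scipy.stats import gamma as gamma_dist
    h = gamma_dist.pdf(tr_grid, peak) - ratio * gamma_dist.pdf(tr_grid, undershoot)
    return h / h.max()


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate (constant) series cannot be standardized")
    return (x - x.mean()) / sd


def neural_regressor(
    truth: GroundTruth, config: SimConfig, n_scans: int
) -> np.ndarray:
    """Scan-grid neural predictor that coupled voxels follow.

    ``coupling_mode='hrf'``: the continuous ssVEP amplitude envelope is
    convolved with the canonical double-gamma HRF and sampled at scan
    onsets.  ``coupling_mode='shift'``: the envelope, averaged per scan,
    is shifted by ``round(hrf_lag / tr)`` scans.
    """
    fs, tr = truth.fs, config.tr
    env = truth.ssvep_envelope
    if config.coupling_mode == "hrf":
        hrf_t = np.arange(0, 32.0, 1 / fs)
        hrf = double_gamma_hrf(hrf_t)
        conv = signal.fftconvolve(env, hrf, mode="full")[: env.size] / fs
        idx = np.minimum((np.arange(n_scans) * tr * fs).astype(int), env.size - 1)
        z = conv[idx]
    else:
        per_scan = _scan_average(env, fs, tr, n_scans)
        shift = int(round(config.hrf_lag / tr))
        z = np.roll(per_scan, shift)
        if shift > 0:
            z[:shift] = per_scan[0]
    return _standardize(z)


def _scan_average(x: np.ndarray, fs: float, tr: float, n_scans: int) -> np.ndarray:
    out = np.empty(n_scans)
    for k in range(n_scans):
        a = int(round(k * tr * fs))
        b = min(int(round((k + 1) * tr * fs)), x.size)
        out[k] = x[a:b].mean() if b > a else x[-1]
    return out


def simulate_bold(
    truth: GroundTruth,
    schedule: TrialSchedule,
    config: SimConfig,
) -> BoldDataset:
    """BOLD voxel series coupled to the ssVEP amplitude.

    Coupled voxels are ``coupling * z + sqrt(1-coupling^2) * noise`` with
    ``z`` the standardized neural regressor, so their population
    correlation with ``z`` equals ``coupling``; remaining voxels are
    independent noise (white, or AR(1) when ``bold_ar1 > 0``).
    """
    if config.n_coupled > config.n_voxels:
        raise ValueError("n_coupled exceeds n_voxels")
    duration = truth.source_matrix.shape[1] / truth.fs
    n_scans = int(duration / config.tr)
    if n_scans * config.tr < schedule.span():
        raise ScheduleError("scan grid does not cover the trial schedule")
    z = neural_regressor(truth, config, n_scans)
    rng = phase_seed(config, schedule.phase_id, "bold")
    noise = rng.standard_normal((config.n_voxels, n_scans))
    if config.bold_ar1 > 0:
        phi = config.bold_ar1
        for k in range(1, n_scans):
            noise[:, k] = phi * noise[:, k - 1] + np.sqrt(1 - phi**2) * noise[:, k]
    series = noise
    rho = config.coupling
    coupled = coupled_voxel_ids(config)
    series[coupled] = rho * z[None, :] + np.sqrt(1 - rho**2) * noise[coupled]
    truth.coupled_voxel_ids = coupled
    return BoldDataset(
        series=series,
        tr=config.tr,
        mask=np.ones(config.n_voxels, dtype=bool),
        scan_onsets=np.arange(n_scans) * config.tr,
        grid_shape=config.grid_shape,
    )


def coupled_voxel_ids(config: SimConfig) -> np.ndarray:
    """Coupled voxels form a contiguous block in the 3-D grid (one 'region')."""
    nx, ny, nz = config.grid_shape
    if nx * ny * nz != config.n_voxels:
        return np.arange(config.n_coupled)
    side = max(1, int(round(config.n_coupled ** (1 / 3))))
    ids = []
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if x < side and y < side and len(ids) < config.n_coupled:
                    ids.append(np.ravel_multi_index((x, y, z), config.grid_shape))
    ids = sorted(ids)[: config.n_coupled]
    return np.asarray(ids)


@dataclass
class PhaseSim:
    """Everything generated for one experimental phase."""

    schedule: TrialSchedule
    truth: GroundTruth
    recording: Recording
    bold: BoldDataset


def simulate_phase(config: SimConfig, phase_id: str) -> PhaseSim:
    schedule = make_schedule(config, phase_id)
    truth = simulate_sources(schedule, config)
    rec = mix_to_sensors(truth, config, schedule=schedule)
    bold = simulate_bold(truth, schedule, config)
    return PhaseSim(schedule=schedule, truth=truth, recording=rec, bold=bold)


def simulate_participant(config: SimConfig, phases=PHASES) -> dict[str, PhaseSim]:
    """Simulate all experimental phases for one participant."""
    return {p: simulate_phase(config, p) for p in phases}


def participant_config(config: SimConfig, participant: int) -> SimConfig:
    """Derive an independent participant-level configuration (new seed)."""
    child = np.random.SeedSequence([int(config.seed), 7000 + participant])
    return replace(config, seed=int(child.generate_state(1)[0] % (2**31)))
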