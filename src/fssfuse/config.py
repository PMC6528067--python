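"""Run configuration: every tunable of the pipeline in one round-trippable object.

A single global seed fans out to per-stage seeds (simulation, ICA,
annealing, permutations) so each stage is independently reproducible.
The emitted YAML carries an ``annotations`` block describing the role of
each protocol-level default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .fss import AnnealSchedule, ContrastParams
from .simulate import SimConfig

#: role descriptions for the protocol-level numeric defaults, emitted
#: next to the resolved configuration.
ANNOTATIONS = {
    "lambda_weight": "weight of the functional constraint in the contrast (10 for steady-state recovery)",
    "a1": "slope constant of the log-cosh ICA nonlinearity",
    "t_s/t_e/t_b": "stimulation integral window 0-5 s, baseline -1-0 s, relative to trial onset",
    "band_center/band_halfwidth": "zero-phase narrowband filter 10 +/- 0.5 Hz at the steady-state frequency",
    "lag": "hemodynamic latency of BOLD relative to neural activity, consensus 4 s",
    "alpha_voxel/alpha_group": "per-participant and group-level significance levels (0.05)",
    "sim.n_trials": "40 trials per experimental phase",
    "sim.stim_duration": "stimulus presented for 5.1 s, contrast reversing every 100 ms",
    "sim.tr": "fMRI repetition time 1.98 s",
    "sim.fs": "EEG sampling rate 250 Hz after down-sampling",
    "epoch_window": "per-trial epochs from 1 s pre-stimulus to 7 s post-onset",
    "offset_window": "late inter-trial window 5.6-7 s used as a validity check",
}


@dataclass
class RunConfig:
    """All module parameters plus seeds and bookkeeping."""

    sim: SimConfig = field(default_factory=SimConfig)
    # extraction
    lambda_weight: float = 10.0
    a1: float = 1.0
    t_s: float = 0.0
    t_e: float = 5.0
    t_b: float = -1.0
    band_center: float = 10.0
    band_halfwidth: float = 0.5
    broad_band: tuple[float, float] = (0.5, 30.0)
    epoch_window: tuple[float, float] = (-1.0, 7.0)
    combine: str = "sum"
    n_ica_components: int | None = 16
    anneal: AnnealSchedule = field(default_factory=AnnealSchedule)
    # fusion
    lag: float = 4.0
    n_perm: int = 1000
    alpha_voxel: float = 0.05
    alpha_group: float = 0.05
    min_shift: int = 10
    scan_summary: str = "envelope"
    # run-level
    mode: str = "fss"           # fss | ica | both
    n_participants: int = 1
    raw_channel: str = "Oz"
    seed: int = 0

    def contrast_params(self, mode: str | None = None) -> ContrastParams:
        lam = 0.0 if (mode or self.mode) == "ica" else self.lambda_weight
        return ContrastParams(lambda_weight=lam, a1=self.a1,
                              t_s=self.t_s, t_e=self.t_e, t_b=self.t_b)

    def stage_seed(self, stage: str, extra: int = 0) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        ss = np.random.SeedSequence([int(self.seed), _STAGES[stage], int(extra)])
        return int(ss.generate_state(1)[0] % (2**31))

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = replace(self, seed=int(seed))
        cfg.sim = replace(cfg.sim, seed=cfg.stage_seed("simulate"))
        cfg.anneal = replace(cfg.anneal, seed=cfg.stage_seed("anneal"))
        return cfg


_STAGES = {"simulate": 1, "ica": 2, "anneal": 3, "permute": 4, "group": 5}


def _tupleize(obj, template):
    """yaml gives lists; restore tuples where the dataclass default had one."""
    if isinstance(template, tuple) and isinstance(obj, list):
        return tuple(obj)
    return obj


def _listify(obj):
    if isinstance(obj, tuple):
        return [_listify(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    return obj


def to_dict(config: RunConfig) -> dict:
    return _listify(asdict(config))


def from_dict(d: dict) -> RunConfig:
    d = dict(d)
    d.pop("annotations", None)
    sim_d = d.pop("sim", {})
    ann_d = d.pop("anneal", {})
    sim_defaults = SimConfig()
    sim = SimConfig(**{k: _tupleize(v, getattr(sim_defaults, k))
                       for k, v in sim_d.items()})
    ann = AnnealSchedule(**ann_d)
    defaults = RunConfig()
    kwargs = {k: _tupleize(v, getattr(defaults, k)) for k, v in d.items()
              if k in {f.name for f in fields(RunConfig)} - {"sim", "anneal"}}
    return RunConfig(sim=sim, anneal=ann, **kwargs)


def to_yaml(config: RunConfig, path: Path | None = None,
            annotate: bool = True) -> str:
    d = to_dict(config)
    if annotate:
        d["annotations"] = ANNOTATIONS
    text = yaml.safe_dump(d, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def from_yaml(path_or_text: Path | str) -> RunConfig:
    s = str(path_or_text)
    if "\n" not in s and Path(s).exists():
        s = Path(s).read_text()
    return from_dict(yaml.safe_load(s))
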