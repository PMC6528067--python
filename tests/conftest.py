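"""Shared fixtures.

The two expensive study fixtures (20-seed extraction comparison; 5-seed
6-participant group fusion) are session-scoped and computed once; the
acceptance tests and trend tests all read from them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from fssfuse.config import RunConfig
from fssfuse.pipeline import extract_participant, run_study
from fssfuse.simulate import SimConfig, coupled_voxel_ids, simulate_phase

warnings.filterwarnings("ignore", message="fastICA stopped")


@pytest.fixture(scope="session")
def default_phase_sim():
    """One default-condition phase (31 ch, 40 trials) with ground truth."""
    return simulate_phase(SimConfig(seed=7), "HAB")


@pytest.fixture(scope="session")
def small_sim_cfg():
    """Short simulation for unit tests: fewer trials, shorter intervals."""
    return SimConfig(n_trials=8, iti_max=2.0, seed=11)


def _median_corr(run, mode):
    vals = [abs(np.corrcoef(run.results[mode].sources[p],
                            run.sims[p].truth.ssvep_source)[0, 1])
            for p in run.sims]
    return float(np.median(vals))


@pytest.fixture(scope="session")
def study20():
    """20 independent default co-simulations, extracted in both modes.

    Per seed: median |corr| with the true source for the FSS and the
    lambda=0 (ICA) solutions, plus the per-phase evoked SNR of each.
    """
    records = []
    for seed in range(1, 21):
        cfg = RunConfig(mode="both").with_seed(seed)
        run = extract_participant(cfg, participant=0,
                                  with_fusion=False, with_snr=True)
        records.append({
            "seed": seed,
            "corr_fss": _median_corr(run, "fss"),
            "corr_ica": _median_corr(run, "ica"),
            "snr_fss": float(np.median([r.snr_fss for r in run.snr_rows])),
            "snr_ica": float(np.median([r.snr_ica for r in run.snr_rows])),
        })
    return records


@pytest.fixture(scope="session")
def group_study():
    """5 seeded group studies: 6 participants each, FSS + fusion + overlap.

    Returns per-study dicts with the overlap maps and the true coupled
    voxel ids (identical across participants by construction).
    """
    studies = []
    for seed in (101, 102, 103, 104, 105):
        cfg = RunConfig(mode="fss", n_participants=6, n_perm=500).with_seed(seed)
        runs, overlaps = run_study(cfg, with_fusion=True, with_snr=False)
        coupled = coupled_voxel_ids(cfg.sim)
        truecoup = np.zeros(cfg.sim.n_voxels, dtype=bool)
        truecoup[coupled] = True
        studies.append({"overlaps": overlaps, "true_coupled": truecoup,
                        "config": cfg})
    return studies
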