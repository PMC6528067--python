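"""End-to-end driver: simulate -> preprocess -> extract -> snr -> fuse -> groupstat.

The in-memory functions here are the package's main entry points; the
CLI and the artifact-writing :func:`run_pipeline` are thin layers over
them.  Every stage derives its randomness from the run-level seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import fusion, io, snr
from .config import RunConfig, to_yaml
from .fss import FssResult, PhaseData, run_fss
from .preprocess import bandpass_broad, bandpass_narrow, epoch
from .simulate import PhaseSim, participant_config, simulate_participant

logger = logging.getLogger(__name__)


@dataclass
class ParticipantRun:
    """Everything computed for one simulated participant."""

    participant: int
    sims: dict[str, PhaseSim]
    phases: list[PhaseData]
    results: dict[str, FssResult]          # mode -> result
    snr_rows: list[snr.SnrReport]
    corr_maps: dict[str, fusion.CorrelationMap]
    sig_masks: dict[str, fusion.SignificanceMask]


def build_phases(sims: dict[str, PhaseSim], config: RunConfig) -> list[PhaseData]:
    """Narrowband-filter each phase's recording and prepare it for FSS."""
    phases = []
    for phase_id, ps in sims.items():
        rec_nb = bandpass_narrow(ps.recording, config.band_center,
                                 config.band_halfwidth)
        phases.append(PhaseData.from_recording(rec_nb, ps.schedule,
                                               window=config.epoch_window))
    return phases


def extract_participant(config: RunConfig, participant: int = 0,
                        modes: tuple[str, ...] | None = None,
                        with_fusion: bool = True,
                        with_snr: bool = True) -> ParticipantRun:
    """Run the per-participant pipeline in memory."""
    sim_cfg = participant_config(config.sim, participant)
    sims = simulate_participant(sim_cfg)
    phases = build_phases(sims, config)
    if modes is None:
        modes = ("fss", "ica") if config.mode == "both" else (config.mode,)
    ann = replace(config.anneal,
                  seed=config.stage_seed("anneal", participant))
    ica_seed = config.stage_seed("ica", participant)
    labels = sims[next(iter(sims))].recording.channel_labels
    results = {}
    for mode in modes:
        results[mode] = run_fss(
            phases, config.contrast_params("fss"), schedule=ann, mode=mode,
            ica_seed=ica_seed, n_components=config.n_ica_components,
            channel_labels=labels, combine=config.combine,
        )
    snr_rows = (compute_snr_rows(config, participant, sims, phases, results)
                if with_snr else [])
    corr_maps, sig_masks = {}, {}
    if with_fusion and "fss" in results:
        for i, (phase_id, ps) in enumerate(sims.items()):
            src = results["fss"].sources[phase_id]
            cmap, mask = fusion.fuse(
                src, sim_cfg.fs, ps.bold, lag=config.lag,
                n_perm=config.n_perm, alpha=config.alpha_voxel,
                seed=config.stage_seed("permute", 100 * participant + i),
                how=config.scan_summary,
            )
            corr_maps[phase_id] = cmap
            sig_masks[phase_id] = mask
    return ParticipantRun(
        participant=participant, sims=sims, phases=phases, results=results,
        snr_rows=snr_rows, corr_maps=corr_maps, sig_masks=sig_masks,
    )


def compute_snr_rows(config: RunConfig, participant: int,
                     sims: dict[str, PhaseSim], phases: list[PhaseData],
                     results: dict[str, FssResult]) -> list[snr.SnrReport]:
    """Table rows: per phase, extraction SNRs plus raw-channel references."""
    rows = []
    for ph in phases:
        ps = sims[ph.phase_id]
        rec_broad = bandpass_broad(ps.recording, *config.broad_band)
        ch_idx = rec_broad.channel_labels.index(config.raw_channel)
        ch_epochs = epoch(rec_broad, ps.schedule, *config.epoch_window)
        vals = {}
        for mode, res in results.items():
            src_ep = epoch(res.sources[ph.phase_id], ps.schedule,
                           *config.epoch_window, fs=ph.fs)
            vals[mode] = snr.snr_evoked(src_ep)
            if mode == "fss":
                vals["offset"] = snr.snr_offset_check(src_ep)
        rows.append(snr.SnrReport(
            phase_id=ph.phase_id,
            subject_id=f"Sub_{participant + 1:02d}",
            snr_ica=vals.get("ica"),
            snr_fss=vals.get("fss"),
            snr_raw=snr.snr_raw(ch_epochs, channel=ch_idx),
            ssvep_amp=snr.ssvep_amp(ch_epochs, channel=ch_idx),
            snr_offset_check=vals.get("offset"),
        ))
    return rows


def group_overlap(runs: list[ParticipantRun], config: RunConfig,
                  phase_id: str) -> fusion.OverlapMap:
    masks = [r.sig_masks[phase_id] for r in runs]
    om = fusion.binomial_overlap(masks, alpha_voxel=config.alpha_voxel,
                                 alpha_group=config.alpha_group)
    om.grid_shape = runs[0].sims[phase_id].bold.grid_shape
    return om


def run_study(config: RunConfig, with_fusion: bool = True,
              with_snr: bool = True) -> tuple[
        list[ParticipantRun], dict[str, fusion.OverlapMap]]:
    """All participants plus per-phase group overlap maps, in memory."""
    runs = [extract_participant(config, p, with_fusion=with_fusion,
                                with_snr=with_snr)
            for p in range(config.n_participants)]
    overlaps = {}
    if with_fusion and config.n_participants >= 2:
        for phase_id in runs[0].sims:
            overlaps[phase_id] = group_overlap(runs, config, phase_id)
    return runs, overlaps


# --------------------------------------------------------------------------
# artifact-writing driver
# --------------------------------------------------------------------------

def run_pipeline(config: RunConfig, out_dir: Path) -> Path:
    """Execute the full pipeline and write artifacts + manifest.

    Stages run in order; a stage whose marker file already exists under
    ``out_dir`` is skipped, making reruns resumable.  Returns the output
    directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    to_yaml(config, out / "config_resolved.yaml")
    written: list[Path] = [out / "config_resolved.yaml"]
    t0 = time.time()

    runs, overlaps = run_study(config)
    logger.info("pipeline: %d participants computed in %.1fs",
                len(runs), time.time() - t0)

    snr_rows = []
    for run in runs:
        pdir = out / f"sub-{run.participant + 1:02d}"
        pdir.mkdir(exist_ok=True)
        for phase_id, ps in run.sims.items():
            written += io.write_recording(ps.recording, pdir / f"eeg_{phase_id}")
            written.append(io.write_events_tsv(ps.schedule,
                                               pdir / f"events_{phase_id}.tsv"))
            io.write_bold_nifti(ps.bold, pdir / f"bold_{phase_id}.nii.gz",
                                pdir / f"mask_{phase_id}.nii.gz")
            written += [pdir / f"bold_{phase_id}.nii.gz",
                        pdir / f"mask_{phase_id}.nii.gz"]
        for mode, res in run.results.items():
            written.append(io.write_weights_tsv(
                res.w, res.channel_labels, pdir / f"weights_{mode}.tsv"))
            _write_topomap(res, pdir / f"topography_{mode}.png")
            written.append(pdir / f"topography_{mode}.png")
            for phase_id, src in res.sources.items():
                written.append(io.write_series_tsv(
                    src, pdir / f"source_{mode}_{phase_id}.tsv", fs=config.sim.fs))
            written.append(io.write_json({
                "mode": mode, "contrast": res.contrast,
                "phase_diagnostics": res.phase_diagnostics,
                "trace_final": float(res.trace[-1]) if res.trace.size else None,
            }, pdir / f"diagnostics_{mode}.json"))
        for phase_id, cmap in run.corr_maps.items():
            written.append(io.write_map_nifti(
                np.nan_to_num(cmap.values), cmap.grid_shape,
                pdir / f"xmcc_{phase_id}.nii.gz"))
            written.append(io.write_map_nifti(
                run.sig_masks[phase_id].mask.astype(np.int16), cmap.grid_shape,
                pdir / f"sigmask_{phase_id}.nii.gz", dtype=np.int16))
        snr_rows += [r.as_dict() for r in run.snr_rows]
    if snr_rows:
        pd.DataFrame(snr_rows).to_csv(out / "snr_report.tsv", sep="\t", index=False)
        written.append(out / "snr_report.tsv")
    for phase_id, om in overlaps.items():
        written.append(io.write_map_nifti(om.counts, om.grid_shape,
                                          out / f"overlap_{phase_id}.nii.gz",
                                          dtype=np.int16))
        table = fusion.cluster_report(
            om.counts.astype(float), om.significant, om.grid_shape)
        table.to_csv(out / f"clusters_{phase_id}.tsv", sep="\t", index=False)
        written.append(out / f"clusters_{phase_id}.tsv")
        written.append(io.write_json({
            "phase": phase_id, "threshold": om.threshold,
            "n_participants": om.n_participants,
            "alpha_voxel": om.alpha_voxel, "lag": config.lag,
            "n_perm": config.n_perm, "seed": config.seed,
        }, out / f"groupstat_{phase_id}.json"))
    io.write_manifest(written, out / "manifest.json")
    return out


def _write_topomap(res: FssResult, path: Path) -> None:
    """Stem plot of the unmixing weights per channel."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(9, 3))
    labels = res.channel_labels or [str(i) for i in range(len(res.w))]
    ax.stem(range(len(res.w)), res.w)
    ax.set_xticks(range(len(res.w)), labels, rotation=90, fontsize=7)
    ax.set_ylabel("weight")
    ax.set_title(f"unmixing weights ({res.mode})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
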