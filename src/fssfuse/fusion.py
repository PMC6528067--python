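"""ssVEP-BOLD fusion statistics.

The extracted source is summarized to the scan grid (per-scan mean of
its instantaneous amplitude envelope — averaging the raw 10 Hz
oscillation over a ~2 s scan would cancel to zero), shifted by the
hemodynamic lag (4 s by consensus, i.e. 2 scans at TR = 1.98 s), and
correlated voxel-wise with BOLD.  The map statistic is the bivariate
cross multivariate correlation coefficient (xMCC), which here equals the
absolute Pearson correlation — sign is not meaningful because source
polarity is unrecoverable.  Per-participant significance comes from a
circular-shift permutation null; group robustness from a binomial test
on the inter-subject overlap count, Bonferroni-corrected over voxels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .fss import hilbert_envelope
from .simulate import BoldDataset

logger = logging.getLogger(__name__)


@dataclass
class ScanSeries:
    """Unit-variance neural summary on the scan grid."""

    values: np.ndarray
    tr: float
    lag_applied: int = 0  # scans

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_scans(self) -> int:
        return self.values.size


@dataclass
class CorrelationMap:
    """|correlation| per voxel; NaN marks degenerate (zero-variance) voxels."""

    values: np.ndarray
    lag_seconds: float
    grid_shape: tuple[int, int, int] | None = None


@dataclass
class SignificanceMask:
    """Per-voxel permutation-test outcome for one participant."""

    mask: np.ndarray            # boolean
    p_values: np.ndarray
    alpha: float
    n_permutations: int
    seed: int


@dataclass
class OverlapMap:
    """Cross-participant overlap counts and the binomial group threshold."""

    counts: np.ndarray
    threshold: int
    n_participants: int
    alpha_voxel: float
    grid_shape: tuple[int, int, int] | None = None

    @property
    def significant(self) -> np.ndarray:
        return self.counts >= self.threshold


def summarize_to_scans(source: np.ndarray, fs: float, bold: BoldDataset,
                       how: str = "envelope") -> ScanSeries:
    """Per-scan summary of the source's instantaneous amplitude.

    ``how='envelope'`` (default) averages the Hilbert envelope over each
    scan's [onset, onset + TR) interval; ``how='absmean'`` averages the
    absolute value instead.  The result is standardized to unit
    variance; a constant summary is degenerate and rejected.
    """
    source = np.asarray(source, dtype=float)
    n_scans = bold.n_scans
    need = int(n_scans * bold.tr * fs)
    if source.size < need:
        raise ValueError(
            f"source covers {source.size / fs:.1f}s but scans need "
            f"{n_scans * bold.tr:.1f}s"
        )
    if how == "envelope":
        amp = hilbert_envelope(source, pad=int(round(fs)))
    elif how == "absmean":
        amp = np.abs(source)
    else:
        raise ValueError("how must be 'envelope' or 'absmean'")
    vals = np.empty(n_scans)
    for k in range(n_scans):
        a = int(round(k * bold.tr * fs))
        b = min(int(round((k + 1) * bold.tr * fs)), amp.size)
        vals[k] = amp[a:b].mean()
    sd = vals.std()
    if sd <= 1e-9 * max(float(np.abs(vals).max()), 1e-30):
        raise ValueError("constant per-scan summary (degenerate source)")
    return ScanSeries(values=(vals - vals.mean()) / sd, tr=bold.tr)


def lag_align(series: ScanSeries, bold: BoldDataset,
              lag: float = 4.0) -> tuple[ScanSeries, BoldDataset]:
    """Pair the neural series with BOLD ``lag`` seconds later.

    The lag is applied as an integer-scan shift, round(lag / TR) — 2
    scans at the 4 s consensus latency and TR = 1.98 s — and both arrays
    are trimmed to the overlapping support.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    shift = int(round(lag / bold.tr))
    if shift >= bold.n_scans:
        raise ValueError("lag exceeds the scan series")
    if shift == 0:
        return series, bold
    neural = ScanSeries(values=series.values[:-shift], tr=series.tr,
                        lag_applied=shift)
    trimmed = BoldDataset(
        series=bold.series[:, shift:], tr=bold.tr, mask=bold.mask,
        scan_onsets=bold.scan_onsets[shift:], grid_shape=bold.grid_shape,
    )
    return neural, trimmed


def _abs_corr(z: np.ndarray, voxels: np.ndarray) -> np.ndarray:
    """|Pearson r| of one standardized series against each voxel row."""
    n = z.size
    v = voxels - voxels.mean(axis=1, keepdims=True)
    sd = v.std(axis=1)
    zc = (z - z.mean()) / z.std()
    out = np.full(voxels.shape[0], np.nan)
    ok = sd > 0
    out[ok] = np.abs(v[ok] @ zc) / (n * sd[ok])
    return out


def xmcc_map(series: ScanSeries, bold: BoldDataset,
             lag_seconds: float | None = None) -> CorrelationMap:
    """Voxel-wise |Pearson correlation| with the (already lagged) series."""
    if series.n_scans != bold.n_scans:
        raise ValueError("series and BOLD disagree on scan count (lag-align first)")
    vals = _abs_corr(series.values, bold.series)
    vals[~bold.mask] = np.nan
    n_bad = int(np.isnan(vals[bold.mask]).sum())
    if n_bad:
        logger.warning("%d in-mask voxels have zero variance; set missing", n_bad)
    return CorrelationMap(
        values=vals,
        lag_seconds=series.lag_applied * series.tr if lag_seconds is None else lag_seconds,
        grid_shape=bold.grid_shape,
    )


def permutation_threshold(series: ScanSeries, bold: BoldDataset,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, min_shift: int = 10,
                          tail: str = "voxel") -> SignificanceMask:
    """Permutation test of no linear relation, per voxel.

    The null is built by circularly shifting the neural series by random
    offsets of at least ``min_shift`` scans (preserving its
    autocorrelation) and recomputing the correlation map.  p-values use
    the add-one estimator (1 + #{null >= observed}) / (1 + n_perm);
    ``tail='max'`` compares against the per-permutation maximum across
    voxels instead (family-wise control).
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    n = series.n_scans
    if n - 2 * min_shift <= 0:
        raise ValueError("too few scans for the minimum circular shift")
    rng = np.random.default_rng(seed)
    observed = _abs_corr(series.values, bold.series)
    shifts = rng.integers(min_shift, n - min_shift, size=n_perm)
    # vectorized null: standardized voxels against all shifted series at once
    v = bold.series - bold.series.mean(axis=1, keepdims=True)
    sd = v.std(axis=1)
    ok = sd > 0
    vz = np.zeros_like(v)
    vz[ok] = v[ok] / sd[ok, None]
    z = series.values
    zc = (z - z.mean()) / z.std()
    shifted = zc[(np.arange(n)[None, :] - shifts[:, None]) % n]
    null = np.abs(shifted @ vz.T) / n
    null[:, ~ok] = np.nan
    if tail == "max":
        null = np.nanmax(null, axis=1, keepdims=True)
    exceed = np.sum(null >= observed[None, :], axis=0)
    p = (1.0 + exceed) / (1.0 + n_perm)
    p[np.isnan(observed)] = 1.0
    mask = (p < alpha) & bold.mask
    return SignificanceMask(mask=mask, p_values=p, alpha=alpha,
                            n_permutations=n_perm, seed=seed)


def binomial_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


def binomial_overlap(masks: list[SignificanceMask | np.ndarray],
                     alpha_voxel: float = 0.05,
                     alpha_group: float = 0.05) -> OverlapMap:
    """Group-level overlap of per-participant significance masks.

    Counts, per voxel, how many participants are individually
    significant; the overlap threshold is the smallest count k whose
    binomial tail P(X >= k | n_participants, alpha_voxel), Bonferroni
    corrected by the number of voxels, stays below ``alpha_group``.
    """
    if len(masks) < 2:
        raise ValueError("need at least two participants")
    arrays = [m.mask if isinstance(m, SignificanceMask) else np.asarray(m, bool)
              for m in masks]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("participant masks have inconsistent geometry")
    counts = np.sum(arrays, axis=0).astype(int)
    n_sub = len(arrays)
    n_vox = int(arrays[0].size)
    threshold = n_sub + 1  # unattainable unless some k passes
    for k in range(1, n_sub + 1):
        if n_vox * binomial_tail(k, n_sub, alpha_voxel) < alpha_group:
            threshold = k
            break
    return OverlapMap(counts=counts, threshold=threshold,
                      n_participants=n_sub, alpha_voxel=alpha_voxel)


def cluster_report(values: np.ndarray, significant: np.ndarray,
                   grid_shape: tuple[int, int, int] | None) -> pd.DataFrame:
    """Connected-component summary of a thresholded map.

    26-connectivity components of the significant voxels on the 3-D
    grid; one row per cluster with its size, maximal map value and peak
    voxel coordinate.
    """
    if grid_shape is None:
        raise ValueError(
            "no 3-D layout available; report flat voxel indices instead"
        )
    sig = np.asarray(significant, bool).reshape(grid_shape)
    vol = np.asarray(values, float).reshape(grid_shape)
    labels, n_clusters = ndimage.label(sig, structure=np.ones((3, 3, 3)))
    rows = []
    for cid in range(1, n_clusters + 1):
        in_c = labels == cid
        vals = np.where(in_c, np.nan_to_num(vol, nan=-np.inf), -np.inf)
        peak = np.unravel_index(np.argmax(vals), grid_shape)
        rows.append({
            "cluster_id": cid,
            "size_voxels": int(in_c.sum()),
            "max_value": float(vol[peak]),
            "peak_x": peak[0], "peak_y": peak[1], "peak_z": peak[2],
        })
    return pd.DataFrame(rows, columns=["cluster_id", "size_voxels", "max_value",
                                       "peak_x", "peak_y", "peak_z"])


def fuse(source: np.ndarray, fs: float, bold: BoldDataset, lag: float = 4.0,
         n_perm: int = 1000, alpha: float = 0.05, seed: int = 0,
         how: str = "envelope") -> tuple[CorrelationMap, SignificanceMask]:
    """One participant's full fusion: summarize, lag, map, threshold."""
    series = summarize_to_scans(source, fs, bold, how=how)
    neural, trimmed = lag_align(series, bold, lag=lag)
    cmap = xmcc_map(neural, trimmed, lag_seconds=lag)
    mask = permutation_threshold(neural, trimmed, n_perm=n_perm,
                                 alpha=alpha, seed=seed)
    return cmap, mask
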