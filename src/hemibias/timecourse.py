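"""Percent-signal-change normalisation, ROI averaging, run concatenation.

The order of operations is pinned: each voxel's series is converted to
percent signal change (per run), voxels are then averaged within the ROI,
and runs are concatenated last.  PSC-then-average is not the same as
average-then-PSC when voxel means differ, and the former keeps every voxel
on a common percent scale before it enters the ROI mean.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

_ZERO_MEAN_TOL = 1e-12


class ZeroMeanSeriesError(ValueError):
    """The temporal mean is (numerically) zero; PSC is undefined."""


def percent_signal_change(series: np.ndarray) -> np.ndarray:
    """Convert a raw series to percent signal change about its temporal mean.

    ``psc(t) = 100 * (x(t) - mean(x)) / mean(x)``; the output has zero mean
    and is invariant to positive rescaling of the input.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or series.size < 2:
        raise ValueError("series must be 1D with length >= 2")
    mean = series.mean()
    if abs(mean) <= _ZERO_MEAN_TOL:
        raise ZeroMeanSeriesError("temporal mean is zero; cannot normalise")
    return 100.0 * (series - mean) / mean


def extract_roi_mean(run_data: np.ndarray, mask) -> np.ndarray:
    """Average percent-signal-change series over the voxels of an ROI.

    Parameters
    ----------
    run_data
        4D array (x, y, z, t) of raw BOLD values for one run.
    mask
        :class:`~hemibias.roi.ROIMask` of kind ``volume`` (or any object
        with a ``members`` list of voxel index triples).

    Each member voxel is normalised to percent signal change FIRST and the
    per-TR unweighted mean is taken afterwards.  Voxels with a zero temporal
    mean cannot be normalised: they are excluded with a logged count, and an
    error is raised only if no voxel survives.
    """
    run_data = np.asarray(run_data, dtype=float)
    if run_data.ndim != 4:
        raise ValueError("run_data must be 4D (x, y, z, t)")
    members = list(mask.members)
    if not members:
        raise ValueError("mask has no member voxels")
    idx = np.asarray(members)
    if idx.min() < 0 or (idx >= run_data.shape[:3]).any():
        raise ValueError("mask voxel outside the run grid")
    voxels = run_data[idx[:, 0], idx[:, 1], idx[:, 2], :]  # (n_vox, T)
    means = voxels.mean(axis=1)
    usable = np.abs(means) > _ZERO_MEAN_TOL
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.warning("excluded %d zero-mean voxels from ROI average", n_dropped)
    if not usable.any():
        raise ZeroMeanSeriesError("all ROI voxels have zero temporal mean")
    psc = 100.0 * (voxels[usable] - means[usable, None]) / means[usable, None]
    return psc.mean(axis=0)


def concatenate_runs(runs: list[np.ndarray]) -> tuple[np.ndarray, tuple[int, ...]]:
    """Concatenate per-run normalised series; returns (series, run_lengths).

    Normalisation is per run, so each segment of the output is mean-zero on
    its own; concatenation adds no demeaning of its own.
    """
    if not runs:
        raise ValueError("at least one run is required")
    runs = [np.asarray(r, dtype=float) for r in runs]
    if any(r.ndim != 1 for r in runs):
        raise ValueError("each run must be a 1D series")
    return np.concatenate(runs), tuple(len(r) for r in runs)
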