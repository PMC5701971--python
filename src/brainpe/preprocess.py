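"""Temporal preprocessing of already-registered 4-D fMRI volumes.

Spatial preprocessing (slice timing, realignment, template normalization) is
out of scope: volumes are assumed registered to a common grid.  The stages
here are the temporal ones applied before entropy mapping, in this order:

1. discard the first k volumes (scanner equilibration / subject adaptation),
2. voxelwise linear detrend (scanner drift removal),
3. optionally, regression of nuisance signals (global mean, 6 motion
   parameters, CSF and WM means).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume4D",
    "NuisanceSet",
    "load_volume4d",
    "drop_initial_volumes",
    "linear_detrend",
    "detrend_volume",
    "regress_nuisance",
    "extract_mean_signal",
]


@dataclass
class Volume4D:
    """A 4-D BOLD series: data (x, y, z, t), world affine, repetition time (s)."""

    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float = 3.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4-D data (x, y, z, t), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 transform")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*img.header.get_zooms()[:3], self.tr_seconds))
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_volume4d(path: str | Path, tr_seconds: float | None = None) -> Volume4D:
    """Read a 4-D NIfTI file; TR is taken from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(data=data, affine=np.asarray(img.affine), tr_seconds=tr_seconds)


@dataclass
class NuisanceSet:
    """Per-timepoint nuisance regressors (columns) with labels.

    Typical columns: global signal, 6 rigid-body motion parameters, CSF mean,
    WM mean.  An empty set (0 columns) is allowed and corresponds to
    intercept-only regression, i.e. mean centering.
    """

    regressors: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.regressors = np.asarray(self.regressors, dtype=float)
        if self.regressors.ndim == 1:
            self.regressors = self.regressors[:, None]
        if self.regressors.ndim != 2:
            raise ValueError("regressors must be a (timepoints, k) matrix")
        k = self.regressors.shape[1]
        if not self.labels:
            self.labels = tuple(f"reg{i}" for i in range(k))
        if len(self.labels) != k:
            raise ValueError("one label per regressor column required")

    @property
    def n_regressors(self) -> int:
        return self.regressors.shape[1]


def drop_initial_volumes(vol: Volume4D, k: int = 10) -> Volume4D:
    """Remove the first ``k`` timepoints (default 10); affine and TR unchanged."""
    if k < 0:
        raise ValueError("k must be non-negative")
    if k >= vol.n_timepoints:
        raise ValueError(f"cannot discard {k} of {vol.n_timepoints} timepoints: nothing left")
    return replace(vol, data=vol.data[..., k:])


def linear_detrend(series: Sequence[float] | np.ndarray) -> np.ndarray:
    """Remove the OLS line (intercept + slope * time index) from a series.

    The residuals have exactly zero mean and zero refitted slope.  Requires at
    least 3 samples so the residual is not trivially null.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("linear detrend needs a 1-D series of at least 3 samples")
    t = np.arange(x.size, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def detrend_volume(vol: Volume4D, mask: np.ndarray | None = None) -> Volume4D:
    """Voxelwise linear detrend of a 4-D volume (in-mask voxels only).

    Out-of-mask voxels are left untouched; they are excluded from all
    downstream statistics anyway.
    """
    t = np.arange(vol.n_timepoints, dtype=float)
    design = np.column_stack([np.ones_like(t), t])
    flat = vol.data.reshape(-1, vol.n_timepoints)
    if mask is not None:
        if mask.shape != vol.shape3d:
            raise ValueError("mask shape does not match volume grid")
        idx = np.flatnonzero(mask.reshape(-1))
    else:
        idx = np.arange(flat.shape[0])
    y = flat[idx].T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    out = flat.copy()
    out[idx] = (y - design @ beta).T
    return replace(vol, data=out.reshape(vol.data.shape))


def regress_nuisance(series: Sequence[float] | np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Residualize a series on an intercept plus the nuisance regressors.

    Raises when the design (intercept + regressors) is rank deficient, naming
    the offending columns.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if nuisance.regressors.shape[0] != x.size:
        raise ValueError(
            f"nuisance rows ({nuisance.regressors.shape[0]}) != series length ({x.size})"
        )
    design = np.column_stack([np.ones(x.size), nuisance.regressors])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = _collinear_columns(design, ("intercept", *nuisance.labels))
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ beta


def _collinear_columns(design: np.ndarray, labels: tuple[str, ...]) -> list[str]:
    """Greedily identify columns that add no rank to the preceding ones."""
    bad = []
    kept = np.empty((design.shape[0], 0))
    for j in range(design.shape[1]):
        cand = np.column_stack([kept, design[:, j]])
        if np.linalg.matrix_rank(cand) == kept.shape[1]:
            bad.append(labels[j])
        else:
            kept = cand
    return bad


def extract_mean_signal(vol: Volume4D, mask: np.ndarray) -> np.ndarray:
    """Mean time series over a boolean 3-D mask (e.g., global/CSF/WM signal)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError(f"mask shape {mask.shape} does not match grid {vol.shape3d}")
    if not mask.any():
        raise ValueError("mask is empty")
    return vol.data[mask].mean(axis=0)
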