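"""Voxelwise map construction: permutation-entropy maps, regional homogeneity
(Kendall's W) maps, masked Gaussian smoothing, and tissue summaries.

Smoothing is applied to the finished PE/ReHo maps, never to the 4-D data:
smoothing the raw series would artificially inflate regional similarity and
bias both measures.  The orchestrator enforces this stage order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from scipy.stats import rankdata

from .entropy import PEParams, pe_norm_rows, validate_params
from .preprocess import Volume4D

__all__ = [
    "VolumeMap",
    "ReHoParams",
    "pe_map",
    "kendall_w",
    "reho_map",
    "gaussian_smooth_map",
    "tissue_mean",
    "FWHM_TO_SIGMA",
]

#: sigma = FWHM / (2 * sqrt(2 * ln 2))
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

# neighborhood size -> offsets: 7 = faces, 19 = faces+edges, 27 = full cube
_NEIGHBORHOODS = {
    7: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 1
    ],
    19: [
        (dx, dy, dz)
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if abs(dx) + abs(dy) + abs(dz) <= 2
    ],
    27: [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)],
}


@dataclass
class VolumeMap:
    """A 3-D scalar field (PE, ReHo, F, r, ...) with affine and validity mask.

    Values are defined only where ``mask`` is True; elsewhere the data holds
    NaN, the on-disk sentinel as well (never 0, which would bias smoothing).
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"map data must be 3-D, got shape {self.data.shape}")
        if self.mask.shape != self.data.shape:
            raise ValueError("mask shape must match data shape")
        self.data = np.where(self.mask, self.data, np.nan)

    @property
    def values(self) -> np.ndarray:
        """In-mask values as a flat vector (mask order)."""
        return self.data[self.mask]

    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def save(self, path: str | Path, sidecar: bool = True) -> None:
        """Write NIfTI (NaN outside mask) plus a JSON metadata sidecar."""
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        nib.save(img, str(path))
        if sidecar:
            side = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
            Path(f"{side}.json").write_text(json.dumps(self.meta, indent=2, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "VolumeMap":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=float)
        mask = np.isfinite(data)
        meta: dict = {}
        side = Path(str(path)).with_suffix("").with_suffix("")
        sidecar = Path(f"{side}.json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        return cls(data=data, affine=np.asarray(img.affine), mask=mask, meta=meta)


@dataclass(frozen=True)
class ReHoParams:
    """Regional-homogeneity neighborhood: 7, 19 or 27 voxels (center included)."""

    neighborhood: int = 27

    def __post_init__(self) -> None:
        if self.neighborhood not in _NEIGHBORHOODS:
            raise ValueError(f"neighborhood must be one of {sorted(_NEIGHBORHOODS)}")


def pe_map(
    vol: Volume4D,
    mask: np.ndarray,
    params: PEParams = PEParams(),
    *,
    force: bool = False,
) -> VolumeMap:
    """Normalized permutation entropy of every in-mask voxel's time series."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask shape does not match volume grid")
    verdict = validate_params(vol.n_timepoints, params)
    if not verdict.valid and not force:
        raise ValueError(f"invalid PE parameters for this series length: {verdict.message}")
    data = np.full(vol.shape3d, np.nan)
    rows = vol.data[mask]  # (n_voxels, t)
    if rows.shape[0]:
        data[mask] = pe_norm_rows(rows, params)
    meta = {"measure": "pe_norm", "m": params.m, "l": params.l, "n_timepoints": vol.n_timepoints}
    return VolumeMap(data=data, affine=vol.affine, mask=mask, meta=meta)


def kendall_w(rank_matrix: np.ndarray) -> float:
    """Kendall's coefficient of concordance W of K rank columns over n timepoints.

    ``rank_matrix`` is (n, K): each column holds the within-series ranks
    (1..n, midranks for ties; no tie-correction term).  W is in [0, 1] and
    equals 1 iff all columns are identical permutations.
    """
    r = np.asarray(rank_matrix, dtype=float)
    if r.ndim != 2:
        raise ValueError("rank matrix must be 2-D (timepoints x series)")
    n, k = r.shape
    if k < 2 or n < 2:
        raise ValueError("need at least 2 series and 2 timepoints")
    row_sums = r.sum(axis=1)
    rbar = row_sums.mean()
    s = float(np.sum(row_sums**2) - n * rbar**2)
    denom = (k**2) * (n**3 - n) / 12.0
    return s / denom


def reho_map(vol: Volume4D, mask: np.ndarray, params: ReHoParams = ReHoParams()) -> VolumeMap:
    """Kendall's W of each in-mask voxel with its in-mask neighbors.

    The neighborhood shrinks at mask edges (only in-mask members count);
    voxels with fewer than 2 members are excluded from the output mask.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != vol.shape3d:
        raise ValueError("mask shape does not match volume grid")
    if not mask.any():
        raise ValueError("mask is empty")
    n_t = vol.n_timepoints
    ranks = np.zeros_like(vol.data)
    ranks[mask] = rankdata(vol.data[mask], axis=-1, method="average")

    offsets = _NEIGHBORHOODS[params.neighborhood]
    rank_sum = np.zeros(vol.data.shape)  # per-timepoint sum of member ranks
    count = np.zeros(vol.shape3d)
    for off in offsets:
        shifted_r = _shift3d(ranks, off)
        shifted_m = _shift3d(mask.astype(float), off)
        rank_sum += shifted_r
        count += shifted_m

    k = count
    with np.errstate(divide="ignore", invalid="ignore"):
        rbar = k * (n_t + 1) / 2.0
        s = (rank_sum**2).sum(axis=-1) - n_t * rbar**2
        denom = (k**2) * (n_t**3 - n_t) / 12.0
        w = s / denom
    out_mask = mask & (k >= 2)
    data = np.where(out_mask, w, np.nan)
    meta = {"measure": "reho", "neighborhood": params.neighborhood, "n_timepoints": n_t}
    return VolumeMap(data=data, affine=vol.affine, mask=out_mask, meta=meta)


def _shift3d(arr: np.ndarray, offset: tuple[int, int, int]) -> np.ndarray:
    """Shift a 3-D (or 3+1-D) array by an integer voxel offset, zero-filled."""
    out = np.zeros_like(arr)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, d in enumerate(offset):
        n = arr.shape[ax]
        if abs(d) >= n:
            return out
        if d >= 0:
            src[ax], dst[ax] = slice(0, n - d), slice(d, n)
        else:
            src[ax], dst[ax] = slice(-d, n), slice(0, n + d)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def gaussian_smooth_map(vmap: VolumeMap, fwhm_mm: float) -> VolumeMap:
    """Masked Gaussian smoothing of a scalar map.

    The kernel is an axis-separable discrete Gaussian with
    ``sigma_mm = fwhm / (2*sqrt(2 ln 2))`` converted to voxel units per axis,
    truncated at 4 sigma.  Weights are renormalized over the in-mask support,
    so constants are preserved exactly and no sentinel value leaks in.
    """
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return VolumeMap(
            data=vmap.data.copy(),
            affine=vmap.affine,
            mask=vmap.mask.copy(),
            meta={**vmap.meta, "fwhm_mm": 0.0},
        )
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vmap.voxel_sizes()
    filled = np.where(vmap.mask, vmap.data, 0.0)
    num = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="constant", truncate=4.0)
    den = ndimage.gaussian_filter(
        vmap.mask.astype(float), sigma=sigma_vox, mode="constant", truncate=4.0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        sm = np.where(vmap.mask & (den > 0), num / np.where(den > 0, den, 1.0), np.nan)
    return VolumeMap(
        data=sm,
        affine=vmap.affine,
        mask=vmap.mask.copy(),
        meta={**vmap.meta, "fwhm_mm": float(fwhm_mm)},
    )


def tissue_mean(vmap: VolumeMap, tissue_mask: np.ndarray) -> float:
    """Mean map value over the intersection of the map mask and a tissue mask."""
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    if tissue_mask.shape != vmap.data.shape:
        raise ValueError("tissue mask shape does not match map grid")
    both = tissue_mask & vmap.mask
    if not both.any():
        raise ValueError("tissue mask does not intersect the map mask")
    return float(vmap.data[both].mean())
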