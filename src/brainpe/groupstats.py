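"""Group-level statistics on subject maps.

Covers the full battery: covariate-adjusted voxelwise one-way ANOVA (partial
F for the group factor), permutation-based cluster-extent correction, sphere
ROI extraction in world (MNI) coordinates, Bonferroni-corrected pairwise
post-hoc t tests, and Pearson correlations with clinical scores or other
subject-level maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from nibabel.affines import apply_affine
from scipy import ndimage, stats

from .maps import VolumeMap

__all__ = [
    "CohortDesign",
    "RoiSpec",
    "ClusterRecord",
    "GROUP_ORDER",
    "voxelwise_group_f",
    "cluster_threshold",
    "sphere_roi_mask",
    "roi_mean",
    "posthoc_pairwise",
    "pearson_corr",
    "report_tables",
]

GROUP_ORDER = ("NC", "EMCI", "LMCI", "AD")

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}  # neighbors -> ndimage connectivity rank


@dataclass
class CohortDesign:
    """Per-subject design: group label, covariates and clinical scores.

    Wraps a DataFrame with columns ``subject_id, group, age, sex`` and the
    clinical scores ``mmse`` (0-30, higher = better cognition), ``faq``
    (0-50, higher = worse daily function), ``cdr`` (0 / 0.5 / 1).
    """

    table: pd.DataFrame
    group_order: tuple[str, ...] = GROUP_ORDER

    REQUIRED = ("subject_id", "group", "age", "sex")
    SCORES = ("mmse", "faq", "cdr")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"cohort table is missing required columns: {missing}")
        unknown = set(self.table["group"]) - set(self.group_order)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}; expected {self.group_order}")
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "CohortDesign":
        return cls(pd.read_csv(path), **kwargs)

    @property
    def groups(self) -> np.ndarray:
        return self.table["group"].to_numpy()

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def present_groups(self) -> list[str]:
        present = set(self.groups)
        return [g for g in self.group_order if g in present]

    def group_dummies(self) -> np.ndarray:
        """Treatment-coded indicators for all but the first present group."""
        present = self.present_groups()
        return np.column_stack([(self.groups == g).astype(float) for g in present[1:]])

    def covariate_matrix(self, covariates: Sequence[str]) -> np.ndarray:
        cols = []
        for c in covariates:
            if c not in self.table.columns:
                raise ValueError(f"covariate column {c!r} absent from cohort table")
            v = self.table[c].to_numpy(dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"covariate {c!r} has missing values")
            cols.append(v)
        return np.column_stack(cols) if cols else np.empty((self.n_subjects, 0))


@dataclass(frozen=True)
class RoiSpec:
    """A spherical ROI: name, world-space (MNI, mm) center, radius in mm."""

    name: str
    center: tuple[float, float, float]
    radius: float = 8.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("ROI radius must be non-negative")


@dataclass
class ClusterRecord:
    """One suprathreshold cluster: member voxels, extent, peak location/F."""

    voxels: np.ndarray  # (n, 3) integer coordinates
    size: int
    peak_ijk: tuple[int, int, int]
    peak_world: tuple[float, float, float]
    peak_f: float
    p_cluster: float

    def as_row(self) -> dict:
        return {
            "cluster_voxels": self.size,
            "peak_x": self.peak_world[0],
            "peak_y": self.peak_world[1],
            "peak_z": self.peak_world[2],
            "peak_f": self.peak_f,
            "p_cluster": self.p_cluster,
        }


def _stack_maps(maps: Sequence[VolumeMap]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Common mask (intersection), subjects-by-voxels matrix, shared affine."""
    if not maps:
        raise ValueError("no subject maps given")
    shape = maps[0].data.shape
    affine = maps[0].affine
    mask = np.ones(shape, dtype=bool)
    for m in maps:
        if m.data.shape != shape or not np.allclose(m.affine, affine):
            raise ValueError("subject maps must share grid shape and affine")
        mask &= m.mask
    if not mask.any():
        raise ValueError("no voxel is in-mask across all subjects")
    y = np.stack([m.data[mask] for m in maps])  # (n_subjects, n_voxels)
    return mask, y, affine


def _partial_f(
    y: np.ndarray, dummies: np.ndarray, covars: np.ndarray
) -> tuple[np.ndarray, np.ndarray, tuple[int, int]]:
    """Partial F for the group factor: full (intercept+dummies+covars) vs
    reduced (intercept+covars) residual sums of squares, per column of y."""
    n = y.shape[0]
    intercept = np.ones((n, 1))
    x_full = np.column_stack([intercept, dummies, covars])
    x_red = np.column_stack([intercept, covars])
    if np.linalg.matrix_rank(x_full) < x_full.shape[1]:
        raise ValueError("singular design matrix (collinear group/covariate columns)")
    df1 = dummies.shape[1]
    df2 = n - x_full.shape[1]
    if df2 < 1:
        raise ValueError("not enough subjects for the requested model")
    rss_full = _rss(x_full, y)
    rss_red = _rss(x_red, y)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = np.where(np.isfinite(f), np.maximum(f, 0.0), 0.0)
    p = stats.f.sf(f, df1, df2)
    return f, p, (df1, df2)


def _rss(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(x)
    resid = y - q @ (q.T @ y)
    return (resid**2).sum(axis=0)


def voxelwise_group_f(
    maps: Sequence[VolumeMap],
    design: CohortDesign,
    covariates: Sequence[str] = ("age", "sex"),
) -> tuple[VolumeMap, VolumeMap]:
    """Voxelwise ANOVA for the group factor, adjusted for covariates.

    Fits, per voxel, a linear model with group indicators plus covariate
    columns and returns the partial F map for the group factor together with
    its parametric p map.  Without covariates this is textbook one-way ANOVA.
    """
    if len(maps) != design.n_subjects:
        raise ValueError("one map per design row required")
    present = design.present_groups()
    if len(present) < 2:
        raise ValueError("need at least 2 groups")
    counts = design.table["group"].value_counts()
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 subjects")
    mask, y, affine = _stack_maps(maps)
    f, p, (df1, df2) = _partial_f(y, design.group_dummies(), design.covariate_matrix(covariates))
    meta = {"measure": "group_F", "df": [df1, df2], "covariates": list(covariates)}
    f_map = VolumeMap(data=_unflatten(f, mask), affine=affine, mask=mask, meta=meta)
    p_map = VolumeMap(
        data=_unflatten(p, mask), affine=affine, mask=mask, meta={**meta, "measure": "group_p"}
    )
    return f_map, p_map


def _unflatten(vals: np.ndarray, mask: np.ndarray) -> np.ndarray:
    out = np.full(mask.shape, np.nan)
    out[mask] = vals
    return out


def cluster_threshold(
    maps: Sequence[VolumeMap],
    design: CohortDesign,
    covariates: Sequence[str] = ("age", "sex"),
    *,
    p_voxel: float = 0.005,
    n_perm: int = 1000,
    extent_alpha: float = 0.05,
    connectivity: int = 6,
    seed: int | np.random.Generator | None = None,
    force: bool = False,
) -> tuple[list[ClusterRecord], dict]:
    """Permutation cluster-extent correction of the voxelwise group F map.

    Voxels with parametric ``p < p_voxel`` form connected components
    (face-adjacency by default).  Significance of each component's extent is
    assessed against the null distribution of the *maximum* cluster size
    obtained by permuting group labels (covariates held fixed) ``n_perm``
    times; components larger than the ``1 - extent_alpha`` null quantile are
    returned, sorted by decreasing size.
    """
    if not 0 < p_voxel < 1:
        raise ValueError("p_voxel must lie in (0, 1)")
    if n_perm < 100 and not force:
        raise ValueError("n_perm < 100 gives an unusable null; pass force=True to override")
    if connectivity not in _CONNECTIVITY:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY[connectivity])

    mask, y, affine = _stack_maps(maps)
    dummies = design.group_dummies()
    covars = design.covariate_matrix(covariates)
    f, p, df = _partial_f(y, dummies, covars)

    f_thresh = stats.f.isf(p_voxel, *df)
    obs_sizes, labels, n_lab = _cluster_sizes(p < p_voxel, mask, structure)

    groups = design.groups
    null_max = np.empty(n_perm)
    for i in range(n_perm):
        for _ in range(100):  # redraw on singular permuted designs (tiny-n edge case)
            perm = rng.permutation(design.n_subjects)
            perm_dummies = _dummies_for(groups[perm], design.group_order)
            try:
                f_p, _, _ = _partial_f(y, perm_dummies, covars)
                break
            except ValueError:
                continue
        else:
            raise ValueError("could not find a non-singular permutation of the design")
        sizes, _, _ = _cluster_sizes(f_p > f_thresh, mask, structure)
        null_max[i] = max(sizes) if sizes else 0

    size_crit = float(np.quantile(null_max, 1.0 - extent_alpha))
    records: list[ClusterRecord] = []
    f_vol = _unflatten(f, mask)
    for lab in range(1, n_lab + 1):
        members = np.argwhere(labels == lab)
        size = len(members)
        if size <= size_crit:
            continue
        vals = f_vol[tuple(members.T)]
        peak = members[int(np.argmax(vals))]
        p_cluster = (1.0 + np.sum(null_max >= size)) / (n_perm + 1.0)
        records.append(
            ClusterRecord(
                voxels=members,
                size=size,
                peak_ijk=tuple(int(v) for v in peak),
                peak_world=tuple(float(v) for v in apply_affine(affine, peak)),
                peak_f=float(vals.max()),
                p_cluster=float(p_cluster),
            )
        )
    records.sort(key=lambda r: r.size, reverse=True)
    info = {
        "f_threshold": float(f_thresh),
        "p_voxel": p_voxel,
        "n_perm": n_perm,
        "extent_alpha": extent_alpha,
        "size_criterion": size_crit,
        "connectivity": connectivity,
        "null_max_sizes": null_max,
    }
    return records, info


def _dummies_for(groups: np.ndarray, order: Sequence[str]) -> np.ndarray:
    present = [g for g in order if g in set(groups)]
    return np.column_stack([(groups == g).astype(float) for g in present[1:]])


def _cluster_sizes(
    supra_flat: np.ndarray, mask: np.ndarray, structure: np.ndarray
) -> tuple[list[int], np.ndarray, int]:
    supra = np.zeros(mask.shape, dtype=bool)
    supra[mask] = supra_flat
    labels, n_lab = ndimage.label(supra, structure=structure)
    if n_lab == 0:
        return [], labels, 0
    sizes = ndimage.sum_labels(supra, labels, index=np.arange(1, n_lab + 1)).astype(int)
    return list(sizes), labels, n_lab


def sphere_roi_mask(
    shape: tuple[int, int, int], affine: np.ndarray, roi: RoiSpec
) -> np.ndarray:
    """Boolean mask of voxels whose center lies within ``radius`` mm of the
    ROI's world-space center (voxel-center-in-sphere; no partial volumes)."""
    affine = np.asarray(affine, dtype=float)
    ijk = np.indices(shape).reshape(3, -1).T
    world = apply_affine(affine, ijk)
    d2 = ((world - np.asarray(roi.center)) ** 2).sum(axis=1)
    inside = (d2 <= roi.radius**2 + 1e-9).reshape(shape)
    # the voxel whose volume contains the center always belongs to the ROI
    # (covers radii smaller than half a voxel, including radius 0)
    home = np.round(apply_affine(np.linalg.inv(affine), np.asarray(roi.center))).astype(int)
    if all(0 <= home[a] < shape[a] for a in range(3)):
        inside[tuple(home)] = True
    if not inside.any():
        raise ValueError(f"ROI {roi.name!r} (center {roi.center}, r={roi.radius}) lies outside the grid")
    return inside


def roi_mean(vmap: VolumeMap, roi_mask: np.ndarray) -> float:
    """Mean map value over an ROI, intersected with the map's validity mask."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    both = roi_mask & vmap.mask
    if not both.any():
        raise ValueError("ROI does not intersect the map mask")
    return float(vmap.data[both].mean())


def posthoc_pairwise(
    roi_values: np.ndarray,
    design: CohortDesign,
    *,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """All pairwise two-sample t tests between groups, Bonferroni-adjusted.

    Uses the pooled-variance t by default (``welch=True`` for unequal
    variances).  Adjusted p = min(1, raw p x number of pairs).  Pairs
    involving a group with fewer than 2 subjects are skipped.
    """
    roi_values = np.asarray(roi_values, dtype=float)
    if roi_values.shape[0] != design.n_subjects:
        raise ValueError("one value per subject required")
    present = design.present_groups()
    if len(present) < 2:
        raise ValueError("need at least 2 groups")
    pairs = [(a, b) for i, a in enumerate(present) for b in present[i + 1 :]]
    rows = []
    for a, b in pairs:
        xa = roi_values[design.groups == a]
        xb = roi_values[design.groups == b]
        if len(xa) < 2 or len(xb) < 2:
            rows.append({"group_a": a, "group_b": b, "t": np.nan, "p_raw": np.nan, "p_bonf": np.nan,
                         "significant": False, "note": "skipped: group with < 2 subjects"})
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=not welch)
        p_adj = min(1.0, float(p) * len(pairs))
        rows.append({"group_a": a, "group_b": b, "t": float(t), "p_raw": float(p),
                     "p_bonf": p_adj, "significant": p_adj < alpha, "note": ""})
    return pd.DataFrame(rows)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson's r with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def report_tables(
    out_dir: str | Path,
    clusters: Sequence[ClusterRecord] | None = None,
    roi_results: pd.DataFrame | None = None,
    correlations: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> dict[str, Path]:
    """Write the cluster table, ROI table, correlation table and a JSON run
    manifest as delimited text; returns the paths written."""
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    cluster_rows = [
        {"region": f"cluster_{i + 1}", **c.as_row()} for i, c in enumerate(clusters or [])
    ]
    cluster_df = pd.DataFrame(
        cluster_rows,
        columns=["region", "cluster_voxels", "peak_x", "peak_y", "peak_z", "peak_f", "p_cluster"],
    )
    written["clusters"] = out / "cluster_table.csv"
    cluster_df.to_csv(written["clusters"], index=False)

    if roi_results is not None:
        written["roi"] = out / "roi_table.csv"
        roi_results.to_csv(written["roi"], index=False)
    if correlations is not None:
        written["correlations"] = out / "correlation_table.csv"
        correlations.to_csv(written["correlations"], index=False)
    if manifest is not None:
        written["manifest"] = out / "run_manifest.json"
        written["manifest"].write_text(json.dumps(manifest, indent=2, default=str))
    return written
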