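"""Attractor feature extraction: the 73-feature SPAR vector plus mean R-R.

Each attractor is partitioned into 7 regions — the central core disk
(r <= r_c) and 6 equal pi/3 angular "arm" sectors covering r > r_c — and
quantified by a frozen manifest of exactly 73 attractor-derived features
covering its size, shape, symmetry and density distribution:

* 5 global features (maximum bin density, occupied-area fraction, core
  radius, core mass fraction, outer radius);
* 9 quantity families x 7 summary statistics (mean, median, min, max, SD,
  25th, 75th percentile) = 63: radial distances, per-arm lengths, per-arm
  peak densities, per-arm masses, per-arm angular deviations from the
  expected position, theta-core density values, theta-arm density values,
  3-fold symmetry residuals, and per-sector core radial extents;
* 5 core/shape features (core peak density, core total density, centroid
  distance, principal-axis orientation, density entropy).

The mean R-R interval joins as the 74th feature, restoring the heart-rate
information that the attractor's time normalization removes.  Names and
order are frozen; a golden test guards the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .attractor import (
    AttractorImage,
    AttractorPoints,
    DensityProfile,
    compute_core_radius,
    density_image,
    density_profiles,
    embed,
)
from .exceptions import ParameterError
from .preprocess import SubStrip

__all__ = [
    "RegionPartition",
    "FeatureVector",
    "FEATURE_NAMES",
    "N_ATTRACTOR_FEATURES",
    "META_COLUMNS",
    "partition_regions",
    "extract_features",
    "substrip_features",
    "feature_table",
]

_STATS = ("mean", "median", "min", "max", "sd", "q25", "q75")
_FAMILIES = (
    "r_all",
    "arm_length",
    "arm_peak_density",
    "arm_mass",
    "arm_angle_dev",
    "theta_core_density",
    "theta_arm_density",
    "symmetry_residual",
    "core_sector_extent",
)
_GLOBAL = ("max_density", "occupied_fraction", "core_radius", "core_mass_fraction", "outer_radius")
_SHAPE = (
    "core_peak_density",
    "core_total_density",
    "centroid_distance",
    "principal_axis_angle",
    "density_entropy",
)

FEATURE_NAMES: tuple[str, ...] = (
    _GLOBAL
    + tuple(f"{fam}_{st}" for fam in _FAMILIES for st in _STATS)
    + _SHAPE
    + ("mean_rr",)
)
N_ATTRACTOR_FEATURES = len(FEATURE_NAMES) - 1  # all but mean_rr

assert N_ATTRACTOR_FEATURES == 73 and len(FEATURE_NAMES) == 74


@dataclass
class RegionPartition:
    """Core disk + 6 equal angular arm sectors; every point in one region.

    ``region_ids[i]`` is 0 for the core and 1..6 for the arm sectors;
    ``arm_centers`` are the sector centre angles ``arm_phase + k pi/3``.
    """

    core_radius: float
    arm_phase: float
    arm_centers: np.ndarray
    region_ids: np.ndarray

    @property
    def n_regions(self) -> int:
        return 7


def _sector_of(theta: np.ndarray, arm_phase: float) -> np.ndarray:
    """Sector index 0..5 for angles, sectors of width pi/3 centred at arm_phase + k pi/3."""
    rel = np.mod(theta - arm_phase + np.pi / 6, 2 * np.pi)
    return np.minimum((rel / (np.pi / 3)).astype(int), 5)


def partition_regions(
    points: AttractorPoints, core_radius: float, arm_phase: float | None = None
) -> RegionPartition:
    """Assign every attractor point to the core or one of 6 arm sectors.

    ``arm_phase`` anchors the first sector centre; by default it aligns to
    the largest peak of the theta density of the arm (r > r_c) points.
    """
    r = points.r
    theta = points.theta
    if arm_phase is None:
        arm = theta[r > core_radius]
        if arm.size:
            counts, edges = np.histogram(arm, bins=72, range=(0, 2 * np.pi))
            k = int(np.argmax(counts))
            arm_phase = float(0.5 * (edges[k] + edges[k + 1]))
        else:
            arm_phase = 0.0
    ids = np.zeros(r.size, dtype=int)
    out = r > core_radius
    ids[out] = 1 + _sector_of(theta[out], arm_phase)
    centers = np.mod(arm_phase + np.arange(6) * np.pi / 3, 2 * np.pi)
    return RegionPartition(
        core_radius=float(core_radius),
        arm_phase=float(arm_phase),
        arm_centers=centers,
        region_ids=ids,
    )


def _stats(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        return np.zeros(len(_STATS))
    return np.array(
        [
            np.mean(x),
            np.median(x),
            np.min(x),
            np.max(x),
            np.std(x),
            np.percentile(x, 25),
            np.percentile(x, 75),
        ]
    )


def _wrap_sector(a: np.ndarray | float) -> np.ndarray | float:
    """Wrap an angular difference to [-pi/6, pi/6)."""
    return np.mod(np.asarray(a) + np.pi / 6, np.pi / 3) - np.pi / 6


@dataclass
class FeatureVector:
    """The 74 named per-sub-strip features (73 attractor + mean R-R)."""

    names: tuple[str, ...]
    values: np.ndarray
    quality_mask: tuple[str, ...] = ()  # families flagged for empty regions

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def extract_features(
    points: AttractorPoints,
    image: AttractorImage,
    profiles: DensityProfile,
    partition: RegionPartition,
    mean_rr: float,
) -> FeatureVector:
    """Compute the frozen 74-feature vector for one sub-strip attractor."""
    r = points.r
    n = r.size
    if n == 0:
        raise ParameterError("empty point set")
    r_c = partition.core_radius
    flags: list[str] = []

    grid = image.grid
    gmax = float(grid.max())
    global_vals = np.array(
        [
            gmax,
            float(np.mean(grid > 0.01 * gmax)) if gmax > 0 else 0.0,
            r_c,
            float(np.mean(r <= r_c)),
            float(np.percentile(r, 99)),
        ]
    )

    # Per-arm raw quantities (6 values each); empty arms contribute 0, flagged.
    theta_grid = profiles.theta_grid
    sector_of_bin = _sector_of(theta_grid, partition.arm_phase)
    arm_length = np.zeros(6)
    arm_peak = np.zeros(6)
    arm_mass = np.zeros(6)
    arm_dev = np.zeros(6)
    core_extent = np.zeros(6)
    core_mask = points.r <= r_c
    core_sector = _sector_of(points.theta[core_mask], partition.arm_phase)
    r_core = r[core_mask]
    for k in range(6):
        in_arm = partition.region_ids == (k + 1)
        if in_arm.any():
            arm_length[k] = np.percentile(r[in_arm], 95)
            arm_mass[k] = in_arm.sum() / n
        else:
            flags.append(f"arm_{k}_empty")
        bins_k = sector_of_bin == k
        dens_k = profiles.theta_arm_density[bins_k]
        if dens_k.size and dens_k.any():
            arm_peak[k] = dens_k.max()
            peak_angle = theta_grid[bins_k][int(np.argmax(dens_k))]
            arm_dev[k] = _wrap_sector(peak_angle - partition.arm_centers[k])
        sel = core_sector == k
        if sel.any():
            core_extent[k] = np.percentile(r_core[sel], 95)

    # 3-fold symmetry residuals: rebin the points rotated by 2 pi / 3 on the
    # identical grid and compare per occupied bin.
    edges = np.linspace(-image.extent, image.extent, image.n_bins + 1)
    rot = points.rotated(2 * np.pi / 3)
    grid_rot, _, _ = np.histogram2d(rot.v, rot.w, bins=[edges, edges])
    inside = grid_rot.sum()
    grid_rot = grid_rot / inside if inside else grid_rot
    occupied = (grid > 0) | (grid_rot > 0)
    sym_res = np.abs(grid - grid_rot)[occupied]

    families = (
        r,
        arm_length,
        arm_peak,
        arm_mass,
        arm_dev,
        profiles.theta_core_density,
        profiles.theta_arm_density,
        sym_res,
        core_extent,
    )
    family_vals = np.concatenate([_stats(np.asarray(f, dtype=np.float64)) for f in families])

    # Core / shape features.
    centers = 0.5 * (edges[:-1] + edges[1:])
    cv, cw = np.meshgrid(centers, centers, indexing="ij")
    in_core_bins = np.hypot(cv, cw) <= r_c
    core_peak = float(grid[in_core_bins].max()) if in_core_bins.any() else 0.0
    core_total = float(grid[in_core_bins].sum()) if in_core_bins.any() else 0.0
    mv, mw = float(np.mean(points.v)), float(np.mean(points.w))
    svv = float(np.var(points.v))
    sww = float(np.var(points.w))
    svw = float(np.mean((points.v - mv) * (points.w - mw)))
    axis_angle = 0.5 * np.arctan2(2 * svw, svv - sww)
    p = grid[grid > 0]
    entropy = float(-np.sum(p * np.log(p)))
    shape_vals = np.array([core_peak, core_total, np.hypot(mv, mw), axis_angle, entropy])

    values = np.concatenate([global_vals, family_vals, shape_vals, [mean_rr]])
    if not np.all(np.isfinite(values)):
        raise ParameterError("non-finite feature value produced")
    return FeatureVector(names=FEATURE_NAMES, values=values, quality_mask=tuple(flags))


META_COLUMNS = ("subject_id", "strip_index", "sub_index", "label", "n_quality_flags")


def feature_table(substrips: list[SubStrip], **kwargs) -> "pandas.DataFrame":  # noqa: F821
    """One row per sub-strip: metadata columns plus the 74 named features."""
    import pandas as pd

    rows = []
    for s in substrips:
        fv = substrip_features(s, **kwargs)
        row = {
            "subject_id": s.subject_id,
            "strip_index": s.strip_index,
            "sub_index": s.sub_index,
            "label": s.label,
            "n_quality_flags": len(fv.quality_mask),
        }
        row.update(fv.as_dict())
        rows.append(row)
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


def substrip_features(
    substrip: SubStrip,
    n_bins: int | None = None,
    core_fraction: float = 0.5,
    arm_phase: float | None = None,
) -> FeatureVector:
    """Convenience chain: embed -> image -> core radius -> profiles -> features."""
    points = embed(substrip)
    kwargs = {} if n_bins is None else {"n_bins": n_bins}
    image = density_image(points, **kwargs)
    r_c = compute_core_radius(points, core_fraction)
    profiles = density_profiles(points, r_c)
    partition = partition_regions(points, r_c, arm_phase=arm_phase)
    return extract_features(points, image, profiles, partition, substrip.mean_rr)
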