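"""Tracer-spread quantification in CT-like volumes.

A contrast-agent bolus is segmented relative to an air reference (voxels
at or above 1.02× the mean air intensity belong to the tracer), its
axis-aligned extent is measured per anatomical axis, and the fold-change
in spread between two serial scans is converted into an interstitial
flow-velocity estimate relative to a sedentary baseline.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Sequence

import numpy as np
from scipy import ndimage

from .geometry import STRUCTURE_26, Cluster, ClusterSet
from .volume import Volume3D, axis_index

logger = logging.getLogger(__name__)

__all__ = [
    "TracerSpread",
    "VelocityEstimate",
    "segment_tracer",
    "axis_spread",
    "measure_spread",
    "spread_fold_change",
    "estimate_flow_velocity",
]


@dataclasses.dataclass
class TracerSpread:
    """Per-axis extent of a segmented tracer cluster."""

    extent: tuple[float, float, float]  # physical units (mm)
    n_voxels: int
    air_reference: float  # mean air intensity used for thresholding

    def __post_init__(self) -> None:
        if any(e < 0 for e in self.extent):
            raise ValueError("extents must be non-negative")
        if (self.n_voxels == 0) != all(e == 0 for e in self.extent):
            raise ValueError("extent must be zero exactly when the cluster is empty")


@dataclasses.dataclass
class VelocityEstimate:
    """Interstitial flow velocity scaled from a sedentary baseline."""

    baseline_u: float  # μm/s
    fold_range: tuple[float, float]
    u_range: tuple[float, float]  # μm/s


def _roi_slices(air_roi) -> tuple[slice, slice, slice]:
    out = []
    for part in air_roi:
        if isinstance(part, slice):
            out.append(part)
        else:
            lo, hi = part
            out.append(slice(int(lo), int(hi)))
    if len(out) != 3:
        raise ValueError("air_roi must describe three axes")
    return tuple(out)


def segment_tracer(vol: Volume3D, air_roi, ratio: float = 1.02) -> ClusterSet:
    """Segment the tracer cluster against an air reference region.

    The threshold is ``ratio`` × the mean intensity over ``air_roi``
    (a voxel box given as three (lo, hi) pairs or slices); voxels at or
    above the threshold — inclusive — are foreground, and the largest
    26-connected component is returned as the tracer cluster.
    """
    data = np.asarray(vol.data, dtype=float)
    sl = _roi_slices(air_roi)
    air = data[sl]
    if air.size == 0:
        raise ValueError("air_roi selects no voxels")
    air_mean = float(air.mean())
    threshold = ratio * air_mean

    fg = data >= threshold
    fg[sl] = False  # the reference region itself is never tracer
    labels, n = ndimage.label(fg, structure=STRUCTURE_26)
    if n == 0:
        logger.warning("no voxels reach %.4g x air mean; empty tracer cluster", ratio)
        return ClusterSet(labels=labels, clusters=[], volume=vol)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = int(np.argmax(sizes))
    labels = np.where(labels == keep, 1, 0)
    idx = np.argwhere(labels == 1)
    cluster = Cluster(id=1, indices=idx, intensities=data[tuple(idx.T)])
    return ClusterSet(labels=labels, clusters=[cluster], volume=vol)


def axis_spread(clusters: ClusterSet, axis: int | str, spacing: float | None = None) -> float:
    """Extent of the tracer cluster along one axis.

    Extent = (max index − min index + 1) × spacing; 0 for an empty set.
    """
    ax = axis_index(axis)
    if spacing is None:
        spacing = clusters.spacing[ax]
    if not clusters.clusters:
        return 0.0
    idx = np.concatenate([c.indices[:, ax] for c in clusters.clusters])
    return float((idx.max() - idx.min() + 1) * spacing)


def measure_spread(clusters: ClusterSet, air_reference: float | None = None) -> TracerSpread:
    """Per-axis extents of the segmented tracer cluster."""
    extent = tuple(axis_spread(clusters, ax) for ax in range(3))
    n = sum(c.size for c in clusters.clusters)
    if air_reference is None:
        air_reference = float("nan")
    return TracerSpread(extent=extent, n_voxels=n, air_reference=air_reference)


def spread_fold_change(pre: TracerSpread, post: TracerSpread) -> tuple[float, float, float]:
    """Per-axis post/pre ratio of tracer extents."""
    if any(e <= 0 for e in pre.extent):
        raise ValueError("pre-scan extent is zero on some axis; fold change undefined")
    return tuple(p / q for p, q in zip(post.extent, pre.extent))


def estimate_flow_velocity(
    baseline_u: float, fold_range: Sequence[float]
) -> VelocityEstimate:
    """Scale a sedentary baseline flow speed by an observed fold range.

    With the literature baseline of 0.2 μm/s and a measured two- to
    three-fold spread enhancement this gives 0.4–0.6 μm/s.
    """
    low, high = float(fold_range[0]), float(fold_range[1])
    if baseline_u <= 0:
        raise ValueError("baseline_u must be positive")
    if not (0 < low <= high):
        raise ValueError("fold range must satisfy 0 < low <= high")
    return VelocityEstimate(
        baseline_u=float(baseline_u),
        fold_range=(low, high),
        u_range=(baseline_u * low, baseline_u * high),
    )
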