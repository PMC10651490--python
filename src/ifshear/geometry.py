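"""Interstitial-space geometry from fluorescence volumes.

The chain mirrors a two-photon analysis of dye-filled brain extracellular
space: resample to isotropic voxels and box-smooth, keep the top 20% of
voxels by fluorescence as interstitial clusters, trim oversized clusters,
discard specks, then characterise each cluster's in-plane footprint with a
second-moment ellipse. Cross-sectional areas are summarised by a
log-normal fit (mode and FWHM), and cluster orientation is compared
against the centroidal line of the structure (linear + sigmoid fit of
per-slice centres of mass).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

from .volume import Volume3D, axis_index

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "ClusterSet",
    "EllipseFit",
    "PoreSizeDistribution",
    "CenterLine",
    "OrientationSummary",
    "preprocess_volume",
    "extract_interstitial_clusters",
    "fit_cluster_ellipses",
    "cross_section_areas",
    "estimate_cross_section_distribution",
    "compute_centroidal_line",
    "orientation_summary",
]

# 26-connectivity in 3D: thin diagonal channels stay connected
STRUCTURE_26 = np.ones((3, 3, 3), dtype=int)


# ---------------------------------------------------------------------------
# Types


@dataclasses.dataclass
class Cluster:
    id: int
    indices: np.ndarray  # (n, 3) voxel indices
    intensities: np.ndarray  # (n,)

    @property
    def size(self) -> int:
        return int(self.indices.shape[0])


@dataclasses.dataclass
class ClusterSet:
    """Labelled connected components of the extracted foreground."""

    labels: np.ndarray  # 3D int grid, 0 = background
    clusters: list[Cluster]
    volume: Volume3D  # source volume the clusters were extracted from

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def spacing(self) -> tuple[float, float, float]:
        return self.volume.spacing


@dataclasses.dataclass
class EllipseFit:
    """Second-central-moment ellipse of a cluster's in-plane footprint."""

    cluster_id: int
    centroid: tuple[float, float]  # physical in-plane coordinates
    major_axis: float  # length = 4 * sqrt(largest eigenvalue)
    minor_axis: float
    angle: float  # major-axis orientation, rad in [-pi/2, pi/2)
    area: float  # footprint voxel count x in-plane voxel area
    n_voxels: int

    @property
    def elongation(self) -> float:
        return self.major_axis / self.minor_axis


@dataclasses.dataclass
class PoreSizeDistribution:
    """Log-normal summary of cross-sectional areas (mode and FWHM)."""

    log_mu: float
    log_sigma: float
    mode: float
    fwhm_low: float
    fwhm_high: float
    n: int

    @property
    def fwhm(self) -> float:
        return self.fwhm_high - self.fwhm_low


@dataclasses.dataclass
class CenterLine:
    """Centroidal line of a binary structure along a parameter axis.

    ``points`` holds the fitted curve sampled at the foreground slices;
    the first transverse axis is fitted linearly, the second by a
    four-parameter sigmoid c + d / (1 + exp(-(y - y0)/s)).
    """

    parameter_axis: int
    parameter_values: np.ndarray  # physical coordinates along the axis
    points: np.ndarray  # (n, 3) physical coordinates of the fitted line
    residuals: np.ndarray  # (n, 2) residuals for the two transverse axes
    linear_coeffs: tuple[float, float]  # slope, intercept of first transverse axis
    sigmoid_params: tuple[float, float, float, float] | None  # (c, d, y0, s)
    sigmoid_fallback_slope: tuple[float, float] | None = None

    @property
    def sigmoid_converged(self) -> bool:
        return self.sigmoid_params is not None

    def tangent(self, y: float) -> np.ndarray:
        """Unit tangent of the fitted line at parameter coordinate y."""
        axes = [a for a in range(3) if a != self.parameter_axis]
        vec = np.zeros(3)
        vec[self.parameter_axis] = 1.0
        vec[axes[0]] = self.linear_coeffs[0]
        if self.sigmoid_params is not None:
            c, d, y0, s = self.sigmoid_params
            e = math.exp(-(y - y0) / s)
            vec[axes[1]] = d * e / (s * (1.0 + e) ** 2)
        else:
            vec[axes[1]] = self.sigmoid_fallback_slope[0]
        return vec / np.linalg.norm(vec)


@dataclasses.dataclass
class OrientationSummary:
    """Alignment of cluster major axes with a reference direction."""

    signed_angles: np.ndarray  # rad, in [-pi/2, pi/2)
    acute_angles: np.ndarray  # rad, in [0, pi/2]
    circular_mean: float  # rad (axial statistics, doubled-angle space)
    resultant_length: float  # in [0, 1]; 1 = perfectly aligned
    circular_sd: float  # rad
    elongations: np.ndarray


# ---------------------------------------------------------------------------
# Preprocessing


def preprocess_volume(
    vol: Volume3D, target_voxel: float, smooth_width_voxels: int = 5
) -> Volume3D:
    """Resample to isotropic voxels (trilinear) and box-smooth.

    ``smooth_width_voxels`` must be odd; a width of 1 disables smoothing.
    Output voxel centres follow the same physical-centre convention as the
    input, so a constant volume stays constant.
    """
    if target_voxel <= 0:
        raise ValueError("target_voxel must be positive")
    w = int(smooth_width_voxels)
    if w < 1 or w % 2 == 0:
        raise ValueError("smooth_width_voxels must be odd and >= 1")
    extents = [n * s for n, s in zip(vol.shape, vol.spacing)]
    if any(target_voxel > e for e in extents):
        raise ValueError("target_voxel exceeds the physical extent of the volume")

    new_shape = tuple(int(round(e / target_voxel)) for e in extents)
    # physical centre of output voxel j: (j + 0.5) * target; input index
    # coordinate of a physical position p on axis a: p / spacing[a] - 0.5
    axes_coords = [
        ((np.arange(m) + 0.5) * target_voxel) / s - 0.5
        for m, s in zip(new_shape, vol.spacing)
    ]
    grid = np.meshgrid(*axes_coords, indexing="ij")
    resampled = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float), np.stack(grid), order=1, mode="nearest"
    )
    if w > 1:
        resampled = ndimage.uniform_filter(resampled, size=w, mode="nearest")
    return Volume3D(resampled, (target_voxel,) * 3)


# ---------------------------------------------------------------------------
# Cluster extraction


def _build_cluster_set(fg: np.ndarray, vol: Volume3D) -> ClusterSet:
    labels, n = ndimage.label(fg, structure=STRUCTURE_26)
    clusters = []
    if n:
        data = np.asarray(vol.data)
        all_idx = np.argwhere(labels > 0)
        lab_of = labels[tuple(all_idx.T)]
        order = np.argsort(lab_of, kind="stable")
        all_idx = all_idx[order]
        lab_of = lab_of[order]
        bounds = np.searchsorted(lab_of, np.arange(1, n + 2))
        for cid in range(1, n + 1):
            idx = all_idx[bounds[cid - 1] : bounds[cid]]
            clusters.append(
                Cluster(id=cid, indices=idx, intensities=data[tuple(idx.T)])
            )
    return ClusterSet(labels=labels, clusters=clusters, volume=vol)


def extract_interstitial_clusters(
    vol: Volume3D,
    top_fraction: float = 0.20,
    huge_size: int = 5000,
    trim_fraction: float = 0.50,
    min_size: int = 50,
) -> ClusterSet:
    """Extract interstitial clusters from a smoothed fluorescence volume.

    1. Foreground = voxels strictly above the (1 - top_fraction) sample
       quantile of intensity (an all-constant volume therefore yields an
       empty foreground, not an error).
    2. 26-connected components are labelled.
    3. Components larger than ``huge_size`` voxels lose their
       ceil(trim_fraction * size) lowest-intensity voxels (ties broken by
       voxel index order), after which the foreground is re-labelled.
    4. Components smaller than ``min_size`` voxels are discarded.
    """
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must lie in (0, 1)")
    data = np.asarray(vol.data, dtype=float)
    threshold = float(np.quantile(data, 1.0 - top_fraction))
    fg = data > threshold

    labels, n = ndimage.label(fg, structure=STRUCTURE_26)
    if n:
        sizes = np.bincount(labels.ravel())
        for cid in np.nonzero(sizes > huge_size)[0]:
            if cid == 0:
                continue
            idx = np.argwhere(labels == cid)
            vals = data[tuple(idx.T)]
            # stable sort: equal intensities removed in voxel index order
            order = np.argsort(vals, kind="stable")
            n_remove = math.ceil(trim_fraction * idx.shape[0])
            removed = idx[order[:n_remove]]
            fg[tuple(removed.T)] = False
        # re-label so the size filter sees the post-trim components
        labels, n = ndimage.label(fg, structure=STRUCTURE_26)

    if n:
        sizes = np.bincount(labels.ravel())
        small = np.nonzero(sizes < min_size)[0]
        small = small[small != 0]
        if small.size:
            fg[np.isin(labels, small)] = False

    return _build_cluster_set(fg, vol)


# ---------------------------------------------------------------------------
# Ellipse fitting


def _plane_axes(plane: str | Sequence[int | str]) -> tuple[int, int]:
    if isinstance(plane, str):
        if len(plane) != 2:
            raise ValueError(f"plane must name two axes, got {plane!r}")
        return axis_index(plane[0]), axis_index(plane[1])
    a, b = plane
    return axis_index(a), axis_index(b)


def select_slice(vol: Volume3D, stack_axis: int) -> int:
    """Index of the slice with the highest mean fluorescence."""
    data = np.asarray(vol.data, dtype=float)
    other = tuple(a for a in range(3) if a != stack_axis)
    return int(np.argmax(data.mean(axis=other)))


def fit_cluster_ellipses(
    clusters: ClusterSet,
    plane: str | Sequence[int | str] = "xz",
    slice_index: int | str = "max_mean_fluorescence",
) -> list[EllipseFit]:
    """Fit a second-moment ellipse to each cluster footprint in one slice.

    The analysed slice is either given explicitly or chosen as the plane
    with the highest mean fluorescence along the stack direction. Axis
    lengths are 4·sqrt(eigenvalue) of the footprint's covariance (with the
    per-voxel square moment s²/12 added, so a one-voxel-wide footprint has
    a finite minor axis). Footprints of fewer than 3 voxels are skipped.
    """
    ax_a, ax_b = _plane_axes(plane)
    if ax_a == ax_b:
        raise ValueError("plane axes must differ")
    stack_axis = ({0, 1, 2} - {ax_a, ax_b}).pop()
    if slice_index == "max_mean_fluorescence":
        k = select_slice(clusters.volume, stack_axis)
    else:
        k = int(slice_index)

    sp = clusters.spacing
    fits: list[EllipseFit] = []
    for cl in clusters.clusters:
        in_slice = cl.indices[:, stack_axis] == k
        foot = cl.indices[in_slice]
        if foot.shape[0] < 3:
            logger.info(
                "cluster %d skipped in slice %d: footprint of %d voxel(s) < 3",
                cl.id, k, foot.shape[0],
            )
            continue
        coords = np.stack(
            [(foot[:, ax_a] + 0.5) * sp[ax_a], (foot[:, ax_b] + 0.5) * sp[ax_b]],
            axis=1,
        )
        centroid = coords.mean(axis=0)
        cov = np.cov(coords.T, bias=True)
        # square-voxel self-moment keeps degenerate footprints measurable
        cov = cov + np.diag([sp[ax_a] ** 2 / 12.0, sp[ax_b] ** 2 / 12.0])
        evals, evecs = np.linalg.eigh(cov)
        minor, major = 4.0 * np.sqrt(np.maximum(evals, 0.0))
        if (evals[1] - evals[0]) <= 1e-12 * max(evals[1], 1e-300):
            angle = 0.0  # isotropic footprint: orientation undefined
        else:
            v = evecs[:, 1]
            angle = math.atan2(v[1], v[0])
            if angle >= math.pi / 2:
                angle -= math.pi
            elif angle < -math.pi / 2:
                angle += math.pi
        fits.append(
            EllipseFit(
                cluster_id=cl.id,
                centroid=(float(centroid[0]), float(centroid[1])),
                major_axis=float(major),
                minor_axis=float(minor),
                angle=float(angle),
                area=float(foot.shape[0] * sp[ax_a] * sp[ax_b]),
                n_voxels=int(foot.shape[0]),
            )
        )
    return fits


def cross_section_areas(fits: Sequence[EllipseFit]) -> np.ndarray:
    """Footprint areas (physical units²) of fitted clusters."""
    return np.array([f.area for f in fits], dtype=float)


# ---------------------------------------------------------------------------
# Pore-size distribution


def estimate_cross_section_distribution(
    areas: Sequence[float], voxel_area: float = 1.0
) -> PoreSizeDistribution:
    """Maximum-likelihood log-normal fit of cross-sectional areas.

    ``areas`` may be physical areas (``voxel_area=1``) or voxel counts to
    be scaled by ``voxel_area``. The mode is exp(μ̂ - σ̂²) and the FWHM
    bounds of the fitted density are mode · exp(±σ̂·sqrt(2 ln 2)) — the
    closed-form half-maximum roots of the log-normal density.
    """
    a = np.asarray(areas, dtype=float) * float(voxel_area)
    if a.size < 10:
        raise ValueError(f"need at least 10 areas, got {a.size}")
    if np.any(a <= 0) or np.any(~np.isfinite(a)):
        raise ValueError("all areas must be positive and finite")
    log_a = np.log(a)
    mu = float(np.mean(log_a))
    sigma = float(np.std(log_a))  # MLE (ddof=0)
    if sigma < 1e-12:
        raise ValueError("degenerate sample: all areas identical (sigma -> 0)")
    mode = math.exp(mu - sigma**2)
    half_width = sigma * math.sqrt(2.0 * math.log(2.0))
    return PoreSizeDistribution(
        log_mu=mu,
        log_sigma=sigma,
        mode=mode,
        fwhm_low=mode * math.exp(-half_width),
        fwhm_high=mode * math.exp(half_width),
        n=int(a.size),
    )


# ---------------------------------------------------------------------------
# Centroidal line


def _sigmoid(y: np.ndarray, c: float, d: float, y0: float, s: float) -> np.ndarray:
    return c + d / (1.0 + np.exp(-(y - y0) / s))


def compute_centroidal_line(mask: Volume3D, parameter_axis: int | str = "y") -> CenterLine:
    """Fit the centroidal line of a binary structure.

    Per-slice unweighted centres of mass are computed along
    ``parameter_axis``; the first transverse coordinate is fitted by
    linear least squares and the second by a four-parameter sigmoid
    (falling back to a linear fit, flagged on the result, if the sigmoid
    does not converge).
    """
    p_ax = axis_index(parameter_axis)
    axes = [a for a in range(3) if a != p_ax]
    data = np.asarray(mask.data) > 0
    sp = mask.spacing

    slice_idx = []
    cent_a = []
    cent_b = []
    for i in range(data.shape[p_ax]):
        sl = np.take(data, i, axis=p_ax)
        if not sl.any():
            continue
        idx = np.argwhere(sl)
        slice_idx.append(i)
        cent_a.append((idx[:, 0].mean() + 0.5) * sp[axes[0]])
        cent_b.append((idx[:, 1].mean() + 0.5) * sp[axes[1]])
    if len(slice_idx) < 4:
        raise ValueError("mask must be non-empty in at least 4 slices along the axis")

    y = (np.asarray(slice_idx) + 0.5) * sp[p_ax]
    a = np.asarray(cent_a)
    b = np.asarray(cent_b)

    slope, intercept = np.polyfit(y, a, 1)
    a_fit = slope * y + intercept

    sig_params: tuple[float, float, float, float] | None
    fallback = None
    try:
        span = float(b.max() - b.min())
        p0 = [float(b.min()), span if span > 0 else 1.0, float(np.median(y)),
              max((y.max() - y.min()) / 10.0, 1e-6)]
        popt, _ = optimize.curve_fit(_sigmoid, y, b, p0=p0, maxfev=10000)
        if not np.all(np.isfinite(popt)):
            raise RuntimeError("non-finite sigmoid parameters")
        sig_params = tuple(float(v) for v in popt)
        b_fit = _sigmoid(y, *sig_params)
    except (RuntimeError, optimize.OptimizeWarning) as exc:
        logger.warning("sigmoid fit did not converge (%s); falling back to linear", exc)
        sig_params = None
        s2, i2 = np.polyfit(y, b, 1)
        fallback = (float(s2), float(i2))
        b_fit = s2 * y + i2

    points = np.zeros((len(y), 3))
    points[:, p_ax] = y
    points[:, axes[0]] = a_fit
    points[:, axes[1]] = b_fit
    residuals = np.stack([a - a_fit, b - b_fit], axis=1)
    return CenterLine(
        parameter_axis=p_ax,
        parameter_values=y,
        points=points,
        residuals=residuals,
        linear_coeffs=(float(slope), float(intercept)),
        sigmoid_params=sig_params,
        sigmoid_fallback_slope=fallback,
    )


# ---------------------------------------------------------------------------
# Orientation statistics


def orientation_summary(
    ellipses: Sequence[EllipseFit],
    line: CenterLine | None = None,
    plane: str | Sequence[int | str] = "xz",
    parameter_coordinate: float | None = None,
) -> OrientationSummary:
    """Angles between cluster major axes and the local centroidal-line tangent.

    The line tangent is projected into the analysis plane; if no line is
    given the reference is the plane's first axis. Statistics use axial
    (doubled-angle) circular conventions: resultant length 1 means all
    major axes parallel, and the circular s.d. reduces to the ordinary
    s.d. for small scatter.
    """
    if not ellipses:
        raise ValueError("need at least one ellipse")
    ax_a, ax_b = _plane_axes(plane)

    if line is None:
        ref_angle = 0.0
    else:
        if parameter_coordinate is None:
            parameter_coordinate = float(np.median(line.parameter_values))
        tan = line.tangent(parameter_coordinate)
        ref_angle = math.atan2(tan[ax_b], tan[ax_a])

    deltas = []
    for e in ellipses:
        d = e.angle - ref_angle
        # axial difference, wrapped to [-pi/2, pi/2)
        d = (d + math.pi / 2) % math.pi - math.pi / 2
        deltas.append(d)
    deltas = np.asarray(deltas)

    z = np.exp(2j * deltas).mean()
    resultant = float(np.abs(z))
    circ_mean = float(np.angle(z) / 2.0)
    circ_sd = (
        float(0.5 * math.sqrt(-2.0 * math.log(resultant))) if resultant > 0 else math.inf
    )
    return OrientationSummary(
        signed_angles=deltas,
        acute_angles=np.abs(deltas),
        circular_mean=circ_mean,
        resultant_length=resultant,
        circular_sd=circ_sd,
        elongations=np.array([e.elongation for e in ellipses]),
    )
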