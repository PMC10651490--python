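"""Synthetic inputs with known ground truth for every pipeline stage.

The study this pipeline supports did not deposit raw imaging or
physiological recordings, so each analysis stage is exercised against
generated data whose ground truth is known exactly:

* ``generate_pore_volume`` — channel-like bright interstitial structures
  with log-normal cross-sections and a preferred orientation, embedded in
  Gaussian background noise (stand-in for two-photon fluorescence stacks).
* ``generate_tracer_volume`` — anisotropically spreading contrast-agent
  blobs plus an air reference region (stand-in for serial μCT scans).
* ``generate_beat_series`` — beat-by-beat SBP/RRI series carrying low-
  (~0.1 Hz) and high-frequency (~0.25 Hz) oscillations plus ectopic and
  dropout artifacts.
* ``generate_nerve_signal`` — cardiac-locked sympathetic-nerve bursts with
  additive white noise and a DC offset.

All randomness flows from one `numpy.random.Generator` seeded per call;
the same spec and seed give bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .cardio import BeatSeries
from .nerve import NerveSignal
from .volume import Volume3D

__all__ = [
    "PoreVolumeSpec",
    "BeatSeriesSpec",
    "TracerPair",
    "generate_pore_volume",
    "generate_tracer_volume",
    "generate_beat_series",
    "generate_nerve_signal",
    "sample_cross_section_areas",
]


# ---------------------------------------------------------------------------
# Pore / channel volumes


@dataclasses.dataclass
class PoreVolumeSpec:
    """Parameters of a synthetic channel volume.

    Channels are straight tubes with elliptical cross-section (circular by
    default) whose areas are i.i.d. log-normal and whose directions scatter
    around ``orientation_axis``. Defaults describe a thin 64×24×64 voxel
    substack at 0.1 μm isotropic spacing in which the channels occupy
    roughly the extracellular volume fraction (~20%) that the extraction
    stage assumes, and in which a single channel stays below the
    huge-cluster trim threshold of the extraction rules (that rule exists
    to split merged blobs, not to halve intact tubes).
    """

    shape: tuple[int, int, int] = (64, 24, 64)
    spacing: tuple[float, float, float] = (0.1, 0.1, 0.1)  # μm / voxel
    n_channels: int = 8
    lognormal_mu: float = math.log(0.8)  # log μm²
    lognormal_sigma: float = 0.4
    orientation_axis: tuple[float, float, float] = (0.0, 1.0, 0.0)
    orientation_jitter: float = 0.1  # rad, s.d. of each transverse angle
    aspect_ratio: float = 1.0
    fg_intensity: float = 100.0
    bg_intensity: float = 10.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("shape must be positive per axis")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive per axis")
        if self.n_channels < 0:
            raise ValueError("n_channels must be >= 0")
        if self.lognormal_sigma <= 0:
            raise ValueError("lognormal_sigma must be > 0")
        if not (0 <= self.orientation_jitter < math.pi / 2):
            raise ValueError("orientation_jitter must lie in [0, pi/2)")
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.aspect_ratio < 1.0:
            raise ValueError("aspect_ratio is major/minor and must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def sample_cross_section_areas(
    lognormal_mu: float, lognormal_sigma: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw channel cross-sectional areas (the sampler the renderer uses)."""
    return rng.lognormal(lognormal_mu, lognormal_sigma, n)


def _orthonormal_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane perpendicular to ``axis``."""
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, axis)) > 0.9:
        helper = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    return e1, e2


def generate_pore_volume(
    spec: PoreVolumeSpec, max_retries: int = 200
) -> tuple[Volume3D, dict]:
    """Render straight bright channels in a noisy background.

    Channel directions are ``axis`` tilted by two independent transverse
    angles drawn from N(0, orientation_jitter), so the signed angle seen in
    any plane containing the axis is itself N(0, orientation_jitter).
    Channel centres are drawn uniformly over the mid-plane and re-drawn
    (up to ``max_retries`` times each) until cross-sections do not overlap.

    Returns the volume and a ground-truth dict with one entry per channel:
    cross-sectional ``area`` (μm²), unit ``direction``, ``center`` (μm) and
    the signed transverse angles ``angle_e1``/``angle_e2`` (rad).
    """
    rng = np.random.default_rng(spec.seed)
    axis = np.asarray(spec.orientation_axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError("orientation_axis must be non-zero")
    axis = axis / norm
    e1, e2 = _orthonormal_frame(axis)

    shape = tuple(int(n) for n in spec.shape)
    spacing = tuple(float(s) for s in spec.spacing)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    center_box = extent / 2.0

    areas = sample_cross_section_areas(
        spec.lognormal_mu, spec.lognormal_sigma, spec.n_channels, rng
    )
    radii_equiv = np.sqrt(areas / math.pi)  # radius of the equal-area circle

    # lay out channel centres in the plane perpendicular to the mean axis
    placed: list[dict] = []
    for i in range(spec.n_channels):
        a1 = rng.normal(0.0, spec.orientation_jitter) if spec.orientation_jitter else 0.0
        a2 = rng.normal(0.0, spec.orientation_jitter) if spec.orientation_jitter else 0.0
        direction = axis + math.tan(a1) * e1 + math.tan(a2) * e2
        direction /= np.linalg.norm(direction)
        # semi-axes of the elliptical cross-section (area preserved)
        semi_major = math.sqrt(areas[i] * spec.aspect_ratio / math.pi)
        semi_minor = math.sqrt(areas[i] / (spec.aspect_ratio * math.pi))
        margin = max(spacing)
        for attempt in range(max_retries + 1):
            # uniform in-plane offset, kept away from the lateral faces
            o1 = rng.uniform(0.0, 1.0)
            o2 = rng.uniform(0.0, 1.0)
            span1 = float(abs(e1 @ extent))
            span2 = float(abs(e2 @ extent))
            c1 = (o1 - 0.5) * (span1 - 2 * (semi_major + margin))
            c2 = (o2 - 0.5) * (span2 - 2 * (semi_major + margin))
            center = center_box + c1 * e1 + c2 * e2
            ok = True
            for prev in placed:
                d_perp = (center - prev["center"])
                d_perp = d_perp - (d_perp @ axis) * axis
                min_sep = semi_major + prev["semi_major"] + margin
                if np.linalg.norm(d_perp) < min_sep:
                    ok = False
                    break
            if ok:
                break
        else:  # pragma: no cover - defensive
            ok = False
        if not ok:
            raise RuntimeError(
                f"could not place channel {i} without overlap after {max_retries} retries; "
                "reduce n_channels or the cross-sectional areas"
            )
        placed.append(
            dict(
                center=center,
                direction=direction,
                semi_major=semi_major,
                semi_minor=semi_minor,
                area=float(areas[i]),
                angle_e1=float(a1),
                angle_e2=float(a2),
            )
        )

    # rasterise: voxel centres in physical coordinates
    grids = np.meshgrid(
        (np.arange(shape[0]) + 0.5) * spacing[0],
        (np.arange(shape[1]) + 0.5) * spacing[1],
        (np.arange(shape[2]) + 0.5) * spacing[2],
        indexing="ij",
    )
    coords = np.stack(grids, axis=-1)  # (nx, ny, nz, 3)
    mask = np.zeros(shape, dtype=bool)
    for ch in placed:
        v = coords - ch["center"]
        along = v @ ch["direction"]
        v_perp = v - along[..., None] * ch["direction"]
        if spec.aspect_ratio == 1.0:
            r2 = np.einsum("...k,...k->...", v_perp, v_perp)
            mask |= r2 <= ch["semi_major"] ** 2
        else:
            u1 = np.cross(ch["direction"], axis)
            nu = np.linalg.norm(u1)
            u1 = e1 if nu < 1e-12 else u1 / nu
            u2 = np.cross(ch["direction"], u1)
            q1 = (v_perp @ u1) / ch["semi_minor"]
            q2 = (v_perp @ u2) / ch["semi_major"]
            mask |= q1**2 + q2**2 <= 1.0

    data = np.full(shape, spec.bg_intensity, dtype=float)
    data[mask] = spec.fg_intensity
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, shape)

    ground_truth = {
        "channels": [
            {k: ch[k] for k in ("area", "direction", "center", "angle_e1", "angle_e2")}
            for ch in placed
        ],
        "foreground_fraction": float(mask.mean()),
    }
    return Volume3D(data, spacing), ground_truth


# ---------------------------------------------------------------------------
# Tracer volumes


@dataclasses.dataclass
class TracerPair:
    """Serial pre/post tracer scans with an air reference region."""

    pre: Volume3D
    post: Volume3D
    air_roi: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    ground_truth: dict


def generate_tracer_volume(
    pre_spread_sd: Sequence[float],
    post_spread_sd: Sequence[float],
    air_intensity: float = 100.0,
    tracer_peak: float = 150.0,
    shape: Sequence[int] = (48, 48, 48),
    spacing: Sequence[float] = (0.1, 0.1, 0.1),  # mm / voxel
    seed: int = 0,
    noise_sd: float = 0.0,
    threshold_ratio: float = 1.02,
) -> TracerPair:
    """Two serial CT-like scans of an anisotropic Gaussian tracer bolus.

    The tissue background is set to the air level so that only tracer
    voxels exceed the ``threshold_ratio`` × air segmentation threshold; the
    air reference is a fixed corner box (first quarter of each axis).
    Ground truth records, per scan, the analytic per-axis extent of the
    above-threshold level set; a boundary-truncated blob raises no error
    but is flagged in ``ground_truth['warnings']``.
    """
    pre_sd = np.asarray(pre_spread_sd, dtype=float)
    post_sd = np.asarray(post_spread_sd, dtype=float)
    if pre_sd.shape != (3,) or post_sd.shape != (3,):
        raise ValueError("spread s.d. must have one value per axis")
    if np.any(pre_sd <= 0) or np.any(post_sd < pre_sd):
        raise ValueError("require post_spread_sd >= pre_spread_sd > 0 per axis")
    if tracer_peak <= 0 or air_intensity <= 0:
        raise ValueError("intensities must be positive")

    rng = np.random.default_rng(seed)
    shape = tuple(int(n) for n in shape)
    spacing = tuple(float(s) for s in spacing)
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    # bolus sits in the far octant so it stays clear of the air corner
    center = extent * 0.625

    air_roi = tuple((0, max(1, n // 4)) for n in shape)

    grids = np.meshgrid(
        *[(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)], indexing="ij"
    )

    # blob is above threshold where peak*exp(-d^2/2sd^2) >= (ratio-1)*air
    rel = tracer_peak / ((threshold_ratio - 1.0) * air_intensity)
    warnings: list[str] = []

    def _scan(sd: np.ndarray) -> tuple[Volume3D, list[float]]:
        q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, sd))
        data = air_intensity + tracer_peak * np.exp(-0.5 * q)
        sl = tuple(slice(lo, hi) for lo, hi in air_roi)
        data[sl] = air_intensity
        if noise_sd > 0:
            data = data + rng.normal(0.0, noise_sd, shape)
        extents = []
        for ax in range(3):
            if rel <= 1.0:
                extents.append(0.0)
                continue
            half = sd[ax] * math.sqrt(2.0 * math.log(rel))
            if center[ax] - half < 0 or center[ax] + half > extent[ax]:
                warnings.append(f"tracer blob truncated by volume boundary on axis {ax}")
            extents.append(2.0 * half)
        return Volume3D(data, spacing), extents

    pre_vol, pre_ext = _scan(pre_sd)
    post_vol, post_ext = _scan(post_sd)
    ground_truth = {
        "center_mm": center.tolist(),
        "pre_extent_mm": pre_ext,
        "post_extent_mm": post_ext,
        "warnings": warnings,
    }
    return TracerPair(pre_vol, post_vol, air_roi, ground_truth)


# ---------------------------------------------------------------------------
# Beat series


@dataclasses.dataclass
class BeatSeriesSpec:
    """Parameters of a synthetic beat-by-beat SBP/RRI recording.

    Defaults give a 600-s resting recording at ~1 s interbeat interval with
    a 0.1 Hz low-frequency oscillation (Mayer-wave band) and a 0.25 Hz
    respiratory high-frequency oscillation in the R-R intervals, plus a
    low-frequency systolic-pressure oscillation.
    """

    duration: float = 600.0  # s
    mean_rri: float = 1.0  # s
    lf_freq: float = 0.10  # Hz
    hf_freq: float = 0.25  # Hz
    lf_amp_rri: float = 0.03  # s
    hf_amp_rri: float = 0.02  # s
    mean_sbp: float = 140.0  # mm Hg
    mean_dbp: float = 85.0  # mm Hg
    lf_amp_sbp: float = 3.0  # mm Hg
    ectopic_rate: float = 0.0  # fraction of beats
    dropout_rate: float = 0.0  # fraction of beats
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.04 <= self.lf_freq <= 0.15):
            raise ValueError("lf_freq must lie in the LF band [0.04, 0.15] Hz")
        if not (0.15 <= self.hf_freq <= 0.4):
            raise ValueError("hf_freq must lie in the HF band [0.15, 0.4] Hz")
        if self.mean_sbp <= self.mean_dbp:
            raise ValueError("mean_sbp must exceed mean_dbp")
        for name in ("ectopic_rate", "dropout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.duration <= 0 or self.mean_rri <= 0:
            raise ValueError("duration and mean_rri must be positive")


def generate_beat_series(spec: BeatSeriesSpec) -> tuple[BeatSeries, dict]:
    """Simulate a beat series with LF/HF oscillations and artifacts.

    The interbeat interval of the beat at time t_{i-1} is
    ``mean_rri + lf_amp_rri*sin(2π lf t) + hf_amp_rri*sin(2π hf t)`` and
    SBP carries the analogous LF term. Ectopic beats (count =
    round(ectopic_rate × n)) have their RRI halved or doubled at recorded
    positions; dropout beats have their pressure readings blanked and
    flagged invalid. Ground truth records band content and every artifact.
    """
    rng = np.random.default_rng(spec.seed)

    times = [0.0]
    t = 0.0
    while True:
        rri = (
            spec.mean_rri
            + spec.lf_amp_rri * math.sin(2 * math.pi * spec.lf_freq * t)
            + spec.hf_amp_rri * math.sin(2 * math.pi * spec.hf_freq * t)
        )
        if rri <= 0:
            raise ValueError("oscillation amplitudes exceed mean_rri; RRI went non-positive")
        t += rri
        if t > spec.duration:
            break
        times.append(t)
    times = np.asarray(times)
    n = len(times)
    rri = np.empty(n)
    rri[0] = spec.mean_rri
    rri[1:] = np.diff(times)

    # ectopic beats: halve or double the RRI at recorded positions
    n_ectopic = int(round(spec.ectopic_rate * n))
    eligible = np.arange(12, n)  # leave history for the relative cleaning rule
    ectopic_idx = np.sort(rng.choice(eligible, size=min(n_ectopic, len(eligible)), replace=False))
    ectopic_kind = []
    for j in ectopic_idx:
        if rng.random() < 0.5:
            rri[j] *= 0.5
            ectopic_kind.append("halved")
        else:
            rri[j] *= 2.0
            ectopic_kind.append("doubled")
    times = np.concatenate([[0.0], np.cumsum(rri[1:])])

    sbp = spec.mean_sbp + spec.lf_amp_sbp * np.sin(2 * math.pi * spec.lf_freq * times)
    dbp = np.full(n, float(spec.mean_dbp))
    bp_valid = np.ones(n, dtype=bool)

    n_drop = int(round(spec.dropout_rate * n))
    dropout_idx = np.sort(rng.choice(np.arange(n), size=n_drop, replace=False))
    sbp[dropout_idx] = np.nan
    dbp[dropout_idx] = np.nan
    bp_valid[dropout_idx] = False

    series = BeatSeries(times=times, sbp=sbp, dbp=dbp, rri=rri, bp_valid=bp_valid)
    ground_truth = {
        "lf_freq": spec.lf_freq,
        "hf_freq": spec.hf_freq,
        "lf_amp_rri": spec.lf_amp_rri,
        "hf_amp_rri": spec.hf_amp_rri,
        "lf_amp_sbp": spec.lf_amp_sbp,
        "ectopic_indices": ectopic_idx.tolist(),
        "ectopic_kind": ectopic_kind,
        "dropout_indices": dropout_idx.tolist(),
    }
    return series, ground_truth


# ---------------------------------------------------------------------------
# Nerve signal


def generate_nerve_signal(
    fs: float,
    beat_times: Sequence[float],
    burst_amp: float = 1.0,
    noise_sd: float = 0.0,
    dc_offset: float = 0.0,
    seed: int = 0,
    burst_width: float = 0.03,
    carrier_freq: float = 300.0,
    amp_jitter: float = 0.0,
    burst_delay: float = 0.15,
) -> tuple[NerveSignal, dict]:
    """Cardiac-locked multifibre nerve bursts with additive white noise.

    Each heartbeat contributes a Gaussian-envelope burst (s.d.
    ``burst_width`` s) of a ``carrier_freq`` oscillation, centred
    ``burst_delay`` seconds after the beat time (the systolic latency of
    baroreceptor discharge; the default keeps each burst inside its own
    interbeat window), with amplitude ``burst_amp`` optionally jittered
    per beat by ±``amp_jitter`` (fractional, uniform). Ground truth
    records the per-beat burst amplitude; the rectified-integrated
    readout is proportional to it.
    """
    if fs < 1000:
        raise ValueError("nerve recordings require fs >= 1000 Hz")
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size == 0:
        raise ValueError("need at least one beat time")
    rng = np.random.default_rng(seed)

    duration = float(beat_times[-1]) + 0.5
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    signal = np.full(n, float(dc_offset))

    amps = burst_amp * (1.0 + amp_jitter * rng.uniform(-1.0, 1.0, beat_times.size))
    for tb, a in zip(beat_times + burst_delay, amps):
        lo = max(0, int((tb - 5 * burst_width) * fs))
        hi = min(n, int((tb + 5 * burst_width) * fs) + 1)
        tt = t[lo:hi]
        env = np.exp(-0.5 * ((tt - tb) / burst_width) ** 2)
        signal[lo:hi] += a * env * np.sin(2 * math.pi * carrier_freq * (tt - tb))

    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, n)

    ground_truth = {"burst_amplitudes": amps.tolist(), "burst_width": burst_width}
    return NerveSignal(samples=signal, rate=float(fs), beat_times=beat_times), ground_truth
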