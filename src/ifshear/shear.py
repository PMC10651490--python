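"""Darcy permeability and interstitial fluid shear stress.

The interstitial space is treated as a porous medium. The Kozeny–Carman
relation gives the Darcy permeability from the extracellular volume
fraction ε, the Kozeny constant K (shape/tortuosity, 4.5–5.5 for
channel-like oriented pores) and an equivalent pore diameter d derived
from the measured cross-sectional area:

    K_p = ε³ d² / (36 K (1 − ε)²)

The shear stress on cell surfaces bounding the pores follows the standard
porous-media estimate

    τ = μ u / sqrt(K_p)

with μ the fluid's dynamic viscosity and u the superficial (Darcy) flow
speed. τ is monotone in every argument, so the extreme values over
parameter ranges are attained at corners of the range cross-product.

Both formulas are exposed as pluggable strategies so an alternative
permeability or shear algebra can be swapped without touching callers.
All computation is in SI units; the range-level interface accepts the
field's customary μm/s, μm² and mPa·s and converts at the boundary.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Callable, Mapping, Sequence

__all__ = [
    "DEFAULT_CONFIG",
    "ShearStressEstimate",
    "ShearStressRange",
    "equivalent_diameter",
    "kozeny_carman_permeability",
    "darcy_shear_stress",
    "shear_stress_point",
    "shear_stress_range",
    "shear_stress_envelope",
]

#: Default biophysical inputs, in interface units.
#: - flow speed during head motion: 2–3 × the 0.2 μm/s sedentary baseline
#: - Kozeny constant for oriented channel-like pores
#: - pore cross-sectional area from the two-photon analysis
#: - extracellular volume fraction of brain tissue (~0.2)
#: - CSF-like interstitial-fluid viscosity at body temperature
DEFAULT_CONFIG: dict = {
    "u_um_per_s": (0.4, 0.6),
    "kozeny": (4.5, 5.5),
    "area_um2": (0.0083, 0.18),
    "epsilon": 0.2,
    "mu_mpa_s": 0.8,
}

KOZENY_DEFAULT_BOUNDS = (4.5, 5.5)


@dataclasses.dataclass
class ShearStressEstimate:
    """A single permeability/shear evaluation with its inputs."""

    kp: float  # Darcy permeability, m²
    tau: float  # shear stress, Pa
    inputs: dict  # provenance: the SI inputs used


@dataclasses.dataclass
class ShearStressRange:
    """Envelope of τ over the cross-product of input ranges."""

    tau_min: float  # Pa
    tau_max: float  # Pa
    corner_min: dict  # SI inputs attaining tau_min
    corner_max: dict  # SI inputs attaining tau_max
    kp_range: tuple[float, float]  # m²


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle with the given cross-sectional area."""
    if area <= 0:
        raise ValueError("area must be positive")
    return math.sqrt(4.0 * area / math.pi)


def kozeny_carman_permeability(epsilon: float, kozeny_k: float, diameter: float) -> float:
    """Darcy permeability K_p = ε³ d² / (36 K (1 − ε)²), in m²."""
    if not (0.0 < epsilon < 1.0):
        raise ValueError("epsilon must lie strictly between 0 and 1")
    if kozeny_k <= 0:
        raise ValueError("kozeny_k must be positive")
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    return epsilon**3 * diameter**2 / (36.0 * kozeny_k * (1.0 - epsilon) ** 2)


def darcy_shear_stress(mu: float, u: float, kp: float) -> float:
    """Shear stress τ = μ u / sqrt(K_p), in Pa (SI inputs)."""
    if mu <= 0 or u <= 0 or kp <= 0:
        raise ValueError("mu, u and kp must all be positive")
    return mu * u / math.sqrt(kp)


PermeabilityFn = Callable[[float, float, float], float]
ShearFn = Callable[[float, float, float], float]


def shear_stress_point(
    u: float,
    mu: float,
    epsilon: float,
    kozeny_k: float,
    area: float,
    permeability_fn: PermeabilityFn = kozeny_carman_permeability,
    shear_fn: ShearFn = darcy_shear_stress,
) -> ShearStressEstimate:
    """Evaluate the permeability/shear chain at one SI parameter point."""
    d = equivalent_diameter(area)
    kp = permeability_fn(epsilon, kozeny_k, d)
    tau = shear_fn(mu, u, kp)
    return ShearStressEstimate(
        kp=kp,
        tau=tau,
        inputs={"u": u, "mu": mu, "epsilon": epsilon, "kozeny_k": kozeny_k,
                "area": area, "diameter": d},
    )


def _as_range(value) -> tuple[float, float]:
    if isinstance(value, (int, float)):
        return float(value), float(value)
    lo, hi = float(value[0]), float(value[1])
    if lo > hi:
        raise ValueError(f"range low {lo} exceeds high {hi}")
    return lo, hi


def shear_stress_range(
    u: float | Sequence[float],
    mu: float | Sequence[float],
    epsilon: float | Sequence[float],
    kozeny_k: float | Sequence[float],
    area: float | Sequence[float],
    permeability_fn: PermeabilityFn = kozeny_carman_permeability,
    shear_fn: ShearFn = darcy_shear_stress,
) -> ShearStressRange:
    """Envelope of τ over all corner combinations of the input ranges.

    τ is monotone in each argument (increasing in μ, u and K; decreasing
    in d and, for ε < 0.5, in ε), so the extremes over the full
    cross-product are attained at corners; all 2⁵ corners are evaluated
    and the attaining ones returned. Inputs are SI (m/s, Pa·s, m²).
    """
    ranges = [_as_range(v) for v in (u, mu, epsilon, kozeny_k, area)]
    best_min = best_max = None
    kps = []
    for corner in itertools.product(*ranges):
        est = shear_stress_point(*corner, permeability_fn=permeability_fn, shear_fn=shear_fn)
        kps.append(est.kp)
        if best_min is None or est.tau < best_min.tau:
            best_min = est
        if best_max is None or est.tau > best_max.tau:
            best_max = est
    return ShearStressRange(
        tau_min=best_min.tau,
        tau_max=best_max.tau,
        corner_min=best_min.inputs,
        corner_max=best_max.inputs,
        kp_range=(min(kps), max(kps)),
    )


def shear_stress_envelope(config: Mapping | None = None, **overrides) -> ShearStressRange:
    """Shear-stress envelope from a config in interface units.

    Config keys (each a scalar or a (low, high) pair):
    ``u_um_per_s`` (μm/s), ``kozeny``, ``area_um2`` (μm²), ``epsilon``,
    ``mu_mpa_s`` (mPa·s). Missing keys fall back to ``DEFAULT_CONFIG``.
    """
    cfg = dict(DEFAULT_CONFIG)
    if config:
        cfg.update(config)
    cfg.update(overrides)
    unknown = set(cfg) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")

    def scale(value, factor):
        lo, hi = _as_range(value)
        return lo * factor, hi * factor

    return shear_stress_range(
        u=scale(cfg["u_um_per_s"], 1e-6),      # μm/s -> m/s
        mu=scale(cfg["mu_mpa_s"], 1e-3),       # mPa·s -> Pa·s
        epsilon=_as_range(cfg["epsilon"]),
        kozeny_k=_as_range(cfg["kozeny"]),
        area=scale(cfg["area_um2"], 1e-12),    # μm² -> m²
    )
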