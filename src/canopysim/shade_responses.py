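"""Neighbour-detection signals and shade-avoidance response rules.

A leaf senses neighbours through two channels: physical touching of laminas
belonging to different plants, and a low red:far-red ratio (R:FR < 0.5 by
default) at its lamina tip.  Either signal triggers the shade-avoidance
syndrome (SAS) for that leaf on that day: a fixed hyponastic angle
increment (capped at a maximum leaf angle) and accelerated petiole
elongation.  Hyponasty is irreversible here — angles never relax.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .canopy_scene import MM, Scene
from .radiation import RadiationResult, tip_r_fr_all


@dataclass
class SASParams:
    """Shade-avoidance phenotype of a plant.

    hyponasty_rate in degrees per triggered day, capped at ``max_angle``;
    ``elongation_multiplier`` is the fractional extra petiole elongation per
    unit allocated biomass while triggered (0 = no response).
    """

    r_fr_threshold: float = 0.5
    hyponasty_rate: float = 5.0
    max_angle: float = 80.0
    elongation_multiplier: float = 0.5
    touch_enabled: bool = True

    def __post_init__(self) -> None:
        if self.hyponasty_rate < 0:
            raise ValueError("hyponasty_rate must be >= 0")
        if not (0 < self.max_angle <= 90):
            raise ValueError("max_angle must lie in (0, 90] degrees")
        if self.elongation_multiplier < 0:
            raise ValueError("elongation_multiplier must be >= 0")


#: Phenotype presets: the canopy rate is set per simulation run; weak-SAS
#: competitors cannot move their leaves and elongate slowly, strong-SAS
#: competitors respond like a vigorous canopy plant at 16°/day.
PRESETS: dict[str, SASParams] = {
    "canopy": SASParams(hyponasty_rate=5.0, elongation_multiplier=0.5),
    "weak_sas_competitor": SASParams(hyponasty_rate=0.0, elongation_multiplier=0.15),
    "strong_sas_competitor": SASParams(hyponasty_rate=16.0, elongation_multiplier=0.5),
}


def phenotype_preset(name: str, hyponasty_rate: float | None = None) -> SASParams:
    base = PRESETS[name]
    rate = base.hyponasty_rate if hyponasty_rate is None else hyponasty_rate
    return SASParams(
        r_fr_threshold=base.r_fr_threshold,
        hyponasty_rate=rate,
        max_angle=base.max_angle,
        elongation_multiplier=base.elongation_multiplier,
        touch_enabled=base.touch_enabled,
    )


@dataclass
class SignalState:
    """Per-leaf neighbour signals for one day, keyed (plant_index, leaf_index)."""

    touched: dict[tuple[int, int], bool] = field(default_factory=dict)
    tip_r_fr: dict[tuple[int, int], float] = field(default_factory=dict)
    triggered: dict[tuple[int, int], bool] = field(default_factory=dict)
    low_confidence: list[tuple[int, int]] = field(default_factory=list)

    def is_triggered(self, plant_index: int, leaf_index: int) -> bool:
        return self.triggered.get((plant_index, leaf_index), False)


# ---------------------------------------------------------------------------
# touch detection
# ---------------------------------------------------------------------------

def _lamina_samples(scene: Scene, n_boundary: int = 16):
    """Sample points on every lamina (boundary ring + interior cross) for
    approximate polygon-to-polygon distance tests."""
    geom = scene.geometry()
    lam = geom.kinds == 0
    centers = geom.centers[lam]
    ax1, ax2 = geom.ax1[lam], geom.ax2[lam]
    a, b = geom.a[lam], geom.b[lam]
    plants = geom.plant_idx[lam]
    leaves = geom.leaf_idx[lam]
    t = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    ring = np.column_stack([np.cos(t), np.sin(t)])
    interior = np.array([[0.0, 0.0], [0.5, 0.0], [-0.5, 0.0], [0.0, 0.5],
                         [0.0, -0.5], [0.35, 0.35], [-0.35, 0.35],
                         [0.35, -0.35], [-0.35, -0.35]])
    unit = np.vstack([ring, interior])  # (S, 2) on the unit disc
    pts = (centers[:, None, :]
           + unit[None, :, 0:1] * ax1[:, None, :] * a[:, None, None]
           + unit[None, :, 1:2] * ax2[:, None, :] * b[:, None, None])
    radius = np.maximum(a, b)
    return pts, centers, radius, plants, leaves


def detect_touch(scene: Scene, tolerance: float = 2.0,
                 include_same_plant: bool = False) -> dict[tuple[int, int], bool]:
    """Per-leaf booleans: lamina within ``tolerance`` mm of another plant's
    lamina in 3D.  Symmetric by construction.

    Distances are evaluated between dense point samples of each lamina, an
    approximation accurate to roughly the sample spacing (well below leaf
    scale for rosette organs).
    """
    tol_m = tolerance * MM
    pts, centers, radius, plants, leaves = _lamina_samples(scene)
    n = len(centers)
    touched = {(int(p), int(l)): False for p, l in zip(plants, leaves)}
    if n < 2:
        return touched
    # bounding-sphere prefilter
    dc = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    limit = radius[:, None] + radius[None, :] + tol_m
    cand = np.triu(dc <= limit, k=1)
    if not include_same_plant:
        cand &= plants[:, None] != plants[None, :]
    for i, j in zip(*np.nonzero(cand)):
        ki = (int(plants[i]), int(leaves[i]))
        kj = (int(plants[j]), int(leaves[j]))
        if touched[ki] and touched[kj]:
            continue
        d2 = np.sum((pts[i][:, None, :] - pts[j][None, :, :]) ** 2, axis=2)
        if d2.min() <= tol_m * tol_m:
            touched[ki] = True
            touched[kj] = True
    return touched


# ---------------------------------------------------------------------------
# signal evaluation and responses
# ---------------------------------------------------------------------------

def evaluate_signals(scene: Scene, radiation: RadiationResult, sas_of_plant,
                     day: int | None = None, touch_tolerance: float = 2.0,
                     min_sensor_hits: int = 5) -> SignalState:
    """Combine touch and tip R:FR into the per-leaf trigger state.

    ``sas_of_plant`` maps a plant index to its :class:`SASParams`.  A leaf is
    triggered iff it is touched (when the phenotype has touch sensing) or
    its tip R:FR is below the phenotype threshold — strictly below, so a
    ratio exactly at the threshold does not trigger.  Tip sensors crossed by
    too few rays are treated as not-triggered and flagged low-confidence.
    """
    state = SignalState()
    any_touch_enabled = any(
        sas_of_plant(pi).touch_enabled for pi in range(len(scene.plants))
    )
    touched = (detect_touch(scene, tolerance=touch_tolerance)
               if any_touch_enabled else {})
    ratios = tip_r_fr_all(radiation)
    for si, (pi, li) in enumerate(zip(radiation.sensor_plant, radiation.sensor_leaf)):
        key = (int(pi), int(li))
        sas = sas_of_plant(int(pi))
        ratio = float(ratios[si])
        confident = radiation.tip_hits[si] >= min_sensor_hits
        if not confident:
            state.low_confidence.append(key)
        is_touched = bool(touched.get(key, False)) and sas.touch_enabled
        low_rfr = confident and (ratio < sas.r_fr_threshold)
        state.touched[key] = is_touched
        state.tip_r_fr[key] = ratio
        state.triggered[key] = is_touched or low_rfr
    return state


def update_hyponasty(current_angle: float, triggered: bool, sas: SASParams) -> float:
    """New petiole elevation after one day: one rate increment if triggered,
    hard-capped at ``max_angle``; never decreases."""
    if not triggered:
        return current_angle
    return min(current_angle + sas.hyponasty_rate, sas.max_angle)


def elongation_signal(triggered: bool, sas: SASParams) -> float:
    """Petiole elongation multiplier for the growth step (1 = baseline)."""
    return 1.0 + sas.elongation_multiplier if triggered else 1.0


def control_phenotype() -> SASParams:
    """A phenotype with all neighbour responses disabled."""
    return SASParams(r_fr_threshold=0.0, hyponasty_rate=0.0,
                     elongation_multiplier=0.0, touch_enabled=False)
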