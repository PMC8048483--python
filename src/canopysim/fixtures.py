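"""Deterministic micro-scenes with hand-computable expectations.

These fixtures are the no-data test surface: every expectation is either an
exact identity (source calibration, geometry arithmetic) or the output of a
stated brute-force oracle (exhaustive vertical ray casting, closed-form
layer transmission with interreflections).  They are generated
programmatically — nothing is checked in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import canopy_scene as cs
from .canopy_scene import MM, LeafOrgan, Scene, SceneGeometry, SceneLayout
from .radiation import OpticalProps, SoilTileGrid
from .shade_responses import SASParams

FIXTURE_NAMES = ("empty_scene", "single_leaf", "overlapping_pair",
                 "two_layer_rfr", "mini_canopy_2x2", "saturating_hyponasty")


@dataclass
class FixtureCase:
    """A named scene/config plus a map metric → (value, tolerance, provenance)."""

    name: str
    scene: object
    expected: dict[str, tuple[float, float, str]]
    extra: dict = field(default_factory=dict)


class PrimitiveScene:
    """A scene defined directly by horizontal/tilted elliptical patches and
    free-standing tip sensors, bypassing plant bookkeeping.

    Used for analytic layer fixtures (e.g. a lamina layer held at a given
    height) that a rooted rosette cannot realise.  Duck-types the parts of
    :class:`~canopysim.canopy_scene.Scene` the radiation model consumes.
    """

    def __init__(self, layout: SceneLayout):
        self.layout = layout
        self.plants: list = []
        self._centers: list = []
        self._ax1: list = []
        self._ax2: list = []
        self._a: list = []
        self._b: list = []
        self._kinds: list = []
        self._sensors: list = []

    def add_horizontal_ellipse(self, center_xy, z: float, semi_x: float,
                               semi_y: float) -> None:
        self._centers.append([center_xy[0], center_xy[1], z])
        self._ax1.append([1.0, 0.0, 0.0])
        self._ax2.append([0.0, 1.0, 0.0])
        self._a.append(semi_x)
        self._b.append(semi_y)
        self._kinds.append(0)

    def add_horizontal_rect(self, center_xy, z: float, half_x: float,
                            half_y: float) -> None:
        """An opaque-black rectangle (petiole-type primitive) — handy for
        exact occlusion tests."""
        self._centers.append([center_xy[0], center_xy[1], z])
        self._ax1.append([1.0, 0.0, 0.0])
        self._ax2.append([0.0, 1.0, 0.0])
        self._a.append(half_x)
        self._b.append(half_y)
        self._kinds.append(1)

    def add_sensor(self, position, normal=(0.0, 0.0, 1.0)) -> None:
        self._sensors.append((np.array(position, dtype=float),
                              np.array(normal, dtype=float)))

    def geometry(self) -> SceneGeometry:
        n = len(self._a)
        if n:
            geom = SceneGeometry(
                centers=np.array(self._centers),
                ax1=np.array(self._ax1),
                ax2=np.array(self._ax2),
                a=np.array(self._a),
                b=np.array(self._b),
                normals=np.tile([0.0, 0.0, 1.0], (n, 1)),
                kinds=np.array(self._kinds, dtype=np.int8),
                plant_idx=np.arange(n, dtype=np.int64),
                leaf_idx=np.zeros(n, dtype=np.int64),
            )
        else:
            geom = SceneGeometry.empty()
        if self._sensors:
            geom.sensor_centers = np.array([s[0] for s in self._sensors])
            geom.sensor_normals = np.array([s[1] for s in self._sensors])
            geom.sensor_plant = np.arange(len(self._sensors), dtype=np.int64)
            geom.sensor_leaf = np.zeros(len(self._sensors), dtype=np.int64)
        return geom


def _small_layout(half: float = 0.05) -> SceneLayout:
    return SceneLayout(pattern="uniform",
                       canopy_positions=np.zeros((0, 2)),
                       competitor_positions=np.zeros((0, 2)),
                       plot_bounds=(-half, half, -half, half),
                       density=0.0)


def _rosette_with_leaf(position, lamina_length_mm, lamina_width_mm,
                       petiole_length_mm=0.0, angle=0.0, azimuth=0.0,
                       plant_id=0):
    sas = SASParams(hyponasty_rate=0.0, elongation_multiplier=0.0)
    plant = cs.build_rosette(sas, 0, position, plant_id=plant_id)
    plant.leaves.append(LeafOrgan(
        rank=1, petiole_length=petiole_length_mm, petiole_angle=angle,
        azimuth=azimuth, lamina_length=lamina_length_mm,
        lamina_width=lamina_width_mm,
        lamina_biomass=1.0, petiole_biomass=0.1 if petiole_length_mm else 0.0))
    return plant


def layer_transmission(tau: float, rho: float, n_layers: int) -> float:
    """Downward transmission through ``n_layers`` infinite horizontal layers
    including all interreflection orders (transfer-matrix recursion)."""
    T, R = 1.0, 0.0  # transmission and top-reflectance of the stack so far
    for _ in range(n_layers):
        denom = 1.0 - R * rho
        T, R = T * tau / denom, rho + tau * tau * R / denom
    return T


def make_fixture(name: str, source_par: float = 220.0, r_fr: float = 2.3
                 ) -> FixtureCase:
    optics = OpticalProps()
    if name == "empty_scene":
        scene = PrimitiveScene(_small_layout())
        scene.add_sensor((0.0, 0.0, 0.01))  # bare sensor in open air
        return FixtureCase(name, scene, {
            "soil_par": (source_par, 0.0, "source calibration identity"),
            "tip_r_fr": (r_fr, 0.0, "source R:FR identity"),
        })
    if name == "single_leaf":
        layout = _small_layout()
        plant = _rosette_with_leaf((-0.01, 0.0), 20.0, 10.0)
        scene = Scene([plant], layout)
        region = layout.plot_bounds
        area_ratio = (math.pi * 20.0 * 10.0 / 4.0) * MM * MM / layout.plot_area
        return FixtureCase(name, scene, {
            "cover": (area_ratio, 0.0, "ellipse area / region area"),
            "lamina_area_mm2": (157.07963, 1e-3, "π·20·10/4"),
        }, extra={"region": region})
    if name == "overlapping_pair":
        layout = _small_layout()
        a = _rosette_with_leaf((-0.005, 0.0), 20.0, 10.0, azimuth=0.0, plant_id=0)
        b = _rosette_with_leaf((0.005, 0.0), 20.0, 10.0, azimuth=180.0, plant_id=1)
        scene = Scene([a, b], layout)
        return FixtureCase(name, scene, {
            "touched_leaves": (2.0, 0.0, "x-y overlap at equal height"),
        })
    if name == "two_layer_rfr":
        layout = _small_layout(half=0.025)
        scene = PrimitiveScene(layout)
        for z in (0.02, 0.04):
            scene.add_horizontal_ellipse((0.0, 0.0), z, 0.1, 0.1)
        scene.add_sensor((0.0, 0.0, 0.005))
        t_r = layer_transmission(optics.r.transmittance, optics.r.reflectance, 2)
        t_fr = layer_transmission(optics.fr.transmittance, optics.fr.reflectance, 2)
        expected_ratio = r_fr * t_r / t_fr
        return FixtureCase(name, scene, {
            "tip_r_fr": (expected_ratio, 0.0,
                         "closed-form two-layer transmission with interreflections"),
        })
    if name == "mini_canopy_2x2":
        spacing = 0.025
        layout = cs.uniform_grid(2, 2, spacing)
        # lamina reach (petiole+lamina lengths) just above half the spacing
        reach_mm = spacing / 2.0 / MM + 2.0
        plants = []
        for i, (x, y) in enumerate(layout.canopy_positions):
            az = 0.0 if x < 0 else 180.0  # each leaf faces its row neighbour
            plants.append(_rosette_with_leaf((x, y), reach_mm * 0.7, reach_mm * 0.35,
                                             petiole_length_mm=reach_mm * 0.3,
                                             azimuth=az, plant_id=i))
        scene = Scene(plants, layout)
        return FixtureCase(name, scene, {
            "touched_leaves": (4.0, 0.0,
                               "lamina reach exceeds half the plant spacing"),
        })
    if name == "saturating_hyponasty":
        sas = SASParams(hyponasty_rate=10.0)
        theta0 = 30.0
        days_to_cap = math.ceil((sas.max_angle - theta0) / sas.hyponasty_rate)
        return FixtureCase(name, None, {
            "days_to_cap": (float(days_to_cap), 0.0, "⌈(80−θ₀)/rate⌉"),
            "final_angle": (sas.max_angle, 0.0, "hard cap"),
        }, extra={"theta0": theta0, "sas": sas})
    raise ValueError(f"unknown fixture {name!r}")


def all_fixtures() -> list[FixtureCase]:
    return [make_fixture(n) for n in FIXTURE_NAMES]


def fixtures_to_json() -> dict:
    out = {}
    for case in all_fixtures():
        out[case.name] = {
            metric: {"value": v, "tolerance": tol, "provenance": prov}
            for metric, (v, tol, prov) in case.expected.items()
        }
    return out


# ---------------------------------------------------------------------------
# brute-force vertical-ray oracle
# ---------------------------------------------------------------------------

def brute_force_light_oracle(scene, tiles: SoilTileGrid, par: float = 220.0,
                             resolution: int = 40) -> np.ndarray:
    """Exhaustive vertical ray casting with exact ellipse intersection.

    Assumes opaque (fully absorbing) laminas and a vertical collimated
    source: each soil tile's PAR equals ``par`` times its uncovered area
    fraction, evaluated on a resolution×resolution subgrid per tile.
    Independent of the Monte-Carlo tracer; used to validate it to 3σ.
    """
    geom = scene.geometry()
    centers = geom.centers[:, :2]
    m1 = geom.ax1[:, :2] * geom.a[:, None]
    m2 = geom.ax2[:, :2] * geom.b[:, None]
    kinds = geom.kinds
    x0, x1, y0, y1 = tiles.region
    out = np.zeros(tiles.n_tiles)
    dx = (x1 - x0) / tiles.nx
    dy = (y1 - y0) / tiles.ny
    for ix in range(tiles.nx):
        for iy in range(tiles.ny):
            xs = x0 + ix * dx + (np.arange(resolution) + 0.5) * dx / resolution
            ys = y0 + iy * dy + (np.arange(resolution) + 0.5) * dy / resolution
            gx, gy = np.meshgrid(xs, ys, indexing="ij")
            pts = np.column_stack([gx.ravel(), gy.ravel()])
            covered = np.zeros(len(pts), dtype=bool)
            for ci, a1, a2, kind in zip(centers, m1, m2, kinds):
                det = a1[0] * a2[1] - a1[1] * a2[0]
                if abs(det) < 1e-18:
                    continue
                rel = pts - ci
                s = (a2[1] * rel[:, 0] - a2[0] * rel[:, 1]) / det
                u = (-a1[1] * rel[:, 0] + a1[0] * rel[:, 1]) / det
                if kind == 0:
                    covered |= s * s + u * u <= 1.0
                else:  # opaque petiole ribbon: rectangle in local coords
                    covered |= (np.abs(s) <= 1.0) & (np.abs(u) <= 1.0)
            out[ix * tiles.ny + iy] = par * (1.0 - covered.mean())
    return out
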