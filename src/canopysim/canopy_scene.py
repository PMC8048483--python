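"""3D rosette and stand geometry.

An *Arabidopsis* rosette is modelled as a collection of leaves, each a
straight petiole carrying a planar elliptical lamina.  Organ dimensions are
kept in millimetres (the natural scale of rosette organs); all 3D
coordinates are SI metres, z-up, with the soil plane at z = 0 and the plot
centred on the origin.

The module provides planting layouts (uniform grids, row patterns,
competitor interleaving), the central-plant selection used for
edge-exclusion metrics, and scene-level summaries (vertical cover fraction,
leaf area index).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

MM = 1e-3  # metres per millimetre
GOLDEN_ANGLE_DEG = 137.5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LeafOrgan:
    """One petiole + lamina unit.

    Lengths and widths in mm, biomass in mg, angles in degrees.
    ``petiole_angle`` is the elevation of the petiole above the horizontal
    plane; the lamina lies in the plane spanned by the petiole axis and the
    horizontal direction perpendicular to it, so a 90° leaf is vertical.
    """

    rank: int
    age_days: float = 0.0
    petiole_length: float = 0.0
    petiole_angle: float = 30.0
    azimuth: float = 0.0
    lamina_length: float = 0.0
    lamina_width: float = 0.0
    lamina_biomass: float = 0.0
    petiole_biomass: float = 0.0

    def __post_init__(self) -> None:
        if self.rank < 1:
            raise ValueError("leaf rank must be >= 1")
        if not (0.0 <= self.petiole_angle <= 90.0):
            raise ValueError("petiole_angle must lie in [0, 90] degrees")
        self.azimuth = self.azimuth % 360.0

    @property
    def lamina_area_mm2(self) -> float:
        """One-sided lamina area, mm² (ellipse, π·L·W/4)."""
        return math.pi * self.lamina_length * self.lamina_width / 4.0

    def axis_direction(self) -> np.ndarray:
        """Unit vector along the petiole, pointing away from the shoot base."""
        th = math.radians(self.petiole_angle)
        az = math.radians(self.azimuth)
        return np.array(
            [math.cos(th) * math.cos(az), math.cos(th) * math.sin(az), math.sin(th)]
        )

    def tip_point(self, base_xy: Sequence[float]) -> np.ndarray:
        """Distal lamina tip in metres for a plant based at ``base_xy``."""
        d = self.axis_direction()
        base = np.array([base_xy[0], base_xy[1], 0.0])
        return base + d * (self.petiole_length + self.lamina_length) * MM


@dataclass
class PlantState:
    """A rosette: role, phenotype, position and its ordered leaves."""

    id: int
    role: str  # "canopy" | "competitor"
    position: tuple[float, float]
    germination_day: int
    phenotype: object  # SASParams; kept loose to avoid a circular import
    leaves: list[LeafOrgan] = field(default_factory=list)
    carbon_pool: float = 0.0  # mg
    first_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if self.germination_day < 0:
            raise ValueError("germination_day must be >= 0")
        if self.role not in ("canopy", "competitor"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def biomass(self) -> float:
        """Total plant biomass in mg (organs + labile carbon pool)."""
        return sum(l.lamina_biomass + l.petiole_biomass for l in self.leaves) + self.carbon_pool

    @property
    def organ_biomass(self) -> float:
        return sum(l.lamina_biomass + l.petiole_biomass for l in self.leaves)

    def next_leaf_azimuth(self) -> float:
        """Phyllotactic azimuth for the next leaf (golden-angle spiral)."""
        n = len(self.leaves)
        return (self.first_azimuth + n * GOLDEN_ANGLE_DEG) % 360.0


@dataclass
class SceneLayout:
    pattern: str  # "uniform" | "row"
    canopy_positions: np.ndarray  # (n, 2) metres
    competitor_positions: np.ndarray  # (m, 2)
    plot_bounds: tuple[float, float, float, float]  # x0, x1, y0, y1
    density: float  # canopy plants per m²

    @property
    def plot_area(self) -> float:
        x0, x1, y0, y1 = self.plot_bounds
        return (x1 - x0) * (y1 - y0)

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"id": i, "role": "canopy", "x": float(x), "y": float(y)}
            for i, (x, y) in enumerate(self.canopy_positions)
        ]
        n = len(rows)
        rows += [
            {"id": n + i, "role": "competitor", "x": float(x), "y": float(y)}
            for i, (x, y) in enumerate(self.competitor_positions)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


class Scene:
    """A set of plants plus the layout they stand in.

    Provides flattened geometry arrays for the radiation model: every lamina
    becomes a planar ellipse (centre, two in-plane unit axes with semi-axis
    lengths, normal) and every petiole a thin rectangle.
    """

    def __init__(self, plants: Iterable[PlantState], layout: SceneLayout):
        self.plants: list[PlantState] = list(plants)
        self.layout = layout

    # -- geometry flattening -------------------------------------------------

    def geometry(self) -> "SceneGeometry":
        centers, ax1, ax2, a, b, normals = [], [], [], [], [], []
        kinds, plant_idx, leaf_idx = [], [], []
        sensor_c, sensor_n, sensor_plant, sensor_leaf = [], [], [], []
        up = np.array([0.0, 0.0, 1.0])
        for pi, plant in enumerate(self.plants):
            base = np.array([plant.position[0], plant.position[1], 0.0])
            for li, leaf in enumerate(plant.leaves):
                d = leaf.axis_direction()
                h = np.array(
                    [-math.sin(math.radians(leaf.azimuth)),
                     math.cos(math.radians(leaf.azimuth)), 0.0]
                )
                pet_len = leaf.petiole_length * MM
                lam_len = leaf.lamina_length * MM
                lam_w = leaf.lamina_width * MM
                pet_tip = base + d * pet_len
                if pet_len > 0:
                    # petiole as a thin rectangle in the (axis, horizontal) plane
                    centers.append(base + d * (pet_len / 2.0))
                    ax1.append(d)
                    ax2.append(h)
                    a.append(pet_len / 2.0)
                    b.append(0.5 * MM)  # 1 mm wide ribbon
                    n = np.cross(d, h)
                    normals.append(n / np.linalg.norm(n))
                    kinds.append(1)
                    plant_idx.append(pi)
                    leaf_idx.append(li)
                if lam_len > 0 and lam_w > 0:
                    centers.append(pet_tip + d * (lam_len / 2.0))
                    ax1.append(d)
                    ax2.append(h)
                    a.append(lam_len / 2.0)
                    b.append(lam_w / 2.0)
                    n = np.cross(d, h)
                    normals.append(n / np.linalg.norm(n))
                    kinds.append(0)
                    plant_idx.append(pi)
                    leaf_idx.append(li)
                # tip sensor: small non-occluding disc at the distal point
                tip = pet_tip + d * lam_len
                nrm = np.cross(d, h)
                sensor_c.append(tip)
                sensor_n.append(nrm / np.linalg.norm(nrm))
                sensor_plant.append(pi)
                sensor_leaf.append(li)
        if centers:
            geom = SceneGeometry(
                centers=np.array(centers),
                ax1=np.array(ax1),
                ax2=np.array(ax2),
                a=np.array(a),
                b=np.array(b),
                normals=np.array(normals),
                kinds=np.array(kinds, dtype=np.int8),
                plant_idx=np.array(plant_idx, dtype=np.int64),
                leaf_idx=np.array(leaf_idx, dtype=np.int64),
            )
        else:
            geom = SceneGeometry.empty()
        if sensor_c:
            geom.sensor_centers = np.array(sensor_c)
            geom.sensor_normals = np.array(sensor_n)
            geom.sensor_plant = np.array(sensor_plant, dtype=np.int64)
            geom.sensor_leaf = np.array(sensor_leaf, dtype=np.int64)
        return geom

    # -- serialisation -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layout": {
                "pattern": self.layout.pattern,
                "plot_bounds": list(self.layout.plot_bounds),
                "density": self.layout.density,
            },
            "plants": [
                {
                    "id": p.id,
                    "role": p.role,
                    "position": list(p.position),
                    "germination_day": p.germination_day,
                    "carbon_pool": p.carbon_pool,
                    "leaves": [
                        {
                            "rank": l.rank,
                            "age_days": l.age_days,
                            "petiole_length": l.petiole_length,
                            "petiole_angle": l.petiole_angle,
                            "azimuth": l.azimuth,
                            "lamina_length": l.lamina_length,
                            "lamina_width": l.lamina_width,
                            "lamina_biomass": l.lamina_biomass,
                            "petiole_biomass": l.petiole_biomass,
                        }
                        for l in p.leaves
                    ],
                }
                for p in self.plants
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class SceneGeometry:
    """Flattened primitive arrays consumed by the radiation model."""

    centers: np.ndarray  # (N, 3)
    ax1: np.ndarray  # (N, 3) unit, in-plane
    ax2: np.ndarray  # (N, 3) unit, in-plane
    a: np.ndarray  # (N,) semi-axis along ax1, m
    b: np.ndarray  # (N,) semi-axis along ax2, m
    normals: np.ndarray  # (N, 3) unit
    kinds: np.ndarray  # 0 = lamina ellipse, 1 = petiole rectangle
    plant_idx: np.ndarray
    leaf_idx: np.ndarray
    sensor_centers: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    sensor_normals: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    sensor_plant: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    sensor_leaf: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))

    @classmethod
    def empty(cls) -> "SceneGeometry":
        z3 = np.zeros((0, 3))
        z = np.zeros(0)
        return cls(z3, z3.copy(), z3.copy(), z, z.copy(), z3.copy(),
                   np.zeros(0, dtype=np.int8), np.zeros(0, dtype=np.int64),
                   np.zeros(0, dtype=np.int64))

    @property
    def n_primitives(self) -> int:
        return len(self.a)

    @property
    def z_max(self) -> float:
        if self.n_primitives == 0 and len(self.sensor_centers) == 0:
            return 0.0
        zs = [0.0]
        if self.n_primitives:
            zs.append(float((self.centers[:, 2] + self.a + self.b).max()))
        if len(self.sensor_centers):
            zs.append(float(self.sensor_centers[:, 2].max()))
        return max(zs)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_rosette(phenotype, germination_day: int, position: tuple[float, float],
                  plant_id: int = 0, role: str = "canopy",
                  first_azimuth: float = 0.0) -> PlantState:
    """A freshly sown plant: no leaves, empty carbon pool."""
    if germination_day < 0:
        raise ValueError("germination_day must be >= 0")
    return PlantState(
        id=plant_id, role=role, position=tuple(position),
        germination_day=int(germination_day), phenotype=phenotype,
        first_azimuth=float(first_azimuth) % 360.0,
    )


def lamina_mesh(leaf: LeafOrgan, base_xy: Sequence[float], refinement: int = 32) -> np.ndarray:
    """Polygonal approximation of the lamina ellipse, (k, 3) vertices in metres.

    Returns an empty (0, 3) array for a zero-dimension lamina.  The polygon
    area converges to π·L·W/4 (in m²) as ``refinement`` grows.
    """
    if refinement < 3:
        raise ValueError("refinement must be >= 3")
    if leaf.lamina_length <= 0 or leaf.lamina_width <= 0:
        return np.zeros((0, 3))
    d = leaf.axis_direction()
    h = np.array([-math.sin(math.radians(leaf.azimuth)),
                  math.cos(math.radians(leaf.azimuth)), 0.0])
    base = np.array([base_xy[0], base_xy[1], 0.0])
    center = base + d * (leaf.petiole_length + leaf.lamina_length / 2.0) * MM
    t = np.linspace(0.0, 2.0 * math.pi, refinement, endpoint=False)
    pts = (center[None, :]
           + np.cos(t)[:, None] * d[None, :] * (leaf.lamina_length / 2.0 * MM)
           + np.sin(t)[:, None] * h[None, :] * (leaf.lamina_width / 2.0 * MM))
    return pts


def polygon_area_3d(vertices: np.ndarray) -> float:
    """Area of a planar polygon given its 3D vertices."""
    if len(vertices) < 3:
        return 0.0
    v0 = vertices[0]
    cross = np.zeros(3)
    for i in range(1, len(vertices) - 1):
        cross += np.cross(vertices[i] - v0, vertices[i + 1] - v0)
    return float(np.linalg.norm(cross)) / 2.0


def uniform_grid(nx: int, ny: int, spacing: float) -> SceneLayout:
    """Centered rectangular grid; density over the (nx·s)×(ny·s) footprint."""
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    xs = (np.arange(nx) - (nx - 1) / 2.0) * spacing
    ys = (np.arange(ny) - (ny - 1) / 2.0) * spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    half_x, half_y = nx * spacing / 2.0, ny * spacing / 2.0
    density = (nx * ny) / (nx * spacing * ny * spacing)
    return SceneLayout(
        pattern="uniform",
        canopy_positions=pos,
        competitor_positions=np.zeros((0, 2)),
        plot_bounds=(-half_x, half_x, -half_y, half_y),
        density=density,
    )


def row_layout(n_rows: int, row_spacing: float, within_spacing: float,
               plants_per_row: int) -> SceneLayout:
    """Parallel rows (rows run along y, spaced along x)."""
    if row_spacing <= 0 or within_spacing <= 0:
        raise ValueError("row and within-row spacings must be positive")
    if n_rows < 1 or plants_per_row < 1:
        raise ValueError("need at least one row and one plant per row")
    xs = (np.arange(n_rows) - (n_rows - 1) / 2.0) * row_spacing
    ys = (np.arange(plants_per_row) - (plants_per_row - 1) / 2.0) * within_spacing
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pos = np.column_stack([gx.ravel(), gy.ravel()])
    half_x = n_rows * row_spacing / 2.0
    half_y = plants_per_row * within_spacing / 2.0
    density = (n_rows * plants_per_row) / (4.0 * half_x * half_y)
    return SceneLayout(
        pattern="row",
        canopy_positions=pos,
        competitor_positions=np.zeros((0, 2)),
        plot_bounds=(-half_x, half_x, -half_y, half_y),
        density=density,
    )


def interleave_competitors(layout: SceneLayout, n: int) -> SceneLayout:
    """Place ``n`` competitors at between-plant cell centres, symmetric about
    the plot centre (a centred √n×√n block for square ``n``)."""
    if n == 0:
        return layout
    pos = layout.canopy_positions
    xs = np.unique(np.round(pos[:, 0], 12))
    ys = np.unique(np.round(pos[:, 1], 12))
    if len(xs) < 2 or len(ys) < 2:
        raise ValueError("layout has no interior inter-plant gaps")
    cx = (xs[:-1] + xs[1:]) / 2.0  # cell centres between canopy columns
    cy = (ys[:-1] + ys[1:]) / 2.0
    k = int(round(math.sqrt(n)))
    if k * k != n:
        raise ValueError("competitor count must be a perfect square for the "
                         "centred-block placement")
    if k > len(cx) or k > len(cy):
        raise ValueError(f"cannot place {n} competitors: not enough interior gaps")

    def central(vals: np.ndarray, k: int) -> np.ndarray:
        # symmetric, evenly spaced selection about the plot centre
        vals = np.sort(vals)
        has_zero = np.any(np.isclose(vals, 0.0))
        pos = np.sort(vals[vals > 1e-15])
        if has_zero:
            if k % 2 == 1:  # centre cell plus even-multiple pairs
                pairs = pos[1::2][: (k - 1) // 2]
                sel = np.concatenate([[0.0], pairs, -pairs])
            else:  # odd-multiple pairs, uniform competitor spacing
                pairs = pos[0::2][: k // 2]
                sel = np.concatenate([pairs, -pairs])
        else:  # cell centres at half-multiples: innermost pairs are uniform
            if k % 2 == 1:
                raise ValueError("odd competitor row count needs a centre cell")
            pairs = pos[: k // 2]
            sel = np.concatenate([pairs, -pairs])
        if len(sel) != k:
            raise ValueError(f"cannot place {k}×{k} competitors symmetrically")
        return np.sort(sel)

    sel_x = central(cx, k)
    sel_y = central(cy, k)
    gx, gy = np.meshgrid(sel_x, sel_y, indexing="ij")
    comp = np.column_stack([gx.ravel(), gy.ravel()])
    return SceneLayout(
        pattern=layout.pattern,
        canopy_positions=layout.canopy_positions,
        competitor_positions=comp,
        plot_bounds=layout.plot_bounds,
        density=layout.density,
    )


def central_selection(positions: np.ndarray, k: int) -> np.ndarray:
    """Indices of the ``k`` positions nearest the centroid of all positions.

    Ties broken by (x, y) lexicographic order; deterministic.
    """
    positions = np.asarray(positions, dtype=float)
    if k > len(positions):
        raise ValueError("k exceeds the number of available plants")
    centroid = positions.mean(axis=0)
    d = np.linalg.norm(positions - centroid, axis=1)
    order = np.lexsort((positions[:, 1], positions[:, 0], np.round(d, 12)))
    return np.sort(order[:k])


def _projected_ellipses(geom: SceneGeometry):
    """2×2 maps from the unit disc to each lamina's vertical (x-y) projection."""
    lam = geom.kinds == 0
    c = geom.centers[lam][:, :2]
    m1 = geom.ax1[lam][:, :2] * geom.a[lam][:, None]
    m2 = geom.ax2[lam][:, :2] * geom.b[lam][:, None]
    return c, m1, m2


def vertical_cover_fraction(scene: Scene, region: tuple[float, float, float, float],
                            resolution: int = 200) -> float:
    """Fraction of a rectangular ground region covered by the vertical
    projection of any lamina, on a resolution×resolution point grid."""
    x0, x1, y0, y1 = region
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    if x1 <= x0 or y1 <= y0:
        raise ValueError("empty region")
    geom = scene.geometry()
    if geom.n_primitives == 0:
        return 0.0
    xs = x0 + (np.arange(resolution) + 0.5) * (x1 - x0) / resolution
    ys = y0 + (np.arange(resolution) + 0.5) * (y1 - y0) / resolution
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    covered = np.zeros(len(pts), dtype=bool)
    c, m1, m2 = _projected_ellipses(geom)
    for ci, a1, a2 in zip(c, m1, m2):
        det = a1[0] * a2[1] - a1[1] * a2[0]
        if abs(det) < 1e-18:  # edge-on lamina: measure-zero projection
            continue
        rel = pts[~covered] - ci
        s = (a2[1] * rel[:, 0] - a2[0] * rel[:, 1]) / det
        u = (-a1[1] * rel[:, 0] + a1[0] * rel[:, 1]) / det
        inside = s * s + u * u <= 1.0
        idx = np.flatnonzero(~covered)
        covered[idx[inside]] = True
    return float(covered.mean())


def leaf_area_index(scene: Scene, region: tuple[float, float, float, float]) -> float:
    """One-sided lamina area of plants based inside ``region`` per region area."""
    x0, x1, y0, y1 = region
    area = (x1 - x0) * (y1 - y0)
    if area <= 0:
        raise ValueError("region area must be positive")
    total = 0.0
    for p in scene.plants:
        x, y = p.position
        if x0 <= x <= x1 and y0 <= y <= y1:
            total += sum(l.lamina_area_mm2 for l in p.leaves) * MM * MM
    return total / area
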