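"""Monte-Carlo multi-band light transport over a rosette canopy.

Three bands are transported with shared ray paths and per-band weights:
PAR (photosynthetic flux driving growth), and red (R) / far-red (FR) used
only for the neighbour-detection signal.  Leaves absorb most R but scatter
most FR, so the R:FR ratio sampled at lamina-tip sensors drops under and
beside foliage — the phytochrome shade cue.

The domain is laterally periodic over the plot footprint (a torus), the
standard device for simulating the interior of a larger canopy: rays
leaving one side re-enter on the opposite side, so an empty scene returns
exactly the source flux at the soil and energy accounting closes without a
side-leakage term.

Scattering is handled with per-band importance weights on a single sampled
path: at each lamina hit, each band deposits its absorbed fraction, the ray
continues as a Lambertian reflection or transmission (chosen 50:50) and the
band weights are re-scaled by the band's reflectance or transmittance.
Termination is by unbiased Russian roulette below a relative-weight
threshold, which keeps the per-band energy balance exact in expectation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .canopy_scene import Scene, SceneGeometry, SceneLayout

logger = logging.getLogger(__name__)

BANDS = ("par", "r", "fr")
_EPS_T = 1e-7  # minimum travel before the next interaction, m


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class LightSourceSpec:
    """Diffuse overhead light source.

    ``par_intensity`` is the PAR flux (µmol m⁻² s⁻¹) through an unobstructed
    horizontal plane; ``r_fr_ratio`` the red:far-red ratio of the incident
    light.  ``angular_model`` is one of ``overcast-diffuse`` (cosine-weighted
    hemisphere, the default growth-chamber-like sky), ``uniform-hemisphere``
    or ``vertical`` (collimated downward, used for analytic tests).
    """

    par_intensity: float = 220.0
    r_fr_ratio: float = 2.3
    angular_model: str = "overcast-diffuse"
    n_rays: int = 20_000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.par_intensity <= 0 or self.r_fr_ratio <= 0:
            raise ValueError("par_intensity and r_fr_ratio must be positive")
        if self.angular_model not in ("overcast-diffuse", "uniform-hemisphere", "vertical"):
            raise ValueError(f"unknown angular model {self.angular_model!r}")
        if self.n_rays < 1:
            raise ValueError("n_rays must be >= 1")


@dataclass
class BandOptics:
    absorptance: float
    reflectance: float
    transmittance: float

    def __post_init__(self) -> None:
        vals = (self.absorptance, self.reflectance, self.transmittance)
        if any(v < 0 or v > 1 for v in vals):
            raise ValueError("optical coefficients must lie in [0, 1]")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ValueError("absorptance + reflectance + transmittance must equal 1")


@dataclass
class OpticalProps:
    """Per-band lamina optics; petioles are opaque black in every band.

    Defaults give strong red depletion and far-red scattering, typical of
    green leaves, so the R:FR shade trigger is reachable under one to two
    leaf layers.
    """

    par: BandOptics = field(default_factory=lambda: BandOptics(0.85, 0.075, 0.075))
    r: BandOptics = field(default_factory=lambda: BandOptics(0.90, 0.05, 0.05))
    fr: BandOptics = field(default_factory=lambda: BandOptics(0.10, 0.45, 0.45))

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        bands = (self.par, self.r, self.fr)
        return (np.array([b.absorptance for b in bands]),
                np.array([b.reflectance for b in bands]),
                np.array([b.transmittance for b in bands]))


@dataclass
class SoilTileGrid:
    """Non-overlapping rectangular tiles covering a declared soil region."""

    region: tuple[float, float, float, float]  # x0, x1, y0, y1 (m)
    nx: int
    ny: int

    def __post_init__(self) -> None:
        x0, x1, y0, y1 = self.region
        if x1 <= x0 or y1 <= y0 or self.nx < 1 or self.ny < 1:
            raise ValueError("degenerate soil-tile grid")

    @property
    def tile_area(self) -> float:
        x0, x1, y0, y1 = self.region
        return (x1 - x0) * (y1 - y0) / (self.nx * self.ny)

    @property
    def n_tiles(self) -> int:
        return self.nx * self.ny

    @classmethod
    def central(cls, layout: SceneLayout, k: int = 16, nx: int = 8, ny: int = 8
                ) -> "SoilTileGrid":
        """Tiles under the central ``k`` canopy plants (their Voronoi-like
        footprint on the plant grid); with the default 10×10 / 2.5 cm layout
        and k=16 this is the 10 cm × 10 cm (100 cm²) central region."""
        from .canopy_scene import central_selection

        idx = central_selection(layout.canopy_positions, k)
        pos = layout.canopy_positions[idx]
        xs = np.unique(np.round(layout.canopy_positions[:, 0], 12))
        spacing = float(np.min(np.diff(xs))) if len(xs) > 1 else 0.025
        x0, x1 = pos[:, 0].min() - spacing / 2, pos[:, 0].max() + spacing / 2
        y0, y1 = pos[:, 1].min() - spacing / 2, pos[:, 1].max() + spacing / 2
        return cls(region=(x0, x1, y0, y1), nx=nx, ny=ny)


@dataclass
class RadiationResult:
    """Per-organ absorbed PAR, per-tile soil PAR and per-leaf tip R:FR for
    one time step, plus per-band energy-balance totals."""

    absorbed_par: np.ndarray          # per primitive, µmol s⁻¹
    prim_plant: np.ndarray
    prim_leaf: np.ndarray
    soil_tile_par: np.ndarray         # (nx*ny,) µmol m⁻² s⁻¹
    tiles: SoilTileGrid | None
    tip_r: np.ndarray                 # per sensor, band-weight tallies
    tip_fr: np.ndarray
    tip_hits: np.ndarray
    sensor_plant: np.ndarray
    sensor_leaf: np.ndarray
    emitted: np.ndarray               # per band totals (µmol s⁻¹ for PAR)
    absorbed: np.ndarray
    soil: np.ndarray
    escaped: np.ndarray
    n_rays: int
    n_degenerate_skipped: int = 0

    def absorbed_par_per_plant(self, n_plants: int) -> np.ndarray:
        out = np.zeros(n_plants)
        if len(self.absorbed_par):
            np.add.at(out, self.prim_plant, self.absorbed_par)
        return out

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [
            {"record": "organ", "plant": int(p), "leaf": int(l), "value": float(v)}
            for p, l, v in zip(self.prim_plant, self.prim_leaf, self.absorbed_par)
        ]
        rows += [
            {"record": "tile", "plant": -1, "leaf": int(i), "value": float(v)}
            for i, v in enumerate(self.soil_tile_par)
        ]
        ratios = tip_r_fr_all(self)
        rows += [
            {"record": "tip_r_fr", "plant": int(p), "leaf": int(l), "value": float(r)}
            for p, l, r in zip(self.sensor_plant, self.sensor_leaf, ratios)
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------

def _lambertian(normals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Cosine-weighted directions about each (unit) normal."""
    n = len(normals)
    u1 = rng.random(n)
    u2 = rng.random(n)
    r = np.sqrt(u1)
    phi = 2.0 * math.pi * u2
    local = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.sqrt(1.0 - u1)])
    # orthonormal frame per normal
    nz = normals
    helper = np.where(np.abs(nz[:, 2:3]) < 0.9,
                      np.tile([0.0, 0.0, 1.0], (n, 1)),
                      np.tile([1.0, 0.0, 0.0], (n, 1)))
    t1 = np.cross(helper, nz)
    t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
    t2 = np.cross(nz, t1)
    return (local[:, 0:1] * t1 + local[:, 1:2] * t2 + local[:, 2:3] * nz)


def _emit(source: LightSourceSpec, bounds, z_top: float, n: int,
          rng: np.random.Generator):
    x0, x1, y0, y1 = bounds
    ox = x0 + rng.random(n) * (x1 - x0)
    oy = y0 + rng.random(n) * (y1 - y0)
    origins = np.column_stack([ox, oy, np.full(n, z_top)])
    if source.angular_model == "vertical":
        dirs = np.tile([0.0, 0.0, -1.0], (n, 1))
    elif source.angular_model == "overcast-diffuse":
        down = np.tile([0.0, 0.0, -1.0], (n, 1))
        dirs = _lambertian(down, rng)
    else:  # uniform-hemisphere
        u = rng.random(n)
        phi = 2.0 * math.pi * rng.random(n)
        cz = -u  # cos of zenith angle, uniform in solid angle would be u; flux weight uniform
        sz = np.sqrt(1.0 - cz * cz)
        dirs = np.column_stack([sz * np.cos(phi), sz * np.sin(phi), cz])
        dirs[:, 2] = np.minimum(dirs[:, 2], -1e-6)
    return origins, dirs


# ---------------------------------------------------------------------------
# the tracer
# ---------------------------------------------------------------------------

def trace(scene: Scene, source: LightSourceSpec, optics: OpticalProps | None = None,
          tiles: SoilTileGrid | None = None, rng: np.random.Generator | None = None,
          rr_threshold: float = 1e-3, max_bounces: int = 40,
          max_wraps: int = 200, chunk: int = 2048,
          sensor_radius: float = 5e-3) -> RadiationResult:
    """Trace ``source.n_rays`` rays through the scene.

    Stochastic but fully reproducible given ``rng`` (or ``source.seed``).
    Per band, emitted = absorbed + soil + escaped up to Monte-Carlo error.
    """
    if optics is None:
        optics = OpticalProps()
    if rng is None:
        rng = np.random.default_rng(source.seed)
    geom = scene.geometry()

    # drop degenerate primitives (zero-area laminas / petioles)
    good = (geom.a > 0) & (geom.b > 0)
    n_skipped = int((~good).sum())
    if n_skipped:
        logger.debug("skipping %d degenerate primitives", n_skipped)
    centers = geom.centers[good]
    ax1, ax2 = geom.ax1[good], geom.ax2[good]
    aa, bb = geom.a[good], geom.b[good]
    normals = geom.normals[good]
    kinds = geom.kinds[good]
    n_prim = len(aa)
    if n_prim:
        c_dot_n = np.einsum("pj,pj->p", centers, normals)
        c_dot_1 = np.einsum("pj,pj->p", centers, ax1)
        c_dot_2 = np.einsum("pj,pj->p", centers, ax2)
    n_sens_pre = len(geom.sensor_centers)
    if n_sens_pre:
        s_dot_n = np.einsum("sj,sj->s", geom.sensor_centers, geom.sensor_normals)

    abs_b, refl_b, trans_b = optics.arrays()

    bounds = scene.layout.plot_bounds
    x0, x1, y0, y1 = bounds
    domain_area = (x1 - x0) * (y1 - y0)
    z_top = max(geom.z_max, 0.01) + 0.005

    n_rays = source.n_rays
    # per-ray band weights: PAR in µmol s⁻¹, R and FR in arbitrary flux units
    band_flux = np.array([source.par_intensity, source.r_fr_ratio, 1.0])
    w0 = band_flux * domain_area / n_rays

    absorbed_prim = np.zeros(n_prim)
    absorbed_tot = np.zeros(3)
    soil_tot = np.zeros(3)
    escaped_tot = np.zeros(3)
    tile_par = np.zeros(tiles.n_tiles) if tiles is not None else np.zeros(0)

    n_sens = len(geom.sensor_centers)
    tip_r = np.zeros(n_sens)
    tip_fr = np.zeros(n_sens)
    tip_hits = np.zeros(n_sens, dtype=np.int64)
    sens_c = geom.sensor_centers
    sens_n = geom.sensor_normals

    for start in range(0, n_rays, chunk):
        m = min(chunk, n_rays - start)
        O, D = _emit(source, bounds, z_top, m, rng)
        W = np.tile(w0, (m, 1))
        bounces = np.zeros(m, dtype=np.int32)
        wraps = np.zeros(m, dtype=np.int32)
        alive = np.ones(m, dtype=bool)

        for _ in range(10 * (max_bounces + max_wraps)):
            idx = np.flatnonzero(alive)
            if len(idx) == 0:
                break
            o, d, w = O[idx], D[idx], W[idx]
            k = len(idx)

            with np.errstate(divide="ignore", invalid="ignore"):
                t_soil = np.where(d[:, 2] < 0, -o[:, 2] / d[:, 2], np.inf)
                t_top = np.where(d[:, 2] > 0, (z_top - o[:, 2]) / d[:, 2], np.inf)
                tx = np.where(d[:, 0] > 0, (x1 - o[:, 0]) / d[:, 0],
                              np.where(d[:, 0] < 0, (x0 - o[:, 0]) / d[:, 0], np.inf))
                ty = np.where(d[:, 1] > 0, (y1 - o[:, 1]) / d[:, 1],
                              np.where(d[:, 1] < 0, (y0 - o[:, 1]) / d[:, 1], np.inf))
            t_wrap = np.minimum(np.maximum(tx, _EPS_T), np.maximum(ty, _EPS_T))

            t_prim = np.full(k, np.inf)
            hit_prim = np.full(k, -1, dtype=np.int64)
            if n_prim:
                denom = d @ normals.T  # (k, n_prim)
                with np.errstate(divide="ignore", invalid="ignore"):
                    t_all = (c_dot_n[None, :] - o @ normals.T) / denom
                t_all = np.where(np.abs(denom) > 1e-12, t_all, np.inf)
                t_all = np.where(t_all > _EPS_T, t_all, np.inf)
                # hit point in primitive-local coordinates, via dot products
                with np.errstate(invalid="ignore"):
                    s = (o @ ax1.T + t_all * (d @ ax1.T) - c_dot_1[None, :]) / aa[None, :]
                    u = (o @ ax2.T + t_all * (d @ ax2.T) - c_dot_2[None, :]) / bb[None, :]
                s = np.nan_to_num(s, nan=np.inf, posinf=np.inf, neginf=np.inf)
                u = np.nan_to_num(u, nan=np.inf, posinf=np.inf, neginf=np.inf)
                inside = np.where(kinds[None, :] == 0,
                                  s * s + u * u <= 1.0,
                                  (np.abs(s) <= 1.0) & (np.abs(u) <= 1.0))
                t_all = np.where(inside, t_all, np.inf)
                hit_prim = np.argmin(t_all, axis=1)
                t_prim = t_all[np.arange(k), hit_prim]

            t_event = np.minimum.reduce([t_soil, t_top, t_wrap, t_prim])

            # ---- sensor tallies along each segment (sensors do not occlude)
            if n_sens:
                with np.errstate(divide="ignore", invalid="ignore"):
                    den_s = d @ sens_n.T
                    t_s = (s_dot_n[None, :] - o @ sens_n.T) / den_s
                valid = (np.abs(den_s) > 1e-12) & (t_s > 0) & (t_s < t_event[:, None])
                if valid.any():
                    dist2 = np.zeros_like(t_s)
                    for j in range(3):
                        comp = o[:, j:j + 1] + t_s * d[:, j:j + 1] - sens_c[None, :, j]
                        comp = np.where(valid, comp, 0.0)
                        dist2 += comp * comp
                    crossing = valid & (dist2 <= sensor_radius ** 2)
                    ri, si = np.nonzero(crossing)
                    np.add.at(tip_r, si, w[ri, 1])
                    np.add.at(tip_fr, si, w[ri, 2])
                    np.add.at(tip_hits, si, 1)

            # ---- resolve events
            hit_soil = t_soil <= t_event
            hit_top = ~hit_soil & (t_top <= t_event)
            hit_wrap = ~hit_soil & ~hit_top & (t_wrap <= t_event)
            hit_geom = ~hit_soil & ~hit_top & ~hit_wrap

            if hit_soil.any():
                sel = np.flatnonzero(hit_soil)
                px = o[sel, 0] + t_soil[sel] * d[sel, 0]
                py = o[sel, 1] + t_soil[sel] * d[sel, 1]
                soil_tot += w[sel].sum(axis=0)
                if tiles is not None:
                    rx0, rx1, ry0, ry1 = tiles.region
                    inx = (px >= rx0) & (px < rx1) & (py >= ry0) & (py < ry1)
                    if inx.any():
                        ix = ((px[inx] - rx0) / (rx1 - rx0) * tiles.nx).astype(int)
                        iy = ((py[inx] - ry0) / (ry1 - ry0) * tiles.ny).astype(int)
                        ix = np.clip(ix, 0, tiles.nx - 1)
                        iy = np.clip(iy, 0, tiles.ny - 1)
                        np.add.at(tile_par, ix * tiles.ny + iy, w[sel[inx], 0])
                alive[idx[sel]] = False

            if hit_top.any():
                sel = np.flatnonzero(hit_top)
                escaped_tot += w[sel].sum(axis=0)
                alive[idx[sel]] = False

            if hit_wrap.any():
                sel = np.flatnonzero(hit_wrap)
                gi = idx[sel]
                newp = o[sel] + (t_wrap[sel, None] + _EPS_T) * d[sel]
                newp[:, 0] = x0 + np.mod(newp[:, 0] - x0, x1 - x0)
                newp[:, 1] = y0 + np.mod(newp[:, 1] - y0, y1 - y0)
                O[gi] = newp
                wraps[gi] += 1
                overspun = wraps[gi] >= max_wraps
                if overspun.any():
                    escaped_tot += W[gi[overspun]].sum(axis=0)
                    alive[gi[overspun]] = False

            if hit_geom.any():
                sel = np.flatnonzero(hit_geom)
                gi = idx[sel]
                prim = hit_prim[sel]
                pts = o[sel] + t_prim[sel, None] * d[sel]
                wsel = w[sel]
                is_pet = kinds[prim] == 1
                # petioles: opaque black, absorb everything
                if is_pet.any():
                    pp = prim[is_pet]
                    np.add.at(absorbed_prim, pp, wsel[is_pet, 0])
                    absorbed_tot += wsel[is_pet].sum(axis=0)
                    alive[gi[is_pet]] = False
                is_lam = ~is_pet
                if is_lam.any():
                    lp = prim[is_lam]
                    gil = gi[is_lam]
                    wl = wsel[is_lam]
                    dep = wl * abs_b[None, :]
                    np.add.at(absorbed_prim, lp, dep[:, 0])
                    absorbed_tot += dep.sum(axis=0)
                    wl = wl - dep
                    # 50:50 reflect/transmit with per-band importance reweight
                    nrm = normals[lp]
                    d_in = d[sel][is_lam]
                    side = np.sign(np.einsum("ij,ij->i", d_in, nrm))  # +1: along normal
                    reflect = rng.random(len(lp)) < 0.5
                    # reflected rays leave on the incoming side, transmitted on the far side
                    out_sign = np.where(reflect, -side, side)
                    new_dirs = _lambertian(nrm * out_sign[:, None], rng)
                    factor = np.where(reflect[:, None], refl_b[None, :] / 0.5,
                                      trans_b[None, :] / 0.5)
                    # reweight relative to post-absorption weight
                    with np.errstate(divide="ignore", invalid="ignore"):
                        wl = wl * factor / (1.0 - abs_b[None, :])
                    wl = np.nan_to_num(wl, nan=0.0, posinf=0.0)
                    O[gil] = pts[is_lam] + new_dirs * _EPS_T
                    D[gil] = new_dirs
                    W[gil] = wl
                    bounces[gil] += 1
                    # Russian roulette, unbiased termination
                    relw = np.max(wl / w0[None, :], axis=1)
                    candidate = (relw < rr_threshold) | (bounces[gil] >= max_bounces)
                    if candidate.any():
                        ci = np.flatnonzero(candidate)
                        survive = rng.random(len(ci)) < 0.5
                        kill = gil[ci[~survive]]
                        alive[kill] = False  # weight lost: RR keeps this unbiased
                        keep = gil[ci[survive]]
                        W[keep] *= 2.0
                    dead = np.max(wl, axis=1) <= 0
                    if dead.any():
                        alive[gil[dead]] = False

    emitted = band_flux * domain_area
    soil_par_tiles = tile_par / tiles.tile_area if tiles is not None else tile_par
    return RadiationResult(
        absorbed_par=absorbed_prim,
        prim_plant=geom.plant_idx[good],
        prim_leaf=geom.leaf_idx[good],
        soil_tile_par=soil_par_tiles,
        tiles=tiles,
        tip_r=tip_r,
        tip_fr=tip_fr,
        tip_hits=tip_hits,
        sensor_plant=geom.sensor_plant,
        sensor_leaf=geom.sensor_leaf,
        emitted=emitted,
        absorbed=absorbed_tot,
        soil=soil_tot,
        escaped=escaped_tot,
        n_rays=n_rays,
        n_degenerate_skipped=n_skipped,
    )


# ---------------------------------------------------------------------------
# result queries
# ---------------------------------------------------------------------------

def tip_r_fr(result: RadiationResult, sensor_index: int, min_hits: int = 5
             ) -> tuple[float, bool]:
    """R:FR fluence ratio at one tip sensor and a confidence flag.

    Returns ``inf`` when no far-red reaches the sensor (never raises); the
    flag is False when fewer than ``min_hits`` rays crossed the sensor.
    """
    r = result.tip_r[sensor_index]
    fr = result.tip_fr[sensor_index]
    confident = bool(result.tip_hits[sensor_index] >= min_hits)
    if fr <= 0.0:
        return math.inf, confident
    return float(r / fr), confident


def tip_r_fr_all(result: RadiationResult) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.where(result.tip_fr > 0, result.tip_r / result.tip_fr, np.inf)
    return ratios


def soil_par_summary(result: RadiationResult, tiles: SoilTileGrid | None = None
                     ) -> float:
    """Area-weighted mean PAR (µmol m⁻² s⁻¹) over the central soil tiles."""
    if tiles is None:
        tiles = result.tiles
    if tiles is None or len(result.soil_tile_par) == 0:
        raise ValueError("no soil tiles defined")
    return float(result.soil_tile_par.mean())  # equal-area tiles
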