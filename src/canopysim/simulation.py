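"""Daily-step orchestration of canopy competition scenarios.

Three scenarios follow the in-silico experiment: (1) a monoculture canopy
with no invaders, (2) the canopy plus shade-blind "weak-SAS" competitors
(no hyponasty, slow elongation), (3) the canopy plus "strong-SAS"
competitors (16°/day hyponasty, full elongation).  Within a scenario the
canopy's hyponasty rate is the experimental variable, swept over
{1, 5, 10, 15, 20}°/day.

Each simulated day executes, in fixed order: leaf initiation, the
Monte-Carlo light trace, signal evaluation, hyponasty and elongation
responses, photosynthesis, carbon allocation, organ growth, and metric
recording — so responses always act on the morning canopy state.
Everything is reproducible bit-for-bit from the master seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from . import canopy_scene as cs
from . import physiology as phys
from . import radiation as rad
from . import shade_responses as sas_mod
from .canopy_scene import Scene, SceneLayout
from .physiology import GrowthParams
from .radiation import LightSourceSpec, OpticalProps, SoilTileGrid
from .shade_responses import SASParams

SCENARIO_NAMES = {1: "no_competitors", 2: "weak_sas_competitors",
                  3: "strong_sas_competitors"}


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class ScenarioConfig:
    """Full parameter set for one scenario × hyponasty-rate combination."""

    scenario: int = 1
    hyponasty_rate: float = 5.0
    n_stands: int = 10
    days: int = 44
    nx: int = 10
    ny: int = 10
    spacing: float = 0.025
    n_competitors: int = 16
    competitor_delay_days: int = 3
    central_canopy: int = 16
    central_competitors: int = 4
    source: LightSourceSpec = field(default_factory=LightSourceSpec)
    optics: OpticalProps = field(default_factory=OpticalProps)
    growth: GrowthParams = field(default_factory=GrowthParams)
    canopy_elongation_multiplier: float = 0.5
    weak_elongation_multiplier: float = 0.15
    strong_elongation_multiplier: float = 0.5
    strong_hyponasty_rate: float = 16.0
    max_angle: float = 80.0
    r_fr_threshold: float = 0.5
    touch_tolerance_mm: float = 2.0
    tile_nx: int = 8
    tile_ny: int = 8
    cover_resolution: int = 80
    master_seed: int = 12345

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2, 3):
            raise ValueError("scenario must be 1, 2 or 3")
        if self.days < 1:
            raise ValueError("days must be >= 1")

    # phenotypes ------------------------------------------------------------

    def canopy_phenotype(self) -> SASParams:
        return SASParams(r_fr_threshold=self.r_fr_threshold,
                         hyponasty_rate=self.hyponasty_rate,
                         max_angle=self.max_angle,
                         elongation_multiplier=self.canopy_elongation_multiplier)

    def competitor_phenotype(self) -> SASParams | None:
        if self.scenario == 1:
            return None
        if self.scenario == 2:
            return SASParams(r_fr_threshold=self.r_fr_threshold,
                             hyponasty_rate=0.0, max_angle=self.max_angle,
                             elongation_multiplier=self.weak_elongation_multiplier)
        return SASParams(r_fr_threshold=self.r_fr_threshold,
                         hyponasty_rate=self.strong_hyponasty_rate,
                         max_angle=self.max_angle,
                         elongation_multiplier=self.strong_elongation_multiplier)

    # (de)serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        if "source" in data and isinstance(data["source"], dict):
            data["source"] = LightSourceSpec(**data["source"])
        if "optics" in data and isinstance(data["optics"], dict):
            data["optics"] = OpticalProps(
                **{k: rad.BandOptics(**v) for k, v in data["optics"].items()})
        if "growth" in data and isinstance(data["growth"], dict):
            data["growth"] = GrowthParams(**data["growth"])
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass
class StandTimeSeries:
    """Daily metrics for one simulated stand."""

    stand: int
    days: np.ndarray
    soil_par: np.ndarray          # mean central soil PAR, µmol m⁻² s⁻¹
    canopy_biomass_gm2: np.ndarray  # central canopy plants, g m⁻²
    competitor_biomass_g: np.ndarray  # mean central competitor, g
    lai: np.ndarray
    cover: np.ndarray
    mean_leaf_angle: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for metric in ("soil_par", "canopy_biomass_gm2", "competitor_biomass_g",
                       "lai", "cover", "mean_leaf_angle"):
            frames.append(pd.DataFrame({
                "stand": self.stand, "day": self.days,
                "metric": metric, "value": getattr(self, metric)}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    stands: list[StandTimeSeries]

    def tidy(self) -> pd.DataFrame:
        df = pd.concat([ts.to_dataframe() for ts in self.stands],
                       ignore_index=True)
        df.insert(0, "scenario", self.config.scenario)
        df.insert(1, "hyponasty_rate", self.config.hyponasty_rate)
        return df

    def summary(self) -> dict:
        last = {m: np.array([getattr(ts, m)[-1] for ts in self.stands])
                for m in ("soil_par", "canopy_biomass_gm2",
                          "competitor_biomass_g", "lai", "cover")}
        out = {"scenario": self.config.scenario,
               "hyponasty_rate": self.config.hyponasty_rate,
               "n_stands": len(self.stands),
               "days": int(self.config.days)}
        for m, vals in last.items():
            out[f"{m}_mean"] = float(vals.mean())
            out[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        out["soil_par_series_mean"] = [
            float(v) for v in np.mean([ts.soil_par for ts in self.stands], axis=0)]
        return out


# ---------------------------------------------------------------------------
# stand construction and stepping
# ---------------------------------------------------------------------------

def _stand_seed_seq(config: ScenarioConfig, stand: int, *extra: int
                    ) -> np.random.SeedSequence:
    key = [int(config.master_seed), int(config.scenario),
           int(round(config.hyponasty_rate * 10)), int(stand), *map(int, extra)]
    return np.random.SeedSequence(key)


def build_stand(config: ScenarioConfig, stand: int) -> Scene:
    """Construct the day-0 scene for one replicate stand."""
    layout = cs.uniform_grid(config.nx, config.ny, config.spacing)
    if config.scenario != 1 and config.n_competitors > 0:
        layout = cs.interleave_competitors(layout, config.n_competitors)
    rng = np.random.default_rng(_stand_seed_seq(config, stand, 777))
    plants: list[cs.PlantState] = []
    canopy_sas = config.canopy_phenotype()
    for i, (x, y) in enumerate(layout.canopy_positions):
        plants.append(cs.build_rosette(
            canopy_sas, germination_day=0, position=(float(x), float(y)),
            plant_id=i, role="canopy", first_azimuth=rng.uniform(0, 360)))
    comp_sas = config.competitor_phenotype()
    if comp_sas is not None:
        n0 = len(plants)
        for j, (x, y) in enumerate(layout.competitor_positions):
            plants.append(cs.build_rosette(
                comp_sas, germination_day=config.competitor_delay_days,
                position=(float(x), float(y)), plant_id=n0 + j,
                role="competitor", first_azimuth=rng.uniform(0, 360)))
    return Scene(plants, layout)


def step_day(scene: Scene, day: int, config: ScenarioConfig,
             tiles: SoilTileGrid, rng: np.random.Generator) -> dict:
    """Advance the stand by one 24 h step; returns the day's metrics."""
    growth = config.growth
    # 1. leaf initiation (advances leaf ages)
    for plant in scene.plants:
        phys.initiate_leaves(plant, day, growth)
    # 2. radiation
    result = rad.trace(scene, config.source, config.optics, tiles, rng=rng)
    # 3. neighbour signals
    signals = sas_mod.evaluate_signals(
        scene, result, lambda pi: scene.plants[pi].phenotype,
        touch_tolerance=config.touch_tolerance_mm)
    # 4. hyponasty + elongation multipliers
    multipliers: list[np.ndarray] = []
    for pi, plant in enumerate(scene.plants):
        mult = np.ones(len(plant.leaves))
        for li, leaf in enumerate(plant.leaves):
            trig = signals.is_triggered(pi, li)
            leaf.petiole_angle = sas_mod.update_hyponasty(
                leaf.petiole_angle, trig, plant.phenotype)
            mult[li] = sas_mod.elongation_signal(trig, plant.phenotype)
        multipliers.append(mult)
    # 5–7. photosynthesis, allocation, growth
    absorbed = result.absorbed_par_per_plant(len(scene.plants))
    for pi, plant in enumerate(scene.plants):
        if day < plant.germination_day:
            continue
        carbon = phys.daily_assimilation(plant, float(absorbed[pi]), growth)
        available = carbon + plant.carbon_pool
        lam_inc, pet_inc, leftover = phys.allocate(plant, available, growth)
        plant.carbon_pool = leftover
        phys.grow_organs(plant, lam_inc, pet_inc, growth, multipliers[pi])
    # 8. metrics
    return _record_metrics(scene, result, config, day)


def _central_indices(scene: Scene, config: ScenarioConfig
                     ) -> tuple[np.ndarray, np.ndarray]:
    canopy = [p for p in scene.plants if p.role == "canopy"]
    comp = [p for p in scene.plants if p.role == "competitor"]
    canopy_pos = np.array([p.position for p in canopy])
    k_can = min(config.central_canopy, len(canopy))
    can_idx = cs.central_selection(canopy_pos, k_can)
    if comp:
        comp_pos = np.array([p.position for p in comp])
        k_comp = min(config.central_competitors, len(comp))
        comp_idx = cs.central_selection(comp_pos, k_comp)
    else:
        comp_idx = np.zeros(0, dtype=int)
    return can_idx, comp_idx


def _record_metrics(scene: Scene, result: rad.RadiationResult,
                    config: ScenarioConfig, day: int) -> dict:
    can_idx, comp_idx = _central_indices(scene, config)
    canopy = [p for p in scene.plants if p.role == "canopy"]
    comp = [p for p in scene.plants if p.role == "competitor"]
    footprint = len(can_idx) * config.spacing ** 2  # m², one grid cell per plant
    canopy_mg = sum(canopy[i].biomass for i in can_idx)
    canopy_gm2 = canopy_mg * 1e-3 / footprint if footprint > 0 else 0.0
    comp_g = (float(np.mean([comp[i].biomass for i in comp_idx])) * 1e-3
              if len(comp_idx) else 0.0)
    region = result.tiles.region if result.tiles is not None \
        else scene.layout.plot_bounds
    return {
        "day": day,
        "soil_par": rad.soil_par_summary(result),
        "canopy_biomass_gm2": canopy_gm2,
        "competitor_biomass_g": comp_g,
        "lai": cs.leaf_area_index(scene, scene.layout.plot_bounds),
        "cover": cs.vertical_cover_fraction(scene, region,
                                            config.cover_resolution),
        "mean_leaf_angle": float(np.mean(
            [l.petiole_angle for p in scene.plants for l in p.leaves]))
        if any(p.leaves for p in scene.plants) else 0.0,
    }


def run_stand(config: ScenarioConfig, stand: int) -> StandTimeSeries:
    scene = build_stand(config, stand)
    tiles = SoilTileGrid.central(scene.layout,
                                 k=min(config.central_canopy,
                                       len(scene.layout.canopy_positions)),
                                 nx=config.tile_nx, ny=config.tile_ny)
    metrics: list[dict] = []
    for day in range(config.days):
        rng = np.random.default_rng(_stand_seed_seq(config, stand, day))
        metrics.append(step_day(scene, day, config, tiles, rng))
    return StandTimeSeries(
        stand=stand,
        days=np.array([m["day"] for m in metrics]),
        soil_par=np.array([m["soil_par"] for m in metrics]),
        canopy_biomass_gm2=np.array([m["canopy_biomass_gm2"] for m in metrics]),
        competitor_biomass_g=np.array([m["competitor_biomass_g"] for m in metrics]),
        lai=np.array([m["lai"] for m in metrics]),
        cover=np.array([m["cover"] for m in metrics]),
        mean_leaf_angle=np.array([m["mean_leaf_angle"] for m in metrics]),
    )


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Simulate ``config.n_stands`` independently seeded replicate stands."""
    stands = [run_stand(config, s) for s in range(config.n_stands)]
    return ScenarioResult(config=config, stands=stands)


def sweep_hyponasty(config: ScenarioConfig,
                    rates: tuple[float, ...] = (1, 5, 10, 15, 20)
                    ) -> dict[float, ScenarioResult]:
    """One scenario run per canopy hyponasty rate (the in-silico sweep)."""
    if not rates:
        raise ValueError("rates must be non-empty")
    out: dict[float, ScenarioResult] = {}
    for rate in rates:
        cfg = dataclasses.replace(config, hyponasty_rate=float(rate))
        out[float(rate)] = run_scenario(cfg)
    return out


def summarize_stand(ts: StandTimeSeries) -> dict:
    """Final-day metrics record for one stand."""
    return {
        "stand": ts.stand,
        "final_day": int(ts.days[-1]),
        "canopy_biomass_gm2": float(ts.canopy_biomass_gm2[-1]),
        "competitor_biomass_g": float(ts.competitor_biomass_g[-1]),
        "soil_par": float(ts.soil_par[-1]),
        "lai": float(ts.lai[-1]),
        "cover": float(ts.cover[-1]),
    }


# ---------------------------------------------------------------------------
# ANOVA + LSD lettering on simulation outputs
# ---------------------------------------------------------------------------

def anova_lsd(groups: dict, alpha: float = 0.05) -> dict:
    """One-way ANOVA with unprotected pairwise LSD comparisons.

    ``groups`` maps label → 1D array of replicate values.  Returns the F
    statistic, its p-value, and compact letters (groups sharing a letter are
    not significantly different at ``alpha``).
    """
    labels = list(groups)
    data = [np.asarray(groups[l], dtype=float) for l in labels]
    k = len(labels)
    n_tot = sum(len(d) for d in data)
    if k < 2 or n_tot <= k:
        raise ValueError("need >= 2 groups with replication")
    grand = np.concatenate(data).mean()
    ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_b, df_w = k - 1, n_tot - k
    mse = ss_within / df_w
    f_stat = (ss_between / df_b) / mse if mse > 0 else math.inf
    p = float(scipy.stats.f.sf(f_stat, df_b, df_w))
    t_crit = scipy.stats.t.ppf(1 - alpha / 2, df_w)
    means = {l: d.mean() for l, d in zip(labels, data)}
    ns = {l: len(d) for l, d in zip(labels, data)}
    differs = {}
    for i, li in enumerate(labels):
        for lj in labels[i + 1:]:
            lsd = t_crit * math.sqrt(mse * (1 / ns[li] + 1 / ns[lj]))
            differs[(li, lj)] = abs(means[li] - means[lj]) > lsd
    letters = _compact_letters(labels, means, differs)
    return {"F": float(f_stat), "p": p, "df": (df_b, df_w),
            "means": {l: float(m) for l, m in means.items()},
            "letters": letters}


def _compact_letters(labels, means, differs):
    order = sorted(labels, key=lambda l: -means[l])
    classes: list[list] = []

    def same(a, b):
        key = (a, b) if (a, b) in differs else (b, a)
        return not differs[key]

    for lab in order:
        placed = False
        for cls in classes:
            if all(same(lab, other) for other in cls):
                cls.append(lab)
                placed = True
        if not placed:
            classes.append([lab])
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {l: "" for l in labels}
    for ci, cls in enumerate(classes):
        for lab in cls:
            out[lab] += alphabet[ci % len(alphabet)]
    return out


# ---------------------------------------------------------------------------
# output writers (atomic)
# ---------------------------------------------------------------------------

def _atomic_write(path: str, writer) -> None:
    tmp = f"{path}.tmp"
    writer(tmp)
    os.replace(tmp, path)


def write_scenario_outputs(result: ScenarioResult, out_dir: str,
                           prefix: str = "scenario") -> dict:
    """Write tidy CSV + JSON summary; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    tag = f"{prefix}{result.config.scenario}_rate{result.config.hyponasty_rate:g}"
    csv_path = os.path.join(out_dir, f"{tag}_timeseries.csv")
    json_path = os.path.join(out_dir, f"{tag}_summary.json")
    _atomic_write(csv_path, lambda p: result.tidy().to_csv(p, index=False))
    payload = {"config": result.config.to_dict(), "summary": result.summary(),
               "stands": [summarize_stand(ts) for ts in result.stands]}
    _atomic_write(json_path, lambda p: _dump_json(payload, p))
    return {"csv": csv_path, "json": json_path}


def _dump_json(payload, path) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def plot_sweep(sweep: dict[float, ScenarioResult], out_dir: str,
               prefix: str = "sweep") -> list[str]:
    """PAR-through-time curves per rate and final competitor-biomass bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    fig, ax = plt.subplots(figsize=(6, 4))
    for rate, res in sorted(sweep.items()):
        series = np.mean([ts.soil_par for ts in res.stands], axis=0)
        ax.plot(res.stands[0].days, series, label=f"{rate:g}°/day")
    ax.set_xlabel("day")
    ax.set_ylabel("central soil PAR (µmol m⁻² s⁻¹)")
    ax.legend(title="hyponasty rate", fontsize=8)
    p1 = os.path.join(out_dir, f"{prefix}_soil_par.png")
    fig.tight_layout()
    fig.savefig(p1, dpi=150)
    plt.close(fig)
    paths.append(p1)

    rates = sorted(sweep)
    means = [np.mean([ts.competitor_biomass_g[-1] for ts in sweep[r].stands])
             for r in rates]
    sds = [np.std([ts.competitor_biomass_g[-1] for ts in sweep[r].stands], ddof=1)
           if len(sweep[r].stands) > 1 else 0.0 for r in rates]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar([f"{r:g}" for r in rates], means, yerr=sds, color="#76a665")
    ax.set_xlabel("canopy hyponasty rate (°/day)")
    ax.set_ylabel("final competitor biomass (g)")
    p2 = os.path.join(out_dir, f"{prefix}_competitor_biomass.png")
    fig.tight_layout()
    fig.savefig(p2, dpi=150)
    plt.close(fig)
    paths.append(p2)
    return paths
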