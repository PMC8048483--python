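"""Daily photosynthesis, carbon allocation and organ growth.

Absorbed PAR is converted to biomass with a linear light-use efficiency
(LUE), the simplest model preserving the light→growth causality a canopy
competition experiment probes.  Carbon is allocated among expanding organs
in proportion to an age-dependent sink demand (a symmetric beta-shaped
curve over a fixed expansion window), and organ dimensions follow biomass
through fixed conversion rules: lamina area via SLA (specific leaf area),
petiole length via a linear mass-per-length density, stretched by the
shade-avoidance elongation multiplier on triggered days.

The quantitative defaults are a joint calibration chosen so that a dense
(1,600 plants m⁻²) rosette stand with minimal hyponasty closes its canopy
within about 30 simulated days; they are knobs, not measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .canopy_scene import LeafOrgan, PlantState

MICROMOL_TO_MOL = 1e-6
SECONDS_PER_HOUR = 3600.0


@dataclass
class GrowthParams:
    """Whole-plant growth parameters (mg, mm, days).

    lue: mg biomass per mol absorbed PAR; sla: mm² lamina per mg;
    petiole_density: mg per mm of petiole at reference thickness;
    sink potentials are per-organ asymptotic sizes reached only when carbon
    is non-limiting.
    """

    photoperiod_h: float = 9.0
    lue: float = 900.0
    plastochron_days: float = 1.5
    expansion_days: float = 12.0
    lamina_potential_mg: float = 14.0
    petiole_potential_mg: float = 3.5
    sla: float = 45.0
    petiole_density: float = 0.2
    max_leaf_count: int = 15
    lamina_aspect: float = 2.0  # length : width
    initial_lamina_mg: float = 0.25
    initial_petiole_mg: float = 0.05
    initial_angle_deg: float = 30.0
    seed_reserve_mg: float = 1.2

    def __post_init__(self) -> None:
        for name in ("photoperiod_h", "lue", "plastochron_days", "expansion_days",
                     "lamina_potential_mg", "petiole_potential_mg", "sla",
                     "petiole_density", "lamina_aspect"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_leaf_count < 1:
            raise ValueError("max_leaf_count must be >= 1")


# ---------------------------------------------------------------------------
# geometry/biomass conversions
# ---------------------------------------------------------------------------

def lamina_dimensions(biomass_mg: float, params: GrowthParams) -> tuple[float, float]:
    """(length, width) in mm of an elliptical lamina of given biomass:
    area = sla·m, ellipse π·L·W/4 with fixed aspect L/W."""
    area = params.sla * biomass_mg
    if area <= 0:
        return 0.0, 0.0
    length = math.sqrt(4.0 * area * params.lamina_aspect / math.pi)
    return length, length / params.lamina_aspect


def _beta_cdf(x: np.ndarray) -> np.ndarray:
    """CDF of the symmetric Beta(3, 3) sink curve on [0, 1]."""
    x = np.clip(x, 0.0, 1.0)
    return 10 * x ** 3 - 15 * x ** 4 + 6 * x ** 5


def sink_demands(plant: PlantState, params: GrowthParams
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Potential growth demand (mg) of each leaf's lamina and petiole for the
    coming day, from the beta-shaped expansion curve; organs past the
    expansion window, or at their potential, demand nothing."""
    n = len(plant.leaves)
    lam = np.zeros(n)
    pet = np.zeros(n)
    T = params.expansion_days
    for i, leaf in enumerate(plant.leaves):
        frac = _beta_cdf(np.array([(leaf.age_days + 1.0) / T])) - \
            _beta_cdf(np.array([leaf.age_days / T]))
        lam[i] = min(params.lamina_potential_mg * float(frac[0]),
                     max(params.lamina_potential_mg - leaf.lamina_biomass, 0.0))
        pet[i] = min(params.petiole_potential_mg * float(frac[0]),
                     max(params.petiole_potential_mg - leaf.petiole_biomass, 0.0))
    return lam, pet


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def daily_assimilation(plant: PlantState, absorbed_par: float,
                       params: GrowthParams) -> float:
    """Carbon gain (mg) for one day from the plant's total absorbed PAR
    (µmol s⁻¹), integrated over the photoperiod at linear LUE."""
    if absorbed_par < 0:
        raise ValueError("absorbed PAR must be >= 0")
    mol = absorbed_par * MICROMOL_TO_MOL * SECONDS_PER_HOUR * params.photoperiod_h
    return params.lue * mol


def allocate(plant: PlantState, carbon: float, params: GrowthParams
             ) -> tuple[np.ndarray, np.ndarray, float]:
    """Split ``carbon`` (mg) across organs in proportion to sink demand.

    Returns (lamina increments, petiole increments, leftover).  When demand
    exceeds supply every organ gets its proportional share and the
    increments sum to ``carbon`` exactly; surplus carbon beyond total demand
    is returned as leftover (retained in the plant's labile pool).
    """
    if carbon < 0:
        raise ValueError("carbon must be >= 0")
    lam_d, pet_d = sink_demands(plant, params)
    total = lam_d.sum() + pet_d.sum()
    if total <= 0 or carbon == 0:
        return np.zeros_like(lam_d), np.zeros_like(pet_d), carbon
    spend = min(carbon, total)
    lam_inc = lam_d * (spend / total)
    pet_inc = pet_d * (spend / total)
    return lam_inc, pet_inc, carbon - spend


def grow_organs(plant: PlantState, lam_inc: np.ndarray, pet_inc: np.ndarray,
                params: GrowthParams,
                elongation_multipliers: np.ndarray | None = None) -> PlantState:
    """Apply allocated increments: lamina area grows by sla·Δm, petiole
    length by Δm/density times the per-leaf elongation multiplier (>1 on
    SAS-triggered days).  Biomass bookkeeping is exact; dimensions never
    shrink."""
    n = len(plant.leaves)
    if elongation_multipliers is None:
        elongation_multipliers = np.ones(n)
    for i, leaf in enumerate(plant.leaves):
        if lam_inc[i] > 0:
            leaf.lamina_biomass += float(lam_inc[i])
            leaf.lamina_length, leaf.lamina_width = lamina_dimensions(
                leaf.lamina_biomass, params)
        if pet_inc[i] > 0:
            leaf.petiole_biomass += float(pet_inc[i])
            leaf.petiole_length += float(pet_inc[i]) / params.petiole_density \
                * float(elongation_multipliers[i])
    return plant


def initiate_leaves(plant: PlantState, stand_day: int, params: GrowthParams
                    ) -> PlantState:
    """Create new leaves on plastochron multiples since germination.

    Leaf count target at age a days is ⌊a / plastochron⌋ (capped); each new
    leaf is paid for from the plant's carbon pool (seed reserve early on) at
    seed dimensions and the default initial elevation.  Ages of existing
    leaves advance by one day per call.
    """
    if stand_day < plant.germination_day:
        return plant
    if stand_day == plant.germination_day and plant.carbon_pool == 0.0:
        plant.carbon_pool = params.seed_reserve_mg
    for leaf in plant.leaves:
        leaf.age_days += 1.0
    age = stand_day - plant.germination_day
    target = min(int(age / params.plastochron_days), params.max_leaf_count)
    cost = params.initial_lamina_mg + params.initial_petiole_mg
    while len(plant.leaves) < target and plant.carbon_pool >= cost:
        rank = len(plant.leaves) + 1
        length, width = lamina_dimensions(params.initial_lamina_mg, params)
        leaf = LeafOrgan(
            rank=rank,
            age_days=0.0,
            petiole_length=params.initial_petiole_mg / params.petiole_density,
            petiole_angle=min(params.initial_angle_deg,
                              getattr(plant.phenotype, "max_angle", 90.0)),
            azimuth=plant.next_leaf_azimuth(),
            lamina_length=length,
            lamina_width=width,
            lamina_biomass=params.initial_lamina_mg,
            petiole_biomass=params.initial_petiole_mg,
        )
        plant.carbon_pool -= cost
        plant.leaves.append(leaf)
    return plant
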