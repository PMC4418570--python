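"""Pond food-web sub-model supplying the population's functional response.

Six pools are tracked for a 36 m² pond: autotrophic food ``A`` and
heterotrophic food ``H`` (kcal pond⁻¹), dissolved inorganic nitrogen and
phosphorus ``N_w``, ``P_w`` (mg L⁻¹) and their sediment stores ``N_s``,
``P_s`` (g pond⁻¹).  Phytoplankton growth is co-limited by light
(photoperiod-scaled irradiance with self-shading), a Liebig minimum of two
Monod nutrient terms, and a Gaussian temperature response around an
optimum.  Autotrophic production cascades into the heterotrophic pool,
which sediments and decomposes; nutrients cycle between water, sediment,
plankton and fish excretion.  Monsoon days inject a fixed fraction of the
reference dissolved nutrient stocks, compensating the slow losses so that
the annual budget is approximately balanced.

The fish feed on ``A + H``; the population-level functional response is the
saturating share ``f = F / (F + s·B)`` of available food relative to fish
biomass demand, applied identically to every fish on a given day
(paralleling feeding) before individual scatter and male-appetite factors.

Daily explicit (Euler) stepping matches the 1-day step of the population
model.  All pools are floored at zero; with monsoon inputs disabled the
total nutrient inventories are non-increasing (closed system).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FoodParams",
    "FoodState",
    "temperature_factor",
    "nutrient_limitation",
    "light_factor",
    "population_f",
    "step_food_day",
    "total_nitrogen",
    "total_phosphorus",
]

#: J per kcal, for coupling DEB energy fluxes to the kcal-based food pools
J_PER_KCAL = 4184.0


@dataclass(frozen=True)
class FoodParams:
    """Food sub-model constants (pond-aquaculture values) plus pond geometry."""

    G2Kcal: float = 1.88     # kcal g⁻¹ fish wet mass
    s: float = 21.08         # demand scaling of f (-)
    h_n: float = 0.2         # mg L⁻¹
    h_p: float = 0.02        # mg L⁻¹
    K_n: float = 0.01        # g kcal⁻¹ d⁻¹ N fixation
    K_fn: float = 0.017      # g kcal⁻¹ fish N content
    K_an: float = 0.0224     # g kcal⁻¹ phytoplankton N content
    K_hn: float = 0.0192     # g kcal⁻¹ heterotroph N content
    K_sn: float = 0.003      # d⁻¹ sediment N release
    K_nl: float = 0.17       # d⁻¹ dissolved N loss to air
    K_ap: float = 0.001      # g kcal⁻¹ phytoplankton P content
    K_hp: float = 0.001      # g kcal⁻¹ heterotroph P content
    K_pr: float = 0.0006     # m d⁻¹ sediment P release velocity
    K_ps: float = 0.28       # m d⁻¹ dissolved P sedimentation velocity
    K_s: float = 0.14        # d⁻¹ heterotroph sedimentation
    K_d: float = 0.12        # d⁻¹ heterotroph decomposition
    lambda_max: float = 1.6  # d⁻¹ max phytoplankton growth
    K_r: float = 0.1         # d⁻¹ phytoplankton respiration
    K_ml: float = 0.6        # d⁻¹ autotroph → heterotroph transfer
    Ir: float = 6.547        # 10⁶ cal m⁻² d⁻¹ reference solar radiation
    Ir_a: float = 1.7e-5     # pond kcal⁻¹ autotroph self-shading
    Ir_b: float = 1.5e-5     # pond kcal⁻¹ heterotroph shading
    T_opta: float = 30.0     # °C optimal phytoplankton temperature
    k_T1: float = 0.004      # °C⁻² below-optimum penalty
    K_T2: float = 0.008      # °C⁻² above-optimum penalty
    F_inputs: float = 0.0142  # monsoon daily input fraction of reference stocks
    # pond geometry and reference stocks (dissolved nutrients at start)
    area_m2: float = 36.0
    depth_m: float = 0.5
    N_ref_g: float = 2000.0  # g, reference pond N stock scaling monsoon inputs
    P_ref_g: float = 200.0   # g, reference pond P stock scaling monsoon inputs

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"food parameter {name} must be non-negative")

    @property
    def volume_L(self) -> float:
        return self.area_m2 * self.depth_m * 1000.0

    def replace(self, **kwargs) -> "FoodParams":
        return replace(self, **kwargs)


@dataclass
class FoodState:
    """Instantaneous pond pools; all non-negative."""

    A: float = 500.0     # kcal pond⁻¹
    H: float = 500.0     # kcal pond⁻¹
    N_w: float = 0.2     # mg L⁻¹
    P_w: float = 0.02    # mg L⁻¹
    N_s: float = 800.0   # g pond⁻¹ (≈ 22 g N m⁻²; dry-season baseline, monsoon-dominated budget)
    P_s: float = 80.0    # g pond⁻¹

    def __post_init__(self):
        for name in ("A", "H", "N_w", "P_w", "N_s", "P_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"food pool {name} must be non-negative")

    def copy(self) -> "FoodState":
        return FoodState(self.A, self.H, self.N_w, self.P_w, self.N_s, self.P_s)


def temperature_factor(T, params: FoodParams = FoodParams()):
    """Gaussian phytoplankton temperature response, 1 at the optimum."""
    T = np.asarray(T, dtype=float)
    k = np.where(T < params.T_opta, params.k_T1, params.K_T2)
    out = np.exp(-k * (T - params.T_opta) ** 2)
    return out if out.ndim else float(out)


def nutrient_limitation(N_w, P_w, params: FoodParams = FoodParams()):
    """Liebig minimum of Monod terms for dissolved N and P."""
    N_w = np.asarray(N_w, dtype=float)
    P_w = np.asarray(P_w, dtype=float)
    if np.any(N_w < 0) or np.any(P_w < 0):
        raise ValueError("nutrient concentrations must be non-negative")
    out = np.minimum(N_w / (params.h_n + N_w), P_w / (params.h_p + P_w))
    return out if out.ndim else float(out)


def light_factor(A, H, photoperiod, params: FoodParams = FoodParams()):
    """Light limitation with self-shading.

    Surface irradiance scales with photoperiod (12 h ≡ the reference
    radiation ``Ir``), capped at 1; the plankton standing crop shades
    itself through the two extinction coefficients.
    """
    irradiance_ratio = min(float(photoperiod) / 12.0, 1.0)
    shading = np.exp(-(params.Ir_a * np.asarray(A, dtype=float) + params.Ir_b * np.asarray(H, dtype=float)))
    out = irradiance_ratio * shading
    return out if np.ndim(out) else float(out)


def population_f(F_total, fish_biomass_kcal, params: FoodParams = FoodParams()):
    """Population-level scaled functional response ``f = F / (F + s·B)``.

    Every fish alive on a given day shares this value (paralleling
    feeding); individual scatter and the male appetite factor are applied
    afterwards.  ``f = 1`` when there are no fish and food exists; 0 when
    there is no food.
    """
    F_total = float(F_total)
    B = float(fish_biomass_kcal)
    if F_total < 0 or B < 0:
        raise ValueError("food and biomass must be non-negative")
    if F_total == 0.0:
        return 0.0
    return F_total / (F_total + params.s * B)


def total_nitrogen(state: FoodState, params: FoodParams = FoodParams()) -> float:
    """Pond N inventory (g): dissolved + sediment + plankton-bound."""
    return (
        state.N_w * params.volume_L / 1000.0
        + state.N_s
        + params.K_an * state.A
        + params.K_hn * state.H
    )


def total_phosphorus(state: FoodState, params: FoodParams = FoodParams()) -> float:
    """Pond P inventory (g): dissolved + sediment + plankton-bound."""
    return (
        state.P_w * params.volume_L / 1000.0
        + state.P_s
        + params.K_ap * state.A
        + params.K_hp * state.H
    )


def step_food_day(
    state: FoodState,
    T: float,
    photoperiod: float,
    consumption_kcal: float,
    monsoon: bool = False,
    params: FoodParams = FoodParams(),
) -> FoodState:
    """One-day explicit update of all six pools.

    Fluxes (each named after one rate constant):

    * autotrophs: growth ``λ_max·min(light, nutrient)·θ(T)·A``, respiration
      ``K_r·A``, transfer ``K_ml·A`` to the heterotroph pool;
    * heterotrophs: sedimentation ``K_s·H``, decomposition ``K_d·H``;
    * nitrogen: phytoplankton demand ``K_an·growth`` met first by fixation
      ``K_n·A`` (atmospheric) then by dissolved uptake; sediment release
      ``K_sn·N_s``; decomposition return ``K_hn·K_d·H``; settling organic N
      ``K_hn·K_s·H`` into sediment; atmospheric loss ``K_nl·N_w``; fish
      excretion ``K_fn·consumption`` back to water;
    * phosphorus: uptake ``K_ap·growth``; sediment release at velocity
      ``K_pr`` and dissolved-P sedimentation at velocity ``K_ps`` (both
      converted to first-order rates via the water depth); decomposition
      and settling analogous to N;
    * monsoon days add ``F_inputs`` of the reference dissolved stocks;
    * fish consumption is removed from A and H proportionally to pool size.

    Consumption is capped at the available food; all pools are floored at
    zero (flooring events indicate the daily step overshooting a small
    pool and are the mass-balance diagnostic to watch).
    """
    F_avail = state.A + state.H
    consumption = min(float(consumption_kcal), F_avail)
    if consumption < 0:
        raise ValueError("consumption must be non-negative")

    vol_m3 = params.volume_L / 1000.0  # mg/L ↔ g conversions: g = (mg/L)·vol_m3
    theta = temperature_factor(T, params)
    phi = nutrient_limitation(state.N_w, state.P_w, params)
    lam = light_factor(state.A, state.H, photoperiod, params)

    # all plankton/microbial rates share the temperature response: winter
    # slows production and turnover alike, so the pools persist year-round
    growth = params.lambda_max * min(lam, phi) * theta * state.A      # kcal/d
    # daily-step guard: new production cannot take up more N or P than the
    # dissolved pools hold (the continuous system never would; the 1-day
    # Euler step can overshoot on a fast-draining pool)
    if params.K_an > 0:
        growth = min(growth, 0.8 * state.N_w * vol_m3 / params.K_an)
    if params.K_ap > 0:
        growth = min(growth, 0.8 * state.P_w * vol_m3 / params.K_ap)
    respiration = params.K_r * theta * state.A
    transfer = params.K_ml * theta * state.A
    sedimentation_H = params.K_s * theta * state.H
    decomposition = params.K_d * theta * state.H

    # fish consumption split across A and H proportionally
    if F_avail > 0:
        cons_A = consumption * state.A / F_avail
        cons_H = consumption * state.H / F_avail
    else:
        cons_A = cons_H = 0.0

    # --- nitrogen budget (g/day) ---
    n_demand = params.K_an * growth
    loss_N_air = params.K_nl * state.N_w * vol_m3
    # atmospheric fixation meets part of the demand, but never beyond the
    # concurrent loss to air: the atmosphere is not a net N source, keeping
    # the pond inventory non-increasing in the closed (no-monsoon) system
    fixation = min(params.K_n * state.A, n_demand, loss_N_air)
    uptake_N = n_demand - fixation                   # from dissolved pool
    release_N = params.K_sn * theta * state.N_s
    return_N = params.K_hn * decomposition
    settle_N = params.K_hn * sedimentation_H
    loss_N = loss_N_air
    excretion_N = params.K_fn * consumption

    # --- phosphorus budget (g/day) ---
    uptake_P = params.K_ap * growth
    release_P = (params.K_pr / params.depth_m) * theta * state.P_s
    settle_Pw = (1.0 - np.exp(-params.K_ps / params.depth_m)) * state.P_w * vol_m3
    return_P = params.K_hp * decomposition
    settle_P = params.K_hp * sedimentation_H
    excretion_P = 0.0  # fish P retention; P returns only via the detrital path

    # combined outflux on a dissolved pool may not exceed the stock
    out_N = uptake_N + loss_N
    if out_N > state.N_w * vol_m3 > 0:
        scale = state.N_w * vol_m3 / out_N
        uptake_N *= scale
        loss_N *= scale
    out_P = uptake_P + settle_Pw
    if out_P > state.P_w * vol_m3 > 0:
        scale = state.P_w * vol_m3 / out_P
        uptake_P *= scale
        settle_Pw *= scale

    monsoon_N = params.F_inputs * params.N_ref_g if monsoon else 0.0
    monsoon_P = params.F_inputs * params.P_ref_g if monsoon else 0.0

    raw = {
        "A": state.A + growth - respiration - transfer - cons_A,
        "H": state.H + transfer - sedimentation_H - decomposition - cons_H,
        "N_w": state.N_w
        + (release_N + return_N + excretion_N + monsoon_N - uptake_N - loss_N) / vol_m3,
        "P_w": state.P_w
        + (release_P + return_P + excretion_P + monsoon_P - uptake_P - settle_Pw) / vol_m3,
        "N_s": state.N_s + settle_N - release_N,
        "P_s": state.P_s + settle_P + settle_Pw - release_P,
    }
    overshoot = {k: v for k, v in raw.items() if v < -1e-9}
    if overshoot:
        logger.warning("food pools floored at 0 (daily step overshoot): %s", overshoot)
    return FoodState(**{k: max(v, 0.0) for k, v in raw.items()})
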