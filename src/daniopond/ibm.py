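"""Spatial individual-based model of a zebrafish pond population.

The pond is a 30 × 30 grid of 20 × 20 cm patches (36 m², 0.5 m deep) of
three habitat types: vegetation cover (juvenile refuge), breeding grounds
(male territories) and open water.  Fish agents carry a DEB state and move
daily; broods (egg–larvae agents) sit on their spawning patch accumulating
degree-days until hatching.  The daily schedule is fixed:

1. environment update — temperature, photoperiod, fish biomass, the food
   sub-model step and the shared population functional response ``f``;
2. movement, agents in uniformly random order (juveniles seek vegetation,
   males seek free breeding territories, spawning-ready females seek free
   territorial males);
3. survival challenges (size-allometric + density-dependent + senescent
   mortality; egg predation is handled with the broods);
4. DEB growth of survivors (10 Euler substeps) at individual effective f;
5. brood degree-day update and hatching, puberty transitions, spawning;
6. daily summary row appended.

The population is stored structure-of-arrays for throughput; agent-level
views are available for inspection.  Every run is reproducible from its
seed, and a census identity (today's count = yesterday's + hatched − died)
is asserted every day.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from . import environment as env_mod
from . import food as food_mod
from .deb import DEBParams, compound_parameters, length_mass, temperature_correction
from .environment import EnvironmentSeries
from .food import FoodParams, FoodState

__all__ = [
    "IBMParams",
    "PondGrid",
    "PopulationState",
    "init_population",
    "daily_step",
    "move_agents",
    "mortality_probability",
    "egg_step",
    "hatch_success",
    "brood_male_fraction",
    "puberty_and_spawn",
    "length_histogram",
    "run_ibm",
]

JUVENILE, FEMALE, MALE = 0, 1, 2
OPEN, VEGETATION, BREEDING = 0, 1, 2


@dataclass(frozen=True)
class IBMParams:
    """Population-model constants (pond geometry, survival, reproduction)."""

    W_d: float = 0.5          # m water depth
    W_v: float = 18.0         # m³ water volume
    Np_b: int = 207           # breeding-ground patches
    Np_v: int = 207           # vegetation patches
    Nb_j: int = 300           # initial juveniles
    Nb_m: int = 35            # initial males
    Nb_f: int = 35            # initial females
    End: int = 1110           # d simulation duration
    sigma: float = 0.235      # inter-individual energy-acquisition log-sd
    P_tau: float = 12.0       # h photoperiod reproduction threshold
    T_tau: float = 22.5       # °C temperature reproduction threshold
    H_half: float = 24.0      # g m⁻³ female density halving hatching
    H_max: float = 0.89       # optimal hatching rate
    R_tau: int = 263          # eggs per spawn
    SR_mu: float = 50.0       # sex-ratio genetic mean (% males)
    SR_sigma: float = 23.1    # sex-ratio genetic sd
    SR_a: float = -0.0496     # °C⁻¹ temperature slope on sex ratio
    SR_b: float = 27.9        # °C neutral temperature for sex ratio
    pi_a: float = 0.0292      # d⁻¹ natural mortality scale
    pi_b: float = -0.3820     # allometric mortality exponent
    pi_c: float = 0.9576      # d⁻¹ density-independent mortality constant
    pi_d: float = 0.0089      # density-dependent mortality constant
    pi_p: float = 0.025       # d⁻¹ egg predation probability
    pi_e: float = 2.839e-06   # d⁻¹ per day senescent mortality slope
    pi_g: float = 550.0       # d senescence onset age
    H_a: float = 60.9         # °C·d degree-days to hatch
    H_b: float = 10.3         # °C degree-day base temperature
    grid_size: int = 30
    deb_substeps: int = 10

    def replace(self, **kwargs) -> "IBMParams":
        return replace(self, **kwargs)


class PondGrid:
    """Habitat layout and precomputed Moore-neighbourhood tables."""

    def __init__(self, params: IBMParams, rng: np.random.Generator):
        n = params.grid_size
        self.n = n
        n_patches = n * n
        habitat = np.zeros(n_patches, dtype=np.int8)
        special = rng.choice(n_patches, size=params.Np_v + params.Np_b, replace=False)
        habitat[special[: params.Np_v]] = VEGETATION
        habitat[special[params.Np_v:]] = BREEDING
        self.habitat = habitat
        self.territory_owner = np.full(n_patches, -1, dtype=np.int64)

        # Moore neighbourhoods (pond edges do not wrap)
        neigh = np.full((n_patches, 8), -1, dtype=np.int32)
        counts = np.zeros(n_patches, dtype=np.int32)
        for r in range(n):
            for c in range(n):
                p = r * n + c
                k = 0
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        if dr == 0 and dc == 0:
                            continue
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < n and 0 <= cc < n:
                            neigh[p, k] = rr * n + cc
                            k += 1
                counts[p] = k
        self.neigh = neigh
        self.neigh_count = counts

        # vegetation / breeding patches reachable from each patch (self incl.
        # for breeding: a male standing on a free breeding patch may claim it)
        self.veg_neigh, self.veg_count = self._filtered(neigh, counts, VEGETATION, include_self=False)
        self.breed_neigh, self.breed_count = self._filtered(neigh, counts, BREEDING, include_self=True)

    def _filtered(self, neigh, counts, habitat_code, include_self):
        n_patches = neigh.shape[0]
        out = np.full((n_patches, 9), -1, dtype=np.int32)
        out_counts = np.zeros(n_patches, dtype=np.int32)
        for p in range(n_patches):
            k = 0
            if include_self and self.habitat[p] == habitat_code:
                out[p, k] = p
                k += 1
            for j in range(counts[p]):
                q = neigh[p, j]
                if self.habitat[q] == habitat_code:
                    out[p, k] = q
                    k += 1
            out_counts[p] = k
        return out, out_counts

    def set_habitat(self, habitat: np.ndarray) -> None:
        """Replace the habitat map and rebuild the neighbourhood tables."""
        self.habitat = np.asarray(habitat, dtype=np.int8)
        self.veg_neigh, self.veg_count = self._filtered(
            self.neigh, self.neigh_count, VEGETATION, include_self=False
        )
        self.breed_neigh, self.breed_count = self._filtered(
            self.neigh, self.neigh_count, BREEDING, include_self=True
        )

    def random_neighbor(self, patches: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        idx = (rng.random(patches.size) * self.neigh_count[patches]).astype(np.int64)
        return self.neigh[patches, idx]


@dataclass
class PopulationState:
    """Structure-of-arrays population state plus grid, food and summaries."""

    day: int
    grid: PondGrid
    food: FoodState
    rng: np.random.Generator
    seed: int
    # fish arrays (aligned)
    stage: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int8))
    age: np.ndarray = field(default_factory=lambda: np.empty(0))
    generation: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    e: np.ndarray = field(default_factory=lambda: np.empty(0))
    l: np.ndarray = field(default_factory=lambda: np.empty(0))
    R: np.ndarray = field(default_factory=lambda: np.empty(0))
    scatter: np.ndarray = field(default_factory=lambda: np.empty(0))
    patch: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    latent_male: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=bool))
    territory: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    satiety: np.ndarray = field(default_factory=lambda: np.empty(0))
    # brood arrays (aligned)
    brood_eggs: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    brood_age: np.ndarray = field(default_factory=lambda: np.empty(0))
    brood_dd: np.ndarray = field(default_factory=lambda: np.empty(0))
    brood_patch: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))
    brood_gen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int32))
    brood_genetic: np.ndarray = field(default_factory=lambda: np.empty(0))  # G draw, % males
    brood_Tsum: np.ndarray = field(default_factory=lambda: np.empty(0))
    summaries: list = field(default_factory=list)

    @property
    def n_fish(self) -> int:
        return self.stage.size

    @property
    def n_broods(self) -> int:
        return self.brood_eggs.size

    def lengths(self, deb: DEBParams) -> np.ndarray:
        """Physical standard lengths (mm)."""
        return self.l * compound_parameters(deb).L_inf

    def masses(self, deb: DEBParams) -> np.ndarray:
        """Wet masses (mg)."""
        if self.n_fish == 0:
            return np.empty(0)
        return length_mass(self.lengths(deb))

    def biomass_g(self, deb: DEBParams) -> float:
        return float(np.sum(self.masses(deb))) / 1000.0

    def agents(self, deb: DEBParams) -> pd.DataFrame:
        """Agent-level view of the fish population."""
        return pd.DataFrame(
            {
                "stage": np.array(["juvenile", "female", "male"])[self.stage],
                "age": self.age,
                "generation": self.generation,
                "e": self.e,
                "l": self.l,
                "length_mm": self.lengths(deb),
                "mass_mg": self.masses(deb),
                "egg_buffer": self.R,
                "scatter": self.scatter,
                "patch": self.patch,
                "satiety": self.satiety,
                "territory": self.territory,
            }
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.summaries)


def init_population(
    deb: DEBParams,
    ibm: IBMParams,
    food_params: FoodParams,
    seed: int,
    food_state: FoodState | None = None,
) -> PopulationState:
    """Founding population: 300 juveniles + 35 males + 35 females.

    Fish are placed uniformly at random; juvenile scaled lengths are drawn
    between first feeding and puberty, adult ones above puberty; each fish
    receives a lognormal energy-acquisition scatter (median 1).
    """
    rng = np.random.default_rng(seed)
    grid = PondGrid(ibm, rng)
    n = ibm.Nb_j + ibm.Nb_m + ibm.Nb_f
    state = PopulationState(
        day=0,
        grid=grid,
        food=food_state.copy() if food_state is not None else FoodState(),
        rng=rng,
        seed=seed,
    )
    stage = np.concatenate(
        [
            np.full(ibm.Nb_j, JUVENILE, dtype=np.int8),
            np.full(ibm.Nb_m, MALE, dtype=np.int8),
            np.full(ibm.Nb_f, FEMALE, dtype=np.int8),
        ]
    )
    l = np.where(
        stage == JUVENILE,
        rng.uniform(deb.l_b, deb.l_p, n),
        rng.uniform(deb.l_p, 0.92, n),
    )
    state.stage = stage
    state.l = l
    state.e = rng.uniform(0.8, 1.0, n)
    state.R = np.where(stage == FEMALE, rng.uniform(0, ibm.R_tau, n), 0.0)
    state.age = np.where(stage == JUVENILE, rng.uniform(20, 150, n), rng.uniform(200, 500, n))
    state.generation = np.zeros(n, dtype=np.int32)
    state.scatter = rng.lognormal(mean=0.0, sigma=ibm.sigma, size=n)
    state.patch = rng.integers(0, grid.habitat.size, n)
    state.latent_male = np.concatenate(
        [
            rng.random(ibm.Nb_j) < 0.5,
            np.ones(ibm.Nb_m, dtype=bool),
            np.zeros(ibm.Nb_f, dtype=bool),
        ]
    )
    state.territory = np.full(n, -1, dtype=np.int64)
    state.satiety = np.zeros(n)
    return state


def mortality_probability(
    mass_mg,
    stage,
    age,
    biomass_density,
    params: IBMParams = IBMParams(),
):
    """Daily death probability per fish.

    ``m = π_a·π_c·W^π_b  +  π_d·D (juveniles)  +  π_e·(age − π_g)⁺``,
    with W the wet mass (mg) and D the total fish biomass density (g m⁻³),
    clamped to [0, 1].  The allometric term is Lorenzen-type: small fish
    die faster.
    """
    W = np.asarray(mass_mg, dtype=float)
    stage = np.asarray(stage)
    age = np.asarray(age, dtype=float)
    m = params.pi_a * params.pi_c * W ** params.pi_b
    m = m + np.where(stage == JUVENILE, params.pi_d * float(biomass_density), 0.0)
    m = m + np.where(age > params.pi_g, params.pi_e * (age - params.pi_g), 0.0)
    out = np.clip(m, 0.0, 1.0)
    return out if out.ndim else float(out)


def hatch_success(female_density, params: IBMParams = IBMParams()):
    """Hatching probability, halved at female density H_half (g m⁻³)."""
    d = np.asarray(female_density, dtype=float)
    if np.any(d < 0):
        raise ValueError("female density must be non-negative")
    out = params.H_max * params.H_half / (params.H_half + d)
    return out if out.ndim else float(out)


def brood_male_fraction(
    T_mean,
    params: IBMParams = IBMParams(),
    rng: np.random.Generator | None = None,
    genetic: float | np.ndarray | None = None,
):
    """Male fraction of a brood from genetics and incubation temperature.

    ``p = clamp₀¹(G/100 + SR_a·(T_mean − SR_b))`` with the genetic
    component ``G ~ Normal(SR_mu, SR_sigma)`` truncated to [0, 100].
    ``genetic`` bypasses the draw (used when G was drawn at spawning).
    """
    if genetic is None:
        rng = rng if rng is not None else np.random.default_rng()
        genetic = _truncated_normal(rng, params.SR_mu, params.SR_sigma, 0.0, 100.0, np.shape(T_mean))
    p = np.asarray(genetic, dtype=float) / 100.0 + params.SR_a * (np.asarray(T_mean, dtype=float) - params.SR_b)
    out = np.clip(p, 0.0, 1.0)
    return out if out.ndim else float(out)


def _truncated_normal(rng, mu, sigma, lo, hi, shape):
    if sigma == 0:
        return np.full(shape, float(np.clip(mu, lo, hi)))
    out = rng.normal(mu, sigma, shape)
    bad = (out < lo) | (out > hi)
    while np.any(bad):
        out = np.where(bad, rng.normal(mu, sigma, shape), out)
        bad = (out < lo) | (out > hi)
    return out


# ---------------------------------------------------------------------------
# daily DEB kernel (10 Euler substeps over the whole population at once)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _deb_day_kernel(e, l, R, f_ind, is_repro_female, cT, g, k_M, R_M,
                    alpha, l_b, l_p, l_f, substeps):  # pragma: no cover
    h = 1.0 / substeps
    lp3 = l_p ** 3
    lf3 = l_f ** 3
    for i in range(e.size):
        ei = e[i]
        li = l[i]
        Ri = R[i]
        fi = f_ind[i]
        for _ in range(substeps):
            li3 = li * li * li
            s_f = alpha * lf3 / (li3 + lf3)
            fe = 0.0 if li < l_b else fi
            de = cT * k_M * g / li * ((1.0 - s_f) * fe - ei)
            r_B = cT * k_M * g / (3.0 * (ei + g))
            dl = r_B * (ei - li)
            dR = 0.0
            if is_repro_female[i] and li >= l_p:
                dR = R_M / (1.0 - lp3) * ((g + li) / (g + ei) * ei * li * li - lp3)
                dR = cT * dR if dR > 0.0 else 0.0
            ei = max(ei + h * de, 0.0)
            li = max(li + h * dl, 1e-4)
            Ri = Ri + h * dR
        e[i] = ei
        l[i] = li
        R[i] = Ri


def move_agents(state: PopulationState, deb: DEBParams, ibm: IBMParams,
                window_open: bool) -> None:
    """One movement round.

    Juveniles not on vegetation step to a random vegetated Moore neighbour
    (random neighbour if none); territory-less males claim a free breeding
    patch in their neighbourhood (exclusively, first in random order wins)
    or move randomly; spawning-ready females jump to a neighbouring patch
    held by a free territorial male if any; other adults move randomly.
    Territory holders stay put.
    """
    grid = state.grid
    rng = state.rng
    if state.n_fish == 0:
        return

    # juveniles (no interactions): vectorised
    juv = np.flatnonzero(state.stage == JUVENILE)
    if juv.size:
        p = state.patch[juv]
        on_veg = grid.habitat[p] == VEGETATION
        movers = juv[~on_veg]
        if movers.size:
            pm = state.patch[movers]
            vc = grid.veg_count[pm]
            has_veg = vc > 0
            tgt = grid.random_neighbor(pm, rng)
            idx = (rng.random(movers.size) * np.maximum(vc, 1)).astype(np.int64)
            veg_tgt = grid.veg_neigh[pm, idx]
            state.patch[movers] = np.where(has_veg, veg_tgt, tgt)

    # adults, in uniformly random order (territory claiming is exclusive)
    adults = np.flatnonzero(state.stage != JUVENILE)
    if adults.size == 0:
        return
    order = rng.permutation(adults)
    habitat = grid.habitat
    owner = grid.territory_owner
    ready = (state.stage == FEMALE) & (state.R >= ibm.R_tau) & window_open
    for i in order:
        p = state.patch[i]
        if state.stage[i] == MALE:
            if state.territory[i] >= 0:
                continue
            nb = grid.breed_neigh[p]
            cnt = grid.breed_count[p]
            free = [nb[j] for j in range(cnt) if owner[nb[j]] < 0]
            if free:
                q = free[int(rng.integers(len(free)))]
                owner[q] = i
                state.territory[i] = q
                state.patch[i] = q
            else:
                state.patch[i] = grid.neigh[p, int(rng.integers(grid.neigh_count[p]))]
        else:  # female
            if ready[i]:
                nb = grid.neigh[p]
                cnt = grid.neigh_count[p]
                cand = [nb[j] for j in range(cnt) if owner[nb[j]] >= 0]
                if cand:
                    state.patch[i] = cand[int(rng.integers(len(cand)))]
                    continue
            state.patch[i] = grid.neigh[p, int(rng.integers(grid.neigh_count[p]))]


def _remove_fish(state: PopulationState, keep: np.ndarray) -> None:
    """Drop fish not in ``keep`` (boolean mask), releasing their territories."""
    # territory_owner is rebuilt from scratch after compaction
    for name in ("stage", "age", "generation", "e", "l", "R", "scatter",
                 "patch", "latent_male", "territory", "satiety"):
        setattr(state, name, getattr(state, name)[keep])
    owned = state.territory >= 0
    state.grid.territory_owner[:] = -1
    state.grid.territory_owner[state.territory[owned]] = np.flatnonzero(owned)


def egg_step(state: PopulationState, T: float, deb: DEBParams, ibm: IBMParams) -> int:
    """Predation, degree-day accumulation and hatching for every brood.

    Each day the surviving egg count is binomially thinned at the egg
    predation rate and the brood accumulates ``(T − H_b)⁺`` degree-days.
    At ``H_a`` accumulated degree-days the brood hatches: the hatchling
    count is the surviving eggs times the female-density-dependent hatching
    success, each hatchling entering as a juvenile at the first-feeding
    length with full reserves and a latent sex drawn from the brood's male
    fraction.  Returns the number of hatchlings added.
    """
    if state.n_broods == 0:
        return 0
    rng = state.rng
    state.brood_eggs = rng.binomial(state.brood_eggs, 1.0 - ibm.pi_p)
    state.brood_age = state.brood_age + 1.0
    state.brood_dd = state.brood_dd + max(0.0, T - ibm.H_b)
    state.brood_Tsum = state.brood_Tsum + T

    hatch = state.brood_dd >= ibm.H_a
    empty = state.brood_eggs <= 0
    n_hatched = 0
    if np.any(hatch):
        fem = state.stage == FEMALE
        fem_density = float(np.sum(state.masses(deb)[fem])) / 1000.0 / ibm.W_v
        success = hatch_success(fem_density, ibm)
        idx = np.flatnonzero(hatch & ~empty)
        n_new = np.round(state.brood_eggs[idx] * success).astype(np.int64)
        live = n_new > 0
        idx, n_new = idx[live], n_new[live]
        if idx.size:
            T_mean = state.brood_Tsum[idx] / state.brood_age[idx]
            p_male = brood_male_fraction(T_mean, ibm, genetic=state.brood_genetic[idx])
            n_hatched = int(np.sum(n_new))
            _add_fish(
                state,
                n=n_hatched,
                stage=JUVENILE,
                l=deb.l_b,
                patch=np.repeat(state.brood_patch[idx], n_new),
                generation=np.repeat(state.brood_gen[idx], n_new),
                latent_male=rng.random(n_hatched) < np.repeat(np.atleast_1d(p_male), n_new),
                scatter=rng.lognormal(0.0, ibm.sigma, n_hatched),
            )
    keep = ~(hatch | empty)
    for name in ("brood_eggs", "brood_age", "brood_dd", "brood_patch",
                 "brood_gen", "brood_genetic", "brood_Tsum"):
        setattr(state, name, getattr(state, name)[keep])
    return n_hatched


def _add_fish(state, n, stage, l, patch, generation, latent_male, scatter):
    patch = np.broadcast_to(np.asarray(patch, dtype=np.int64), (n,))
    generation = np.broadcast_to(np.asarray(generation, dtype=np.int32), (n,))
    state.stage = np.concatenate([state.stage, np.full(n, stage, dtype=np.int8)])
    state.age = np.concatenate([state.age, np.zeros(n)])
    state.generation = np.concatenate([state.generation, generation])
    state.e = np.concatenate([state.e, np.ones(n)])
    state.l = np.concatenate([state.l, np.full(n, float(l))])
    state.R = np.concatenate([state.R, np.zeros(n)])
    state.scatter = np.concatenate([state.scatter, scatter])
    state.patch = np.concatenate([state.patch, patch])
    state.latent_male = np.concatenate([state.latent_male, latent_male])
    state.territory = np.concatenate([state.territory, np.full(n, -1, dtype=np.int64)])
    state.satiety = np.concatenate([state.satiety, np.zeros(n)])


def puberty_and_spawn(
    state: PopulationState,
    T: float,
    window_open: bool,
    deb: DEBParams,
    ibm: IBMParams,
) -> int:
    """Puberty transitions, then spawning; returns the number of new broods.

    Juveniles at or past the puberty length reveal their latent sex.  A
    female whose egg buffer holds at least one clutch, inside the
    reproduction window and standing on the patch of a free territorial
    male, spawns exactly one clutch of ``R_tau`` eggs (buffer keeps the
    remainder); each territorial male mates at most once per day.
    """
    rng = state.rng
    mature = (state.stage == JUVENILE) & (state.l >= deb.l_p)
    if np.any(mature):
        state.stage[mature] = np.where(state.latent_male[mature], MALE, FEMALE)

    if not window_open:
        return 0
    owner = state.grid.territory_owner
    ready = np.flatnonzero((state.stage == FEMALE) & (state.R >= ibm.R_tau))
    if ready.size == 0:
        return 0
    mated_today: set[int] = set()
    n_spawn = 0
    for i in rng.permutation(ready):
        p = state.patch[i]
        male_idx = owner[p]
        if male_idx < 0 or male_idx in mated_today:
            continue
        mated_today.add(int(male_idx))
        state.R[i] -= ibm.R_tau
        G = _truncated_normal(rng, ibm.SR_mu, ibm.SR_sigma, 0.0, 100.0, ())
        state.brood_eggs = np.concatenate([state.brood_eggs, [ibm.R_tau]]).astype(np.int64)
        state.brood_age = np.concatenate([state.brood_age, [0.0]])
        state.brood_dd = np.concatenate([state.brood_dd, [0.0]])
        state.brood_patch = np.concatenate([state.brood_patch, [p]]).astype(np.int64)
        state.brood_gen = np.concatenate(
            [state.brood_gen, [state.generation[i] + 1]]
        ).astype(np.int32)
        state.brood_genetic = np.concatenate([state.brood_genetic, [float(G)]])
        state.brood_Tsum = np.concatenate([state.brood_Tsum, [0.0]])
        n_spawn += 1
    return n_spawn


def daily_step(
    state: PopulationState,
    env: EnvironmentSeries,
    deb: DEBParams,
    ibm: IBMParams,
    food_params: FoodParams,
    monsoon_window: tuple = env_mod.MONSOON_WINDOW,
    start_day_of_year: int = 121,
) -> None:
    """Advance the population by one day following the fixed schedule."""
    day = state.day + 1
    T, photoperiod = env_mod.conditions_at(env, day)
    window_open = env_mod.reproduction_window(T, photoperiod, ibm.T_tau, ibm.P_tau)
    monsoon = env_mod.monsoon_active(day, monsoon_window, start_day_of_year)
    comp = compound_parameters(deb)
    cT = temperature_correction(T, deb)

    n_before = state.n_fish

    # (1) environment, food and the shared functional response
    masses = state.masses(deb)
    biomass_g = float(np.sum(masses)) / 1000.0
    F_total = state.food.A + state.food.H
    f_pop = food_mod.population_f(F_total, food_params.G2Kcal * biomass_g, food_params)
    if state.n_fish:
        s_f = deb.alpha * (1.0 - 1.0 / (1.0 + (deb.l_f / state.l) ** 3))
        # maximum assimilation (J/d) summed over fish, converted to kcal
        demand_kcal = cT * deb.p_Am * float(np.sum((1.0 - s_f) * (state.l * comp.L_m) ** 2)) / food_mod.J_PER_KCAL
    else:
        demand_kcal = 0.0
    consumption = f_pop * demand_kcal
    state.food = food_mod.step_food_day(state.food, T, photoperiod, consumption, monsoon, food_params)

    # (2) movement
    move_agents(state, deb, ibm, bool(window_open))

    # (3) survival
    n_died = 0
    if state.n_fish:
        density = biomass_g / ibm.W_v
        m = mortality_probability(masses, state.stage, state.age, density, ibm)
        survive = state.rng.random(state.n_fish) >= m
        n_died = int(np.sum(~survive))
        if n_died:
            _remove_fish(state, survive)

    # (4) DEB growth of survivors
    if state.n_fish:
        is_male_adult = state.stage == MALE
        f_ind = np.clip(
            state.scatter * f_pop * np.where(is_male_adult, deb.f_lim, 1.0), 0.0, 1.0
        )
        state.satiety = f_ind
        is_repro_female = state.stage == FEMALE
        _deb_day_kernel(
            state.e, state.l, state.R, f_ind, is_repro_female,
            cT, comp.g, comp.k_M, deb.R_M,
            deb.alpha, deb.l_b, deb.l_p, deb.l_f, ibm.deb_substeps,
        )
        state.age = state.age + 1.0

    # (5) broods hatch, puberty, spawning
    n_hatched = egg_step(state, T, deb, ibm)
    puberty_and_spawn(state, T, bool(window_open), deb, ibm)

    # census identity
    if state.n_fish != n_before - n_died + n_hatched:
        raise AssertionError(
            f"census violation on day {day}: {n_before} - {n_died} + {n_hatched} "
            f"!= {state.n_fish}"
        )

    # (6) summaries
    lengths = state.lengths(deb)
    juv = state.stage == JUVENILE
    fem = state.stage == FEMALE
    mal = state.stage == MALE
    state.summaries.append(
        {
            "day": day,
            "temperature": T,
            "photoperiod": photoperiod,
            "window_open": bool(window_open),
            "monsoon": bool(monsoon),
            "n_fish": state.n_fish,
            "n_juveniles": int(np.sum(juv)),
            "n_females": int(np.sum(fem)),
            "n_males": int(np.sum(mal)),
            "n_broods": state.n_broods,
            "n_hatched": n_hatched,
            "n_died": n_died,
            "biomass_g": state.biomass_g(deb),
            "mean_length_juv": float(np.mean(lengths[juv])) if np.any(juv) else np.nan,
            "mean_length_fem": float(np.mean(lengths[fem])) if np.any(fem) else np.nan,
            "mean_length_mal": float(np.mean(lengths[mal])) if np.any(mal) else np.nan,
            "f": f_pop,
            "frac_le_15mm": float(np.mean(lengths <= 15.0)) if lengths.size else np.nan,
            "food_A": state.food.A,
            "food_H": state.food.H,
            "N_w": state.food.N_w,
            "P_w": state.food.P_w,
            "N_s": state.food.N_s,
            "P_s": state.food.P_s,
        }
    )
    state.day = day


def length_histogram(
    lengths_mm: np.ndarray,
    min_length: float = 18.4,
    bin_width: float = 1.0,
    max_length: float = 60.0,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Normalised length-frequency histogram above a sampling cutoff.

    Returns ``(bin_lower_edges, frequencies, excluded_fraction)``; bins are
    half-open ``[k, k + bin)`` so a fish exactly on an edge falls in the
    upper class.  Frequencies sum to 1 whenever any fish passes the cutoff;
    the excluded fraction is the share of fish at or below ``min_length``.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    lengths_mm = np.asarray(lengths_mm, dtype=float)
    if lengths_mm.size == 0:
        return np.arange(0.0, max_length, bin_width), np.zeros(int(max_length / bin_width)), np.nan
    excluded = float(np.mean(lengths_mm <= min_length))
    kept = lengths_mm[lengths_mm > min_length]
    edges = np.arange(0.0, max_length + bin_width, bin_width)
    counts, _ = np.histogram(kept, bins=edges)
    freq = counts / counts.sum() if counts.sum() else counts.astype(float)
    return edges[:-1], freq, excluded


def run_ibm(
    deb: DEBParams | None = None,
    ibm: IBMParams | None = None,
    food_params: FoodParams | None = None,
    env: EnvironmentSeries | None = None,
    n_days: int | None = None,
    seed: int = 0,
    food_state: FoodState | None = None,
    start_day_of_year: int = 121,
    monsoon_window: tuple = env_mod.MONSOON_WINDOW,
) -> PopulationState:
    """Initialise and run one replicate for ``n_days`` (default: End)."""
    deb = deb if deb is not None else DEBParams()
    ibm = ibm if ibm is not None else IBMParams()
    food_params = food_params if food_params is not None else FoodParams()
    n_days = n_days if n_days is not None else ibm.End
    if env is None:
        env = env_mod.generate_monsoon_scenario(
            years=max(1, int(np.ceil(n_days / 365))), start_day_of_year=start_day_of_year
        )
    state = init_population(deb, ibm, food_params, seed, food_state)
    for _ in range(n_days):
        daily_step(state, env, deb, ibm, food_params, monsoon_window, start_day_of_year)
    return state
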