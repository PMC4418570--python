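"""Organism-level dynamic energy budget (DEB) model for zebrafish.

The model is a food-limited, fixed-size-at-puberty variant of the standard
DEB framework.  State is reduced to three variables: the scaled reserve
density ``e`` (-), the scaled length ``l = L / L_inf`` (-), and the egg
buffer ``R`` (cumulative unspawned eggs).  Growth follows a von Bertalanffy
approach to the asymptote, made sigmoid in physical length by a
size-dependent ingestion reduction ``s_f(l)``: small fish can only access a
fraction of the food they encounter, which replaces the metabolic
acceleration hypothesis of earlier zebrafish DEB models.

All rates respond to water temperature through an Arrhenius factor applied
to the primary rate parameters (assimilation ``{p_Am}``, conductance
``v_dot`` and somatic maintenance ``[p_M]``); the compound ratios ``g`` and
``E_m`` are therefore temperature-invariant.

Every rate function accepts scalar or ``numpy`` array state, so the same
code drives single-fish trajectories and the vectorised population model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

__all__ = [
    "DEBParams",
    "CompoundParams",
    "DEBState",
    "temperature_correction",
    "compound_parameters",
    "ingestion_reduction",
    "reserve_rate",
    "growth_rate",
    "reproduction_rate",
    "effective_f",
    "step_deb",
    "length_mass",
    "mass_length",
    "simulate_trajectory",
]

#: smallest scaled length the integrator will ever produce
L_FLOOR = 1e-4

#: default allometric constants (natural-log convention, W in mg, L in mm)
W_A = 3.205
W_B = -5.193


@dataclass(frozen=True)
class DEBParams:
    """Primary DEB parameters.

    Defaults are the calibrated zebrafish values.  Units: ``T_A``, ``T_R``
    in K; ``p_Am`` J d⁻¹ mm⁻²; ``v_dot`` mm d⁻¹; ``p_M`` J d⁻¹ mm⁻³;
    ``E_G`` J mm⁻³; ``E_0`` J; ``L_0`` mm; ``R_M`` eggs d⁻¹; the rest
    dimensionless.
    """

    T_A: float = 3000.0
    T_R: float = 293.0
    delta: float = 0.20
    p_Am: float = 4.72
    v_dot: float = 0.60
    kappa: float = 0.70
    alpha: float = 0.84
    l_b: float = 0.079
    l_p: float = 0.58
    l_f: float = 0.163
    p_M: float = 0.44
    E_G: float = 2.35
    E_0: float = 1.25
    L_0: float = 0.25
    R_M: float = 406.0
    f_lim: float = 0.92

    def __post_init__(self) -> None:
        for name in (
            "T_A", "T_R", "delta", "p_Am", "v_dot", "kappa", "alpha",
            "l_b", "l_p", "l_f", "p_M", "E_G", "E_0", "L_0", "R_M", "f_lim",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"DEB parameter {name} must be finite and > 0, got {value!r}")
        for name in ("kappa", "alpha", "f_lim", "l_b", "l_p", "l_f"):
            if getattr(self, name) > 1.0:
                raise ValueError(f"DEB parameter {name} must lie in (0, 1], got {getattr(self, name)!r}")
        if not (self.l_b < self.l_f < self.l_p):
            raise ValueError(
                f"scaled lengths must satisfy l_b < l_f < l_p, got "
                f"l_b={self.l_b}, l_f={self.l_f}, l_p={self.l_p}"
            )

    def replace(self, **kwargs) -> "DEBParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class CompoundParams:
    """Derived (compound) DEB parameters."""

    g: float        #: energy investment ratio (-)
    k_M: float      #: maintenance rate coefficient (d⁻¹)
    E_m: float      #: maximum reserve density (J mm⁻³)
    L_m: float      #: maximum structural length (mm)
    L_inf: float    #: maximum physical length (mm), L_m / delta


@dataclass
class DEBState:
    """Instantaneous DEB state of one fish (or an array of fish).

    ``e`` scaled reserve density, ``l`` scaled length, ``R`` egg buffer
    (cumulative unspawned eggs).  All three may be scalars or equally-shaped
    numpy arrays; the boolean flags broadcast the same way.
    """

    e: float | np.ndarray = 1.0
    l: float | np.ndarray = 0.079
    R: float | np.ndarray = 0.0
    is_male: bool | np.ndarray = False
    past_puberty: bool | np.ndarray = False

    def validate(self) -> None:
        e, l, R = map(np.asarray, (self.e, self.l, self.R))
        if np.any(e < 0):
            raise ValueError("scaled reserve density e must be >= 0")
        if np.any(l <= 0) or np.any(l > 1.0 + 1e-9):
            raise ValueError("scaled length l must lie in (0, 1]")
        if np.any(R < 0):
            raise ValueError("egg buffer R must be >= 0")

    def copy(self) -> "DEBState":
        def _c(x):
            return np.array(x, copy=True) if isinstance(x, np.ndarray) else x
        return DEBState(_c(self.e), _c(self.l), _c(self.R), _c(self.is_male), _c(self.past_puberty))


def temperature_correction(T, params: DEBParams):
    """Arrhenius rate-correction factor at water temperature ``T`` (°C).

    ``exp(T_A / T_R − T_A / T_K)`` with ``T_K = T + 273.15``; equals 1 at
    the reference temperature.  Multiplies the rate parameters ``p_Am``,
    ``v_dot`` and ``p_M``.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError(f"water temperature must be finite, got {T!r}")
    if np.any(T <= -273.15):
        raise ValueError(f"water temperature below absolute zero: {T!r}")
    out = np.exp(params.T_A / params.T_R - params.T_A / (T + 273.15))
    return out if out.ndim else float(out)


def compound_parameters(params: DEBParams) -> CompoundParams:
    """Standard DEB compound parameters from the primary set."""
    E_m = params.p_Am / params.v_dot
    g = params.E_G / (params.kappa * E_m)
    k_M = params.p_M / params.E_G
    L_m = params.kappa * params.p_Am / params.p_M
    return CompoundParams(g=g, k_M=k_M, E_m=E_m, L_m=L_m, L_inf=L_m / params.delta)


def ingestion_reduction(l, params: DEBParams):
    """Size-dependent ingestion reduction ``s_f(l) = α·[1 − (1 + l_f³/l³)⁻¹]``.

    Strictly decreasing in ``l``; tends to ``α`` as ``l → 0`` and to 0 as
    ``l`` grows, so small fish assimilate only a fraction ``1 − s_f`` of
    their encounter rate.
    """
    l = np.asarray(l, dtype=float)
    if np.any(l <= 0):
        raise ValueError("scaled length must be > 0")
    out = params.alpha * (1.0 - 1.0 / (1.0 + (params.l_f / l) ** 3))
    return out if out.ndim else float(out)


def reserve_rate(state: DEBState, f, T, params: DEBParams):
    """Reserve dynamics de/dt = c_T·k_M·g/l · [(1 − s_f)·f − e].

    ``f`` is forced to zero below the first-feeding length ``l_b`` (mouth
    not yet open).
    """
    c = compound_parameters(params)
    l = np.asarray(state.l, dtype=float)
    if np.any(l == 0):
        raise ValueError("scaled length must be non-zero")
    f_eff = np.where(l < params.l_b, 0.0, np.asarray(f, dtype=float))
    cT = temperature_correction(T, params)
    out = cT * c.k_M * c.g / l * ((1.0 - ingestion_reduction(l, params)) * f_eff - state.e)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def growth_rate(state: DEBState, T, params: DEBParams):
    """Scaled-length growth dl/dt = r_B·(e − l), r_B = c_T·k_M·g / (3(e+g)).

    Negative when reserves fall below the current length (shrinking is
    allowed but floored by the integrator; starvation never kills).
    """
    c = compound_parameters(params)
    cT = temperature_correction(T, params)
    r_B = cT * c.k_M * c.g / (3.0 * (np.asarray(state.e, dtype=float) + c.g))
    out = np.asarray(r_B * (np.asarray(state.e) - np.asarray(state.l)))
    return out if out.ndim else float(out)


def reproduction_rate(state: DEBState, T, params: DEBParams):
    """Egg production rate (eggs d⁻¹) for a post-puberty female.

    ``dR/dt = c_T · R_M/(1−l_p³) · [(g+l)/(g+e) · e·l² − l_p³]``, clamped at
    zero from below, and exactly zero below the puberty length ``l_p``.
    Evaluates to ``R_M`` at (e, l) = (1, 1) at the reference temperature.
    """
    c = compound_parameters(params)
    e = np.asarray(state.e, dtype=float)
    l = np.asarray(state.l, dtype=float)
    lp3 = params.l_p ** 3
    raw = params.R_M / (1.0 - lp3) * ((c.g + l) / (c.g + e) * e * l * l - lp3)
    cT = temperature_correction(T, params)
    out = np.where(l < params.l_p, 0.0, np.maximum(raw, 0.0) * cT)
    out = np.asarray(out)
    return out if out.ndim else float(out)


def effective_f(f, state: DEBState, scatter=1.0, params: DEBParams | None = None):
    """Individual functional response from the population-level ``f``.

    Applies the per-fish energy-acquisition scatter and, for post-puberty
    males, the appetite factor ``f_lim``; the result is clamped to [0, 1].
    """
    params = params if params is not None else DEBParams()
    f = np.asarray(f, dtype=float)
    scatter = np.asarray(scatter, dtype=float)
    if np.any(f < 0) or np.any(f > 1):
        raise ValueError("population functional response f must lie in [0, 1]")
    if np.any(scatter <= 0):
        raise ValueError("scatter multiplier must be > 0")
    male_factor = np.where(
        np.logical_and(np.asarray(state.is_male), np.asarray(state.past_puberty)),
        params.f_lim,
        1.0,
    )
    out = np.clip(scatter * f * male_factor, 0.0, 1.0)
    return out if out.ndim else float(out)


def step_deb(
    state: DEBState,
    f,
    T,
    dt: float = 1.0,
    substeps: int = 10,
    params: DEBParams | None = None,
) -> DEBState:
    """Advance (e, l, R) over ``dt`` days by forward Euler in ``substeps`` steps.

    The default 10 substeps per day reproduce the 1/10-day DEB sub-step of
    the daily population model.  ``l`` is floored at a small positive value;
    ``R`` is non-decreasing (spawning is handled outside the integrator).
    """
    params = params if params is not None else DEBParams()
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    h = dt / substeps
    out = state.copy()
    for _ in range(substeps):
        de = reserve_rate(out, f, T, params)
        dl = growth_rate(out, T, params)
        dR = np.where(
            np.logical_and(np.logical_not(np.asarray(out.is_male)), np.asarray(out.past_puberty)),
            reproduction_rate(out, T, params),
            0.0,
        )
        out.e = np.maximum(np.asarray(out.e) + h * de, 0.0)
        out.l = np.maximum(np.asarray(out.l) + h * dl, L_FLOOR)
        out.R = np.asarray(out.R) + h * dR
        if out.e.ndim == 0:
            out.e, out.l, out.R = float(out.e), float(out.l), float(out.R)
    bad = ~np.isfinite(np.asarray(out.e)) | ~np.isfinite(np.asarray(out.l))
    if np.any(bad):
        raise FloatingPointError(
            f"non-finite DEB state after step: e={out.e!r}, l={out.l!r} (f={f!r}, T={T!r})"
        )
    return out


def length_mass(L, W_a: float = W_A, W_b: float = W_B):
    """Wet mass (mg) from standard length (mm): ``W = exp(W_a·ln L + W_b)``."""
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise ValueError("length must be > 0")
    out = np.exp(W_a * np.log(L) + W_b)
    return out if out.ndim else float(out)


def mass_length(W, W_a: float = W_A, W_b: float = W_B):
    """Standard length (mm) from wet mass (mg); exact inverse of length_mass."""
    W = np.asarray(W, dtype=float)
    if np.any(W <= 0):
        raise ValueError("mass must be > 0")
    out = np.exp((np.log(W) - W_b) / W_a)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fast scalar trajectory kernel (shared by calibration and sensitivity runs)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _trajectory_kernel(
    t_end, dt, e0, l0,
    T_A, T_R, alpha, l_b, l_p, l_f, g, k_M, R_M, T_c, f,
    out_days, out_l, out_R,
):  # pragma: no cover - exercised through simulate_trajectory
    cT = np.exp(T_A / T_R - T_A / (T_c + 273.15))
    e = e0
    l = l0
    R = 0.0
    n_steps = int(np.round(t_end / dt))
    idx = 0
    t = 0.0
    lp3 = l_p ** 3
    for step in range(n_steps + 1):
        while idx < out_days.size and t >= out_days[idx] - 1e-9:
            out_l[idx] = l
            out_R[idx] = R
            idx += 1
        if step == n_steps:
            break
        s_f = alpha * (1.0 - 1.0 / (1.0 + (l_f / l) ** 3))
        f_eff = 0.0 if l < l_b else f
        de = cT * k_M * g / l * ((1.0 - s_f) * f_eff - e)
        r_B = cT * k_M * g / (3.0 * (e + g))
        dl = r_B * (e - l)
        if l < l_p:
            dR = 0.0
        else:
            dR = R_M / (1.0 - lp3) * ((g + l) / (g + e) * e * l * l - lp3)
            dR = cT * dR if dR > 0.0 else 0.0
        e = max(e + dt * de, 0.0)
        l = max(l + dt * dl, 1e-4)
        R = R + dt * dR
        t += dt
    while idx < out_days.size:
        out_l[idx] = l
        out_R[idx] = R
        idx += 1


def simulate_trajectory(
    params: DEBParams,
    f: float,
    T: float,
    days: np.ndarray,
    e0: float = 1.0,
    l0: float | None = None,
    dt: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate a single fish at constant ``f`` and ``T``.

    Returns ``(length_mm, cumulative_eggs)`` sampled at ``days`` (dpf).
    Starts at the first-feeding length ``l_b`` by default with full reserves.
    """
    days = np.asarray(days, dtype=float)
    comp = compound_parameters(params)
    l0 = params.l_b if l0 is None else l0
    out_l = np.empty(days.size)
    out_R = np.empty(days.size)
    _trajectory_kernel(
        float(days[-1]), dt, e0, l0,
        params.T_A, params.T_R, params.alpha, params.l_b, params.l_p, params.l_f,
        comp.g, comp.k_M, params.R_M, float(T), float(f),
        days, out_l, out_R,
    )
    return out_l * comp.L_inf, out_R
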