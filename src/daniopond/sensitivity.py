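"""Global sensitivity analysis: Morris screening and Sobol variance shares.

Two complementary methods, matching their usual division of labour:

* **Sobol** variance decomposition for the (cheap) organism-level DEB
  model — first-order indices ``Si`` quantify the share of output variance
  a parameter explains alone, total indices ``STi`` include interactions.
  Sampling uses scrambled Sobol' sequences in a Saltelli A/B/AB_i layout;
  estimators are the Saltelli-2010 first-order and Jansen total forms.
* **Morris** elementary-effects screening for the (expensive)
  individual-based model — one-at-a-time trajectories on a level grid
  give, per parameter, the mean ``μ``, mean absolute ``μ*`` and standard
  deviation ``σ`` of the elementary effects; large σ flags nonlinearity or
  interactions.  Ranking uses the composite global index ``√(μ*² + σ²)``.

A "dummy" parameter with no influence on the model is always appended as
a negative control: its indices estimate the analysis noise floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import qmc

from . import ibm as ibm_mod
from .deb import DEBParams, simulate_trajectory

__all__ = [
    "SensitivityDesign",
    "morris_design",
    "morris_effects",
    "sobol_design",
    "sobol_indices",
    "deb_sobol_analysis",
    "ibm_morris_analysis",
    "LENGTH_OUTPUT_DAYS",
    "EGG_OUTPUT_DAYS",
    "IBM_OUTPUT_DAYS",
]

#: evaluation days for the DEB outputs (dpf)
LENGTH_OUTPUT_DAYS = (25, 50, 75, 100, 200, 400)
EGG_OUTPUT_DAYS = (100, 200, 400)
#: evaluation days for the IBM outputs (post-stabilisation year)
IBM_OUTPUT_DAYS = (1095, 1156, 1217, 1277, 1339, 1400)

DUMMY = "dummy"


@dataclass
class SensitivityDesign:
    """Parameter names, ranges and sampling settings for either method.

    A dummy parameter is appended automatically unless already present.
    """

    names: list
    bounds: np.ndarray              # (k, 2) low/high
    method: str = "morris"          # "morris" or "sobol"
    trajectories: int = 10          # Morris r
    levels: int = 4                 # Morris p (even)
    n_base: int = 256               # Sobol base sample N
    seed: int = 0

    def __post_init__(self):
        self.names = list(self.names)
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if DUMMY not in self.names:
            self.names.append(DUMMY)
            self.bounds = np.vstack([self.bounds, [0.0, 1.0]])
        if self.bounds.shape != (len(self.names), 2):
            raise ValueError("bounds must be (k, 2) matching names")
        if np.any(~np.isfinite(self.bounds)) or np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("each bound must be finite with low < high")
        if self.method not in ("morris", "sobol"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def k(self) -> int:
        return len(self.names)


# ---------------------------------------------------------------------------
# Morris elementary effects
# ---------------------------------------------------------------------------

def morris_design(design: SensitivityDesign) -> np.ndarray:
    """Sampling plan of ``r`` one-at-a-time trajectories.

    Returns an ``(r·(k+1), k)`` array in physical units.  Each trajectory
    starts on a random point of the p-level grid and changes exactly one
    coordinate by ``Δ = p / (2(p−1))`` (in unit space) per step, each
    coordinate exactly once, in random order.
    """
    if design.trajectories < 2:
        raise ValueError("need at least 2 trajectories")
    if design.levels % 2:
        raise ValueError("levels must be even")
    rng = np.random.default_rng(design.seed)
    k, p, r = design.k, design.levels, design.trajectories
    delta = p / (2.0 * (p - 1.0))
    grid = np.arange(p) / (p - 1.0)
    starts = grid[grid <= 1.0 - delta + 1e-12]
    rows = []
    for _ in range(r):
        x = rng.choice(starts, size=k)
        order = rng.permutation(k)
        rows.append(x.copy())
        for j in order:
            x = x.copy()
            x[j] += delta
            rows.append(x)
    unit = np.array(rows)
    lo, hi = design.bounds[:, 0], design.bounds[:, 1]
    return lo + unit * (hi - lo)


def morris_effects(design: SensitivityDesign, X: np.ndarray, Y: np.ndarray) -> pd.DataFrame:
    """Elementary-effect statistics from an evaluated Morris plan.

    ``Y`` may be 1-D or ``(n_points, n_outputs)``; with several outputs the
    statistics are averaged over outputs after per-output normalisation of
    the effects is *not* applied (effects are per unit of the scaled
    parameter, as usual).  Returns a frame indexed by parameter with
    columns ``mu``, ``mu_star``, ``sigma``, ``global_index``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T  # (n, m)
    k, r = design.k, design.trajectories
    if X.shape[0] != r * (k + 1) or Y.shape[0] != X.shape[0]:
        missing = r * (k + 1) - Y.shape[0]
        raise ValueError(
            f"plan/outputs mismatch: expected {r * (k + 1)} evaluations, got "
            f"X:{X.shape[0]} Y:{Y.shape[0]} ({missing} missing)"
        )
    lo, hi = design.bounds[:, 0], design.bounds[:, 1]
    unit = (X - lo) / (hi - lo)
    m = Y.shape[1]
    effects = np.full((r, k, m), np.nan)
    for t in range(r):
        block = slice(t * (k + 1), (t + 1) * (k + 1))
        u = unit[block]
        y = Y[block]
        for step in range(k):
            du = u[step + 1] - u[step]
            j = int(np.argmax(np.abs(du)))
            effects[t, j] = (y[step + 1] - y[step]) / du[j]
    mu = np.nanmean(effects, axis=0)          # (k, m)
    mu_star = np.nanmean(np.abs(effects), axis=0)
    sigma = np.nanstd(effects, axis=0, ddof=1)
    out = pd.DataFrame(
        {
            "mu": mu.mean(axis=1),
            "mu_star": mu_star.mean(axis=1),
            "sigma": sigma.mean(axis=1),
        },
        index=pd.Index(design.names, name="parameter"),
    )
    out["global_index"] = np.hypot(out["mu_star"], out["sigma"])
    return out


# ---------------------------------------------------------------------------
# Sobol indices (Saltelli sampling)
# ---------------------------------------------------------------------------

def sobol_design(design: SensitivityDesign) -> np.ndarray:
    """Saltelli evaluation plan: blocks ``A``, ``B``, then ``AB_i`` per parameter.

    ``(k + 2)·N`` rows in physical units, built from a scrambled Sobol'
    sequence of dimension ``2k``.
    """
    k, N = design.k, design.n_base
    sampler = qmc.Sobol(d=2 * k, scramble=True, seed=design.seed)
    base = sampler.random(N)
    A, B = base[:, :k], base[:, k:]
    blocks = [A, B]
    for i in range(k):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        blocks.append(ABi)
    unit = np.vstack(blocks)
    lo, hi = design.bounds[:, 0], design.bounds[:, 1]
    return lo + unit * (hi - lo)


def sobol_indices(
    design: SensitivityDesign,
    Y: np.ndarray,
    n_boot: int = 0,
) -> pd.DataFrame:
    """First-order ``Si`` (Saltelli 2010) and total ``STi`` (Jansen) indices.

    ``Y`` is the evaluated plan from :func:`sobol_design`, 1-D or
    ``(rows, n_outputs)`` (indices are averaged over outputs).  With
    ``n_boot > 0`` percentile bootstrap half-widths over the base sample
    are attached; a small base sample triggers a warning.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float).T).T
    k, N = design.k, design.n_base
    if Y.shape[0] != (k + 2) * N:
        raise ValueError(f"expected {(k + 2) * N} evaluations, got {Y.shape[0]}")
    if N < 64:
        import warnings

        warnings.warn(f"Sobol base sample N={N} is small; indices will be noisy")

    def _indices(sample_idx):
        yA = Y[sample_idx]
        yB = Y[N + sample_idx]
        Si = np.empty((k, Y.shape[1]))
        STi = np.empty((k, Y.shape[1]))
        var = np.var(np.concatenate([yA, yB]), axis=0, ddof=1)
        var = np.where(var > 0, var, np.inf)
        for i in range(k):
            yABi = Y[(2 + i) * N + sample_idx]
            Si[i] = np.mean(yB * (yABi - yA), axis=0) / var
            STi[i] = 0.5 * np.mean((yA - yABi) ** 2, axis=0) / var
        return Si.mean(axis=1), STi.mean(axis=1)

    idx = np.arange(N)
    Si, STi = _indices(idx)
    out = pd.DataFrame(
        {"Si": Si, "STi": STi}, index=pd.Index(design.names, name="parameter")
    )
    if n_boot:
        rng = np.random.default_rng(design.seed + 1)
        boots = np.array([_indices(rng.integers(0, N, N)) for _ in range(n_boot)])
        out["Si_ci"] = 1.96 * boots[:, 0, :].std(axis=0)
        out["STi_ci"] = 1.96 * boots[:, 1, :].std(axis=0)
    return out


# ---------------------------------------------------------------------------
# model-specific drivers
# ---------------------------------------------------------------------------

#: DEB parameters analysed by default, with ±20 % ranges around the defaults
#: (the experimental temperature and functional response get natural ranges)
def default_deb_design(n_base: int = 256, seed: int = 0, rel: float = 0.2) -> SensitivityDesign:
    p = DEBParams()
    names = ["T_exp", "T_R", "delta", "p_Am", "f", "p_M", "kappa"]
    bounds = [
        (22.0, 32.0),
        (p.T_R * (1 - rel * 0.1), p.T_R * (1 + rel * 0.1)),  # K scale: ±2 %
        (p.delta * (1 - rel), p.delta * (1 + rel)),
        (p.p_Am * (1 - rel), p.p_Am * (1 + rel)),
        (0.5, 1.0),
        (p.p_M * (1 - rel), p.p_M * (1 + rel)),
        (p.kappa * (1 - rel), min(p.kappa * (1 + rel), 0.99)),
    ]
    return SensitivityDesign(names, np.array(bounds), method="sobol", n_base=n_base, seed=seed)


def _deb_outputs(row: np.ndarray, names: list, base: DEBParams) -> np.ndarray:
    """Lengths at LENGTH_OUTPUT_DAYS and cumulative eggs at EGG_OUTPUT_DAYS."""
    overrides = {}
    T_exp, f = 27.0, 0.8
    for name, value in zip(names, row):
        if name == DUMMY:
            continue
        elif name == "T_exp":
            T_exp = value
        elif name == "f":
            f = value
        else:
            overrides[name] = value
    params = base.replace(**overrides)
    days = np.array(sorted(set(LENGTH_OUTPUT_DAYS) | set(EGG_OUTPUT_DAYS)), dtype=float)
    L, R = simulate_trajectory(params, f=f, T=T_exp, days=days)
    lookup = {d: i for i, d in enumerate(days)}
    out_L = [L[lookup[d]] for d in LENGTH_OUTPUT_DAYS]
    out_R = [R[lookup[d]] for d in EGG_OUTPUT_DAYS]
    return np.array(out_L + out_R)


def deb_sobol_analysis(
    design: SensitivityDesign | None = None,
    base: DEBParams | None = None,
    outputs: str = "length",
    n_boot: int = 0,
) -> pd.DataFrame:
    """Sobol analysis of the DEB layer.

    Outputs are predicted lengths at 25–400 dpf (``outputs="length"``) or
    cumulative eggs at 100–400 dpf (``outputs="eggs"``), following the
    standard evaluation grid.  Returns the index frame sorted by ``Si``.
    """
    design = design if design is not None else default_deb_design()
    base = base if base is not None else DEBParams()
    X = sobol_design(design)
    nL = len(LENGTH_OUTPUT_DAYS)
    Y = np.array([_deb_outputs(row, design.names, base) for row in X])
    Y = Y[:, :nL] if outputs == "length" else Y[:, nL:]
    return sobol_indices(design, Y, n_boot=n_boot).sort_values("Si", ascending=False)


def ibm_morris_analysis(
    param_bounds: dict,
    trajectories: int = 4,
    levels: int = 4,
    replicates: int = 3,
    n_days: int = 400,
    output_days: tuple | None = None,
    seed: int = 0,
    base_overrides: dict | None = None,
) -> pd.DataFrame:
    """Morris screening of the full population model.

    ``param_bounds`` maps flat config keys (``"ibm.P_tau"``,
    ``"deb.p_Am"``, ``"food.K_s"``, …) to (low, high) ranges.  Each design
    point is evaluated as the mean over ``replicates`` seeded runs of the
    outputs (total abundance, juvenile frequency, adult and juvenile mean
    length) at ``output_days``.  Defaults are desk-scale; the full protocol
    uses 30 replicates and the post-stabilisation output days.
    """
    from .config import load_config

    names = list(param_bounds)
    bounds = np.array([param_bounds[n] for n in names], dtype=float)
    design = SensitivityDesign(
        names, bounds, method="morris", trajectories=trajectories, levels=levels, seed=seed
    )
    X = morris_design(design)
    output_days = output_days or tuple(d for d in IBM_OUTPUT_DAYS if d <= n_days) or (n_days,)

    rows = []
    for pt, row in enumerate(X):
        overrides = dict(base_overrides or {})
        for name, value in zip(design.names, row):
            if name != DUMMY:
                overrides[name] = float(value)
        cfg = load_config(overrides=overrides)
        vals = []
        for rep in range(replicates):
            # common random numbers: the same replicate seeds at every
            # design point, so the dummy parameter sees zero variability
            state = ibm_mod.run_ibm(
                deb=cfg.deb, ibm=cfg.ibm, food_params=cfg.food,
                n_days=n_days, seed=seed * 1000 + rep,
                start_day_of_year=cfg.run.start_day_of_year,
            )
            s = state.summary_frame().set_index("day")
            sel = s.loc[[d for d in output_days if d in s.index]]
            n = sel["n_fish"].to_numpy(dtype=float)
            juv_freq = np.where(n > 0, sel["n_juveniles"] / np.maximum(n, 1), 0.0)
            vals.append(
                np.concatenate(
                    [
                        n,
                        juv_freq,
                        np.nan_to_num(sel["mean_length_juv"].to_numpy(dtype=float)),
                        np.nan_to_num(sel["mean_length_fem"].to_numpy(dtype=float)),
                    ]
                )
            )
        rows.append(np.mean(vals, axis=0))
    return morris_effects(design, X, np.array(rows)).sort_values(
        "global_index", ascending=False
    )
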