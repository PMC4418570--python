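"""Synthetic observation generators.

These generators produce growth tables, fecundity series and field-style
length histograms *from the model itself*, so every calibration and
comparison path can be exercised end-to-end without external data.  They
mimic the layout of the real experiments: eight growth measurement days
between 49 and 107 dpf for three feeding groups, daily fecundity
monitoring over 21 days at 29 °C and 11 days at 26 °C, and a 120-fish
field sample censored below a length cutoff.  All generators are
seed-deterministic and round-trip through the calibration readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ibm as ibm_mod
from .calibration import ObservationSet
from .deb import DEBParams, simulate_trajectory

__all__ = [
    "SyntheticSpec",
    "make_growth_data",
    "make_fecundity_data",
    "make_field_histogram",
    "GROWTH_DAYS",
]

#: measurement schedule of the growth experiment (dpf)
GROWTH_DAYS = (49, 56, 63, 70, 77, 91, 104, 107)


@dataclass
class SyntheticSpec:
    """Generating configuration for the synthetic datasets.

    ``growth_groups`` maps group name → (temperature °C, f, n fish);
    defaults mimic three feeding regimes at 27 °C.  ``fecundity_groups``
    maps group name → (temperature °C, f, n monitoring days, adult scaled
    length).  ``noise_length`` / ``noise_eggs`` are Gaussian observation
    sds (mm / eggs).
    """

    params: DEBParams = field(default_factory=DEBParams)
    growth_days: tuple = GROWTH_DAYS
    growth_groups: dict = field(
        default_factory=lambda: {
            "food_1.00": (27.0, 0.93, 15),
            "food_0.75": (27.0, 0.81, 15),
            "food_0.50": (27.0, 0.70, 15),
        }
    )
    fecundity_groups: dict = field(
        default_factory=lambda: {
            "fec_29C": (29.0, 0.93, 21, 0.75),
            "fec_26C": (26.0, 0.48, 11, 0.75),
        }
    )
    noise_length: float = 0.5
    noise_eggs: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_length < 0 or self.noise_eggs < 0:
            raise ValueError("noise sds must be non-negative")
        if np.any(np.diff(self.growth_days) <= 0):
            raise ValueError("growth measurement days must be increasing")


def make_growth_data(spec: SyntheticSpec | None = None) -> ObservationSet:
    """Growth observations (means ± sd per measurement day and group)."""
    spec = spec if spec is not None else SyntheticSpec()
    rng = np.random.default_rng(spec.seed)
    days = np.asarray(spec.growth_days, dtype=float)
    rows = []
    for group, (T, f, n) in sorted(spec.growth_groups.items()):
        L, _ = simulate_trajectory(spec.params, f=f, T=T, days=days)
        for d, mu in zip(days, L):
            obs = mu + spec.noise_length * rng.standard_normal(n)
            mean = float(np.mean(obs)) if spec.noise_length > 0 else float(mu)
            sd = float(np.std(obs, ddof=1)) if spec.noise_length > 0 else 0.0
            rows.append(
                {"group": group, "day": d, "mean_length": mean, "sd": sd,
                 "n": n, "temperature": T}
            )
    return ObservationSet(growth=pd.DataFrame(rows), fecundity=pd.DataFrame(
        columns=["group", "day", "cumulative_eggs", "temperature", "l0"]))


def make_fecundity_data(spec: SyntheticSpec | None = None) -> ObservationSet:
    """Cumulative egg series at two temperatures (non-decreasing by design)."""
    spec = spec if spec is not None else SyntheticSpec()
    rng = np.random.default_rng(spec.seed + 1)
    rows = []
    for group, (T, f, n_days, l0) in sorted(spec.fecundity_groups.items()):
        days = np.arange(1.0, n_days + 1.0)
        _, R = simulate_trajectory(spec.params, f=f, T=T, days=days, l0=l0, e0=1.0)
        noise = np.maximum(spec.noise_eggs * rng.standard_normal(days.size), -R)
        obs = np.maximum.accumulate(np.maximum(R + noise, 0.0)) if spec.noise_eggs > 0 else R
        for d, eggs in zip(days, obs):
            rows.append(
                {"group": group, "day": d, "cumulative_eggs": float(eggs),
                 "temperature": T, "l0": l0}
            )
    return ObservationSet(
        growth=pd.DataFrame(columns=["group", "day", "mean_length", "sd", "n", "temperature"]),
        fecundity=pd.DataFrame(rows),
    )


def make_observations(spec: SyntheticSpec | None = None) -> ObservationSet:
    """Combined growth + fecundity observation set from one spec."""
    spec = spec if spec is not None else SyntheticSpec()
    return ObservationSet(
        growth=make_growth_data(spec).growth,
        fecundity=make_fecundity_data(spec).fecundity,
    )


def make_field_histogram(
    cutoff: float = 15.0,
    sample_size: int = 120,
    n_days: int = 1110,
    seed: int = 0,
    deb: DEBParams | None = None,
    ibm: "ibm_mod.IBMParams | None" = None,
    **run_kwargs,
) -> tuple[np.ndarray, np.ndarray, ibm_mod.PopulationState]:
    """Field-sampling stand-in: run the IBM, sample 120 fish above a cutoff.

    Returns (bin lower edges, normalised 1-mm frequencies, final state).
    The sample is drawn without replacement when enough fish qualify.
    """
    state = ibm_mod.run_ibm(deb=deb, ibm=ibm, n_days=n_days, seed=seed, **run_kwargs)
    rng = np.random.default_rng(seed + 99)
    lengths = state.lengths(deb if deb is not None else DEBParams())
    eligible = lengths[lengths > cutoff]
    if eligible.size == 0:
        edges, freq, _ = ibm_mod.length_histogram(np.empty(0), min_length=cutoff)
        return edges, freq, state
    take = min(sample_size, eligible.size)
    sample = rng.choice(eligible, size=take, replace=eligible.size < sample_size)
    edges, freq, _ = ibm_mod.length_histogram(sample, min_length=cutoff)
    return edges, freq, state
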