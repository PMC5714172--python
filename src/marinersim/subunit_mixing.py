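"""Dimer-composition statistics for mixtures of two monomer pools.

Mixing a pool of XX homodimers with a pool of YY homodimers (monomer
fraction ``f`` of species Y) yields heterodimers only to the extent that
subunits exchange.  Transposase dimers are stable on the hour scale but
equilibrate on extended incubation, reaching the binomial 1:2:1 pattern
for an equimolar mix.  The exchange law used here is dissociation
limited: each dimer dissociates with first-order rate ``k`` and the freed
monomers re-pair at random from the pool, giving exponential relaxation
of the heterodimer fraction toward its binomial equilibrium.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MixMode",
    "MixingScenario",
    "DimerComposition",
    "dimer_distribution",
    "exchange_timecourse",
    "fit_exchange_rate",
]

from enum import Enum


class MixMode(str, Enum):
    HOMODIMERS_ONLY = "homodimers_only"
    EQUILIBRATED = "equilibrated"
    KINETIC = "kinetic"


@dataclass(frozen=True)
class MixingScenario:
    mode: MixMode = MixMode.EQUILIBRATED
    exchange_rate: Optional[float] = None  # per hour, kinetic mode only
    duration: Optional[float] = None       # hours, kinetic mode only

    def __post_init__(self) -> None:
        mode = MixMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if mode is MixMode.KINETIC:
            if self.exchange_rate is None or self.duration is None:
                raise ValueError("kinetic mixing needs exchange_rate and duration")
            if self.exchange_rate < 0 or self.duration < 0:
                raise ValueError("exchange_rate and duration must be nonnegative")


HOMODIMERS_ONLY = MixingScenario(MixMode.HOMODIMERS_ONLY)
EQUILIBRATED = MixingScenario(MixMode.EQUILIBRATED)


def get_scenario(scenario: str | MixingScenario) -> MixingScenario:
    if isinstance(scenario, MixingScenario):
        return scenario
    return MixingScenario(MixMode(scenario))


@dataclass(frozen=True)
class DimerComposition:
    """Probabilities of the three dimer species XX, XY, YY."""

    p_XX: float
    p_XY: float
    p_YY: float

    def __post_init__(self) -> None:
        probs = (self.p_XX, self.p_XY, self.p_YY)
        if any(p < -1e-12 or p > 1 + 1e-12 for p in probs):
            raise ValueError(f"probabilities out of [0,1]: {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"probabilities must sum to 1: {probs}")

    @property
    def monomer_fraction_Y(self) -> float:
        return self.p_YY + 0.5 * self.p_XY

    def as_tuple(self) -> tuple:
        return (self.p_XX, self.p_XY, self.p_YY)


def dimer_distribution(f: float, scenario: str | MixingScenario) -> DimerComposition:
    """Dimer-species distribution at monomer fraction ``f`` of species Y.

    homodimers_only: (1-f, 0, f); equilibrated: the binomial
    ((1-f)^2, 2f(1-f), f^2); kinetic: the exchange trajectory endpoint
    at the scenario's duration.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"monomer fraction f={f} outside [0, 1]")
    sc = get_scenario(scenario)
    if sc.mode is MixMode.HOMODIMERS_ONLY:
        return DimerComposition(1.0 - f, 0.0, f)
    if sc.mode is MixMode.EQUILIBRATED:
        return DimerComposition((1.0 - f) ** 2, 2.0 * f * (1.0 - f), f ** 2)
    start = DimerComposition(1.0 - f, 0.0, f)
    tc = exchange_timecourse(start, sc.exchange_rate, [sc.duration])
    row = tc.iloc[-1]
    return DimerComposition(row.p_XX, row.p_XY, row.p_YY)


def exchange_timecourse(initial: DimerComposition, exchange_rate: float,
                        times: Sequence[float]) -> pd.DataFrame:
    """Trajectory of dimer compositions under dissociation-limited exchange.

    Each dimer dissociates at ``exchange_rate`` (per hour); freed
    monomers instantly re-pair at random from the pool, whose species-Y
    fraction ``f`` is conserved.  The heterodimer probability then obeys
    dp_XY/dt = k (2 f (1-f) - p_XY), an exponential relaxation to the
    binomial limit; the homodimer species relax likewise.

    Returns a DataFrame with columns ``time_h, p_XX, p_XY, p_YY``.
    """
    if exchange_rate < 0:
        raise ValueError("exchange_rate must be nonnegative")
    t = np.asarray(list(times), dtype=float)
    if t.size == 0:
        raise ValueError("times must be nonempty")
    if np.any(t < 0):
        raise ValueError("times must be nonnegative")
    f = initial.monomer_fraction_Y
    eq = np.array([(1 - f) ** 2, 2 * f * (1 - f), f ** 2])
    p0 = np.array(initial.as_tuple())
    decay = np.exp(-exchange_rate * t)[:, None]
    traj = eq[None, :] + (p0 - eq)[None, :] * decay
    out = pd.DataFrame(traj, columns=["p_XX", "p_XY", "p_YY"])
    out.insert(0, "time_h", t)
    return out


def fit_exchange_rate(table: pd.DataFrame) -> float:
    """Least-squares exchange rate (per hour) from a noisy time course.

    Expects the ``exchange_timecourse`` column layout.  The pool monomer
    fraction is taken from the data (mean implied f), and a single rate
    is fitted to all three species trajectories jointly.
    """
    from scipy.optimize import minimize_scalar

    t = table["time_h"].to_numpy(dtype=float)
    obs = table[["p_XX", "p_XY", "p_YY"]].to_numpy(dtype=float)
    f = float(np.mean(obs[:, 2] + 0.5 * obs[:, 1]))
    p0 = DimerComposition(1.0 - f, 0.0, f)

    def rss(log_k: float) -> float:
        pred = exchange_timecourse(p0, np.exp(log_k), t)
        return float(((pred[["p_XX", "p_XY", "p_YY"]].to_numpy() - obs) ** 2).sum())

    res = minimize_scalar(rss, bounds=(np.log(1e-4), np.log(1e3)), method="bounded")
    return float(np.exp(res.x))
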