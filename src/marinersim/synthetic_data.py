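"""Synthetic band-quantification datasets for every pipeline stage.

Emulates the study's measurements — product-fraction curves over mutant
fractions, reaction time courses, and dimer-species abundances during
subunit exchange — as the corresponding model prediction plus additive
truncated-Gaussian densitometry noise (fractions are perturbed, clipped
to [0, 1] and renormalised).  All generators are pure functions of their
truth parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mechanism_core import PRODUCT_LABELS
from .endpoint_predictor import mix_curve
from .cleavage_kinetics import KineticRates, simulate_timecourse
from .subunit_mixing import DimerComposition, exchange_timecourse
from .model_fit import QuantTable

__all__ = ["NoiseSpec", "gen_mixing_dataset", "gen_timecourse_dataset",
           "gen_exchange_dataset"]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive per-fraction Gaussian noise of densitometry."""

    sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be nonnegative")


def _perturb(fractions: np.ndarray, noise: NoiseSpec) -> np.ndarray:
    if noise.sd == 0:
        return fractions.copy()
    rng = np.random.default_rng(noise.seed)
    noisy = np.clip(fractions + rng.normal(0.0, noise.sd, fractions.shape),
                    0.0, 1.0)
    sums = noisy.sum(axis=1)
    # an all-zero row can only arise from extreme noise; fall back to uniform
    noisy[sums == 0] = 1.0 / fractions.shape[1]
    sums = noisy.sum(axis=1)
    return noisy / sums[:, None]


def gen_mixing_dataset(truth: Tuple[str, str, str], f_grid: Sequence[float],
                       noise: NoiseSpec = NoiseSpec()) -> QuantTable:
    """Noisy mixing-series lanes from a (model, scenario, ordering) truth."""
    model, scenario, ordering = truth
    curve = mix_curve(model, scenario, ordering, f_grid)
    fracs = _perturb(curve.table[list(PRODUCT_LABELS)].to_numpy(), noise)
    df = pd.DataFrame(fracs, columns=list(PRODUCT_LABELS))
    df.insert(0, "lane", np.arange(1, len(df) + 1))
    df.insert(1, "f", curve.table["f"].to_numpy())
    return QuantTable(df, series_type="mixing",
                      scenario_label=f"synthetic:{model}/{scenario}/{ordering}")


def gen_timecourse_dataset(truth: Tuple[str, Sequence, KineticRates],
                           times: Sequence[float],
                           noise: NoiseSpec = NoiseSpec()) -> QuantTable:
    """Noisy reaction time course from (model, subunit_states, rates)."""
    model, subunit_states, rates = truth
    tc = simulate_timecourse(model, subunit_states, rates=rates, times=times)
    fracs = _perturb(tc.table[list(PRODUCT_LABELS)].to_numpy(), noise)
    df = pd.DataFrame(fracs, columns=list(PRODUCT_LABELS))
    df.insert(0, "lane", np.arange(1, len(df) + 1))
    df.insert(1, "time_h", tc.times)
    return QuantTable(df, series_type="timecourse",
                      scenario_label=f"synthetic:{model}")


def gen_exchange_dataset(f: float, exchange_rate: float,
                         times: Sequence[float],
                         noise: NoiseSpec = NoiseSpec()) -> pd.DataFrame:
    """Noisy dimer-species abundances during subunit exchange.

    Starts from pure homodimer pools at mutant/long fraction ``f``;
    columns as :func:`exchange_timecourse`.
    """
    start = DimerComposition(1.0 - f, 0.0, f)
    tc = exchange_timecourse(start, exchange_rate, times)
    species = ["p_XX", "p_XY", "p_YY"]
    tc[species] = _perturb(tc[species].to_numpy(), noise)
    return tc
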