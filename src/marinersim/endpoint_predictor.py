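"""Endpoint product distributions of transposase mixing reactions.

The central in-silico experiment: dope wild-type transposase with a
catalytically dead mutant at monomer fraction ``f`` and predict, for each
cleavage-topology model, the endpoint distribution of the gel-visible
products (SC, N, L, EX) of a supercoiled excision substrate.  Each
substrate molecule is processed by exactly one synaptic complex whose
subunit composition is drawn from the mixing scenario; within each dimer
the two subunits occupy the two active-site slots in either orientation
with probability 1/2; a nick occurs iff its slot's subunit is active and
the ordering rule permits it at endpoint (gated nicks never fire here;
leak-through is the kinetic model's business).

The enumeration is exact (at most 16 activity configurations), so the
curves carry no free parameters and no Monte-Carlo error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mechanism_core import (
    ALL_NICKS,
    Arity,
    CatalyticState,
    CleavageModel,
    FIVE_PRIME_NICKS,
    NickID,
    OrderingRule,
    ProductClass,
    PRODUCT_LABELS,
    classify_product,
    get_model,
    get_ordering,
)
from .subunit_mixing import MixingScenario, dimer_distribution, get_scenario

__all__ = [
    "ProductDistribution",
    "MixCurve",
    "predict_endpoint",
    "mix_curve",
    "peak_product",
    "closed_form_endpoint",
    "endpoint_nicks",
    "slot_activity_weights",
]


@dataclass(frozen=True)
class ProductDistribution:
    """Fractions of the four product classes; sums to 1."""

    SC: float
    N: float
    L: float
    EX: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if np.any(vals < -1e-9) or np.any(vals > 1 + 1e-9):
            raise ValueError(f"fractions out of [0,1]: {vals}")
        if abs(float(vals.sum()) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1: {vals}")

    def as_array(self) -> np.ndarray:
        return np.array([self.SC, self.N, self.L, self.EX], dtype=float)

    def as_dict(self) -> Dict[str, float]:
        return dict(zip(PRODUCT_LABELS, self.as_array()))

    def __getitem__(self, label: str) -> float:
        return self.as_dict()[label]


@dataclass
class MixCurve:
    """Product distributions over a grid of mutant monomer fractions."""

    table: pd.DataFrame  # columns f, SC, N, L, EX
    model: CleavageModel
    scenario: MixingScenario
    ordering: OrderingRule

    def __post_init__(self) -> None:
        f = self.table["f"].to_numpy()
        if f.size == 0:
            raise ValueError("empty mix-curve grid")
        if np.any(np.diff(f) <= 0) or f.min() < 0 or f.max() > 1:
            raise ValueError("f grid must be strictly increasing within [0,1]")

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out["model"] = self.model.name
        out["scenario"] = self.scenario.mode.value
        out["ordering"] = self.ordering.mode.value
        out.to_csv(path, index=False)


def slot_activity_weights(model: CleavageModel, scenario: MixingScenario,
                          f: float) -> List[Tuple[Tuple[bool, ...], float]]:
    """Probability-weighted slot-activity configurations of one complex.

    Each dimer's composition is drawn independently from the mixing
    scenario at mutant fraction ``f`` (species Y = dead); a mixed dimer
    places its active subunit in either slot with probability 1/2.
    Returns (activity per slot, weight) pairs with weights summing to 1.
    """
    comp = dimer_distribution(f, scenario)
    # per-dimer states: (slot activities within the dimer, probability)
    per_dimer = [
        ((True, True), comp.p_XX),
        ((True, False), comp.p_XY / 2.0),
        ((False, True), comp.p_XY / 2.0),
        ((False, False), comp.p_YY),
    ]
    configs: List[Tuple[Tuple[bool, ...], float]] = []
    n_dimers = len(model.dimer_groups)
    for combo in itertools.product(per_dimer, repeat=n_dimers):
        w = 1.0
        activity = [False] * len(model.slots)
        for group, (acts, p) in zip(model.dimer_groups, combo):
            w *= p
            for slot, a in zip(group, acts):
                activity[slot] = a
        if w > 0.0:
            configs.append((tuple(activity), w))
    return configs


def endpoint_nicks(model: CleavageModel, slot_activity: Sequence[bool],
                   ordering: OrderingRule) -> frozenset:
    """Set of nicks present at t -> infinity for one activity configuration.

    A nick's slot being active is necessary; the ordering rule is applied
    as a fixed point (a gated 3' nick occurs only if its gate is
    eventually satisfied by nicks that do occur).
    """
    occurred = {n for n in FIVE_PRIME_NICKS if slot_activity[model.slot_of(n)]}
    # 3' nicks: gate depends only on 5' nicks, so one pass suffices
    for n in ALL_NICKS - FIVE_PRIME_NICKS:
        if slot_activity[model.slot_of(n)] and ordering.permits_at_endpoint(
                n, frozenset(occurred)):
            occurred.add(n)
    return frozenset(occurred)


def predict_endpoint(model, scenario, ordering, f: float) -> ProductDistribution:
    """Exact endpoint product distribution at mutant monomer fraction ``f``."""
    m = get_model(model)
    sc = get_scenario(scenario)
    rule = get_ordering(ordering)
    frac = dict.fromkeys(PRODUCT_LABELS, 0.0)
    for activity, w in slot_activity_weights(m, sc, f):
        product = classify_product(endpoint_nicks(m, activity, rule))
        frac[product.value] += w
    total = sum(frac.values())
    return ProductDistribution(**{k: v / total for k, v in frac.items()})


def subunit_state_activity(states: Sequence[CatalyticState | str]) -> Tuple[bool, ...]:
    """Per-slot activity booleans from explicit catalytic states."""
    return tuple(CatalyticState(s) is CatalyticState.ACTIVE for s in states)


def mix_curve(model, scenario, ordering, f_grid: Iterable[float]) -> MixCurve:
    """Row-wise endpoint prediction over a grid of mutant fractions."""
    m = get_model(model)
    sc = get_scenario(scenario)
    rule = get_ordering(ordering)
    grid = [float(f) for f in f_grid]
    if not grid:
        raise ValueError("empty f grid")
    rows = [predict_endpoint(m, sc, rule, f).as_array() for f in grid]
    table = pd.DataFrame(rows, columns=list(PRODUCT_LABELS))
    table.insert(0, "f", grid)
    return MixCurve(table, m, sc, rule)


def peak_product(curve: MixCurve, product: str) -> Tuple[float, float]:
    """Argmax and max of one product fraction over f in [0, 1].

    Starts from the curve's grid, then refines with bounded scalar
    optimisation of the continuous predictor.  Ties (within 1e-12) are
    broken toward the smaller f.
    """
    if product not in PRODUCT_LABELS:
        raise ValueError(f"unknown product label {product!r}; "
                         f"expected one of {PRODUCT_LABELS}")

    def value(f: float) -> float:
        return predict_endpoint(curve.model, curve.scenario,
                                curve.ordering, f)[product]

    f_grid = curve.table["f"].to_numpy(dtype=float)
    vals = curve.table[product].to_numpy(dtype=float)
    # grid argmax with smallest-f tie-break
    best = float(vals.max())
    i = int(np.flatnonzero(vals >= best - 1e-12)[0])
    f_best, v_best = float(f_grid[i]), float(vals[i])
    # refine on the bracketing interval
    lo = float(f_grid[max(i - 1, 0)])
    hi = float(f_grid[min(i + 1, len(f_grid) - 1)])
    if hi > lo:
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(lambda f: -value(f), bounds=(lo, hi),
                              method="bounded",
                              options={"xatol": 1e-10})
        if -res.fun > v_best + 1e-12:
            f_best, v_best = float(res.x), float(-res.fun)
    return f_best, v_best


def closed_form_endpoint(model, scenario, ordering,
                         f: float) -> Optional[ProductDistribution]:
    """Hand-derived closed forms for the standard strict-gate cases.

    Returns None ("not available") outside the tabulated cases.  Writing
    a = 1 - f for the active-monomer fraction:

    homodimers_only (complexes are all-active or contain dead dimers):
      * mm models: an all-active dimer excises (EX = a); an all-dead one
        leaves SC = f.  No partial products.
      * dd_13_24 / dd_14_23: the two dimers are independent; one active
        dimer alone contributes a single 5' nick (its 3' nick is gated),
        so EX = a^2, N = 2af, SC = f^2.
      * dd_12_34: the 5'-role dimer alone yields both 5' nicks (N); the
        3'-role dimer alone is fully gated (SC).  EX = a^2, N = af,
        SC = f + ... i.e. SC = f^2 + fa = f.

    equilibrated (subunits binomially redistributed):
      * mm_13_24 / mm_14_23: a mixed dimer performs exactly one 5' nick
        (its 3' nick is gated): EX = a^2, N = 2af, SC = f^2.
      * mm_12_34: a mixed dimer nicks both 5' positions if the active
        subunit holds the 5' role (N), nothing otherwise (SC):
        EX = a^2, N = af, SC = f^2 + af = f.
      * dd models (all three): the four slots are i.i.d. active with
        probability a, so the dimer grouping is immaterial:
        EX = a^4, L = 2 a^3 f, N = a^2 f^2 + 2af, SC = f^2.
        The linear fraction L(f) = 2 f (1-f)^3 peaks at f = 1/4 with
        maximum 27/128.
    """
    m = get_model(model)
    sc = get_scenario(scenario)
    rule = get_ordering(ordering)
    if rule.mode.value != "strict_gate":
        return None
    a = 1.0 - f
    from .subunit_mixing import MixMode

    if sc.mode is MixMode.HOMODIMERS_ONLY:
        if m.arity is Arity.DIMER:
            return ProductDistribution(SC=f, N=0.0, L=0.0, EX=a)
        if m.name.startswith("dd_12"):
            return ProductDistribution(SC=f, N=a * f, L=0.0, EX=a * a)
        return ProductDistribution(SC=f * f, N=2 * a * f, L=0.0, EX=a * a)
    if sc.mode is MixMode.EQUILIBRATED:
        if m.arity is Arity.DIMER_OF_DIMERS:
            return ProductDistribution(SC=f * f, N=a * a * f * f + 2 * a * f,
                                       L=2 * a ** 3 * f, EX=a ** 4)
        if m.name.startswith("mm_12"):
            return ProductDistribution(SC=f, N=a * f, L=0.0, EX=a * a)
        return ProductDistribution(SC=f * f, N=2 * a * f, L=0.0, EX=a * a)
    return None


def sample_endpoint(model, scenario, ordering, f: float, n: int,
                    rng: np.random.Generator) -> ProductDistribution:
    """Monte-Carlo endpoint estimate (test oracle for predict_endpoint).

    Draws ``n`` complexes: each dimer's two subunits are sampled from the
    scenario's composition law and assigned to slots in random
    orientation; the endpoint nicks are then classified per molecule.
    """
    m = get_model(model)
    sc = get_scenario(scenario)
    rule = get_ordering(ordering)
    comp = dimer_distribution(f, sc)
    p = np.array([comp.p_XX, comp.p_XY / 2, comp.p_XY / 2, comp.p_YY])
    dimer_states = [(True, True), (True, False), (False, True), (False, False)]
    counts = dict.fromkeys(PRODUCT_LABELS, 0)
    n_dimers = len(m.dimer_groups)
    draws = rng.choice(4, size=(n, n_dimers), p=p)
    for row in draws:
        activity = [False] * len(m.slots)
        for group, k in zip(m.dimer_groups, row):
            for slot, act in zip(group, dimer_states[k]):
                activity[slot] = act
        product = classify_product(endpoint_nicks(m, activity, rule))
        counts[product.value] += 1
    return ProductDistribution(**{k: v / n for k, v in counts.items()})
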