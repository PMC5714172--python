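"""Discriminating cleavage-topology models against band quantifications.

Gel lanes of a mixing series are densitometry-quantified into fractions
of the four product classes per lane.  Each candidate (model, scenario,
ordering) yields a parameter-free predicted curve, so discrimination is
a straight residual-sum-of-squares comparison: candidates are grouped
into analytic equivalence classes (distinct topologies can predict
identical curves), ranked by RSS, and a candidate class is excluded when
its RSS exceeds the best class's by more than a configurable ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .mechanism_core import PRODUCT_LABELS, get_model, get_ordering
from .subunit_mixing import get_scenario
from .endpoint_predictor import mix_curve, predict_endpoint

__all__ = ["QuantTable", "FitReport", "normalize_lanes", "fit_mixing_data",
           "Candidate"]

#: tolerated deviation of a raw lane's fraction sum from 1
ROW_SUM_TOL = 0.02


@dataclass
class QuantTable:
    """Per-lane product fractions of a mixing series or time course.

    ``table`` columns: lane, then ``f`` (mixing) or ``time_h``
    (timecourse), then SC, N, L, EX.  Fractions are validated to sum to
    1 within ``ROW_SUM_TOL`` and then renormalised exactly.
    """

    table: pd.DataFrame
    series_type: str = "mixing"          # mixing | timecourse
    scenario_label: str = ""

    def __post_init__(self) -> None:
        if self.series_type not in ("mixing", "timecourse"):
            raise ValueError(f"unknown series type {self.series_type!r}")
        df = self.table.copy()
        missing = [c for c in ("lane", self.index_column, *PRODUCT_LABELS)
                   if c not in df.columns]
        if missing:
            raise ValueError(f"quant table missing columns {missing}")
        fracs = df[list(PRODUCT_LABELS)].to_numpy(dtype=float)
        if np.any(fracs < 0) or np.any(fracs > 1):
            bad = df["lane"].iloc[
                int(np.argwhere((fracs < 0) | (fracs > 1))[0][0])]
            raise ValueError(f"lane {bad!r}: fractions outside [0, 1]")
        sums = fracs.sum(axis=1)
        off = np.abs(sums - 1.0) > ROW_SUM_TOL
        if np.any(off):
            bad = df["lane"].iloc[int(np.flatnonzero(off)[0])]
            raise ValueError(
                f"lane {bad!r}: fractions sum to {sums[off][0]:.4f}, "
                f"more than {ROW_SUM_TOL} away from 1")
        df[list(PRODUCT_LABELS)] = fracs / sums[:, None]
        if self.series_type == "mixing":
            fvals = df["f"].to_numpy(dtype=float)
            if np.any((fvals < 0) | (fvals > 1)):
                raise ValueError("mutant fractions f must lie in [0, 1]")
        self.table = df

    @property
    def index_column(self) -> str:
        return "f" if self.series_type == "mixing" else "time_h"

    def fractions(self) -> np.ndarray:
        return self.table[list(PRODUCT_LABELS)].to_numpy(dtype=float)


def normalize_lanes(intensities, lane_ids: Optional[Sequence] = None,
                    index_values: Optional[Sequence[float]] = None,
                    series_type: str = "mixing") -> QuantTable:
    """Raw band intensities (n_lanes x 4, SC/N/L/EX order) to fractions."""
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != 4:
        raise ValueError("expected four band intensities per lane")
    if np.any(arr < 0):
        raise ValueError("band intensities must be nonnegative")
    sums = arr.sum(axis=1)
    if np.any(sums == 0):
        lane = (lane_ids or list(range(1, len(arr) + 1)))[
            int(np.flatnonzero(sums == 0)[0])]
        raise ValueError(f"lane {lane!r}: all band intensities are zero")
    fracs = arr / sums[:, None]
    n = len(arr)
    df = pd.DataFrame(fracs, columns=list(PRODUCT_LABELS))
    df.insert(0, "lane", list(lane_ids) if lane_ids is not None
              else list(range(1, n + 1)))
    idx_col = "f" if series_type == "mixing" else "time_h"
    df.insert(1, idx_col,
              list(index_values) if index_values is not None else np.nan)
    return QuantTable(df, series_type=series_type)


@dataclass(frozen=True)
class Candidate:
    model: str
    scenario: str
    ordering: str = "strict_gate"

    def label(self) -> str:
        return f"{self.model}/{self.scenario}/{self.ordering}"


@dataclass
class FitReport:
    """Ranked candidate comparison against one mixing series."""

    table: pd.DataFrame      # candidate, class_id, rss, rank, excluded
    rejection_ratio: float

    @property
    def best_class(self) -> int:
        return int(self.table.iloc[0]["class_id"])

    def best_class_members(self) -> List[str]:
        t = self.table
        return list(t.loc[t["class_id"] == self.best_class, "candidate"])

    def excluded(self) -> List[str]:
        return list(self.table.loc[self.table["excluded"], "candidate"])

    def summary(self) -> str:
        lines = [f"candidate ranking (rejection ratio {self.rejection_ratio}x):"]
        for _, row in self.table.iterrows():
            flag = "EXCLUDED" if row["excluded"] else "viable"
            lines.append(f"  {row['candidate']:<45s} class {row['class_id']}"
                         f"  RSS {row['rss']:.6g}  {flag}")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


#: grid used to decide whether two candidates are analytically equivalent
_EQ_GRID = np.linspace(0.0, 1.0, 101)
_EQ_TOL = 1e-9


def _curve_on(candidate: Candidate, fvals: np.ndarray) -> np.ndarray:
    m = get_model(candidate.model)
    sc = get_scenario(candidate.scenario)
    rule = get_ordering(candidate.ordering)
    return np.array([predict_endpoint(m, sc, rule, f).as_array()
                     for f in fvals])


@lru_cache(maxsize=128)
def _eq_curve(candidate: Candidate) -> np.ndarray:
    """Candidate's curve on the fixed equivalence grid (cached)."""
    return _curve_on(candidate, _EQ_GRID)


def fit_mixing_data(data: QuantTable, candidates: Sequence[Candidate],
                    rejection_ratio: float = 2.0) -> FitReport:
    """Parameter-free RSS comparison of candidates against a mixing series.

    RSS is summed over all four product classes and all lanes.
    Candidates are first grouped into analytic equivalence classes
    (identical predicted curves on a fine grid within 1e-9) so that
    indistinguishable topologies tie exactly; a candidate is excluded
    when its RSS exceeds ``rejection_ratio`` times the best RSS.
    """
    if data.series_type != "mixing":
        raise ValueError("fit_mixing_data expects a mixing series")
    if not candidates:
        raise ValueError("candidate list is empty")
    fvals = data.table["f"].to_numpy(dtype=float)
    obs = data.fractions()

    ref_curves = [_eq_curve(c) for c in candidates]
    class_ids: List[int] = []
    reps: List[np.ndarray] = []
    for rc in ref_curves:
        for cid, rep in enumerate(reps):
            if np.max(np.abs(rc - rep)) < _EQ_TOL:
                class_ids.append(cid)
                break
        else:
            class_ids.append(len(reps))
            reps.append(rc)

    # one RSS per equivalence class, shared by its members
    class_rss = {}
    for cand, cid in zip(candidates, class_ids):
        if cid not in class_rss:
            pred = _curve_on(cand, fvals)
            class_rss[cid] = float(((pred - obs) ** 2).sum())
    rss = np.array([class_rss[cid] for cid in class_ids])
    best = rss.min()
    excluded = rss > rejection_ratio * best
    order = np.argsort(rss, kind="stable")
    table = pd.DataFrame({
        "candidate": [candidates[i].label() for i in order],
        "model": [candidates[i].model for i in order],
        "scenario": [candidates[i].scenario for i in order],
        "ordering": [candidates[i].ordering for i in order],
        "class_id": [class_ids[i] for i in order],
        "rss": rss[order],
        "excluded": excluded[order],
    })
    table["rank"] = table["rss"].rank(method="min").astype(int)
    return FitReport(table, rejection_ratio)
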