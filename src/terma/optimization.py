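"""Brute-force parameter search and window-ratio coupling analysis.

The search evaluates every admissible combination of the five decision
variables (F1, F2, W1, W2, beta) on a training set of annotated records,
pools TP/FP/FN across records (micro-averaging, matching how beat totals
are reported per database) and ranks combinations by the overall accuracy
J = (SE + +P)/2 in descending order.  The search is exhaustive by design;
no heuristic shortcuts are taken.

The coupling scan probes the interaction of the two moving-average
windows: for each W2/W1 ratio (and offset fraction), it classifies the
detector as *coupling* (J > 0.5), *non_coupling* (J is NaN, i.e. no
blocks of interest were generated) or *intermediate*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import SignalRecord, TermaParams, detect
from .evaluation import AnnotationSet, EvalResult, match_events, result_from_counts

__all__ = ["GridSpec", "ParetoSolution", "grid_search", "coupling_scan"]


@dataclass(frozen=True)
class GridSpec:
    """Explicit value lists for the five decision variables.

    Discretization is the caller's responsibility: the published training
    procedure states only parameter ranges, so no implicit stepping is
    imposed here.  Combinations with ``F1 >= F2`` or ``W1 >= W2`` are
    skipped during the search, not rejected up front.
    """

    f1_values: tuple[float, ...]
    f2_values: tuple[float, ...]
    w1_values: tuple[float, ...]
    w2_values: tuple[float, ...]
    beta_values: tuple[float, ...]

    def __post_init__(self) -> None:
        for name in ("f1_values", "f2_values", "w1_values", "w2_values", "beta_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if list(vals) != sorted(vals):
                raise ValueError(f"{name} must be sorted ascending")
            object.__setattr__(self, name, vals)

    def combinations(self):
        """Yield admissible TermaParams in deterministic grid order."""
        for f1, f2, w1, w2, beta in itertools.product(
            self.f1_values, self.f2_values, self.w1_values, self.w2_values,
            self.beta_values,
        ):
            if f1 >= f2 or w1 >= w2:
                continue
            yield TermaParams(F1=f1, F2=f2, W1_ms=w1, W2_ms=w2, beta=beta)


@dataclass(frozen=True)
class ParetoSolution:
    params: TermaParams
    result: EvalResult
    rank: int


def _pooled_counts(
    records: list[tuple[SignalRecord, AnnotationSet]],
    params: TermaParams,
    tolerance_ms: float,
    peak_on: str,
) -> tuple[int, int, int]:
    tp = fp = fn = 0
    for record, annotations in records:
        res = detect(record, params, peak_on=peak_on)
        t, f, n, _ = match_events(res.peaks, annotations, tolerance_ms)
        tp, fp, fn = tp + t, fp + f, fn + n
    return tp, fp, fn


def _sort_key(sol: tuple[TermaParams, EvalResult]):
    params, res = sol
    j = res.j if not math.isnan(res.j) else -math.inf
    se = res.se if not math.isnan(res.se) else -math.inf
    # Maximal J first; ties prefer higher SE, then the cheaper detector.
    return (-j, -se, params.W2_ms, params.W1_ms, params.beta, params.F1)


def grid_search(
    records: list[tuple[SignalRecord, AnnotationSet]],
    grid: GridSpec,
    tolerance_ms: float = 75.0,
    *,
    peak_on: str = "filtered",
) -> list[ParetoSolution]:
    """Exhaustively evaluate the grid and rank combinations by J.

    Every admissible combination is run on every record; TP/FP/FN are
    pooled across records before computing SE, +P and J.  Solutions are
    returned sorted by J descending (NaN-J last), with a documented,
    fully deterministic tie-break, so identical inputs always yield the
    identical ranking.  Rank 1 is the optimal solution.
    """
    if not records or all(len(a) == 0 for _, a in records):
        raise ValueError("need at least one record with at least one annotation")
    evaluated: list[tuple[TermaParams, EvalResult]] = []
    for params in grid.combinations():
        tp, fp, fn = _pooled_counts(records, params, tolerance_ms, peak_on)
        evaluated.append((params, result_from_counts(tp, fp, fn, tolerance_ms)))
    if not evaluated:
        raise ValueError("grid is empty after admissibility filtering (F1<F2, W1<W2)")
    evaluated.sort(key=_sort_key)
    return [
        ParetoSolution(params=p, result=r, rank=i + 1)
        for i, (p, r) in enumerate(evaluated)
    ]


def solutions_to_frame(solutions: list[ParetoSolution]) -> pd.DataFrame:
    """Ranked solutions as a DataFrame (one row per combination)."""
    rows = [
        {
            "F1": s.params.F1, "F2": s.params.F2,
            "W1_ms": s.params.W1_ms, "W2_ms": s.params.W2_ms,
            "beta": s.params.beta,
            "TP": s.result.tp, "FP": s.result.fp, "FN": s.result.fn,
            "SE": s.result.se, "PP": s.result.pp, "J": s.result.j,
            "rank": s.rank,
        }
        for s in solutions
    ]
    return pd.DataFrame(rows)


def classify_coupling(j: float) -> str:
    """Coupling class of an overall accuracy value."""
    if math.isnan(j):
        return "non_coupling"
    return "coupling" if j > 0.5 else "intermediate"


def coupling_scan(
    records: list[tuple[SignalRecord, AnnotationSet]],
    base_params: TermaParams,
    ratios: list[float],
    betas: list[float] | None = None,
    tolerance_ms: float = 75.0,
    *,
    peak_on: str = "filtered",
) -> pd.DataFrame:
    """Scan W2/W1 ratios (and offsets) and classify each cell's coupling.

    For every ``(ratio, beta)``, the detector runs with
    ``W2 = ratio * W1`` (W1, F1, F2 from ``base_params``) and the pooled
    J decides the class: ``coupling`` when J > 0.5, ``non_coupling`` when
    J is NaN (no detections at all), ``intermediate`` otherwise.

    Returns a DataFrame with columns ratio, beta, TP, FP, FN, SE, PP, J,
    coupling_class.
    """
    if any(r <= 1 for r in ratios):
        raise ValueError("ratios must all exceed 1 (W2 must exceed W1)")
    if betas is None:
        betas = [base_params.beta]
    rows = []
    for ratio in ratios:
        for beta in betas:
            params = TermaParams(
                F1=base_params.F1, F2=base_params.F2,
                W1_ms=base_params.W1_ms, W2_ms=ratio * base_params.W1_ms,
                beta=beta,
            )
            tp, fp, fn = _pooled_counts(records, params, tolerance_ms, peak_on)
            res = result_from_counts(tp, fp, fn, tolerance_ms)
            rows.append(
                {
                    "ratio": ratio, "beta": beta,
                    "TP": tp, "FP": fp, "FN": fn,
                    "SE": res.se, "PP": res.pp, "J": res.j,
                    "coupling_class": classify_coupling(res.j),
                }
            )
    return pd.DataFrame(rows)
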