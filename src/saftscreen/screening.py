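"""Prediction-error statistics, ranking and one-point kij calibration.

Deviations between calculated and measured drug weight-fraction
solubilities are summarized as AARD (average absolute relative
deviation, %) and ARD (signed average relative deviation, %; negative
means systematic underestimation).  Group totals pool the underlying
per-point deviations by default, so systems with more data weigh more;
an unweighted per-system mean is available as an alternative mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import linregress

from .parameters import FusionProperties
from .phase_equilibria import (BinaryContext, P_DEFAULT, solve_sle_point)
from .saft_core import ComponentModel


# ---------------------------------------------------------------------------
# experimental datasets
# ---------------------------------------------------------------------------

@dataclass
class ExperimentalDataset:
    """Measured drug solubility points for one drug-polymer system."""

    api: str
    polymer: str
    points: list[tuple[float, float]]  # (T in K, w_drug)
    provenance: str = ""

    def __post_init__(self):
        if not self.points:
            raise ValueError("a dataset needs at least one point")
        for T, w in self.points:
            if not 0.0 < w < 1.0:
                raise ValueError(f"weight fraction out of (0, 1): {w}")
            if T <= 0:
                raise ValueError(f"non-positive temperature {T}")

    @property
    def system_id(self) -> str:
        return f"{self.api}-{self.polymer}"

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([T for T, _ in self.points])

    @property
    def w_exp(self) -> np.ndarray:
        return np.array([w for _, w in self.points])


_DATA_HEADER = "system_id\tapi\tpolymer\tT_K\tw_api_exp"


def write_experimental_data(datasets: Iterable[ExperimentalDataset],
                            path: str | Path) -> None:
    lines = [_DATA_HEADER]
    for ds in datasets:
        for T, w in ds.points:
            lines.append(f"{ds.system_id}\t{ds.api}\t{ds.polymer}"
                         f"\t{T:.4f}\t{w:.10e}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_experimental_data(path: str | Path) -> list[ExperimentalDataset]:
    lines = Path(path).read_text().strip().splitlines()
    if lines[0] != _DATA_HEADER:
        raise ValueError(f"{path}: unexpected header {lines[0]!r}")
    grouped: dict[str, ExperimentalDataset] = {}
    order: list[str] = []
    rows: dict[str, list[tuple[float, float]]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for line in lines[1:]:
        sid, api, polymer, T_s, w_s = line.split("\t")
        rows.setdefault(sid, []).append((float(T_s), float(w_s)))
        meta[sid] = (api, polymer)
        if sid not in order:
            order.append(sid)
    return [ExperimentalDataset(api=meta[sid][0], polymer=meta[sid][1],
                                points=rows[sid], provenance=str(path))
            for sid in order]


# ---------------------------------------------------------------------------
# deviation statistics
# ---------------------------------------------------------------------------

def _check_pair(exp, calc):
    exp = np.asarray(exp, dtype=float)
    calc = np.asarray(calc, dtype=float)
    if exp.shape != calc.shape or exp.ndim != 1 or exp.size == 0:
        raise ValueError("exp and calc must be equal-length 1-D vectors")
    if np.any(exp <= 0):
        raise ValueError("experimental values must be positive")
    return exp, calc


def relative_deviations(exp, calc) -> np.ndarray:
    """Signed per-point relative deviations (calc - exp)/exp."""
    exp, calc = _check_pair(exp, calc)
    return (calc - exp) / exp


def aard(exp, calc) -> float:
    """Average absolute relative deviation in percent."""
    return 100.0 * float(np.mean(np.abs(relative_deviations(exp, calc))))


def ard(exp, calc) -> float:
    """Signed average relative deviation in percent (negative means
    underestimation)."""
    return 100.0 * float(np.mean(relative_deviations(exp, calc)))


@dataclass
class GroupStats:
    aard: float
    ard: float
    n: int


@dataclass
class ErrorSummary:
    per_system: dict[tuple[str, str], GroupStats]
    per_api: dict[str, GroupStats]
    per_polymer: dict[str, GroupStats]
    total: GroupStats
    mode: str = "pool"


@dataclass
class PredictionRecord:
    api: str
    polymer: str
    w_exp: np.ndarray
    w_calc: np.ndarray


def _group_stats(devs: Sequence[np.ndarray], mode: str) -> GroupStats:
    if mode == "pool":
        pooled = np.concatenate(devs)
        return GroupStats(aard=100.0 * float(np.mean(np.abs(pooled))),
                          ard=100.0 * float(np.mean(pooled)),
                          n=int(pooled.size))
    if mode == "mean":  # unweighted mean of per-system statistics
        aards = [100.0 * float(np.mean(np.abs(d))) for d in devs]
        ards = [100.0 * float(np.mean(d)) for d in devs]
        return GroupStats(aard=float(np.mean(aards)), ard=float(np.mean(ards)),
                          n=int(sum(d.size for d in devs)))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def aggregate_errors(records: Iterable[PredictionRecord],
                     mode: str = "pool") -> ErrorSummary:
    """Per-system statistics plus pooled margins per drug, per polymer
    and overall."""
    records = list(records)
    if not records:
        raise ValueError("no prediction records to aggregate")
    per_system = {}
    by_api: dict[str, list[np.ndarray]] = {}
    by_poly: dict[str, list[np.ndarray]] = {}
    all_devs: list[np.ndarray] = []
    for rec in records:
        dev = relative_deviations(rec.w_exp, rec.w_calc)
        per_system[(rec.api, rec.polymer)] = _group_stats([dev], "pool")
        by_api.setdefault(rec.api, []).append(dev)
        by_poly.setdefault(rec.polymer, []).append(dev)
        all_devs.append(dev)
    return ErrorSummary(
        per_system=per_system,
        per_api={k: _group_stats(v, mode) for k, v in by_api.items()},
        per_polymer={k: _group_stats(v, mode) for k, v in by_poly.items()},
        total=_group_stats(all_devs, mode),
        mode=mode)


def correlate_r2(descriptor, errors) -> float:
    """Coefficient of determination of an ordinary least-squares line."""
    x = np.asarray(descriptor, dtype=float)
    y = np.asarray(errors, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("descriptor has zero variance")
    res = linregress(x, y)
    return float(res.rvalue ** 2)


# ---------------------------------------------------------------------------
# predictions and kij calibration
# ---------------------------------------------------------------------------

def predict_weight_fractions(api: ComponentModel, polymer: ComponentModel,
                             fusion: FusionProperties,
                             temperatures: Sequence[float], kij: float = 0.0,
                             p: float = P_DEFAULT) -> np.ndarray:
    """Predicted drug weight-fraction solubility at the given temperatures."""
    order = np.argsort(np.asarray(temperatures))[::-1]
    out = np.empty(len(temperatures))
    x_warm = None
    for idx in order:
        T = float(temperatures[idx])
        pt = solve_sle_point(api, polymer, fusion, T, kij, p, x_init=x_warm)
        x_warm = pt.x_api
        out[idx] = pt.w_api
    return out


def predict_dataset(api: ComponentModel, polymer: ComponentModel,
                    fusion: FusionProperties, dataset: ExperimentalDataset,
                    kij: float = 0.0, p: float = P_DEFAULT) -> PredictionRecord:
    w_calc = predict_weight_fractions(api, polymer, fusion,
                                      dataset.temperatures, kij, p)
    return PredictionRecord(api=dataset.api, polymer=dataset.polymer,
                            w_exp=dataset.w_exp, w_calc=w_calc)


class KijRangeError(RuntimeError):
    pass


def fit_kij_to_point(api: ComponentModel, polymer: ComponentModel,
                     fusion: FusionProperties, T_exp: float, w_exp: float,
                     bracket: tuple[float, float] = (-0.2, 0.2),
                     p: float = P_DEFAULT) -> float:
    """Temperature-independent kij reproducing one experimental point.

    One-dimensional bracketed root finding on the predicted-minus-
    measured weight fraction; raises KijRangeError when no kij inside
    the bracket reproduces the point.
    """
    def f(k):
        pt = solve_sle_point(api, polymer, fusion, T_exp, float(k), p)
        return pt.w_api - w_exp

    lo, hi = bracket
    f0 = f(0.0)
    if abs(f0) < 1e-9:
        return 0.0
    flo, fhi = f(lo), f(hi)
    if flo * fhi > 0:
        raise KijRangeError(
            f"no kij in [{lo}, {hi}] reproduces w={w_exp} at T={T_exp} K "
            f"(residuals {flo:.3e}, {fhi:.3e})")
    # higher kij weakens cross attraction and lowers solubility; pick the
    # sub-bracket against the k=0 prediction to save evaluations
    if f0 * fhi <= 0:
        lo, flo = 0.0, f0
    else:
        hi, fhi = 0.0, f0
    k = brentq(f, lo, hi, xtol=1e-10, rtol=8.9e-16)
    return float(k)


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

@dataclass
class PolymerPrediction:
    polymer: str
    w_pred: float
    aaps: bool = False


@dataclass
class RankEntry:
    rank: int
    polymer: str
    w_pred: float
    aaps: bool
    penalized: bool


@dataclass
class RankingTable:
    api: str
    T_rank: float
    entries: list[RankEntry] = field(default_factory=list)
    experimental_order: list[str] | None = None

    @property
    def order(self) -> list[str]:
        return [e.polymer for e in self.entries]


def apply_aaps_penalty(order: list[PolymerPrediction]) -> list[PolymerPrediction]:
    """Demote each flagged polymer one slot past the next unflagged one.

    Flagged entries are processed in their original predicted order; a
    penalty that would move an entry past the end clamps to the end.
    Applying the procedure twice (without re-flagging) is idempotent in
    the sense that every flagged polymer sits exactly one position below
    its unpenalized slot relative to the unflagged entries.
    """
    out = list(order)
    for pred in [q for q in order if q.aaps]:
        i = out.index(pred)
        j = i + 1
        while j < len(out) and out[j].aaps:
            j += 1
        # insert after the next unflagged entry below (or clamp at end)
        out.pop(i)
        insert_at = min(j, len(out))
        out.insert(insert_at, pred)
    return out


def rank_polymers(api: str, predictions: Sequence[PolymerPrediction],
                  T_rank: float, penalty: bool = True,
                  experimental_order: Sequence[str] | None = None) -> RankingTable:
    """Order polymers by predicted solubility (descending), then demote
    demixing-flagged carriers by one position each."""
    if not predictions:
        raise ValueError("nothing to rank")
    base = sorted(predictions, key=lambda q: -q.w_pred)
    final = apply_aaps_penalty(base) if penalty else base
    table = RankingTable(api=api, T_rank=T_rank,
                         experimental_order=(list(experimental_order)
                                             if experimental_order else None))
    unpenalized = {q.polymer: r for r, q in enumerate(base)}
    for r, q in enumerate(final, start=1):
        table.entries.append(RankEntry(
            rank=r, polymer=q.polymer, w_pred=q.w_pred, aaps=q.aaps,
            penalized=(r - 1) != unpenalized[q.polymer]))
    return table


def ranking_temperature(datasets: Sequence[ExperimentalDataset]) -> float:
    """Lowest temperature common to all systems of one drug: the max over
    systems of each system's minimum measured temperature."""
    if not datasets:
        raise ValueError("no datasets")
    return float(max(min(ds.temperatures) for ds in datasets))


def experimental_reference_order(
        datasets: Sequence[ExperimentalDataset], T_rank: float,
        components: dict[str, ComponentModel],
        api_component: ComponentModel, fusion: FusionProperties,
        p: float = P_DEFAULT) -> list[str]:
    """Experimental polymer order at T_rank for one drug.

    Systems with a measurement at (or below) T_rank are interpolated in
    ln w; single-point systems are extrapolated by calibrating a one-point
    kij and re-predicting at T_rank.
    """
    scores: list[tuple[str, float]] = []
    for ds in datasets:
        Ts, ws = ds.temperatures, ds.w_exp
        if ds.n >= 2 and Ts.min() <= T_rank <= Ts.max():
            order = np.argsort(Ts)
            w_at = math.exp(float(np.interp(T_rank, Ts[order],
                                            np.log(ws[order]))))
        else:
            i_near = int(np.argmin(np.abs(Ts - T_rank)))
            kij = fit_kij_to_point(api_component, components[ds.polymer],
                                   fusion, float(Ts[i_near]),
                                   float(ws[i_near]), p=p)
            w_at = predict_weight_fractions(
                api_component, components[ds.polymer], fusion, [T_rank],
                kij, p)[0]
        scores.append((ds.polymer, w_at))
    scores.sort(key=lambda q: -q[1])
    return [name for name, _ in scores]
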