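"""Drug parameter estimation from solubility data in small solvents.

Four chain parameters (m, sigma, u/kB, epsHB/kB) are fitted to measured
drug mole-fraction solubilities in one or more low-molar-mass solvents;
the association volume stays fixed (0.01 by default) and the association
scheme is prescribed, following the routine strategy for drugs.  The
search uses simulated annealing with Metropolis acceptance — geometric
cooling, Gaussian proposals scaled to the bound widths — followed by an
optional derivative-free local polish of the best state found.  The loss
defaults to the mean squared deviation in ln x, which balances
magnitudes across solvents and temperatures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .parameters import FusionProperties
from .phase_equilibria import NoSleRootError, P_DEFAULT, solve_sle_point
from .saft_core import ComponentModel, SaftError, SegmentParameters

PARAM_NAMES = ("m", "sigma", "u_over_kB", "epsHB_over_kB")

#: loss assigned to parameter vectors for which the forward model fails
PENALTY_LOSS = 1e6


@dataclass
class SolventSolubilityData:
    """Measured (T, x_drug) solubility points in one solvent."""

    solvent: ComponentModel
    points: list[tuple[float, float]]

    def __post_init__(self):
        for T, x in self.points:
            if not 0.0 < x < 1.0:
                raise ValueError(f"mole fraction out of (0, 1): {x}")


@dataclass
class FitConfig:
    molar_mass: float
    fusion: FusionProperties
    bounds: dict[str, tuple[float, float]]
    n_donor: int = 3
    n_acceptor: int = 3
    kappaHB: float = 0.01
    anneal_T0: float = 1.0
    cooling: float = 0.95
    moves_per_level: int = 50
    anneal_Tmin: float = 1e-3
    proposal_scale: float = 0.02  # fraction of each bound width
    seed: int = 0
    polish: bool = True
    pressure: float = P_DEFAULT

    def __post_init__(self):
        for name in PARAM_NAMES:
            if name not in self.bounds:
                raise ValueError(f"missing bounds for {name!r}")
            lo, hi = self.bounds[name]
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name!r} must be finite and "
                                 f"ordered, got ({lo}, {hi})")


@dataclass
class FitResult:
    params: dict[str, float]
    loss: float
    trajectory: list[tuple[int, float]]  # (evaluation index, best-so-far)
    n_evaluations: int
    residuals: np.ndarray  # per-datum ln x deviations at the optimum
    seed: int


def component_from_params(vec, config: FitConfig,
                          name: str = "fitAPI") -> ComponentModel:
    m, sigma, u, eps = (float(v) for v in vec)
    seg = SegmentParameters(
        segment_count_ratio=m / config.molar_mass, sigma=sigma, u_over_kB=u,
        epsHB_over_kB=eps, kappaHB=config.kappaHB,
        n_donor=config.n_donor, n_acceptor=config.n_acceptor)
    return ComponentModel(name=name, molar_mass=config.molar_mass,
                          segments=((seg, 1.0),), role="API")


def _residuals(vec, config: FitConfig,
               datasets: list[SolventSolubilityData]) -> np.ndarray:
    api = component_from_params(vec, config)
    res = []
    for ds in datasets:
        x_warm = None
        for T, x_exp in sorted(ds.points, key=lambda q: -q[0]):
            pt = solve_sle_point(api, ds.solvent, config.fusion, T,
                                 p=config.pressure, x_init=x_warm)
            x_warm = pt.x_api
            res.append(math.log(pt.x_api) - math.log(x_exp))
    return np.asarray(res)


def fit_objective(vec, config: FitConfig,
                  datasets: list[SolventSolubilityData]) -> float:
    """Mean squared deviation in ln x; PENALTY_LOSS outside bounds or on
    forward-model failure."""
    for v, name in zip(vec, PARAM_NAMES):
        lo, hi = config.bounds[name]
        if not lo <= v <= hi:
            return PENALTY_LOSS
    try:
        res = _residuals(vec, config, datasets)
    except (SaftError, NoSleRootError, ValueError):
        return PENALTY_LOSS
    return float(np.mean(res ** 2))


def fit_api_parameters(config: FitConfig,
                       datasets: list[SolventSolubilityData]) -> FitResult:
    """Simulated-annealing estimate of the four free drug parameters.

    Deterministic under a fixed seed; returns the best state ever
    visited, not the final one.
    """
    if not datasets:
        raise ValueError("no datasets to fit")
    rng = np.random.default_rng(config.seed)
    lo = np.array([config.bounds[n][0] for n in PARAM_NAMES])
    hi = np.array([config.bounds[n][1] for n in PARAM_NAMES])
    width = hi - lo

    def loss_of(vec):
        return fit_objective(vec, config, datasets)

    current = lo + rng.uniform(0.25, 0.75, 4) * width
    cur_loss = loss_of(current)
    best, best_loss = current.copy(), cur_loss
    trajectory = [(0, best_loss)]
    n_eval = 1

    Tsa = config.anneal_T0
    while Tsa > config.anneal_Tmin:
        for _ in range(config.moves_per_level):
            prop = current + rng.normal(0.0, config.proposal_scale, 4) * width
            prop = np.clip(prop, lo, hi)
            p_loss = loss_of(prop)
            n_eval += 1
            delta = p_loss - cur_loss
            if delta <= 0 or rng.random() < math.exp(-delta / Tsa):
                current, cur_loss = prop, p_loss
            if p_loss < best_loss:
                best, best_loss = prop.copy(), p_loss
                trajectory.append((n_eval, best_loss))
        Tsa *= config.cooling

    if config.polish and best_loss < PENALTY_LOSS:
        # polish in bound-normalized coordinates so the tolerance is
        # meaningful across parameters of very different magnitude
        def loss_scaled(t):
            return loss_of(lo + t * width)

        sol = minimize(loss_scaled, (best - lo) / width, method="Nelder-Mead",
                       options=dict(xatol=1e-6, fatol=1e-18, maxfev=400))
        n_eval += sol.nfev
        if sol.fun < best_loss:
            best, best_loss = lo + np.asarray(sol.x) * width, float(sol.fun)
            trajectory.append((n_eval, best_loss))

    residuals = (_residuals(best, config, datasets)
                 if best_loss < PENALTY_LOSS else np.array([]))
    return FitResult(
        params=dict(zip(PARAM_NAMES, (float(v) for v in best))),
        loss=best_loss, trajectory=trajectory, n_evaluations=n_eval,
        residuals=residuals, seed=config.seed)
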