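"""Seeded toy components and synthetic solubility datasets.

Mirrors the structure of calorimetry-derived drug-in-polymer solubility
studies: a handful of points per system, clustered at high temperatures
below the drug's melting point, with multiplicative noise.  Every
generator is deterministic under its seed and keeps the noise-free
ground truth alongside the data, so the full screening pipeline can be
closed-loop tested without external data.

The fixture roster covers the qualitatively distinct association
archetypes: self-associating polymers, polymers with acceptor sites but
no self-association energy (induced cross-association), completely
nonassociating polymers, and a two-segment copolymer.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import FusionProperties
from .param_fitting import SolventSolubilityData
from .phase_equilibria import aaps_scan, P_DEFAULT
from .saft_core import ComponentModel, SegmentParameters
from .screening import (ExperimentalDataset, PolymerPrediction,
                        predict_weight_fractions, ranking_temperature,
                        rank_polymers)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ToyApi:
    component: ComponentModel
    fusion: FusionProperties


@dataclass
class ComponentRoster:
    apis: list[ToyApi]
    polymers: list[ComponentModel]
    solvents: list[ComponentModel]
    seed: int


def make_fixture_components(seed: int = 0, n_apis: int = 3) -> ComponentRoster:
    """Deterministic toy roster: drugs, four polymer archetypes, solvents.

    All segment parameters stay within the envelope spanned by typical
    drug parameter tables (m/M 0.01-0.05 mol/g, sigma 2.9-4.5 A,
    u/kB 220-480 K, epsHB/kB 500-2000 K); melting data stay within
    T_m 348-492 K and dH_fus 26-40 kJ/mol.
    """
    rng = np.random.default_rng(seed)
    apis = []
    for i in range(n_apis):
        seg = SegmentParameters(
            segment_count_ratio=rng.uniform(0.020, 0.035),
            sigma=rng.uniform(3.2, 3.8),
            u_over_kB=rng.uniform(300.0, 360.0),
            epsHB_over_kB=rng.uniform(900.0, 1500.0),
            kappaHB=0.02, n_donor=2, n_acceptor=2)
        comp = ComponentModel(name=f"API{i + 1}",
                              molar_mass=float(rng.uniform(250.0, 350.0)),
                              segments=((seg, 1.0),), role="API")
        fusion = FusionProperties(
            T_m=float(rng.uniform(390.0, 450.0)),
            dH_fus=float(rng.uniform(26.0, 34.0)),
            dCp_a=float(rng.uniform(80.0, 120.0)))
        apis.append(ToyApi(component=comp, fusion=fusion))

    # nonassociating, weakly attractive: the demixing-prone archetype
    seg_non = SegmentParameters(
        segment_count_ratio=rng.uniform(0.028, 0.034),
        sigma=rng.uniform(3.6, 4.0), u_over_kB=rng.uniform(220.0, 235.0))
    p_non = ComponentModel("PNON", float(rng.uniform(5000.0, 9000.0)),
                           ((seg_non, 1.0),), role="polymer")

    # acceptor sites without self-association energy: induced association
    seg_ind = SegmentParameters(
        segment_count_ratio=rng.uniform(0.024, 0.030),
        sigma=rng.uniform(3.3, 3.7), u_over_kB=rng.uniform(290.0, 330.0),
        epsHB_over_kB=0.0, kappaHB=0.02, n_donor=0, n_acceptor=8)
    p_ind = ComponentModel("PIND", float(rng.uniform(3000.0, 6000.0)),
                           ((seg_ind, 1.0),), role="polymer")

    # self-associating
    seg_self = SegmentParameters(
        segment_count_ratio=rng.uniform(0.022, 0.028),
        sigma=rng.uniform(3.1, 3.5), u_over_kB=rng.uniform(280.0, 320.0),
        epsHB_over_kB=rng.uniform(1500.0, 2000.0), kappaHB=0.02,
        n_donor=4, n_acceptor=4)
    p_self = ComponentModel("PSELF", float(rng.uniform(4000.0, 8000.0)),
                            ((seg_self, 1.0),), role="polymer")

    # two-segment-type copolymer (plain backbone + acceptor-carrying unit)
    seg_co_a = SegmentParameters(
        segment_count_ratio=rng.uniform(0.026, 0.032),
        sigma=rng.uniform(3.5, 3.9), u_over_kB=rng.uniform(250.0, 280.0))
    seg_co_b = SegmentParameters(
        segment_count_ratio=rng.uniform(0.024, 0.030),
        sigma=rng.uniform(3.2, 3.6), u_over_kB=rng.uniform(300.0, 330.0),
        epsHB_over_kB=0.0, kappaHB=0.02, n_donor=0, n_acceptor=4)
    p_co = ComponentModel("PCOPO", float(rng.uniform(4000.0, 7000.0)),
                          ((seg_co_a, 0.55), (seg_co_b, 0.45)),
                          role="polymer")

    solvents = []
    for j in range(4):
        seg = SegmentParameters(
            segment_count_ratio=rng.uniform(0.040, 0.050),
            sigma=rng.uniform(3.0, 3.4), u_over_kB=rng.uniform(220.0, 260.0),
            epsHB_over_kB=rng.uniform(1800.0, 2400.0), kappaHB=0.03,
            n_donor=1, n_acceptor=1)
        solvents.append(ComponentModel(
            name=f"SOLV{j + 1}", molar_mass=float(rng.uniform(46.0, 90.0)),
            segments=((seg, 1.0),), role="solvent"))

    return ComponentRoster(apis=apis, polymers=[p_non, p_ind, p_self, p_co],
                           solvents=solvents, seed=seed)


def demixing_pair() -> tuple[ToyApi, ComponentModel]:
    """A fixed drug-polymer pair tuned to split into two amorphous phases."""
    seg_api = SegmentParameters(0.025, 3.4, 320.0, 1200.0, 0.02, 2, 2)
    api = ComponentModel("DMXAPI", 300.0, ((seg_api, 1.0),), role="API")
    fusion = FusionProperties(T_m=420.0, dH_fus=30.0, dCp_a=100.0)
    seg_p = SegmentParameters(0.03, 3.8, 210.0)
    poly = ComponentModel("DMXPOLY", 8000.0, ((seg_p, 1.0),), role="polymer")
    return ToyApi(component=api, fusion=fusion), poly


def miscible_pair() -> tuple[ToyApi, ComponentModel]:
    """A fixed drug-polymer pair with strong induced association: no split."""
    seg_api = SegmentParameters(0.025, 3.4, 320.0, 1200.0, 0.02, 2, 2)
    api = ComponentModel("MSCAPI", 300.0, ((seg_api, 1.0),), role="API")
    fusion = FusionProperties(T_m=420.0, dH_fus=30.0, dCp_a=100.0)
    seg_p = SegmentParameters(0.028, 3.5, 315.0, 0.0, 0.02, 0, 8)
    poly = ComponentModel("MSCPOLY", 4000.0, ((seg_p, 1.0),), role="polymer")
    return ToyApi(component=api, fusion=fusion), poly


# ---------------------------------------------------------------------------
# dataset generators
# ---------------------------------------------------------------------------

@dataclass
class GeneratedDataset:
    dataset: ExperimentalDataset
    w_true: np.ndarray
    truncated: int = 0


def _apply_noise(values: np.ndarray, noise_cv: float,
                 rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Multiplicative lognormal noise truncated to (0, 1)."""
    if noise_cv == 0.0:
        return values.copy(), 0
    noisy = values * np.exp(rng.normal(0.0, noise_cv, size=values.shape))
    clipped = np.clip(noisy, 1e-12, 1.0 - 1e-12)
    n_trunc = int(np.sum(clipped != noisy))
    if n_trunc:
        logger.info("truncated %d noisy values into (0, 1)", n_trunc)
    return clipped, n_trunc


def generate_polymer_solubility_data(
        api: ToyApi, polymer: ComponentModel, n_points: int = 4,
        T_window: float = 60.0, noise_cv: float = 0.0, seed: int = 0,
        kij: float = 0.0, p: float = P_DEFAULT) -> GeneratedDataset:
    """Sparse high-temperature solubility points for one system.

    Temperatures sit in [T_m - T_window, T_m), mimicking the usual
    clustering of calorimetry data just below the melting point.
    """
    rng = np.random.default_rng(seed)
    Tm = api.fusion.T_m
    temps = np.sort(rng.uniform(Tm - T_window, Tm - 1.0, n_points))
    w_true = predict_weight_fractions(api.component, polymer, api.fusion,
                                      temps, kij, p)
    w_noisy, n_trunc = _apply_noise(w_true, noise_cv, rng)
    ds = ExperimentalDataset(
        api=api.component.name, polymer=polymer.name,
        points=[(float(T), float(w)) for T, w in zip(temps, w_noisy)],
        provenance=f"synthetic(seed={seed}, noise_cv={noise_cv}, kij={kij})")
    return GeneratedDataset(dataset=ds, w_true=w_true, truncated=n_trunc)


def generate_solvent_solubility_data(
        api: ToyApi, solvents: list[ComponentModel], T_grid=None,
        noise_cv: float = 0.0, seed: int = 0,
        p: float = P_DEFAULT) -> list[SolventSolubilityData]:
    """Mole-fraction solubility datasets for parameter-fitting tests."""
    from .phase_equilibria import solve_sle_point

    rng = np.random.default_rng(seed)
    if T_grid is None:
        T_grid = np.linspace(api.fusion.T_m - 120.0, api.fusion.T_m - 20.0, 6)
    out = []
    for solvent in solvents:
        xs = []
        x_warm = None
        for T in sorted(np.asarray(T_grid, dtype=float), reverse=True):
            pt = solve_sle_point(api.component, solvent, api.fusion, T,
                                 p=p, x_init=x_warm)
            x_warm = pt.x_api
            xs.append((T, pt.x_api))
        x_true = np.array([x for _, x in xs])
        x_noisy, _ = _apply_noise(x_true, noise_cv, rng)
        out.append(SolventSolubilityData(
            solvent=solvent,
            points=[(float(T), float(x))
                    for (T, _), x in zip(xs, x_noisy)]))
    return out


# ---------------------------------------------------------------------------
# full synthetic screening study
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    n_apis: int = 3
    n_points: int = 4
    T_window: float = 60.0
    noise_cv: float = 0.0
    kij: float = 0.0
    aaps_range: tuple[float, float] = (250.0, 500.0)
    aaps_step: float = 50.0
    penalty: bool = True


@dataclass
class SyntheticStudy:
    config: StudyConfig
    seed: int
    roster: ComponentRoster
    datasets: list[ExperimentalDataset]
    w_true: dict[str, np.ndarray]  # system_id -> noise-free curve
    aaps_flags: dict[str, bool]  # system_id -> split predicted
    T_rank: dict[str, float]  # api name -> ranking temperature
    truth_rank: dict[str, list[str]]  # api name -> polymer order

    def datasets_for(self, api_name: str) -> list[ExperimentalDataset]:
        return [ds for ds in self.datasets if ds.api == api_name]


def generate_screening_study(config: StudyConfig | None = None,
                             seed: int = 0) -> SyntheticStudy:
    """Full cross of the fixture roster with datasets and ground truth.

    The ground-truth polymer order per drug comes from the noise-free
    forward model at the ranking temperature, with the demixing penalty
    applied from the scan flags, so downstream ranking can be verified
    exactly.
    """
    config = config or StudyConfig()
    roster = make_fixture_components(seed, n_apis=config.n_apis)
    datasets: list[ExperimentalDataset] = []
    w_true: dict[str, np.ndarray] = {}
    aaps_flags: dict[str, bool] = {}
    sub = np.random.default_rng(seed).integers(0, 2 ** 31, size=1000)
    k = 0
    for api in roster.apis:
        for polymer in roster.polymers:
            gen = generate_polymer_solubility_data(
                api, polymer, config.n_points, config.T_window,
                config.noise_cv, seed=int(sub[k]), kij=config.kij)
            k += 1
            datasets.append(gen.dataset)
            w_true[gen.dataset.system_id] = gen.w_true
            scan = aaps_scan(api.component, polymer, config.aaps_range,
                             config.aaps_step, config.kij)
            aaps_flags[gen.dataset.system_id] = scan.has_split

    T_rank: dict[str, float] = {}
    truth_rank: dict[str, list[str]] = {}
    for api in roster.apis:
        name = api.component.name
        T_rank[name] = ranking_temperature(
            [ds for ds in datasets if ds.api == name])
        preds = []
        for polymer in roster.polymers:
            w = predict_weight_fractions(api.component, polymer, api.fusion,
                                         [T_rank[name]], config.kij)[0]
            preds.append(PolymerPrediction(
                polymer=polymer.name, w_pred=float(w),
                aaps=aaps_flags[f"{name}-{polymer.name}"]))
        table = rank_polymers(name, preds, T_rank[name],
                              penalty=config.penalty)
        truth_rank[name] = table.order
    return SyntheticStudy(config=config, seed=seed, roster=roster,
                          datasets=datasets, w_true=w_true,
                          aaps_flags=aaps_flags, T_rank=T_rank,
                          truth_rank=truth_rank)
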