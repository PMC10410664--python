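"""Solid-liquid and liquid-liquid equilibrium of drug-polymer binaries.

The solubility of the crystalline drug in the amorphous polymer solves

    ln(x * gamma(x)) = -dG_fus / (R T)

self-consistently in the drug mole fraction x.  Demixing (amorphous-
amorphous phase separation, AAPS) is located with the alternating-tangent
construction on the reduced Gibbs energy of mixing: each binodal phase is
solved for one at a time as the touching point of the tangent drawn from
the current estimate of the other phase, which is robust for strongly
asymmetric polymer mixtures.  Temperature scans assemble full phase
diagrams.  All equilibrium work uses the liquid branch at a default
pressure of 0.1 MPa.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from . import saft_core as sc
from .parameters import FusionProperties, R_GAS, fusion_gibbs_energy
from .saft_core import ComponentModel, SaftError, binary_mixture

logger = logging.getLogger(__name__)

#: default pressure for all equilibrium calculations, Pa
P_DEFAULT = 1e5


class EquilibriumError(RuntimeError):
    pass


class NoSleRootError(EquilibriumError):
    pass


# ---------------------------------------------------------------------------
# composition conversion
# ---------------------------------------------------------------------------

def mole_weight_convert(value: float, M_api: float, M_poly: float,
                        direction: str = "x_to_w") -> float:
    """Convert between drug mole fraction and weight fraction.

    ``direction`` is ``"x_to_w"`` or ``"w_to_x"``; the two are exact
    inverses of each other.
    """
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"fraction must lie in [0, 1], got {value}")
    if M_api <= 0 or M_poly <= 0:
        raise ValueError("molar masses must be positive")
    if direction == "x_to_w":
        num = value * M_api
        return num / (num + (1.0 - value) * M_poly)
    if direction == "w_to_x":
        num = value / M_api
        return num / (num + (1.0 - value) / M_poly)
    raise ValueError(f"unknown direction {direction!r}")


# ---------------------------------------------------------------------------
# binary evaluation context
# ---------------------------------------------------------------------------

class BinaryContext:
    """Cached activity evaluations for one (drug, polymer, T, kij, p).

    Keeps the equation-of-state workspace, the pure-liquid reference
    fugacities and a memo of ln-activities per composition, plus a warm
    density start that tracks the last solved state.
    """

    def __init__(self, api: ComponentModel, polymer: ComponentModel,
                 T: float, kij: float = 0.0, p: float = P_DEFAULT):
        self.api, self.polymer = api, polymer
        self.T, self.kij, self.p = float(T), float(kij), float(p)
        self.mix = binary_mixture(api, polymer, 0.5, kij)
        self.ws = sc.get_workspace(self.mix, T)
        self.lnphi_pure = np.array([
            sc.pure_ln_phi_liquid(api, T, p),
            sc.pure_ln_phi_liquid(polymer, T, p)])
        self._eta_warm: float | None = None
        self._memo: dict[float, np.ndarray] = {}

    def ln_phi(self, x_api: float) -> np.ndarray:
        x = np.array([x_api, 1.0 - x_api])
        rho, eta = self.ws.solve_density(x, self.p, "liquid",
                                         eta_init=self._eta_warm)
        self._eta_warm = eta
        return self.ws.ln_phi(x, rho)

    def ln_gamma(self, x_api: float) -> np.ndarray:
        return self.ln_phi(x_api) - self.lnphi_pure

    def ln_activities_pair(self, x_api: float, x_poly: float) -> np.ndarray:
        """(ln a_drug, ln a_polymer) for an explicitly given pair.

        Passing both fractions keeps precision when one of them is many
        orders of magnitude below 1 (strongly asymmetric binodals).
        """
        key = (x_api, x_poly)
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        if x_api <= 0.0 or x_poly <= 0.0:
            raise ValueError("composition must be interior for activities")
        x = np.array([x_api, x_poly])
        rho, eta = self.ws.solve_density(x, self.p, "liquid",
                                         eta_init=self._eta_warm)
        self._eta_warm = eta
        lng = self.ws.ln_phi(x, rho) - self.lnphi_pure
        out = np.array([math.log(x_api), math.log(x_poly)]) + lng
        self._memo[key] = out
        return out

    def ln_activities(self, x_api: float) -> np.ndarray:
        return self.ln_activities_pair(x_api, 1.0 - x_api)

    def gibbs_mix_pair(self, x_api: float, x_poly: float) -> float:
        """Reduced molar Gibbs energy of mixing, Dg_mix/(RT)."""
        la = self.ln_activities_pair(x_api, x_poly)
        return x_api * la[0] + x_poly * la[1]

    def gibbs_mix(self, x_api: float) -> float:
        return self.gibbs_mix_pair(x_api, 1.0 - x_api)

    def dgibbs_mix_pair(self, x_api: float, x_poly: float) -> float:
        """d(Dg_mix/RT)/dx_api; equals ln a_drug - ln a_polymer."""
        la = self.ln_activities_pair(x_api, x_poly)
        return la[0] - la[1]

    def dgibbs_mix(self, x_api: float) -> float:
        return self.dgibbs_mix_pair(x_api, 1.0 - x_api)


# ---------------------------------------------------------------------------
# SLE
# ---------------------------------------------------------------------------

@dataclass
class SlePoint:
    T: float
    x_api: float
    w_api: float
    residual: float
    all_roots: tuple[float, ...] = ()


@dataclass
class SolubilityCurve:
    api: str
    polymer: str
    strategy: str = "REF"
    kij: float = 0.0
    points: list[SlePoint] = field(default_factory=list)
    failures: list[tuple[float, str]] = field(default_factory=list)


def ideal_solubility(fusion: FusionProperties, T: float) -> float:
    """Closed-form mole-fraction solubility with gamma = 1."""
    return math.exp(-fusion_gibbs_energy(fusion, T) / (R_GAS * T))


def solve_sle_point(api: ComponentModel, polymer: ComponentModel,
                    fusion: FusionProperties, T: float, kij: float = 0.0,
                    p: float = P_DEFAULT, ideal: bool = False,
                    x_init: float | None = None,
                    context: BinaryContext | None = None,
                    scan_roots: bool = False) -> SlePoint:
    """Drug mole fraction solving the solubility equation at T.

    Damped successive substitution on x = x_ideal / gamma(x), with a
    bracketed fallback on the log-residual.  With ``scan_roots`` the
    full (0, 1] interval is searched and the smallest root is returned
    with all roots reported in ``all_roots``.
    """
    x_id = ideal_solubility(fusion, T)
    Mw = (api.molar_mass, polymer.molar_mass)
    if ideal or x_id >= 1.0:
        x = min(x_id, 1.0)
        return SlePoint(T, x, mole_weight_convert(x, *Mw), 0.0)

    ctx = context or BinaryContext(api, polymer, T, kij, p)

    def resid(x):
        return math.log(x) + float(ctx.ln_gamma(x)[0]) - math.log(x_id)

    x = min(max(x_init if x_init is not None else x_id, 1e-12), 1.0 - 1e-12)
    converged = False
    lx = math.log(x)
    lx_prev = r_prev = None
    for _ in range(60):
        try:
            lng = float(ctx.ln_gamma(x)[0])
        except SaftError as exc:
            raise NoSleRootError(
                f"activity evaluation failed at x={x:.3g}: {exc}") from exc
        r = lx + lng - math.log(x_id)
        if abs(r) < 1e-11:
            converged = True
            break
        # secant step in ln x (first step: plain substitution direction)
        step = -r
        if lx_prev is not None and lx != lx_prev:
            slope = (r - r_prev) / (lx - lx_prev)
            if slope > 0.1:
                step = -r / slope
        step = max(min(step, 1.5), -1.5)
        lx_prev, r_prev = lx, r
        lx = min(lx + step, math.log(1.0 - 1e-12))
        x = math.exp(lx)

    if not converged:
        # local bracket expansion around the substitution estimate
        lo, hi = x / 1.05, min(x * 1.05, 1.0 - 1e-12)
        try:
            flo, fhi = resid(lo), resid(hi)
            for _ in range(40):
                if flo * fhi <= 0:
                    x = brentq(resid, lo, hi, xtol=1e-15, rtol=8.9e-16)
                    converged = True
                    break
                lo = max(lo / 1.6, 1e-14)
                hi = min(hi * 1.6, 1.0 - 1e-12)
                flo, fhi = resid(lo), resid(hi)
        except SaftError:
            pass

    roots: tuple[float, ...] = ()
    if not converged or scan_roots:
        grid = np.unique(np.concatenate([
            np.geomspace(1e-10, 0.1, 12), np.linspace(0.1, 1.0 - 1e-10, 12)]))
        vals = []
        for xg in grid:
            try:
                vals.append(resid(xg))
            except SaftError:
                vals.append(np.nan)
        found = []
        for i in range(len(grid) - 1):
            va, vb = vals[i], vals[i + 1]
            if np.isnan(va) or np.isnan(vb) or va * vb > 0:
                continue
            found.append(brentq(resid, grid[i], grid[i + 1],
                                xtol=1e-15, rtol=8.9e-16))
        if found:
            roots = tuple(sorted(found))
            if len(roots) > 1:
                logger.warning("multiple SLE roots at T=%.2f K: %s", T, roots)
            x = roots[0] if (scan_roots or not converged) else x
            converged = True
        elif not converged:
            raise NoSleRootError(
                f"no solubility root in (0, 1] at T={T} K "
                f"(last residual {resid(x):.3e})")
    return SlePoint(T, x, mole_weight_convert(x, *Mw), resid(x), roots)


def solubility_curve(api: ComponentModel, polymer: ComponentModel,
                     fusion: FusionProperties, T_grid=None, kij: float = 0.0,
                     p: float = P_DEFAULT, ideal: bool = False,
                     strategy: str = "REF") -> SolubilityCurve:
    """Solubility point per grid temperature, warm-started downward in T.

    The default grid runs from 298 K to T_m in 1 K steps.  Per-point
    failures are recorded, not fatal; the curve fails only if every point
    does.
    """
    if T_grid is None:
        T_grid = np.arange(298.0, fusion.T_m + 1e-9, 1.0)
        if T_grid[-1] < fusion.T_m:
            T_grid = np.append(T_grid, fusion.T_m)
    T_grid = np.asarray(T_grid, dtype=float)
    if np.any(np.diff(T_grid) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if T_grid[-1] > fusion.T_m + 1e-9:
        raise ValueError("grid must not exceed the melting temperature")

    curve = SolubilityCurve(api=api.name, polymer=polymer.name,
                            strategy=strategy, kij=kij)
    x_warm: float | None = None
    for T in T_grid[::-1]:  # walk down from the melting point
        try:
            pt = solve_sle_point(api, polymer, fusion, T, kij, p,
                                 ideal=ideal, x_init=x_warm)
            curve.points.append(pt)
            x_warm = pt.x_api
        except (EquilibriumError, SaftError) as exc:
            curve.failures.append((float(T), str(exc)))
    curve.points.sort(key=lambda q: q.T)
    if not curve.points:
        raise EquilibriumError(
            f"all {len(T_grid)} solubility points failed for "
            f"{api.name}-{polymer.name}")
    return curve


# ---------------------------------------------------------------------------
# LLE
# ---------------------------------------------------------------------------

@dataclass
class BinodalPoint:
    T: float
    x_L1: float  # drug-lean phase
    x_L2: float  # drug-rich phase
    activity_residual: float
    #: ln of the polymer mole fraction in the drug-rich phase; carries the
    #: information lost when x_L2 rounds to 1.0 in double precision
    ln_x_poly_L2: float = float("nan")
    #: the drug-rich phase is pure drug to within floating-point range
    pure_rich: bool = False


@dataclass
class BinodalCurve:
    api: str
    polymer: str
    strategy: str = "REF"
    kij: float = 0.0
    points: list[BinodalPoint] = field(default_factory=list)
    failures: list[tuple[float, str]] = field(default_factory=list)

    @property
    def has_split(self) -> bool:
        return bool(self.points)


def _pair_grid() -> list[tuple[float, float]]:
    """(x_drug, x_poly) scan pairs, log-refined toward both edges."""
    lo = np.geomspace(1e-12, 0.05, 14)
    mid = np.linspace(0.06, 0.94, 28)
    pairs = [(float(x), 1.0 - float(x)) for x in lo]
    pairs += [(float(x), 1.0 - float(x)) for x in mid]
    pairs += [(1.0 - float(e), float(e)) for e in np.geomspace(0.05, 1e-12, 14)]
    return pairs


def _u_coord(pair: tuple[float, float]) -> float:
    """Monotone log-stretched coordinate of a composition pair."""
    xa, xb = pair
    return math.log(xa) if xa <= 0.5 else -math.log(xb)


def _spinodal_window(ctx: BinaryContext) -> tuple[int, int, list] | None:
    """Indices bracketing the unstable region on the scan grid.

    Instability is judged from the slope of d(Dg)/dx in a log-stretched
    coordinate, which keeps the test well-conditioned at the edges.
    """
    pairs = _pair_grid()
    u = np.array([_u_coord(q) for q in pairs])
    dg = []
    for xa, xb in pairs:
        try:
            dg.append(ctx.dgibbs_mix_pair(xa, xb))
        except (SaftError, ValueError):
            dg.append(np.nan)
    dg = np.asarray(dg)
    slope = np.diff(dg) / np.diff(u)
    bad = [i for i in np.where(slope < -1e-8)[0]
           if not (np.isnan(dg[i]) or np.isnan(dg[i + 1]))]
    if not bad:
        return None
    return min(bad), max(bad) + 1, pairs


#: floor for ln(mole fraction) in branch searches; exp(-690) is at the edge
#: of double range
_LN_FLOOR = -690.0


def solve_lle_point(api: ComponentModel, polymer: ComponentModel, T: float,
                    kij: float = 0.0, p: float = P_DEFAULT,
                    context: BinaryContext | None = None,
                    tol: float = 1e-8) -> BinodalPoint | None:
    """Binodal compositions at T, or None when the mixture is stable.

    A curvature scan of the mixing Gibbs energy separates genuine
    one-phase behavior from solver failure; when an unstable window
    exists, the two binodal branches are refined by alternating tangent
    constructions (one phase solved at a time) until the component
    activities match across phases within ``tol`` in ln a.  Branch
    searches run in log-composition coordinates so that strongly
    asymmetric splits (trace polymer in the drug-rich phase) stay
    representable.
    """
    ctx = context or BinaryContext(api, polymer, T, kij, p)
    window = _spinodal_window(ctx)
    if window is None:
        return None
    i_lo, i_hi, pairs = window
    lean_hi = pairs[i_lo]   # last scanned pair before the unstable run
    rich_lo = pairs[i_hi]   # first scanned pair after it

    def G(pair):
        return ctx.gibbs_mix_pair(*pair)

    def dG(pair):
        return ctx.dgibbs_mix_pair(*pair)

    def tangent_root(other, to_pair, u_lo, u_hi):
        """u in [u_lo, u_hi] where the tangent at to_pair(u) hits `other`."""
        g_o = G(other)

        def f(u):
            pair = to_pair(u)
            # x_other - x expressed through the polymer fractions, which
            # stays exact when both drug fractions are close to 1
            dx = pair[1] - other[1]
            return dG(pair) * dx - (g_o - G(pair))

        us = np.linspace(u_lo, u_hi, 16)
        vals = []
        for uv in us:
            try:
                vals.append(f(float(uv)))
            except (SaftError, ValueError):
                vals.append(np.nan)
        for i in range(len(us) - 1):
            va, vb = vals[i], vals[i + 1]
            if np.isnan(va) or np.isnan(vb) or va * vb > 0:
                continue
            return float(brentq(f, us[i], us[i + 1], xtol=1e-13,
                                rtol=8.9e-16))
        return None

    lean_pair = (max(lean_hi[0] * 0.5, 1e-13), 1.0 - max(lean_hi[0] * 0.5, 1e-13))
    rich_pair = rich_lo
    resid = math.inf

    def to_lean(u):
        xa = math.exp(u)
        return (xa, 1.0 - xa)

    def to_rich(v):
        xb = math.exp(v)
        return (1.0 - xb, xb)

    for _ in range(60):
        u = tangent_root(rich_pair, to_lean, _LN_FLOOR,
                         math.log(lean_hi[0]))
        if u is None:
            raise EquilibriumError(
                f"alternating-tangent iteration lost the drug-lean branch "
                f"at T={T} K")
        lean_pair = to_lean(u)
        v = tangent_root(lean_pair, to_rich, _LN_FLOOR,
                         math.log(rich_lo[1]))
        if v is None:
            # polymer effectively fully excluded from the drug-rich phase:
            # the drug-rich phase is pure drug; close the system on
            # unit drug activity instead
            return _pure_rich_split(ctx, T, math.log(lean_hi[0]), tol)
        rich_pair = to_rich(v)
        la1 = ctx.ln_activities_pair(*lean_pair)
        la2 = ctx.ln_activities_pair(*rich_pair)
        resid = float(np.max(np.abs(la1 - la2)))
        if resid < tol:
            break
    else:
        raise EquilibriumError(
            f"alternating tangents did not converge at T={T} K "
            f"(activity residual {resid:.3e})")
    if abs(rich_pair[0] - lean_pair[0]) < 1e-8:
        return None  # trivial root: no physical split
    return BinodalPoint(T=T, x_L1=lean_pair[0], x_L2=rich_pair[0],
                        activity_residual=resid,
                        ln_x_poly_L2=math.log(rich_pair[1]))


def _pure_rich_split(ctx: BinaryContext, T: float, u_hi: float,
                     tol: float) -> BinodalPoint | None:
    """Degenerate split against an (effectively) pure drug-rich phase.

    When the polymer mole fraction in the drug-rich phase underflows,
    the equilibrium conditions collapse to unit drug activity in the
    lean phase; the trace polymer content is reported in ln space.
    """
    def f(u):
        xa = math.exp(u)
        return float(ctx.ln_activities_pair(xa, 1.0 - xa)[0])

    us = np.linspace(_LN_FLOOR, u_hi, 24)
    vals = []
    for uv in us:
        try:
            vals.append(f(float(uv)))
        except (SaftError, ValueError):
            vals.append(np.nan)
    root = None
    for i in range(len(us) - 1):
        va, vb = vals[i], vals[i + 1]
        if np.isnan(va) or np.isnan(vb) or va * vb > 0:
            continue
        root = float(brentq(f, us[i], us[i + 1], xtol=1e-13, rtol=8.9e-16))
    if root is None:
        return None
    x1 = math.exp(root)
    la = ctx.ln_activities_pair(x1, 1.0 - x1)
    # ln x_poly in the rich phase from the polymer activity equality,
    # evaluated against the pure-drug limit of the polymer's ln gamma
    lng_inf = float(ctx.ln_gamma(1.0 - 1e-12)[1])
    return BinodalPoint(T=T, x_L1=x1, x_L2=1.0,
                        activity_residual=abs(la[0]),
                        ln_x_poly_L2=float(la[1]) - lng_inf,
                        pure_rich=True)


def aaps_scan(api: ComponentModel, polymer: ComponentModel,
              T_range: tuple[float, float] = (200.0, 600.0),
              step: float = 2.0, kij: float = 0.0, p: float = P_DEFAULT,
              strategy: str = "REF") -> BinodalCurve:
    """Scan temperatures for demixing; empty curve means no AAPS predicted."""
    lo, hi = T_range
    if not (0 < lo < hi):
        raise ValueError(f"bad temperature range {T_range}")
    curve = BinodalCurve(api=api.name, polymer=polymer.name,
                         strategy=strategy, kij=kij)
    for T in np.arange(lo, hi + 1e-9, step):
        try:
            pt = solve_lle_point(api, polymer, float(T), kij, p)
        except (EquilibriumError, SaftError) as exc:
            curve.failures.append((float(T), str(exc)))
            continue
        if pt is not None:
            curve.points.append(pt)
    return curve


# ---------------------------------------------------------------------------
# phase-diagram bundle and serialization
# ---------------------------------------------------------------------------

@dataclass
class PhaseDiagram:
    api: str
    polymer: str
    strategy: str
    kij: float
    solubility: SolubilityCurve
    binodal: BinodalCurve
    M_api: float
    M_poly: float


def build_phase_diagram(api: ComponentModel, polymer: ComponentModel,
                        fusion: FusionProperties, strategy: str = "REF",
                        kij: float = 0.0, p: float = P_DEFAULT,
                        sle_grid=None,
                        aaps_range: tuple[float, float] = (200.0, 600.0),
                        aaps_step: float = 2.0) -> PhaseDiagram:
    sle = solubility_curve(api, polymer, fusion, sle_grid, kij, p,
                           strategy=strategy)
    lle = aaps_scan(api, polymer, aaps_range, aaps_step, kij, p,
                    strategy=strategy)
    return PhaseDiagram(api=api.name, polymer=polymer.name, strategy=strategy,
                        kij=kij, solubility=sle, binodal=lle,
                        M_api=api.molar_mass, M_poly=polymer.molar_mass)


_HEADER = "T_K\tx_api\tw_api\tbranch"


def write_phase_diagram(diagram: PhaseDiagram, path: str | Path) -> None:
    """Fixed-precision delimited text, one row per curve point."""
    lines = [f"# api={diagram.api} polymer={diagram.polymer} "
             f"strategy={diagram.strategy} kij={diagram.kij:.6f} "
             f"M_api={diagram.M_api:.4f} M_poly={diagram.M_poly:.4f}",
             _HEADER]
    for pt in diagram.solubility.points:
        lines.append(f"{pt.T:.4f}\t{pt.x_api:.10e}\t{pt.w_api:.10e}\tSLE")
    for bp in diagram.binodal.points:
        for x, branch in ((bp.x_L1, "AAPS_L1"), (bp.x_L2, "AAPS_L2")):
            w = mole_weight_convert(x, diagram.M_api, diagram.M_poly)
            lines.append(f"{bp.T:.4f}\t{x:.10e}\t{w:.10e}\t{branch}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_phase_diagram(path: str | Path) -> PhaseDiagram:
    text = Path(path).read_text().strip().splitlines()
    meta = dict(tok.split("=") for tok in text[0].lstrip("# ").split())
    sle = SolubilityCurve(api=meta["api"], polymer=meta["polymer"],
                          strategy=meta["strategy"], kij=float(meta["kij"]))
    lle = BinodalCurve(api=meta["api"], polymer=meta["polymer"],
                       strategy=meta["strategy"], kij=float(meta["kij"]))
    pending: dict[float, dict[str, float]] = {}
    for line in text[2:]:
        T_s, x_s, w_s, branch = line.split("\t")
        T, x, w = float(T_s), float(x_s), float(w_s)
        if branch == "SLE":
            sle.points.append(SlePoint(T, x, w, 0.0))
        else:
            pending.setdefault(T, {})[branch] = x
    for T, bx in sorted(pending.items()):
        lle.points.append(BinodalPoint(T=T, x_L1=bx["AAPS_L1"],
                                       x_L2=bx["AAPS_L2"],
                                       activity_residual=0.0))
    return PhaseDiagram(api=meta["api"], polymer=meta["polymer"],
                        strategy=meta["strategy"], kij=float(meta["kij"]),
                        solubility=sle, binodal=lle,
                        M_api=float(meta["M_api"]),
                        M_poly=float(meta["M_poly"]))
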