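"""Segment-based PC-SAFT equation of state.

Residual Helmholtz energy as hard-chain + dispersion + association,
formulated on segment types so that both homopolymers (one segment type)
and copolymers (several segment types with bond fractions) are supported.

Internal units: temperature K, length angstrom (A), number density in
molecules per A^3, pressure Pa.  Energies are reduced by k_B throughout
(u/kB and epsHB/kB carry units of K).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np

K_BOLTZMANN = 1.380649e-23  # J/K
N_AVOGADRO = 6.02214076e23  # 1/mol
R_GAS = K_BOLTZMANN * N_AVOGADRO  # J/(mol K)

#: close-packing bound for the packing fraction of hard spheres
ETA_MAX = 0.7405

# Universal model constants for the dispersion power series
# (rows: order in the chain-length correction; columns: eta powers 0..6).
_A_UNIV = np.array([
    [0.9105631445, 0.6361281449, 2.6861347891, -26.547362491,
     97.759208784, -159.59154087, 91.297774084],
    [-0.3084016918, 0.1860531159, -2.5030047259, 21.419793629,
     -65.255885330, 83.318680481, -33.746922930],
    [-0.0906148351, 0.4527842806, 0.5962700728, -1.7241829131,
     -4.1302112531, 13.776631870, -8.6728470368],
])
_B_UNIV = np.array([
    [0.7240946941, 2.2382791861, -4.0025849485, -21.003576815,
     26.855641363, 206.55133841, -355.60235612],
    [-0.5755498075, 0.6995095521, 3.8925673390, -17.215471648,
     192.67226447, -161.82646165, -165.20769346],
    [0.0976883116, -0.2557574982, -9.1558561530, 20.642075974,
     -38.804430052, 93.626774077, -29.666905585],
])

_K_POWERS = np.arange(7.0)


class SaftError(Exception):
    """Base class for equation-of-state failures."""


class InvalidParameterError(SaftError, ValueError):
    """Parameter set violates its physical constraints."""


class InvalidStateError(SaftError, ValueError):
    """Requested thermodynamic state is outside the model's validity."""


class ConvergenceError(SaftError, RuntimeError):
    """An iterative solver did not reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class NoDensityRootError(SaftError, RuntimeError):
    """No density root matching the request exists in the search bracket."""


class PureStateError(SaftError, RuntimeError):
    """The pure-liquid reference state could not be solved."""


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentParameters:
    """Per-segment-type PC-SAFT parameters.

    ``segment_count_ratio`` is m/M in mol/g: the number of segments this
    monomer contributes per gram of chain mass.  ``n_donor`` and
    ``n_acceptor`` are hydrogen-bond site counts per molecule hosted on
    this segment type.
    """

    segment_count_ratio: float
    sigma: float
    u_over_kB: float
    epsHB_over_kB: float = 0.0
    kappaHB: float = 0.0
    n_donor: int = 0
    n_acceptor: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")
        if self.u_over_kB <= 0:
            raise InvalidParameterError(f"u/kB must be positive, got {self.u_over_kB}")
        if self.segment_count_ratio <= 0:
            raise InvalidParameterError("m/M must be positive")
        if self.kappaHB < 0 or self.epsHB_over_kB < 0:
            raise InvalidParameterError("association parameters must be nonnegative")
        if self.epsHB_over_kB > 0 and self.kappaHB == 0:
            raise InvalidParameterError("epsHB > 0 requires kappaHB > 0")
        if self.n_donor < 0 or self.n_acceptor < 0:
            raise InvalidParameterError("site counts must be nonnegative")
        if (self.n_donor != int(self.n_donor)) or (self.n_acceptor != int(self.n_acceptor)):
            raise InvalidParameterError("site counts must be integers")


@dataclass(frozen=True)
class CrossParameters:
    sigma: float
    u_over_kB: float
    epsHB_over_kB: float
    kappaHB: float


def cross_parameters(seg_i: SegmentParameters, seg_j: SegmentParameters,
                     kij: float = 0.0) -> CrossParameters:
    """Conventional combining rules between two segment types.

    sigma: arithmetic mean; dispersion energy: geometric mean corrected by
    (1 - kij); association energy: arithmetic mean; association volume:
    geometric mean scaled by the cubed ratio of geometric to arithmetic
    mean diameters.  A partner with sites but zero self-association energy
    still picks up half the other partner's energy (induced
    cross-association).
    """
    u = math.sqrt(seg_i.u_over_kB * seg_j.u_over_kB) * (1.0 - kij)
    if u < 0:
        raise InvalidParameterError(
            f"cross dispersion energy became negative (kij={kij})")
    sig = 0.5 * (seg_i.sigma + seg_j.sigma)
    eps = 0.5 * (seg_i.epsHB_over_kB + seg_j.epsHB_over_kB)
    kap = math.sqrt(seg_i.kappaHB * seg_j.kappaHB) * (
        math.sqrt(seg_i.sigma * seg_j.sigma) / sig) ** 3
    return CrossParameters(sigma=sig, u_over_kB=u, epsHB_over_kB=eps, kappaHB=kap)


@dataclass(frozen=True)
class ComponentModel:
    """A chain molecule built from one or more segment types.

    ``segments`` holds (parameters, mass fraction of the chain) pairs; the
    number of segments of type alpha is (m/M)_alpha * molar_mass *
    mass_fraction_alpha.  ``bond_fractions`` optionally assigns the
    fraction of chain bonds joining each unordered segment-type pair;
    when omitted, bonds are distributed proportionally to segment-number
    fractions (random copolymer).
    """

    name: str
    molar_mass: float
    segments: tuple[tuple[SegmentParameters, float], ...]
    bond_fractions: tuple[tuple[tuple[int, int], float], ...] | None = None
    role: str = "API"

    def __post_init__(self):
        if self.molar_mass <= 0:
            raise InvalidParameterError(f"molar mass must be positive for {self.name}")
        fracs = [f for _, f in self.segments]
        if not self.segments or any(f <= 0 for f in fracs):
            raise InvalidParameterError("segment fractions must be positive")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"segment mass fractions must sum to 1, got {sum(fracs)}")
        if self.m <= 0:
            raise InvalidParameterError("total segment number must be positive")
        if self.bond_fractions is not None:
            tot = sum(f for _, f in self.bond_fractions)
            if abs(tot - 1.0) > 1e-9:
                raise InvalidParameterError("bond fractions must sum to 1")

    @property
    def m_alpha(self) -> np.ndarray:
        """Segment numbers per type."""
        return np.array([p.segment_count_ratio * self.molar_mass * f
                         for p, f in self.segments])

    @property
    def m(self) -> float:
        """Total segment number of the chain."""
        return float(self.m_alpha.sum())

    @property
    def segment_fractions(self) -> np.ndarray:
        ma = self.m_alpha
        return ma / ma.sum()

    def bond_matrix(self) -> np.ndarray:
        """Number of bonds joining each unordered segment-type pair.

        Entries sum to m - 1 over the upper triangle (incl. diagonal).
        """
        n = len(self.segments)
        nbonds = self.m - 1.0
        out = np.zeros((n, n))
        if nbonds <= 0:
            return out
        if self.bond_fractions is not None:
            for (a, b), f in self.bond_fractions:
                out[a, b] += f * nbonds
                if a != b:
                    out[b, a] = out[a, b]
            return out
        z = self.segment_fractions
        for a in range(n):
            for b in range(n):
                out[a, b] = z[a] * z[b] * nbonds
        # fold ordered pairs into unordered bookkeeping
        return out

    def has_sites(self) -> bool:
        return any(p.n_donor > 0 or p.n_acceptor > 0 for p, _ in self.segments)


def make_homopolymer(name: str, molar_mass: float, params: SegmentParameters,
                     role: str = "polymer") -> ComponentModel:
    return ComponentModel(name=name, molar_mass=molar_mass,
                          segments=((params, 1.0),), role=role)


@dataclass(frozen=True)
class MixtureSpec:
    """Components, mole fractions and the binary-interaction matrix."""

    components: tuple[ComponentModel, ...]
    mole_fractions: tuple[float, ...]
    kij: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self):
        x = np.asarray(self.mole_fractions, dtype=float)
        if np.any(x < 0):
            raise InvalidParameterError("mole fractions must be nonnegative")
        if abs(x.sum() - 1.0) > 1e-12:
            raise InvalidParameterError(
                f"mole fractions must sum to 1 within 1e-12, got {x.sum()!r}")
        k = self.kij_matrix()
        if not np.allclose(k, k.T):
            raise InvalidParameterError("kij matrix must be symmetric")
        if np.any(np.abs(np.diag(k)) > 0):
            raise InvalidParameterError("kij diagonal must be zero")

    def kij_matrix(self) -> np.ndarray:
        n = len(self.components)
        if self.kij is None:
            return np.zeros((n, n))
        return np.asarray(self.kij, dtype=float)

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.mole_fractions, dtype=float)


def binary_mixture(comp_a: ComponentModel, comp_b: ComponentModel,
                   x_a: float, kij: float = 0.0) -> MixtureSpec:
    """Convenience constructor for the ubiquitous two-component case."""
    return MixtureSpec(components=(comp_a, comp_b),
                       mole_fractions=(x_a, 1.0 - x_a),
                       kij=((0.0, kij), (kij, 0.0)))


# ---------------------------------------------------------------------------
# evaluation workspace
# ---------------------------------------------------------------------------

@dataclass
class HelmholtzBreakdown:
    hc: float
    disp: float
    assoc: float

    @property
    def total(self) -> float:
        return self.hc + self.disp + self.assoc


@dataclass
class StateEval:
    """One evaluation of the reduced residual Helmholtz energy and Z."""

    a_res: float
    breakdown: HelmholtzBreakdown
    Z: float
    site_fractions: np.ndarray  # per site class; empty if no sites
    eta: float
    dadx: np.ndarray | None = None  # unconstrained d(a_res)/dx_k at fixed rho


@dataclass
class ResidualState:
    temperature: float
    pressure: float
    density: float  # molecules / A^3
    eta: float
    Z: float
    a_res_reduced: float
    breakdown: HelmholtzBreakdown
    ln_phi: np.ndarray


class Workspace:
    """Precomputed, composition-independent tables for one (mixture, T).

    Building a workspace is the expensive step; evaluations at varying
    (x, rho) reuse it, which is what the phase-equilibrium iterations rely
    on for speed.
    """

    def __init__(self, components: Sequence[ComponentModel], kij: np.ndarray,
                 T: float):
        if T <= 0:
            raise InvalidStateError(f"temperature must be positive, got {T}")
        self.components = tuple(components)
        self.T = float(T)
        self.kij = np.asarray(kij, dtype=float)
        ncomp = len(self.components)

        self.m = np.array([c.m for c in self.components])

        # flat list of segment slots (component index, local type index)
        slots: list[tuple[int, int, SegmentParameters, float]] = []
        for i, comp in enumerate(self.components):
            ma = comp.m_alpha
            for a, (par, _) in enumerate(comp.segments):
                slots.append((i, a, par, float(ma[a])))
        self.slot_comp = np.array([s[0] for s in slots], dtype=int)
        self.slot_m = np.array([s[3] for s in slots])
        sigma = np.array([s[2].sigma for s in slots])
        u = np.array([s[2].u_over_kB for s in slots])
        # temperature-dependent hard-sphere diameters
        self.d = sigma * (1.0 - 0.12 * np.exp(-3.0 * u / T))
        nslot = len(slots)

        # zeta prefactors per component: c[n, i] = sum_alpha m_ia d_a^n
        self.czeta = np.zeros((4, ncomp))
        for n in range(4):
            np.add.at(self.czeta[n], self.slot_comp, self.slot_m * self.d ** n)

        # dispersion: component-pair sums over segment pairs
        a1 = np.zeros((ncomp, ncomp))
        a2 = np.zeros((ncomp, ncomp))
        for s in range(nslot):
            i, _, pi, mi = slots[s]
            for t in range(nslot):
                j, _, pj, mj = slots[t]
                cr = cross_parameters(pi, pj, self.kij[i, j])
                us = cr.u_over_kB / T
                s3 = cr.sigma ** 3
                a1[i, j] += mi * mj * us * s3
                a2[i, j] += mi * mj * us * us * s3
        self.A1 = a1
        self.A2 = a2

        # hard-chain bond bookkeeping: per component, arrays of
        # (q = d_a d_b / (d_a + d_b), bond count)
        self.bond_comp: list[int] = []
        self.bond_q: list[float] = []
        self.bond_n: list[float] = []
        slot_of = {}
        for s, (i, a, _, _) in enumerate(slots):
            slot_of[(i, a)] = s
        for i, comp in enumerate(self.components):
            bm = comp.bond_matrix()
            na = len(comp.segments)
            for a in range(na):
                for b in range(a, na):
                    nb = bm[a, b] if a == b else bm[a, b] + bm[b, a]
                    if nb <= 0:
                        continue
                    da = self.d[slot_of[(i, a)]]
                    db = self.d[slot_of[(i, b)]]
                    self.bond_comp.append(i)
                    self.bond_q.append(da * db / (da + db))
                    self.bond_n.append(nb)
        self.bond_comp = np.array(self.bond_comp, dtype=int)
        self.bond_q = np.array(self.bond_q)
        self.bond_n = np.array(self.bond_n)

        # association site classes
        site_comp: list[int] = []
        site_n: list[float] = []
        site_kind: list[int] = []  # 0 donor, 1 acceptor
        site_slot: list[int] = []
        self.site_labels: list[tuple[str, str]] = []
        for s, (i, a, par, _) in enumerate(slots):
            comp = self.components[i]
            for kind, count in ((0, par.n_donor), (1, par.n_acceptor)):
                if count > 0 and par.kappaHB > 0:
                    site_comp.append(i)
                    site_n.append(float(count))
                    site_kind.append(kind)
                    site_slot.append(s)
                    self.site_labels.append(
                        (comp.name, ("donor" if kind == 0 else "acceptor")
                         + (f"@{a}" if len(comp.segments) > 1 else "")))
        self.site_comp = np.array(site_comp, dtype=int)
        self.site_n = np.array(site_n)
        nsite = len(site_comp)
        self.nsite = nsite
        # pairwise association strength prefactors and g-related q values
        self.assoc_K = np.zeros((nsite, nsite))
        self.assoc_q = np.zeros((nsite, nsite))
        for s in range(nsite):
            ps = slots[site_slot[s]][2]
            for t in range(nsite):
                if site_kind[s] == site_kind[t]:
                    continue  # donors bond only to acceptors
                pt = slots[site_slot[t]][2]
                cr = cross_parameters(ps, pt, 0.0)
                if cr.kappaHB <= 0 or cr.epsHB_over_kB <= 0:
                    continue
                self.assoc_K[s, t] = cr.sigma ** 3 * cr.kappaHB * math.expm1(
                    cr.epsHB_over_kB / T)
                ds = self.d[site_slot[s]]
                dt = self.d[site_slot[t]]
                self.assoc_q[s, t] = ds * dt / (ds + dt)
        self._site_eye = np.eye(nsite)

    # -- helpers ----------------------------------------------------------

    def eta_coefficient(self, x: np.ndarray) -> float:
        """zeta3 / rho for the given (possibly unnormalized) composition."""
        return math.pi / 6.0 * float(self.czeta[3] @ x)

    def rho_from_eta(self, eta: float, x: np.ndarray) -> float:
        return eta / self.eta_coefficient(x)

    # -- association ------------------------------------------------------

    def _solve_sites(self, x: np.ndarray, rho: float, g_assoc: np.ndarray,
                     X0: np.ndarray | None) -> np.ndarray:
        """Damped successive substitution on the mass-action equations."""
        n = self.nsite
        A = (self.assoc_K * g_assoc) * (rho * (x[self.site_comp]
                                               * self.site_n))[None, :]
        X = np.full(n, 0.5) if X0 is None else X0.copy()
        eye = self._site_eye
        # Newton with damped-substitution fallback steps; machine-tight
        # tolerance because downstream derivatives amplify residual noise
        for _ in range(300):
            AX = A @ X
            F = X * (1.0 + AX) - 1.0
            if np.abs(F).max() < 1e-14:
                return X
            J = eye * (1.0 + AX)[:, None] + X[:, None] * A
            try:
                Xn = X - np.linalg.solve(J, F)
            except np.linalg.LinAlgError:
                Xn = None
            if Xn is not None and (Xn > 0.0).all() and (Xn <= 1.0 + 1e-12).all():
                X = np.minimum(Xn, 1.0)
            else:
                X = 0.5 * (X + 1.0 / (1.0 + AX))
        F = X * (1.0 + A @ X) - 1.0
        last = float(np.abs(F).max())
        if last < 1e-12:
            return X
        raise ConvergenceError(
            f"association solver did not converge (residual {last:.3e})",
            residual=last)

    # -- main evaluation --------------------------------------------------

    def evaluate(self, x: np.ndarray, rho: float,
                 X0: np.ndarray | None = None,
                 derivatives: bool = False) -> StateEval:
        """Reduced residual Helmholtz energy, breakdown and Z at (x, rho).

        ``x`` may be unnormalized (needed for unconstrained composition
        derivatives); all expressions are evaluated literally.  With
        ``derivatives`` the analytic unconstrained composition gradient of
        the total (at fixed rho and T) is returned as well.
        """
        x = np.asarray(x, dtype=float)
        if rho < 0:
            raise InvalidStateError("density must be nonnegative")
        zdot = (math.pi / 6.0 * rho) * self.czeta  # d zeta_n / d x_k
        z0, z1, z2, z3 = zdot @ x
        if z3 >= ETA_MAX:
            raise InvalidStateError(
                f"packing fraction {z3:.4f} at or above close packing")
        eta = z3
        mbar = float(self.m @ x)
        om = 1.0 - eta
        ncomp = len(self.components)

        if rho == 0.0 or z0 == 0.0:
            bd = HelmholtzBreakdown(0.0, 0.0, 0.0)
            return StateEval(0.0, bd, 1.0, np.ones(self.nsite), 0.0,
                             np.zeros(ncomp) if derivatives else None)

        log_om = math.log(om)
        # hard sphere (per segment), its density derivative, and its
        # gradient in the zeta variables
        Nhs = (3.0 * z1 * z2 / om + z2 ** 3 / (z3 * om * om)
               + (z2 ** 3 / z3 ** 2 - z0) * log_om)
        a_hs = Nhs / z0
        Z_hs = (z3 / om + 3.0 * z1 * z2 / (z0 * om * om)
                + z2 ** 3 * (3.0 - z3) / (z0 * om ** 3))

        # chain connectivity: site-site contact values for bonded pairs
        def g_and_rdg(q):
            g = 1.0 / om + q * 3.0 * z2 / (om * om) + q * q * 2.0 * z2 * z2 / om ** 3
            rdg = (z3 / (om * om)
                   + q * (3.0 * z2 / (om * om) + 6.0 * z2 * z3 / om ** 3)
                   + q * q * (4.0 * z2 * z2 / om ** 3 + 6.0 * z2 * z2 * z3 / om ** 4))
            return g, rdg

        def g_grad(q):
            """(dg/dzeta2, dg/dzeta3) for contact pair parameter q."""
            dg2 = 3.0 * q / (om * om) + 4.0 * q * q * z2 / om ** 3
            dg3 = (1.0 / (om * om) + 6.0 * q * z2 / om ** 3
                   + 6.0 * q * q * z2 * z2 / om ** 4)
            return dg2, dg3

        a_chain = 0.0
        Z_chain = 0.0
        g_b = rdg_b = None
        if self.bond_q.size:
            g_b, rdg_b = g_and_rdg(self.bond_q)
            xb = x[self.bond_comp] * self.bond_n
            a_chain = -float(xb @ np.log(g_b))
            Z_chain = -float(xb @ (rdg_b / g_b))
        a_hc = mbar * a_hs + a_chain
        Z_hc = mbar * Z_hs + Z_chain

        # dispersion
        mm1 = (mbar - 1.0) / mbar
        mm2 = mm1 * (mbar - 2.0) / mbar
        acoef = _A_UNIV[0] + mm1 * _A_UNIV[1] + mm2 * _A_UNIV[2]
        bcoef = _B_UNIV[0] + mm1 * _B_UNIV[1] + mm2 * _B_UNIV[2]
        etap = eta ** _K_POWERS
        I1 = float(acoef @ etap)
        I2 = float(bcoef @ etap)
        dI1 = float(acoef @ ((_K_POWERS + 1.0) * etap))  # d(eta I1)/d eta
        dI2 = float(bcoef @ ((_K_POWERS + 1.0) * etap))
        f1 = (8.0 * eta - 2.0 * eta * eta) / om ** 4
        f2 = (20.0 * eta - 27.0 * eta ** 2 + 12.0 * eta ** 3
              - 2.0 * eta ** 4) / (om * (2.0 - eta)) ** 2
        C1 = 1.0 / (1.0 + mbar * f1 + (1.0 - mbar) * f2)
        C2 = -C1 * C1 * (mbar * (-4.0 * eta * eta + 20.0 * eta + 8.0) / om ** 5
                         + (1.0 - mbar) * (2.0 * eta ** 3 + 12.0 * eta ** 2
                                           - 48.0 * eta + 40.0)
                         / (om * (2.0 - eta)) ** 3)
        A1x = self.A1 @ x
        A2x = self.A2 @ x
        s1 = float(x @ A1x)
        s2 = float(x @ A2x)
        a_disp = -2.0 * math.pi * rho * I1 * s1 - math.pi * rho * mbar * C1 * I2 * s2
        Z_disp = (-2.0 * math.pi * rho * dI1 * s1
                  - math.pi * rho * mbar * (C1 * dI2 + C2 * eta * I2) * s2)

        # association
        a_assoc = 0.0
        Z_assoc = 0.0
        X = np.ones(self.nsite)
        g_a = rdg_a = wX = None
        if self.nsite:
            g_a, rdg_a = g_and_rdg(self.assoc_q)
            X = self._solve_sites(x, rho, g_a, X0)
            w = x[self.site_comp] * self.site_n
            a_assoc = float(w @ (np.log(X) - 0.5 * X + 0.5))
            # stationarity of the association functional: only the explicit
            # density dependence (rho itself and g) contributes
            delta = self.assoc_K * g_a
            wX = w * X
            Z_assoc = -0.5 * rho * float(
                wX @ ((delta + self.assoc_K * rdg_a) @ wX))

        bd = HelmholtzBreakdown(hc=a_hc, disp=a_disp, assoc=a_assoc)
        Z = 1.0 + Z_hc + Z_disp + Z_assoc
        if not derivatives:
            return StateEval(bd.total, bd, Z, X, eta)

        # ---- analytic unconstrained composition gradient at fixed rho ----
        # hard-sphere part via its zeta gradient: a_hs = N/zeta0
        dN = np.array([
            -log_om,
            3.0 * z2 / om,
            (3.0 * z1 / om + 3.0 * z2 ** 2 / (z3 * om * om)
             + 3.0 * z2 ** 2 / z3 ** 2 * log_om),
            (3.0 * z1 * z2 / (om * om)
             + z2 ** 3 * (2.0 / (z3 * om ** 3) - 1.0 / (z3 ** 2 * om ** 2))
             - 2.0 * z2 ** 3 / z3 ** 3 * log_om
             - (z2 ** 3 / z3 ** 2 - z0) / om),
        ])
        da_hs_dz = dN / z0
        da_hs_dz[0] -= a_hs / z0
        dahs_dx = da_hs_dz @ zdot  # shape (ncomp,)

        dadx = self.m * a_hs + mbar * dahs_dx
        if self.bond_q.size:
            dg2_b, dg3_b = g_grad(self.bond_q)
            xb = x[self.bond_comp] * self.bond_n
            # explicit x_k factor of component-k bonds
            np.add.at(dadx, self.bond_comp, -self.bond_n * np.log(g_b))
            coef = xb / g_b
            dadx -= (float(coef @ dg2_b) * zdot[2] + float(coef @ dg3_b) * zdot[3])

        # dispersion gradient
        dmm1 = 1.0 / mbar ** 2
        dmm2 = (3.0 * mbar - 4.0) / mbar ** 3
        dI1_dm = float((dmm1 * _A_UNIV[1] + dmm2 * _A_UNIV[2]) @ etap)
        dI2_dm = float((dmm1 * _B_UNIV[1] + dmm2 * _B_UNIV[2]) @ etap)
        I1p = float(acoef @ (_K_POWERS * eta ** np.maximum(_K_POWERS - 1.0, 0.0)))
        I2p = float(bcoef @ (_K_POWERS * eta ** np.maximum(_K_POWERS - 1.0, 0.0)))
        dC1_dm = -C1 * C1 * (f1 - f2)
        deta_dx = zdot[3]
        dadx += (-2.0 * math.pi * rho) * (
            (I1p * deta_dx + dI1_dm * self.m) * s1 + I1 * 2.0 * A1x)
        dadx += (-math.pi * rho) * (
            self.m * C1 * I2 * s2
            + mbar * (C2 * deta_dx + dC1_dm * self.m) * I2 * s2
            + mbar * C1 * (I2p * deta_dx + dI2_dm * self.m) * s2
            + mbar * C1 * I2 * 2.0 * A2x)

        # association gradient: stationarity leaves the explicit terms
        if self.nsite:
            lnX_site = self.site_n * np.log(X)
            np.add.at(dadx, self.site_comp, lnX_site)
            dg2_a, dg3_a = g_grad(self.assoc_q)
            q2 = 0.5 * rho * float(wX @ ((self.assoc_K * dg2_a) @ wX))
            q3 = 0.5 * rho * float(wX @ ((self.assoc_K * dg3_a) @ wX))
            dadx -= q2 * zdot[2] + q3 * zdot[3]

        return StateEval(bd.total, bd, Z, X, eta, dadx)

    def pressure(self, x: np.ndarray, rho: float,
                 X0: np.ndarray | None = None) -> float:
        st = self.evaluate(x, rho, X0)
        return st.Z * rho * 1e30 * K_BOLTZMANN * self.T

    # -- density solving --------------------------------------------------

    def solve_density(self, x: np.ndarray, p: float,
                      phase_hint: str | None = "liquid",
                      eta_init: float | None = None) -> tuple[float, float]:
        """Return (rho, eta) with p_calc(rho) = p on the requested branch."""
        from scipy.optimize import brentq

        if p <= 0:
            raise InvalidStateError("pressure must be positive")
        x = np.asarray(x, dtype=float)
        c3 = self.eta_coefficient(x)
        X_warm: list[np.ndarray | None] = [None]

        def f(eta):
            rho = eta / c3
            st = self.evaluate(x, rho, X0=X_warm[0])
            X_warm[0] = st.site_fractions
            return st.Z * rho * 1e30 * K_BOLTZMANN * self.T - p

        lo_eta = 1e-14
        # warm start: try successively wider local brackets first
        if eta_init is not None and 0 < eta_init < 0.72:
            a, b = max(lo_eta, eta_init * 0.998), min(0.73, eta_init * 1.002)
            try:
                fa, fb = f(a), f(b)
                for _ in range(30):
                    if fa * fb <= 0:
                        eta = brentq(f, a, b, xtol=1e-14, rtol=8.9e-16)
                        return eta / c3, eta
                    a, b = max(lo_eta, a * 0.93), min(0.73, b * 1.05)
                    fa, fb = f(a), f(b)
            except (InvalidStateError, ConvergenceError):
                pass

        # scan for sign changes; floor anchored at the ideal-gas packing
        # fraction so arbitrarily low-pressure vapor roots stay inside the
        # bracket
        eta_ig = p / (K_BOLTZMANN * self.T * 1e30) * c3
        grid = np.concatenate([
            np.geomspace(max(min(1e-12, eta_ig * 1e-2), 1e-35), 1e-3, 18),
            np.linspace(2e-3, 0.73, 60)])
        if phase_hint == "liquid":
            # largest root: walk down from close packing, stop at the
            # first bracket
            prev = None
            for e in grid[::-1]:
                try:
                    v = f(e)
                except (InvalidStateError, ConvergenceError):
                    prev = None
                    continue
                if prev is not None and v * prev[1] <= 0:
                    eta = brentq(f, e, prev[0], xtol=1e-14, rtol=8.9e-16)
                    return eta / c3, eta
                prev = (e, v)
            raise NoDensityRootError(
                f"no liquid density root for p={p} Pa at T={self.T} K")
        if phase_hint == "vapor":
            prev = None
            for e in grid:
                try:
                    v = f(e)
                except (InvalidStateError, ConvergenceError):
                    prev = None
                    continue
                if prev is not None and v * prev[1] <= 0:
                    eta = brentq(f, prev[0], e, xtol=1e-14, rtol=8.9e-16)
                    return eta / c3, eta
                prev = (e, v)
            raise NoDensityRootError(
                f"no vapor density root for p={p} Pa at T={self.T} K")
        vals = []
        for e in grid:
            try:
                vals.append(f(e))
            except (InvalidStateError, ConvergenceError):
                vals.append(np.nan)
        roots = []
        for i in range(len(grid) - 1):
            va, vb = vals[i], vals[i + 1]
            if np.isnan(va) or np.isnan(vb) or va * vb > 0:
                continue
            eta = brentq(f, grid[i], grid[i + 1], xtol=1e-14, rtol=8.9e-16)
            roots.append(eta)
        if not roots:
            raise NoDensityRootError(
                f"no density root for p={p} Pa at T={self.T} K")
        # no hint: lowest molar Gibbs energy,
        # g/RT = a_res + (Z-1) + ln rho + const
        best, eta = np.inf, roots[0]
        for e in roots:
            rho = e / c3
            st = self.evaluate(x, rho)
            g = st.a_res + (st.Z - 1.0) + math.log(rho)
            if g < best:
                best, eta = g, e
        return eta / c3, eta

    # -- fugacity ---------------------------------------------------------

    def ln_phi(self, x: np.ndarray, rho: float) -> np.ndarray:
        """Log fugacity coefficients at fixed (T, rho, x).

        Standard relation from the reduced residual Helmholtz energy, its
        analytic unconstrained composition derivatives (at fixed number
        density) and Z.
        """
        x = np.asarray(x, dtype=float)
        st = self.evaluate(x, rho, derivatives=True)
        if st.Z <= 0:
            raise InvalidStateError("non-positive compressibility factor")
        dadx = st.dadx
        mu_res = st.a_res + (st.Z - 1.0) + dadx - float(x @ dadx)
        return mu_res - math.log(st.Z)


@lru_cache(maxsize=256)
def _workspace_cached(components: tuple[ComponentModel, ...],
                      kij_flat: tuple[float, ...], T: float) -> Workspace:
    n = len(components)
    kij = np.array(kij_flat).reshape(n, n)
    return Workspace(components, kij, T)


def get_workspace(mixture: MixtureSpec, T: float) -> Workspace:
    kij = mixture.kij_matrix()
    return _workspace_cached(mixture.components, tuple(kij.ravel()), float(T))


# ---------------------------------------------------------------------------
# public functional interface
# ---------------------------------------------------------------------------

def reduced_residual_helmholtz(mixture: MixtureSpec, T: float,
                               rho: float) -> HelmholtzBreakdown:
    ws = get_workspace(mixture, T)
    return ws.evaluate(mixture.x, rho).breakdown


def compressibility_factor(mixture: MixtureSpec, T: float, rho: float) -> float:
    ws = get_workspace(mixture, T)
    return ws.evaluate(mixture.x, rho).Z


def pressure(mixture: MixtureSpec, T: float, rho: float) -> float:
    ws = get_workspace(mixture, T)
    return ws.pressure(mixture.x, rho)


def association_site_fractions(mixture: MixtureSpec, T: float,
                               rho: float) -> dict[tuple[str, str], float]:
    """Unbonded site fractions keyed by (component name, site label)."""
    ws = get_workspace(mixture, T)
    st = ws.evaluate(mixture.x, rho)
    return {lab: float(xa) for lab, xa in zip(ws.site_labels, st.site_fractions)}


def solve_density(mixture: MixtureSpec, T: float, p: float,
                  phase_hint: str | None = "liquid") -> tuple[float, float]:
    ws = get_workspace(mixture, T)
    return ws.solve_density(mixture.x, p, phase_hint)


def ln_fugacity_coefficients(mixture: MixtureSpec, T: float, p: float,
                             phase_hint: str | None = "liquid") -> np.ndarray:
    ws = get_workspace(mixture, T)
    rho, _ = ws.solve_density(mixture.x, p, phase_hint)
    return ws.ln_phi(mixture.x, rho)


def residual_state(mixture: MixtureSpec, T: float, p: float,
                   phase_hint: str | None = "liquid") -> ResidualState:
    ws = get_workspace(mixture, T)
    rho, eta = ws.solve_density(mixture.x, p, phase_hint)
    st = ws.evaluate(mixture.x, rho)
    ln_phi = ws.ln_phi(mixture.x, rho)
    return ResidualState(temperature=T, pressure=p, density=rho, eta=eta,
                         Z=st.Z, a_res_reduced=st.a_res, breakdown=st.breakdown,
                         ln_phi=ln_phi)


def pure_ln_phi_liquid(component: ComponentModel, T: float, p: float) -> float:
    """ln phi of the pure liquid; wraps failures in PureStateError."""
    mix = MixtureSpec(components=(component,), mole_fractions=(1.0,))
    try:
        return float(ln_fugacity_coefficients(mix, T, p, "liquid")[0])
    except SaftError as exc:
        raise PureStateError(
            f"pure-liquid state of {component.name} unsolvable at "
            f"T={T} K, p={p} Pa: {exc}") from exc


def activity_coefficient(mixture: MixtureSpec, i: int, T: float,
                         p: float) -> float:
    """gamma_i = phi_i(mixture) / phi_i(pure liquid), same T and p."""
    ln_phi_mix = ln_fugacity_coefficients(mixture, T, p, "liquid")
    ln_phi_pure = pure_ln_phi_liquid(mixture.components[i], T, p)
    return math.exp(float(ln_phi_mix[i]) - ln_phi_pure)
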