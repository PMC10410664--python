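"""Built-in component data, parameter-file loading, fusion thermodynamics.

Drug (API) records ship with the package: molar masses, fusion properties
and two parametrization strategies (REF for all seven drugs, ALT for four
of them).  Polymer molar masses and monomer makeup are built in, but
polymer PC-SAFT segment parameters are user-supplied (literature values
live outside this package); the YAML schema below covers homopolymers,
copolymers and low-molar-mass solvents.

Parameter file schema (YAML, version 1)::

    version: 1
    apis:
      - name: MYAPI
        strategy: REF            # REF | ALT
        molar_mass: 300.0        # g/mol
        m_over_M: 0.02           # mol/g
        sigma: 3.5               # angstrom
        u_over_kB: 300.0         # K
        epsHB_over_kB: 1000.0    # K
        kappaHB: 0.02
        sites: "4 (2, 2)"        # total (donors, acceptors)
        fusion: {T_m: 420.0, dH_fus: 30.0, dCp_a: 100.0, dCp_b: 0.0}
    polymers:
      - name: MYPOLY
        molar_mass: 5000.0
        segments:
          - {monomer: unitA, mass_fraction: 1.0, m_over_M: 0.03,
             sigma: 3.7, u_over_kB: 250.0, epsHB_over_kB: 0.0,
             kappaHB: 0.02, sites: "10 (0, 10)"}
    solvents:
      - name: mysolvent
        molar_mass: 46.07
        m_over_M: 0.05
        sigma: 3.2
        u_over_kB: 200.0
        epsHB_over_kB: 2500.0
        kappaHB: 0.03
        sites: "2 (1, 1)"
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .saft_core import (ComponentModel, InvalidParameterError,
                        SegmentParameters)

logger = logging.getLogger(__name__)

R_GAS = 8.31446261815324  # J/(mol K)


class SchemaError(ValueError):
    """A parameter file violates the documented schema."""


# ---------------------------------------------------------------------------
# fusion thermodynamics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FusionProperties:
    """Melting data of a crystalline drug.

    ``dH_fus`` is in kJ/mol at T_m; the liquid-minus-crystal heat
    capacity difference is the linear function dCp_a + dCp_b * T in
    J/(K mol).
    """

    T_m: float
    dH_fus: float
    dCp_a: float
    dCp_b: float = 0.0
    polymorph: str = ""

    def __post_init__(self):
        if self.T_m <= 0:
            raise InvalidParameterError("T_m must be positive")
        if self.dH_fus <= 0:
            raise InvalidParameterError("enthalpy of fusion must be positive")
        for T in (250.0, self.T_m):
            if self.dCp(T) <= 0:
                raise InvalidParameterError(
                    f"dCp_fus must stay positive on [250 K, T_m]; "
                    f"dCp({T} K) = {self.dCp(T)}")

    def dCp(self, T: float) -> float:
        return self.dCp_a + self.dCp_b * T


def fusion_gibbs_energy(fusion: FusionProperties, T: float) -> float:
    """Molar Gibbs-energy difference liquid minus crystal, J/mol.

    Exact for a linear dCp(T): both the enthalpic integral of dCp and the
    entropic integral of dCp/T are evaluated in closed form.  Zero at T_m
    and positive below it.
    """
    Tm = fusion.T_m
    if T <= 0 or T > Tm:
        raise ValueError(f"T must lie in (0, T_m]; got {T} K with T_m {Tm} K")
    a, b = fusion.dCp_a, fusion.dCp_b
    dH = fusion.dH_fus * 1e3
    int_cp = a * (Tm - T) + 0.5 * b * (Tm * Tm - T * T)
    int_cp_over_T = a * math.log(Tm / T) + b * (Tm - T)
    return dH * (1.0 - T / Tm) - int_cp + T * int_cp_over_T


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

_SITES_RE = re.compile(r"^\s*(\d+)\s*\(\s*(\d+)\s*,\s*(\d+)\s*\)\s*$")


def parse_sites(scheme: str) -> tuple[int, int]:
    """Parse a site scheme like ``"4 (2, 2)"`` into (donors, acceptors)."""
    mobj = _SITES_RE.match(str(scheme))
    if not mobj:
        raise SchemaError(f"cannot parse association scheme {scheme!r}")
    total, don, acc = (int(g) for g in mobj.groups())
    if don + acc != total:
        raise SchemaError(
            f"site scheme {scheme!r}: donors + acceptors != total")
    return don, acc


@dataclass(frozen=True)
class SmallMoleculeRecord:
    """One homonuclear-chain component (drug or solvent)."""

    name: str
    strategy: str
    molar_mass: float
    m_over_M: float
    sigma: float
    u_over_kB: float
    epsHB_over_kB: float
    kappaHB: float
    n_donor: int
    n_acceptor: int

    def to_segment(self) -> SegmentParameters:
        return SegmentParameters(
            segment_count_ratio=self.m_over_M, sigma=self.sigma,
            u_over_kB=self.u_over_kB, epsHB_over_kB=self.epsHB_over_kB,
            kappaHB=self.kappaHB, n_donor=self.n_donor,
            n_acceptor=self.n_acceptor)


@dataclass(frozen=True)
class PolymerSegmentRecord:
    monomer: str
    mass_fraction: float
    m_over_M: float
    sigma: float
    u_over_kB: float
    epsHB_over_kB: float = 0.0
    kappaHB: float = 0.0
    n_donor: int = 0
    n_acceptor: int = 0


@dataclass(frozen=True)
class PolymerRecord:
    name: str
    molar_mass: float
    segments: tuple[PolymerSegmentRecord, ...]

    def to_component(self) -> ComponentModel:
        segs = tuple(
            (SegmentParameters(
                segment_count_ratio=s.m_over_M, sigma=s.sigma,
                u_over_kB=s.u_over_kB, epsHB_over_kB=s.epsHB_over_kB,
                kappaHB=s.kappaHB, n_donor=s.n_donor, n_acceptor=s.n_acceptor),
             s.mass_fraction)
            for s in self.segments)
        return ComponentModel(name=self.name, molar_mass=self.molar_mass,
                              segments=segs, role="polymer")


# ---------------------------------------------------------------------------
# built-in tables
# ---------------------------------------------------------------------------

API_MOLAR_MASS = {
    "GSF": 352.77, "IBP": 206.28, "IMC": 357.79, "NPX": 230.26,
    "NIF": 346.34, "PCM": 151.16, "SIM": 418.60,
}

API_FUSION = {
    "GSF": FusionProperties(491.85, 37.90, 93.84, 0.0, "I"),
    "IBP": FusionProperties(348.55, 26.40, 176.16440, -0.3449480, "I"),
    "IMC": FusionProperties(433.35, 38.10, 238.18385, -0.2785901, "gamma"),
    "NPX": FusionProperties(429.25, 32.40, 99.30, 0.0, "I"),
    "NIF": FusionProperties(445.75, 39.30, 121.22, 0.0, "alpha"),
    "PCM": FusionProperties(442.55, 28.00, 99.80, 0.0, "I"),
    "SIM": FusionProperties(412.45, 27.75, 278.77100, -0.331300, "I"),
}

# (m_over_M, sigma, u_over_kB, epsHB_over_kB, kappaHB, n_donor, n_acceptor)
_API_PARAMS = {
    ("GSF", "REF"): (0.040179, 3.3720, 221.26, 1985.49, 0.02, 2, 2),
    ("IBP", "REF"): (0.012226, 4.4320, 374.65, 879.42, 0.03, 2, 2),
    ("IBP", "ALT"): (0.026365, 4.0179, 309.40, 516.47, 0.089457, 2, 2),
    ("IMC", "REF"): (0.039920, 3.5350, 262.79, 886.40, 0.02, 3, 3),
    ("IMC", "ALT"): (0.022072, 3.8225, 374.51, 1295.43, 0.011350, 3, 3),
    ("NPX", "REF"): (0.035200, 2.9390, 229.45, 934.20, 0.02, 2, 2),
    ("NPX", "ALT"): (0.019162, 4.1142, 470.92, 1202.65, 0.009524, 2, 2),
    ("NIF", "REF"): (0.023470, 3.5810, 309.44, 1221.58, 0.02, 2, 2),
    ("PCM", "REF"): (0.049775, 3.5080, 398.28, 1994.23, 0.01, 2, 2),
    ("PCM", "ALT"): (0.021406, 3.9819, 432.09, 1635.92, 0.054320, 2, 2),
    ("SIM", "REF"): (0.010695, 3.0711, 296.07, 1449.58, 0.01, 3, 3),
}

POLYMER_MOLAR_MASS = {
    "EUD": 212000.0, "HPMCAS": 120000.0, "PDL": 16400.0, "PLGA50": 9877.0,
    "PLGA75": 12900.0, "PVA": 32000.0, "PVPK12": 2500.0, "PVPK25": 25700.0,
    "PVPK30": 49000.0, "PVPVAc64": 65000.0, "SOL": 118000.0,
}

#: monomer repeat-unit molar masses, g/mol (for mole-ratio -> mass-fraction
#: conversion of copolymer records)
MONOMER_MOLAR_MASS = {
    "methacrylic acid": 86.09, "ethyl acrylate": 100.12,
    "lactic acid": 72.06, "glycolic acid": 58.04,
    "vinyl alcohol": 44.05, "N-vinyl-2-pyrrolidone": 111.14,
    "vinyl acetate": 86.09,
}

#: monomer makeup of the built-in copolymer carriers, as mole ratios
POLYMER_MONOMERS = {
    "EUD": (("methacrylic acid", 1.0), ("ethyl acrylate", 1.0)),
    "PDL": (("lactic acid", 1.0),),
    "PLGA50": (("lactic acid", 1.0), ("glycolic acid", 1.0)),
    "PLGA75": (("lactic acid", 3.0), ("glycolic acid", 1.0)),
    "PVA": (("vinyl alcohol", 1.0),),
    "PVPK12": (("N-vinyl-2-pyrrolidone", 1.0),),
    "PVPK25": (("N-vinyl-2-pyrrolidone", 1.0),),
    "PVPK30": (("N-vinyl-2-pyrrolidone", 1.0),),
    "PVPVAc64": (("N-vinyl-2-pyrrolidone", 1.2), ("vinyl acetate", 1.0)),
}


def mass_fractions_from_mole_ratio(monomers) -> tuple[float, ...]:
    """Convert (monomer name, mole ratio) pairs to mass fractions."""
    masses = [MONOMER_MOLAR_MASS[name] * ratio for name, ratio in monomers]
    tot = sum(masses)
    return tuple(m / tot for m in masses)


# ---------------------------------------------------------------------------
# library
# ---------------------------------------------------------------------------

class ParameterLibrary:
    """Resolvable component records: built-ins plus user-file entries."""

    def __init__(self):
        self.apis: dict[tuple[str, str], SmallMoleculeRecord] = {}
        self.solvents: dict[str, SmallMoleculeRecord] = {}
        self.polymers: dict[str, PolymerRecord] = {}
        self.fusion: dict[str, FusionProperties] = dict(API_FUSION)
        self.molar_mass: dict[str, float] = dict(API_MOLAR_MASS)
        self.polymer_molar_mass: dict[str, float] = dict(POLYMER_MOLAR_MASS)
        for (name, strategy), row in _API_PARAMS.items():
            mM, sig, u, eps, kap, nd, na = row
            self.apis[(name, strategy)] = SmallMoleculeRecord(
                name=name, strategy=strategy,
                molar_mass=API_MOLAR_MASS[name], m_over_M=mM, sigma=sig,
                u_over_kB=u, epsHB_over_kB=eps, kappaHB=kap,
                n_donor=nd, n_acceptor=na)

    # -- registration -----------------------------------------------------

    def add_api(self, record: SmallMoleculeRecord,
                fusion: FusionProperties | None = None):
        key = (record.name, record.strategy)
        if key in self.apis:
            logger.warning("overriding built-in API record %s/%s", *key)
        self.apis[key] = record
        self.molar_mass[record.name] = record.molar_mass
        if fusion is not None:
            self.fusion[record.name] = fusion

    def add_polymer(self, record: PolymerRecord):
        if record.name in self.polymers:
            logger.warning("overriding polymer record %s", record.name)
        self.polymers[record.name] = record
        self.polymer_molar_mass[record.name] = record.molar_mass

    def add_solvent(self, record: SmallMoleculeRecord):
        if record.name in self.solvents:
            logger.warning("overriding solvent record %s", record.name)
        self.solvents[record.name] = record


def build_component(library: ParameterLibrary, name: str,
                    strategy: str = "REF") -> ComponentModel:
    """Resolve a library record into a ComponentModel.

    Drugs resolve via (name, strategy); polymers and solvents by name
    (strategy ignored).  Total segment numbers come out as
    (m/M) * molar mass.
    """
    if (name, strategy) in library.apis:
        rec = library.apis[(name, strategy)]
        return ComponentModel(name=name, molar_mass=rec.molar_mass,
                              segments=((rec.to_segment(), 1.0),), role="API")
    if name in library.polymers:
        return library.polymers[name].to_component()
    if name in library.solvents:
        rec = library.solvents[name]
        return ComponentModel(name=name, molar_mass=rec.molar_mass,
                              segments=((rec.to_segment(), 1.0),),
                              role="solvent")
    if any(n == name for n, _ in library.apis):
        raise KeyError(
            f"no {strategy!r} parameter set exists for API {name!r}")
    raise KeyError(f"unknown component {name!r}")


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

def _require(entry: dict, field_name: str, where: str):
    if field_name not in entry:
        raise SchemaError(f"{where}: missing required field {field_name!r}")
    return entry[field_name]


def _check_association(entry: dict, where: str, n_donor: int, n_acceptor: int):
    kap = float(entry.get("kappaHB", 0.0))
    eps = float(entry.get("epsHB_over_kB", 0.0))
    if kap > 0 and eps == 0 and (n_donor + n_acceptor) == 0:
        raise SchemaError(
            f"{where}: kappaHB > 0 with epsHB = 0 and no sites is meaningless")
    if eps > 0 and kap == 0:
        raise SchemaError(f"{where}: epsHB > 0 requires kappaHB > 0")


def _small_molecule_from_entry(entry: dict, where: str,
                               strategy_default: str = "REF") -> SmallMoleculeRecord:
    name = str(_require(entry, "name", where))
    nd, na = parse_sites(entry.get("sites", "0 (0, 0)"))
    _check_association(entry, f"{where} {name!r}", nd, na)
    try:
        return SmallMoleculeRecord(
            name=name,
            strategy=str(entry.get("strategy", strategy_default)),
            molar_mass=float(_require(entry, "molar_mass", f"{where} {name!r}")),
            m_over_M=float(_require(entry, "m_over_M", f"{where} {name!r}")),
            sigma=float(_require(entry, "sigma", f"{where} {name!r}")),
            u_over_kB=float(_require(entry, "u_over_kB", f"{where} {name!r}")),
            epsHB_over_kB=float(entry.get("epsHB_over_kB", 0.0)),
            kappaHB=float(entry.get("kappaHB", 0.0)),
            n_donor=nd, n_acceptor=na)
    except InvalidParameterError as exc:
        raise SchemaError(f"{where} {name!r}: {exc}") from exc


def _fusion_from_entry(entry: dict, where: str) -> FusionProperties:
    try:
        return FusionProperties(
            T_m=float(_require(entry, "T_m", where)),
            dH_fus=float(_require(entry, "dH_fus", where)),
            dCp_a=float(_require(entry, "dCp_a", where)),
            dCp_b=float(entry.get("dCp_b", 0.0)),
            polymorph=str(entry.get("polymorph", "")))
    except InvalidParameterError as exc:
        raise SchemaError(f"{where}: {exc}") from exc


def load_parameter_library(path: str | Path | None = None) -> ParameterLibrary:
    """Built-ins merged with a user parameter file (user wins on collision)."""
    lib = ParameterLibrary()
    if path is None:
        return lib
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    version = raw.get("version", 1)
    if version != 1:
        raise SchemaError(f"{path}: unsupported schema version {version}")

    for entry in raw.get("apis", []) or []:
        rec = _small_molecule_from_entry(entry, f"{path}:apis")
        fusion = None
        if "fusion" in entry:
            fusion = _fusion_from_entry(entry["fusion"],
                                        f"{path}:apis {rec.name!r}:fusion")
        lib.add_api(rec, fusion)

    for entry in raw.get("solvents", []) or []:
        lib.add_solvent(_small_molecule_from_entry(entry, f"{path}:solvents"))

    for entry in raw.get("polymers", []) or []:
        where = f"{path}:polymers"
        name = str(_require(entry, "name", where))
        if "molar_mass" not in entry:
            raise SchemaError(f"{where} {name!r}: polymer without molar_mass "
                              "is rejected")
        molar_mass = float(entry["molar_mass"])
        seg_entries = _require(entry, "segments", f"{where} {name!r}")
        segs = []
        fracs = []
        for k, se in enumerate(seg_entries):
            sw = f"{where} {name!r}:segments[{k}]"
            nd, na = parse_sites(se.get("sites", "0 (0, 0)"))
            _check_association(se, sw, nd, na)
            if "mass_fraction" in se:
                frac = float(se["mass_fraction"])
            elif "mole_ratio" in se:
                frac = None  # resolved after the loop
            else:
                frac = 1.0 if len(seg_entries) == 1 else None
                if frac is None:
                    raise SchemaError(
                        f"{sw}: copolymer segment needs mass_fraction or "
                        "mole_ratio")
            fracs.append((frac, se))
            segs.append(dict(
                monomer=str(se.get("monomer", f"unit{k}")),
                m_over_M=float(_require(se, "m_over_M", sw)),
                sigma=float(_require(se, "sigma", sw)),
                u_over_kB=float(_require(se, "u_over_kB", sw)),
                epsHB_over_kB=float(se.get("epsHB_over_kB", 0.0)),
                kappaHB=float(se.get("kappaHB", 0.0)),
                n_donor=nd, n_acceptor=na))
        if any(f is None for f, _ in fracs):
            try:
                mf = mass_fractions_from_mole_ratio(
                    [(se.get("monomer"), float(se.get("mole_ratio", 1.0)))
                     for _, se in fracs])
            except KeyError as exc:
                raise SchemaError(
                    f"{where} {name!r}: unknown monomer {exc} for mole-ratio "
                    "conversion; give mass_fraction instead") from exc
            fracs = [(f, se) for f, (_, se) in zip(mf, fracs)]
        try:
            seg_records = tuple(
                PolymerSegmentRecord(mass_fraction=float(f), **s)
                for (f, _), s in zip(fracs, segs))
            rec = PolymerRecord(name=name, molar_mass=molar_mass,
                                segments=seg_records)
            rec.to_component()  # validates resolvability eagerly
        except InvalidParameterError as exc:
            raise SchemaError(f"{where} {name!r}: {exc}") from exc
        lib.add_polymer(rec)
    return lib


def dump_parameter_library(lib: ParameterLibrary, path: str | Path,
                           include_builtin: bool = False) -> None:
    """Write library records back to the YAML schema (user records only by
    default); a written file loads back to identical records."""
    builtin = ParameterLibrary()

    def fmt_sites(nd, na):
        return f"{nd + na} ({nd}, {na})"

    apis = []
    for key, rec in sorted(lib.apis.items()):
        if not include_builtin and builtin.apis.get(key) == rec:
            continue
        entry = dict(name=rec.name, strategy=rec.strategy,
                     molar_mass=rec.molar_mass, m_over_M=rec.m_over_M,
                     sigma=rec.sigma, u_over_kB=rec.u_over_kB,
                     epsHB_over_kB=rec.epsHB_over_kB, kappaHB=rec.kappaHB,
                     sites=fmt_sites(rec.n_donor, rec.n_acceptor))
        fus = lib.fusion.get(rec.name)
        if fus is not None and (include_builtin
                                or builtin.fusion.get(rec.name) != fus):
            entry["fusion"] = dict(T_m=fus.T_m, dH_fus=fus.dH_fus,
                                   dCp_a=fus.dCp_a, dCp_b=fus.dCp_b,
                                   polymorph=fus.polymorph)
        apis.append(entry)
    solvents = [dict(name=r.name, molar_mass=r.molar_mass,
                     m_over_M=r.m_over_M, sigma=r.sigma,
                     u_over_kB=r.u_over_kB, epsHB_over_kB=r.epsHB_over_kB,
                     kappaHB=r.kappaHB,
                     sites=fmt_sites(r.n_donor, r.n_acceptor))
                for r in lib.solvents.values()]
    polymers = []
    for rec in lib.polymers.values():
        polymers.append(dict(
            name=rec.name, molar_mass=rec.molar_mass,
            segments=[dict(monomer=s.monomer, mass_fraction=s.mass_fraction,
                           m_over_M=s.m_over_M, sigma=s.sigma,
                           u_over_kB=s.u_over_kB,
                           epsHB_over_kB=s.epsHB_over_kB, kappaHB=s.kappaHB,
                           sites=fmt_sites(s.n_donor, s.n_acceptor))
                      for s in rec.segments]))
    payload = {"version": 1}
    if apis:
        payload["apis"] = apis
    if solvents:
        payload["solvents"] = solvents
    if polymers:
        payload["polymers"] = polymers
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


# ---------------------------------------------------------------------------
# packaged table copies (for the checksum test)
# ---------------------------------------------------------------------------

def packaged_table(name: str) -> str:
    """Raw text of a packaged data table (``api_parameters``, ``api_fusion``,
    ``molar_masses``)."""
    return resources.files("saftscreen.data").joinpath(f"{name}.tsv").read_text()
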