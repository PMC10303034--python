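"""Elements, water and water+nanoparticle mixtures with photon coefficients.

The package ships compact per-element tables of mass interaction
coefficients (photoelectric, incoherent, coherent, mass energy-absorption;
cm^2/g) on a 1-300 keV grid with absorption-edge doublets, built from
published reference tabulations and exact Klein-Nishina integrals (see
``scripts/build_element_tables.py`` in the repository). Mixtures combine the
elemental coefficients through Bragg additivity with log-log interpolation;
edge discontinuities are preserved because each edge is represented by a pair
of grid points an infinitesimal relative distance apart.

Concentrations follow the added-mass convention: dissolving C mg of
nanoparticle material per mL of water leaves the volume unchanged, so the
nanoparticle mass fraction is C/(1000+C) and the density (1000+C)/1000 g/cm^3.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Literal

import numpy as np

from .errors import EnergyRangeError, InvalidConfigurationError

__all__ = [
    "Element",
    "Material",
    "CrossSectionTable",
    "element",
    "cross_section_table",
    "water",
    "nanoparticle_mixture",
    "mass_attenuation",
    "mass_energy_absorption",
    "linear_attenuation",
    "NANOPARTICLE_MATERIALS",
    "WATER_DENSITY",
]

Process = Literal["photoelectric", "incoherent", "coherent", "total"]

WATER_DENSITY = 1.000  # g/cm^3
ELEMENT_DENSITY = {"Al": 2.70, "Cu": 8.96}  # filter metals, g/cm^3


@dataclass(frozen=True)
class Element:
    symbol: str
    Z: int
    atomic_mass: float  # g/mol

    def __post_init__(self):
        if self.Z < 1:
            raise InvalidConfigurationError(f"Z must be >= 1, got {self.Z}")
        if self.atomic_mass <= 0:
            raise InvalidConfigurationError("atomic mass must be positive")


@dataclass(frozen=True)
class CrossSectionTable:
    """Per-element mass coefficients on a strictly increasing energy grid."""

    symbol: str
    energy_kev: np.ndarray
    mu_rho_photoelectric: np.ndarray
    mu_rho_incoherent: np.ndarray
    mu_rho_coherent: np.ndarray
    mu_en_rho: np.ndarray
    edges_kev: tuple[float, ...] = ()
    omega_k: float | None = None  # K fluorescence yield
    kline_kev: float | None = None  # mean K x-ray energy
    jump_k: float | None = None  # K-edge jump ratio

    def __post_init__(self):
        e = self.energy_kev
        if np.any(np.diff(e) <= 0):
            raise InvalidConfigurationError(f"{self.symbol}: energy grid not increasing")
        for name in ("mu_rho_photoelectric", "mu_rho_incoherent",
                     "mu_rho_coherent", "mu_en_rho"):
            if np.any(getattr(self, name) < 0):
                raise InvalidConfigurationError(f"{self.symbol}: negative {name}")

    @property
    def k_edge_kev(self) -> float | None:
        return max(self.edges_kev) if self.edges_kev else None

    def _column(self, process: str) -> np.ndarray:
        if process == "photoelectric":
            return self.mu_rho_photoelectric
        if process == "incoherent":
            return self.mu_rho_incoherent
        if process == "coherent":
            return self.mu_rho_coherent
        if process == "total":
            return (self.mu_rho_photoelectric + self.mu_rho_incoherent
                    + self.mu_rho_coherent)
        if process == "muen":
            return self.mu_en_rho
        raise InvalidConfigurationError(f"unknown process {process!r}")

    def coefficient(self, energy_kev, process: str = "total") -> np.ndarray:
        """Log-log interpolated coefficient (cm^2/g); edge-aware by doublets."""
        if process == "total":
            # sum of the interpolated channels, so additivity is exact
            return (self.coefficient(energy_kev, "photoelectric")
                    + self.coefficient(energy_kev, "incoherent")
                    + self.coefficient(energy_kev, "coherent"))
        e = np.asarray(energy_kev, dtype=float)
        lo, hi = self.energy_kev[0], self.energy_kev[-1]
        if np.any(e < lo * (1 - 1e-9)) or np.any(e > hi * (1 + 1e-9)):
            raise EnergyRangeError(
                f"energy outside [{lo:.3g}, {hi:.3g}] keV coverage of {self.symbol}")
        col = np.maximum(self._column(process), 1e-300)
        out = np.exp(np.interp(np.log(np.clip(e, lo, hi)),
                               np.log(self.energy_kev), np.log(col)))
        out = np.where(out < 1e-250, 0.0, out)
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class Material:
    """A homogeneous material: density plus elemental mass fractions."""

    name: str
    density: float  # g/cm^3
    composition: tuple[tuple[Element, float], ...]

    def __post_init__(self):
        if self.density <= 0:
            raise InvalidConfigurationError("density must be positive")
        fracs = np.array([w for _, w in self.composition])
        if np.any(fracs <= 0):
            raise InvalidConfigurationError("mass fractions must be positive")
        if abs(fracs.sum() - 1.0) > 1e-9:
            raise InvalidConfigurationError(
                f"mass fractions sum to {fracs.sum():.12f}, not 1")

    @property
    def mass_fractions(self) -> dict[str, float]:
        return {el.symbol: w for el, w in self.composition}


# ---------------------------------------------------------------------------
# Table registry
# ---------------------------------------------------------------------------

_TABLES: dict[str, CrossSectionTable] = {}
_ELEMENTS: dict[str, Element] = {}


def _load_table(symbol: str) -> CrossSectionTable:
    text = (resources.files("nanodose.data") / f"{symbol}.txt").read_text()
    meta: dict[str, str] = {}
    rows = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                meta[key.strip()] = val.strip()
            continue
        rows.append([float(v) for v in line.split()])
    data = np.array(rows)
    edges = tuple(float(v) for v in meta.get("edges_keV", "").split(",") if v)
    return CrossSectionTable(
        symbol=symbol,
        energy_kev=data[:, 0],
        mu_rho_photoelectric=data[:, 1],
        mu_rho_incoherent=data[:, 2],
        mu_rho_coherent=data[:, 3],
        mu_en_rho=data[:, 4],
        edges_kev=edges,
        omega_k=float(meta["omega_K"]) if "omega_K" in meta else None,
        kline_kev=float(meta["kline_keV"]) if "kline_keV" in meta else None,
        jump_k=float(meta["jump_K"]) if "jump_K" in meta else None,
    ), Element(symbol, int(meta["Z"]), float(meta["A_g_per_mol"]))


def cross_section_table(symbol: str) -> CrossSectionTable:
    if symbol not in _TABLES:
        try:
            table, el = _load_table(symbol)
        except FileNotFoundError as exc:
            raise InvalidConfigurationError(
                f"no cross-section table for element {symbol!r}") from exc
        _TABLES[symbol] = table
        _ELEMENTS[symbol] = el
    return _TABLES[symbol]


def element(symbol: str) -> Element:
    cross_section_table(symbol)
    return _ELEMENTS[symbol]


# ---------------------------------------------------------------------------
# Materials
# ---------------------------------------------------------------------------

def water() -> Material:
    h, o = element("H"), element("O")
    m_h2o = 2 * h.atomic_mass + o.atomic_mass
    return Material(
        name="water",
        density=WATER_DENSITY,
        composition=((h, 2 * h.atomic_mass / m_h2o), (o, o.atomic_mass / m_h2o)),
    )


def _iron_oxide_fractions(stoichiometry: str) -> tuple[tuple[str, float], ...]:
    fe, o = element("Fe"), element("O")
    if stoichiometry == "Fe3O4":
        n_fe, n_o = 3, 4
    elif stoichiometry == "Fe2O3":
        n_fe, n_o = 2, 3
    else:
        raise InvalidConfigurationError(f"unknown iron oxide {stoichiometry!r}")
    m = n_fe * fe.atomic_mass + n_o * o.atomic_mass
    return (("Fe", n_fe * fe.atomic_mass / m), ("O", n_o * o.atomic_mass / m))


NANOPARTICLE_MATERIALS = ("gold", "platinum", "iodine", "silver", "iron_oxide")
_NP_ELEMENTS = {"gold": "Au", "platinum": "Pt", "iodine": "I", "silver": "Ag"}


def nanoparticle_mixture(np_name: str, concentration_mg_per_ml: float,
                         iron_oxide_stoichiometry: str = "Fe3O4") -> Material:
    """Water loaded with nanoparticles at C mg per mL of water.

    The nanoparticle mass fraction is C/(1000+C) and the density
    (1000+C)/1000 g/cm^3 (added mass, unchanged volume). Iron oxide expands
    to Fe and O by stoichiometric mass fractions (magnetite by default).
    """
    c = concentration_mg_per_ml
    if c < 0:
        raise InvalidConfigurationError(f"negative concentration {c}")
    if np_name not in NANOPARTICLE_MATERIALS:
        raise InvalidConfigurationError(
            f"unknown nanoparticle material {np_name!r}; "
            f"expected one of {NANOPARTICLE_MATERIALS}")
    if c == 0:
        return water()

    w_np = c / (1000.0 + c)
    density = WATER_DENSITY * (1000.0 + c) / 1000.0
    w = water()
    parts: dict[str, float] = {el.symbol: (1 - w_np) * frac
                               for el, frac in w.composition}
    if np_name == "iron_oxide":
        np_parts = _iron_oxide_fractions(iron_oxide_stoichiometry)
        label = iron_oxide_stoichiometry
    else:
        np_parts = ((_NP_ELEMENTS[np_name], 1.0),)
        label = _NP_ELEMENTS[np_name]
    for sym, frac in np_parts:
        parts[sym] = parts.get(sym, 0.0) + w_np * frac

    comp = tuple((element(sym), frac) for sym, frac in parts.items())
    return Material(name=f"water+{label}@{c:g}mg/mL", density=density,
                    composition=comp)


# ---------------------------------------------------------------------------
# Mixture-rule coefficients
# ---------------------------------------------------------------------------

def mass_attenuation(material: Material, energy_kev,
                     process: Process = "total"):
    """Bragg-additivity mass attenuation coefficient (cm^2/g)."""
    out = None
    for el, frac in material.composition:
        term = frac * cross_section_table(el.symbol).coefficient(energy_kev, process)
        out = term if out is None else out + term
    return out


def mass_energy_absorption(material: Material, energy_kev):
    """Mass energy-absorption coefficient of the mixture (cm^2/g)."""
    out = None
    for el, frac in material.composition:
        term = frac * cross_section_table(el.symbol).coefficient(energy_kev, "muen")
        out = term if out is None else out + term
    return out


def linear_attenuation(material: Material, energy_kev):
    """Total linear attenuation coefficient (cm^-1)."""
    return mass_attenuation(material, energy_kev, "total") * material.density
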