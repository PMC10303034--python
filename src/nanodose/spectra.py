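"""Filtered kilovoltage x-ray tube spectra.

The tube output is modelled as a Kramers bremsstrahlung continuum,
N(E) proportional to Z_anode * (E_max - E) / E, discretised on 1 keV bins
between the 1 keV transport cutoff and the tube potential, then attenuated
through the stated added filtration (2.4 mm Al for the 105 kVp beam; 1 mm Al
plus 1.2 mm Cu for the 220 kVp beam). Optional tungsten K lines can be
superimposed; they are off by default because the anode angle and inherent
filtration of the modelled treatment head are not published, which makes the
spectrum model the dominant systematic of the whole study.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .errors import InvalidConfigurationError, InvalidStateError
from .materials import ELEMENT_DENSITY, cross_section_table

__all__ = [
    "FilterLayer",
    "BeamSpectrum",
    "kramers_unfiltered",
    "apply_filtration",
    "sample_energy",
    "half_value_layer",
    "beam_105",
    "beam_220",
    "write_spectrum",
    "read_spectrum",
]

PHOTON_CUTOFF_KEV = 1.0

# Tungsten K emission: (energy keV, relative intensity)
_W_K_LINES = ((57.98, 0.59), (59.32, 1.00), (67.24, 0.33), (69.10, 0.08))


@dataclass(frozen=True)
class FilterLayer:
    material_symbol: str
    thickness_mm: float

    def __post_init__(self):
        if self.thickness_mm <= 0:
            raise InvalidConfigurationError(
                f"filter thickness must be > 0, got {self.thickness_mm}")
        if self.material_symbol not in ELEMENT_DENSITY:
            raise InvalidConfigurationError(
                f"no filter density for {self.material_symbol!r}")


@dataclass(frozen=True)
class BeamSpectrum:
    """Discrete photon-number spectrum of a (possibly filtered) tube beam."""

    kvp: float
    energy_bins: np.ndarray  # bin centers, keV
    weights: np.ndarray  # relative photon numbers, sum to 1
    filtration: tuple[FilterLayer, ...] = ()

    def __post_init__(self):
        e, w = self.energy_bins, self.weights
        if e.shape != w.shape or e.ndim != 1:
            raise InvalidConfigurationError("bins and weights must match 1-d")
        if np.any(np.diff(e) <= 0):
            raise InvalidConfigurationError("energy bins must strictly increase")
        if e[0] < PHOTON_CUTOFF_KEV or e[-1] > self.kvp:
            raise InvalidConfigurationError(
                "bins must lie within [cutoff, kvp]")
        if np.any(w < 0):
            raise InvalidConfigurationError("negative spectrum weight")
        if abs(w.sum() - 1.0) > 1e-12:
            raise InvalidStateError(f"weights sum to {w.sum()!r}, not 1")

    @property
    def mean_energy(self) -> float:
        return float(np.sum(self.energy_bins * self.weights))

    def normalized(self, weights: np.ndarray) -> "BeamSpectrum":
        total = weights.sum()
        if total <= 0:
            raise InvalidStateError("spectrum has no remaining intensity")
        return replace(self, weights=weights / total)


def kramers_unfiltered(kvp: float, anode_z: int = 74,
                       n_bins: int | None = None, k_lines: bool = False,
                       k_line_fraction: float = 0.08) -> BeamSpectrum:
    """Kramers-law continuum on 1 keV bins (or ``n_bins`` equal bins).

    ``k_lines`` superimposes the tungsten K doublets carrying
    ``k_line_fraction`` of the emitted photon number (only meaningful for
    kvp above the K shell at 69.5 keV).
    """
    if not 40.0 <= kvp <= 300.0:
        raise InvalidConfigurationError(f"kvp {kvp} outside supported 40-300 kV")
    if n_bins is None:
        edges = np.arange(PHOTON_CUTOFF_KEV, kvp + 1e-9, 1.0)
        if edges[-1] < kvp:
            edges = np.append(edges, kvp)
    else:
        if n_bins < 10:
            raise InvalidConfigurationError("n_bins must be >= 10")
        edges = np.linspace(PHOTON_CUTOFF_KEV, kvp, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    weights = anode_z * (kvp - centers) / centers * np.diff(edges)
    weights = np.clip(weights, 0.0, None)
    if k_lines:
        line_e = np.array([e for e, _ in _W_K_LINES])
        line_i = np.array([i for _, i in _W_K_LINES])
        usable = line_e < kvp
        if usable.any():
            add = np.zeros_like(weights)
            idx = np.searchsorted(edges, line_e[usable]) - 1
            np.add.at(add, np.clip(idx, 0, len(weights) - 1), line_i[usable])
            add *= k_line_fraction * weights.sum() / add.sum() / (1 - k_line_fraction)
            weights = weights + add
    spectrum = BeamSpectrum(kvp=float(kvp), energy_bins=centers,
                            weights=weights / weights.sum())
    return spectrum


def apply_filtration(spectrum: BeamSpectrum,
                     filters) -> BeamSpectrum:
    """Attenuate each bin by exp(-sum_i (mu/rho)_i rho_i t_i), renormalize."""
    layers = tuple(f if isinstance(f, FilterLayer) else FilterLayer(*f)
                   for f in filters)
    if not layers:
        return spectrum
    atten = np.zeros_like(spectrum.weights)
    for layer in layers:
        mu_rho = cross_section_table(layer.material_symbol).coefficient(
            spectrum.energy_bins, "total")
        atten += mu_rho * ELEMENT_DENSITY[layer.material_symbol] \
            * layer.thickness_mm / 10.0
    out = spectrum.normalized(spectrum.weights * np.exp(-atten))
    return replace(out, filtration=spectrum.filtration + layers)


def sample_energy(spectrum: BeamSpectrum, rng: np.random.Generator,
                  n: int) -> np.ndarray:
    """Draw ``n`` photon energies by inverse-CDF sampling over the bins."""
    if n < 1:
        raise InvalidConfigurationError("n must be >= 1")
    if abs(spectrum.weights.sum() - 1.0) > 1e-9:
        raise InvalidStateError("spectrum weights are not normalized")
    cdf = np.cumsum(spectrum.weights)
    idx = np.searchsorted(cdf, rng.random(n), side="right")
    return spectrum.energy_bins[np.clip(idx, 0, len(cdf) - 1)]


def half_value_layer(spectrum: BeamSpectrum, attenuator: str = "Al") -> float:
    """Thickness (mm) of ``attenuator`` halving the energy-fluence output.

    Solves sum w(E) E exp(-mu(E) t) = 0.5 * sum w(E) E by bisection to
    1e-4 mm.
    """
    if np.all(spectrum.weights <= 0):
        raise InvalidStateError("spectrum has no intensity")
    mu = cross_section_table(attenuator).coefficient(
        spectrum.energy_bins, "total") * ELEMENT_DENSITY[attenuator] / 10.0  # mm^-1
    ef = spectrum.weights * spectrum.energy_bins
    target = 0.5 * ef.sum()

    def transmitted(t_mm):
        return np.sum(ef * np.exp(-mu * t_mm)) - target

    hi = 1.0
    while transmitted(hi) > 0:
        hi *= 2.0
        if hi > 1e4:
            raise InvalidStateError("half-value layer did not bracket")
    return float(brentq(transmitted, 0.0, hi, xtol=1e-4))


def beam_105(k_lines: bool = False) -> BeamSpectrum:
    """The filtered 105 kVp beam: Kramers continuum through 2.4 mm Al."""
    return apply_filtration(kramers_unfiltered(105, k_lines=k_lines),
                            [FilterLayer("Al", 2.4)])


def beam_220(k_lines: bool = False) -> BeamSpectrum:
    """The filtered 220 kVp beam: Kramers continuum through 1 mm Al + 1.2 mm Cu."""
    return apply_filtration(kramers_unfiltered(220, k_lines=k_lines),
                            [FilterLayer("Al", 1.0), FilterLayer("Cu", 1.2)])


def write_spectrum(spectrum: BeamSpectrum, path) -> None:
    """Two-column text export: energy_keV, weight."""
    filt = "; ".join(f"{f.thickness_mm} mm {f.material_symbol}"
                     for f in spectrum.filtration) or "none"
    header = f"kvp: {spectrum.kvp}\nfiltration: {filt}\ncolumns: energy_keV weight"
    import pathlib
    pathlib.Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, np.column_stack([spectrum.energy_bins, spectrum.weights]),
               header=header)


def read_spectrum(path) -> BeamSpectrum:
    kvp = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") and "kvp:" in line:
                kvp = float(line.split("kvp:")[1].strip())
    data = np.loadtxt(path)
    if kvp is None:
        kvp = float(data[-1, 0])
    return BeamSpectrum(kvp=kvp, energy_bins=data[:, 0],
                        weights=data[:, 1] / data[:, 1].sum())
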