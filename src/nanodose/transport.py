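"""Analog Monte Carlo photon transport through a homogeneous phantom.

Physics model:

* photons are emitted from a point source toward a circular field on the
  phantom entry surface and transported analogically (no variance reduction);
* interaction channels are photoelectric, incoherent (Compton) and coherent
  (Rayleigh), selected proportionally to the partial mass attenuation
  coefficients of the mixture;
* Compton scattering samples the exact Klein-Nishina angular distribution by
  rejection; Rayleigh uses the Thomson angular form (no form factors) and
  deposits nothing;
* energy transferred to electrons is deposited in the voxel of the
  interaction (kerma approximation; secondary-electron ranges at these
  energies are well below the 1 cm depth bins);
* photoabsorption in a high-Z element (Ag, I, Pt, Au) above its K edge can
  relax by emitting a K x-ray (yield omega_K, single mean line energy) which
  is transported like any other photon; lower-energy fluorescence is
  deposited locally. This matters because the 60-70 keV K photons of Pt/Au
  have centimetre mean free paths and carry a large share of the transferred
  energy out of the interaction voxel;
* photons below the 1 keV cutoff deposit their remaining energy locally.

Energy is conserved exactly per batch: emitted = deposited + escaped.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import InvalidConfigurationError, InvalidStateError
from .materials import Material, cross_section_table
from .scoring import DoseGrid
from .spectra import BeamSpectrum, sample_energy

__all__ = [
    "PhantomGeometry",
    "SourceConfig",
    "TransportConfig",
    "PhotonState",
    "MaterialLookup",
    "emit_photon",
    "distance_to_interaction",
    "select_interaction",
    "klein_nishina_scatter",
    "rayleigh_scatter",
    "transport_history",
    "run_simulation",
]

MEC2_KEV = 510.99895


@dataclass(frozen=True)
class PhantomGeometry:
    """Rectangular water-box phantom; the beam travels along +z (depth)."""

    size_cm: tuple[float, float, float] = (10.0, 10.0, 12.0)
    voxel_cm: tuple[float, float, float] = (0.5, 0.5, 1.0)

    def __post_init__(self):
        for s, v in zip(self.size_cm, self.voxel_cm):
            if s <= 0 or v <= 0:
                raise InvalidConfigurationError("extents must be positive")
            n = s / v
            if abs(n - round(n)) > 1e-9:
                raise InvalidConfigurationError(
                    f"voxel size {v} does not tile extent {s}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(int(round(s / v))
                     for s, v in zip(self.size_cm, self.voxel_cm))

    @property
    def half_lateral(self) -> tuple[float, float]:
        return self.size_cm[0] / 2.0, self.size_cm[1] / 2.0

    def edges(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        if axis < 2:
            h = self.size_cm[axis] / 2.0
            return np.linspace(-h, h, n + 1)
        return np.linspace(0.0, self.size_cm[2], n + 1)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        hx, hy = self.half_lateral
        x, y, z = pos[:, 0], pos[:, 1], pos[:, 2]
        return ((np.abs(x) < hx) & (np.abs(y) < hy)
                & (z > 0.0) & (z < self.size_cm[2]))

    def voxel_index(self, pos: np.ndarray):
        hx, hy = self.half_lateral
        nx, ny, nz = self.shape
        ix = np.clip(((pos[:, 0] + hx) / self.voxel_cm[0]).astype(np.intp), 0, nx - 1)
        iy = np.clip(((pos[:, 1] + hy) / self.voxel_cm[1]).astype(np.intp), 0, ny - 1)
        iz = np.clip((pos[:, 2] / self.voxel_cm[2]).astype(np.intp), 0, nz - 1)
        return ix, iy, iz


@dataclass(frozen=True)
class SourceConfig:
    """Point source on the central axis, circular field on the entry surface."""

    ssd_cm: float = 20.0
    field_diameter_cm: float = 5.0

    def __post_init__(self):
        if self.ssd_cm <= 0 or self.field_diameter_cm <= 0:
            raise InvalidConfigurationError("SSD and field diameter must be > 0")

    @property
    def position(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.ssd_cm])


@dataclass(frozen=True)
class TransportConfig:
    n_histories: int = 2_000_000
    n_batches: int = 10
    photon_cutoff_kev: float = 1.0
    rng_seed: int = 0
    k_fluorescence: bool = True

    def __post_init__(self):
        if self.photon_cutoff_kev < 1.0:
            raise InvalidConfigurationError("photon cutoff must be >= 1 keV")
        if self.n_batches < 2:
            raise InvalidConfigurationError("need at least 2 batches")
        if self.n_histories % self.n_batches:
            raise InvalidConfigurationError(
                "n_histories must be divisible by n_batches")


@dataclass
class PhotonState:
    position: np.ndarray
    direction: np.ndarray
    energy: float
    alive: bool = True

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-9:
            raise InvalidStateError("direction must be a unit vector")
        if self.energy < 0:
            raise InvalidStateError("energy must be non-negative")


class MaterialLookup:
    """Precomputed per-material coefficient tables for fast transport."""

    def __init__(self, material: Material,
                 channel_override: dict[str, float] | None = None):
        self.material = material
        grids = [cross_section_table(el.symbol).energy_kev
                 for el, _ in material.composition]
        grid = np.unique(np.concatenate(grids))
        scale = {"photoelectric": 1.0, "incoherent": 1.0, "coherent": 1.0}
        if channel_override:
            scale.update(channel_override)
        pe = inc = coh = 0.0
        for el, w in material.composition:
            table = cross_section_table(el.symbol)
            pe = pe + w * table.coefficient(grid, "photoelectric")
            inc = inc + w * table.coefficient(grid, "incoherent")
            coh = coh + w * table.coefficient(grid, "coherent")
        pe, inc, coh = scale["photoelectric"] * pe, \
            scale["incoherent"] * inc, scale["coherent"] * coh
        total = pe + inc + coh
        if np.all(total <= 0):
            raise InvalidStateError("material has vanishing cross section")
        # grid points with no cross section (possible when channels are
        # artificially disabled) become transparent: huge free path, and a
        # photoelectric label that can never be drawn there
        safe = np.maximum(total, 1e-300)
        self._log_e = np.log(grid)
        self._mu_lin = np.maximum(total * material.density, 1e-30)
        self._cum_pe = np.where(total > 0, pe / safe, 1.0)
        self._cum_inc = np.where(total > 0, (pe + inc) / safe, 1.0)

        # K-fluorescence emitters: heavy elements with tabulated yields
        self.fluorescence: list[tuple[float, np.ndarray, float]] = []
        for el, w in material.composition:
            table = cross_section_table(el.symbol)
            if table.omega_k is None or table.k_edge_kev is None:
                continue
            p_k = 1.0 - 1.0 / table.jump_k
            p_emit = np.where(
                grid >= table.k_edge_kev,
                w * table.coefficient(grid, "photoelectric")
                / np.maximum(pe, 1e-300) * p_k * table.omega_k,
                0.0)
            self.fluorescence.append(
                (table.k_edge_kev, p_emit, table.kline_kev))

    def mu_linear(self, energy_kev: np.ndarray) -> np.ndarray:
        return np.interp(np.log(energy_kev), self._log_e, self._mu_lin)

    def channel_cum(self, energy_kev: np.ndarray):
        log_e = np.log(energy_kev)
        return (np.interp(log_e, self._log_e, self._cum_pe),
                np.interp(log_e, self._log_e, self._cum_inc))

    def fluorescence_probability(self, energy_kev, p_emit_grid) -> np.ndarray:
        return np.interp(np.log(energy_kev), self._log_e, p_emit_grid)


@lru_cache(maxsize=32)
def _cached_lookup(material: Material) -> MaterialLookup:
    return MaterialLookup(material)


# ---------------------------------------------------------------------------
# Elementary samplers
# ---------------------------------------------------------------------------

def emit_photon(source: SourceConfig, spectrum: BeamSpectrum,
                rng: np.random.Generator) -> PhotonState:
    """Emit one photon from the point source toward the field disk."""
    pos, direction, energy = _emit_batch(source, spectrum, rng, 1)
    return PhotonState(position=pos[0], direction=direction[0],
                       energy=float(energy[0]))


def _emit_batch(source: SourceConfig, spectrum: BeamSpectrum,
                rng: np.random.Generator, n: int):
    r = source.field_diameter_cm / 2.0 * np.sqrt(rng.random(n))
    phi = 2.0 * np.pi * rng.random(n)
    target = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n)])
    direction = target - source.position
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    pos = np.broadcast_to(source.position, (n, 3)).copy()
    return pos, direction, sample_energy(spectrum, rng, n)


def distance_to_interaction(mu, rng: np.random.Generator):
    """Exponential free path s = -ln(U)/mu, U uniform on (0, 1]."""
    mu = np.asarray(mu, dtype=float)
    if np.any(mu <= 0):
        raise InvalidStateError("attenuation coefficient must be positive")
    u = 1.0 - rng.random(mu.shape if mu.ndim else None)  # in (0, 1]
    out = -np.log(u) / mu
    return out if mu.ndim else float(out)


def select_interaction(material: Material, energy_kev: float,
                       rng: np.random.Generator) -> str:
    """Choose a channel proportionally to the partial coefficients."""
    lookup = _cached_lookup(material)
    e = np.asarray([energy_kev], dtype=float)
    if lookup.mu_linear(e)[0] <= 1e-20:
        raise InvalidStateError("all partial coefficients vanish here")
    f_pe, f_inc = lookup.channel_cum(e)
    u = rng.random()
    if u < f_pe[0]:
        return "photoelectric"
    if u < f_inc[0]:
        return "incoherent"
    return "coherent"


def _kn_sample_cost(energy_kev: np.ndarray, rng: np.random.Generator):
    """Klein-Nishina polar-angle cosine by rejection (envelope at theta=0)."""
    alpha = np.asarray(energy_kev, dtype=float) / MEC2_KEV
    out = np.empty_like(alpha)
    todo = np.arange(alpha.size)
    while todo.size:
        mu = rng.uniform(-1.0, 1.0, todo.size)
        ratio = 1.0 / (1.0 + alpha[todo] * (1.0 - mu))
        f = ratio * ratio * (ratio + 1.0 / ratio - (1.0 - mu * mu))
        accept = rng.random(todo.size) * 2.0 <= f
        out[todo[accept]] = mu[accept]
        todo = todo[~accept]
    return out


def klein_nishina_scatter(energy_kev, rng: np.random.Generator):
    """Sample a Compton event: returns (scattered energy keV, polar angle rad)."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    if np.any(e <= 0):
        raise InvalidStateError("energy must be positive")
    cost = _kn_sample_cost(e, rng)
    scattered = e / (1.0 + (e / MEC2_KEV) * (1.0 - cost))
    theta = np.arccos(np.clip(cost, -1.0, 1.0))
    if np.isscalar(energy_kev):
        return float(scattered[0]), float(theta[0])
    return scattered, theta


def rayleigh_scatter(energy_kev, rng: np.random.Generator):
    """Sample a Thomson-form coherent polar angle (energy unchanged)."""
    e = np.atleast_1d(np.asarray(energy_kev, dtype=float))
    if np.any(e <= 0):
        raise InvalidStateError("energy must be positive")
    out = np.empty(e.size)
    todo = np.arange(e.size)
    while todo.size:
        mu = rng.uniform(-1.0, 1.0, todo.size)
        accept = rng.random(todo.size) <= 0.5 * (1.0 + mu * mu)
        out[todo[accept]] = mu[accept]
        todo = todo[~accept]
    theta = np.arccos(np.clip(out, -1.0, 1.0))
    return float(theta[0]) if np.isscalar(energy_kev) else theta


def _rotate_directions(direction: np.ndarray, cost: np.ndarray,
                       phi: np.ndarray) -> np.ndarray:
    """Deflect unit vectors by polar cosine ``cost`` and azimuth ``phi``."""
    sint = np.sqrt(np.clip(1.0 - cost * cost, 0.0, None))
    u, v, w = direction[:, 0], direction[:, 1], direction[:, 2]
    out = np.empty_like(direction)
    rho = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    safe = rho > 1e-10
    cp, sp = np.cos(phi), np.sin(phi)
    with np.errstate(invalid="ignore", divide="ignore"):
        out[:, 0] = u * cost + sint * (u * w * cp - v * sp) / rho
        out[:, 1] = v * cost + sint * (v * w * cp + u * sp) / rho
        out[:, 2] = w * cost - rho * sint * cp
    # beam along +-z: rotate about the z axis directly
    sign = np.sign(w)
    out[~safe, 0] = (sint * cp)[~safe]
    out[~safe, 1] = (sint * sp)[~safe]
    out[~safe, 2] = (cost * sign)[~safe]
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def _isotropic_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    cost = rng.uniform(-1.0, 1.0, n)
    phi = 2.0 * np.pi * rng.random(n)
    sint = np.sqrt(1.0 - cost * cost)
    return np.column_stack([sint * np.cos(phi), sint * np.sin(phi), cost])


def _advance_to_box(pos, direction, energy, geometry: PhantomGeometry):
    """Move photons outside the box to their entry point; drop the misses.

    Returns (pos, direction, energy, escaped_energy).
    """
    hx, hy = geometry.half_lateral
    lo = np.array([-hx, -hy, 0.0])
    hi = np.array([hx, hy, geometry.size_cm[2]])
    inside = geometry.contains(pos)
    if inside.all():
        return pos, direction, energy, 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = (lo - pos) / direction
        t2 = (hi - pos) / direction
    t_near = np.nanmax(np.minimum(t1, t2), axis=1)
    t_far = np.nanmin(np.maximum(t1, t2), axis=1)
    hits = (t_far > t_near) & (t_far > 0)
    enters = np.where(inside, True, hits)
    escaped = float(energy[~enters].sum())
    pos, direction, energy = pos[enters], direction[enters], energy[enters]
    outside = ~geometry.contains(pos)
    t = np.clip(np.nanmax(np.minimum(
        (lo - pos[outside]) / direction[outside],
        (hi - pos[outside]) / direction[outside]), axis=1), 0.0, None)
    pos[outside] += direction[outside] * (t + 1e-12)[:, None]
    return pos, direction, energy, escaped


def _transport_arrays(pos, direction, energy, lookup: MaterialLookup,
                      geometry: PhantomGeometry, config: TransportConfig,
                      rng: np.random.Generator, deposits: np.ndarray) -> float:
    """Transport photon arrays to extinction; returns escaped energy (keV)."""
    pos, direction, energy, escaped = _advance_to_box(
        pos.copy(), direction.copy(), energy.copy(), geometry)
    cutoff = config.photon_cutoff_kev
    fluor = lookup.fluorescence if config.k_fluorescence else []

    while energy.size:
        mu = lookup.mu_linear(energy)
        step = distance_to_interaction(mu, rng)
        pos = pos + direction * step[:, None]
        inside = geometry.contains(pos)
        escaped += float(energy[~inside].sum())
        pos, direction, energy = pos[inside], direction[inside], energy[inside]
        if not energy.size:
            break
        n = energy.size
        ix, iy, iz = geometry.voxel_index(pos)

        u = rng.random(n)
        f_pe, f_inc = lookup.channel_cum(energy)
        is_pe = u < f_pe
        is_coh = u >= f_inc
        is_inc = ~is_pe & ~is_coh

        deposit = np.zeros(n)
        alive = np.ones(n, dtype=bool)
        new_energy = energy.copy()

        # --- photoelectric: local deposit, optional K x-ray re-emission ---
        if is_pe.any():
            e_pe = energy[is_pe]
            dep_pe = e_pe.copy()
            alive_pe = np.zeros(e_pe.size, dtype=bool)
            e_out = np.zeros(e_pe.size)
            if fluor:
                u2 = rng.random(e_pe.size)
                cum = np.zeros(e_pe.size)
                for _, p_grid, line_kev in fluor:
                    p = lookup.fluorescence_probability(e_pe, p_grid)
                    sel = (u2 >= cum) & (u2 < cum + p) & (e_pe > line_kev)
                    dep_pe[sel] = e_pe[sel] - line_kev
                    e_out[sel] = line_kev
                    alive_pe[sel] = True
                    cum += p
            deposit[is_pe] = dep_pe
            new_energy[is_pe] = e_out
            alive[is_pe] = alive_pe
            if alive_pe.any():
                idx = np.flatnonzero(is_pe)[alive_pe]
                direction[idx] = _isotropic_directions(idx.size, rng)

        # --- incoherent: Klein-Nishina energy split ---
        if is_inc.any():
            e_in = energy[is_inc]
            cost = _kn_sample_cost(e_in, rng)
            e_sc = e_in / (1.0 + (e_in / MEC2_KEV) * (1.0 - cost))
            below = e_sc < cutoff
            deposit[is_inc] = np.where(below, e_in, e_in - e_sc)
            new_energy[is_inc] = np.where(below, 0.0, e_sc)
            alive[is_inc] = ~below
            idx = np.flatnonzero(is_inc)[~below]
            if idx.size:
                phi = 2.0 * np.pi * rng.random(idx.size)
                direction[idx] = _rotate_directions(
                    direction[idx], cost[~below], phi)

        # --- coherent: elastic deflection only ---
        if is_coh.any():
            idx = np.flatnonzero(is_coh)
            mu_c = np.cos(rayleigh_scatter(energy[idx], rng))
            phi = 2.0 * np.pi * rng.random(idx.size)
            direction[idx] = _rotate_directions(direction[idx], mu_c, phi)

        np.add.at(deposits, (ix, iy, iz), deposit)
        pos, direction, energy = pos[alive], direction[alive], new_energy[alive]

    return escaped


def transport_history(photon: PhotonState, geometry: PhantomGeometry,
                      material: Material, config: TransportConfig,
                      scorer: DoseGrid, rng: np.random.Generator,
                      batch: int = 0) -> None:
    """Transport a single photon, mutating ``scorer`` in place."""
    if abs(np.linalg.norm(photon.direction) - 1.0) > 1e-9:
        raise InvalidStateError("direction must be a unit vector")
    if not photon.alive:
        return
    lookup = _cached_lookup(material)
    deposits = np.zeros(geometry.shape)
    escaped = _transport_arrays(photon.position[None, :],
                                photon.direction[None, :],
                                np.array([photon.energy]),
                                lookup, geometry, config, rng, deposits)
    scorer.add(batch, deposits, emitted=photon.energy, escaped=escaped)
    photon.alive = False


def run_simulation(spectrum: BeamSpectrum, material: Material,
                   geometry: PhantomGeometry | None = None,
                   source: SourceConfig | None = None,
                   config: TransportConfig | None = None,
                   chunk_size: int = 250_000,
                   lookup: MaterialLookup | None = None) -> DoseGrid:
    """Simulate a full run and return the scored dose grid.

    Histories are split into ``config.n_batches`` batches with independent
    deterministic substreams spawned from ``config.rng_seed``; batch spread
    provides the statistical uncertainty of every derived quantity.
    """
    geometry = geometry or PhantomGeometry()
    source = source or SourceConfig()
    config = config or TransportConfig()
    lookup = lookup or MaterialLookup(material)
    grid = DoseGrid.empty(
        edges=(geometry.edges(0), geometry.edges(1), geometry.edges(2)),
        n_batches=config.n_batches,
        n_histories=config.n_histories,
        material_name=material.name,
        density=material.density,
        config_echo={
            "kvp": spectrum.kvp,
            "ssd_cm": source.ssd_cm,
            "field_diameter_cm": source.field_diameter_cm,
            "n_histories": config.n_histories,
            "n_batches": config.n_batches,
            "photon_cutoff_kev": config.photon_cutoff_kev,
            "rng_seed": config.rng_seed,
            "k_fluorescence": config.k_fluorescence,
        },
    )
    per_batch = config.n_histories // config.n_batches
    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_batches)
    for b, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        deposits = np.zeros(geometry.shape)
        emitted = escaped = 0.0
        done = 0
        while done < per_batch:
            n = min(chunk_size, per_batch - done)
            pos, direction, energy = _emit_batch(source, spectrum, rng, n)
            emitted += float(energy.sum())
            escaped += _transport_arrays(pos, direction, energy, lookup,
                                         geometry, config, rng, deposits)
            done += n
        grid.add(b, deposits, emitted=emitted, escaped=escaped)
    return grid
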