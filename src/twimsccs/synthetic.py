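"""Synthetic data generators: every pipeline stage testable without downloads.

Three generators cover the pipeline's inputs:

* :func:`gen_calibrant_set` — drift-time tables manufactured by inverting the
  traveling-wave forward model (EDC correction + power law), optionally with
  multiplicative Gaussian noise on the drift times. Noise-free tables are
  exactly consistent with the calibration equations, so fitting them must
  recover the generating parameters to machine precision — the round-trip
  oracle used throughout the test suite.
* :func:`gen_bead_chain` — multi-domain bead-chain structures in *extended*
  (domains strung out along an axis, mimicking a linker-connected multidomain
  protein in solution) or *collapsed* (domains close-packed, mimicking the
  gas-phase-collapsed state) conformations. Bead content is identical across
  conformations, so any projected-area difference is purely conformational.
* :func:`gen_random_sequence` — uniform random protein/RNA/DNA sequences.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence as Seq

import numpy as np

from .calibration import CalibrantIon
from .masses import ALPHABETS, GAS_MASS_N2, Sequence, mz_from_mass, reduced_mass
from .structures import Structure

__all__ = [
    "ForwardModelSpec",
    "BeadChainSpec",
    "DEFAULT_CALIBRANT_IONS",
    "gen_calibrant_set",
    "gen_analyte_drift_time",
    "gen_bead_chain",
    "gen_random_sequence",
]


@dataclass(frozen=True)
class ForwardModelSpec:
    """Ground-truth parameters of a synthetic traveling-wave instrument.

    The power law is ln Ω' = X_true·ln t'_D + ln_A_true. On noise-free data
    the final linear calibration is then exactly Ω = A·t''_D, so the implied
    linear-map truth is ``slope_true = exp(ln_A_true)`` and
    ``intercept_true = 0`` — exposed as read-only properties rather than free
    fields, because independent values would make the generated table
    internally inconsistent.

    ``noise_sd_rel`` is the relative standard deviation of multiplicative
    Gaussian noise applied to the drift times (0 = noise-free).
    """

    X_true: float = 0.55
    ln_A_true: float = 6.0
    c_edc: float = 1.57
    gas_mass: float = GAS_MASS_N2
    noise_sd_rel: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.X_true <= 0:
            raise ValueError("X_true must be positive")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")

    @property
    def slope_true(self) -> float:
        return math.exp(self.ln_A_true)

    @property
    def intercept_true(self) -> float:
        return 0.0


#: Default synthetic calibrant panel: four multi-charge protein species with
#: masses and CCS values shaped like the classic native calibrant ladder
#: (a ~37 kDa dimer up to a ~237 kDa tetramer, three charge states each, CCS
#: growing roughly as mass^(2/3)). The numbers are synthetic stand-ins in
#: realistic ranges, not literature database values.
DEFAULT_CALIBRANT_IONS: tuple[tuple[str, float, int, float], ...] = (
    ("dimer_37k", 36_700.0, 11, 3290.0),
    ("dimer_37k", 36_700.0, 12, 3350.0),
    ("dimer_37k", 36_700.0, 13, 3430.0),
    ("tetramer_103k", 103_000.0, 19, 5480.0),
    ("tetramer_103k", 103_000.0, 20, 5550.0),
    ("tetramer_103k", 103_000.0, 21, 5630.0),
    ("tetramer_148k", 147_500.0, 23, 6880.0),
    ("tetramer_148k", 147_500.0, 24, 6940.0),
    ("tetramer_148k", 147_500.0, 25, 7010.0),
    ("tetramer_237k", 237_000.0, 30, 9250.0),
    ("tetramer_237k", 237_000.0, 31, 9330.0),
    ("tetramer_237k", 237_000.0, 32, 9420.0),
)


def _noiseless_drift_time(spec: ForwardModelSpec, mass: float, z: int,
                          ccs: float) -> float:
    """Invert the forward model: CCS → drift time in ms."""
    mu = reduced_mass(mass, spec.gas_mass)
    omega_prime = ccs * math.sqrt(mu) / z
    ln_t_prime = (math.log(omega_prime) - spec.ln_A_true) / spec.X_true
    t_prime = math.exp(ln_t_prime)
    mz = mz_from_mass(mass, z)
    return t_prime + spec.c_edc * math.sqrt(mz) / 1000.0


gen_analyte_drift_time = _noiseless_drift_time


def gen_calibrant_set(
    spec: ForwardModelSpec,
    ions: Seq[tuple[str, float, int, float]] | None = None,
) -> list[CalibrantIon]:
    """Generate a calibrant drift-time table from the forward model.

    ``ions`` is a sequence of ``(label, mass_Da, z, ccs_Å²)``; by default the
    panel in :data:`DEFAULT_CALIBRANT_IONS`. Drift times are the exact model
    inversion, times ``(1 + noise_sd_rel·N(0,1))`` when noise is requested.

    Raises
    ------
    ValueError
        If any CCS is non-positive, or noise drives a drift time below the
        EDC correction (the generated ion would be unphysical).
    """
    ions = DEFAULT_CALIBRANT_IONS if ions is None else ions
    rng = np.random.default_rng(spec.seed)
    out = []
    for label, mass, z, ccs in ions:
        if ccs <= 0:
            raise ValueError(f"calibrant {label!r}: ccs must be positive")
        t_d = _noiseless_drift_time(spec, mass, z, ccs)
        if spec.noise_sd_rel > 0:
            t_d *= 1.0 + spec.noise_sd_rel * rng.standard_normal()
        edc_shift = spec.c_edc * math.sqrt(mz_from_mass(mass, z)) / 1000.0
        if t_d <= edc_shift:
            raise ValueError(
                f"calibrant {label!r}: generated drift time {t_d:.4f} ms does "
                "not survive the EDC correction"
            )
        out.append(CalibrantIon(label, mass, z, ccs, t_d))
    return out


@dataclass(frozen=True)
class BeadChainSpec:
    """A toy multidomain molecule: ``n_domains`` spherical domains of
    ``beads_per_domain`` hard-sphere beads each, joined by linkers.

    ``conformation="extended"`` places domain centroids collinearly at a
    spacing of one domain diameter plus ``linker_length``;
    ``"collapsed"`` close-packs the centroids at one domain diameter.
    ``domain_radius`` defaults to ``1.2·bead_radius·beads_per_domain^(1/3)``,
    a loosely packed ball.
    """

    n_domains: int = 5
    beads_per_domain: int = 40
    bead_radius: float = 2.7
    linker_length: float = 12.0
    conformation: str = "extended"
    seed: int | None = None
    domain_radius: float | None = None

    def __post_init__(self) -> None:
        if self.n_domains < 1 or self.beads_per_domain < 1:
            raise ValueError("counts must be >= 1")
        if self.bead_radius <= 0 or self.linker_length <= 0:
            raise ValueError("bead_radius and linker_length must be positive")
        if self.conformation not in ("extended", "collapsed"):
            raise ValueError(f"unknown conformation {self.conformation!r}")
        if self.domain_radius is not None and self.domain_radius <= 0:
            raise ValueError("domain_radius must be positive")

    @property
    def effective_domain_radius(self) -> float:
        if self.domain_radius is not None:
            return self.domain_radius
        return 1.2 * self.bead_radius * self.beads_per_domain ** (1.0 / 3.0)


def _close_packed_centroids(n: int, spacing: float) -> np.ndarray:
    """First ``n`` sites of an FCC lattice (nearest-neighbour = ``spacing``),
    sorted by distance from the origin — a deterministic compact cluster."""
    a1 = np.array([1.0, 0.0, 0.0])
    a2 = np.array([0.5, math.sqrt(3.0) / 2.0, 0.0])
    a3 = np.array([0.5, math.sqrt(3.0) / 6.0, math.sqrt(2.0 / 3.0)])
    k = max(2, int(math.ceil(n ** (1.0 / 3.0))) + 1)
    idx = np.arange(-k, k + 1)
    i, j, l = np.meshgrid(idx, idx, idx, indexing="ij")
    pts = (i[..., None] * a1 + j[..., None] * a2 + l[..., None] * a3).reshape(-1, 3)
    # stable sort: by norm, then lexicographically for reproducible ties
    order = np.lexsort((pts[:, 2], pts[:, 1], pts[:, 0],
                        np.round(np.linalg.norm(pts, axis=1), 9)))
    return pts[order][:n] * spacing


def gen_bead_chain(spec: BeadChainSpec) -> Structure:
    """Build a bead-chain :class:`Structure` with radii pre-assigned.

    Beads are drawn uniformly inside each domain sphere with one shared RNG,
    consumed identically for both conformations, so the same seed yields the
    same bead cloud around differently placed centroids — bead count and
    radii are conserved across conformations by construction.
    """
    rng = np.random.default_rng(spec.seed)
    R = spec.effective_domain_radius
    if spec.conformation == "extended":
        spacing = 2.0 * R + spec.linker_length
        centroids = np.column_stack([
            np.arange(spec.n_domains) * spacing,
            np.zeros(spec.n_domains),
            np.zeros(spec.n_domains),
        ])
    else:
        centroids = _close_packed_centroids(spec.n_domains, 2.0 * R)

    n_total = spec.n_domains * spec.beads_per_domain
    # uniform points in the unit ball: normalised Gaussians scaled by U^(1/3)
    directions = rng.standard_normal((n_total, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii_frac = rng.uniform(0.0, 1.0, n_total) ** (1.0 / 3.0)
    offsets = directions * (radii_frac[:, None] * R)
    coords = np.repeat(centroids, spec.beads_per_domain, axis=0) + offsets

    return Structure(
        id=f"beadchain_{spec.conformation}_{spec.n_domains}x{spec.beads_per_domain}",
        elements=["C"] * n_total,
        coords=coords,
        radii=np.full(n_total, spec.bead_radius),
    )


def gen_random_sequence(kind: str, length: int, seed: int | None = None) -> Sequence:
    """Uniform random sequence over the alphabet of ``kind``."""
    if length < 1:
        raise ValueError("length must be >= 1")
    alphabet = sorted(ALPHABETS[kind])
    rng = np.random.default_rng(seed)
    residues = "".join(rng.choice(alphabet, size=length))
    return Sequence(kind, residues)
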