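"""Parametric free-energy and diffusivity landscapes.

A landscape is the ground truth the synthetic umbrella-sampling generator
samples from: a potential of mean force W(z) (kcal/mol) and a
position-dependent diffusivity D(z) (Å²/ps) along the transmembrane axis z,
each written as a baseline plus a sum of Gaussian terms

    g(z) = A · exp(−(z − c)² / (2 w²))

with amplitude A, center c (Å) and width w (Å).  This form is flexible
enough to express the qualitative shape of a lipid-bilayer permeation
profile — a deep interior well, a small headgroup barrier and a flat water
plateau — while staying analytically differentiable and integrable, which
is what parameter-recovery tests need.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Boltzmann constant in kcal/(mol K)
KB_KCAL_MOL_K = 1.987204259e-3


class LandscapeError(ValueError):
    """Raised for invalid landscape definitions or out-of-domain evaluation."""


@dataclass(frozen=True)
class GaussianTerm:
    """One Gaussian component A·exp(−(z−c)²/(2w²))."""

    amplitude: float
    center: float  # Å
    width: float  # Å, > 0

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise LandscapeError(f"Gaussian width must be > 0, got {self.width}")

    def __call__(self, z):
        u = (np.asarray(z, dtype=float) - self.center) / self.width
        return self.amplitude * np.exp(-0.5 * u * u)

    def derivative(self, z):
        z = np.asarray(z, dtype=float)
        u = (z - self.center) / self.width
        return -self.amplitude * u / self.width * np.exp(-0.5 * u * u)


@dataclass(frozen=True)
class ThermoState:
    """Temperature and the derived inverse thermal energy β = 1/(k_B T)."""

    temperature: float  # K
    boltzmann_constant: float = KB_KCAL_MOL_K  # kcal/(mol K)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def kT(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(k_B·T) in mol/kcal."""
        return 1.0 / self.kT


def _sum_terms(terms: tuple[GaussianTerm, ...], baseline: float, z):
    out = np.full_like(np.asarray(z, dtype=float), baseline)
    for t in terms:
        out = out + t(z)
    return out


def _sum_derivatives(terms: tuple[GaussianTerm, ...], z):
    out = np.zeros_like(np.asarray(z, dtype=float))
    for t in terms:
        out = out + t.derivative(z)
    return out


@dataclass(frozen=True)
class LandscapeSpec:
    """Ground-truth W(z) and D(z) for synthetic umbrella-sampling campaigns.

    Parameters
    ----------
    w_terms, d_terms
        Gaussian components of the free energy (kcal/mol) and of the
        diffusivity (Å²/ps).
    w_baseline
        Additive constant of W; by convention the water-phase plateau of W
        is 0, so this is normally 0.
    d_baseline
        Additive constant of D (Å²/ps); must keep D(z) > 0 everywhere.
    z_range
        Domain (z_min, z_max) in Å on which the landscape is defined.
    """

    w_terms: tuple[GaussianTerm, ...] = ()
    d_terms: tuple[GaussianTerm, ...] = ()
    w_baseline: float = 0.0
    d_baseline: float = 0.1
    z_range: tuple[float, float] = (-40.0, 40.0)

    def __post_init__(self) -> None:
        lo, hi = self.z_range
        if not lo < hi:
            raise LandscapeError(f"z_range must satisfy z_min < z_max, got {self.z_range}")
        zz = np.linspace(lo, hi, 2001)
        d = _sum_terms(tuple(self.d_terms), self.d_baseline, zz)
        if np.any(d <= 0):
            raise LandscapeError("D(z) must be strictly positive on z_range")
        w = _sum_terms(tuple(self.w_terms), self.w_baseline, zz)
        if not np.all(np.isfinite(w)):
            raise LandscapeError("W(z) must be finite on z_range")

    # -- evaluation -------------------------------------------------------

    def _check_domain(self, z) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        lo, hi = self.z_range
        if np.any(z < lo) or np.any(z > hi):
            raise LandscapeError(
                f"z outside landscape domain [{lo}, {hi}]"
            )
        return z

    def free_energy(self, z):
        """W(z) in kcal/mol."""
        z = self._check_domain(z)
        return _sum_terms(tuple(self.w_terms), self.w_baseline, z)

    def diffusivity(self, z):
        """D(z) in Å²/ps."""
        z = self._check_domain(z)
        return _sum_terms(tuple(self.d_terms), self.d_baseline, z)

    def free_energy_gradient(self, z):
        """dW/dz in kcal/(mol Å)."""
        z = self._check_domain(z)
        return _sum_derivatives(tuple(self.w_terms), z)

    def diffusivity_gradient(self, z):
        """dD/dz in Å/ps."""
        z = self._check_domain(z)
        return _sum_derivatives(tuple(self.d_terms), z)


def evaluate_landscape(spec: LandscapeSpec, z):
    """Evaluate (W, D) at position(s) ``z`` inside the landscape domain."""
    return spec.free_energy(z), spec.diffusivity(z)


def membrane_mimic(
    well_depth: float = -7.0,
    well_width: float = 6.0,
    barrier_height: float = 1.5,
    barrier_center: float = 18.0,
    barrier_width: float = 2.5,
    d_core: float = 0.01,
    d_water: float = 0.1,
    d_edge: float = 16.0,
    z_range: tuple[float, float] = (-42.0, 42.0),
) -> LandscapeSpec:
    """A symmetric bilayer-like landscape for tests and demonstrations.

    W(z): a deep well at the bilayer center (the hydrophobic interior, depth
    ``well_depth`` kcal/mol), a small barrier at ±``barrier_center`` Å (the
    headgroup region), and a flat W = 0 plateau in water.  D(z): ``d_core``
    Å²/ps in the interior rising sigmoid-like (as a complement of a wide
    Gaussian) to ``d_water`` in bulk water — roughly an order of magnitude
    higher, the shape seen for small drug-like solutes.
    """
    w_terms = (
        GaussianTerm(well_depth, 0.0, well_width),
        GaussianTerm(barrier_height, -barrier_center, barrier_width),
        GaussianTerm(barrier_height, +barrier_center, barrier_width),
    )
    # D(z): wide negative Gaussian dip (width d_edge) on a d_water base, so
    # D(0) = d_core exactly and D → d_water in bulk water.
    d_terms = (GaussianTerm(-(d_water - d_core), 0.0, d_edge),)
    return LandscapeSpec(
        w_terms=w_terms,
        d_terms=d_terms,
        w_baseline=0.0,
        d_baseline=d_water,
        z_range=z_range,
    )
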