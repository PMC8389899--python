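"""Synthetic umbrella-sampling campaigns by 1-D overdamped Langevin dynamics.

Each umbrella window is a harmonically restrained simulation of the solute's
transmembrane coordinate z on a parametric landscape (:class:`LandscapeSpec`).
Positions evolve by the Euler–Maruyama discretisation of the overdamped
Langevin equation with position-dependent diffusivity,

    z ← z + β·D(z)·F(z)·dt + D'(z)·dt + sqrt(2·D(z)·dt)·ξ,

where F = −d(W + bias)/dz, bias = ½·k·(z − z₀)², and ξ ~ N(0, 1).  The
D'(z)·dt spurious-drift term is required for the chain's stationary density
to be the Boltzmann distribution ∝ exp(−β(W + bias)) when D varies with z;
without it the generator would not satisfy its own sampling contract.

Randomness comes from numpy's PCG64 via per-window ``SeedSequence`` spawns of
a master seed, so campaigns are bit-reproducible across runs and platforms.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .landscape import LandscapeError, LandscapeSpec, ThermoState


@dataclass
class UmbrellaWindow:
    """One biased window: restraint definition plus its position time series.

    ``times`` are in ps (strictly increasing, uniform spacing), ``positions``
    in Å.  ``discard_fraction`` of the leading samples is treated as burn-in
    and excluded from every downstream estimate.
    """

    center: float  # Å
    force_constant: float  # kcal/(mol Å²)
    times: np.ndarray
    positions: np.ndarray
    discard_fraction: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.shape != self.positions.shape or self.times.ndim != 1:
            raise ValueError("times and positions must be 1-D arrays of equal length")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")
        if not 0 <= self.discard_fraction < 1:
            raise ValueError("discard_fraction must be in [0, 1)")
        if len(self.times) == 0:
            raise ValueError("window series is empty")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=0.0):
            raise ValueError("time stamps must be uniformly spaced")

    @property
    def dt(self) -> float:
        """Sampling interval in ps."""
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def n_discard(self) -> int:
        return int(np.floor(self.discard_fraction * len(self.times)))

    @property
    def retained_times(self) -> np.ndarray:
        return self.times[self.n_discard:]

    @property
    def retained_positions(self) -> np.ndarray:
        return self.positions[self.n_discard:]


@njit(cache=True)
def _langevin_chain(
    z0, n_steps, dt, beta, k, center,
    w_amp, w_cen, w_wid, d_amp, d_cen, d_wid,
    w_base, d_base, z_lo, z_hi, noise, out,
):  # pragma: no cover - exercised via run_langevin_window
    z = z0
    for i in range(n_steps):
        D = d_base
        dDdz = 0.0
        for t in range(d_amp.shape[0]):
            u = (z - d_cen[t]) / d_wid[t]
            g = d_amp[t] * np.exp(-0.5 * u * u)
            D += g
            dDdz += -g * u / d_wid[t]
        if D <= 0.0:
            return i  # signals landscape error at step i
        dWdz = 0.0
        for t in range(w_amp.shape[0]):
            u = (z - w_cen[t]) / w_wid[t]
            dWdz += -w_amp[t] * u / w_wid[t] * np.exp(-0.5 * u * u)
        force = -(dWdz + k * (z - center))
        z = z + beta * D * force * dt + dDdz * dt + np.sqrt(2.0 * D * dt) * noise[i]
        # reflective walls keep the chain inside the landscape domain
        if z < z_lo:
            z = 2.0 * z_lo - z
        elif z > z_hi:
            z = 2.0 * z_hi - z
        out[i] = z
    return -1


def _term_arrays(terms):
    amp = np.array([t.amplitude for t in terms], dtype=float)
    cen = np.array([t.center for t in terms], dtype=float)
    wid = np.array([t.width for t in terms], dtype=float)
    return amp, cen, wid


def run_langevin_window(
    spec: LandscapeSpec,
    thermo: ThermoState,
    center: float,
    force_constant: float,
    n_steps: int,
    dt: float,
    seed,
    discard_fraction: float = 0.1,
    z0: float | None = None,
) -> UmbrellaWindow:
    """Simulate one umbrella window and return its position time series.

    The initial position defaults to the bias center, mirroring the practice
    of starting each window from a steered-MD snapshot at that depth.  The
    recorded series holds ``n_steps`` samples at times dt·(1..n_steps).

    ``seed`` may be an int or a ``numpy.random.SeedSequence``.
    """
    if n_steps <= 0:
        raise ValueError(f"n_steps must be > 0, got {n_steps}")
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    if force_constant < 0:
        raise ValueError("force_constant must be >= 0")
    lo, hi = spec.z_range
    if not lo <= center <= hi:
        raise LandscapeError(f"window center {center} outside landscape domain")

    if isinstance(seed, np.random.SeedSequence):
        seed_seq = seed
        seed_label = seed_seq.entropy
    else:
        seed_seq = np.random.SeedSequence(int(seed))
        seed_label = int(seed)
    rng = np.random.Generator(np.random.PCG64(seed_seq))
    noise = rng.standard_normal(n_steps)

    w_amp, w_cen, w_wid = _term_arrays(spec.w_terms)
    d_amp, d_cen, d_wid = _term_arrays(spec.d_terms)
    out = np.empty(n_steps, dtype=float)
    start = float(center if z0 is None else z0)
    bad = _langevin_chain(
        start, n_steps, dt, thermo.beta, force_constant, center,
        w_amp, w_cen, w_wid, d_amp, d_cen, d_wid,
        spec.w_baseline, spec.d_baseline, lo, hi, noise, out,
    )
    if bad >= 0:
        raise LandscapeError(f"D(z) <= 0 encountered during sampling at step {bad}")
    times = dt * np.arange(1, n_steps + 1)
    return UmbrellaWindow(
        center=center,
        force_constant=force_constant,
        times=times,
        positions=out,
        discard_fraction=discard_fraction,
        seed=seed_label if isinstance(seed_label, int) else None,
    )


def window_centers(n_windows: int = 35, spacing: float = 1.0, origin: float = 0.0) -> np.ndarray:
    """Ladder of bias centers: ``origin + spacing·{0, 1, …, n_windows−1}``.

    The default ladder (35 windows, 1.0 Å apart, starting at the bilayer
    center z = 0) spans one leaflet out into bulk water.
    """
    if n_windows < 2:
        raise ValueError("n_windows must be >= 2")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    return origin + spacing * np.arange(n_windows, dtype=float)


def simulate_campaign(
    spec: LandscapeSpec,
    thermo: ThermoState,
    n_windows: int = 35,
    spacing: float = 1.0,
    force_constant: float = 2.5,
    n_steps: int = 2_000_000,
    dt: float = 0.05,
    seed: int = 0,
    origin: float = 0.0,
    discard_fraction: float = 0.1,
) -> list[UmbrellaWindow]:
    """Run the full window ladder in memory.

    Per-window seeds are spawned deterministically from the master seed via
    ``numpy.random.SeedSequence(seed).spawn``, so the campaign is exactly
    reproducible and windows are statistically independent.
    """
    centers = window_centers(n_windows, spacing, origin)
    lo, hi = spec.z_range
    if centers[0] < lo or centers[-1] > hi:
        raise LandscapeError(
            f"window ladder [{centers[0]}, {centers[-1]}] exceeds landscape "
            f"domain [{lo}, {hi}]"
        )
    children = np.random.SeedSequence(int(seed)).spawn(len(centers))
    windows = []
    for c, child in zip(centers, children):
        windows.append(
            run_langevin_window(
                spec, thermo, float(c), force_constant, n_steps, dt, child,
                discard_fraction=discard_fraction,
            )
        )
    return windows


def generate_campaign(
    spec: LandscapeSpec,
    thermo: ThermoState,
    outdir,
    n_windows: int = 35,
    spacing: float = 1.0,
    force_constant: float = 2.5,
    n_steps: int = 2_000_000,
    dt: float = 0.05,
    seed: int = 0,
    origin: float = 0.0,
    discard_fraction: float = 0.1,
):
    """Simulate a campaign and write time-series + metadata files to ``outdir``.

    Returns ``(windows, metadata_path)``.  File formats are described in
    :mod:`memperm.io`.
    """
    from . import io as mio

    windows = simulate_campaign(
        spec, thermo, n_windows, spacing, force_constant, n_steps, dt, seed,
        origin=origin, discard_fraction=discard_fraction,
    )
    meta_path = mio.write_campaign(windows, outdir, master_seed=seed)
    return windows, meta_path
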