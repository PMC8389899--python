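"""Weighted histogram analysis method (WHAM) for umbrella-sampling data.

Given per-window histograms of the biased coordinate, WHAM solves the
self-consistency equations

    p_j = M_j / Σ_i N_i · exp(β f_i) · exp(−β b_ij)
    exp(−β f_i) = Σ_j p_j · exp(−β b_ij)

for the unbiased probabilities p_j on the global bin grid and the per-window
free-energy offsets f_i, where M_j is the total count in bin j, N_i the
sample count of window i and b_ij = ½ k_i (z_j − c_i)² the bias energy of
window i at bin center z_j.  Iteration stops when the largest change of any
window offset between successive iterations falls below the configured
tolerance.  The potential of mean force is then W_j = −k_B T · ln p_j,
shifted so that the bulk-water plateau averages to zero.

Per-bin statistical uncertainties come from a moving-block bootstrap of the
window time series (blocks respect the autocorrelation the raw samples
carry), re-running the WHAM solve for each resampled campaign.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landscape import ThermoState
from .simulate import UmbrellaWindow


class WhamError(RuntimeError):
    """Raised for WHAM configuration, data or convergence failures."""


@dataclass(frozen=True)
class WhamConfig:
    """Histogram and solver settings.

    ``n_bins`` defaults to 720 and ``tolerance`` (on the window offsets, in
    kcal/mol) to 1e-8, the conventional settings for single-leaflet drug
    permeation profiles.
    """

    n_bins: int = 720
    tolerance: float = 1e-8
    max_iterations: int = 500_000
    z_range: tuple[float, float] | None = None  # auto from data when None

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise WhamError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.tolerance <= 0:
            raise WhamError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise WhamError("max_iterations must be >= 1")


@dataclass(frozen=True)
class BootstrapConfig:
    """Moving-block bootstrap settings.

    ``block_length`` is in ps; the default of ``None`` means 50 sampling
    intervals, resolved against the data.  100 trials is the conventional
    count for per-bin PMF uncertainties.
    """

    n_trials: int = 100
    block_length: float | None = None  # ps
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise WhamError("n_trials must be >= 2")
        if self.block_length is not None and self.block_length <= 0:
            raise WhamError("block_length must be > 0")


@dataclass
class HistogramSet:
    """Per-window counts on a shared uniform bin grid."""

    bin_edges: np.ndarray  # (n_bins + 1,)
    counts: np.ndarray  # (n_windows, n_bins)
    n_samples: np.ndarray  # (n_windows,)
    centers: np.ndarray  # bias centers, Å
    force_constants: np.ndarray  # kcal/(mol Å²)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1


@dataclass
class FreeEnergyProfile:
    """W(z) on a uniform grid, optionally with per-bin standard errors.

    ``W`` is NaN on bins with no counts; the profile carries the label of
    the zero-reference convention applied to it.
    """

    z_grid: np.ndarray  # Å, uniform, strictly increasing
    W: np.ndarray  # kcal/mol
    stderr: np.ndarray | None = None
    reference_convention: str = "raw"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z_grid = np.asarray(self.z_grid, dtype=float)
        self.W = np.asarray(self.W, dtype=float)
        if self.z_grid.shape != self.W.shape:
            raise ValueError("z_grid and W must have the same shape")
        dz = np.diff(self.z_grid)
        # tolerance accommodates grids round-tripped through text files
        if np.any(dz <= 0) or not np.allclose(dz, dz[0], rtol=1e-4, atol=0.0):
            raise ValueError("z_grid must be strictly increasing and uniform")

    @property
    def spacing(self) -> float:
        return float(self.z_grid[1] - self.z_grid[0])


# ---------------------------------------------------------------------------
# histograms

def build_histograms(windows: list[UmbrellaWindow], config: WhamConfig) -> HistogramSet:
    """Bin each window's retained samples on a common uniform grid.

    The grid spans the union of window supports padded by one bin width
    (unless the config pins an explicit ``z_range``).  Counts are conserved:
    every retained sample of every window lands in exactly one bin.
    """
    if not windows:
        raise WhamError("no windows supplied")
    samples = []
    for i, w in enumerate(windows):
        x = w.retained_positions
        if len(x) == 0:
            raise WhamError(f"window {i} (center {w.center}) empty after burn-in discard")
        samples.append(x)

    if config.z_range is not None:
        lo, hi = config.z_range
    else:
        lo = min(float(np.min(x)) for x in samples)
        hi = max(float(np.max(x)) for x in samples)
        pad = (hi - lo) / config.n_bins
        lo, hi = lo - pad, hi + pad
    edges = np.linspace(lo, hi, config.n_bins + 1)

    counts = np.empty((len(windows), config.n_bins))
    n_samples = np.empty(len(windows), dtype=int)
    for i, x in enumerate(samples):
        if np.any(x < lo) or np.any(x > hi):
            raise WhamError(
                f"window {i} (center {windows[i].center}) has samples outside "
                f"the histogram range [{lo:.4g}, {hi:.4g}]"
            )
        counts[i], _ = np.histogram(x, bins=edges)
        n_samples[i] = len(x)
        if counts[i].sum() != n_samples[i]:
            raise WhamError(f"count conservation violated for window {i}")
    return HistogramSet(
        bin_edges=edges,
        counts=counts,
        n_samples=n_samples,
        centers=np.array([w.center for w in windows], dtype=float),
        force_constants=np.array([w.force_constant for w in windows], dtype=float),
    )


# ---------------------------------------------------------------------------
# solver

def _bias_matrix(hist: HistogramSet) -> np.ndarray:
    """b_ij = ½ k_i (z_j − c_i)² in kcal/mol."""
    z = hist.bin_centers[None, :]
    c = hist.centers[:, None]
    k = hist.force_constants[:, None]
    return 0.5 * k * (z - c) ** 2


def wham_solve(
    hist: HistogramSet,
    thermo: ThermoState,
    config: WhamConfig | None = None,
    f_init: np.ndarray | None = None,
) -> FreeEnergyProfile:
    """Solve the WHAM equations and return the PMF on the bin centers.

    Stops when max_i |Δf_i| < tolerance; raises on non-convergence.  With a
    single window the fixed point is reached in one iteration and equals the
    bias-subtracted Boltzmann inversion of the histogram.  ``f_init`` allows
    warm-starting (used heavily by the bootstrap).

    The returned profile is shifted so its minimum is 0 and labelled
    ``"min_zero"``; apply :func:`reference_to_plateau` (or symmetrize first)
    to re-reference to bulk water.
    """
    config = config or WhamConfig()
    kT = thermo.kT
    beta = thermo.beta

    M = hist.counts.sum(axis=0)  # (n_bins,)
    N = hist.n_samples.astype(float)  # (n_windows,)
    if M.sum() == 0:
        raise WhamError("all histogram bins are empty")
    bias = _bias_matrix(hist)
    A = np.exp(-beta * bias)  # (n_windows, n_bins); underflow to 0 is fine

    _warn_on_poor_overlap(hist)

    f = np.zeros(len(N)) if f_init is None else np.array(f_init, dtype=float)
    occupied = M > 0
    n_iter = 0
    residual = np.inf
    for n_iter in range(1, config.max_iterations + 1):
        weight = N * np.exp(beta * f)  # (n_windows,)
        denom = weight @ A  # (n_bins,)
        p = np.zeros_like(M)
        p[occupied] = M[occupied] / denom[occupied]
        p /= p.sum()
        with np.errstate(divide="ignore"):
            f_new = -kT * np.log(A @ p)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f)))
        f = f_new
        if residual < config.tolerance:
            break
    else:
        raise WhamError(
            f"WHAM did not converge in {config.max_iterations} iterations "
            f"(final offset residual {residual:.3e})"
        )

    with np.errstate(divide="ignore"):
        W = np.where(occupied, -kT * np.log(np.where(occupied, p, 1.0)), np.nan)
    W = W - np.nanmin(W)
    return FreeEnergyProfile(
        z_grid=hist.bin_centers,
        W=W,
        reference_convention="min_zero",
        meta={
            "iterations": n_iter,
            "residual": residual,
            "offsets": f,
            "probability": p,
            "counts": M,
            "temperature": thermo.temperature,
            "n_bins": hist.n_bins,
            "tolerance": config.tolerance,
        },
    )


def _warn_on_poor_overlap(hist: HistogramSet) -> None:
    order = np.argsort(hist.centers)
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hist.counts[a] > 0) & (hist.counts[b] > 0)):
            warnings.warn(
                f"adjacent windows at {hist.centers[a]} and {hist.centers[b]} Å "
                "share no occupied bin; WHAM offsets between them are weakly "
                "determined",
                stacklevel=3,
            )


# ---------------------------------------------------------------------------
# referencing and symmetrization

def reference_to_plateau(
    profile: FreeEnergyProfile, plateau_width: float = 3.0,
    plateau_edge: float | None = None,
) -> FreeEnergyProfile:
    """Shift W so the outermost ``plateau_width`` Å of the profile average 0.

    The permeability integral needs W measured relative to bulk water.  The
    plateau is taken as the ``plateau_width`` Å of largest |z| up to
    ``plateau_edge`` (default: the end of the grid): for a half profile
    (bilayer center → water) that is the high-z end, and for a symmetrized
    profile both outer ends, averaged together.  Pass ``plateau_edge`` at the
    outermost bias center when the histogram range extends past the sampled
    region — the sparse bins beyond the last window would otherwise inject
    their noise into the absolute reference.
    """
    z, W = profile.z_grid, profile.W
    zmax = float(np.max(np.abs(z))) if plateau_edge is None else float(plateau_edge)
    mask = (np.abs(z) >= zmax - plateau_width) & (np.abs(z) <= zmax)
    vals = W[mask & np.isfinite(W)]
    if len(vals) == 0:
        raise WhamError("no finite W values in the plateau region to reference to")
    shift = float(np.mean(vals))
    return FreeEnergyProfile(
        z_grid=z.copy(),
        W=W - shift,
        stderr=None if profile.stderr is None else profile.stderr.copy(),
        reference_convention="water_zero",
        meta={**profile.meta, "plateau_width": plateau_width, "reference_shift": shift},
    )


def symmetrize_profile(profile: FreeEnergyProfile, center: float = 0.0) -> FreeEnergyProfile:
    """Average W(center+δ) with W(center−δ) onto a grid symmetric about center.

    Valid for single-component symmetric bilayers, where the two leaflets are
    statistically equivalent.  Where only one side of the profile covers a
    |δ|, its value is mirrored unchanged.  Uncertainties of the two mirrored
    bins are combined in quadrature and halved; the operation is idempotent.
    """
    z, W = profile.z_grid, profile.W
    if not (z[0] <= center <= z[-1]):
        raise ValueError(f"symmetrization center {center} outside the profile grid")
    dz = profile.spacing
    delta_max = max(z[-1] - center, center - z[0])
    n = int(round(delta_max / dz))
    delta = dz * np.arange(n + 1)

    finite = np.isfinite(W)
    if not np.any(finite):
        raise ValueError("profile has no finite values to symmetrize")
    zf, Wf = z[finite], W[finite]

    def sample(vals, zq):
        out = np.interp(zq, zf, vals)
        out[(zq < zf[0] - 1e-9) | (zq > zf[-1] + 1e-9)] = np.nan
        return out

    Wp = sample(Wf, center + delta)
    Wm = sample(Wf, center - delta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        half = np.nanmean(np.vstack([Wp, Wm]), axis=0)

    err_half = None
    if profile.stderr is not None:
        E = profile.stderr[finite]
        ep = sample(E, center + delta)
        em = sample(E, center - delta)
        both = np.isfinite(ep) & np.isfinite(em)
        err_half = np.where(both, 0.5 * np.sqrt(ep**2 + em**2),
                            np.where(np.isfinite(ep), ep, em))

    z_sym = np.concatenate([center - delta[:0:-1], center + delta])
    W_sym = np.concatenate([half[:0:-1], half])
    e_sym = None if err_half is None else np.concatenate([err_half[:0:-1], err_half])
    return FreeEnergyProfile(
        z_grid=z_sym,
        W=W_sym,
        stderr=e_sym,
        reference_convention=profile.reference_convention + "+symmetrized",
        meta={**profile.meta, "symmetrization_center": center},
    )


# ---------------------------------------------------------------------------
# bootstrap

@dataclass
class BootstrapPMF:
    """Bootstrap output: the point-estimate profile with stderr, plus the
    per-trial W replicas (n_trials × n_bins) for downstream propagation."""

    profile: FreeEnergyProfile
    replicas: np.ndarray
    z_grid: np.ndarray


def _block_resample_counts(bin_idx, n_bins, block, rng):
    """Histogram of a moving-block resample of a digitized series."""
    n = len(bin_idx)
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n - block + 1, size=n_blocks)
    take = (starts[:, None] + np.arange(block)[None, :]).ravel()[:n]
    return np.bincount(bin_idx[take], minlength=n_bins)


def bootstrap_pmf(
    windows: list[UmbrellaWindow],
    thermo: ThermoState,
    wham_config: WhamConfig | None = None,
    boot_config: BootstrapConfig | None = None,
    plateau_edge: float | None = None,
) -> BootstrapPMF:
    """Moving-block bootstrap of the PMF.

    Within each window, contiguous blocks of the retained series are resampled
    with replacement and re-histogrammed; WHAM is re-solved per trial (warm-
    started from the full-data offsets).  Per-bin stderr is the standard
    deviation of W over trials, computed after each trial is shifted to the
    same reference as the point estimate so that the overall additive
    constant does not inflate the errors.
    """
    wham_config = wham_config or WhamConfig()
    boot_config = boot_config or BootstrapConfig()
    hist = build_histograms(windows, wham_config)
    base = wham_solve(hist, thermo, wham_config)
    base = reference_to_plateau(base, plateau_edge=plateau_edge)
    f0 = base.meta["offsets"]

    dt = windows[0].dt
    if boot_config.block_length is None:
        block = 50
    else:
        block = max(1, int(round(boot_config.block_length / dt)))
    # pre-digitize each window once; resampling then only permutes bin labels
    edges = hist.bin_edges
    digitized = []
    for w in windows:
        x = w.retained_positions
        if block >= len(x):
            raise WhamError(
                f"bootstrap block ({block} samples) is not shorter than the "
                f"retained series ({len(x)} samples)"
            )
        idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, hist.n_bins - 1)
        digitized.append(idx.astype(np.int64))

    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence(boot_config.seed)))
    trials = np.empty((boot_config.n_trials, hist.n_bins))
    loose = WhamConfig(
        n_bins=wham_config.n_bins,
        tolerance=wham_config.tolerance,
        max_iterations=wham_config.max_iterations,
        z_range=(edges[0], edges[-1]),
    )
    for t in range(boot_config.n_trials):
        counts = np.empty_like(hist.counts)
        for i, idx in enumerate(digitized):
            counts[i] = _block_resample_counts(idx, hist.n_bins, block, rng)
        h = HistogramSet(
            bin_edges=edges,
            counts=counts,
            n_samples=counts.sum(axis=1).astype(int),
            centers=hist.centers,
            force_constants=hist.force_constants,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prof = wham_solve(h, thermo, loose, f_init=f0)
        trials[t] = reference_to_plateau(prof, plateau_edge=plateau_edge).W

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        stderr = np.nanstd(trials, axis=0, ddof=1)
    out = FreeEnergyProfile(
        z_grid=base.z_grid.copy(),
        W=base.W.copy(),
        stderr=stderr,
        reference_convention=base.reference_convention,
        meta={**base.meta, "bootstrap_trials": boot_config.n_trials,
              "bootstrap_block_samples": block, "bootstrap_seed": boot_config.seed},
    )
    return BootstrapPMF(profile=out, replicas=trials, z_grid=base.z_grid.copy())
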