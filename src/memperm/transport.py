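"""Local diffusivity and inhomogeneous solubility–diffusion permeability.

Diffusivity per umbrella window comes from the positional-autocorrelation
estimator for harmonically restrained sampling:

    D(⟨Z⟩) = ⟨δZ²⟩² / ∫₀^∞ ⟨δZ(t) δZ(0)⟩ dt,    δZ(t) = z(t) − ⟨Z⟩,

i.e. the squared positional variance of the biased window divided by the
integrated positional autocorrelation function (ACF).  For an
Ornstein–Uhlenbeck window (harmonic restraint on locally flat W, constant
D) the ACF is σ²·e^(−t/τ) with σ² = k_BT/k and τ = k_BT/(kD), so the
estimator returns σ⁴/(σ²τ) = σ²/τ = D exactly — this closed form anchors
the unit tests.  The empirical ACF integral is truncated at its first
zero-crossing (noisy tails otherwise make it diverge).

Permeability follows the inhomogeneous solubility–diffusion model:

    1/P = R = ∫ exp(β W(z)) / D(z) dz,    β = 1/(k_B T),

integrated across the membrane on a uniform grid (1.0 Å by default) between
the bilayer center and the bulk-water plateau, with W referenced to zero in
water.  Internally everything is Å / ps / kcal·mol⁻¹; conversions to cm²/s
and cm/s are applied only when reporting (1 Å²/ps = 1e-4 cm²/s,
1 Å = 1e-8 cm).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .landscape import ThermoState
from .simulate import UmbrellaWindow
from .wham import FreeEnergyProfile

#: unit conversions at the reporting boundary
A2_PER_PS_TO_CM2_PER_S = 1e-4
ANGSTROM_TO_CM = 1e-8
#: 1 ps/Å of internal resistivity, expressed in s/cm
PS_PER_A_TO_S_PER_CM = 1e-12 / 1e-8


class EstimationError(RuntimeError):
    """Raised when a diffusivity estimate cannot be formed from the data."""


@dataclass
class DiffusivityProfile:
    """Per-window D estimates and their interpolation onto a uniform grid."""

    points_z: np.ndarray  # window mean positions, Å
    points_D: np.ndarray  # Å²/ps
    grid_z: np.ndarray | None = None
    grid_D: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points_z = np.asarray(self.points_z, dtype=float)
        self.points_D = np.asarray(self.points_D, dtype=float)
        if np.any(self.points_D <= 0):
            raise ValueError("diffusivity must be > 0 at every point")
        order = np.argsort(self.points_z)
        self.points_z = self.points_z[order]
        self.points_D = self.points_D[order]

    @property
    def points_D_cm2_s(self) -> np.ndarray:
        return self.points_D * A2_PER_PS_TO_CM2_PER_S


@dataclass
class ResistivityProfile:
    """Local permeation resistance r(z) = exp(βW)/D and its running integral.

    ``integrand`` is in ps/Å² and ``cumulative_R`` in ps/Å (internal units);
    ``cumulative_R`` is non-decreasing because the integrand is positive.
    """

    z_grid: np.ndarray
    integrand: np.ndarray
    cumulative_R: np.ndarray
    temperature: float
    meta: dict = field(default_factory=dict)

    @property
    def total_R(self) -> float:
        """Total resistance over the grid, ps/Å."""
        return float(self.cumulative_R[-1])


@dataclass
class PermeabilityResult:
    """Permeability in reporting units.

    ``R`` in s/cm, ``P`` in cm/s, ``log10_P`` of P in cm/s; ``mode`` records
    whether R was integrated over the half membrane (center → water) or the
    full width of a symmetrized profile.
    """

    R: float
    P: float
    log10_P: float
    bounds: tuple[float, float]
    mode: str
    temperature: float
    stderr_log10_P: float | None = None

    @classmethod
    def from_internal(cls, R_ps_per_A: float, bounds, mode, temperature,
                      stderr_log10_P=None) -> "PermeabilityResult":
        if R_ps_per_A <= 0:
            raise ValueError("total resistance must be > 0")
        R = R_ps_per_A * PS_PER_A_TO_S_PER_CM
        P = 1.0 / R
        return cls(R=R, P=P, log10_P=float(np.log10(P)), bounds=tuple(bounds),
                   mode=mode, temperature=temperature, stderr_log10_P=stderr_log10_P)


# ---------------------------------------------------------------------------
# diffusivity estimation

def autocorrelation(x: np.ndarray, max_lag: int | None = None) -> np.ndarray:
    """Biased positional ACF ⟨δx(t)δx(0)⟩ via FFT, lags 0..max_lag.

    The biased (1/n) normalisation keeps the ACF positive-semidefinite and
    the integral estimate stable; max_lag defaults to n//2.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        raise EstimationError("series too short for an autocorrelation")
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    d = x - x.mean()
    m = 1 << int(np.ceil(np.log2(2 * n)))
    F = np.fft.rfft(d, m)
    acf = np.fft.irfft(F * np.conj(F), m)[: max_lag + 1]
    return acf / n


def integrate_acf_to_zero_crossing(acf: np.ndarray, dt: float,
                                   floor_fraction: float = 0.01) -> float:
    """Trapezoid integral of the ACF from lag 0 to its truncation point.

    Integration stops at the first zero-crossing or where the ACF first
    drops below ``floor_fraction`` of the variance (lag-0 value), whichever
    comes first; if neither happens the full range is used.  Stopping at the
    floor even before a zero-crossing avoids conditioning on the noisy ACF
    tail staying positive, which would bias the integral high (and the
    diffusivity low).
    """
    neg = np.nonzero(acf < 0.0)[0]
    small = np.nonzero(acf < floor_fraction * acf[0])[0]
    cands = [c[0] for c in (neg, small) if len(c)]
    cut = min(cands) if cands else len(acf) - 1
    if cut < 1:
        raise EstimationError("ACF non-positive at the first lag; series is noise-dominated")
    return float(np.trapezoid(acf[: cut + 1], dx=dt))


def estimate_window_diffusivity(
    window: UmbrellaWindow, max_lag: int | None = None
) -> tuple[float, float]:
    """Estimate (⟨Z⟩, D) for one umbrella window, D in Å²/ps.

    Requires a retained series much longer than the position relaxation time
    (k_BT/(kD) for an OU window) so the ACF integral is well resolved.
    """
    x = window.retained_positions
    var = float(np.var(x))
    if var == 0.0:
        raise EstimationError("window series has zero variance")
    acf = autocorrelation(x, max_lag=max_lag)
    tau_int = integrate_acf_to_zero_crossing(acf, window.dt)
    if tau_int <= 0:
        raise EstimationError(
            "non-positive ACF integral; sampling too short relative to the "
            "autocorrelation time"
        )
    return float(np.mean(x)), var**2 / tau_int


def diffusivity_profile(
    windows: list[UmbrellaWindow], max_lag: int | None = None
) -> DiffusivityProfile:
    """Per-window diffusivity estimates collected into a profile."""
    zs, Ds = [], []
    for w in windows:
        z, D = estimate_window_diffusivity(w, max_lag=max_lag)
        zs.append(z)
        Ds.append(D)
    return DiffusivityProfile(points_z=np.array(zs), points_D=np.array(Ds))


def symmetrize_diffusivity(diff: DiffusivityProfile, center: float = 0.0) -> DiffusivityProfile:
    """Mirror D points about ``center``, averaging coincident mirror pairs.

    Used when permeability is computed over the full width of a symmetrized
    PMF: the diffusivity profile must cover the same span, and for a
    symmetric bilayer D(center+δ) = D(center−δ).
    """
    z = diff.points_z - center
    zs = np.concatenate([z, -z])
    Ds = np.concatenate([diff.points_D, diff.points_D])
    order = np.argsort(zs)
    zs, Ds = zs[order], Ds[order]
    uz, inv = np.unique(np.round(zs, 9), return_inverse=True)
    uD = np.zeros_like(uz)
    cnt = np.zeros_like(uz)
    np.add.at(uD, inv, Ds)
    np.add.at(cnt, inv, 1.0)
    return DiffusivityProfile(points_z=uz + center, points_D=uD / cnt, meta=dict(diff.meta))


# ---------------------------------------------------------------------------
# grid alignment and integration

def interpolate_profiles(
    pmf: FreeEnergyProfile,
    diff: DiffusivityProfile,
    spacing: float = 1.0,
    bounds: tuple[float, float] | None = None,
):
    """Linearly interpolate W and D onto one uniform grid (default 1.0 Å).

    The grid covers ``bounds`` when given, else the overlap of the two
    inputs, snapped to integer multiples of ``spacing``.  Extrapolation is
    refused: requesting a span beyond either input raises.  NaN stretches of
    W (empty interior bins) are bridged linearly between the nearest finite
    neighbours.  Returns ``(z_grid, W_grid, D_grid)``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    finite = np.isfinite(pmf.W)
    if not np.any(finite):
        raise ValueError("PMF has no finite values")
    wz = pmf.z_grid[finite]
    lo = max(wz[0], diff.points_z[0])
    hi = min(wz[-1], diff.points_z[-1])
    if bounds is not None:
        blo, bhi = bounds
        if blo < lo - 1e-9 or bhi > hi + 1e-9:
            raise ValueError(
                f"requested span [{blo}, {bhi}] exceeds data support [{lo:.4g}, {hi:.4g}]"
            )
        lo, hi = blo, bhi
        z_grid = lo + spacing * np.arange(int(np.floor((hi - lo) / spacing + 1e-9)) + 1)
    else:
        start = np.ceil(lo / spacing - 1e-9) * spacing
        stop = np.floor(hi / spacing + 1e-9) * spacing
        z_grid = start + spacing * np.arange(int(round((stop - start) / spacing)) + 1)
    if len(z_grid) < 2:
        raise ValueError("aligned grid has fewer than 2 points")
    W_grid = np.interp(z_grid, wz, pmf.W[finite])
    D_grid = np.interp(z_grid, diff.points_z, diff.points_D)
    return z_grid, W_grid, D_grid


def compute_resistivity(
    pmf: FreeEnergyProfile,
    diff: DiffusivityProfile,
    thermo: ThermoState,
    bounds: tuple[float, float] | None = None,
    spacing: float = 1.0,
) -> ResistivityProfile:
    """Resistivity integrand exp(βW)/D and its cumulative trapezoid integral.

    W must be referenced to zero in bulk water for the result to be a
    permeation resistance; the profile's reference convention is echoed in
    the metadata rather than enforced.
    """
    z, W, D = interpolate_profiles(pmf, diff, spacing=spacing, bounds=bounds)
    integrand = np.exp(thermo.beta * W) / D
    cum = np.concatenate([[0.0], cumulative_trapezoid(integrand, z)])
    return ResistivityProfile(
        z_grid=z,
        integrand=integrand,
        cumulative_R=cum,
        temperature=thermo.temperature,
        meta={
            "spacing": spacing,
            "reference_convention": pmf.reference_convention,
            "interpolation": "linear",
        },
    )


def detect_water_edge(
    pmf: FreeEnergyProfile, threshold: float = 0.1, run_length: int = 3,
    spacing: float = 1.0,
) -> float:
    """Innermost |z| from which W stays within ``threshold`` of zero.

    Scans the water-referenced PMF on a uniform ``spacing`` grid outward from
    the bilayer center and returns the start of the first run of at least
    ``run_length`` consecutive points with |W| < threshold — the edge of the
    bulk-water plateau, used as the default upper integration bound.
    """
    finite = np.isfinite(pmf.W)
    wz, Wv = pmf.z_grid[finite], pmf.W[finite]
    zmax = np.floor(wz[-1] / spacing) * spacing
    zq = spacing * np.arange(0.0, zmax / spacing + 1e-9)
    if len(zq) < run_length:
        return float(wz[-1])
    Wq = np.interp(zq, wz, Wv)
    flat = np.abs(Wq) < threshold
    for i in range(len(zq) - run_length + 1):
        if flat[i : i + run_length].all():
            return float(zq[i])
    return float(zq[-1])


def compute_permeability(
    res: ResistivityProfile, mode: str = "half",
) -> PermeabilityResult:
    """Total resistance → permeability, in reporting units.

    ``half``: R is the cumulative integral over the profile as given
    (bilayer center → water).  ``full``: the profile must span both leaflets;
    R is the integral over the full width, which equals twice the half-
    membrane value for a symmetric profile.  P = 1/R, reported in cm/s with
    its base-10 logarithm.
    """
    if mode not in ("half", "full"):
        raise ValueError(f"mode must be 'half' or 'full', got {mode!r}")
    R_int = res.total_R
    if R_int <= 0:
        raise ValueError("degenerate input: total resistance is zero")
    return PermeabilityResult.from_internal(
        R_int, bounds=(float(res.z_grid[0]), float(res.z_grid[-1])),
        mode=mode, temperature=res.temperature,
    )


def propagate_uncertainty(
    replicas: np.ndarray,
    z_grid: np.ndarray,
    diff: DiffusivityProfile,
    thermo: ThermoState,
    bounds: tuple[float, float] | None = None,
    spacing: float = 1.0,
    mode: str = "half",
) -> float:
    """Std of log10 P over bootstrap PMF replicas.

    Each replica W(z) (rows of ``replicas`` on ``z_grid``) is pushed through
    the same resistivity integral as the point estimate; the spread of
    log10 P over replicas is the reported uncertainty.  Diffusivity is held
    at its point estimate — the PMF enters P exponentially and dominates the
    uncertainty budget.
    """
    replicas = np.asarray(replicas, dtype=float)
    if replicas.ndim != 2 or replicas.shape[0] < 2:
        raise ValueError("need at least 2 bootstrap replicas")
    if replicas.shape[1] != len(z_grid):
        raise ValueError("replica grid does not match z_grid")
    logs = []
    for Wrep in replicas:
        prof = FreeEnergyProfile(z_grid=np.asarray(z_grid, float), W=Wrep,
                                 reference_convention="water_zero")
        res = compute_resistivity(prof, diff, thermo, bounds=bounds, spacing=spacing)
        logs.append(compute_permeability(res, mode=mode).log10_P)
    return float(np.std(logs, ddof=1))
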