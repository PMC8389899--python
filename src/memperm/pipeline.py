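"""End-to-end orchestration: simulate → WHAM → symmetrize → bootstrap →
diffusivity → permeability, with deterministic seeding and stage manifests.

A run is described by a :class:`RunConfig` (loadable from a YAML file).  Each
stage writes its tabular product plus a JSON manifest (stage name, parameter
echo, SHA-256 digests of the outputs, timestamp); reruns with an identical
config and seed reproduce identical outputs, so the digests — which exclude
the timestamp — are stable.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .landscape import GaussianTerm, LandscapeSpec, ThermoState, membrane_mimic
from .simulate import UmbrellaWindow, simulate_campaign
from .transport import (
    compute_permeability,
    compute_resistivity,
    detect_water_edge,
    diffusivity_profile,
    propagate_uncertainty,
    symmetrize_diffusivity,
)
from .wham import (
    BootstrapConfig,
    FreeEnergyProfile,
    WhamConfig,
    bootstrap_pmf,
    build_histograms,
    reference_to_plateau,
    symmetrize_profile,
    wham_solve,
)

log = logging.getLogger("memperm")


@dataclass
class RunConfig:
    """Everything a reproducible run needs.

    ``landscape`` is either a :class:`LandscapeSpec`, the string
    ``"membrane_mimic"``, or ``None`` (analysis-only run reading an existing
    ``metadata`` file).  The master ``seed`` drives both the simulator and
    the bootstrap through independent deterministic substreams.
    """

    landscape: LandscapeSpec | str | None = "membrane_mimic"
    metadata: str | None = None  # existing campaign to analyse instead
    temperature: float = 303.0
    # campaign
    n_windows: int = 35
    spacing: float = 1.0
    force_constant: float = 2.5
    n_steps: int = 2_000_000
    dt: float = 0.05
    origin: float = 0.0
    discard_fraction: float = 0.1
    write_series: bool = False
    # wham
    n_bins: int = 720
    tolerance: float = 1e-8
    max_iterations: int = 500_000
    symmetrize_about: float | None = 0.0
    # bootstrap
    bootstrap: bool = True
    n_trials: int = 100
    block_length: float | None = None
    # transport
    bounds: tuple[float, float] | None = None
    mode: str = "half"
    grid_spacing: float = 1.0
    max_lag: int | None = None
    # bookkeeping
    outdir: str = "memperm_run"
    seed: int = 0
    log_level: str = "INFO"

    def resolve_landscape(self) -> LandscapeSpec | None:
        if self.landscape is None or isinstance(self.landscape, LandscapeSpec):
            return self.landscape
        if self.landscape == "membrane_mimic":
            return membrane_mimic()
        raise ValueError(f"unknown landscape preset {self.landscape!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        land = raw.get("landscape")
        if isinstance(land, dict):
            raw["landscape"] = LandscapeSpec(
                w_terms=tuple(GaussianTerm(*t) for t in land.get("w_terms", [])),
                d_terms=tuple(GaussianTerm(*t) for t in land.get("d_terms", [])),
                w_baseline=float(land.get("w_baseline", 0.0)),
                d_baseline=float(land.get("d_baseline", 0.1)),
                z_range=tuple(land.get("z_range", (-40.0, 40.0))),
            )
        if "bounds" in raw and raw["bounds"] is not None:
            raw["bounds"] = tuple(raw["bounds"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _derived_seed(master: int, stream: int) -> int:
    """Deterministic 31-bit child seed for a named substream."""
    state = np.random.SeedSequence([int(master), int(stream)]).generate_state(1)[0]
    return int(state % (2**31))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(outdir: Path, stage: str, params: dict, outputs: list[Path],
                    inputs: dict | None = None) -> None:
    manifest = {
        "stage": stage,
        "parameters": params,
        "inputs": inputs or {},
        "outputs": {p.name: _digest(p) for p in outputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=2) + "\n")


@dataclass
class PipelineResult:
    """In-memory handles to every stage product of one run."""

    windows: list[UmbrellaWindow]
    pmf_half: FreeEnergyProfile
    pmf: FreeEnergyProfile  # symmetrized (or half if symmetrization disabled)
    diffusivity: "object"
    permeability: dict
    summary: dict
    outdir: Path


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Stages run in order; any failure aborts with the stage named, and the
    products of completed stages remain on disk with their manifests.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thermo = ThermoState(temperature=config.temperature)
    stage = "configure"
    try:
        # ---- simulate ----------------------------------------------------
        stage = "simulate"
        if config.metadata is not None:
            windows = mio.read_campaign(config.metadata, config.discard_fraction)
            log.info("loaded %d windows from %s", len(windows), config.metadata)
        else:
            spec = config.resolve_landscape()
            if spec is None:
                raise ValueError("config needs either a landscape or a metadata file")
            sim_seed = _derived_seed(config.seed, 0)
            log.info("simulating %d windows (%d steps each, dt=%g ps)",
                     config.n_windows, config.n_steps, config.dt)
            windows = simulate_campaign(
                spec, thermo, config.n_windows, config.spacing,
                config.force_constant, config.n_steps, config.dt, sim_seed,
                origin=config.origin, discard_fraction=config.discard_fraction,
            )
            if config.write_series:
                meta = mio.write_campaign(windows, outdir / "windows", master_seed=sim_seed)
                _write_manifest(outdir, stage, _campaign_params(config), [meta])

        # ---- wham --------------------------------------------------------
        stage = "wham"
        wham_cfg = WhamConfig(n_bins=config.n_bins, tolerance=config.tolerance,
                              max_iterations=config.max_iterations)
        hist = build_histograms(windows, wham_cfg)
        # pin the water reference inside the sampled region: bins beyond the
        # outermost bias center are too sparse to anchor the zero
        z_edge = float(max(w.center for w in windows))
        pmf_half = reference_to_plateau(wham_solve(hist, thermo, wham_cfg),
                                        plateau_edge=z_edge)
        log.info("WHAM converged in %d iterations (residual %.2e)",
                 pmf_half.meta["iterations"], pmf_half.meta["residual"])
        p_half = mio.write_profile_tsv(pmf_half, outdir / "pmf_half.tsv",
                                       _wham_params(config))
        _write_manifest(outdir, stage, _wham_params(config), [p_half])

        # ---- bootstrap (before symmetrize so stderr rides along) ---------
        stage = "bootstrap"
        boot = None
        if config.bootstrap:
            boot_cfg = BootstrapConfig(
                n_trials=config.n_trials, block_length=config.block_length,
                seed=_derived_seed(config.seed, 1),
            )
            log.info("bootstrap: %d trials", boot_cfg.n_trials)
            boot = bootstrap_pmf(windows, thermo, wham_cfg, boot_cfg,
                                 plateau_edge=z_edge)
            pmf_half = boot.profile

        # ---- symmetrize --------------------------------------------------
        stage = "symmetrize"
        if config.symmetrize_about is not None:
            pmf = symmetrize_profile(pmf_half, config.symmetrize_about)
            pmf = reference_to_plateau(pmf, plateau_edge=z_edge)
        else:
            pmf = pmf_half
        p_pmf = mio.write_profile_tsv(pmf, outdir / "pmf.tsv", _wham_params(config))
        _write_manifest(outdir, stage, {"center": config.symmetrize_about}, [p_pmf])

        # ---- diffusivity -------------------------------------------------
        stage = "diffusivity"
        diff = diffusivity_profile(windows, max_lag=config.max_lag)
        p_diff = mio.write_diffusivity_tsv(diff, outdir / "diffusivity.tsv",
                                           {"max_lag": config.max_lag})
        _write_manifest(outdir, stage, {"max_lag": config.max_lag}, [p_diff])

        # ---- permeate ----------------------------------------------------
        stage = "permeate"
        if config.symmetrize_about is not None:
            diff_full = symmetrize_diffusivity(diff, config.symmetrize_about)
        else:
            diff_full = diff
        if config.bounds is not None:
            z_lo, z_hi = config.bounds
        else:
            z_lo, z_hi = 0.0, detect_water_edge(pmf, spacing=config.grid_spacing)
            # never exceed the diffusivity support
            z_hi = min(z_hi, np.floor(diff_full.points_z[-1] / config.grid_spacing)
                       * config.grid_spacing)
        res_half = compute_resistivity(pmf, diff_full, thermo, bounds=(z_lo, z_hi),
                                       spacing=config.grid_spacing)
        perm = {"half": compute_permeability(res_half, mode="half")}
        if config.symmetrize_about is not None:
            res_full = compute_resistivity(pmf, diff_full, thermo,
                                           bounds=(-z_hi + 2 * z_lo, z_hi),
                                           spacing=config.grid_spacing)
            perm["full"] = compute_permeability(res_full, mode="full")
        if boot is not None:
            stderr = propagate_uncertainty(
                boot.replicas, boot.z_grid, diff_full, thermo,
                bounds=(z_lo, z_hi), spacing=config.grid_spacing, mode="half",
            )
            for r in perm.values():
                # R differs between modes by a z-independent factor, so the
                # bootstrap spread of log10 P is common to both
                r.stderr_log10_P = stderr
        p_res = mio.write_resistivity_tsv(res_half, outdir / "resistivity.tsv",
                                          {"bounds": (z_lo, z_hi)})
        p_perm = mio.write_permeability_report(perm, outdir / "permeability.json",
                                               _transport_params(config, (z_lo, z_hi)))
        _write_manifest(outdir, stage, _transport_params(config, (z_lo, z_hi)),
                        [p_res, p_perm])

        # ---- summary -----------------------------------------------------
        stage = "summary"
        Wf = pmf.W[np.isfinite(pmf.W)]
        summary = {
            "W_min_kcal_mol": float(np.min(Wf)),
            "W_max_kcal_mol": float(np.max(Wf)),
            "barrier_height_kcal_mol": float(np.max(Wf)),
            "bounds_A": [float(z_lo), float(z_hi)],
            "temperature_K": config.temperature,
            "seed": config.seed,
        }
        for mode, r in perm.items():
            summary[f"R_{mode}_s_cm"] = r.R
            summary[f"P_{mode}_cm_s"] = r.P
            summary[f"log10_P_{mode}"] = r.log10_P
            if r.stderr_log10_P is not None:
                summary[f"stderr_log10_P_{mode}"] = r.stderr_log10_P
        (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        log.info("summary: %s", summary)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        windows=windows, pmf_half=pmf_half, pmf=pmf, diffusivity=diff,
        permeability=perm, summary=summary, outdir=outdir,
    )


def _campaign_params(config: RunConfig) -> dict:
    return {
        "n_windows": config.n_windows, "spacing": config.spacing,
        "force_constant": config.force_constant, "n_steps": config.n_steps,
        "dt": config.dt, "origin": config.origin,
        "discard_fraction": config.discard_fraction,
        "temperature": config.temperature, "seed": config.seed,
    }


def _wham_params(config: RunConfig) -> dict:
    return {
        "n_bins": config.n_bins, "tolerance": config.tolerance,
        "temperature": config.temperature, "seed": config.seed,
        "bootstrap_trials": config.n_trials if config.bootstrap else 0,
    }


def _transport_params(config: RunConfig, bounds) -> dict:
    return {
        "bounds": [float(b) for b in bounds], "mode": config.mode,
        "grid_spacing": config.grid_spacing, "temperature": config.temperature,
        "seed": config.seed,
    }
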