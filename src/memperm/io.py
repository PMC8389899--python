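"""Readers and writers for the pipeline's plain-text formats.

Time series: two whitespace-separated numeric columns (time ps, position Å)
with ``#`` comment headers carrying the window center, force constant and
seed.  Window metadata: one ``path center force_constant`` line per window
(the dialect understood by the common umbrella-sampling WHAM tools), with
``#`` comments allowed and relative paths resolved against the metadata
file's directory.  Tabular outputs are TSV with a ``#`` header echoing the
parameters that produced them.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import UmbrellaWindow
from .transport import (
    A2_PER_PS_TO_CM2_PER_S,
    DiffusivityProfile,
    PermeabilityResult,
    ResistivityProfile,
)
from .wham import FreeEnergyProfile


class ParseError(ValueError):
    """Raised for malformed input files, with the offending line number."""


# ---------------------------------------------------------------------------
# time series

def write_timeseries(window: UmbrellaWindow, path) -> Path:
    path = Path(path)
    header = (
        f"# center_A {window.center!r}\n"
        f"# force_constant_kcal_mol_A2 {window.force_constant!r}\n"
        f"# seed {window.seed}\n"
        f"# discard_fraction {window.discard_fraction!r}\n"
        "# columns: time_ps position_A\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, np.column_stack([window.times, window.positions]), fmt="%.10g")
    return path


def read_timeseries(path, discard_fraction: float = 0.1,
                    center: float | None = None,
                    force_constant: float | None = None) -> UmbrellaWindow:
    """Read one window time series; headers override missing restraint info.

    The leading ``discard_fraction`` of rows is treated as burn-in (the
    returned window keeps all rows but exposes only the retained part to
    estimators).
    """
    path = Path(path)
    meta: dict[str, float] = {}
    times, positions = [], []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if len(parts) == 2:
                    try:
                        meta[parts[0]] = float(parts[1])
                    except ValueError:
                        pass
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected two columns, got {line!r}")
            try:
                t, z = float(parts[0]), float(parts[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric row {line!r}") from exc
            times.append(t)
            positions.append(z)
    if not times:
        raise ParseError(f"{path}: no data rows")
    if center is None:
        center = meta.get("center_A")
    if force_constant is None:
        force_constant = meta.get("force_constant_kcal_mol_A2")
    if center is None or force_constant is None:
        raise ParseError(
            f"{path}: window center/force constant neither in header nor supplied"
        )
    seed = meta.get("seed")
    try:
        w = UmbrellaWindow(
            center=float(center),
            force_constant=float(force_constant),
            times=np.asarray(times),
            positions=np.asarray(positions),
            discard_fraction=discard_fraction,
            seed=None if seed is None else int(seed),
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return w


# ---------------------------------------------------------------------------
# metadata

def write_campaign(windows: list[UmbrellaWindow], outdir, master_seed=None) -> Path:
    """Write one time-series file per window plus the metadata file.

    Returns the metadata path ``outdir/windows.meta``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    lines = ["# path center_A force_constant_kcal_mol_A2"]
    if master_seed is not None:
        lines.insert(0, f"# master_seed {master_seed}")
    width = max(3, len(str(len(windows) - 1)))
    for i, w in enumerate(windows):
        name = f"window_{i:0{width}d}.dat"
        write_timeseries(w, outdir / name)
        lines.append(f"{name} {w.center:.6g} {w.force_constant:.6g}")
    meta = outdir / "windows.meta"
    meta.write_text("\n".join(lines) + "\n")
    return meta


def read_metadata(path) -> list[tuple[Path, float, float]]:
    """Parse a metadata file into (series_path, center, force_constant) rows."""
    path = Path(path)
    entries = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{ln}: expected 'path center force_constant', got {raw.strip()!r}"
                )
            try:
                center, k = float(parts[1]), float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{ln}: non-numeric center/force constant") from exc
            series = Path(parts[0])
            if not series.is_absolute():
                series = path.parent / series
            entries.append((series, center, k))
    if not entries:
        raise ParseError(f"{path}: no window entries (only comments/blank lines)")
    missing = [str(p) for p, _, _ in entries if not p.exists()]
    if missing:
        raise FileNotFoundError(f"{path}: missing series files: {', '.join(missing)}")
    return entries


def read_campaign(meta_path, discard_fraction: float = 0.1) -> list[UmbrellaWindow]:
    """Load every window referenced by a metadata file."""
    return [
        read_timeseries(p, discard_fraction=discard_fraction, center=c, force_constant=k)
        for p, c, k in read_metadata(meta_path)
    ]


# ---------------------------------------------------------------------------
# tabular outputs

def _header_lines(params: dict) -> str:
    return "".join(f"# {k} = {v}\n" for k, v in params.items())


def write_profile_tsv(profile: FreeEnergyProfile, path, params: dict | None = None) -> Path:
    path = Path(path)
    cols = {"z_A": profile.z_grid, "W_kcal_mol": profile.W}
    if profile.stderr is not None:
        cols["stderr_kcal_mol"] = profile.stderr
    df = pd.DataFrame(cols)
    hdr = {"reference_convention": profile.reference_convention}
    hdr.update(params or {})
    with open(path, "w") as fh:
        fh.write(_header_lines(hdr))
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return path


def read_profile_tsv(path) -> FreeEnergyProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    ref = "unknown"
    with open(path) as fh:
        for line in fh:
            if line.startswith("# reference_convention"):
                ref = line.split("=", 1)[1].strip()
            elif not line.startswith("#"):
                break
    return FreeEnergyProfile(
        z_grid=df["z_A"].to_numpy(),
        W=df["W_kcal_mol"].to_numpy(),
        stderr=df["stderr_kcal_mol"].to_numpy() if "stderr_kcal_mol" in df else None,
        reference_convention=ref,
    )


def write_diffusivity_tsv(diff: DiffusivityProfile, path, params: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "z_A": diff.points_z,
        "D_A2_ps": diff.points_D,
        "D_cm2_s": diff.points_D * A2_PER_PS_TO_CM2_PER_S,
    })
    with open(path, "w") as fh:
        fh.write(_header_lines(params or {}))
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return path


def read_diffusivity_tsv(path) -> DiffusivityProfile:
    df = pd.read_csv(path, sep="\t", comment="#")
    return DiffusivityProfile(points_z=df["z_A"].to_numpy(), points_D=df["D_A2_ps"].to_numpy())


def write_resistivity_tsv(res: ResistivityProfile, path, params: dict | None = None) -> Path:
    path = Path(path)
    df = pd.DataFrame({
        "z_A": res.z_grid,
        "integrand_ps_A2": res.integrand,
        "cumulative_R_ps_A": res.cumulative_R,
    })
    hdr = {"temperature_K": res.temperature}
    hdr.update(params or {})
    with open(path, "w") as fh:
        fh.write(_header_lines(hdr))
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")
    return path


def write_permeability_report(results: dict[str, PermeabilityResult], path,
                              params: dict | None = None) -> Path:
    """Machine-readable key/value report (JSON) for one or more modes."""
    path = Path(path)
    payload = {"parameters": params or {}}
    for mode, r in results.items():
        payload[mode] = {
            "R_s_cm": r.R,
            "P_cm_s": r.P,
            "log10_P_cm_s": r.log10_P,
            "bounds_A": list(r.bounds),
            "mode": r.mode,
            "temperature_K": r.temperature,
            "stderr_log10_P": r.stderr_log10_P,
        }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
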