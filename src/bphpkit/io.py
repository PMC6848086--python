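"""Plain-text I/O: tab-separated tables with ``#`` metadata headers, YAML configs.

All tabular artifacts (spectra, basis sets, trajectories, observation tables)
are written as TSV with a block of ``# key = value`` metadata lines embedding
the tool version, the seed and a hash of the generating parameters, so any
output file records how to regenerate it.  Numeric columns round-trip at full
double precision.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .kinetics import (
    DarkComponent,
    IlluminationProtocol,
    LightSource,
    PhotochromeParams,
    ProtocolSegment,
    StateTrajectory,
)
from .spectral import ChromophoreBasis, GroundState, SpectrumMeasurement

__all__ = [
    "build_metadata",
    "write_table",
    "read_table",
    "write_spectrum",
    "read_spectrum",
    "write_basis",
    "read_basis",
    "write_trajectory",
    "read_trajectory",
    "save_protocol",
    "load_protocol",
    "save_params",
    "load_params",
]

_FLOAT_FORMAT = "%.17g"


def build_metadata(seed: int | None = None, **params) -> dict[str, str]:
    """Standard metadata block: tool, version, seed, parameter hash."""
    payload = json.dumps(params, sort_keys=True, default=str)
    meta = {
        "tool": "bphpkit",
        "version": __version__,
        "seed": "none" if seed is None else str(seed),
        "param_hash": hashlib.sha256(payload.encode()).hexdigest()[:12],
    }
    for k, v in params.items():
        meta[str(k)] = str(v)
    return meta


def write_table(path, df: pd.DataFrame, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for k, v in (metadata or {}).items():
            fh.write(f"# {k} = {v}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def read_table(
    path,
    required_columns: list[str] | None = None,
    numeric_columns: list[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV with ``#`` metadata lines; validate schema.

    Missing required columns and non-numeric cells raise ``ValueError``
    naming the offending column (and row).  Decimal parsing is
    locale-independent (C locale semantics of ``float``), including
    exponent notation.
    """
    path = Path(path)
    metadata: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.lstrip().startswith("#"):
                stripped = line.lstrip()[1:].strip()
                if "=" in stripped:
                    k, v = stripped.split("=", 1)
                    metadata[k.strip()] = v.strip()
                continue
            body_lines.append(line)
    if not body_lines:
        raise ValueError(f"{path}: no table body found")
    df = pd.read_csv(_io.StringIO("".join(body_lines)), sep="\t", dtype=str)
    df.columns = [c.strip() for c in df.columns]
    for col in required_columns or []:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    numeric = numeric_columns if numeric_columns is not None else list(df.columns)
    for col in numeric:
        if col not in df.columns:
            continue
        try:
            df[col] = df[col].astype(float)
        except (TypeError, ValueError):
            for row_idx, cell in df[col].items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} in column {col!r}, "
                        f"row {row_idx}"
                    ) from None
            raise
    return df, metadata


# --- spectra & bases -------------------------------------------------------


def write_spectrum(path, spectrum: SpectrumMeasurement, seed: int | None = None, **params) -> None:
    df = pd.DataFrame(
        {"wavelength_nm": spectrum.wavelengths, "absorbance": spectrum.absorbance}
    )
    meta = build_metadata(seed=seed, noise_sigma=spectrum.noise_sigma, **params)
    write_table(path, df, meta)


def read_spectrum(path) -> SpectrumMeasurement:
    df, meta = read_table(path, required_columns=["wavelength_nm", "absorbance"])
    sigma = float(meta.get("noise_sigma", 0.0))
    return SpectrumMeasurement(
        df["wavelength_nm"].to_numpy(), df["absorbance"].to_numpy(), noise_sigma=sigma
    )


def write_basis(path, basis: ChromophoreBasis, seed: int | None = None) -> None:
    df = pd.DataFrame(
        {
            "wavelength_nm": basis.wavelengths,
            "eps_pr": basis.eps_pr,
            "eps_pfr": basis.eps_pfr,
        }
    )
    meta = build_metadata(
        seed=seed, protein_id=basis.protein_id, ground_state=basis.ground_state.value
    )
    write_table(path, df, meta)


def read_basis(path) -> ChromophoreBasis:
    df, meta = read_table(
        path, required_columns=["wavelength_nm", "eps_pr", "eps_pfr"]
    )
    return ChromophoreBasis(
        protein_id=meta.get("protein_id", Path(path).stem),
        wavelengths=df["wavelength_nm"].to_numpy(),
        eps_pr=df["eps_pr"].to_numpy(),
        eps_pfr=df["eps_pfr"].to_numpy(),
        ground_state=GroundState(meta.get("ground_state", "pr_ground")),
    )


# --- trajectories -----------------------------------------------------------


def _trace_column(wavelength: float) -> str:
    return f"A_{wavelength:g}nm"


def write_trajectory(path, traj: StateTrajectory, seed: int | None = None, **params) -> None:
    data = {"time_s": traj.times, "f_pfr": traj.f_pfr}
    for i, w in enumerate(traj.wavelengths):
        data[_trace_column(w)] = traj.absorbance[i]
    meta = build_metadata(
        seed=seed,
        noise_sigma=traj.noise_sigma,
        observation_nm=",".join(f"{w:g}" for w in traj.wavelengths),
        **params,
    )
    write_table(path, pd.DataFrame(data), meta)


def read_trajectory(path) -> StateTrajectory:
    df, meta = read_table(path, required_columns=["time_s", "f_pfr"])
    wavelengths = []
    traces = []
    for col in df.columns:
        if col.startswith("A_") and col.endswith("nm"):
            wavelengths.append(float(col[2:-2]))
            traces.append(df[col].to_numpy())
    return StateTrajectory(
        times=df["time_s"].to_numpy(),
        f_pfr=df["f_pfr"].to_numpy(),
        wavelengths=tuple(wavelengths),
        absorbance=np.vstack(traces) if traces else None,
        noise_sigma=float(meta.get("noise_sigma", 0.0)),
    )


# --- structured configs -----------------------------------------------------


def save_protocol(path, protocol: IlluminationProtocol) -> None:
    doc = {
        "segments": [
            {
                "sources": [
                    {"wavelength_nm": s.wavelength, "irradiance": s.irradiance}
                    for s in seg.sources
                ],
                "duration_s": seg.duration,
            }
            for seg in protocol.segments
        ],
        "observe_nm": list(protocol.observation_wavelengths),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_protocol(path) -> IlluminationProtocol:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    segments = tuple(
        ProtocolSegment(
            sources=tuple(
                LightSource(float(s["wavelength_nm"]), float(s["irradiance"]))
                for s in seg.get("sources", [])
            ),
            duration=float(seg["duration_s"]),
        )
        for seg in doc["segments"]
    )
    return IlluminationProtocol(
        segments=segments,
        observation_wavelengths=tuple(float(w) for w in doc.get("observe_nm", [])),
    )


def save_params(path, params: PhotochromeParams) -> None:
    doc = {
        "phi_fwd": params.phi_fwd,
        "phi_rev": params.phi_rev,
        "ground_state": params.ground_state.value,
        "dark_components": [
            {"amplitude_fraction": c.amplitude_fraction, "rate_s": c.rate}
            for c in params.dark_components
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False), encoding="utf-8")


def load_params(path) -> PhotochromeParams:
    doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return PhotochromeParams(
        phi_fwd=float(doc["phi_fwd"]),
        phi_rev=float(doc["phi_rev"]),
        ground_state=GroundState(doc["ground_state"]),
        dark_components=tuple(
            DarkComponent(float(c["amplitude_fraction"]), float(c["rate_s"]))
            for c in doc.get("dark_components", [])
        ),
    )
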