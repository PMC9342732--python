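"""Readers and writers for the package's TSV/CSV/JSON formats.

Data matrices travel as tab-separated text with a header row; analysis
results are JSON documents that echo the effective configuration (seed,
tolerances, model choices) so any result can be re-run from its own output.
"""

from __future__ import annotations

import json
from dataclasses import is_dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .nse import NSECurve, NSEDataset
from .undulation import HeightField
from .xds import DiffuseMap

__all__ = [
    "SchemaError",
    "MAP_COLUMNS",
    "NSE_COLUMNS",
    "read_table",
    "read_diffuse_map",
    "write_diffuse_map",
    "read_nse_table",
    "write_nse_table",
    "read_height_fields",
    "write_height_fields",
    "read_lipid_table",
    "write_result",
    "validate_result",
    "RESULT_SCHEMA",
]

MAP_COLUMNS = ("qz", "q_par", "intensity", "sigma")
NSE_COLUMNS = ("q", "t_ns", "I_rel", "sigma")

#: Minimal schema every result JSON must satisfy: required top-level keys
#: and the type of each.
RESULT_SCHEMA = {"result": dict, "config": dict, "provenance": dict}


class SchemaError(ValueError):
    """A table or result document does not match its declared schema."""


def read_table(path, columns, sep: str = "\t") -> pd.DataFrame:
    """Read a delimited table and validate it against expected columns.

    Every listed column must be present and numeric; the first offending
    row/column is named in the error. Row numbers refer to data rows
    (header excluded, 1-based).
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    if df.empty:
        raise SchemaError(f"{path}: table has no data rows")
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 1
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at data row {row}"
            )
        if coerced.isna().any():
            row = int(coerced.isna().idxmax()) + 1
            raise SchemaError(f"{path}: empty cell in column {col!r} at data row {row}")
        df[col] = coerced
    return df


# -- diffuse maps -----------------------------------------------------------


def read_diffuse_map(path) -> DiffuseMap:
    """Read a diffuse map from TSV (columns qz, q_par, intensity, sigma)."""
    df = read_table(path, MAP_COLUMNS)
    qz = np.unique(df["qz"].to_numpy())
    qpar = np.unique(df["q_par"].to_numpy())
    inten = np.full((qz.size, qpar.size), np.nan)
    sig = np.full_like(inten, np.nan)
    iz = np.searchsorted(qz, df["qz"].to_numpy())
    ip = np.searchsorted(qpar, df["q_par"].to_numpy())
    inten[iz, ip] = df["intensity"].to_numpy()
    sig[iz, ip] = df["sigma"].to_numpy()
    if np.isnan(inten).any():
        raise SchemaError(f"{path}: map rows do not cover the full (qz, q_par) grid")
    return DiffuseMap(qz=qz, qpar=qpar, intensity=inten, sigma=sig)


def write_diffuse_map(path, dmap: DiffuseMap) -> None:
    """Write a diffuse map row-major over the (qz, q_par) grid."""
    qz, qp = np.meshgrid(dmap.qz, dmap.qpar, indexing="ij")
    df = pd.DataFrame(
        {
            "qz": qz.ravel(),
            "q_par": qp.ravel(),
            "intensity": dmap.intensity.ravel(),
            "sigma": dmap.sigma.ravel(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


# -- NSE tables -------------------------------------------------------------


def read_nse_table(path, T: float | None = None, viscosity: float | None = None) -> NSEDataset:
    """Read per-q spin-echo decays from TSV (columns q, t_ns, I_rel, sigma)."""
    df = read_table(path, NSE_COLUMNS)
    curves = []
    for q, grp in df.groupby("q", sort=True):
        curves.append(
            NSECurve(
                q=float(q),
                t=grp["t_ns"].to_numpy(),
                i_rel=grp["I_rel"].to_numpy(),
                sigma=grp["sigma"].to_numpy(),
            )
        )
    kwargs = {}
    if T is not None:
        kwargs["T"] = T
    return NSEDataset(curves=curves, viscosity=viscosity, **kwargs)


def write_nse_table(path, dataset: NSEDataset) -> None:
    rows = []
    for c in dataset.curves:
        for t, y, s in zip(c.t, c.i_rel, c.sigma):
            rows.append((c.q, t, y, s))
    pd.DataFrame(rows, columns=list(NSE_COLUMNS)).to_csv(path, sep="\t", index=False)


# -- height fields ----------------------------------------------------------


def write_height_fields(path, frames: list[HeightField]) -> None:
    """Stacked-frame text format: one header line, then frames of N rows each."""
    if not frames:
        raise ValueError("no frames to write")
    L, N, T = frames[0].L, frames[0].N, frames[0].T
    with open(path, "w") as fh:
        fh.write(f"# L={L} N={N} T={T} frames={len(frames)}\n")
        for f in frames:
            np.savetxt(fh, f.heights, delimiter="\t")


def read_height_fields(path) -> list[HeightField]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise SchemaError(f"{path}: missing '# L=... N=... T=...' header line")
        fields = dict(
            item.split("=") for item in header.lstrip("#").split() if "=" in item
        )
        try:
            L = float(fields["L"])
            N = int(fields["N"])
            T = float(fields["T"])
            n_frames = int(fields.get("frames", 1))
        except (KeyError, ValueError) as exc:
            raise SchemaError(f"{path}: malformed header {header!r}") from exc
        data = np.loadtxt(fh, delimiter="\t")
    if data.shape != (n_frames * N, N):
        raise SchemaError(
            f"{path}: expected {n_frames}×{N} rows of {N} columns, got {data.shape}"
        )
    return [
        HeightField(L=L, heights=data[i * N : (i + 1) * N], T=T)
        for i in range(n_frames)
    ]


# -- lipid tables ------------------------------------------------------------


def read_lipid_table(path):
    """Read a lipid list CSV with columns name, tails[, mole_fraction].

    ``tails`` uses the ``18:2-14:1`` descriptor syntax. Returns a list of
    ``(LipidSpec, mole_fraction)`` pairs (fraction ``None`` when absent).
    """
    from .lipids import LipidSpec

    df = pd.read_csv(path)
    for col in ("name", "tails"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
    out = []
    for i, row in df.iterrows():
        try:
            spec = LipidSpec.from_string(str(row["tails"]), name=str(row["name"]))
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: bad tail descriptor at data row {i + 1}: {exc}")
        frac = float(row["mole_fraction"]) if "mole_fraction" in df.columns else None
        out.append((spec, frac))
    return out


# -- results -----------------------------------------------------------------


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if obj != obj else ("inf" if obj > 0 else "-inf")
    return obj


def validate_result(doc: dict) -> None:
    """Check a result document against :data:`RESULT_SCHEMA`."""
    for key, typ in RESULT_SCHEMA.items():
        if key not in doc:
            raise SchemaError(f"result document missing {key!r}")
        if not isinstance(doc[key], typ):
            raise SchemaError(f"result key {key!r} must be a {typ.__name__}")


def write_result(path, result: dict, config: dict, provenance: dict) -> dict:
    """Serialize an analysis result with its configuration echo."""
    from . import __version__

    doc = {
        "result": _jsonable(result),
        "config": _jsonable(config),
        "provenance": {"package": "memkappa", "version": __version__,
                       **_jsonable(provenance)},
    }
    validate_result(doc)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
    return doc
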