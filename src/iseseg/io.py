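"""Readers and writers for the plain-text formats the pipeline speaks.

Events come in as single-column numeric CSV (one fluorescence area per
row, header optional) — the format flow-cytometry software exports.
Tabular artefacts (sample sheets, class tables, frequency tables, RMSE
surfaces) are TSV; structured results (fits, G-tests) are JSON; clone
karyotypes are YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .fitting import FitResult
from .segmodel import ClassDistribution, IseKaryotype

__all__ = [
    "read_events_csv",
    "write_events_csv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_karyotypes",
    "write_karyotypes",
    "read_frequencies_tsv",
    "write_frequencies_tsv",
    "write_class_table",
    "write_fit_result",
]

PathLike = Union[str, Path]

SAMPLE_SHEET_COLUMNS = ["file", "clone_id", "stage", "n_males"]


def read_events_csv(path: PathLike) -> np.ndarray:
    """Load a single-column CSV of fluorescence areas (header optional)."""
    first = pd.read_csv(path, header=None, nrows=1)
    has_header = not np.issubdtype(
        pd.to_numeric(first.iloc[0], errors="coerce").dtype, np.number
    ) or pd.to_numeric(first.iloc[0], errors="coerce").isna().any()
    df = pd.read_csv(path, header=0 if has_header else None)
    if df.shape[1] != 1:
        raise ValueError(f"{path}: expected a single column, got {df.shape[1]}")
    events = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(dtype=float)
    return events


def write_events_csv(path: PathLike, events: np.ndarray,
                     column: str = "YL2-A") -> None:
    pd.DataFrame({column: np.asarray(events, dtype=float)}).to_csv(
        path, index=False
    )


def read_sample_sheet(path: PathLike) -> pd.DataFrame:
    """TSV describing one sample per row: file, clone_id, stage, n_males."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns: {missing}")
    return df


def write_sample_sheet(path: PathLike, df: pd.DataFrame) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_karyotypes(path: PathLike) -> dict:
    """YAML mapping clone id -> karyotype fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of clone ids")
    out = {}
    for clone_id, spec in raw.items():
        sizes = spec.get("ise_sizes_mb")
        out[clone_id] = IseKaryotype(
            n_ise=int(spec["n_ise"]),
            female_2c_mb=float(spec["female_2c_mb"]),
            core_1c_mb=(
                float(spec["core_1c_mb"]) if "core_1c_mb" in spec else None
            ),
            ise_sizes_mb=tuple(sizes) if sizes is not None else None,
            clone_id=str(clone_id),
        )
    return out


def write_karyotypes(path: PathLike, karyotypes: dict) -> None:
    raw = {}
    for clone_id, kar in karyotypes.items():
        entry = {"n_ise": kar.n_ise, "female_2c_mb": kar.female_2c_mb}
        if kar.core_1c_mb is not None:
            entry["core_1c_mb"] = kar.core_1c_mb
        if kar.ise_sizes_mb is not None:
            entry["ise_sizes_mb"] = list(kar.ise_sizes_mb)
        raw[str(clone_id)] = entry
    with open(path, "w") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_frequencies_tsv(path: PathLike) -> list:
    """Observed class frequencies: TSV (clone_id, class_k, frequency).

    Returns ``[(clone_id, ClassDistribution), ...]`` in file order.
    """
    df = pd.read_csv(path, sep="\t")
    need = {"clone_id", "class_k", "frequency"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path} must have columns {sorted(need)}")
    out = []
    for clone_id, grp in df.groupby("clone_id", sort=False):
        grp = grp.sort_values("class_k")
        ks = grp["class_k"].to_numpy()
        if not np.array_equal(ks, np.arange(len(ks))):
            raise ValueError(
                f"clone {clone_id}: class_k must run 0..n without gaps"
            )
        freqs = grp["frequency"].to_numpy(dtype=float)
        out.append(
            (str(clone_id), ClassDistribution(n_ise=len(ks) - 1, freqs=freqs))
        )
    return out


def write_frequencies_tsv(path: PathLike, observations: list) -> None:
    rows = []
    for clone_id, dist in observations:
        for k, f in enumerate(dist.freqs):
            rows.append({"clone_id": clone_id, "class_k": k, "frequency": f})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_class_table(path: PathLike, estimates: list) -> None:
    """Per-sample class table: TSV (class_k, proportion, mean_fluorescence)."""
    rows = [
        {
            "class_k": e.class_k,
            "proportion": e.proportion,
            "mean_fluorescence": e.mean_fluorescence,
        }
        for e in estimates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_fit_result(json_path: PathLike, fit: FitResult,
                     surface_path: PathLike | None = None) -> None:
    """JSON summary of a grid fit; optionally the full RMSE surface as TSV."""
    payload = {
        "best_tb": fit.best_tb,
        "best_cb": None if np.isnan(fit.best_cb) else fit.best_cb,
        "best_rmse": fit.best_rmse,
        "grid_step": fit.grid_step,
        "n_ise": fit.n_ise,
        "n_grid_points": int(len(fit.surface)),
    }
    with open(json_path, "w") as fh:
        json.dump(payload, fh, indent=2)
    if surface_path is not None:
        fit.surface.to_csv(surface_path, sep="\t", index=False)
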