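"""TIFF / CSV / JSON readers and writers with provenance headers.

Fields are stored one single-page 16-bit TIFF per channel, named
``{well}_f{field:02d}_{channel}.tif``. Tabular outputs are CSV with '.'
decimal separators and a ``#``-prefixed header carrying the package version
and the configuration hash, so any result file can be traced to the exact
parameter set that produced it. All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import dataclasses
import io
import json
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

from .infection import InfectionWellSummary
from .simulate import FieldImage, FieldGroundTruth
from .translocation import CellMeasurement, WellSummary

CELL_COLUMNS = [
    "well", "field", "cell_id", "nucleus_mean", "cytoplasm_mean", "nc_ratio", "activation_class",
]
WELL_SUMMARY_COLUMNS = [
    "well", "condition", "n_cells", "n_activated", "n_intermediate",
    "percent_activated", "n_fields_used", "intermediate_policy",
]
INFECTION_COLUMNS = ["well", "condition", "n_nuclei", "n_gfp_positive", "percent_infected"]


def _atomic_write_bytes(path: Path, data: bytes) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def field_tiff_name(well_id: str, field_index: int, channel: str) -> str:
    return f"{well_id}_f{field_index:02d}_{channel}.tif"


def write_field_tiffs(field: FieldImage, outdir: str | Path) -> list[Path]:
    """Write each channel of a field as an unsigned 16-bit single-page TIFF."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ch, arr in field.channels.items():
        data = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        path = outdir / field_tiff_name(field.well_id, field.field_index, ch)
        buf = io.BytesIO()
        tifffile.imwrite(buf, data)
        _atomic_write_bytes(path, buf.getvalue())
        paths.append(path)
    return paths


def read_field(
    imgdir: str | Path, well_id: str, field_index: int, channels: Iterable[str]
) -> FieldImage:
    """Load one field's channels from per-channel TIFFs."""
    imgdir = Path(imgdir)
    loaded: dict[str, np.ndarray] = {}
    for ch in channels:
        path = imgdir / field_tiff_name(well_id, field_index, ch)
        if not path.exists():
            raise FileNotFoundError(
                f"expected channel image {path}; run `hcsquant simulate` (or point "
                f"--outdir at a directory containing it) first"
            )
        loaded[ch] = tifffile.imread(path).astype(float)
    field = FieldImage(well_id=well_id, field_index=field_index, channels=loaded)
    field.validate()
    return field


def write_ground_truth_json(
    truths: Iterable[FieldGroundTruth], path: str | Path, metadata: Mapping | None = None
) -> None:
    doc = {
        "metadata": dict(metadata or {}),
        "fields": [
            {
                "well": t.well_id,
                "field": t.field_index,
                "cells": [dataclasses.asdict(c) for c in t.cells],
            }
            for t in truths
        ],
    }
    _atomic_write_bytes(Path(path), json.dumps(doc, indent=1).encode())


def write_csv(df: pd.DataFrame, path: str | Path, metadata: Mapping | None = None) -> None:
    """CSV with '#'-prefixed provenance header lines, written atomically."""
    header = "".join(f"# {k}={v}\n" for k, v in (metadata or {}).items())
    body = df.to_csv(index=False, float_format="%.10g")
    _atomic_write_bytes(Path(path), (header + body).encode())


def read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"expected upstream artifact {path}; run the producing subcommand first"
        )
    return pd.read_csv(path, comment="#")


def write_json_report(doc: Mapping, path: str | Path) -> None:
    _atomic_write_bytes(Path(path), json.dumps(doc, indent=1, sort_keys=True).encode())


def measurements_to_frame(cells: Iterable[CellMeasurement]) -> pd.DataFrame:
    rows = [
        {
            "well": c.well_id,
            "field": c.field_index,
            "cell_id": c.cell_id,
            "nucleus_mean": c.nucleus_mean,
            "cytoplasm_mean": c.cytoplasm_mean,
            "nc_ratio": c.nc_ratio,
            "activation_class": c.activation_class,
        }
        for c in cells
    ]
    return pd.DataFrame(rows, columns=CELL_COLUMNS)


def summaries_to_frame(summaries: Iterable[WellSummary]) -> pd.DataFrame:
    rows = [
        {
            "well": s.well_id,
            "condition": s.condition,
            "n_cells": s.n_cells,
            "n_activated": s.n_activated,
            "n_intermediate": s.n_intermediate,
            "percent_activated": s.percent_activated,
            "n_fields_used": s.n_fields_used,
            "intermediate_policy": s.intermediate_policy,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=WELL_SUMMARY_COLUMNS)


def infection_summaries_to_frame(summaries: Iterable[InfectionWellSummary]) -> pd.DataFrame:
    rows = [
        {
            "well": s.well_id,
            "condition": s.condition,
            "n_nuclei": s.n_nuclei,
            "n_gfp_positive": s.n_gfp_positive,
            "percent_infected": s.percent_infected,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=INFECTION_COLUMNS)
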