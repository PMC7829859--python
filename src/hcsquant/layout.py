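"""Plate maps and run configuration.

A plate map assigns each well (letter row + zero-padded column, e.g. "B03")
a donor, a stimulus, a dose or multiplicity of infection, and a replicate
index. Stimuli follow the usual innate-immune panel: bacterial endotoxin
(LPS, TLR4 agonist), poly I:C (dsRNA analog, TLR3 agonist), TNF-α, HSV-1
infection, or none for unstimulated controls.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path
from typing import Any, Iterable

import pandas as pd
import yaml

STIMULI = ("LPS", "polyIC", "TNFa", "HSV1", "none")
_WELL_RE = re.compile(r"^([A-P])(\d{2})$")

LAYOUT_COLUMNS = ["well", "donor_id", "stimulus", "dose", "moi", "replicate"]


def parse_well_id(well_id: str) -> tuple[int, int]:
    """"B03" -> (1, 2): 0-based (row, column)."""
    m = _WELL_RE.match(well_id)
    if not m:
        raise ValueError(f"malformed well id {well_id!r} (expected e.g. 'B03')")
    row = ord(m.group(1)) - ord("A")
    col = int(m.group(2)) - 1
    if col < 0:
        raise ValueError(f"well column must be >= 01 in {well_id!r}")
    return row, col


def format_well_id(row: int, col: int) -> str:
    return f"{chr(ord('A') + row)}{col + 1:02d}"


@dataclass(frozen=True)
class WellAnnotation:
    donor_id: str
    stimulus: str = "none"
    dose: float | None = None
    moi: float | None = None
    replicate: int = 1

    def validate(self) -> None:
        if self.stimulus not in STIMULI:
            raise ValueError(f"unknown stimulus {self.stimulus!r}; expected one of {STIMULI}")
        if self.stimulus in ("LPS", "polyIC", "TNFa") and self.dose is None:
            raise ValueError(f"stimulus {self.stimulus} requires a dose")
        if self.stimulus == "HSV1" and self.moi is None:
            raise ValueError("stimulus HSV1 requires an MOI")
        if self.stimulus == "none" and (self.dose not in (None, 0.0) or self.moi not in (None, 0.0)):
            raise ValueError("unstimulated wells must not carry a dose or MOI")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @property
    def condition(self) -> str:
        """Condition label grouping replicate wells: stimulus plus dose/MOI."""
        if self.stimulus == "HSV1":
            return f"HSV1:moi={self.moi:g}"
        if self.stimulus == "none":
            return "none"
        return f"{self.stimulus}:dose={self.dose:g}"


@dataclass
class PlateLayout:
    """A 96-well (8x12 by default) plate map with unique well coordinates."""

    plate_id: str
    wells: dict[str, WellAnnotation] = dc_field(default_factory=dict)
    n_rows: int = 8
    n_cols: int = 12

    def add_well(self, well_id: str, annotation: WellAnnotation) -> None:
        row, col = parse_well_id(well_id)
        if row >= self.n_rows or col >= self.n_cols:
            raise ValueError(f"well {well_id} outside {self.n_rows}x{self.n_cols} plate")
        if well_id in self.wells:
            raise ValueError(f"well {well_id} listed twice in layout")
        annotation.validate()
        self.wells[well_id] = annotation

    def well_ids(self) -> list[str]:
        return sorted(self.wells)

    def replicate_groups(self) -> dict[tuple[str, str], list[str]]:
        """(donor_id, condition) -> replicate well ids."""
        groups: dict[tuple[str, str], list[str]] = {}
        for well_id in self.well_ids():
            ann = self.wells[well_id]
            groups.setdefault((ann.donor_id, ann.condition), []).append(well_id)
        return groups

    @classmethod
    def from_records(cls, plate_id: str, records: Iterable[dict[str, Any]]) -> "PlateLayout":
        layout = cls(plate_id=plate_id)
        for rec in records:
            def _num(key: str) -> float | None:
                v = rec.get(key)
                if v is None or (isinstance(v, float) and pd.isna(v)) or v == "":
                    return None
                return float(v)

            ann = WellAnnotation(
                donor_id=str(rec["donor_id"]),
                stimulus=str(rec.get("stimulus", "none")),
                dose=_num("dose"),
                moi=_num("moi"),
                replicate=int(rec.get("replicate", 1)),
            )
            layout.add_well(str(rec["well"]), ann)
        return layout

    @classmethod
    def from_csv(cls, path: str | Path, plate_id: str | None = None) -> "PlateLayout":
        df = pd.read_csv(path, comment="#")
        return cls.from_records(plate_id or Path(path).stem, df.to_dict("records"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PlateLayout":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_records(doc.get("plate_id", Path(path).stem), doc["wells"])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for well_id in self.well_ids():
            ann = self.wells[well_id]
            rows.append(
                {
                    "well": well_id,
                    "donor_id": ann.donor_id,
                    "stimulus": ann.stimulus,
                    "dose": ann.dose,
                    "moi": ann.moi,
                    "replicate": ann.replicate,
                }
            )
        return pd.DataFrame(rows, columns=LAYOUT_COLUMNS)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass
class RunConfig:
    """Validated bundle of all pipeline parameter sections plus seed/paths."""

    layout: PlateLayout
    sim: "Any"  # SimParams; typed loosely to avoid an import cycle
    segmentation: "Any"  # SegmentationParams
    scoring: "Any"  # ScoringParams
    infection: "Any"  # InfectionParams
    seed: int = 0
    fields_per_well: int = 47
    log_level: str = "INFO"

    def validate(self) -> None:
        self.sim.validate()
        self.segmentation.validate()
        self.scoring.validate()
        self.infection.validate()
        if self.fields_per_well < 1:
            raise ValueError("fields_per_well must be >= 1")
        for ann in self.layout.wells.values():
            ann.validate()

    def config_hash(self) -> str:
        """Stable sha256 over the canonical JSON form, for output provenance."""
        doc = {
            "sim": asdict(self.sim),
            "segmentation": asdict(self.segmentation),
            "scoring": asdict(self.scoring),
            "infection": asdict(self.infection),
            "seed": self.seed,
            "fields_per_well": self.fields_per_well,
            "layout": self.layout.to_frame().to_dict("records"),
        }
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .infection import InfectionParams
        from .segment import SegmentationParams
        from .simulate import SimParams
        from .translocation import ScoringParams

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}

        def section(name: str, factory):
            raw = dict(doc.get(name) or {})
            for key in list(raw):
                if isinstance(raw[key], list):
                    raw[key] = tuple(raw[key])
            try:
                return factory(**raw)
            except TypeError as exc:
                raise ValueError(f"invalid {name!r} section: {exc}") from exc

        layout_doc = doc.get("layout")
        if isinstance(layout_doc, str):
            p = Path(layout_doc)
            if not p.is_absolute():
                p = Path(path).parent / p
            layout = PlateLayout.from_csv(p)
        elif isinstance(layout_doc, dict):
            layout = PlateLayout.from_records(layout_doc.get("plate_id", "plate1"), layout_doc["wells"])
        else:
            raise ValueError("config must provide a 'layout' (CSV path or inline mapping)")

        cfg = cls(
            layout=layout,
            sim=section("sim", SimParams),
            segmentation=section("segmentation", SegmentationParams),
            scoring=section("scoring", ScoringParams),
            infection=section("infection", InfectionParams),
            seed=int(doc.get("seed", 0)),
            fields_per_well=int(doc.get("fields_per_well", 47)),
            log_level=str(doc.get("log_level", "INFO")),
        )
        cfg.validate()
        return cfg
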