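"""Readers and writers for every format the pipeline touches.

All tabular formats are UTF-8 CSV with header rows; trees are newick
with branch lengths in Ma; latitudes are decimal degrees, south
negative. The sampling-fraction file follows the two-part convention:
a first line holding the backbone completeness fraction, then one
``tip<TAB>clade<TAB>fraction`` line per genus.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .assemblage import BELTS, DEFAULT_SOURCE_THRESHOLDS, GeoUnit, OccurrenceRecord
from .events import EventConfiguration, event_table_frame, parse_event_table
from .supermatrix import MonophylyReport, SelectionResult, SequenceRecord
from .trees import DatedTree, parse_newick

__all__ = [
    "PipelineConfig",
    "read_tree", "write_tree", "read_events", "write_events",
    "read_sequence_records", "write_selection", "write_monophyly",
    "read_units", "write_units", "read_occurrences", "write_occurrences",
    "read_profiles", "write_profiles", "write_sampling_fractions",
    "read_sampling_fractions",
]


@dataclasses.dataclass
class PipelineConfig:
    """Global knobs of the analysis pipeline with their conventional defaults."""
    markers: list = dataclasses.field(default_factory=list)
    source_thresholds: dict = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_SOURCE_THRESHOLDS))
    belts: list = dataclasses.field(default_factory=lambda: list(BELTS))
    quartile_metric: str = "netdiv"
    lowess_span: float = 0.5
    null_reps: int = 999
    seg_frac: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if any(t < 1 for t in self.source_thresholds.values()):
            raise ValueError("source thresholds must be >= 1")
        if not 0 < self.lowess_span <= 1:
            raise ValueError("lowess span must lie in (0, 1]")
        if self.null_reps < 1:
            raise ValueError("null_reps must be >= 1")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


# -- trees and events ------------------------------------------------------

def read_tree(path, taxonomy: dict | None = None) -> DatedTree:
    return parse_newick(Path(path).read_text(), taxonomy=taxonomy)


def write_tree(tree: DatedTree, path) -> None:
    Path(path).write_text(tree.to_newick())


def read_events(path, tree: DatedTree, generation: int | None = None) -> EventConfiguration:
    return parse_event_table(pd.read_csv(path), tree, generation=generation)


def write_events(events: EventConfiguration, path, generation: int = 0) -> None:
    event_table_frame(events, generation=generation).to_csv(path, index=False)


# -- sequence records ------------------------------------------------------

def read_sequence_records(path) -> list[SequenceRecord]:
    df = pd.read_csv(path, dtype={"date": str}, keep_default_na=False)
    return [SequenceRecord(species=str(r.species), genus=str(r.genus),
                           marker=str(r.marker), length=int(r.length),
                           published=_as_bool(r.published), date=str(r.date),
                           accession=str(r.accession))
            for r in df.itertuples(index=False)]


def _as_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in ("1", "true", "yes", "y")
    return bool(v)


def write_selection(selections: list[SelectionResult], path) -> None:
    rows = [(s.genus, marker, rec.accession, rec.species, s.composite)
            for s in selections for marker, rec in sorted(s.per_marker.items())]
    pd.DataFrame(rows, columns=["genus", "marker", "accession", "species",
                                "composite"]).to_csv(path, index=False)


def write_monophyly(reports: list[MonophylyReport], path) -> None:
    rows = [(r.genus, r.status, len(r.clades),
             ";".join(sorted(r.core))) for r in reports]
    pd.DataFrame(rows, columns=["genus", "status", "n_clades",
                                "core_tips"]).to_csv(path, index=False)


# -- units, occurrences, profiles ------------------------------------------

def write_units(units: dict[str, GeoUnit], path) -> None:
    rows = []
    for u in units.values():
        row = {"id": u.id, "lat": u.centroid_lat, "lon": u.centroid_lon,
               "area_km2": u.area, "region_group": u.region_group}
        for belt in BELTS:
            row[f"belt_{belt}"] = u.belt_fractions.get(belt, 0.0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_units(path) -> dict[str, GeoUnit]:
    df = pd.read_csv(path)
    units = {}
    for d in df.to_dict("records"):
        fractions = {}
        for belt in BELTS:
            col = f"belt_{belt}"
            if col in d and d[col] > 0:
                fractions[belt] = float(d[col])
        units[str(d["id"])] = GeoUnit(
            id=str(d["id"]), centroid_lat=float(d["lat"]),
            centroid_lon=float(d["lon"]), area=float(d["area_km2"]),
            region_group=str(d["region_group"]), belt_fractions=fractions)
    return units


def write_occurrences(records: list[OccurrenceRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def read_occurrences(path) -> list[OccurrenceRecord]:
    df = pd.read_csv(path)
    return [OccurrenceRecord(genus=str(r.genus), unit=str(r.unit),
                             source_count=int(r.source_count),
                             introduced=_as_bool(r.introduced),
                             granularity=str(r.granularity),
                             overlap=float(r.overlap))
            for r in df.itertuples(index=False)]


def write_profiles(profiles: pd.DataFrame, path) -> None:
    profiles.to_csv(path, index=False)


def read_profiles(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.set_index("genus", drop=False)


# -- sampling fractions ----------------------------------------------------

def write_sampling_fractions(backbone: float, table: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{backbone}\n")
        for r in table.itertuples(index=False):
            fh.write(f"{r.tip}\t{r.clade}\t{r.fraction}\n")


def read_sampling_fractions(path) -> tuple[float, pd.DataFrame]:
    lines = Path(path).read_text().splitlines()
    backbone = float(lines[0])
    rows = [ln.split("\t") for ln in lines[1:] if ln.strip()]
    df = pd.DataFrame(rows, columns=["tip", "clade", "fraction"])
    df["fraction"] = df["fraction"].astype(float)
    return backbone, df
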