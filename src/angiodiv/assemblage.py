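"""Genus x geographic-unit incidence and assemblage metrics.

Occurrence records (from heterogeneous sources: coordinates, recorded
localities, grid cells, range maps) are resolved against geographic
standard units, quality-controlled by regional source-count thresholds,
and summarized per unit: genus richness, mean genus (stem) age, mean
speciation rate, mean net diversification rate, quartile proportions,
and latitudinal-belt membership.

QC rules:

* a locality record is accepted iff >= 80% of its footprint falls in the
  unit; a grid-cell record iff strictly more than half does; coordinate
  records must fall inside the unit; range-map records are accepted;
* records flagged as introduced are removed;
* a presence must be corroborated by at least 3 data sources in Europe,
  2 in Australia/China/Madagascar/North America, 1 elsewhere.

Units are assigned to one of 13 ten-degree latitudinal belts
(S55..N75) iff strictly more than half the unit's area falls in it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeoUnit", "OccurrenceRecord", "BELTS", "BELT_BOUNDS",
    "DEFAULT_SOURCE_THRESHOLDS", "resolve_overlap", "qc_filter",
    "assemblage_summary", "quartile_partition", "unit_quartile_proportions",
    "assign_belts", "belt_genus_union", "annotate_profiles",
]

#: the 13 ten-degree latitudinal belts, equator band first
BELT_BOUNDS: dict[str, tuple[float, float]] = {
    "S5-N5": (-5, 5),
    "S5-S15": (-15, -5), "S15-S25": (-25, -15), "S25-S35": (-35, -25),
    "S35-S45": (-45, -35), "S45-S55": (-55, -45),
    "N5-N15": (5, 15), "N15-N25": (15, 25), "N25-N35": (25, 35),
    "N35-N45": (35, 45), "N45-N55": (45, 55), "N55-N65": (55, 65),
    "N65-N75": (65, 75),
}
BELTS = list(BELT_BOUNDS)

#: minimum corroborating data sources per region group
DEFAULT_SOURCE_THRESHOLDS = {
    "Europe": 3,
    "Australia": 2, "China": 2, "Madagascar": 2, "NorthAmerica": 2,
    "Other": 1,
}

GRANULARITIES = ("coordinate", "locality", "gridcell", "rangemap")


@dataclass(frozen=True)
class GeoUnit:
    id: str
    centroid_lat: float
    centroid_lon: float
    area: float  # km^2
    region_group: str = "Other"
    belt_fractions: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.area > 0:
            raise ValueError(f"unit {self.id!r}: area must be positive")
        total = sum(self.belt_fractions.values())
        if total > 1 + 1e-9 or any(not 0 <= f <= 1 for f in self.belt_fractions.values()):
            raise ValueError(f"unit {self.id!r}: invalid belt fractions")


@dataclass(frozen=True)
class OccurrenceRecord:
    genus: str
    unit: str
    source_count: int = 1
    introduced: bool = False
    granularity: str = "rangemap"
    overlap: float = 1.0  # fraction of the record footprint inside the unit

    def __post_init__(self):
        if not 0 <= self.overlap <= 1:
            raise ValueError("overlap must lie in [0, 1]")
        if self.source_count < 1:
            raise ValueError("source_count must be >= 1")


def resolve_overlap(record: OccurrenceRecord) -> bool:
    """Spatial acceptance of a single occurrence record.

    Locality records need >= 80% footprint overlap with the unit; grid
    cells strictly more than 50%; coordinates must be inside the unit
    (overlap 1); range maps were digitized against the unit system and
    are always accepted.
    """
    g = record.granularity
    if g == "locality":
        return record.overlap >= 0.80
    if g == "gridcell":
        return record.overlap > 0.50
    if g == "coordinate":
        return record.overlap == 1.0
    if g == "rangemap":
        return True
    raise ValueError(f"unknown granularity {record.granularity!r}")


def qc_filter(records: list[OccurrenceRecord], units: dict[str, GeoUnit],
              thresholds: dict[str, int] | None = None) -> pd.DataFrame:
    """Quality-controlled genus x unit incidence.

    Records are first screened spatially (:func:`resolve_overlap`) and
    introduced-range records dropped; the surviving records for each
    (genus, unit) are summarized by their best corroboration (max
    source_count) and the presence kept iff that count meets the unit's
    regional threshold. Returns a frame with columns genus, unit.
    """
    thresholds = dict(DEFAULT_SOURCE_THRESHOLDS if thresholds is None else thresholds)
    best: dict[tuple[str, str], int] = {}
    for rec in records:
        if rec.unit not in units:
            raise ValueError(f"occurrence references unknown unit {rec.unit!r}")
        if rec.introduced or not resolve_overlap(rec):
            continue
        key = (rec.genus, rec.unit)
        best[key] = max(best.get(key, 0), rec.source_count)
    rows = []
    for (genus, unit), count in sorted(best.items()):
        group = units[unit].region_group
        needed = thresholds.get(group, thresholds.get("Other", 1))
        if count >= needed:
            rows.append((genus, unit))
    return pd.DataFrame(rows, columns=["genus", "unit"])


def assemblage_summary(incidence: pd.DataFrame, profiles: pd.DataFrame,
                       units: dict[str, GeoUnit] | None = None) -> pd.DataFrame:
    """Per-unit richness and unweighted means of age and rates.

    ``profiles`` must be indexed by genus with columns stem_age,
    lambda_tip, netdiv_tip. Units present in ``units`` but without any
    incident genus are kept with richness 0 and missing means (they are
    excluded from downstream regressions).
    """
    missing = set(incidence["genus"]) - set(profiles.index)
    if missing:
        raise ValueError(f"no profile for genus {sorted(missing)[0]!r} "
                         f"({len(missing)} missing in total)")
    joined = incidence.join(profiles[["stem_age", "lambda_tip", "netdiv_tip"]],
                            on="genus")
    agg = joined.groupby("unit").agg(
        richness=("genus", "size"),
        mean_age=("stem_age", "mean"),
        mean_lambda=("lambda_tip", "mean"),
        mean_netdiv=("netdiv_tip", "mean"),
    )
    if units is not None:
        empty = [u for u in units if u not in agg.index]
        if empty:
            pad = pd.DataFrame(index=pd.Index(empty, name="unit"),
                               data={"richness": 0, "mean_age": np.nan,
                                     "mean_lambda": np.nan, "mean_netdiv": np.nan})
            agg = pd.concat([agg, pad]).sort_index()
        agg["lat"] = [units[u].centroid_lat for u in agg.index]
        agg["lon"] = [units[u].centroid_lon for u in agg.index]
    return agg


_METRIC_COLUMNS = {"age": "stem_age", "lambda": "lambda_tip", "netdiv": "netdiv_tip"}


def quartile_partition(profiles: pd.DataFrame, metric: str) -> pd.Series:
    """Global quartile labels (1..4) of a per-genus metric.

    Bins split at the interpolated 25/50/75 percentiles over *all*
    genera; a value exactly at a boundary goes to the lower bin.
    """
    col = _METRIC_COLUMNS.get(metric, metric)
    values = profiles[col].astype(float)
    finite = values[np.isfinite(values)]
    if finite.nunique() < 4:
        raise ValueError(f"need >=4 distinct finite values of {metric!r} "
                         "for a quartile partition")
    q25, q50, q75 = np.percentile(finite, [25, 50, 75])
    labels = pd.Series(np.nan, index=values.index, dtype=float)
    labels[values <= q25] = 1
    labels[(values > q25) & (values <= q50)] = 2
    labels[(values > q50) & (values <= q75)] = 3
    labels[values > q75] = 4
    return labels.astype("Int64")


def unit_quartile_proportions(incidence: pd.DataFrame,
                              labels: pd.Series) -> pd.DataFrame:
    """Per-unit proportion of each global quartile among incident genera."""
    df = incidence.copy()
    df["quartile"] = labels.reindex(df["genus"]).to_numpy()
    counts = (df.pivot_table(index="unit", columns="quartile", values="genus",
                             aggfunc="size", fill_value=0)
              .reindex(columns=[1, 2, 3, 4], fill_value=0))
    props = counts.div(counts.sum(axis=1), axis=0)
    props.columns = [f"q{int(c)}" for c in props.columns]
    return props


def assign_belts(units: dict[str, GeoUnit]) -> dict[str, str | None]:
    """Unit -> belt id, or None without a strict area majority.

    A unit belongs to the unique belt holding strictly more than half of
    its area; at most one belt can, since fractions sum to <= 1.
    """
    out = {}
    for uid, unit in units.items():
        belt = None
        for b, frac in unit.belt_fractions.items():
            if frac > 0.5:
                belt = b
                break
        out[uid] = belt
    return out


def belt_genus_union(incidence: pd.DataFrame,
                     assignment: dict[str, str | None]) -> dict[str, set]:
    """Belt -> union of genera over the belt's units.

    Genera occurring in units of several belts enter every one of them.
    """
    out: dict[str, set] = {}
    for genus, unit in incidence[["genus", "unit"]].itertuples(index=False):
        belt = assignment.get(unit)
        if belt is not None:
            out.setdefault(belt, set()).add(genus)
    return out


def annotate_profiles(profiles: pd.DataFrame,
                      woody_fraction: pd.Series | None = None,
                      cam_any_species: pd.Series | None = None,
                      c4_any_species: pd.Series | None = None) -> pd.DataFrame:
    """Attach growth form and photosynthetic-pathway labels.

    A genus is woody if >60% of its species are woody, herbaceous if
    <40% are, otherwise unclassified; it is CAM (or C4) iff any of its
    species is.
    """
    out = profiles.copy()
    if woody_fraction is not None:
        frac = woody_fraction.reindex(out.index).astype(float)
        if ((frac < 0) | (frac > 1)).any():
            raise ValueError("woody fractions must lie in [0, 1]")
        form = pd.Series("unclassified", index=out.index, dtype=object)
        form[frac > 0.6] = "woody"
        form[frac < 0.4] = "herbaceous"
        form[frac.isna()] = "unclassified"
        out["woody_fraction"] = frac
        out["growth_form"] = form
    if cam_any_species is not None:
        out["cam"] = cam_any_species.reindex(out.index).fillna(False).astype(bool)
    if c4_any_species is not None:
        out["c4"] = c4_any_species.reindex(out.index).fillna(False).astype(bool)
    return out
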