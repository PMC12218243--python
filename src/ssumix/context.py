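"""Oceanographic context: euphotic depth, province assignment, seasons, and
group-level relative-abundance summaries."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from ssumix.correction_merge import CorrectedASVTable
from ssumix.errors import ConfigurationError


@dataclass
class SampleContext:
    sample_id: str
    lat: float
    lon: float
    depth: float
    when: datetime | date | None = None
    kd490: float | None = None
    longhurst: str | None = None
    basin: str | None = None
    season: str | None = None
    covariates: dict[str, float] = field(default_factory=dict)

    @property
    def zeu(self) -> float | None:
        if self.kd490 is None or self.kd490 <= 0:
            return None
        return euphotic_depth(self.kd490)


def euphotic_depth(kd490: float) -> float:
    """Euphotic-zone (1% light) depth in meters from the diffuse attenuation
    coefficient at 490 nm: Z_eu = 4.6 / Kd490."""
    if kd490 <= 0:
        raise ConfigurationError("kd490 must be > 0")
    return 4.6 / kd490


@dataclass(frozen=True)
class Province:
    """A named polygon (exterior ring only; antimeridian-crossing polygons
    must be pre-split by the user)."""

    code: str
    ring: tuple[tuple[float, float], ...]  # (lon, lat) vertices

    def __post_init__(self) -> None:
        if len(self.ring) < 3:
            raise ConfigurationError(f"province {self.code}: ring has < 3 vertices")


def load_provinces_geojson(path: str | Path) -> list[Province]:
    """Read provinces from a GeoJSON FeatureCollection of Polygons; the
    feature property ``code`` (or ``name``) labels each province."""
    with open(path) as fh:
        doc = json.load(fh)
    provinces: list[Province] = []
    for feature in doc.get("features", []):
        geom = feature.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise ConfigurationError(
                f"unsupported geometry type {geom.get('type')!r}"
            )
        props = feature.get("properties", {})
        code = props.get("code") or props.get("name")
        if not code:
            raise ConfigurationError("province feature lacks a code/name property")
        ring = tuple((float(x), float(y)) for x, y in geom["coordinates"][0])
        provinces.append(Province(code=code, ring=ring))
    return provinces


def _point_on_segment(px: float, py: float, ax: float, ay: float,
                      bx: float, by: float) -> bool:
    cross = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
    if abs(cross) > 1e-12:
        return False
    return min(ax, bx) - 1e-12 <= px <= max(ax, bx) + 1e-12 and \
        min(ay, by) - 1e-12 <= py <= max(ay, by) + 1e-12


def point_in_ring(lon: float, lat: float, ring: Sequence[tuple[float, float]]) -> bool:
    """Even-odd ray-casting containment; boundary points count as inside."""
    n = len(ring)
    inside = False
    for i in range(n):
        ax, ay = ring[i]
        bx, by = ring[(i + 1) % n]
        if _point_on_segment(lon, lat, ax, ay, bx, by):
            return True
        if (ay > lat) != (by > lat):
            x_cross = ax + (lat - ay) * (bx - ax) / (by - ay)
            if lon < x_cross:
                inside = not inside
    return inside


def assign_longhurst(
    lat: float, lon: float, provinces: Sequence[Province]
) -> str | None:
    """First-listed province containing the point (even-odd rule), else None."""
    for province in provinces:
        if point_in_ring(lon, lat, province.ring):
            return province.code
    return None


_SEASONS_NORTH = {
    12: "Winter", 1: "Winter", 2: "Winter",
    3: "Spring", 4: "Spring", 5: "Spring",
    6: "Summer", 7: "Summer", 8: "Summer",
    9: "Autumn", 10: "Autumn", 11: "Autumn",
}
_FLIP = {"Winter": "Summer", "Summer": "Winter", "Spring": "Autumn",
         "Autumn": "Spring"}


def season_of(when: datetime | date, lat: float) -> str:
    """Meteorological season (DJF/MAM/JJA/SON), flipped south of the equator."""
    season = _SEASONS_NORTH[when.month]
    return _FLIP[season] if lat < 0 else season


def group_relative_abundance(
    table: CorrectedASVTable,
    asv_groups: Mapping[str, str],
    strata: Callable[[str], bool] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-sample group fractions and their unweighted stratum mean.

    Every ASV must have a group label; fractions within each sample sum to 1.
    Raises if the stratum predicate selects no samples.
    """
    missing = set(table.sequences) - set(asv_groups)
    if missing:
        raise ConfigurationError(
            f"{len(missing)} ASVs lack a group label (e.g. {sorted(missing)[:3]})"
        )
    samples = [s for s in table.sample_ids() if strata is None or strata(s)]
    if not samples:
        raise ConfigurationError(f"stratum predicate {strata!r} selects no samples")
    groups = sorted(set(asv_groups[a] for a in table.sequences))
    frac = pd.DataFrame(0.0, index=samples, columns=groups)
    for (s, aid), count in table.counts.items():
        if s in frac.index:
            frac.at[s, asv_groups[aid]] += count
    totals = frac.sum(axis=1)
    if (totals <= 0).any():
        empty = list(totals.index[totals <= 0])
        raise ConfigurationError(f"samples with zero corrected depth: {empty}")
    frac = frac.div(totals, axis=0)
    return frac, frac.mean(axis=0)


def read_metadata(path: str | Path) -> dict[str, SampleContext]:
    """Read the sample metadata TSV (columns: sample_id, lat, lon, depth,
    Date, Time, Kd490 plus optional named covariates)."""
    df = pd.read_csv(path, sep="\t")
    if "sample_id" not in df.columns:
        raise ConfigurationError("metadata must have a sample_id column")
    known = {"sample_id", "lat", "lon", "depth", "Date", "Time", "Kd490",
             "Season", "Longhurst_Short", "Basin"}
    out: dict[str, SampleContext] = {}
    for row in df.to_dict("records"):
        when = None
        if "Date" in row and pd.notna(row["Date"]):
            when = datetime.fromisoformat(str(row["Date"]))
        kd = row.get("Kd490")
        covariates = {
            k: float(v) for k, v in row.items()
            if k not in known and pd.notna(v)
            and isinstance(v, (int, float))
        }
        ctx = SampleContext(
            sample_id=str(row["sample_id"]),
            lat=float(row["lat"]),
            lon=float(row["lon"]),
            depth=float(row["depth"]),
            when=when,
            kd490=float(kd) if kd is not None and pd.notna(kd) else None,
            basin=str(row["Basin"]) if pd.notna(row.get("Basin")) else None,
            covariates=covariates,
        )
        if ctx.when is not None:
            ctx.season = season_of(ctx.when, ctx.lat)
        out[ctx.sample_id] = ctx
    return out


def annotate_contexts(
    contexts: Iterable[SampleContext], provinces: Sequence[Province]
) -> None:
    """Fill the longhurst field of each context in place."""
    for ctx in contexts:
        ctx.longhurst = assign_longhurst(ctx.lat, ctx.lon, provinces)
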