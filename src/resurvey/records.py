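"""Parsing, filtering and pooling of occurrence records into sampling units.

Raw occurrence tables (one row per species observation with a site code,
year, optional date and an elevation interval) are normalized against a
species registry, filtered by explicit quality rules, pooled into
``year#site#meanElevMSL`` sampling units, and converted to a binary
units x species incidence matrix.  Every incidence cell keeps a provenance
list of the surviving input rows that produced it.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Required columns of the occurrence CSV schema.
RECORD_COLUMNS = [
    "species",
    "count",
    "site",
    "year",
    "month",
    "day",
    "elev_low",
    "elev_high",
]


class UnknownSpeciesError(KeyError):
    """Raised when a species string cannot be resolved by the registry."""

    def __init__(self, name: str):
        super().__init__(name)
        self.name = name

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"species name not covered by the registry: {self.name!r}"


@dataclasses.dataclass(frozen=True)
class SpeciesRegistry:
    """Canonical species names plus synonym, complex and parasite metadata.

    Parameters
    ----------
    canonical
        Accepted species names (including complex labels).
    synonyms
        Mapping from outdated or variant names to canonical names.
    complexes
        Mapping from member species name to the complex label it is folded
        into (e.g. two unresolvable sibling species sharing one label).
    parasites
        Canonical names flagged as socio-parasitic.
    drop
        Names that are silently droppable (e.g. genus-level placeholders);
        :meth:`normalize` still raises for them, but callers may test
        :meth:`is_droppable` first.
    """

    canonical: frozenset[str]
    synonyms: Mapping[str, str] = dataclasses.field(default_factory=dict)
    complexes: Mapping[str, str] = dataclasses.field(default_factory=dict)
    parasites: frozenset[str] = frozenset()
    drop: frozenset[str] = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "canonical", frozenset(self.canonical))
        object.__setattr__(self, "parasites", frozenset(self.parasites))
        object.__setattr__(self, "drop", frozenset(self.drop))
        for label in set(self.complexes.values()):
            if label not in self.canonical:
                raise ValueError(f"complex label {label!r} must be canonical")

    def is_droppable(self, name: str) -> bool:
        return name in self.drop

    def normalize(self, name: str) -> str:
        """Resolve ``name`` to its canonical (or complex) label.

        Resolution order: synonym replacement first, then complex folding,
        then identity for canonical names.  Unknown strings raise
        :class:`UnknownSpeciesError` carrying the offending string.
        """
        resolved = self.synonyms.get(name, name)
        resolved = self.complexes.get(resolved, resolved)
        if resolved in self.complexes:  # synonym pointed at a complex member
            resolved = self.complexes[resolved]
        if resolved not in self.canonical:
            raise UnknownSpeciesError(name)
        return resolved


def normalize_species(name: str, registry: SpeciesRegistry) -> str:
    """Functional alias of :meth:`SpeciesRegistry.normalize`."""
    return registry.normalize(name)


@dataclasses.dataclass(frozen=True)
class OccurrenceRecord:
    species: str
    count: int | None
    site: str
    year: int
    month: int | None
    day: int | None
    elev_low: float
    elev_high: float

    def __post_init__(self):
        if self.elev_low > self.elev_high:
            raise ValueError(
                f"elev_low {self.elev_low} > elev_high {self.elev_high}"
            )


@dataclasses.dataclass(frozen=True)
class FilterRules:
    """Explicit record-quality rules; see :func:`filter_records`.

    ``excluded_species`` is scoped per period label so that exclusions that
    only apply to one sampling period (e.g. species with unusable counts in
    the historical data) never touch the other period.
    """

    max_elev_span: float = 500.0
    require_date: bool = True
    elev_window: tuple[float, float] = (1100.0, 2899.0)
    allowed_years: tuple[int, ...] = (1935, 1936, 2020)
    periods: Mapping[str, tuple[int, ...]] = dataclasses.field(
        default_factory=lambda: {"1935/1936": (1935, 1936), "2020": (2020,)}
    )
    excluded_species: Mapping[str, tuple[str, ...]] = dataclasses.field(
        default_factory=dict
    )
    nest_count_threshold: int = 30

    def period_of(self, year: int) -> str | None:
        for label, years in self.periods.items():
            if year in years:
                return label
        return None


def read_records_csv(path) -> pd.DataFrame:
    """Read an occurrence CSV with the documented schema.

    Missing values are empty fields; ``count``, ``month`` and ``day`` become
    nullable integers.
    """
    df = pd.read_csv(path, dtype={"species": str, "site": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {missing}")
    for col in ("count", "month", "day"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    df["year"] = df["year"].astype(int)
    for col in ("elev_low", "elev_high"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    return df


def records_to_frame(recs: Iterable[OccurrenceRecord]) -> pd.DataFrame:
    df = pd.DataFrame([dataclasses.asdict(r) for r in recs])
    if df.empty:
        df = pd.DataFrame(columns=RECORD_COLUMNS)
    for col in ("count", "month", "day"):
        df[col] = df[col].astype("Int64")
    return df[RECORD_COLUMNS]


def normalize_frame(
    df: pd.DataFrame, registry: SpeciesRegistry
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Normalize the species column of a record frame against a registry.

    Names in the registry's drop list are removed (counted in the returned
    log under ``dropped_species``); any other unknown name raises.
    """
    keep = np.ones(len(df), dtype=bool)
    names = []
    n_dropped = 0
    for i, name in enumerate(df["species"]):
        if registry.is_droppable(name):
            keep[i] = False
            n_dropped += 1
            names.append(name)
            continue
        names.append(registry.normalize(name))
    out = df.copy()
    out["species"] = names
    out = out.loc[keep].reset_index(drop=True)
    return out, {"dropped_species": n_dropped}


def _interval_key(row) -> tuple[float, float]:
    return (float(row.elev_low), float(row.elev_high))


def filter_records(
    df: pd.DataFrame, rules: FilterRules | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the record-quality rules and return survivors plus a rule log.

    Rules, in order: allowed years; required recording date; elevation span
    strictly greater than ``max_elev_span`` excluded; elevation interval must
    lie inside ``elev_window``; period-scoped species exclusions; suspected
    single-nest excavations (a site/date/interval group containing exactly
    one species with a total count at or above ``nest_count_threshold``).

    The function is idempotent: filtering an already-filtered frame removes
    nothing further.
    """
    rules = rules or FilterRules()
    df = df.reset_index(drop=True)
    log: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)

    mask = df["year"].isin(rules.allowed_years)
    log["year_not_allowed"] = int((~mask & keep).sum())
    keep &= mask

    if rules.require_date:
        has_date = df["month"].notna() & df["day"].notna()
        log["missing_date"] = int((~has_date & keep).sum())
        keep &= has_date

    span = df["elev_high"] - df["elev_low"]
    mask = span <= rules.max_elev_span  # strict > span excluded
    log["elev_span_gt_max"] = int((~mask & keep).sum())
    keep &= mask

    lo, hi = rules.elev_window
    mask = (df["elev_low"] >= lo) & (df["elev_high"] <= hi)
    log["outside_elev_window"] = int((~mask & keep).sum())
    keep &= mask

    periods = df["year"].map(rules.period_of)
    mask = pd.Series(True, index=df.index)
    for period, excluded in rules.excluded_species.items():
        mask &= ~((periods == period) & df["species"].isin(excluded))
    log["species_excluded_for_period"] = int((~mask & keep).sum())
    keep &= mask

    # Nest-excavation heuristic: within one (site, date, elevation interval)
    # a single species with a very high total count is most plausibly one
    # excavated colony, not a transect observation.
    nest_mask = pd.Series(True, index=df.index)
    sub = df.loc[keep]
    if len(sub):
        grp_cols = ["site", "year", "month", "day", "elev_low", "elev_high"]
        for _, g in sub.groupby(grp_cols, dropna=False):
            if g["species"].nunique() != 1:
                continue
            total = g["count"].dropna().sum()
            if total >= rules.nest_count_threshold:
                nest_mask.loc[g.index] = False
    log["suspected_nest_excavation"] = int((~nest_mask & keep).sum())
    keep &= nest_mask

    for rule, n in log.items():
        if n:
            logger.info("filter_records: %s excluded %d record(s)", rule, n)
    return df.loc[keep].reset_index(drop=True), log


@dataclasses.dataclass(frozen=True)
class SamplingUnit:
    """Pooled records of one year at one site and elevation interval."""

    year: int
    site: str
    elev_low: float
    elev_high: float
    species: frozenset[str]
    record_index: tuple[int, ...] = ()

    @property
    def mean_elev(self) -> float:
        return (self.elev_low + self.elev_high) / 2.0

    @property
    def id(self) -> str:
        return f"{self.year}#{self.site}#{round(self.mean_elev)}MSL"


def _merge_overlapping(intervals: Sequence[tuple[float, float]]):
    """Merge intervals whose overlap has positive length.

    Bins that only touch at a shared boundary (e.g. 1800-1900 and
    1900-2000) describe adjacent strata and are kept separate.
    """
    merged: list[list[float]] = []
    for lo, hi in sorted(intervals):
        if merged and lo < merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def historical_bins(
    df: pd.DataFrame, historical_years: Iterable[int]
) -> dict[str, list[tuple[float, float]]]:
    """Per-site merged elevation intervals present in the historical data."""
    hist = df[df["year"].isin(set(historical_years))]
    bins: dict[str, list[tuple[float, float]]] = {}
    for site, g in hist.groupby("site"):
        ivals = {(float(r.elev_low), float(r.elev_high)) for r in g.itertuples()}
        bins[site] = _merge_overlapping(sorted(ivals))
    return bins


def pool_to_units(
    df: pd.DataFrame,
    bin_replication: Mapping[str, Sequence[tuple[float, float]]] | None = None,
    historical_years: Iterable[int] = (1935, 1936),
    recent_years: Iterable[int] = (2020,),
) -> tuple[list[SamplingUnit], dict[str, int]]:
    """Pool filtered records into per-(year, site, elevation-bin) units.

    Historical records define the per-site elevation bins (overlapping
    historical intervals are merged into their union); recent records are
    re-binned into the historical bins of the same site by interval
    midpoint, ties going to the lower bin.  Recent records at sites or
    elevations without any historical bin are dropped and counted in the
    returned log.
    """
    df = df.reset_index(drop=True)
    historical_years = set(historical_years)
    recent_years = set(recent_years)
    if bin_replication is None:
        bin_replication = historical_bins(df, historical_years)

    def assign_bin(site: str, lo: float, hi: float, historic: bool):
        bins = bin_replication.get(site, [])
        if historic:
            for b in bins:
                if lo >= b[0] and hi <= b[1]:
                    return b
            # historical record outside the declared bins: its own bin
            return (lo, hi)
        mid = (lo + hi) / 2.0
        hits = [b for b in bins if b[0] <= mid <= b[1]]
        if not hits:
            return None
        return min(hits)  # midpoint tie -> lower bin

    pooled: dict[tuple[int, str, tuple[float, float]], dict] = {}
    n_unbinned = 0
    for idx, row in enumerate(df.itertuples()):
        year = int(row.year)
        historic = year in historical_years
        if not historic and year not in recent_years:
            historic = True  # unknown years treated as defining their own bin
        b = assign_bin(row.site, float(row.elev_low), float(row.elev_high), historic)
        if b is None:
            n_unbinned += 1
            logger.warning(
                "pool_to_units: record %d (%s %s %s-%s m) matches no "
                "historical bin of its site; dropped",
                idx, row.site, row.year, row.elev_low, row.elev_high,
            )
            continue
        key = (year, str(row.site), b)
        entry = pooled.setdefault(key, {"species": set(), "records": []})
        entry["species"].add(row.species)
        entry["records"].append(idx)

    units = [
        SamplingUnit(
            year=year,
            site=site,
            elev_low=b[0],
            elev_high=b[1],
            species=frozenset(entry["species"]),
            record_index=tuple(sorted(entry["records"])),
        )
        for (year, site, b), entry in pooled.items()
    ]
    units.sort(key=lambda u: (u.year, u.site, u.elev_low, u.elev_high))
    return units, {"recent_record_without_bin": n_unbinned}


@dataclasses.dataclass
class IncidenceMatrix:
    """Binary units x species matrix with per-cell record provenance."""

    values: pd.DataFrame  # index = unit ids, columns = species, entries 0/1
    units: list[SamplingUnit]
    provenance: dict[tuple[str, str], tuple[int, ...]]

    @property
    def unit_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def species(self) -> list[str]:
        return list(self.values.columns)

    def unit_table(self) -> pd.DataFrame:
        rows = [
            {
                "id": u.id,
                "year": u.year,
                "site": u.site,
                "elev_low": u.elev_low,
                "elev_high": u.elev_high,
                "mean_elev": u.mean_elev,
                "n_species": len(u.species),
            }
            for u in self.units
        ]
        return pd.DataFrame(rows).set_index("id")


def build_incidence(
    units: Sequence[SamplingUnit],
    registry: SpeciesRegistry | None = None,
    df: pd.DataFrame | None = None,
) -> IncidenceMatrix:
    """Construct the presence/absence matrix from pooled sampling units.

    Species columns observed in no unit are removed.  All-zero unit rows
    (possible when every species of a unit was dropped upstream) are kept
    with a warning so that downstream bookkeeping stays aligned.
    """
    if not units:
        raise ValueError("at least one sampling unit is required")
    species = sorted({s for u in units for s in u.species})
    if registry is not None:
        for s in species:
            if s not in registry.canonical:
                raise UnknownSpeciesError(s)
        member_labels = {registry.complexes.get(s) for s in species}
        clash = set(species) & {m for m in registry.complexes}
        if clash and (member_labels & set(species)):
            raise ValueError(
                f"complex members {sorted(clash)} appear alongside their "
                "complex label in one matrix"
            )
    ids = [u.id for u in units]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sampling-unit ids")
    mat = pd.DataFrame(0, index=ids, columns=species, dtype=int)
    provenance: dict[tuple[str, str], tuple[int, ...]] = {}
    for u in units:
        if not u.species:
            logger.warning("build_incidence: unit %s has no species", u.id)
        for s in u.species:
            mat.loc[u.id, s] = 1
            if df is not None:
                recs = [
                    i for i in u.record_index if df.iloc[i]["species"] == s
                ]
                provenance[(u.id, s)] = tuple(recs)
            else:
                provenance[(u.id, s)] = u.record_index
    mat = mat.loc[:, mat.sum(axis=0) > 0]
    return IncidenceMatrix(values=mat, units=list(units), provenance=provenance)


def harmonize(
    df: pd.DataFrame,
    registry: SpeciesRegistry,
    rules: FilterRules | None = None,
) -> tuple[IncidenceMatrix, dict[str, int]]:
    """Full normalize -> filter -> pool -> incidence pipeline."""
    rules = rules or FilterRules()
    df, log_n = normalize_frame(df, registry)
    df, log_f = filter_records(df, rules)
    # The period containing the latest declared year is the resurvey; all
    # earlier periods define the elevation bins.
    latest = max(y for ys in rules.periods.values() for y in ys)
    recent_years = sorted(
        ys for ys in rules.periods.values() if latest in ys
    )[0]
    hist_years = sorted(
        y for ys in rules.periods.values() for y in ys if y not in recent_years
    )
    units, log_p = pool_to_units(
        df, historical_years=hist_years, recent_years=recent_years
    )
    inc = build_incidence(units, registry=registry, df=df)
    return inc, {**log_n, **log_f, **log_p}
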