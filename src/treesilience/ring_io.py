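"""Tree-ring series containers and Tucson decadal (.rwl) input/output.

A :class:`RingSeries` holds one tree's calendar-dated annual ring widths
(TRW, mm) together with its identity metadata: site, species, genus,
taxonomic group (angiosperm/gymnosperm), status (surviving/now-dead) and
diameter at breast height (DBH, cm) at sampling.  A :class:`Dataset`
bundles the series of a study with per-site monthly climate and a per-site
soil table, mirroring a matched-pairs case-control sampling design in
which dying and surviving trees were cored together at the same sites.

Ring widths of zero in .rwl files encode locally absent rings; they are
decoded as missing (NaN) rather than as zero growth, because the
resilience ratios are undefined at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DatasetValidationError, RwlFormatError

__all__ = [
    "RingSeries",
    "Dataset",
    "read_rwl",
    "write_rwl",
    "assemble_dataset",
]

#: stop-marker conventions of the two Tucson dialects
_STOP = {"0.01mm": 999, "0.001mm": -9999}
_PRECISION = {"0.01mm": 0.01, "0.001mm": 0.001}

METADATA_COLUMNS = [
    "tree_id", "site", "species", "genus", "group",
    "status", "dbh_cm", "last_year", "hemisphere",
]
CLIMATE_COLUMNS = ["site", "year", "month", "prcp_mm", "pet_mm"]


@dataclass
class RingSeries:
    """One tree's dated annual ring-width series plus metadata."""

    tree_id: str
    years: np.ndarray            # consecutive calendar years
    trw: np.ndarray              # ring widths, mm (> 0; NaN = locally absent)
    site_id: str = ""
    species: str = ""
    genus: str = ""
    group: str = ""              # "angiosperm" | "gymnosperm"
    status: str = ""             # "surviving" | "now-dead"
    dbh_cm: float = float("nan")

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.trw = np.asarray(self.trw, dtype=float)
        if len(self.years) != len(self.trw):
            raise ValueError(f"{self.tree_id}: years and trw lengths differ")
        if len(self.years) and np.any(np.diff(self.years) != 1):
            raise ValueError(f"{self.tree_id}: years must be strictly consecutive")
        with np.errstate(invalid="ignore"):
            if np.any(self.trw[np.isfinite(self.trw)] <= 0):
                raise ValueError(f"{self.tree_id}: ring widths must be positive")

    @property
    def first_year(self) -> int:
        return int(self.years[0])

    @property
    def last_year(self) -> int:
        """Final dated ring; the death year for now-dead trees."""
        return int(self.years[-1])

    def to_series(self) -> pd.Series:
        return pd.Series(self.trw, index=self.years, name=self.tree_id)


@dataclass
class Dataset:
    """All study inputs, validated and cross-linked."""

    series: dict                     # tree_id -> RingSeries
    metadata: pd.DataFrame           # one row per tree
    climate: pd.DataFrame            # site, year, month, prcp_mm, pet_mm
    soil: pd.DataFrame               # site + ten soil characteristics
    single_status_sites: list = field(default_factory=list)

    @property
    def sites(self) -> list:
        return sorted(self.metadata["site"].unique())

    def site_series(self, site_id) -> list:
        ids = self.metadata.loc[self.metadata["site"] == site_id, "tree_id"]
        return [self.series[t] for t in ids]

    def site_climate(self, site_id) -> pd.DataFrame:
        sub = self.climate[self.climate["site"] == site_id]
        return sub.sort_values(["year", "month"]).reset_index(drop=True)

    def hemisphere(self, site_id) -> str:
        sub = self.metadata.loc[self.metadata["site"] == site_id, "hemisphere"]
        return str(sub.iloc[0]) if len(sub) else "N"


def _detect_dialect(tokens_per_line):
    """Infer the dialect from the terminator token of any series."""
    for tokens in tokens_per_line:
        if tokens and tokens[-1] == "-9999":
            return "0.001mm"
        if tokens and tokens[-1] == "999":
            return "0.01mm"
    raise RwlFormatError(
        "cannot auto-detect dialect (no 999/-9999 terminator found); "
        "pass units_dialect explicitly"
    )


def read_rwl(path, units_dialect="auto"):
    """Read a Tucson decadal .rwl file.

    Parameters
    ----------
    path : str or Path
    units_dialect : {"auto", "0.01mm", "0.001mm"}
        Unit of the integer width fields.  ``auto`` detects the dialect
        from the stop marker (999 for 0.01 mm files, -9999 for 0.001 mm).

    Returns
    -------
    list of RingSeries
        Only ``tree_id``, ``years`` and ``trw`` are populated; identity
        metadata is attached by :func:`assemble_dataset`.
    """
    if units_dialect not in ("auto", "0.01mm", "0.001mm"):
        raise ValueError(f"unknown dialect {units_dialect!r}")
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    tokenised = [(i + 1, ln.split()) for i, ln in enumerate(lines) if ln.strip()]
    if units_dialect == "auto":
        units_dialect = _detect_dialect([t for _, t in tokenised])
    stop = _STOP[units_dialect]
    prec = _PRECISION[units_dialect]

    out = []
    cur_id, cur_years, cur_vals, next_year = None, [], [], None
    seen = set()

    def _close():
        nonlocal cur_id, cur_years, cur_vals, next_year
        if cur_id is not None:
            if cur_id in seen:
                raise RwlFormatError(f"duplicate series id {cur_id!r}", path)
            seen.add(cur_id)
            out.append(RingSeries(cur_id, np.array(cur_years), np.array(cur_vals)))
        cur_id, cur_years, cur_vals, next_year = None, [], [], None

    for lineno, tokens in tokenised:
        # fixed-width files may glue an 8-character id to the decade year
        if len(tokens[0]) > 8 and tokens[0][-4:].isdigit():
            tokens = [tokens[0][:-4], tokens[0][-4:]] + tokens[1:]
        if len(tokens) < 3:
            raise RwlFormatError("expected id, year and data fields", path, lineno)
        sid = tokens[0]
        try:
            year = int(tokens[1])
            vals = [int(t) for t in tokens[2:]]
        except ValueError as exc:
            raise RwlFormatError(f"unparseable field ({exc})", path, lineno) from None
        if sid != cur_id:
            _close()
            cur_id, next_year = sid, year
        if year != next_year:
            raise RwlFormatError(
                f"series {sid!r}: decade starts at {year}, expected {next_year}",
                path, lineno,
            )
        closed = False
        for v in vals:
            if v == stop:
                closed = True
                break
            cur_years.append(next_year)
            cur_vals.append(np.nan if v == 0 else v * prec)
            next_year += 1
        if closed:
            _close()
        else:
            # next line must resume at the following decade boundary
            next_year = cur_years[-1] + 1 if cur_years else year
    if cur_id is not None:
        raise RwlFormatError(f"series {cur_id!r} not terminated by stop marker", path)
    return out


def write_rwl(series, path, units_dialect="0.01mm"):
    """Write RingSeries to a Tucson decadal .rwl file.

    Values are rounded to the dialect resolution; a width that cannot be
    represented in the integer field raises ``ValueError``.
    """
    if units_dialect not in _STOP:
        raise ValueError(f"unknown dialect {units_dialect!r}")
    stop = _STOP[units_dialect]
    prec = _PRECISION[units_dialect]
    with open(path, "w", encoding="utf-8") as fh:
        for s in series:
            ints = []
            for w in s.trw:
                if np.isnan(w):
                    ints.append(0)
                    continue
                v = int(round(w / prec))
                if v <= 0 or v >= abs(stop) or v > 99999:
                    raise ValueError(
                        f"{s.tree_id}: width {w} mm not representable in "
                        f"{units_dialect} dialect"
                    )
                ints.append(v)
            sid = s.tree_id if len(s.tree_id) < 8 else s.tree_id + " "
            year = s.first_year
            i = 0
            while i <= len(ints):  # <= so the terminator gets a line if needed
                decade_end = (year // 10) * 10 + 10
                fields = []
                row_year = year
                while year < decade_end and i < len(ints):
                    fields.append(f"{ints[i]:>6d}")
                    i += 1
                    year += 1
                done = i == len(ints)
                if done and year < decade_end:
                    fields.append(f"{stop:>6d}")
                if fields:
                    fh.write(f"{sid:<8s}{row_year:>4d}{''.join(fields)}\n")
                if done:
                    if year >= decade_end and fields and fields[-1].strip() != str(stop):
                        fh.write(f"{sid:<8s}{year:>4d}{stop:>6d}\n")
                    break


def assemble_dataset(rwl_paths, metadata_csv, climate_csv, soil_csv,
                     units_dialect="auto"):
    """Read and cross-validate all study inputs into a :class:`Dataset`.

    Validation rules
    ----------------
    * every metadata row must resolve to a ring series (hard error);
    * orphan ring series (no metadata) are a hard error;
    * every site with series needs monthly climate covering its span;
    * sites lacking one of the two statuses are flagged (kept for
      chronology building, excluded from the status models).
    """
    raw = []
    for p in rwl_paths:
        raw.extend(read_rwl(p, units_dialect))
    by_id = {}
    for s in raw:
        if s.tree_id in by_id:
            raise DatasetValidationError(
                f"duplicate tree id across files: {s.tree_id}", [s.tree_id])
        by_id[s.tree_id] = s

    meta = pd.read_csv(metadata_csv)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns
                    and c != "hemisphere"]
    if missing_cols:
        raise DatasetValidationError(f"metadata missing columns {missing_cols}",
                                     missing_cols)
    if "hemisphere" not in meta.columns:
        meta["hemisphere"] = "N"

    orphan_meta = sorted(set(meta["tree_id"]) - set(by_id))
    if orphan_meta:
        raise DatasetValidationError(
            f"metadata rows without ring series: {orphan_meta}", orphan_meta)
    orphan_series = sorted(set(by_id) - set(meta["tree_id"]))
    if orphan_series:
        raise DatasetValidationError(
            f"ring series without metadata: {orphan_series}", orphan_series)

    for _, row in meta.iterrows():
        s = by_id[row["tree_id"]]
        s.site_id = str(row["site"])
        s.species = str(row["species"])
        s.genus = str(row["genus"])
        s.group = str(row["group"])
        s.status = str(row["status"])
        s.dbh_cm = float(row["dbh_cm"])
        if int(row["last_year"]) != s.last_year:
            raise DatasetValidationError(
                f"{s.tree_id}: metadata last_year {row['last_year']} "
                f"!= series last year {s.last_year}", [s.tree_id])

    climate = pd.read_csv(climate_csv)
    missing_cols = [c for c in CLIMATE_COLUMNS if c not in climate.columns]
    if missing_cols:
        raise DatasetValidationError(f"climate missing columns {missing_cols}",
                                     missing_cols)
    soil = pd.read_csv(soil_csv)

    # climate coverage per site
    gaps = []
    for site, grp in meta.groupby("site"):
        span = (min(by_id[t].first_year for t in grp["tree_id"]),
                max(by_id[t].last_year for t in grp["tree_id"]))
        cyears = set(climate.loc[climate["site"] == site, "year"])
        need = set(range(span[0], span[1] + 1))
        if not need <= cyears:
            gaps.append((site, sorted(need - cyears)[:5]))
    if gaps:
        raise DatasetValidationError(f"sites with missing climate years: {gaps}",
                                     [g[0] for g in gaps])

    single = []
    for site, grp in meta.groupby("site"):
        if grp["status"].nunique() < 2:
            single.append(site)
            warnings.warn(
                f"site {site} has a single tree status; kept for chronology, "
                "excluded from status models", stacklevel=2)

    return Dataset(series=by_id, metadata=meta, climate=climate, soil=soil,
                   single_status_sites=single)
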