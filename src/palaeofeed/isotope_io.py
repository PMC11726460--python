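"""Table readers/writers and dataset validation.

Input tables are delimited text (CSV by default; ``;`` and tab dialects are
common in European supplementary spreadsheets and supported through
:class:`TableDialect`).  Readers reject individual bad rows with
machine-readable diagnostics rather than aborting the file: curated
archaeological tables routinely contain stray rows, and discarding a whole
site table over one typo is the wrong default.

Every reader returns a :class:`ReadResult` whose accounting invariant
``accepted + rejected == total rows`` is enforced by construction.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .datamodel import (
    BulkSample,
    Dataset,
    DentineIncrement,
    EnamelIncrement,
    Site,
    ToothSeries,
)

__all__ = [
    "TableDialect",
    "RowDiagnostic",
    "ReadResult",
    "read_sites",
    "read_bulk_samples",
    "read_tooth_series",
    "validate_dataset",
    "write_sites",
    "write_bulk_samples",
    "write_tooth_series",
]

NA_VALUES = ["", "NA"]


@dataclass(frozen=True)
class TableDialect:
    """Delimited-text conventions: UTF-8, mandatory header, '.' decimal."""

    delimiter: str = ","
    decimal: str = "."
    encoding: str = "utf-8"


@dataclass(frozen=True)
class RowDiagnostic:
    """One rejected (or flagged) row, with a machine-readable reason."""

    table: str
    row: int  # 0-based data-row index in the source file
    record_id: str
    reason: str
    severity: str = "error"  # error -> rejected; warning -> retained


@dataclass
class ReadResult:
    """Records accepted from one table plus per-row diagnostics."""

    records: list
    diagnostics: list[RowDiagnostic] = field(default_factory=list)
    n_total: int = 0

    @property
    def n_accepted(self) -> int:
        return len(self.records)

    @property
    def n_rejected(self) -> int:
        return sum(1 for d in self.diagnostics if d.severity == "error")


def _read_table(path, dialect: TableDialect) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        decimal=dialect.decimal,
        encoding=dialect.encoding,
        na_values=NA_VALUES,
        keep_default_na=False,
        dtype=str,
    )
    df.columns = [str(c).strip() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{table}: missing mandatory column(s): {', '.join(missing)}")


def _num(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if s in NA_VALUES:
        return None
    return float(s)  # ValueError propagates to the caller's row handler


SITE_COLUMNS = ["site_id", "longitude", "latitude"]
SITE_OPTIONAL = [
    "name", "mfc", "pmw", "pms", "tmw", "tms",
    "river_distance", "strahler", "drainage", "culture",
]


def read_sites(path, dialect: TableDialect = TableDialect()) -> ReadResult:
    """Load the site table (metadata + environmental proxies).

    Mandatory columns: ``site_id``, ``longitude``, ``latitude``.  Unknown
    columns are preserved on ``Site.extra``.  Duplicate ``site_id`` values
    are a structural error (the whole file is refused): sites key everything
    downstream.
    """
    df = _read_table(path, dialect)
    _require_columns(df, SITE_COLUMNS, "sites")
    ids = df["site_id"].astype(str).str.strip()
    dup = sorted(ids[ids.duplicated()].unique())
    if dup:
        raise ValueError(f"sites: duplicate site_id: {', '.join(dup)}")

    known = set(SITE_COLUMNS) | set(SITE_OPTIONAL)
    extra_cols = [c for c in df.columns if c not in known]
    records, diags = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        sid = str(r["site_id"]).strip()
        try:
            lon, lat = _num(r["longitude"]), _num(r["latitude"])
            if lon is None or lat is None:
                diags.append(RowDiagnostic("sites", i, sid, "missing coordinate"))
                continue
            strahler = _num(r.get("strahler"))
            site = Site(
                site_id=sid,
                name=_str_or_none(r.get("name")) or "",
                longitude=lon,
                latitude=lat,
                mfc=_num(r.get("mfc")),
                pmw=_num(r.get("pmw")),
                pms=_num(r.get("pms")),
                tmw=_num(r.get("tmw")),
                tms=_num(r.get("tms")),
                river_distance=_num(r.get("river_distance")),
                strahler=None if strahler is None else int(strahler),
                drainage=_str_or_none(r.get("drainage")),
                culture=_str_or_none(r.get("culture")),
                extra={c: r[c] for c in extra_cols},
            )
        except (TypeError, ValueError) as exc:
            diags.append(RowDiagnostic("sites", i, sid, f"unparseable field: {exc}"))
            continue
        probs = site.problems()
        if probs:
            diags.append(RowDiagnostic("sites", i, sid, "; ".join(probs)))
        else:
            records.append(site)
    return ReadResult(records, diags, n_total=len(df))


def _is_na(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() in NA_VALUES


def _str_or_none(v) -> str | None:
    return None if _is_na(v) else str(v).strip()


def read_bulk_samples(
    path,
    tissue: str,
    taxon: str,
    dialect: TableDialect = TableDialect(),
) -> ReadResult:
    """Load a bulk delta13C table for one tissue/taxon combination.

    Dairy tables (``tissue='dairy_c16'``) must carry both ``d13c_c16`` and
    ``d13c_c18`` columns; a row with a missing C18:0 value still loads (with
    ``d13c_c18`` unset) and is flagged *not classifiable* as a warning,
    because the dairy-origin test needs the C18-C16 spacing.
    """
    df = _read_table(path, dialect)
    if len(df) == 0:
        raise ValueError(f"{path}: empty table")
    # the BulkSample invariant is structural here: fail the whole call
    probe = BulkSample("probe", "probe", tissue, taxon, -20.0)
    combo = [p for p in probe.problems()]
    if combo:
        raise ValueError(f"invalid tissue/taxon combination: {'; '.join(combo)}")

    value_col = "d13c_c16" if tissue == "dairy_c16" else "d13c"
    _require_columns(df, ["sample_id", "site_id", value_col], "bulk")
    if tissue == "dairy_c16":
        _require_columns(df, ["d13c_c18"], "bulk")

    records, diags = [], []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        sid = str(r["sample_id"]).strip()
        try:
            d13c = _num(r[value_col])
            c18 = _num(r.get("d13c_c18")) if tissue == "dairy_c16" else None
        except ValueError as exc:
            diags.append(RowDiagnostic("bulk", i, sid, f"unparseable d13c: {exc}"))
            continue
        if d13c is None:
            diags.append(RowDiagnostic("bulk", i, sid, "missing d13c"))
            continue
        sample = BulkSample(
            sample_id=sid,
            site_id=str(r["site_id"]).strip(),
            tissue=tissue,
            taxon=taxon,
            d13c=d13c,
            d13c_c18=c18,
        )
        probs = sample.problems()
        if probs:
            diags.append(RowDiagnostic("bulk", i, sid, "; ".join(probs)))
            continue
        if tissue == "dairy_c16" and c18 is None:
            diags.append(
                RowDiagnostic("bulk", i, sid, "d13c_c18 missing: not classifiable",
                              severity="warning")
            )
        records.append(sample)
    return ReadResult(records, diags, n_total=len(df))


ENAMEL_COLUMNS = ["tooth_id", "site_id", "crown_height", "position_erj",
                  "d13c_bioap", "d18o_bioap"]
DENTINE_COLUMNS = ["tooth_id", "position_erj", "d15n_glx", "d15n_phe"]


def read_tooth_series(
    enamel_path,
    dentine_path=None,
    dialect: TableDialect = TableDialect(),
) -> ReadResult:
    """Load sequential enamel (and optionally dentine) tables into tooth series.

    Rows are grouped by ``tooth_id`` and sorted occlusal-first (descending
    position from the ERJ, i.e. formation order).  Dentine rows whose
    ``tooth_id`` has no enamel counterpart are retained as dentine-only
    series with a warning diagnostic.
    """
    df = _read_table(enamel_path, dialect)
    _require_columns(df, ENAMEL_COLUMNS, "enamel")

    teeth: dict[str, ToothSeries] = {}
    diags: list[RowDiagnostic] = []
    n_total = len(df)
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        tid = str(r["tooth_id"]).strip()
        try:
            ch = _num(r["crown_height"])
            pos = _num(r["position_erj"])
            d13c = _num(r["d13c_bioap"])
            d18o = _num(r["d18o_bioap"])
        except ValueError as exc:
            diags.append(RowDiagnostic("enamel", i, tid, f"unparseable field: {exc}"))
            continue
        if None in (ch, pos, d13c, d18o):
            diags.append(RowDiagnostic("enamel", i, tid, "missing numeric field"))
            continue
        if not (0.0 <= pos <= ch):
            diags.append(
                RowDiagnostic("enamel", i, tid,
                              f"position_erj {pos} outside [0, crown_height={ch}]")
            )
            continue
        tooth = teeth.setdefault(
            tid, ToothSeries(tid, str(r["site_id"]).strip(), crown_height=ch)
        )
        tooth.enamel.append(EnamelIncrement(tid, pos, d13c, d18o))

    if dentine_path is not None:
        ddf = _read_table(dentine_path, dialect)
        _require_columns(ddf, DENTINE_COLUMNS, "dentine")
        n_total += len(ddf)
        for i, row in enumerate(ddf.itertuples(index=False)):
            r = dict(zip(ddf.columns, row))
            tid = str(r["tooth_id"]).strip()
            try:
                pos = _num(r["position_erj"])
                glx = _num(r["d15n_glx"])
                phe = _num(r["d15n_phe"])
            except ValueError as exc:
                diags.append(RowDiagnostic("dentine", i, tid, f"unparseable field: {exc}"))
                continue
            if None in (pos, glx, phe):
                diags.append(RowDiagnostic("dentine", i, tid, "missing numeric field"))
                continue
            if tid not in teeth:
                diags.append(
                    RowDiagnostic("dentine", i, tid,
                                  "no enamel counterpart: dentine-only series",
                                  severity="warning")
                )
                site_id = str(r.get("site_id") or "").strip()
                ch = _num(r.get("crown_height")) or max(pos, 1.0)
                teeth[tid] = ToothSeries(tid, site_id, crown_height=ch)
            tooth = teeth[tid]
            if not (0.0 <= pos <= tooth.crown_height):
                diags.append(
                    RowDiagnostic("dentine", i, tid,
                                  f"position_erj {pos} outside [0, crown_height="
                                  f"{tooth.crown_height}]")
                )
                continue
            tooth.dentine.append(DentineIncrement(tid, pos, glx, phe))

    for tooth in teeth.values():
        tooth.enamel.sort(key=lambda x: -x.position_erj)
        tooth.dentine.sort(key=lambda x: -x.position_erj)
    records = [teeth[t] for t in teeth]
    return ReadResult(records, diags, n_total=n_total)


def validate_dataset(ds: Dataset) -> dict:
    """Exhaustive report: counts, referential integrity, invariant failures.

    Report-only; the dataset is never modified.  ``n_measurements`` counts
    every isotope determination (one per collagen/dairy-C16 value, one more
    per dairy C18:0, one per enamel delta13C and delta18O, one per dentine
    Glx and Phe delta15N).
    """
    failures: list[dict] = []

    def fail(kind: str, record_id: str, detail: str) -> None:
        failures.append({"kind": kind, "record_id": record_id, "detail": detail})

    seen_samples: set[str] = set()
    for s in ds.bulk:
        if s.sample_id in seen_samples:
            fail("duplicate_sample_id", s.sample_id, "sample_id not unique")
        seen_samples.add(s.sample_id)
        if s.site_id not in ds.sites:
            fail("unknown_site", s.sample_id, f"site_id {s.site_id!r} not in sites")
        for p in s.problems():
            fail("invariant", s.sample_id, p)

    seen_teeth: set[str] = set()
    n_enamel = n_dentine = 0
    for t in ds.teeth:
        if t.tooth_id in seen_teeth:
            fail("duplicate_tooth_id", t.tooth_id, "tooth_id not unique")
        seen_teeth.add(t.tooth_id)
        if t.site_id and t.site_id not in ds.sites:
            fail("unknown_site", t.tooth_id, f"site_id {t.site_id!r} not in sites")
        for p in t.problems():
            fail("invariant", t.tooth_id, p)
        n_enamel += len(t.enamel)
        n_dentine += len(t.dentine)

    for site in ds.sites.values():
        for p in site.problems():
            fail("invariant", site.site_id, p)

    n_c18 = sum(1 for s in ds.bulk if s.d13c_c18 is not None)
    n_measurements = len(ds.bulk) + n_c18 + 2 * n_enamel + 2 * n_dentine
    return {
        "n_sites": len(ds.sites),
        "n_bulk": len(ds.bulk),
        "n_teeth": len(ds.teeth),
        "n_enamel_increments": n_enamel,
        "n_dentine_increments": n_dentine,
        "n_measurements": n_measurements,
        "n_failures": len(failures),
        "failures": failures,
    }


# ---------------------------------------------------------------------------
# writers (round-trip partners of the readers)

def _fmt(v) -> str:
    if v is None:
        return ""
    return repr(v) if isinstance(v, float) else str(v)


def write_sites(sites: Iterable[Site], path, dialect: TableDialect = TableDialect()) -> None:
    rows = []
    for s in sites:
        d = dataclasses.asdict(s)
        extra = d.pop("extra")
        d.update(extra)
        rows.append(d)
    pd.DataFrame(rows).to_csv(
        path, sep=dialect.delimiter, index=False, encoding=dialect.encoding)


def write_bulk_samples(samples: Iterable[BulkSample], path,
                       dialect: TableDialect = TableDialect()) -> None:
    rows = []
    for s in samples:
        d = dataclasses.asdict(s)
        if s.tissue == "dairy_c16":
            d["d13c_c16"] = d.pop("d13c")
        else:
            d.pop("d13c_c18")
        rows.append(d)
    pd.DataFrame(rows).to_csv(
        path, sep=dialect.delimiter, index=False, encoding=dialect.encoding)


def write_tooth_series(teeth: Iterable[ToothSeries], enamel_path,
                       dentine_path=None,
                       dialect: TableDialect = TableDialect()) -> None:
    erows, drows = [], []
    for t in teeth:
        for e in t.enamel:
            erows.append({
                "tooth_id": t.tooth_id, "site_id": t.site_id,
                "crown_height": t.crown_height, "position_erj": e.position_erj,
                "d13c_bioap": e.d13c_bioap, "d18o_bioap": e.d18o_bioap,
            })
        for dn in t.dentine:
            drows.append({
                "tooth_id": t.tooth_id, "site_id": t.site_id,
                "crown_height": t.crown_height, "position_erj": dn.position_erj,
                "d15n_glx": dn.d15n_glx, "d15n_phe": dn.d15n_phe,
            })
    pd.DataFrame(erows).to_csv(enamel_path, sep=dialect.delimiter, index=False,
                               encoding=dialect.encoding)
    if dentine_path is not None:
        pd.DataFrame(drows).to_csv(dentine_path, sep=dialect.delimiter, index=False,
                                   encoding=dialect.encoding)


def write_validation_report(report: dict, path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
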