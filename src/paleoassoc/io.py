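"""Reading and writing occurrence tables, the printed-counts fixture, and
analysis reports.

The on-disk occurrence format is a strict UTF-8 comma-separated table with
the nine columns of :data:`CSV_COLUMNS`, booleans written ``true``/``false``
and an empty ``paralogy_group`` meaning "no group".
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from .records import (
    Epoch,
    OccurrenceRecord,
    Paleoenv,
    TaphCategory,
    Taxon,
    ValidationError,
    validate_records,
)

__all__ = [
    "CSV_COLUMNS",
    "SchemaError",
    "read_occurrences",
    "write_occurrences",
    "CountsFixture",
    "load_table1_fixture",
    "write_report",
    "read_report",
    "import_xlsx",
]

CSV_COLUMNS = (
    "occurrence_id",
    "locality_id",
    "taxon",
    "strat_unit",
    "epoch",
    "paleoenv",
    "taph_category",
    "dubious",
    "paralogy_group",
)

VARIANTS = ("I", "II", "III", "IV")


class SchemaError(ValueError):
    """The input file does not conform to the occurrence CSV schema."""


def _parse_enum(cls, raw: str, row_num: int, field_name: str):
    text = raw.strip()
    for member in cls:
        if text.lower() in (member.value.lower(), member.name.lower()):
            return member
    raise ValidationError(
        f"row {row_num}: invalid {field_name} value {raw!r} "
        f"(expected one of {[m.value for m in cls]})"
    )


def _parse_bool(raw: str, row_num: int, field_name: str) -> bool:
    text = raw.strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no", ""):
        return False
    raise ValidationError(f"row {row_num}: invalid {field_name} value {raw!r}")


def read_occurrences(path: Union[str, Path]) -> list[OccurrenceRecord]:
    """Read and validate an occurrence CSV.

    Raises :class:`SchemaError` when a required column is missing and
    :class:`~paleoassoc.records.ValidationError` on invalid enum values or
    duplicate occurrence ids, naming the offending row.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        records = []
        for row_num, row in enumerate(reader, start=2):
            group = (row.get("paralogy_group") or "").strip() or None
            records.append(
                OccurrenceRecord(
                    occurrence_id=row["occurrence_id"].strip(),
                    locality_id=row["locality_id"].strip(),
                    taxon=_parse_enum(Taxon, row["taxon"], row_num, "taxon"),
                    strat_unit=row["strat_unit"].strip(),
                    epoch=_parse_enum(Epoch, row["epoch"], row_num, "epoch"),
                    paleoenv=_parse_enum(Paleoenv, row["paleoenv"], row_num, "paleoenv"),
                    taph_category=_parse_enum(
                        TaphCategory, row["taph_category"], row_num, "taph_category"
                    ),
                    dubious=_parse_bool(row["dubious"], row_num, "dubious"),
                    paralogy_group=group,
                )
            )
    return validate_records(records)


def write_occurrences(records: Iterable[OccurrenceRecord], path: Union[str, Path]) -> None:
    """Write records in the standard occurrence CSV dialect."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            writer.writerow(
                [
                    rec.occurrence_id,
                    rec.locality_id,
                    rec.taxon.value,
                    rec.strat_unit,
                    rec.epoch.value,
                    rec.paleoenv.value,
                    rec.taph_category.value,
                    "true" if rec.dubious else "false",
                    rec.paralogy_group or "",
                ]
            )


# ---------------------------------------------------------------------------
# Printed-counts fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CountsFixture:
    """Published per-cell occurrence counts for the four dataset variants.

    Two blocks: per (taxon, taphonomic category, variant) coastal and
    terrestrial counts, and per (Cretaceous epoch, variant) counts used by
    the epoch-versus-environment design.  Marine occurrences are already
    excluded from these counts.
    """

    taxon_cells: Mapping[tuple[Taxon, TaphCategory, str, Paleoenv], int]
    epoch_cells: Mapping[tuple[Epoch, str, Paleoenv], int]

    def cell(
        self,
        taxon: Taxon,
        category: TaphCategory,
        variant: str,
        env: Paleoenv,
    ) -> int:
        return self.taxon_cells[(taxon, category, variant, env)]

    def epoch_cell(self, epoch: Epoch, variant: str, env: Paleoenv) -> int:
        return self.epoch_cells[(epoch, variant, env)]

    def taxon_env_total(self, taxon: Taxon, variant: str, env: Paleoenv) -> int:
        """Occurrences of a taxon in one environment, all categories."""
        return sum(
            self.taxon_cells[(taxon, cat, variant, env)] for cat in TaphCategory
        )

    def taxon_total(self, taxon: Taxon, variant: str = "I") -> int:
        """Coastal + terrestrial occurrences of a taxon in one variant."""
        return sum(
            self.taxon_env_total(taxon, variant, env)
            for env in (Paleoenv.COASTAL, Paleoenv.TERRESTRIAL)
        )

    def env_total(self, variant: str, env: Paleoenv) -> int:
        """All-taxa occurrences in one environment for one variant."""
        return sum(self.taxon_env_total(t, variant, env) for t in Taxon)


def load_table1_fixture() -> CountsFixture:
    """Load the packaged fixture of published dataset counts."""
    taxon_cells: dict = {}
    epoch_cells: dict = {}
    text = (
        resources.files("paleoassoc.data").joinpath("table1_counts.tsv").read_text()
    )
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        variant = row["variant"]
        c = int(row["coastal"])
        t = int(row["terrestrial"])
        if row["kind"] == "taxon":
            taxon = next(x for x in Taxon if x.value == row["group"])
            cat = next(x for x in TaphCategory if x.value == row["category"])
            taxon_cells[(taxon, cat, variant, Paleoenv.COASTAL)] = c
            taxon_cells[(taxon, cat, variant, Paleoenv.TERRESTRIAL)] = t
        else:
            epoch = next(x for x in Epoch if x.value == row["group"])
            epoch_cells[(epoch, variant, Paleoenv.COASTAL)] = c
            epoch_cells[(epoch, variant, Paleoenv.TERRESTRIAL)] = t
    return CountsFixture(taxon_cells=taxon_cells, epoch_cells=epoch_cells)


# ---------------------------------------------------------------------------
# Analysis reports
# ---------------------------------------------------------------------------

def _as_dict(result) -> dict:
    return result.to_dict() if hasattr(result, "to_dict") else dict(result)


REPORT_COLUMNS = (
    "test_id",
    "dataset",
    "skipped",
    "skip_reason",
    "statistic",
    "df",
    "p_asymptotic",
    "mc_used",
    "p_mc",
    "p_operative",
    "significant",
    "fisher_or",
    "fisher_p",
    "signs",
)


def _flatten_signs(signs: Optional[Mapping]) -> str:
    if not signs:
        return ""
    parts = []
    for (row, env), sign in signs.items():
        parts.append(f"{row}|{env}={sign}")
    return ";".join(parts)


def write_report(
    results: Sequence,
    path: Union[str, Path],
    format: str = "tsv",
) -> None:
    """Serialize battery results, one row per (test, dataset variant).

    ``format`` is ``"tsv"`` (flat table mirroring the published result
    tables) or ``"json"`` (lossless nested structure; re-reading with
    :func:`read_report` reproduces the input dictionaries).
    """
    if not results:
        raise ValueError("results must be non-empty")
    fmt = format.lower()
    path = Path(path)
    dicts = [_as_dict(r) for r in results]
    if fmt == "json":
        with path.open("w", encoding="utf-8") as fh:
            json.dump(dicts, fh, indent=1, sort_keys=False)
            fh.write("\n")
    elif fmt == "tsv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(REPORT_COLUMNS)
            for d in dicts:
                signs = {
                    (k.split("|")[0], k.split("|")[1]): v
                    for k, v in (d.get("signs") or {}).items()
                }
                writer.writerow(
                    [
                        d.get("test_id", ""),
                        d.get("dataset", ""),
                        d.get("skipped", False),
                        d.get("skip_reason") or "",
                        d.get("statistic", ""),
                        d.get("df", ""),
                        d.get("p_asymptotic", ""),
                        d.get("mc_used", ""),
                        d.get("p_mc", ""),
                        d.get("p_operative", ""),
                        d.get("significant", ""),
                        d.get("fisher_or", ""),
                        d.get("fisher_p", ""),
                        _flatten_signs(signs),
                    ]
                )
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: Union[str, Path]) -> list[dict]:
    """Read back a JSON report written by :func:`write_report`."""
    with Path(path).open(encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Optional spreadsheet importer (best effort; not on the tested path)
# ---------------------------------------------------------------------------

def import_xlsx(
    path: Union[str, Path],
    sheet: Optional[str] = None,
    column_map: Optional[Mapping[str, str]] = None,
) -> list[OccurrenceRecord]:
    """Best-effort import of an occurrence spreadsheet.

    Reads the first (or named) worksheet, maps headers onto the standard
    CSV schema via ``column_map`` (spreadsheet header -> schema field;
    identity by default) and validates as :func:`read_occurrences` does.
    Requires openpyxl (``pip install paleoassoc[xlsx]``).
    """
    import openpyxl  # lazy: optional dependency

    wb = openpyxl.load_workbook(str(path), read_only=True, data_only=True)
    ws = wb[sheet] if sheet else wb.worksheets[0]
    rows = ws.iter_rows(values_only=True)
    header = [str(h).strip() if h is not None else "" for h in next(rows)]
    column_map = dict(column_map or {})
    mapped = [column_map.get(h, h) for h in header]
    missing = [c for c in CSV_COLUMNS if c not in mapped]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    idx = {c: mapped.index(c) for c in CSV_COLUMNS}
    records = []
    for row_num, row in enumerate(rows, start=2):
        if row is None or all(v is None for v in row):
            continue

        def get(col: str) -> str:
            v = row[idx[col]]
            return "" if v is None else str(v)

        records.append(
            OccurrenceRecord(
                occurrence_id=get("occurrence_id").strip(),
                locality_id=get("locality_id").strip(),
                taxon=_parse_enum(Taxon, get("taxon"), row_num, "taxon"),
                strat_unit=get("strat_unit").strip(),
                epoch=_parse_enum(Epoch, get("epoch"), row_num, "epoch"),
                paleoenv=_parse_enum(Paleoenv, get("paleoenv"), row_num, "paleoenv"),
                taph_category=_parse_enum(
                    TaphCategory, get("taph_category"), row_num, "taph_category"
                ),
                dubious=_parse_bool(get("dubious"), row_num, "dubious"),
                paralogy_group=get("paralogy_group").strip() or None,
            )
        )
    return validate_records(records)
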