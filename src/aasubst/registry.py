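"""Catalog of substitution models: filtering, sorting, and on-disk layout.

The catalog persists as one model file per record plus a tab-separated
metadata table with columns ``name, kind, taxonomic_group, year, authors,
reference, comments`` — plain text, diffable, and sufficient for the query
surface (no indexed store is needed at catalog scale).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Callable, Iterable

from .models import (
    MatrixKind,
    ModelRecord,
    RateModel,
    ScoreModel,
    TaxonomicGroup,
)
from .paml import parse_paml, parse_score, write_paml, write_score

METADATA_COLUMNS = ("name", "kind", "taxonomic_group", "year", "authors", "reference", "comments")

_FILTERABLE = {"name", "kind", "taxonomic_group", "year", "authors", "reference", "comments"}


class CatalogError(ValueError):
    pass


def _field_value(record: ModelRecord, field: str):
    if field == "name":
        return record.name
    value = getattr(record, field)
    if isinstance(value, (MatrixKind, TaxonomicGroup)):
        return value.value
    return value


def filter_records(
    records: Iterable[ModelRecord],
    criteria: dict | None = None,
    sort_by: str | None = None,
    reverse: bool = False,
) -> list[ModelRecord]:
    """Select records matching every criterion, preserving input order.

    ``criteria`` maps a field name to either a plain value (equality, with
    enums matched by their string value), a predicate callable, or the
    pseudo-fields ``year_min`` / ``year_max`` for publication-year ranges.
    ``sort_by`` optionally orders the result by a single field.
    """
    criteria = dict(criteria or {})
    records = list(records)

    tests: list[Callable[[ModelRecord], bool]] = []
    for field, wanted in criteria.items():
        if field == "year_min":
            tests.append(lambda r, v=wanted: r.year >= v)
        elif field == "year_max":
            tests.append(lambda r, v=wanted: r.year <= v)
        elif field in _FILTERABLE:
            if callable(wanted):
                tests.append(lambda r, fn=wanted, f=field: fn(_field_value(r, f)))
            else:
                want = wanted.value if isinstance(wanted, (MatrixKind, TaxonomicGroup)) else wanted
                tests.append(lambda r, v=want, f=field: _field_value(r, f) == v)
        else:
            raise CatalogError(f"unknown filter field {field!r}")

    result = [r for r in records if all(t(r) for t in tests)]
    if sort_by is not None:
        if sort_by not in _FILTERABLE:
            raise CatalogError(f"unknown sort field {sort_by!r}")
        result = sorted(result, key=lambda r: _field_value(r, sort_by), reverse=reverse)
    return result


def save_catalog(records: Iterable[ModelRecord], out_dir: str | Path) -> Path:
    """Write a catalog directory: metadata TSV plus one matrix file per model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_path = out_dir / "metadata.tsv"
    with open(meta_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(METADATA_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.name, rec.kind.value, rec.taxonomic_group.value, rec.year,
                 rec.authors, rec.reference, rec.comments]
            )
            text = write_paml(rec.model) if rec.kind is MatrixKind.RATE else write_score(rec.model)
            (out_dir / f"{rec.name}.dat").write_text(text)
    return meta_path


def load_catalog(in_dir: str | Path, alphabet=None) -> list[ModelRecord]:
    """Load a catalog directory written by :func:`save_catalog`."""
    in_dir = Path(in_dir)
    meta_path = in_dir / "metadata.tsv"
    if not meta_path.exists():
        raise CatalogError(f"no metadata.tsv under {in_dir}")
    records: list[ModelRecord] = []
    with open(meta_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            path = in_dir / f"{row['name']}.dat"
            text = path.read_text()
            kind = MatrixKind(row["kind"])
            if kind is MatrixKind.RATE:
                kwargs = {} if alphabet is None else {"alphabet": alphabet}
                model: RateModel | ScoreModel = parse_paml(text, name=row["name"], **kwargs)
            else:
                model = parse_score(text, name=row["name"])
            records.append(
                ModelRecord(
                    model=model,
                    kind=kind,
                    taxonomic_group=TaxonomicGroup(row["taxonomic_group"]),
                    year=int(row["year"]),
                    authors=row["authors"],
                    reference=row["reference"],
                    comments=row["comments"],
                )
            )
    return records
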