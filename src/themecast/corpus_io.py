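"""Reading and writing article metadata.

Two input dialects are supported: Web of Science Core Collection field-tagged
plain-text exports and generic CSV tables. The writer emits the theme table —
the original record columns plus up to ten abstract-keyword columns (A1..A10)
and a final ``theme`` column — in a form that round-trips through
:func:`read_articles`.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConsistencyError, SchemaError

log = logging.getLogger(__name__)

#: WoS field tags understood by the tagged-format parser.
WOS_TAGS = {"PT", "AU", "TI", "AB", "DE", "ID", "C1", "PY", "TC", "DT", "CU"}

N_KEYWORD_COLUMNS = 10  # A1..A10


@dataclass
class ArticleRecord:
    """One publication's metadata.

    Keyword lists come from three sources: indexer-supplied terms
    (``keywords_plus``), author-supplied terms (``author_keywords``) and terms
    extracted from the title+abstract (``abstract_keywords``, filled by
    :mod:`themecast.keyword_sources`).
    """

    id: str
    title: str = ""
    abstract: str = ""
    author_keywords: list[str] = field(default_factory=list)
    keywords_plus: list[str] = field(default_factory=list)
    abstract_keywords: list[str] = field(default_factory=list)
    year: Optional[int] = None
    citations: int = 0
    countries: list[str] = field(default_factory=list)
    institutions: list[str] = field(default_factory=list)
    document_type: str = ""
    authors: list[str] = field(default_factory=list)
    departments: list[str] = field(default_factory=list)
    research_areas: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.citations < 0:
            raise ValueError(f"citations must be >= 0, got {self.citations}")
        if self.year is not None and not (1900 <= self.year <= 2100):
            raise ValueError(f"year out of range: {self.year}")
        for attr in ("author_keywords", "keywords_plus", "abstract_keywords"):
            setattr(self, attr, [k for k in getattr(self, attr) if k.strip()])


def _split_terms(cell: str) -> list[str]:
    return [t.strip() for t in str(cell).split(";") if t.strip()]


def _read_text(path: Path) -> str:
    raw = path.read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


# ---------------------------------------------------------------------------
# CSV dialect

_FIELD_ALIASES: dict[str, tuple[str, ...]] = {
    "id": ("id", "ut", "accession number"),
    "title": ("title", "ti", "article title"),
    "abstract": ("abstract", "ab"),
    "author_keywords": ("author_keywords", "author keywords", "de"),
    "keywords_plus": ("keywords_plus", "keywords plus", "id keywords", "keywords plus(r)"),
    "year": ("year", "py", "publication year"),
    "citations": ("citations", "tc", "times cited", "times cited, all databases"),
    "countries": ("countries", "country", "cu"),
    "institutions": ("institutions", "institution", "affiliations", "c1"),
    "document_type": ("document_type", "document type", "dt"),
    "authors": ("authors", "author", "au"),
    "departments": ("departments", "department"),
    "research_areas": ("research_areas", "research area", "research areas", "sc"),
}

_LIST_FIELDS = {
    "author_keywords", "keywords_plus", "countries", "institutions",
    "authors", "departments", "research_areas",
}


def _resolve_columns(header: Sequence[str],
                     column_map: Optional[Mapping[str, str]]) -> dict[str, str]:
    lower = {h.lower().strip(): h for h in header}
    resolved: dict[str, str] = {}
    for fld, aliases in _FIELD_ALIASES.items():
        if column_map and fld in column_map:
            resolved[fld] = column_map[fld]
            continue
        for alias in aliases:
            if alias in lower:
                resolved[fld] = lower[alias]
                break
    return resolved


def _records_from_rows(rows: list[dict[str, str]],
                       column_map: Optional[Mapping[str, str]]) -> list[ArticleRecord]:
    if not rows:
        return []
    header = list(rows[0].keys())
    cols = _resolve_columns(header, column_map)
    if "title" not in cols:
        raise SchemaError(
            "CSV has no resolvable title column (looked for "
            f"{_FIELD_ALIASES['title']}); available columns: {header}")

    records = []
    for i, row in enumerate(rows):
        kwargs: dict = {}
        for fld, col in cols.items():
            cell = row.get(col, "")
            cell = "" if cell is None else str(cell).strip()
            if fld in _LIST_FIELDS:
                kwargs[fld] = _split_terms(cell)
            elif fld == "year":
                kwargs[fld] = int(float(cell)) if cell else None
            elif fld == "citations":
                kwargs[fld] = int(float(cell)) if cell else 0
            else:
                kwargs[fld] = cell
        kwargs.setdefault("id", "")
        if not kwargs["id"]:
            kwargs["id"] = f"R{i + 1:05d}"
        # theme-table extras: A1..A10 abstract keyword columns
        abstract_kws = []
        for j in range(1, N_KEYWORD_COLUMNS + 1):
            cell = row.get(f"A{j}", "")
            cell = "" if cell is None else str(cell).strip()
            if cell:
                abstract_kws.append(cell)
        if abstract_kws:
            kwargs["abstract_keywords"] = abstract_kws
        records.append(ArticleRecord(**kwargs))
    return records


# ---------------------------------------------------------------------------
# WoS field-tagged dialect

def _parse_wos(text: str) -> list[ArticleRecord]:
    records: list[ArticleRecord] = []
    current: dict[str, list[str]] = {}
    tag = None
    n = 0

    def flush() -> None:
        nonlocal current, n
        if not current:
            return
        n += 1

        def joined(t: str) -> str:
            return " ".join(current.get(t, []))

        def listed(t: str) -> list[str]:
            return _split_terms("; ".join(current.get(t, [])))

        affiliations = current.get("C1", [])
        countries = listed("CU")
        if not countries:
            seen: list[str] = []
            for aff in affiliations:
                country = aff.rstrip(".").rsplit(",", 1)[-1].strip()
                if country and country not in seen:
                    seen.append(country)
            countries = seen
        year = joined("PY")
        cites = joined("TC")
        records.append(ArticleRecord(
            id=f"W{n:05d}",
            title=joined("TI"),
            abstract=joined("AB"),
            author_keywords=listed("DE"),
            keywords_plus=listed("ID"),
            year=int(year) if year.isdigit() else None,
            citations=int(cites) if cites.isdigit() else 0,
            countries=countries,
            institutions=[a for a in affiliations],
            document_type=joined("DT"),
            authors=listed("AU"),
        ))
        current = {}

    for line in text.splitlines():
        if not line.strip():
            continue
        head, rest = line[:2], line[3:] if len(line) > 3 else ""
        if head == "ER":
            flush()
            tag = None
        elif head in ("FN", "VR", "EF"):
            tag = None
        elif head == "  " and tag:  # continuation line
            current.setdefault(tag, []).append(line.strip())
        elif head.strip():
            if head in WOS_TAGS:
                tag = head
                current.setdefault(tag, []).append(rest.strip())
            else:
                log.debug("ignoring unknown WoS tag %r", head)
                tag = None
    flush()
    return records


# ---------------------------------------------------------------------------
# Public API

def read_articles(path: str | Path, format: str = "csv",
                  column_map: Optional[Mapping[str, str]] = None) -> list[ArticleRecord]:
    """Read article records from *path*.

    Parameters
    ----------
    format:
        ``"csv"`` for a comma-separated table with a header row, or
        ``"wos_tagged"`` for a WoS field-tagged plain-text export.
    column_map:
        Optional mapping from canonical field names (e.g. ``"title"``) to the
        CSV column names actually present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = _read_text(path)
    if format == "wos_tagged":
        return _parse_wos(text)
    if format == "csv":
        rows = list(csv.DictReader(text.splitlines()))
        return _records_from_rows(rows, column_map)
    raise ValueError(f"unknown format: {format!r}")


_BASE_COLUMNS = [
    "id", "title", "abstract", "author_keywords", "keywords_plus", "year",
    "citations", "countries", "institutions", "document_type", "authors",
    "departments", "research_areas",
]


def write_theme_table(records: Sequence[ArticleRecord],
                      assignments: Iterable,
                      path: str | Path) -> Path:
    """Write the theme table: record columns + A1..A10 + ``theme``.

    *assignments* is an iterable of objects with ``article_id`` and
    ``theme_label`` attributes (see :class:`themecast.taaa_core.ThemeAssignment`);
    records without an assignment get an empty theme cell.
    """
    by_id = {}
    known = {r.id for r in records}
    for a in assignments:
        if a.article_id not in known:
            raise ConsistencyError(f"assignment references unknown record id {a.article_id!r}")
        if a.article_id in by_id:
            raise ConsistencyError(f"record {a.article_id!r} has more than one assignment")
        by_id[a.article_id] = a

    path = Path(path)
    header = _BASE_COLUMNS + [f"A{j}" for j in range(1, N_KEYWORD_COLUMNS + 1)] + ["theme"]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for r in records:
            row = [
                r.id, r.title, r.abstract,
                "; ".join(r.author_keywords), "; ".join(r.keywords_plus),
                "" if r.year is None else r.year, r.citations,
                "; ".join(r.countries), "; ".join(r.institutions),
                r.document_type, "; ".join(r.authors),
                "; ".join(r.departments), "; ".join(r.research_areas),
            ]
            kws = r.abstract_keywords[:N_KEYWORD_COLUMNS]
            row += kws + [""] * (N_KEYWORD_COLUMNS - len(kws))
            a = by_id.get(r.id)
            row.append("" if a is None or a.theme_label is None else a.theme_label)
            writer.writerow(row)
    return path
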