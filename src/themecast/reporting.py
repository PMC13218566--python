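"""Summary reporting, leadership scoring and plot-ready data exports.

Figures themselves are out of scope: exports are the exact tabular data a
plotting front end (SankeyMATIC, a heatmap renderer, a network tool) needs.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .corpus_io import ArticleRecord
from .errors import ParameterError
from .numeric_mp import DEGSelection
from .taaa_core import ThemeAssignment, h_index

#: Leadership category bands on the advantage coefficient.
DC_BANDS = [(0.8, "super"), (0.7, "quasisuper"), (0.6, "strong"),
            (0.5, "moderate")]

DOMINANCE_THRESHOLD = 0.7


@dataclass
class LeadershipScore:
    """Advantage-coefficient leadership score of one entity.

    From the entity's top-three partner counts n1 >= n2 >= n3 the dominance
    ratio is r = (n1/n2)/(n2/n3) and the coefficient r/(1+r), banded into
    weak/moderate/strong/quasisuper/super with dominance at >= 0.7.
    """

    entity: str
    n1: int
    n2: int
    n3: int
    ratio: float
    coefficient: float
    category: str
    dominance: bool


def advantage_coefficient(n1: float, n2: float, n3: float,
                          entity: str = "") -> LeadershipScore:
    """Leadership score from sorted top-three counts (n1 >= n2 >= n3 > 0)."""
    if min(n1, n2, n3) <= 0:
        raise ParameterError("counts must be positive")
    if not (n1 >= n2 >= n3):
        raise ParameterError(f"counts must be sorted descending, got {(n1, n2, n3)}")
    r = (n1 / n2) / (n2 / n3)
    coef = r / (1.0 + r)
    category = "weak"
    for cutoff, name in DC_BANDS:
        if coef >= cutoff:
            category = name
            break
    return LeadershipScore(entity, n1, n2, n3, r, coef, category,
                           coef >= DOMINANCE_THRESHOLD)


def _top_counts(values: Iterable[str], top: int) -> pd.DataFrame:
    cnt = Counter(v for v in values if v)
    rows = sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    return pd.DataFrame(rows, columns=["value", "count"])


def summary_report(records: Sequence[ArticleRecord],
                   assignments: Optional[Sequence[ThemeAssignment]] = None,
                   top: int = 10) -> dict:
    """Top-``top`` tables for the ten key metadata elements plus the journal
    h-index: country, institution, department, year, article type, author,
    research area, keyword, most-cited articles, and theme."""
    def flat(attr: str) -> list[str]:
        return [v for r in records for v in getattr(r, attr)]

    cited = sorted(records, key=lambda r: (-r.citations, r.id))[:top]
    report = {
        "country": _top_counts(flat("countries"), top),
        "institution": _top_counts(flat("institutions"), top),
        "department": _top_counts(flat("departments"), top),
        "year": _top_counts((str(r.year) for r in records if r.year), top),
        "article_type": _top_counts((r.document_type for r in records), top),
        "author": _top_counts(flat("authors"), top),
        "research_area": _top_counts(flat("research_areas"), top),
        "keyword": _top_counts(
            (k for r in records for k in r.author_keywords + r.keywords_plus), top),
        "top_cited": pd.DataFrame(
            [{"id": r.id, "title": r.title, "citations": r.citations} for r in cited]),
        "journal_h_index": h_index(r.citations for r in records),
    }
    if assignments is not None:
        report["theme"] = _top_counts(
            (a.theme_label for a in assignments if a.theme_label), top)
    return report


def write_summary_report(report: dict, path: str | Path) -> Path:
    """Serialize a summary report to JSON (tables as records)."""
    payload = {k: (v.to_dict(orient="records") if isinstance(v, pd.DataFrame) else v)
               for k, v in report.items()}
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    return path


def export_flows(pairs: Iterable[tuple[str, str]]) -> tuple[str, pd.DataFrame]:
    """Sankey flow export from a two-column co-occurrence table.

    Returns the SankeyMATIC-dialect text (``source [count] target`` lines)
    and a companion edge-list DataFrame for network charts; both carry the
    raw pair frequencies, ordered by count (descending) then labels.
    """
    cnt = Counter((str(a), str(b)) for a, b in pairs)
    if not cnt:
        raise ParameterError("no pairs to export")
    rows = sorted(cnt.items(), key=lambda kv: (-kv[1], kv[0]))
    lines = [f"{a} [{n}] {b}" for (a, b), n in rows]
    edges = pd.DataFrame([{"source": a, "target": b, "count": n}
                          for (a, b), n in rows])
    return "\n".join(lines) + "\n", edges


def export_heatmap(matrix: pd.DataFrame, selection: DEGSelection,
                   assignments: Sequence[ThemeAssignment],
                   true_label: Optional[Sequence] = None) -> dict:
    """Plot-ready dual-heatmap data: the core-term submatrix with rows
    ordered by direction then |log10FC| and columns (persons) ordered by
    theme then label, plus the theme/label annotation tracks."""
    core = [t for t in selection.core_terms if t in matrix.index]
    if not core:
        raise ParameterError("empty core term set")
    st = selection.stats.set_index("item")
    row_order = sorted(
        core,
        key=lambda t: (0 if st.loc[t, "direction"] == "up" else 1,
                       -abs(st.loc[t, "log10_fc"]), t))

    theme_of = {a.article_id: a.theme for a in assignments}
    persons = [str(p) for p in matrix.columns]
    labels = dict(zip(persons, true_label)) if true_label is not None else {}

    def col_key(p: str):
        theme = theme_of.get(p)
        return (theme is None, -1 if theme is None else theme,
                str(labels.get(p, "")), p)

    col_order = sorted(persons, key=col_key)
    ordered = matrix.loc[row_order, col_order]
    return {
        "matrix": ordered,
        "row_order": row_order,
        "col_order": col_order,
        "theme_track": [theme_of.get(p) for p in col_order],
        "label_track": [labels.get(p) for p in col_order] if labels else None,
    }
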