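"""Mode-based article-level theme assignment and core-theme identification.

Each article's keywords map to clusters of the chosen solution; the article's
theme is the statistical mode of those cluster ids, with ties broken toward
the smallest id so assignment is deterministic. Core themes are the themes
whose articles participate in the journal's h-core.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .corpus_io import ArticleRecord
from .coword_cluster import ClusterSolution
from .keyword_sources import record_terms


@dataclass
class ThemeAssignment:
    """Per-article candidate-cluster frequencies and the assigned theme."""

    article_id: str
    candidate_freqs: dict[int, int] = field(default_factory=dict)
    theme: Optional[int] = None
    theme_label: Optional[str] = None


def _is_missing(x) -> bool:
    if x is None or x == "":
        return True
    return isinstance(x, float) and math.isnan(x)


def assign_theme(cluster_ids: Iterable) -> Optional[int]:
    """Dominant cluster id (statistical mode) of a multiset of cluster ids.

    Blank and missing entries are removed first; if nothing remains the
    result is missing (``None``). Among the ids attaining the maximal
    frequency, the smallest id is returned, which makes the rule
    deterministic for every tie pattern (including the all-equal case).
    """
    freq = Counter(int(c) for c in cluster_ids if not _is_missing(c))
    if not freq:
        return None
    best = max(freq.values())
    return min(k for k, v in freq.items() if v == best)


def assign_terms(article_id: str, terms: Sequence[str],
                 solution: ClusterSolution) -> ThemeAssignment:
    """Assignment for one document given its (canonical) term list."""
    ids = [solution.membership[t] for t in terms if t in solution.membership]
    freqs = dict(Counter(ids))
    theme = assign_theme(ids)
    label = solution.leaders[theme] if theme is not None else None
    return ThemeAssignment(article_id, freqs, theme, label)


def assign_all(records: Sequence[ArticleRecord], solution: ClusterSolution,
               source: str) -> list[ThemeAssignment]:
    """Theme assignment for every record, from one keyword source.

    Keywords absent from the cluster solution are ignored; records with no
    mapped keyword get a missing theme (see :func:`coverage`).
    """
    return [assign_terms(r.id, record_terms(r, source), solution) for r in records]


def coverage(assignments: Sequence[ThemeAssignment]) -> int:
    """Number of articles that received a (non-missing) theme."""
    return sum(1 for a in assignments if a.theme is not None)


def h_index(citations: Iterable[int]) -> int:
    """Largest h such that at least h items have >= h citations."""
    ranked = sorted((int(c) for c in citations), reverse=True)
    h = 0
    for i, c in enumerate(ranked, start=1):
        if c >= i:
            h = i
        else:
            break
    return h


@dataclass
class ThemeCoreReport:
    """Per-theme article counts, h-indices and core flags."""

    per_theme: pd.DataFrame  # theme, label, n_articles, h_index, core
    journal_h: int


def theme_h_index(assignments: Sequence[ThemeAssignment],
                  citations: Mapping[str, int]) -> ThemeCoreReport:
    """h-index per theme plus the journal h-index over all articles.

    A theme is flagged *core* when it contains at least one article in the
    journal's h-core, i.e. an article with citations >= the journal h-index.
    Themes are ranked by (h desc, article count desc, label asc).
    """
    journal_h = h_index(citations[a.article_id] for a in assignments)
    rows = []
    themed = [a for a in assignments if a.theme is not None]
    for theme in sorted({a.theme for a in themed}):
        cites = [int(citations[a.article_id]) for a in themed if a.theme == theme]
        label = next(a.theme_label for a in themed if a.theme == theme)
        rows.append({
            "theme": theme,
            "label": "" if label is None else label,
            "n_articles": len(cites),
            "h_index": h_index(cites),
            "core": any(c >= journal_h for c in cites) and journal_h > 0,
        })
    df = pd.DataFrame(rows, columns=["theme", "label", "n_articles", "h_index", "core"])
    if len(df):
        df = df.sort_values(["h_index", "n_articles", "label"],
                            ascending=[False, False, True]).reset_index(drop=True)
    return ThemeCoreReport(df, journal_h)


def core_themes(report: ThemeCoreReport) -> set[str]:
    """Labels of the core themes in a :class:`ThemeCoreReport`."""
    df = report.per_theme
    return set(df.loc[df["core"], "label"])


def core_overlap(set_a: set, set_b: set, set_c: set) -> dict[str, set]:
    """All seven Venn regions of three core-theme sets.

    The regions partition the union; the triple intersection is returned both
    as ``"abc"`` and under the alias ``"common"`` (the cross-source common
    core).
    """
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    regions = {
        "a_only": a - b - c,
        "b_only": b - a - c,
        "c_only": c - a - b,
        "ab": (a & b) - c,
        "ac": (a & c) - b,
        "bc": (b & c) - a,
        "abc": abc,
    }
    regions["common"] = abc
    return regions
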