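"""Per-article term lists from the three keyword sources.

Sources are indexer keywords ("keywords plus"), author keywords and terms
extracted automatically from the title+abstract. All three feed the same
term-document structure used downstream for co-word analysis.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .corpus_io import ArticleRecord
from .errors import EmptyMatrixError, ParameterError

_WS = re.compile(r"\s+")
_TOKEN = re.compile(r"[A-Za-z0-9]+")
_EDGE_PUNCT = " \t\n\r!\"#$%&'()*+,-./:;<=>?@[\\]^_`{|}~"

# A compact standard English stopword list (function words only) plus the
# structured-abstract boilerplate that dominates biomedical abstracts.
_ENGLISH_STOPWORDS = """
a about above after again against all am an and any are as at be because been
before being below between both but by can cannot could did do does doing down
during each few for from further had has have having he her here hers herself
him himself his how i if in into is it its itself just me more most my myself
no nor not now of off on once only or other our ours ourselves out over own
same she should so some such than that the their theirs them themselves then
there these they this those through to too under until up very was we were
what when where which while who whom why will with would you your yours
yourself yourselves
""".split()

_BOILERPLATE = {"BACKGROUND", "METHODS", "RESULTS", "CONCLUSIONS", "OBJECTIVE", "STUDY"}

DEFAULT_STOPWORDS: frozenset[str] = frozenset(
    {w.upper() for w in _ENGLISH_STOPWORDS} | _BOILERPLATE)

SOURCES = ("keywords_plus", "author", "abstract")

_SOURCE_ATTR = {
    "keywords_plus": "keywords_plus",
    "plus": "keywords_plus",
    "author": "author_keywords",
    "abstract": "abstract_keywords",
}


def canonicalize(term: str) -> str:
    """Canonical form of a raw keyword: uppercase, single internal spaces,
    edge punctuation stripped (internal hyphens preserved). Idempotent."""
    t = _WS.sub(" ", str(term)).strip()
    t = t.strip(_EDGE_PUNCT).upper()
    return _WS.sub(" ", t).strip()


def _valid_token(tok: str, stopwords: frozenset[str]) -> bool:
    return len(tok) >= 3 and not tok.isdigit() and tok not in stopwords


def extract_abstract_keywords(record: ArticleRecord, k: int = 10,
                              stopwords: Optional[Iterable[str]] = None) -> list[str]:
    """Top-*k* unigram/bigram terms from the article's title+abstract.

    Tokenization splits on non-alphanumeric boundaries; stopwords, tokens
    shorter than 3 characters and pure numbers are dropped. Bigrams are formed
    from adjacent surviving tokens. Ranking is by frequency (descending) with
    first appearance as the tie-break, so the result is deterministic.
    Returns an empty list when no usable text remains.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    stop = DEFAULT_STOPWORDS if stopwords is None else frozenset(
        canonicalize(s) for s in stopwords)
    text = f"{record.title} {record.abstract}"
    tokens = [t.upper() for t in _TOKEN.findall(text)]
    if not tokens:
        return []

    counts: Counter[str] = Counter()
    first_pos: dict[str, int] = {}
    pos = 0
    prev_valid: Optional[str] = None
    for tok in tokens:
        ok = _valid_token(tok, stop)
        if ok:
            counts[tok] += 1
            first_pos.setdefault(tok, pos)
            pos += 1
            if prev_valid is not None:
                bigram = f"{prev_valid} {tok}"
                counts[bigram] += 1
                first_pos.setdefault(bigram, pos)
            prev_valid = tok
        else:
            prev_valid = None
    if not counts:
        return []
    ranked = sorted(counts, key=lambda t: (-counts[t], first_pos[t]))
    return ranked[:k]


def load_stopwords(path) -> frozenset[str]:
    """Read a stopword file: one term per line, ``#`` starts a comment."""
    terms = set()
    for line in open(path, encoding="utf-8"):
        line = line.split("#", 1)[0].strip()
        if line:
            terms.add(canonicalize(line))
    return frozenset(terms)


@dataclass
class TermDocMatrix:
    """Sparse term-by-document count structure for one keyword source."""

    terms: list[str]
    docs: list[str]
    counts: dict[str, Counter] = field(repr=False)  # term -> doc -> count
    source: str = "author"

    def doc_frequency(self, term: str) -> int:
        return len(self.counts.get(term, ()))

    def doc_set(self, term: str) -> frozenset[str]:
        return frozenset(self.counts.get(term, ()))

    def total_mass(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())

    def doc_terms(self) -> dict[str, list[str]]:
        """Per-document term lists with multiplicity (inverse view)."""
        out: dict[str, list[str]] = {d: [] for d in self.docs}
        for term in self.terms:
            for doc, c in self.counts[term].items():
                out[doc].extend([term] * c)
        return out


def record_terms(record: ArticleRecord, source: str) -> list[str]:
    """Canonicalized keyword list of *record* for the given source."""
    try:
        attr = _SOURCE_ATTR[source]
    except KeyError:
        raise ParameterError(f"unknown source {source!r}; expected one of {SOURCES}")
    return [c for c in (canonicalize(t) for t in getattr(record, attr)) if c]


def build_term_doc(records: Sequence[ArticleRecord], source: str,
                   min_df: int = 1) -> TermDocMatrix:
    """Term-document count matrix over *records* for one keyword source.

    Terms with document frequency below *min_df* are removed; an error is
    raised if no record contributes any term at all.
    """
    counts: dict[str, Counter] = {}
    order: list[str] = []
    for r in records:
        for term in record_terms(r, source):
            if term not in counts:
                counts[term] = Counter()
                order.append(term)
            counts[term][r.id] += 1
    if not counts:
        raise EmptyMatrixError(f"no record has any {source!r} term")
    kept = [t for t in order if len(counts[t]) >= min_df]
    if not kept:
        raise EmptyMatrixError(f"min_df={min_df} removed every term")
    return TermDocMatrix(
        terms=kept,
        docs=[r.id for r in records],
        counts={t: counts[t] for t in kept},
        source=_SOURCE_ATTR[source].replace("author_keywords", "author")
               .replace("abstract_keywords", "abstract"),
    )
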