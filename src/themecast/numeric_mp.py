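"""The numeric-to-theme branch with mapping power.

A person-by-item numeric panel is dichotomized at each item's mean, the
positive cells become "Y<item>" tokens that play the role of keywords, the
token co-occurrence graph is clustered into two testlets, and each person is
assigned the dominant testlet by the same mode rule used for articles.
Mapping power (MP) is Cohen kappa between the resulting two-cluster person
themes and an external binary true label, after choosing the theme-to-label
bijection with the higher observed agreement (cluster ids are arbitrary, so
without alignment the sign of kappa would be too).

The module also carries the differential-expression analogy used for dual
heatmaps: two-group Welch tests and log10 fold changes per item, with the
top-10 up- and downregulated items under each criterion forming the core
term set.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coword_cluster import build_coword_graph, flca_cluster
from .errors import ParameterError
from .keyword_sources import TermDocMatrix, canonicalize
from .taaa_core import ThemeAssignment, assign_terms


@dataclass
class NumericPanel:
    """A persons-by-items real matrix with an optional binary true label."""

    persons: list[str]
    items: list[str]
    values: np.ndarray                      # shape (n_persons, n_items)
    true_label: Optional[np.ndarray] = None
    item_means: Optional[np.ndarray] = None  # filled by dichotomize()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.persons), len(self.items)):
            raise ParameterError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.persons)} persons x {len(self.items)} items")
        if self.true_label is not None:
            self.true_label = np.asarray(self.true_label)
            if self.true_label.shape[0] != len(self.persons):
                raise ParameterError("true_label length must equal n_persons")

    @classmethod
    def from_csv(cls, path, true_label_col: str = "TRUE_LABEL") -> "NumericPanel":
        df = pd.read_csv(path, index_col=0)
        label = None
        if true_label_col in df.columns:
            label = df[true_label_col].to_numpy()
            df = df.drop(columns=[true_label_col])
        return cls([str(p) for p in df.index], [str(c) for c in df.columns],
                   df.to_numpy(float), label)


def dichotomize(panel: NumericPanel) -> NumericPanel:
    """Binary panel: cell = 1 iff the value strictly exceeds its item mean.

    Constant items become all-zero columns (with a warning); the per-item
    means used as thresholds are recorded on the result.
    """
    if len(panel.persons) < 2:
        raise ParameterError("need at least 2 persons to dichotomize")
    means = panel.values.mean(axis=0)
    constant = panel.values.std(axis=0) == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant item(s) dichotomize to all zeros")
    binary = (panel.values > means).astype(float)
    return NumericPanel(list(panel.persons), list(panel.items), binary,
                        panel.true_label, item_means=means)


def tokenize_and_occur(binary: NumericPanel) -> TermDocMatrix:
    """Person-documents over Y-tokens: token ``Y<item>`` present iff cell = 1.

    N-type tokens are discarded; persons with no positive cell keep an empty
    document (they will later get a missing theme).
    """
    vals = binary.values
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ParameterError("tokenize_and_occur expects a binary panel")
    counts: dict[str, Counter] = {}
    terms: list[str] = []
    for j, item in enumerate(binary.items):
        token = canonicalize(f"Y{item}")
        docs = Counter({binary.persons[i]: 1 for i in np.nonzero(vals[:, j])[0]})
        if docs:
            counts[token] = docs
            terms.append(token)
    return TermDocMatrix(terms=terms, docs=list(binary.persons),
                         counts=counts, source="numeric")


def person_tokens(binary: NumericPanel) -> dict[str, list[str]]:
    """Per-person Y-token lists (the person's simulated keyword list)."""
    out: dict[str, list[str]] = {}
    for i, person in enumerate(binary.persons):
        out[person] = [canonicalize(f"Y{binary.items[j]}")
                       for j in np.nonzero(binary.values[i])[0]]
    return out


def numeric_to_theme(panel: NumericPanel, target_clusters: int = 2,
                     tau: float = 0.1) -> list[ThemeAssignment]:
    """Full numeric-to-theme pipeline: dichotomize, tokenize, cluster the
    Y-token co-occurrence graph into ``target_clusters`` testlets, and assign
    each person the dominant testlet. Deterministic."""
    binary = dichotomize(panel)
    tdm = tokenize_and_occur(binary)
    graph = build_coword_graph(tdm)
    solution = flca_cluster(graph, tau=tau,
                            target_clusters=min(target_clusters, len(graph)))
    tokens = person_tokens(binary)
    return [assign_terms(p, tokens[p], solution) for p in binary.persons]


@dataclass
class MappingPowerResult:
    """Mapping power: aligned-kappa agreement of person themes with a label."""

    mp: float                      # Cohen kappa after best alignment
    mapping: dict[int, object]     # theme id -> label value
    report: object                 # AgreementReport of the aligned comparison
    n_excluded: int = 0            # persons without a theme


def mapping_power(assignments: Sequence[ThemeAssignment],
                  true_label: Sequence) -> MappingPowerResult:
    """Cohen kappa between two-cluster person themes and a binary label.

    Both theme-to-label bijections are evaluated and the one with the higher
    observed agreement kept; its kappa is the mapping power. Persons with a
    missing theme are excluded and counted.
    """
    from .agreement_validation import cohen_kappa  # local import avoids a cycle

    if len(assignments) != len(true_label):
        raise ParameterError("assignments and true_label must have equal length")
    pairs = [(a.theme, l) for a, l in zip(assignments, true_label) if a.theme is not None]
    n_excluded = len(assignments) - len(pairs)
    if not pairs:
        raise ParameterError("no person received a theme")
    themes = sorted({t for t, _ in pairs})
    labels = sorted({l for _, l in pairs}, key=str)
    if len(themes) > 2:
        raise ParameterError(
            f"{len(themes)} themes present; rerun the clustering with target_clusters=2")
    if len(labels) > 2:
        raise ParameterError("true_label must be binary")

    best = None
    orders = [labels, labels[::-1]] if len(labels) == 2 else [labels]
    for order in orders:
        mapping = {t: order[i % len(order)] for i, t in enumerate(themes)}
        predicted = [mapping[t] for t, _ in pairs]
        actual = [l for _, l in pairs]
        report = cohen_kappa(predicted, actual)
        if best is None or report.po > best[1].po:
            best = (mapping, report)
    mapping, report = best
    return MappingPowerResult(mp=report.kappa, mapping=mapping,
                              report=report, n_excluded=n_excluded)


# ---------------------------------------------------------------------------
# Differential-expression analogy

@dataclass
class DEGSelection:
    """Two-criterion top-item selection (p-value and fold change)."""

    stats: pd.DataFrame                 # item, p_value, log10_fc, direction
    selected_by_p: list[str] = field(default_factory=list)
    selected_by_fc: list[str] = field(default_factory=list)

    @property
    def core_terms(self) -> list[str]:
        seen, out = set(), []
        for t in self.selected_by_p + self.selected_by_fc:
            if t not in seen:
                seen.add(t)
                out.append(t)
        return out


def deg_select(values: np.ndarray, groups: Sequence, items: Sequence[str],
               top_n: int = 10, pseudocount: float = 0.5) -> DEGSelection:
    """Two-group differential selection of items.

    Per item: a Welch two-sample t-test between the groups and a fold change
    ``(mean_high + pseudocount) / (mean_low + pseudocount)`` on the log10
    scale, where *high* is the lexically larger group label. Direction is
    "up" when log10FC > 0 and "down" when < 0; items with identical group
    means belong to neither pool. ``selected_by_p`` holds the top-``top_n``
    up and down items by p-value, ``selected_by_fc`` the same by |log10FC|;
    their union is the core term set.
    """
    values = np.asarray(values, float)
    groups = np.asarray(groups)
    levels = sorted(set(groups.tolist()), key=str)
    if len(levels) != 2:
        raise ParameterError(f"need exactly 2 groups, got {levels}")
    lo, hi = levels
    a = values[groups == hi]   # "case" group
    b = values[groups == lo]   # "reference" group
    if len(a) == 0 or len(b) == 0:
        raise ParameterError("both groups must be non-empty")

    rows = []
    for j, item in enumerate(items):
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"group of size 1: item {item!r} excluded (p undefined)")
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = stats.ttest_ind(a[:, j], b[:, j], equal_var=False).pvalue
        p = 1.0 if np.isnan(p) else float(p)
        ma, mb = a[:, j].mean(), b[:, j].mean()
        if ma < 0 or mb < 0:
            # the ratio fold change is meant for non-negative scales
            # (presence counts, expression intensities); floor at zero
            warnings.warn(f"negative group mean for item {item!r}; "
                          "fold change floored at the pseudocount")
            ma, mb = max(ma, 0.0), max(mb, 0.0)
        fc = float(np.log10((ma + pseudocount) / (mb + pseudocount)))
        direction = "up" if fc > 0 else ("down" if fc < 0 else "flat")
        rows.append({"item": str(item), "p_value": p, "log10_fc": fc,
                     "direction": direction})
    df = pd.DataFrame(rows, columns=["item", "p_value", "log10_fc", "direction"])

    def top(pool: pd.DataFrame, by_p: bool) -> list[str]:
        if by_p:
            pool = pool.sort_values("item").sort_values("p_value", kind="stable")
        else:
            pool = pool.assign(absfc=pool["log10_fc"].abs())
            pool = pool.sort_values("item").sort_values("absfc", kind="stable",
                                                        ascending=False)
        return pool["item"].head(top_n).tolist()

    up = df[df["direction"] == "up"]
    down = df[df["direction"] == "down"]
    by_p = top(up, True) + top(down, True)
    by_fc = top(up, False) + top(down, False)
    return DEGSelection(stats=df, selected_by_p=by_p, selected_by_fc=by_fc)


def binarize_presence(term_matrix: pd.DataFrame) -> pd.DataFrame:
    """Binarize a terms-by-persons matrix: 1 iff the term's value for that
    person strictly exceeds the term's mean across persons (the same strict
    convention as :func:`dichotomize`, applied to the transposed layout)."""
    values = term_matrix.to_numpy(float)
    means = values.mean(axis=1, keepdims=True)
    return pd.DataFrame((values > means).astype(int),
                        index=term_matrix.index, columns=term_matrix.columns)


@dataclass
class PairedTResult:
    t: float
    p: float
    degenerate: bool = False


def paired_t_within(scores_a: Sequence[float], scores_b: Sequence[float]) -> PairedTResult:
    """Two-sided paired t-test between matched per-person testlet scores.

    A zero-variance difference vector (including identical inputs) cannot
    support a t-test and is flagged degenerate instead of erroring."""
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ParameterError("need two matched 1-d vectors of length >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return PairedTResult(t=float("nan"), p=float("nan"), degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue))
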