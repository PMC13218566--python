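"""Agreement and stability validation.

Cohen kappa with the conventional qualitative bands, plurality collapse of a
fine partition onto a coarse one, top-k hierarchical concordance between two
theme assignments, and resampling stability (bootstrap and random holdout)
summarized by Jensen-Shannon distance and Spearman rank correlation of the
theme-proportion profiles.
"""

from __future__ import annotations

import csv
import math
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr

from .coword_cluster import ClusterSolution
from .errors import ParameterError, TermUniverseError
from .taaa_core import ThemeAssignment

#: Qualitative interpretation bands for kappa (upper bounds, inclusive).
KAPPA_BANDS = [
    (0.00, "poor"),        # kappa < 0
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
]


def kappa_band(kappa: float) -> str:
    if kappa < 0:
        return "poor"
    for upper, name in KAPPA_BANDS[1:]:
        if kappa <= upper + 1e-12:
            return name
    return "almost perfect"


@dataclass
class AgreementReport:
    """Confusion matrix, observed/expected agreement, kappa and its band."""

    labels: list
    confusion: np.ndarray
    n: int
    po: float
    pe: float
    kappa: float
    band: str


def _report_from_confusion(matrix: np.ndarray, labels: Sequence) -> AgreementReport:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ParameterError(f"confusion matrix must be square, got {matrix.shape}")
    n = matrix.sum()
    if n <= 0:
        raise ParameterError("empty confusion matrix")
    po = np.trace(matrix) / n
    pe = float((matrix.sum(axis=1) * matrix.sum(axis=0)).sum()) / n ** 2
    if pe >= 1.0 - 1e-15:
        # degenerate: a single label on both sides
        kappa = 1.0 if po >= 1.0 - 1e-15 else float("nan")
    else:
        kappa = (po - pe) / (1.0 - pe)
    return AgreementReport(list(labels), matrix, int(round(n)), float(po),
                           float(pe), float(kappa), kappa_band(kappa))


def cohen_kappa(labels_a: Union[Sequence, np.ndarray, None] = None,
                labels_b: Optional[Sequence] = None,
                *, confusion: Optional[np.ndarray] = None,
                labels: Optional[Sequence] = None) -> AgreementReport:
    """Unweighted Cohen kappa between two raters.

    Either pass two equal-length label sequences, or a pre-built square
    confusion matrix (with optional label names) — the latter allows direct
    entry of published matrices.
    """
    if confusion is not None:
        lab = labels if labels is not None else list(range(np.asarray(confusion).shape[0]))
        return _report_from_confusion(confusion, lab)
    if labels_a is None or labels_b is None:
        raise ParameterError("need two label sequences or a confusion matrix")
    a, b = list(labels_a), list(labels_b)
    if len(a) != len(b):
        raise ParameterError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ParameterError("empty label sequences")
    lab = sorted(set(a) | set(b), key=str)
    idx = {l: i for i, l in enumerate(lab)}
    m = np.zeros((len(lab), len(lab)))
    for x, y in zip(a, b):
        m[idx[x], idx[y]] += 1
    return _report_from_confusion(m, lab)


def read_confusion_csv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a confusion matrix CSV with a header row and label column."""
    rows = list(csv.reader(open(path, encoding="utf-8")))
    labels = [c.strip() for c in rows[0][1:]]
    matrix = np.array([[float(c) for c in r[1:]] for r in rows[1:]])
    return matrix, labels


def write_confusion_csv(report: AgreementReport, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow([""] + [str(l) for l in report.labels])
        for label, row in zip(report.labels, report.confusion):
            w.writerow([str(label)] + [int(v) for v in row])
    return path


# ---------------------------------------------------------------------------
# Partition comparison

def majority_overlap_map(fine: ClusterSolution, coarse: ClusterSolution) -> dict[int, int]:
    """Map each fine cluster to the coarse cluster holding the plurality of
    its terms (ties toward the smaller coarse id)."""
    fine_terms, coarse_terms = set(fine.membership), set(coarse.membership)
    if fine_terms != coarse_terms:
        diff = sorted(fine_terms ^ coarse_terms)
        raise TermUniverseError(f"term universes differ; symmetric difference: {diff}")
    mapping: dict[int, int] = {}
    for cid in sorted(fine.leaders):
        tally = Counter(coarse.membership[t] for t in fine.members(cid))
        best = max(tally.values())
        mapping[cid] = min(c for c, v in tally.items() if v == best)
    return mapping


def _theme_map(assignments) -> dict[str, Optional[int]]:
    if isinstance(assignments, Mapping):
        return dict(assignments)
    return {a.article_id: a.theme for a in assignments}


@dataclass
class ConcordanceResult:
    fraction: float
    agree: int
    denom: int


def topk_concordance(fine_assignments, coarse_assignments, k: int) -> ConcordanceResult:
    """Fraction of articles whose fine theme is among the top-k most frequent
    fine themes within their coarse community.

    Accepts lists of :class:`ThemeAssignment` or ``{article_id: theme}``
    mappings. Articles with a missing theme on either side are excluded from
    the denominator. Ties in the within-community frequency ranking are
    broken toward the smaller fine id.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    fine = _theme_map(fine_assignments)
    coarse = _theme_map(coarse_assignments)
    ids = [i for i in fine if i in coarse
           and fine[i] is not None and coarse[i] is not None]
    by_comm: dict[int, Counter] = {}
    for i in ids:
        by_comm.setdefault(coarse[i], Counter())[fine[i]] += 1
    topk = {
        comm: set(sorted(cnt, key=lambda t: (-cnt[t], t))[:k])
        for comm, cnt in by_comm.items()
    }
    agree = sum(1 for i in ids if fine[i] in topk[coarse[i]])
    denom = len(ids)
    return ConcordanceResult(agree / denom if denom else float("nan"), agree, denom)


# ---------------------------------------------------------------------------
# Resampling stability

def js_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Jensen-Shannon distance (base-2 logs, bounded in [0, 1])."""
    d = float(jensenshannon(np.asarray(p, float), np.asarray(q, float), base=2))
    return 0.0 if math.isnan(d) else d


@dataclass
class StabilityReport:
    """Resampling summary: JS distance and Spearman correlation statistics."""

    repetitions: int
    core_theme_count: int
    js_mean: float
    js_sd: float
    spearman_mean: float
    spearman_sd: float
    kappa_interval: Optional[tuple[float, float]] = None
    skipped: int = 0


def _themes_of(assignments) -> list:
    if assignments and isinstance(assignments[0], ThemeAssignment):
        return [a.theme for a in assignments if a.theme is not None]
    return [t for t in assignments if t is not None]


def _proportions(themes: Sequence, universe: Sequence) -> np.ndarray:
    cnt = Counter(themes)
    total = sum(cnt.values())
    if total == 0:
        return np.full(len(universe), np.nan)
    return np.array([cnt.get(t, 0) / total for t in universe], float)


def _spearman(p: np.ndarray, q: np.ndarray) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = spearmanr(p, q).statistic
    return float(rho)


def bootstrap_stability(assignments, reps: int = 120, seed: Optional[int] = None,
                        reference_labels: Optional[Sequence] = None) -> StabilityReport:
    """Bootstrap (resampling with replacement) stability of theme proportions.

    Each repetition resamples the themed articles with replacement at the
    original size, and compares the resampled theme-proportion vector to the
    full-sample reference by JS distance and Spearman rank correlation.
    When *reference_labels* (a paired second rater per article) is given,
    kappa is recomputed per repetition and its 2.5th-97.5th percentile
    interval reported.
    """
    if reps < 2:
        raise ParameterError(f"reps must be >= 2, got {reps}")
    themes = _themes_of(assignments)
    if not themes:
        raise ParameterError("no themed articles to resample")
    universe = sorted(set(themes), key=str)
    if len(universe) < 2:
        warnings.warn("fewer than 2 distinct themes: Spearman undefined")
    ref = _proportions(themes, universe)
    rng = np.random.default_rng(seed)
    n = len(themes)
    themes_arr = np.array(themes)
    ref_arr = None if reference_labels is None else np.array(list(reference_labels))
    if ref_arr is not None and len(ref_arr) != n:
        raise ParameterError("reference_labels must pair with the themed articles")

    js, rho, kappas = [], [], []
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        sample = themes_arr[idx]
        p = _proportions(sample.tolist(), universe)
        js.append(js_distance(p, ref))
        rho.append(_spearman(p, ref) if len(universe) >= 2 else float("nan"))
        if ref_arr is not None:
            kappas.append(cohen_kappa(sample.tolist(), ref_arr[idx].tolist()).kappa)

    interval = None
    if kappas:
        interval = (float(np.percentile(kappas, 2.5)), float(np.percentile(kappas, 97.5)))
    return StabilityReport(
        repetitions=reps,
        core_theme_count=len(universe),
        js_mean=float(np.mean(js)), js_sd=float(np.std(js, ddof=1)),
        spearman_mean=float(np.nanmean(rho)) if not all(map(math.isnan, rho)) else float("nan"),
        spearman_sd=float(np.nanstd(rho, ddof=1)) if not all(map(math.isnan, rho)) else float("nan"),
        kappa_interval=interval,
    )


def holdout_robustness(assignments, fraction: float = 0.3, reps: int = 120,
                       seed: Optional[int] = None) -> StabilityReport:
    """Repeated random train/holdout splits of the themed articles.

    Each repetition splits the articles, computes theme proportions on both
    partitions, and records the JS distance and Spearman correlation between
    them. Repetitions where a partition contains no themed article are
    skipped and counted.
    """
    if not (0.0 < fraction < 1.0):
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    if reps < 2:
        raise ParameterError(f"reps must be >= 2, got {reps}")
    themes = np.array(_themes_of(assignments))
    if themes.size == 0:
        raise ParameterError("no themed articles to split")
    universe = sorted(set(themes.tolist()), key=str)
    rng = np.random.default_rng(seed)
    n = themes.size
    n_hold = int(round(n * fraction))

    js, rho = [], []
    skipped = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        hold, train = perm[:n_hold], perm[n_hold:]
        if hold.size == 0 or train.size == 0:
            skipped += 1
            continue
        p = _proportions(themes[train].tolist(), universe)
        q = _proportions(themes[hold].tolist(), universe)
        js.append(js_distance(p, q))
        rho.append(_spearman(p, q) if len(universe) >= 2 else float("nan"))

    if not js:
        raise ParameterError("every repetition was skipped")
    return StabilityReport(
        repetitions=reps,
        core_theme_count=len(universe),
        js_mean=float(np.mean(js)), js_sd=float(np.std(js, ddof=1)),
        spearman_mean=float(np.nanmean(rho)) if not all(map(math.isnan, rho)) else float("nan"),
        spearman_sd=float(np.nanstd(rho, ddof=1)) if not all(map(math.isnan, rho)) else float("nan"),
        skipped=skipped,
    )
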