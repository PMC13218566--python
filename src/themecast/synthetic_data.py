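"""Synthetic corpora and numeric panels with planted ground truth.

These generators define the study conditions for every test in the package:
article corpora with disjoint per-theme keyword vocabularies (overlap enters
only through an explicit noise probability, which makes recovery guarantees
provable), two-domain person panels with a controlled between-group effect,
and expression-like matrices with planted up/down features. All generators
are pure functions of their spec (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus_io import ArticleRecord
from .errors import ParameterError
from .numeric_mp import NumericPanel

_COUNTRIES = ["USA", "Canada", "UK", "Netherlands", "Taiwan", "Japan",
              "Germany", "Australia"]
_DOC_TYPES = ["Article", "Review", "Editorial Material"]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic generators (one spec drives all three)."""

    seed: int = 0
    # corpus
    n_articles: int = 200
    n_themes: int = 5
    keywords_per_article: int = 6
    vocab_per_theme: int = 12
    noise: float = 0.05
    citation_mu: float = 1.0      # lognormal location of citation counts
    citation_sigma: float = 1.2   # lognormal scale
    country_bias: float = 0.6     # P(article gets its theme's home country)
    year_range: tuple[int, int] = (2020, 2025)
    # two-domain numeric panel
    n_per_group: int = 20
    items_per_domain: int = 10
    effect_d: float = 5.0
    noise_sd: float = 1.0
    # expression-like matrix
    n_features: int = 200
    n_up: int = 10
    n_down: int = 10
    effect: float = 3.0
    group_sizes: tuple[int, int] = (31, 52)

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise <= 1.0):
            raise ParameterError(f"noise must be in [0, 1], got {self.noise}")
        for name in ("n_articles", "n_themes", "keywords_per_article",
                     "vocab_per_theme", "n_per_group", "items_per_domain",
                     "n_features"):
            if getattr(self, name) < 1:
                raise ParameterError(f"{name} must be positive")


def theme_vocab(spec: SyntheticSpec, theme: int) -> list[str]:
    """Disjoint keyword vocabulary of one planted theme (1-based)."""
    return [f"T{theme}W{j:02d}" for j in range(spec.vocab_per_theme)]


def gen_corpus(spec: SyntheticSpec) -> tuple[list[ArticleRecord], dict[str, int]]:
    """Synthetic article corpus with one planted theme per article.

    Each article samples ``keywords_per_article`` terms (without replacement)
    from its theme's vocabulary; each keyword is independently replaced by a
    random other-theme term with probability ``noise``. Citations follow a
    discretized lognormal so h-indices are non-degenerate; countries and
    years carry theme-correlated biases so flow/summary outputs are
    non-trivial. Returns the records and the planted theme per article id.
    """
    if spec.vocab_per_theme < spec.keywords_per_article:
        raise ParameterError("vocabulary smaller than keywords_per_article")
    rng = np.random.default_rng(spec.seed)
    vocabs = [theme_vocab(spec, t) for t in range(1, spec.n_themes + 1)]
    y0, y1 = spec.year_range
    records, planted = [], {}
    for i in range(spec.n_articles):
        theme = int(rng.integers(1, spec.n_themes + 1))
        kws = list(rng.choice(vocabs[theme - 1], size=spec.keywords_per_article,
                              replace=False))
        for j in range(len(kws)):
            if spec.n_themes > 1 and rng.random() < spec.noise:
                other = int(rng.integers(1, spec.n_themes))
                if other >= theme:
                    other += 1
                kws[j] = str(rng.choice(vocabs[other - 1]))
        home = _COUNTRIES[(theme - 1) % len(_COUNTRIES)]
        country = home if rng.random() < spec.country_bias else \
            str(rng.choice([c for c in _COUNTRIES if c != home]))
        # later themes skew toward later years
        year = int(np.clip(y0 + rng.binomial(y1 - y0, (theme) / (spec.n_themes + 1)),
                           y0, y1))
        rid = f"A{i:04d}"
        records.append(ArticleRecord(
            id=rid,
            title=f"Study {i} on {kws[0].lower()}",
            abstract=". ".join(f"Findings about {k.lower()} in context" for k in kws) + ".",
            author_keywords=list(kws),
            keywords_plus=list(rng.choice(vocabs[theme - 1],
                                          size=spec.keywords_per_article, replace=False)),
            year=year,
            citations=int(rng.lognormal(spec.citation_mu, spec.citation_sigma)),
            countries=[country],
            institutions=[f"University of {country}"],
            document_type=str(rng.choice(_DOC_TYPES, p=[0.7, 0.2, 0.1])),
            authors=[f"Author {int(rng.integers(0, max(2, spec.n_articles // 4)))}"],
        ))
        planted[rid] = theme
    return records, planted


def gen_two_domain_panel(spec: SyntheticSpec) -> NumericPanel:
    """Two-group, two-domain person panel (the STEM/ARTS construction).

    Group 0 scores high (mean shifted by ``effect_d * noise_sd``) on the
    domain-1 items and at baseline on domain-2; group 1 is mirrored. Gaussian
    noise with sd ``noise_sd``; the binary group membership is returned as
    the panel's true label.
    """
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_per_group, spec.items_per_domain
    shift = spec.effect_d * spec.noise_sd
    means = np.zeros((2 * n, 2 * m))
    means[:n, :m] = shift      # group 0 high on domain 1
    means[n:, m:] = shift      # group 1 high on domain 2
    values = means + rng.normal(0.0, spec.noise_sd, size=(2 * n, 2 * m))
    items = [f"STEM{j + 1:02d}" for j in range(m)] + \
            [f"ARTS{j + 1:02d}" for j in range(m)]
    persons = [f"P{i:03d}" for i in range(2 * n)]
    return NumericPanel(persons, items, values,
                        true_label=np.array([0] * n + [1] * n))


def gen_expression(spec: SyntheticSpec) -> NumericPanel:
    """Expression-like log-scale matrix with planted up/down features.

    Samples-by-features Gaussian matrix (baseline mean 5, sd ``noise_sd``);
    the first ``n_up`` features are shifted by +``effect`` and the next
    ``n_down`` by -``effect`` in group 1; remaining features are null. Group
    sizes default to (31, 52), the shape of a primary-versus-metastatic
    melanoma comparison. Group membership is the true label.
    """
    if spec.n_up + spec.n_down > spec.n_features:
        raise ParameterError("n_up + n_down exceeds n_features")
    rng = np.random.default_rng(spec.seed)
    n0, n1 = spec.group_sizes
    n = n0 + n1
    values = rng.normal(5.0, spec.noise_sd, size=(n, spec.n_features))
    values[n0:, :spec.n_up] += spec.effect
    values[n0:, spec.n_up:spec.n_up + spec.n_down] -= spec.effect
    features = [f"G{j:04d}" for j in range(spec.n_features)]
    samples = [f"S{i:03d}" for i in range(n)]
    return NumericPanel(samples, features, values,
                        true_label=np.array([0] * n0 + [1] * n1))


def planted_feature_names(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    """Names of the planted up- and down-regulated expression features."""
    up = [f"G{j:04d}" for j in range(spec.n_up)]
    down = [f"G{j:04d}" for j in range(spec.n_up, spec.n_up + spec.n_down)]
    return up, down
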