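"""Shared statistical utilities: correlation with significance, pairwise
LSD tests with Bonferroni adjustment, and the compact letter display used
to annotate genotype comparisons."""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationEntry",
    "LetterAssignment",
    "pearson",
    "lsd_bonferroni_letters",
    "compact_letter_display",
    "ALPHA",
]

#: Significance threshold used throughout the package.
ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationEntry:
    label_x: str
    label_y: str
    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.p) and self.p < ALPHA)


def pearson(x, y, label_x: str = "x", label_y: str = "y") -> CorrelationEntry:
    """Sample Pearson correlation with a two-sided p from the exact t
    transform (n - 2 df).

    Zero variance in either argument yields an undefined entry (NaN r and
    p, not significant) rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationEntry(label_x, label_y, float("nan"), float("nan"), n)
    r, p = sps.pearsonr(x, y)
    return CorrelationEntry(label_x, label_y, float(r), float(p), n)


@dataclass
class LetterAssignment:
    """Compact letter display: groups sharing a letter are not significantly
    different under the adjusted pairwise tests."""

    letters: dict            # group label -> letter string, e.g. "ab"
    pairwise: pd.DataFrame   # columns a, b, t, p_adj, significant

    def __getitem__(self, key):
        return self.letters[key]


def _letter_symbols():
    for ch in string.ascii_lowercase:
        yield ch
    for a, b in itertools.product(string.ascii_lowercase, repeat=2):
        yield a + b


def compact_letter_display(
    labels, sig_pairs, means: Optional[Mapping] = None
) -> dict:
    """Insert-and-absorb letter coding from a significance graph.

    ``sig_pairs`` is an iterable of unordered label pairs declared
    significantly different.  Two labels share a letter iff their pair is
    not in ``sig_pairs``.  Letters are assigned in order of descending mean
    (ties broken by label order) for deterministic strings.
    """
    labels = list(labels)
    sig = {frozenset(p) for p in sig_pairs}
    classes = [set(labels)]
    for pair in sorted(sig, key=lambda fs: tuple(sorted(fs))):
        a, b = sorted(pair)
        for cls in [c for c in classes if a in c and b in c]:
            classes.remove(cls)
            classes.extend([cls - {a}, cls - {b}])
        classes = [c for c in classes if c]
        # absorb proper subsets
        classes = [
            c for c in classes
            if not any(c < other for other in classes)
        ]
        # deduplicate
        seen, unique = set(), []
        for c in classes:
            f = frozenset(c)
            if f not in seen:
                seen.add(f)
                unique.append(c)
        classes = unique

    if means is None:
        rank = {lab: i for i, lab in enumerate(labels)}
    else:
        order = sorted(labels, key=lambda g: (-means[g], labels.index(g)))
        rank = {lab: i for i, lab in enumerate(order)}
    classes.sort(key=lambda c: min(rank[x] for x in c))

    assignment = {lab: "" for lab in labels}
    for sym, cls in zip(_letter_symbols(), classes):
        for lab in sorted(cls, key=lambda x: rank[x]):
            assignment[lab] += sym
    return assignment


def lsd_bonferroni_letters(
    means: Mapping,
    mse: float,
    df_error: int,
    n_per_group: Mapping,
    alpha: float = ALPHA,
) -> LetterAssignment:
    """All-pairs least-significant-difference tests with Bonferroni
    adjustment, summarised as a compact letter display.

    t_ij = |m_i - m_j| / sqrt(mse (1/n_i + 1/n_j)); each two-sided p is
    multiplied by the number of pairs (capped at 1).  Letters are produced
    by insert-and-absorb and listed in order of descending mean.
    """
    if mse <= 0:
        raise ValueError("mse must be positive")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    labels = list(means)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    m = len(labels) * (len(labels) - 1) // 2
    rows, sig_pairs = [], []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(mse * (1.0 / n_per_group[a] + 1.0 / n_per_group[b]))
        t = abs(means[a] - means[b]) / se
        p_adj = min(1.0, 2.0 * sps.t.sf(t, df_error) * m)
        significant = p_adj < alpha
        if significant:
            sig_pairs.append((a, b))
        rows.append((a, b, float(t), float(p_adj), significant))
    letters = compact_letter_display(labels, sig_pairs, means=means)
    pairwise = pd.DataFrame(rows, columns=["a", "b", "t", "p_adj", "significant"])
    return LetterAssignment(letters=letters, pairwise=pairwise)
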