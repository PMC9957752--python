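"""Gene-set overlap and global-concordance statistics.

Two cross-dataset comparisons: (1) is the overlap between two gene sets
(e.g. genes up-regulated in a knockout and genes up-regulated in aging)
larger than chance within a declared gene universe?  — a one-sided Fisher
exact (hypergeometric tail) test; (2) are two transcriptome-wide expression
vectors globally concordant? — Pearson correlation on (optionally
log-transformed) matched genes.

The universe definition dominates the overlap p-value; it defaults to the
genes detected in both datasets and must be passed explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ContainmentError,
    InvalidArgumentError,
    UndefinedCorrelationError,
)


@dataclass
class OverlapResult:
    """2x2 overlap table summary with enrichment test."""

    n_universe: int
    n_a: int
    n_b: int
    n_shared: int
    odds_ratio: float
    p_value: float


def fisher_overlap(
    set_a: Iterable[str], set_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """One-sided Fisher exact test for gene-set overlap enrichment.

    p = P(X >= n_shared) under the hypergeometric null for the 2x2 table
    [[shared, a_only], [b_only, neither]]; the odds ratio is the sample
    (unconditional) odds ratio with no continuity correction.  Both sets
    must be contained in the universe.
    """
    a, b, u = set(set_a), set(set_b), set(universe)
    stray = (a | b) - u
    if stray:
        raise ContainmentError(
            f"{len(stray)} genes outside the universe, e.g. {sorted(stray)[:5]}"
        )
    shared = len(a & b)
    table = [
        [shared, len(a) - shared],
        [len(b) - shared, len(u) - len(a) - len(b) + shared],
    ]
    odds_ratio, p = stats.fisher_exact(table, alternative="greater")
    return OverlapResult(
        n_universe=len(u),
        n_a=len(a),
        n_b=len(b),
        n_shared=shared,
        odds_ratio=float(odds_ratio),
        p_value=float(p),
    )


def pearson_concordance(
    expr_a: pd.Series, expr_b: pd.Series, transform: str = "log2p1"
) -> tuple:
    """Pearson correlation of two expression vectors matched on gene id.

    Genes are matched by index intersection; with ``transform="log2p1"``
    both vectors are log2(x+1)-transformed first.  Returns ``(r, p)`` with
    p from the t-distribution of r.  Fewer than 3 shared genes or a
    zero-variance vector is an error.
    """
    if transform not in ("log2p1", "none"):
        raise InvalidArgumentError(f"unknown transform {transform!r}")
    a = pd.Series(expr_a, dtype=float)
    b = pd.Series(expr_b, dtype=float)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise InvalidArgumentError(f"only {len(shared)} shared genes; need >=3")
    x = a.loc[shared].to_numpy()
    y = b.loc[shared].to_numpy()
    if transform == "log2p1":
        x = np.log2(x + 1.0)
        y = np.log2(y + 1.0)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
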