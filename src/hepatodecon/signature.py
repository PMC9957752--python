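"""Gene-signature derivation, cohort scoring and stage-trend testing.

The workflow mirrors a cross-condition signature transfer: rank genes by a
two-group differential test in a reference contrast (e.g. pathway-intact vs
knockout cells), keep the significantly up-regulated ones as the
"active-state" signature, score each sample of an independent bulk cohort
by the mean z-score of signature-gene expression, and test whether the
score tracks an ordinal disease stage with a permutation rank-correlation
test.

The differential engine here is Welch's t on log2(CPM+1); it exists to make
the pipeline closed and testable on synthetic counts, not to replace the
negative-binomial machinery used for real sequencing data.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import CohortMatrix
from .errors import (
    EmptySignatureError,
    InvalidArgumentError,
    InvalidDesignError,
    NormalizationWarning,
    ScoringError,
)

logger = logging.getLogger(__name__)


@dataclass
class SignatureGeneSet:
    """An ordered up-regulated gene set with its source statistics."""

    genes: List[str]
    direction: str  # "up_in_reference"
    source_stats: pd.DataFrame  # per-gene log2fc, p, q (signature genes only)


@dataclass
class ScoreTable:
    """Per-sample signature activity scores with stage labels."""

    table: pd.DataFrame  # index sample_id; columns: score, stage (optional)

    @property
    def scores(self) -> pd.Series:
        return self.table["score"]


def _cpm_log2(values: pd.DataFrame) -> pd.DataFrame:
    totals = values.sum(axis=0)
    cpm = values / totals.replace(0, np.nan) * 1e6
    return np.log2(cpm.fillna(0.0) + 1.0)


def de_rank(matrix: CohortMatrix, reference: Optional[str] = None) -> pd.DataFrame:
    """Per-gene two-group statistics: log2fc, Welch p, BH q.

    ``log2fc`` is the difference of group means on the log2(CPM+1) scale,
    reference minus the other group (positive = up in reference).  The
    reference group defaults to a group literally labelled "reference" if
    one exists, else the first of the sorted labels.  Constant genes get
    p = 1.
    """
    if "group" not in matrix.samples.columns:
        raise InvalidDesignError("cohort has no 'group' column")
    groups = matrix.samples["group"]
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise InvalidDesignError(f"need exactly 2 groups, found {labels}")
    if reference is None:
        reference = "reference" if "reference" in labels else labels[0]
    if reference not in labels:
        raise InvalidDesignError(f"reference group {reference!r} not in {labels}")
    other = [g for g in labels if g != reference][0]
    counts = groups.value_counts()
    if (counts < 2).any():
        raise InvalidDesignError(f"every group needs >=2 samples, got {counts.to_dict()}")

    log2 = _cpm_log2(matrix.values)
    a = log2.loc[:, groups == reference].to_numpy()
    b = log2.loc[:, groups == other].to_numpy()
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "p": p, "q": q}, index=matrix.gene_ids
    )


def derive_signature(
    de_stats: pd.DataFrame,
    min_abs_log2fc: float = 1.0,
    max_q: float = 0.05,
    top_k: Optional[int] = None,
) -> SignatureGeneSet:
    """Select the significantly up-regulated genes as a signature.

    Keeps genes with log2fc >= ``min_abs_log2fc`` and q <= ``max_q``,
    ordered by ascending q then descending log2fc, optionally truncated to
    the ``top_k`` best.  Raises :class:`EmptySignatureError` when nothing
    qualifies.
    """
    if de_stats.empty:
        raise InvalidArgumentError("empty statistics table")
    keep = de_stats[(de_stats["log2fc"] >= min_abs_log2fc) & (de_stats["q"] <= max_q)]
    keep = keep.sort_values(["q", "log2fc"], ascending=[True, False], kind="stable")
    if top_k is not None:
        keep = keep.head(top_k)
    if keep.empty:
        raise EmptySignatureError(
            f"no gene passed log2fc >= {min_abs_log2fc}, q <= {max_q}"
        )
    return SignatureGeneSet(
        genes=list(keep.index), direction="up_in_reference", source_stats=keep
    )


def map_orthologs(
    sig: SignatureGeneSet, orthology: Optional[pd.DataFrame] = None
) -> SignatureGeneSet:
    """Translate signature gene ids for a cross-species cohort.

    ``orthology`` is a 2-column table (source id, target id); without one,
    symbols are passed through unchanged and matching downstream falls back
    to case-insensitive symbol comparison in :func:`score_samples`.
    """
    if orthology is None:
        return sig
    if orthology.shape[1] < 2:
        raise InvalidArgumentError("orthology table needs 2 columns (source, target)")
    lut = dict(zip(orthology.iloc[:, 0], orthology.iloc[:, 1]))
    mapped = [lut[g] for g in sig.genes if g in lut]
    if not mapped:
        raise EmptySignatureError("no signature gene maps through the orthology table")
    stats_mapped = sig.source_stats.loc[[g for g in sig.genes if g in lut]].copy()
    stats_mapped.index = mapped
    return SignatureGeneSet(genes=mapped, direction=sig.direction, source_stats=stats_mapped)


def score_samples(
    matrix: CohortMatrix, sig: SignatureGeneSet, method: str = "zmean"
) -> ScoreTable:
    """Score each sample for signature activity.

    ``zmean`` (default): per gene, z-score log2(x+1) expression across
    samples; the sample score is the mean z over signature genes present in
    the matrix.  ``rank``: mean within-sample percentile rank of the
    signature genes.  Missing signature genes are logged; gene symbols are
    matched case-insensitively as a cross-species fallback when no exact
    match exists.  Scores depend only on the signature rows, so adding
    non-signature genes to the matrix cannot change them.
    """
    if method not in ("zmean", "rank"):
        raise InvalidArgumentError(f"unknown scoring method {method!r}")
    index = matrix.gene_ids
    present = [g for g in sig.genes if g in index]
    if len(present) < len(sig.genes) and not present:
        # cross-species fallback: case-insensitive symbol matching
        lower = {str(g).lower(): g for g in index}
        present = [lower[str(g).lower()] for g in sig.genes if str(g).lower() in lower]
    missing = len(sig.genes) - len(present)
    if not present:
        raise ScoringError("no signature gene overlaps the cohort matrix")
    if missing:
        logger.warning("%d of %d signature genes absent from cohort", missing, len(sig.genes))

    totals = matrix.values.sum(axis=0)
    positive = totals[totals > 0]
    if len(positive) and positive.max() / positive.min() > 10:
        warnings.warn(
            "sample totals differ by more than 10x; scores assume a "
            "pre-normalized matrix",
            NormalizationWarning,
            stacklevel=2,
        )

    if method == "zmean":
        log2 = np.log2(matrix.values.loc[present] + 1.0)
        mu = log2.mean(axis=1)
        sd = log2.std(axis=1, ddof=1)
        z = log2.sub(mu, axis=0).div(sd.replace(0, np.nan), axis=0).fillna(0.0)
        scores = z.mean(axis=0)
    else:
        ranks = matrix.values.rank(axis=0, pct=True)
        scores = ranks.loc[present].mean(axis=0)

    table = pd.DataFrame({"score": scores})
    if "stage" in matrix.samples.columns:
        table["stage"] = matrix.samples["stage"]
    return ScoreTable(table=table)


def stage_trend(
    scores: ScoreTable,
    n_perm: int = 10_000,
    seed: int = 0,
    max_exhaustive: int = 50_000,
) -> dict:
    """Permutation test for a monotone score-vs-stage trend.

    The statistic is Spearman's rho between score and ordinal stage; the
    two-sided p-value comes from permuting stage labels.  When the number
    of label orderings (n!) is at most ``max_exhaustive`` all permutations
    are enumerated, making the p-value exact; otherwise ``n_perm`` seeded
    random permutations are drawn and p = (1 + #extreme) / (1 + n_perm).
    Constant scores have undefined rho, reported as 0 with p = 1.
    """
    table = scores.table
    if "stage" not in table.columns:
        raise InvalidArgumentError("score table has no stage labels")
    stage = table["stage"]
    if pd.api.types.is_numeric_dtype(stage):
        stage_code = stage.astype(float).to_numpy()
    else:
        order = {lab: i for i, lab in enumerate(sorted(stage.unique()))}
        stage_code = stage.map(order).astype(float).to_numpy()
    vals = table["score"].to_numpy(dtype=float)
    levels, counts = np.unique(stage_code, return_counts=True)
    if len(levels) < 2:
        raise InvalidArgumentError("need at least 2 stages")
    if counts.min() < 2:
        raise InvalidArgumentError("need at least 2 samples per stage")
    if np.ptp(vals) == 0:
        return {"rho": 0.0, "p": 1.0, "n": len(vals), "method": "degenerate"}

    # Spearman's rho as Pearson correlation of (tie-averaged) ranks; the
    # rank multiset is permutation-invariant, so permuting one centered
    # rank vector and taking dot products reproduces the permuted rho.
    rank_score = stats.rankdata(vals)
    rank_stage = stats.rankdata(stage_code)
    sc = rank_score - rank_score.mean()
    st = rank_stage - rank_stage.mean()
    denom = float(np.sqrt((sc**2).sum() * (st**2).sum()))
    rho = float(sc @ st / denom)
    n = len(vals)
    eps = 1e-12

    if math.factorial(n) <= max_exhaustive:
        extreme = total = 0
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(sc @ st[list(perm)] / denom) >= abs(rho) - eps:
                extreme += 1
        p = extreme / total
        method = "exhaustive"
    else:
        rng = np.random.default_rng(seed)
        perms = np.argsort(rng.random((n_perm, n)), axis=1)
        rhos = st[perms] @ sc / denom
        extreme = int((np.abs(rhos) >= abs(rho) - eps).sum())
        p = (1 + extreme) / (1 + n_perm)
        method = "permutation"
    return {"rho": rho, "p": float(p), "n": n, "method": method}
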