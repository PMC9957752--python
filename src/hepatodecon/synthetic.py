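"""Synthetic data with known ground truth for every pipeline stage.

Four generators emulate the data the pipeline consumes in practice:

* :func:`make_reference_set` — pure cell-type reference transcriptomes with
  genes that are exclusive to one type (true markers) and genes shared by
  all types, on the reads/kb scale.
* :func:`mix_whole_tissue` — a whole-tissue library that is a known convex
  combination of the reference transcriptomes, optionally with Poisson
  count noise; the mixing weights are the estimand of the deconvolution
  module.
* :func:`make_two_condition_matrix` — a two-group count matrix with planted
  up/down-regulated genes, feeding signature derivation.
* :func:`make_staged_cohort` — a staged bulk cohort in which a signature
  gene set and one designated single gene decline monotonically with stage,
  feeding signature scoring, trend testing and the staging classifier.

All generators take an explicit integer seed and are bit-reproducible for a
fixed seed.  Per-type base expression is log-normal (meanlog 2, sdlog 1 on
the reads/kb scale) for the heavy right tail typical of RNA-seq; transcript
lengths are uniform on [0.5, 10] kb so the reads/kb conversion is exercised
nontrivially; count noise is Poisson.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .containers import CohortMatrix, ExpressionLibrary, NormalizedProfile
from .errors import InvalidArgumentError

MEANLOG = 2.0  # natural-log mean of base expression (reads/kb scale)
SDLOG = 1.0
LENGTH_RANGE_KB = (0.5, 10.0)


@dataclass
class ReferenceSet:
    """Ground-truth cell-type reference panel.

    ``marker_truth`` records, per cell type, the genes generated as exclusive
    to that type (nonzero there, exactly zero everywhere else);
    ``shared_genes`` are expressed in every type with independent levels.
    """

    cell_types: List[str]
    profiles: Dict[str, NormalizedProfile]
    marker_truth: Dict[str, List[str]]
    shared_genes: List[str]
    length_kb: pd.Series
    biotype: pd.Series
    seed: int

    @property
    def gene_ids(self) -> pd.Index:
        return self.length_kb.index


@dataclass
class MixtureTruth:
    """Ground truth for one simulated whole-tissue library."""

    fractions: Dict[str, float]
    depth: float
    seed: int
    noise: str = "none"

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise InvalidArgumentError(f"truth fractions sum to {total}, not 1")
        if self.depth <= 0:
            raise InvalidArgumentError("depth must be positive")


def make_reference_set(
    n_cell_types: int, n_genes: int, n_markers_per_type: int, seed: int
) -> ReferenceSet:
    """Generate pure cell-type transcriptomes with exclusive markers.

    The first ``n_cell_types * n_markers_per_type`` genes (after a seeded
    shuffle of the universe) are split into exclusive marker blocks, one per
    type; the remainder are shared genes expressed in every type with
    independent log-normal levels.
    """
    if n_cell_types < 2:
        raise InvalidArgumentError("need at least 2 cell types")
    if n_markers_per_type < 1:
        raise InvalidArgumentError("need at least 1 marker per type")
    n_marker_total = n_cell_types * n_markers_per_type
    if n_marker_total >= n_genes:
        raise InvalidArgumentError(
            f"{n_marker_total} marker genes do not fit in a universe of {n_genes}"
        )
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(n_genes)], name="gene_id")
    length_kb = pd.Series(rng.uniform(*LENGTH_RANGE_KB, size=n_genes), index=genes)
    biotype = pd.Series("protein_coding", index=genes, dtype=object)

    shuffled = genes[rng.permutation(n_genes)]
    cell_types = [f"type{c}" for c in range(n_cell_types)]
    marker_truth = {
        ct: sorted(shuffled[c * n_markers_per_type : (c + 1) * n_markers_per_type])
        for c, ct in enumerate(cell_types)
    }
    shared = sorted(shuffled[n_marker_total:])

    profiles: Dict[str, NormalizedProfile] = {}
    for ct in cell_types:
        expr = pd.Series(0.0, index=genes)
        expr.loc[shared] = rng.lognormal(MEANLOG, SDLOG, size=len(shared))
        own = marker_truth[ct]
        expr.loc[own] = rng.lognormal(MEANLOG, SDLOG, size=len(own))
        profiles[ct] = NormalizedProfile(
            library_id=ct, molecule_counts=expr, normalization_mode="none"
        )
    return ReferenceSet(
        cell_types=cell_types,
        profiles=profiles,
        marker_truth=marker_truth,
        shared_genes=shared,
        length_kb=length_kb,
        biotype=biotype,
        seed=seed,
    )


def mix_whole_tissue(
    refs: ReferenceSet,
    fractions: Sequence[float] | Dict[str, float],
    depth: float = 1e6,
    noise: str = "none",
    seed: int = 0,
) -> tuple:
    """Simulate a whole-tissue library as a convex mixture of references.

    The mixture is formed on the transcriptome-fraction scale — the tissue
    fraction of gene g is sum_c f_c * fraction_c(g) — then converted back to
    expected read counts via transcript length and scaled so the expected
    molecule total equals ``depth``.  With ``noise="poisson"`` each read
    count is Poisson-resampled around its expectation; with ``noise="none"``
    expected counts are returned exactly (as reals).

    Returns ``(ExpressionLibrary, MixtureTruth)``.
    """
    if isinstance(fractions, dict):
        missing = set(refs.cell_types) - set(fractions)
        if missing:
            raise InvalidArgumentError(f"fractions missing cell types: {sorted(missing)}")
        frac_map = {ct: float(fractions[ct]) for ct in refs.cell_types}
    else:
        if len(fractions) != len(refs.cell_types):
            raise InvalidArgumentError(
                f"{len(fractions)} fractions for {len(refs.cell_types)} cell types"
            )
        frac_map = dict(zip(refs.cell_types, map(float, fractions)))
    total = sum(frac_map.values())
    if abs(total - 1.0) > 1e-9:
        raise InvalidArgumentError(f"fractions sum to {total!r}, not 1")
    if any(f < 0 for f in frac_map.values()):
        raise InvalidArgumentError("fractions must be nonnegative")
    if noise not in ("none", "poisson"):
        raise InvalidArgumentError(f"unknown noise model {noise!r}")
    # renormalize exactly so downstream identities hold to machine precision
    frac_map = {ct: f / total for ct, f in frac_map.items()}

    mix_frac = sum(
        f * refs.profiles[ct].fractions for ct, f in frac_map.items()
    )
    expected_molecules = depth * mix_frac
    expected_reads = expected_molecules * refs.length_kb
    if noise == "poisson":
        rng = np.random.default_rng(seed)
        counts = pd.Series(
            rng.poisson(expected_reads.to_numpy()).astype(float), index=refs.gene_ids
        )
    else:
        counts = expected_reads
    lib = ExpressionLibrary(
        library_id=f"mixture-seed{seed}",
        counts=counts,
        length_kb=refs.length_kb,
        biotype=refs.biotype,
    )
    truth = MixtureTruth(fractions=frac_map, depth=depth, seed=seed, noise=noise)
    return lib, truth


def make_two_condition_matrix(
    n_genes: int,
    n_samples_per_group: int,
    n_up: int,
    n_down: int,
    effect_log2fc: float,
    seed: int,
    base_meanlog: float = 3.0,
    base_sdlog: float = 1.0,
) -> CohortMatrix:
    """Two-group Poisson count matrix with planted fold changes.

    Genes are drawn with log-normal baseline Poisson means; ``n_up`` genes
    are multiplied by ``2**effect_log2fc`` in the *reference* group (so they
    are up-regulated in reference vs comparison) and ``n_down`` genes by the
    inverse.  ``effect_log2fc == 0`` is the null configuration and plants no
    genes; a negative effect is an error.  The planted gene identities are
    recorded in ``truth``.
    """
    if effect_log2fc < 0:
        raise InvalidArgumentError("effect_log2fc must be nonnegative")
    if n_up + n_down >= n_genes:
        raise InvalidArgumentError("planted genes must be fewer than n_genes")
    if n_samples_per_group < 2:
        raise InvalidArgumentError("need at least 2 samples per group")
    rng = np.random.default_rng(seed)
    width = max(5, len(str(n_genes)))
    genes = pd.Index([f"g{i:0{width}d}" for i in range(n_genes)], name="gene_id")
    base = rng.lognormal(base_meanlog, base_sdlog, size=n_genes)

    if effect_log2fc == 0:
        up_genes: List[str] = []
        down_genes: List[str] = []
    else:
        chosen = genes[rng.permutation(n_genes)[: n_up + n_down]]
        up_genes = sorted(chosen[:n_up])
        down_genes = sorted(chosen[n_up:])

    lam_ref = pd.Series(base, index=genes)
    lam_cmp = lam_ref.copy()
    lam_ref.loc[up_genes] *= 2.0 ** effect_log2fc
    lam_ref.loc[down_genes] *= 2.0 ** -effect_log2fc

    n = n_samples_per_group
    ref_ids = [f"ref{i:03d}" for i in range(n)]
    cmp_ids = [f"cmp{i:03d}" for i in range(n)]
    ref_counts = rng.poisson(lam_ref.to_numpy()[:, None], size=(n_genes, n))
    cmp_counts = rng.poisson(lam_cmp.to_numpy()[:, None], size=(n_genes, n))
    values = pd.DataFrame(
        np.hstack([ref_counts, cmp_counts]).astype(float),
        index=genes,
        columns=ref_ids + cmp_ids,
    )
    samples = pd.DataFrame(
        {"group": ["reference"] * n + ["comparison"] * n},
        index=pd.Index(ref_ids + cmp_ids, name="sample_id"),
    )
    truth = {
        "up_genes": up_genes,
        "down_genes": down_genes,
        "effect_log2fc": effect_log2fc,
        "seed": seed,
    }
    return CohortMatrix(values=values, samples=samples, truth=truth)


def make_staged_cohort(
    n_per_stage: Sequence[int],
    signature_genes: Sequence[str],
    stage_effect: float,
    noise_sd: float,
    seed: int,
    n_background: int = 200,
    trend_gene: str = "Smo",
    trend_gene_effect: Optional[float] = None,
    base_log2_mean: float = 5.0,
    base_log2_sd: float = 1.0,
) -> CohortMatrix:
    """Staged bulk cohort whose signature genes decline with stage.

    Each sample at stage s (0-based ordinal) expresses signature genes at
    log2 level ``base - stage_effect * s`` plus Gaussian noise of sd
    ``noise_sd``; background genes have no trend.  One designated single
    gene (``trend_gene``, default "Smo") follows the same declining trend
    with its own effect (default: ``stage_effect``), providing the
    single-gene biomarker for the staging classifier.
    """
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise InvalidArgumentError("signature gene list is empty")
    if len(n_per_stage) < 2:
        raise InvalidArgumentError("need at least 2 stages")
    if any(n < 1 for n in n_per_stage):
        raise InvalidArgumentError("every stage needs at least 1 sample")
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be nonnegative")
    if trend_gene_effect is None:
        trend_gene_effect = stage_effect
    rng = np.random.default_rng(seed)

    background = [f"bg{i:05d}" for i in range(n_background)]
    genes = pd.Index(
        list(dict.fromkeys([trend_gene, *signature_genes, *background])), name="gene_id"
    )
    base = pd.Series(
        rng.normal(base_log2_mean, base_log2_sd, size=len(genes)), index=genes
    )

    sample_ids: List[str] = []
    stages: List[int] = []
    cols = []
    for s, n in enumerate(n_per_stage):
        for i in range(n):
            sid = f"s{s}_{i:03d}"
            sample_ids.append(sid)
            stages.append(s)
            mu = base.copy()
            mu.loc[signature_genes] -= stage_effect * s
            mu.loc[trend_gene] = base.loc[trend_gene] - trend_gene_effect * s
            log2_expr = mu + rng.normal(0.0, noise_sd, size=len(genes))
            cols.append(np.exp2(log2_expr.to_numpy()))
    values = pd.DataFrame(
        np.column_stack(cols), index=genes,
        columns=pd.Index(sample_ids, name="sample_id"),
    )
    samples = pd.DataFrame(
        {"stage": stages}, index=pd.Index(sample_ids, name="sample_id")
    )
    truth = {
        "signature_genes": signature_genes,
        "trend_gene": trend_gene,
        "stage_effect": stage_effect,
        "trend_gene_effect": trend_gene_effect,
        "noise_sd": noise_sd,
        "seed": seed,
    }
    return CohortMatrix(values=values, samples=samples, truth=truth)
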