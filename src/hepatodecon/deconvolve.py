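"""Marker-ratio deconvolution of a tissue transcriptome.

Within one library every transcript t is a fraction of the total
transcriptome T.  For a gene expressed exclusively by cell type c, the ratio
of its fraction in the whole-tissue transcriptome (t_L/T_L) to its fraction
in the pure cell-type transcriptome (t_C/T_C) equals the fraction of that
cell type's transcriptome within the tissue transcriptome:

    (t_L / T_L) / (t_C / T_C) = f_c        (exactly, under exclusivity)

Because both numerator and denominator are fractions, any library-size
normalization cancels (T_L and T_C drop out), so the estimator needs only
linear normalization upstream.  Averaging the ratio over a set of exclusive
markers gives the per-type estimate; summing the non-hepatocyte (NPC)
estimates and subtracting from 1 gives the hepatocyte fraction, which cannot
be estimated from its own markers when isolation artifacts distort isolated
hepatocyte references.  The per-type fractions then apportion the tissue
expression of any multi-cell-type gene into per-type contributions
f_c * fraction_c(g) / fraction_tissue(g).

Note: these are *transcriptome* fractions, not cell-number fractions — cell
types differ in transcripts per cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import NormalizedProfile
from .errors import (
    ApportionmentError,
    ClippingWarning,
    EstimationError,
    InconsistencyWarning,
    InvalidArgumentError,
    MarkerInvalidError,
)
from .markers import MarkerSet

HEPATOCYTE = "hepatocyte"


@dataclass
class CellFractionEstimate:
    """One cell type's estimated transcriptome fraction.

    ``fraction`` is the configured average of ``per_marker_ratios`` clipped
    to [0, 1]; ``raw_fraction`` keeps the pre-clip value and ``clipped``
    records whether clipping occurred.  ``dispersion`` is the sample
    standard deviation of the per-marker ratios.
    """

    cell_type: str
    fraction: float
    per_marker_ratios: List[Tuple[str, float]]
    n_markers: int
    dispersion: float
    average: str = "mean"
    raw_fraction: float = 0.0
    clipped: bool = False
    skipped_markers: List[str] = field(default_factory=list)


@dataclass
class ApportionmentRow:
    """Per-gene split of tissue expression across cell types.

    ``per_type_contribution`` holds the fraction of the gene's total tissue
    expression attributed to each cell type; ``residual`` is the unattributed
    remainder, so contributions + residual = 1 by construction.
    """

    gene: str
    per_type_contribution: Dict[str, float]
    residual: float
    inconsistent: bool = False


def marker_ratio(gene: str, tissue: NormalizedProfile, cell: NormalizedProfile) -> float:
    """Fraction ratio (t_L/T_L) / (t_C/T_C) for one marker gene.

    A marker must be expressed in its own cell type: absence or zero in the
    cell profile raises :class:`MarkerInvalidError`.  Zero in the tissue is
    valid (the cell type may simply be absent) and returns 0.
    """
    if gene not in cell.gene_ids:
        raise MarkerInvalidError(f"gene {gene!r} absent from cell profile {cell.library_id!r}")
    if gene not in tissue.gene_ids:
        raise MarkerInvalidError(f"gene {gene!r} absent from tissue profile {tissue.library_id!r}")
    cell_frac = cell.fractions[gene]
    if cell_frac <= 0:
        raise MarkerInvalidError(
            f"gene {gene!r} has zero expression in cell profile {cell.library_id!r}"
        )
    return float(tissue.fractions[gene] / cell_frac)


def estimate_cell_fraction(
    markers: MarkerSet,
    tissue: NormalizedProfile,
    cell: NormalizedProfile,
    average: str = "mean",
) -> CellFractionEstimate:
    """Average the marker ratios of one cell type into a fraction estimate.

    Markers failing :func:`marker_ratio` preconditions are skipped and
    listed; if none survive an :class:`EstimationError` is raised.  The
    estimate is clipped to [0, 1] with a :class:`ClippingWarning` (the raw
    value is preserved).
    """
    if average not in ("mean", "median"):
        raise InvalidArgumentError(f"unknown average {average!r}")
    ratios: List[Tuple[str, float]] = []
    skipped: List[str] = []
    for gene in markers.genes:
        try:
            ratios.append((gene, marker_ratio(gene, tissue, cell)))
        except MarkerInvalidError:
            skipped.append(gene)
    if not ratios:
        raise EstimationError(
            f"no valid marker for cell type {markers.cell_type!r} "
            f"({len(skipped)} skipped)"
        )
    values = np.array([r for _, r in ratios])
    raw = float(np.mean(values) if average == "mean" else np.median(values))
    dispersion = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    clipped = not (0.0 <= raw <= 1.0)
    fraction = float(min(max(raw, 0.0), 1.0))
    if clipped:
        warnings.warn(
            f"estimate for {markers.cell_type!r} clipped from {raw:.4g} to {fraction:.4g}",
            ClippingWarning,
            stacklevel=2,
        )
    return CellFractionEstimate(
        cell_type=markers.cell_type,
        fraction=fraction,
        per_marker_ratios=ratios,
        n_markers=len(ratios),
        dispersion=dispersion,
        average=average,
        raw_fraction=raw,
        clipped=clipped,
        skipped_markers=skipped,
    )


def estimate_npc_and_hepatocyte(
    estimates: Sequence[CellFractionEstimate], tolerance: float = 0.05
) -> Tuple[float, float]:
    """Sum non-hepatocyte fractions (NPC) and get hepatocyte by subtraction.

    npc = sum of the per-type fractions; hepatocyte = 1 - npc.  An empty
    list degenerates to hepatocyte = 1.  If npc exceeds 1 the hepatocyte
    value is clipped to 0 with an :class:`InconsistencyWarning` (strident
    when npc > 1 + ``tolerance``).
    """
    types = [e.cell_type for e in estimates]
    if len(set(types)) != len(types):
        raise InvalidArgumentError(f"duplicate cell types in estimates: {types}")
    if HEPATOCYTE in types:
        raise InvalidArgumentError(
            "hepatocyte must not appear among the summed NPC estimates"
        )
    npc = float(sum(e.fraction for e in estimates))
    hepatocyte = 1.0 - npc
    if hepatocyte < 0:
        level = "inconsistent" if npc > 1.0 + tolerance else "marginal"
        warnings.warn(
            f"NPC fractions sum to {npc:.4g} (> 1, {level}); hepatocyte clipped to 0",
            InconsistencyWarning,
            stacklevel=2,
        )
        hepatocyte = 0.0
    return npc, hepatocyte


def apportion_gene(
    gene: str,
    estimates: Sequence[CellFractionEstimate],
    cell_profiles: Dict[str, NormalizedProfile],
    tissue: NormalizedProfile,
    hepatocyte_fraction: Optional[float] = None,
    residual_policy: str = "report",
) -> ApportionmentRow:
    """Split one gene's tissue expression into per-cell-type contributions.

    contribution_c = f_c * fraction_c(gene) / fraction_tissue(gene); the
    residual 1 - sum(contributions) is the share not explained by the
    supplied profiles (dominated by hepatocytes when no hepatocyte reference
    exists).  ``residual_policy="assign_hepatocyte"`` credits the residual
    to the hepatocyte entry when no hepatocyte profile was supplied.
    Contributions summing to more than 1.05 mark the row inconsistent.
    """
    if residual_policy not in ("report", "assign_hepatocyte"):
        raise InvalidArgumentError(f"unknown residual policy {residual_policy!r}")
    if gene not in tissue.gene_ids:
        raise ApportionmentError(f"gene {gene!r} absent from tissue profile")
    tissue_frac = tissue.fractions[gene]
    if tissue_frac <= 0:
        raise ApportionmentError(f"gene {gene!r} has zero tissue expression")

    contributions: Dict[str, float] = {}
    for est in estimates:
        ct = est.cell_type
        if ct not in cell_profiles:
            raise InvalidArgumentError(f"no profile supplied for cell type {ct!r}")
        prof = cell_profiles[ct]
        gene_frac = prof.fractions[gene] if gene in prof.gene_ids else 0.0
        contributions[ct] = float(est.fraction * gene_frac / tissue_frac)
    if hepatocyte_fraction is not None and HEPATOCYTE in cell_profiles:
        prof = cell_profiles[HEPATOCYTE]
        gene_frac = prof.fractions[gene] if gene in prof.gene_ids else 0.0
        contributions[HEPATOCYTE] = float(hepatocyte_fraction * gene_frac / tissue_frac)

    residual = 1.0 - sum(contributions.values())
    inconsistent = sum(contributions.values()) > 1.0 + 0.05
    if inconsistent:
        warnings.warn(
            f"contributions for gene {gene!r} sum to {sum(contributions.values()):.4g} > 1",
            InconsistencyWarning,
            stacklevel=2,
        )
    if residual_policy == "assign_hepatocyte" and HEPATOCYTE not in cell_profiles:
        contributions[HEPATOCYTE] = contributions.get(HEPATOCYTE, 0.0) + residual
        residual = 0.0
    return ApportionmentRow(
        gene=gene,
        per_type_contribution=contributions,
        residual=residual,
        inconsistent=inconsistent,
    )


def estimates_table(estimates: Sequence[CellFractionEstimate]) -> pd.DataFrame:
    """Tabulate estimates for reporting (cell_type, fraction, n_markers, ...)."""
    return pd.DataFrame(
        [
            {
                "cell_type": e.cell_type,
                "fraction": e.fraction,
                "raw_fraction": e.raw_fraction,
                "n_markers": e.n_markers,
                "dispersion": e.dispersion,
                "average": e.average,
                "clipped": e.clipped,
            }
            for e in estimates
        ]
    )


def apportionment_table(rows: Sequence[ApportionmentRow]) -> pd.DataFrame:
    """Tabulate apportionment rows: gene, one column per cell type, residual."""
    records = []
    for row in rows:
        rec = {"gene": row.gene, **row.per_type_contribution, "residual": row.residual}
        records.append(rec)
    return pd.DataFrame(records).set_index("gene")
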