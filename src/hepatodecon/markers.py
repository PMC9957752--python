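"""Cell-type-exclusive marker discovery and surrogate-library selection.

A marker for cell type c is a gene essentially unique to c across the
reference panel: its transcriptome fraction in c must reach
``min_own_fraction`` and in every other type must not exceed
``max_other_relative`` times its level in c.  Because the rule operates on
fractions it is invariant to any linear rescaling of the input profiles.

When no tissue-derived reference exists for a cell type (e.g. fibroblasts
or macrophages in liver), candidate libraries from other tissues are ranked
by Pearson correlation with the whole-tissue profile and the best-matching
one is adopted as a surrogate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import NormalizedProfile
from .errors import HepatodeconWarning, InvalidArgumentError, MarkerDeficitError

DEFAULT_MIN_OWN_FRACTION = 1e-5
DEFAULT_MAX_OTHER_RELATIVE = 0.05
DEFAULT_MIN_MARKERS = 5


@dataclass
class MarkerSet:
    """Genes deemed exclusive to one cell type.

    ``specificity`` is, per gene, the ratio of own-type expression to the
    maximum expression across the other types (inf for perfectly exclusive
    genes).
    """

    cell_type: str
    genes: List[str]
    specificity: pd.Series

    def __len__(self) -> int:
        return len(self.genes)


def find_cell_specific_genes(
    profiles: Dict[str, NormalizedProfile],
    min_own_fraction: float = DEFAULT_MIN_OWN_FRACTION,
    max_other_relative: float = DEFAULT_MAX_OTHER_RELATIVE,
    min_markers: int = DEFAULT_MIN_MARKERS,
) -> Dict[str, MarkerSet]:
    """Derive one exclusive marker set per cell type.

    Gene g belongs to the marker set of type c iff fraction_c(g) >=
    ``min_own_fraction`` and fraction_c'(g) <= ``max_other_relative`` *
    fraction_c(g) for every other type c'.  Raises
    :class:`MarkerDeficitError` naming the first type with fewer than
    ``min_markers`` survivors.
    """
    if len(profiles) < 2:
        raise InvalidArgumentError("need at least 2 cell-type profiles")
    frac = pd.concat({ct: p.fractions for ct, p in profiles.items()}, axis=1)
    if frac.isna().any().any():
        raise InvalidArgumentError("profiles do not share one gene universe")

    out: Dict[str, MarkerSet] = {}
    arr = frac.to_numpy()
    types = list(frac.columns)
    for j, ct in enumerate(types):
        own = arr[:, j]
        others = np.delete(arr, j, axis=1)
        max_other = others.max(axis=1)
        # a marker must be expressed in its own type, whatever the threshold
        ok = (own > 0) & (own >= min_own_fraction) & (max_other <= max_other_relative * own)
        genes = list(frac.index[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            spec = np.where(max_other > 0, own / np.where(max_other > 0, max_other, 1.0), np.inf)
        specificity = pd.Series(spec[ok], index=frac.index[ok])
        if len(genes) < min_markers:
            raise MarkerDeficitError(
                f"cell type {ct!r} has only {len(genes)} exclusive genes "
                f"(minimum {min_markers})"
            )
        out[ct] = MarkerSet(cell_type=ct, genes=genes, specificity=specificity)
    return out


def select_surrogate_library(
    candidates: Sequence[NormalizedProfile],
    whole_tissue: NormalizedProfile,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Rank candidate libraries by correlation with the whole-tissue profile.

    Correlation is Pearson's r on log2(1 + molecules-per-million) of the
    transcriptome fractions by default (the log compresses the heavy tail
    so a handful of dominant genes cannot drive the ranking);
    ``log_scale=False`` uses raw fractions.  Returns a DataFrame (candidate,
    r, n_genes) sorted best first; the top row is the surrogate.  A
    zero-variance candidate has undefined correlation and is ranked last
    with a warning.
    """
    if not candidates:
        raise InvalidArgumentError("no candidate libraries supplied")
    tissue_frac = whole_tissue.fractions

    def _transform(frac: pd.Series) -> np.ndarray:
        x = frac.to_numpy()
        return np.log2(1e6 * x + 1.0) if log_scale else x

    y = _transform(tissue_frac)
    rows = []
    for cand in candidates:
        frac = cand.fractions.reindex(tissue_frac.index)
        if frac.isna().any():
            raise InvalidArgumentError(
                f"candidate {cand.library_id!r} does not share the tissue gene universe"
            )
        x = _transform(frac)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(
                f"zero-variance candidate {cand.library_id!r}; correlation undefined",
                HepatodeconWarning,
                stacklevel=2,
            )
            r = np.nan
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append({"candidate": cand.library_id, "r": r, "n_genes": len(x)})
    report = pd.DataFrame(rows)
    # NaN (undefined) correlations sort to the bottom
    report = report.sort_values("r", ascending=False, na_position="last", kind="stable")
    return report.reset_index(drop=True)
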