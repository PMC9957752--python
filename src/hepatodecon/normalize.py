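"""Library preprocessing: biotype filtering, isoform collapsing, reads/kb.

The pipeline order is: remove extraneous biotypes (ribosomal, mitochondrial
and small RNAs dominate raw libraries without carrying cell-type signal),
collapse multi-isoform genes to the most abundant isoform, convert read
counts to molecule counts (reads/kb) by dividing by transcript length, and
finally apply a linear renormalization — either to the library total (giving
transcriptome fractions t/T) or to the median expressed gene.  Only linear
operations are used, so within-library transcript proportions are preserved
throughout.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Set

import numpy as np
import pandas as pd

from .containers import ExpressionLibrary, NormalizedProfile
from .errors import DataError, HepatodeconWarning, InvalidArgumentError

#: Biotypes removed by default: ribosomal RNA, mitochondrial RNA, small RNAs.
DEFAULT_EXCLUDED_BIOTYPES: frozenset = frozenset(
    {"rRNA", "Mt_rRNA", "Mt_tRNA", "miRNA", "snoRNA", "snRNA"}
)


def filter_extraneous(
    lib: ExpressionLibrary,
    excluded_biotypes: Iterable[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> ExpressionLibrary:
    """Drop genes whose biotype is in ``excluded_biotypes``.

    Counts of retained genes are untouched.  An excluded biotype that does
    not occur in the library triggers a warning, not an error, so a shared
    exclusion list can be applied across heterogeneous annotations.
    """
    excluded: Set[str] = set(excluded_biotypes)
    present = set(lib.biotype.dropna().unique())
    unknown = excluded - present
    if unknown:
        warnings.warn(
            f"excluded biotypes not present in library {lib.library_id!r}: {sorted(unknown)}",
            HepatodeconWarning,
            stacklevel=2,
        )
    keep = ~lib.biotype.isin(excluded)
    return ExpressionLibrary(
        library_id=lib.library_id,
        counts=lib.counts[keep],
        length_kb=lib.length_kb[keep],
        biotype=lib.biotype[keep],
        isoform_group=None if lib.isoform_group is None else lib.isoform_group[keep],
    )


def collapse_isoforms(lib: ExpressionLibrary) -> ExpressionLibrary:
    """Reduce each multi-isoform gene to its most abundant isoform.

    The retained row is the isoform with the largest raw count in this
    library; ties are broken by the lexicographically smallest transcript id
    so the choice is deterministic.  After collapsing, rows are indexed by
    gene id.  Libraries without an ``isoform_group`` pass through unchanged.
    """
    if lib.isoform_group is None:
        return lib
    df = pd.DataFrame(
        {
            "count": lib.counts,
            "length_kb": lib.length_kb,
            "biotype": lib.biotype,
            "gene": lib.isoform_group,
        }
    )
    df = df.sort_index()  # transcript-id order fixes tie-breaks
    best = df.sort_values("count", kind="stable", ascending=False).groupby("gene").head(1)
    # restore a stable gene order: first appearance in the original table
    gene_order = df["gene"].drop_duplicates()
    best = best.set_index("gene").loc[gene_order]
    return ExpressionLibrary(
        library_id=lib.library_id,
        counts=best["count"],
        length_kb=best["length_kb"],
        biotype=best["biotype"],
        isoform_group=None,
    )


def to_molecule_counts(lib: ExpressionLibrary) -> NormalizedProfile:
    """Convert read counts to molecule counts (reads/kb).

    Longer transcripts attract proportionally more reads at equal molecule
    number; dividing by transcript length in kb removes that bias.  Raises
    :class:`DataError` naming the first offending gene if any retained gene
    has a non-positive length.
    """
    bad = lib.length_kb.index[~(lib.length_kb > 0)]
    if len(bad):
        raise DataError(
            f"non-positive transcript length for gene {bad[0]!r} in library {lib.library_id!r}"
        )
    return NormalizedProfile(
        library_id=lib.library_id,
        molecule_counts=lib.counts / lib.length_kb,
        normalization_mode="none",
    )


def renormalize(profile: NormalizedProfile, mode: str = "total") -> NormalizedProfile:
    """Linearly rescale a profile.

    mode="total" divides by the library total so values sum to 1 (the
    transcriptome-fraction scale); mode="median" divides by the median over
    genes with nonzero expression (the median of a zero-inflated vector is
    often 0, which would be useless as a scale factor).
    """
    if mode not in ("total", "median"):
        raise InvalidArgumentError(f"unknown normalization mode {mode!r}")
    values = profile.molecule_counts
    if len(values) == 0 or not (values > 0).any():
        raise DataError(f"library {profile.library_id!r} is empty or all zero")
    if mode == "total":
        scale = float(values.sum())
    else:
        scale = float(np.median(values[values > 0]))
    return NormalizedProfile(
        library_id=profile.library_id,
        molecule_counts=values / scale,
        normalization_mode=mode,
    )


def average_profiles(profiles: list, library_id: str) -> NormalizedProfile:
    """Average replicate profiles of one cell type on the fraction scale."""
    if not profiles:
        raise InvalidArgumentError("no profiles to average")
    frac = pd.concat([p.fractions for p in profiles], axis=1)
    if frac.isna().any().any():
        raise DataError("replicate profiles do not share a gene universe")
    return NormalizedProfile(
        library_id=library_id,
        molecule_counts=frac.mean(axis=1),
        normalization_mode="total",
    )
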