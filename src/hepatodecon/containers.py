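"""In-memory containers shared across the pipeline.

The central objects are thin dataclasses around pandas structures:

* :class:`ExpressionLibrary` — one sequencing library's raw gene-level read
  counts together with the per-gene annotation (transcript length in kb,
  biotype, optional isoform grouping) needed to normalize it.
* :class:`NormalizedProfile` — the same library after conversion to molecule
  counts (reads/kb).  Its ``fractions`` (t/T, each gene's share of the total
  transcriptome) are the quantities the ratio estimator consumes.
* :class:`CohortMatrix` — a genes x samples expression table with per-sample
  metadata (group and/or ordinal stage), used by the signature and staging
  components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgumentError


@dataclass
class ExpressionLibrary:
    """Raw read counts for one library plus per-gene annotation.

    Parameters
    ----------
    library_id
        Label for the library (sample / cell type / run id).
    counts
        Per-gene nonnegative read counts, indexed by gene (or transcript) id.
    length_kb
        Transcript length in kilobases, same index as ``counts``.
    biotype
        Gene class label (``protein_coding``, ``rRNA``, ...), same index.
    isoform_group
        Optional mapping transcript id -> gene id; present when rows are
        transcripts that still need collapsing to one row per gene.
    """

    library_id: str
    counts: pd.Series
    length_kb: pd.Series
    biotype: pd.Series
    isoform_group: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        self.counts = pd.Series(self.counts, dtype=float)
        if not self.counts.index.is_unique and self.isoform_group is None:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise DataError(f"duplicate gene ids without isoform grouping: {list(dupes)[:5]}")
        if (self.counts < 0).any():
            bad = self.counts.index[self.counts < 0][0]
            raise DataError(f"negative count for gene {bad!r}")
        self.length_kb = pd.Series(self.length_kb, dtype=float).reindex(self.counts.index)
        self.biotype = pd.Series(self.biotype, dtype=object).reindex(self.counts.index)
        if self.isoform_group is not None:
            self.isoform_group = pd.Series(self.isoform_group, dtype=object).reindex(
                self.counts.index
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def n_genes(self) -> int:
        return len(self.counts)


@dataclass
class NormalizedProfile:
    """Length-normalized expression for one library.

    ``molecule_counts`` are reads/kb values (read count divided by transcript
    length in kb), a per-gene proxy for transcript molecule numbers.  The
    derived ``fractions`` t/T are scale free: any linear renormalization of
    the profile leaves them unchanged, which is what makes the downstream
    ratio estimator invariant to library size.
    """

    library_id: str
    molecule_counts: pd.Series
    normalization_mode: str = "none"  # none | total | median

    def __post_init__(self) -> None:
        self.molecule_counts = pd.Series(self.molecule_counts, dtype=float)
        if (self.molecule_counts < 0).any():
            bad = self.molecule_counts.index[self.molecule_counts < 0][0]
            raise DataError(f"negative molecule count for gene {bad!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.molecule_counts.index

    @property
    def total_molecules(self) -> float:
        return float(self.molecule_counts.sum())

    @property
    def fractions(self) -> pd.Series:
        total = self.total_molecules
        if total <= 0:
            raise DataError(f"library {self.library_id!r} has zero total expression")
        return self.molecule_counts / total


@dataclass
class CohortMatrix:
    """Genes x samples expression with per-sample metadata.

    ``samples`` is indexed by sample id and may carry a ``group`` column
    (two-condition comparisons) and/or a ``stage`` column (ordinal disease
    stage).  ``truth`` records generator ground truth (planted genes, effect
    sizes) when the matrix is synthetic; it is never consulted by estimators.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        self.samples = pd.DataFrame(self.samples)
        if not self.values.columns.equals(self.samples.index):
            missing = self.values.columns.symmetric_difference(self.samples.index)
            raise InvalidArgumentError(
                f"sample sheet does not match matrix columns; mismatched ids: {list(missing)[:5]}"
            )
        if np.isnan(self.values.to_numpy()).any():
            raise DataError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def stage_codes(self) -> pd.Series:
        """Ordinal stage per sample: numeric stages pass through, string
        labels are coded by sorted-unique order."""
        if "stage" not in self.samples.columns:
            raise InvalidArgumentError("cohort has no 'stage' column")
        stage = self.samples["stage"]
        if pd.api.types.is_numeric_dtype(stage):
            return stage.astype(float)
        order = {lab: i for i, lab in enumerate(sorted(stage.unique()))}
        return stage.map(order).astype(float)
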