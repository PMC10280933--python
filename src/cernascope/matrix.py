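"""Expression-matrix container shared by the DE and co-expression stages.

The matrix holds normalized log2 intensities for mRNAs and lncRNAs over a
two-group (case vs control) sample design. It is the single source of truth
for differential expression and for Pearson co-expression; downstream network
stages only ever see gene identifiers and summary statistics derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import read_tsv, write_tsv

BIOTYPES = ("mRNA", "lncRNA")
GROUPS = ("case", "control")


@dataclass
class ExpressionMatrix:
    """Log2 intensities (genes x samples) with gene biotypes and sample groups.

    Parameters
    ----------
    values
        DataFrame of log2 intensities, indexed by gene id, one column per
        sample id. All values must be finite.
    biotypes
        Series mapping gene id -> ``"mRNA"`` or ``"lncRNA"``, aligned with
        ``values.index``.
    groups
        Series mapping sample id -> ``"case"`` or ``"control"``, aligned with
        ``values.columns``. Each group needs at least two samples.
    """

    values: pd.DataFrame
    biotypes: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids in expression matrix")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValueError("non-finite values in expression matrix")
        if set(self.biotypes.index) != set(v.index):
            raise ValueError("biotype annotation does not cover all genes")
        if not self.biotypes.isin(BIOTYPES).all():
            bad = sorted(set(self.biotypes) - set(BIOTYPES))
            raise ValueError(f"unknown biotypes: {bad}")
        if set(self.groups.index) != set(v.columns):
            raise ValueError("group annotation does not cover all samples")
        if not self.groups.isin(GROUPS).all():
            bad = sorted(set(self.groups) - set(GROUPS))
            raise ValueError(f"unknown sample groups: {bad}")
        for g in GROUPS:
            if int((self.groups == g).sum()) < 2:
                raise ValueError(f"group '{g}' has fewer than 2 samples")
        # keep annotations in matrix order
        self.biotypes = self.biotypes.reindex(v.index)
        self.groups = self.groups.reindex(v.columns)

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.groups.index[self.groups == group])

    def group_values(self, group: str) -> np.ndarray:
        """Genes x samples array restricted to one group."""
        return self.values[self.samples_in(group)].to_numpy(dtype=float)

    def genes_of(self, biotype: str) -> pd.Index:
        return self.biotypes.index[self.biotypes == biotype]

    def swap_groups(self) -> "ExpressionMatrix":
        """Relabel case<->control (used for symmetry checks)."""
        flipped = self.groups.map({"case": "control", "control": "case"})
        return ExpressionMatrix(self.values.copy(), self.biotypes.copy(), flipped)


def read_expression(matrix_path: str | Path, samples_path: str | Path) -> ExpressionMatrix:
    """Read the matrix TSV (gene_id, biotype, <sample columns>) + sample sheet."""
    m = read_tsv(matrix_path)
    if "gene_id" not in m.columns or "biotype" not in m.columns:
        raise ValueError(f"{matrix_path}: expected 'gene_id' and 'biotype' columns")
    m = m.set_index("gene_id")
    biotypes = m.pop("biotype")
    s = read_tsv(samples_path)
    if "sample_id" not in s.columns or "group" not in s.columns:
        raise ValueError(f"{samples_path}: expected 'sample_id' and 'group' columns")
    groups = s.set_index("sample_id")["group"]
    return ExpressionMatrix(m, biotypes, groups)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     samples_path: str | Path) -> None:
    out = matrix.values.copy()
    out.insert(0, "biotype", matrix.biotypes)
    out.index.name = "gene_id"
    write_tsv(out.reset_index(), matrix_path)
    sheet = pd.DataFrame({"sample_id": matrix.sample_ids,
                          "group": matrix.groups.to_numpy()})
    write_tsv(sheet, samples_path)
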