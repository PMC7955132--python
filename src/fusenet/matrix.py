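"""Expression matrix container and plain-text I/O.

The central data structure of the pipeline is a genes x samples table of
non-negative FPKM-scale values, carrying a biotype label per gene and a
condition tag (``normal`` or ``cancer``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

VALID_BIOTYPES = frozenset({"protein_coding", "lncRNA", "miRNA"})


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with per-gene biotypes.

    Parameters
    ----------
    values:
        DataFrame indexed by gene id, columns are sample ids, entries are
        non-negative FPKM-scale floats.
    biotypes:
        Series indexed by gene id mapping to a biotype string
        (``protein_coding`` | ``lncRNA`` | ``miRNA`` or any other label,
        which the biotype filter will drop).
    condition:
        ``normal`` or ``cancer``.
    """

    values: pd.DataFrame
    biotypes: pd.Series
    condition: str = field(default="normal")

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = self.values.index.difference(self.biotypes.index)
        if len(missing) > 0:
            raise ValueError(f"genes without biotype annotation: {list(missing[:5])}")
        # keep biotypes aligned to the value rows
        self.biotypes = self.biotypes.reindex(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes: list[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` preserving the stored row order."""
        keep = [g for g in self.values.index if g in set(genes)]
        return ExpressionMatrix(
            values=self.values.loc[keep],
            biotypes=self.biotypes.loc[keep],
            condition=self.condition,
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: first column ``gene_id``, header row of sample ids."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        annotation: pd.Series | str | Path,
        condition: str = "normal",
    ) -> "ExpressionMatrix":
        """Read a matrix TSV plus a (path to a) gene_id -> biotype table."""
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index.name = None
        if not isinstance(annotation, pd.Series):
            annotation = read_annotation(annotation)
        return cls(values=values, biotypes=annotation, condition=condition)


def log_transform(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """log2(FPKM + 1) copy of a matrix; the scale used for network building."""
    import numpy as np

    return ExpressionMatrix(
        values=pd.DataFrame(
            np.log2(matrix.values.to_numpy() + 1.0),
            index=matrix.values.index,
            columns=matrix.values.columns,
        ),
        biotypes=matrix.biotypes,
        condition=matrix.condition,
    )


def read_annotation(path: str | Path) -> pd.Series:
    """Read a 2-column TSV (gene_id, biotype) into a Series."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0], name="biotype")


def write_annotation(biotypes: pd.Series, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": biotypes.index, "biotype": biotypes.to_numpy()})
    df.to_csv(path, sep="\t", index=False)
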