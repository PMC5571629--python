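"""Core containers: count tables and per-sample metadata.

A :class:`CountTable` is an integer abundance matrix (samples x taxa) with
per-sample sequencing depth defined as the row sum.  Metadata travels as a
plain :class:`pandas.DataFrame` indexed by sample id; the conventional
columns ``subject_id``, ``collection_order`` and ``body_site`` are required
by the screening stage and documented there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["CountTable", "read_metadata", "write_metadata"]


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer counts."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.df.to_numpy()
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        if values.size and not np.allclose(values, np.round(values)):
            raise ValueError("counts must be integral")
        self.df = self.df.astype(np.int64)
        if self.df.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate taxon identifiers")

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        return list(self.df.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.df.columns)

    @property
    def depths(self) -> pd.Series:
        """Total reads per sample (row sums)."""
        return self.df.sum(axis=1)

    @property
    def shape(self) -> tuple[int, int]:
        return self.df.shape

    def counts(self) -> np.ndarray:
        return self.df.to_numpy()

    def relative(self) -> pd.DataFrame:
        """Relative abundance (count / depth) per sample."""
        depths = self.depths.to_numpy(dtype=float)
        if (depths == 0).any():
            raise ValueError("cannot compute relative abundance for zero-depth samples")
        return self.df.div(depths, axis=0)

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.df.loc[list(samples)])

    def subset_taxa(self, taxa: Sequence[str]) -> "CountTable":
        missing = [t for t in taxa if t not in self.df.columns]
        if missing:
            raise KeyError(f"taxa not in table: {missing}")
        return CountTable(self.df.loc[:, list(taxa)])

    # -- serialization ---------------------------------------------------
    def to_tsv(self, path) -> None:
        out = self.df.T  # taxa x samples, the common OTU-table orientation
        out.index.name = "#OTU ID"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        return cls(df.T)

    def to_biom_json(self, path) -> None:
        """Write as a minimal BIOM v1.0 (JSON, dense) table."""
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "focaltax",
            "date": "1970-01-01T00:00:00",
            "matrix_type": "dense",
            "matrix_element_type": "int",
            "shape": [len(self.taxa), len(self.samples)],
            "rows": [{"id": t, "metadata": None} for t in self.taxa],
            "columns": [{"id": s, "metadata": None} for s in self.samples],
            "data": self.df.T.to_numpy().tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def from_biom_json(cls, path) -> "CountTable":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        if doc["matrix_type"] == "dense":
            mat = np.asarray(doc["data"])
        else:  # sparse: list of [row, col, value]
            mat = np.zeros((len(taxa), len(samples)))
            for r, c, v in doc["data"]:
                mat[int(r), int(c)] = v
        return cls(pd.DataFrame(mat.T, index=samples, columns=taxa))


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    meta.index = meta.index.astype(str)
    return meta


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t")
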