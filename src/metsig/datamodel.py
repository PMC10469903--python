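"""Core containers for the MetSig pipeline.

The pipeline works on three kinds of objects:

* :class:`ExpressionMatrix` — a gene-by-sample matrix of expression values
  (raw counts, log-normalised values, or row z-scores), wrapping a pandas
  DataFrame whose index holds gene identifiers and whose columns hold sample
  identifiers.
* sample annotation — a plain pandas DataFrame with columns
  ``sample_id, cohort, das28, treatment[, sex]`` (see :mod:`metsig.io`).
* :class:`SignatureDefinition` — an anchor gene plus the ordered list of
  signature genes, with per-gene provenance of the derivation filters passed.

The published six-gene metabolic signature anchored on CDC42 is shipped as a
built-in (:func:`builtin_signature`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

UNITS = ("raw_counts", "log_normalized", "z_scored")

#: the published six-gene metabolic signature and its anchor
METSIG_ANCHOR = "CDC42"
METSIG_GENES = ("ATP5BP", "COX7A2", "PSMB6", "PSME3", "GTF3C6", "GTF2E2")

#: transcription factors whose target sets constrain signature membership
METSIG_TFS = ("NFE2L1", "HOXA2", "NFRKB")


class FormatError(ValueError):
    """Raised when an input file or matrix violates the format contract."""


def _check_unique(ids: pd.Index, what: str) -> None:
    if ids.has_duplicates:
        dup = ids[ids.duplicated()].unique().tolist()
        raise FormatError(f"duplicate {what} id(s): {dup}")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix.

    Parameters
    ----------
    data:
        DataFrame with genes on the index and samples on the columns.
    unit:
        One of ``raw_counts``, ``log_normalized``, ``z_scored``.
    """

    data: pd.DataFrame
    unit: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {UNITS}")
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "gene")
        _check_unique(self.data.columns, "sample")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix must be numeric")
        if np.isnan(values).any():
            raise FormatError("expression matrix contains NaN entries")
        if self.unit == "raw_counts" and (values < 0).any():
            raise FormatError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def restrict(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Row-subset to ``genes`` (order preserved); missing genes are an error."""
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise KeyError(f"gene(s) absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(genes)], unit=self.unit)


@dataclass
class SignatureDefinition:
    """An anchor gene plus the ordered signature gene list.

    ``provenance`` maps each signature gene to a record of the derivation
    filters it passed, e.g. ``{"de_both_cohorts": True, "tf_target":
    ["NFE2L1"], "correlation_pass": True}``.  For hand-built or published
    signatures the record may simply say so.
    """

    anchor_gene: str
    genes: list[str]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature gene list is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature gene list contains duplicates")
        if self.anchor_gene in self.genes:
            raise ValueError(
                f"anchor gene {self.anchor_gene!r} may not be part of the signature"
            )

    def __len__(self) -> int:
        return len(self.genes)


def builtin_signature() -> SignatureDefinition:
    """The published CDC42-anchored six-gene metabolic signature."""
    prov = {g: {"source": "published six-gene metabolic signature"} for g in METSIG_GENES}
    return SignatureDefinition(METSIG_ANCHOR, list(METSIG_GENES), prov)


def validate_annotation(ann: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-annotation table and return it indexed by sample_id.

    Required columns: ``sample_id``, ``cohort``, ``das28``, ``treatment``.
    ``das28`` must lie in [0, 10] (the DAS28 clinical scale).
    """
    required = ["sample_id", "cohort", "das28", "treatment"]
    if "sample_id" not in ann.columns and ann.index.name == "sample_id":
        ann = ann.reset_index()
    missing = [c for c in required if c not in ann.columns]
    if missing:
        raise FormatError(f"annotation is missing column(s): {missing}")
    _check_unique(pd.Index(ann["sample_id"]), "sample")
    das28 = pd.to_numeric(ann["das28"], errors="raise")
    if ((das28 < 0) | (das28 > 10)).any():
        bad = ann.loc[(das28 < 0) | (das28 > 10), "sample_id"].tolist()
        raise FormatError(f"das28 outside [0, 10] for sample(s): {bad}")
    out = ann.copy()
    out["das28"] = das28.astype(float)
    return out.set_index("sample_id", drop=False)


def validate_tf_map(tfmap: dict[str, Iterable[str]]) -> dict[str, set[str]]:
    """Validate a TF→target map: every TF must have a non-empty target set."""
    out: dict[str, set[str]] = {}
    for tf, targets in tfmap.items():
        tset = {str(t) for t in targets}
        if not tset:
            raise FormatError(f"TF {tf!r} has an empty target set")
        out[str(tf)] = tset
    return out
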