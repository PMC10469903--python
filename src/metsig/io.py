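"""Readers and writers for the pipeline's on-disk formats.

* Counts: UTF-8 TSV, header row of sample ids, first column ``gene_id``.
* Annotation: CSV with columns ``sample_id,cohort,das28,treatment[,sex]``.
* TF targets: GMT (TF name, description, tab-separated gene list per line).
* Signatures: JSON with anchor, ordered gene list and per-gene provenance.
* Single-cell: matrix-market triplet (``matrix.mtx`` genes×cells,
  ``features.tsv``, ``barcodes.tsv``); mitochondrial genes are recognised by
  the ``MT-`` prefix unless an explicit list is given.

Writers produce a canonical form (tab/comma delimiters, ``\\n`` endings,
floats via ``%.10g``, integers without a decimal point) so that
``write(read(f))`` is byte-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .datamodel import (
    ExpressionMatrix,
    FormatError,
    SignatureDefinition,
    _check_unique,
    validate_annotation,
    validate_tf_map,
)

_FLOAT_FMT = "%.10g"


def _fmt(value) -> str:
    f = float(value)
    if f == int(f) and abs(f) < 1e15:
        return str(int(f))
    return _FLOAT_FMT % f


def read_counts_tsv(path) -> ExpressionMatrix:
    """Read a gene-by-sample counts TSV into an ExpressionMatrix (raw_counts).

    Row and column order are preserved.  Duplicate gene or sample ids and
    non-numeric cells are format errors naming the offender.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    sample_ids = pd.Index(header[1:])
    _check_unique(sample_ids, "sample")
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected a gene-id column plus >=1 sample column")
    df.columns = [header[0], *sample_ids]
    gene_col = df.columns[0]
    genes = df[gene_col]
    body = df.drop(columns=[gene_col])
    for col in body.columns:
        converted = pd.to_numeric(body[col], errors="coerce")
        bad = converted.isna() & body[col].notna()
        if bad.any():
            row = genes[bad].iloc[0]
            raise FormatError(
                f"{path}: non-numeric value {body.loc[bad, col].iloc[0]!r} "
                f"at gene {row!r}, sample {col!r}"
            )
        if converted.isna().any():
            raise FormatError(f"{path}: missing value in sample {col!r}")
        body[col] = converted
    body.index = pd.Index(genes, name="gene_id")
    return ExpressionMatrix(body, unit="raw_counts")


def write_counts_tsv(m: ExpressionMatrix, path) -> None:
    """Write an ExpressionMatrix as canonical TSV (see module docstring)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(str(s) for s in m.sample_ids) + "\n")
        values = m.data.to_numpy()
        for gene, row in zip(m.gene_ids, values):
            fh.write(str(gene) + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


def read_annotation_csv(path) -> pd.DataFrame:
    """Read and validate a sample-annotation CSV (indexed by sample_id)."""
    ann = pd.read_csv(path)
    return validate_annotation(ann)


def write_annotation_csv(ann: pd.DataFrame, path) -> None:
    cols = [c for c in ["sample_id", "cohort", "das28", "treatment", "sex"] if c in ann.columns]
    out = ann.reset_index(drop=True)[cols]
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(cols) + "\n")
        for _, row in out.iterrows():
            cells = [_fmt(v) if isinstance(v, (int, float, np.floating)) else str(v) for v in row]
            fh.write(",".join(cells) + "\n")


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT file into a TF → target-gene-set mapping."""
    mapping: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
            mapping[parts[0]] = set(parts[2:])
    return validate_tf_map(mapping)


def write_gmt(tfmap: dict[str, set[str]], path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        for tf in sorted(tfmap):
            fh.write("\t".join([tf, "na", *sorted(tfmap[tf])]) + "\n")


def read_signature_json(path) -> SignatureDefinition:
    with Path(path).open(encoding="utf-8") as fh:
        obj = json.load(fh)
    return SignatureDefinition(obj["anchor_gene"], list(obj["genes"]), obj.get("provenance", {}))


def write_signature_json(sig: SignatureDefinition, path) -> None:
    obj = {"anchor_gene": sig.anchor_gene, "genes": sig.genes, "provenance": sig.provenance}
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_sc_mtx(directory, mito_prefix: str = "MT-") -> ad.AnnData:
    """Read a matrix-market triplet directory into an AnnData (cells × genes).

    Expects ``matrix.mtx`` (genes × cells), ``features.tsv``, ``barcodes.tsv``.
    Raw counts go to ``layers['counts']`` and ``X``; ``var['mito']`` marks
    genes whose id starts with ``mito_prefix``.
    """
    directory = Path(directory)
    mat = spio.mmread(directory / "matrix.mtx")
    genes = pd.read_csv(directory / "features.tsv", sep="\t", header=None)[0].astype(str)
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    counts = np.asarray(sparse.csr_matrix(mat).todense()).T  # cells x genes
    adata = ad.AnnData(
        X=counts.astype(float),
        obs=pd.DataFrame(index=pd.Index(cells, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    adata.layers["counts"] = adata.X.copy()
    adata.var["mito"] = adata.var_names.str.startswith(mito_prefix)
    from .sc import compute_qc_metrics  # deferred: sc imports scanpy

    compute_qc_metrics(adata)
    return adata


def write_sc_mtx(adata: ad.AnnData, directory) -> None:
    """Write counts as a matrix-market triplet (genes × cells)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    counts = adata.layers.get("counts", adata.X)
    mat = sparse.coo_matrix(np.asarray(counts).T)  # genes x cells
    spio.mmwrite(str(directory / "matrix.mtx"), mat, field="integer")
    pd.Series(adata.var_names).to_csv(
        directory / "features.tsv", sep="\t", header=False, index=False
    )
    pd.Series(adata.obs_names).to_csv(
        directory / "barcodes.tsv", sep="\t", header=False, index=False
    )
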