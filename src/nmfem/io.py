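"""Readers and writers for the standard on-disk formats.

Expression matrices are TSV/CSV (first column gene id, header row sample
ids; gzip transparent) or MatrixMarket with separate row/column id files.
Gene lengths come as a two-column TSV or as GTF-style exon records.  PPI
networks are two-column edge lists or GraphML.
"""

from __future__ import annotations

import gzip
from importlib import resources
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from nmfem.preprocess import gene_length_from_annotation, validate_matrix

__all__ = [
    "read_expression_matrix",
    "write_expression_matrix",
    "read_gene_lengths",
    "read_exon_intervals",
    "read_gene_list",
    "default_housekeeping_genes",
    "read_labels",
    "read_ppi",
    "write_ppi",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_expression_matrix(path, row_ids=None, col_ids=None) -> pd.DataFrame:
    """Load a genes x samples matrix from TSV/CSV (or MTX with id files)."""
    path = Path(path)
    stem = path.name.removesuffix(".gz")
    if stem.endswith(".mtx"):
        if row_ids is None or col_ids is None:
            raise ValueError("MatrixMarket input needs row_ids and col_ids files")
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        genes = [line.strip() for line in _open_text(row_ids) if line.strip()]
        samples = [line.strip() for line in _open_text(col_ids) if line.strip()]
        m = pd.DataFrame(np.asarray(mat), index=genes, columns=samples)
    else:
        sep = "," if stem.endswith(".csv") else "\t"
        m = pd.read_csv(path, sep=sep, index_col=0)
        m.index = m.index.astype(str)
    m.index.name = None
    m.columns.name = None
    return validate_matrix(m)


def write_expression_matrix(m: pd.DataFrame, path):
    path = Path(path)
    sep = "," if path.name.removesuffix(".gz").endswith(".csv") else "\t"
    m.to_csv(path, sep=sep, index_label="gene_id")


def read_exon_intervals(path) -> dict[str, list[tuple[int, int]]]:
    """Per-gene exon (start, end) intervals from GTF-style records.

    Only ``exon`` features are used; coordinates are 1-based inclusive and
    the gene id is taken from the attributes field.
    """
    import gffutils

    records: dict[str, list[tuple[int, int]]] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            feat = gffutils.feature.feature_from_line(line)
            if feat.featuretype != "exon":
                continue
            gene = (feat.attributes.get("gene_id") or feat.attributes.get("gene_name"))
            if not gene:
                raise ValueError(f"exon record without gene_id: {line[:80]}")
            records.setdefault(gene[0], []).append((feat.start, feat.end))
    if not records:
        raise ValueError(f"no exon records found in {path}")
    return records


def read_gene_lengths(path) -> pd.Series:
    """Gene lengths from a two-column TSV (gene_id, length_bp) or a GTF file."""
    path = Path(path)
    stem = path.name.removesuffix(".gz")
    if stem.endswith((".gtf", ".gff", ".gff3")):
        return gene_length_from_annotation(read_exon_intervals(path))
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene length table needs two columns: gene_id, length_bp")
    first = df.iloc[0, 1]
    try:
        float(first)
    except ValueError:  # header row
        df = df.iloc[1:]
    lengths = pd.Series(df.iloc[:, 1].astype(float).astype(int).to_numpy(),
                        index=df.iloc[:, 0].astype(str), name="length")
    if (lengths < 1).any():
        raise ValueError("gene lengths must be positive integers (bp)")
    if lengths.index.duplicated().any():
        raise ValueError("duplicate gene ids in length table")
    return lengths


def read_gene_list(path) -> list[str]:
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def default_housekeeping_genes() -> list[str]:
    """The packaged default housekeeping list (mouse gene symbols)."""
    text = resources.files("nmfem").joinpath("data/housekeeping_default.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip() and not line.startswith("#")]


def read_labels(path) -> pd.Series:
    """Per-sample labels from a two-column TSV (sample_id, label); header optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.iloc[0, 0] in ("sample_id", "sample", "cell", "cell_id"):
        df = df.iloc[1:]
    return pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="label")


def read_ppi(path) -> nx.Graph:
    """An undirected simple PPI graph from a two-column edge list or GraphML."""
    path = Path(path)
    if path.name.removesuffix(".gz").endswith(".graphml"):
        g = nx.Graph(nx.read_graphml(path))
    else:
        g = nx.Graph()
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise ValueError(f"edge list line with fewer than 2 columns: {line[:80]}")
                g.add_edge(parts[0], parts[1])
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def write_ppi(g: nx.Graph, path):
    path = Path(path)
    if path.suffix == ".graphml":
        nx.write_graphml(g, path)
    else:
        with open(path, "w") as fh:
            for u, v in sorted(g.edges):
                fh.write(f"{u}\t{v}\n")
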