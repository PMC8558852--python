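"""Readers and writers for the pipeline's tabular interchange formats.

Counts travel as TSV (genes x samples, header row of sample ids) or
MatrixMarket with sidecar gene/sample id lists; sample metadata and gene
annotation as TSV; annotation additionally as minimal gene-line GTF.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .synthetic import CountData

__all__ = [
    "write_counts_tsv",
    "read_counts_tsv",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_sample_meta",
    "read_sample_meta",
    "write_annotation",
    "read_annotation",
    "write_annotation_gtf",
    "read_annotation_gtf",
]


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t", index_label="gene_id")
    return path


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_counts_mtx(counts: pd.DataFrame, path: str | Path) -> Path:
    """MatrixMarket matrix plus ``<stem>.genes.txt`` / ``<stem>.samples.txt`` sidecars."""
    path = Path(path)
    scipy.io.mmwrite(path, scipy.sparse.csr_matrix(counts.to_numpy()))
    stem = path.with_suffix("")
    stem.with_suffix(".genes.txt").write_text("\n".join(counts.index) + "\n")
    stem.with_suffix(".samples.txt").write_text("\n".join(counts.columns) + "\n")
    return path if path.suffix == ".mtx" else path.with_suffix(".mtx")


def read_counts_mtx(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    mat = scipy.io.mmread(path).toarray().astype(np.int64)
    stem = path.with_suffix("")
    genes = stem.with_suffix(".genes.txt").read_text().split()
    samples = stem.with_suffix(".samples.txt").read_text().split()
    return pd.DataFrame(mat, index=genes, columns=samples)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    meta.to_csv(path, sep="\t", index_label="sample_id")
    return path


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_annotation(ann: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    ann.to_csv(path, sep="\t", index=False)
    return path


def read_annotation(path: str | Path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    return ann.set_index("gene_id", drop=False)


def write_annotation_gtf(ann: pd.DataFrame, path: str | Path, source: str = "coexdiff") -> Path:
    """Minimal GTF with one ``gene`` line per gene."""
    path = Path(path)
    lines = []
    for _, r in ann.iterrows():
        attrs = (
            f'gene_id "{r["gene_id"]}"; gene_name "{r["symbol"]}"; '
            f'gene_biotype "{r["biotype"]}";'
        )
        lines.append(
            "\t".join(
                [
                    str(r["chrom"]), source, "gene", str(int(r["start"])),
                    str(int(r["end"])), ".", str(r["strand"]), ".", attrs,
                ]
            )
        )
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def read_annotation_gtf(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, _src, feature, start, end, _score, strand, _frame, attrs = line.split("\t")
        if feature != "gene":
            continue
        fields = {}
        for item in attrs.strip().split(";"):
            item = item.strip()
            if not item:
                continue
            key, _, val = item.partition(" ")
            fields[key] = val.strip('"')
        rows.append(
            {
                "gene_id": fields["gene_id"],
                "symbol": fields.get("gene_name", fields["gene_id"]),
                "biotype": fields.get("gene_biotype", ""),
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "strand": strand,
            }
        )
    ann = pd.DataFrame(
        rows, columns=["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"]
    )
    return ann.set_index("gene_id", drop=False)


def load_count_data(counts_path: str | Path, meta_path: str | Path) -> CountData:
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = read_counts_mtx(counts_path)
    else:
        counts = read_counts_tsv(counts_path)
    meta = read_sample_meta(meta_path)
    return CountData(counts=counts, sample_meta=meta.loc[counts.columns])
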