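"""Plain-TSV readers and writers for every table the pipeline exchanges.

All intermediates are UTF-8 TSV with '.' decimal separators so each stage can
be inspected and re-run independently.
"""

from __future__ import annotations

import pandas as pd

#: the four treatment conditions of the RNA-seq design, in display order
CONDITIONS = ("Control", "Paraquat", "Cdk12i", "Cdk12i_Paraquat")

SCREEN_COLUMNS = ["plate_id", "well_id", "gene_id", "dsrna_id", "fluc", "rluc", "control_role"]


def read_screen_table(path) -> pd.DataFrame:
    """Read a well-level screen table.

    Expected header: ``plate_id well_id gene_id dsrna_id fluc rluc control_role``.
    A missing ``control_role`` column is filled with ``"none"``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"plate_id": str, "well_id": str,
                                            "gene_id": str, "dsrna_id": str})
    missing = [c for c in SCREEN_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise ValueError(f"screen table {path} lacks columns: {missing}")
    if "control_role" not in df.columns:
        df["control_role"] = "none"
    df["control_role"] = df["control_role"].fillna("none").astype(str)
    df["fluc"] = df["fluc"].astype(float)
    df["rluc"] = df["rluc"].astype(float)
    if (df["fluc"] < 0).any():
        raise ValueError("negative firefly luminescence counts")
    return df[SCREEN_COLUMNS]


def write_screen_table(df: pd.DataFrame, path) -> None:
    df[SCREEN_COLUMNS].to_csv(path, sep="\t", index=False)


def read_count_matrix(path) -> pd.DataFrame:
    """Read a gene x sample count matrix (first column ``gene_id``)."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if df.columns[0] != "gene_id":
        raise ValueError("count matrix must start with a gene_id column")
    df = df.set_index("gene_id")
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dupes[:5]}")
    if df.columns.duplicated().any():
        raise ValueError("duplicate sample ids")
    counts = df.astype(int)
    if (counts < 0).any().any():
        raise ValueError("negative counts")
    return counts


def write_count_matrix(counts: pd.DataFrame, path) -> None:
    counts.rename_axis("gene_id").to_csv(path, sep="\t")


def read_sample_design(path) -> pd.DataFrame:
    """Read a ``sample_id condition replicate`` design table, indexed by sample."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "condition": str})
    for col in ("sample_id", "condition"):
        if col not in df.columns:
            raise ValueError(f"design table lacks column {col!r}")
    if "replicate" not in df.columns:
        df["replicate"] = df.groupby("condition").cumcount() + 1
    df = df.set_index("sample_id")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample ids in design")
    return df


def write_sample_design(design: pd.DataFrame, path) -> None:
    design.rename_axis("sample_id").to_csv(path, sep="\t")


def read_annotation(path) -> pd.DataFrame:
    """Read a GAF-lite annotation table: ``term_id term_name gene_id`` per line."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("term_id", "term_name", "gene_id"):
        if col not in df.columns:
            raise ValueError(f"annotation table lacks column {col!r}")
    return df[["term_id", "term_name", "gene_id"]]


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann[["term_id", "term_name", "gene_id"]].to_csv(path, sep="\t", index=False)


def read_gene_list(path) -> list[str]:
    with open(path, encoding="utf-8") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")
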