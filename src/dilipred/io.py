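"""Readers and writers for the tabular interchange formats used by the pipeline.

Expression matrices travel as GCT 1.2 (one file per cell line) or as long
TSV with columns (gene, drug, z); labels and feature tables as CSV with a
header row; merged signatures as TSV (drug, gene, rank); extreme sets and
ground truth as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd


def write_gct(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x samples matrix as GCT 1.2.

    Row index = gene ids (Name column; Description left as the gene id),
    columns = sample/drug ids.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("#1.2\n")
        fh.write(f"{matrix.shape[0]}\t{matrix.shape[1]}\n")
        fh.write("Name\tDescription\t" + "\t".join(map(str, matrix.columns)) + "\n")
        for gene, row in matrix.iterrows():
            fh.write(str(gene) + "\t" + str(gene) + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_gct(path: str | Path) -> pd.DataFrame:
    """Read a GCT 1.2 file into a genes x samples DataFrame."""
    path = Path(path)
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValueError(f"unsupported GCT version line: {version!r}")
        nrow, ncol = map(int, fh.readline().split())
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df = df.drop(columns=["Description"])
    if df.shape != (nrow, ncol):
        raise ValueError(f"GCT header promises {(nrow, ncol)}, file contains {df.shape}")
    df.index.name = "gene"
    return df


def write_long_tsv(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a genes x drugs matrix as long TSV (gene, drug, z)."""
    long = matrix.stack().rename("z").rename_axis(["gene", "drug"]).reset_index()
    long.to_csv(path, sep="\t", index=False)


def read_long_tsv(path: str | Path) -> pd.DataFrame:
    """Read a long TSV (gene, drug, z) back into a genes x drugs matrix."""
    long = pd.read_csv(path, sep="\t")
    return long.pivot(index="gene", columns="drug", values="z")


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")
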