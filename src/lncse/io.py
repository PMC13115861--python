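"""Readers and writers for the plain-text formats the pipeline consumes.

BED3/BED6, narrowPeak (BED6+4), two-column chrom.sizes, and the TSV tables
(manifests, correlation peaks, gene annotation, expression matrices).
Writers emit sorted, tab-separated, newline-terminated records with no header
for BED-family files.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .intervals import ChromSizes, IntervalSet

BED6_COLS = ["chrom", "start", "end", "name", "score", "strand"]
NARROWPEAK_COLS = BED6_COLS + ["signal", "pvalue", "qvalue", "summit"]


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return ChromSizes(dict(zip(df["chrom"].astype(str), df["length"].astype(int))))


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_bed(path: str | Path) -> IntervalSet:
    """Read BED3/BED6/narrowPeak; extra columns are kept under standard names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = df.shape[1]
    if ncol < 3:
        raise ValueError(f"{path}: BED file needs >=3 columns, found {ncol}")
    names = (NARROWPEAK_COLS + [f"extra{i}" for i in range(ncol)])[:ncol]
    df.columns = names
    return IntervalSet(df).sort()


def write_bed(ivs: IntervalSet, path: str | Path, columns: list[str] | None = None) -> None:
    df = ivs.sort().df
    cols = columns or [c for c in df.columns if c in set(NARROWPEAK_COLS)]
    # BED column order is fixed; keep only a contiguous prefix of the schema
    ordered = [c for c in NARROWPEAK_COLS if c in cols]
    prefix = []
    for c in NARROWPEAK_COLS:
        if c in ordered:
            prefix.append(c)
        else:
            break
    df[prefix].to_csv(path, sep="\t", header=False, index=False)


def read_manifest(path: str | Path, required: list[str]) -> pd.DataFrame:
    """Read a TSV manifest and check required columns; paths resolved later."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest lacks columns {missing}")
    return df


def read_correlation_peaks(path: str | Path) -> pd.DataFrame:
    """lncRNA-histone-mark correlation peak table.

    Columns: chrom, start, end, lncrna_id, mark, sign [, rho].
    """
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "lncrna_id", "mark", "sign"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: correlation peak table lacks columns {missing}")
    return df


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """genes x samples matrix of log2(TPM+1); first column is the gene id."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df
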