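"""Strict TSV / GMT readers and writers (all tables are plain text)."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

GENOTYPES = ("WT", "myc2", "ein3eil1", "myc2ein3eil1")
TREATMENTS = ("JA", "Mock")


class DataError(ValueError):
    """Malformed input data (exit code 2 territory in the CLI)."""


def read_counts(path) -> pd.DataFrame:
    """Gene x sample integer count matrix; first column = gene id."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise DataError(f"{path}: counts need a gene id column plus samples")
    gene_col = df.columns[0]
    dup = df[gene_col][df[gene_col].duplicated()]
    if not dup.empty:
        raise DataError(f"{path}: duplicate gene id {dup.iloc[0]!r}")
    df = df.set_index(gene_col)
    df.index.name = "gene_id"
    if df.columns.duplicated().any():
        raise DataError(f"{path}: duplicate sample columns")
    for col in df.columns:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any() or (values < 0).any() or (values % 1 != 0).any():
            raise DataError(f"{path}: column {col!r} has non-(non-negative-integer) counts")
        df[col] = values.astype(int)
    return df


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "genotype", "treatment", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"{path}: sample sheet missing columns {sorted(missing)}")
    dup = df["sample_id"][df["sample_id"].duplicated()]
    if not dup.empty:
        raise DataError(f"{path}: duplicate sample id {dup.iloc[0]!r}")
    bad_geno = set(df["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise DataError(f"{path}: unknown genotype(s) {sorted(bad_geno)}")
    bad_treat = set(df["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise DataError(f"{path}: unknown treatment(s) {sorted(bad_treat)}")
    df["replicate"] = df["replicate"].astype(int)
    return df


def validate_design(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    """Every genotype x treatment cell present with >= 2 replicates; columns match."""
    missing_cols = set(samples["sample_id"]) - set(counts.columns)
    if missing_cols:
        raise DataError(f"samples absent from count matrix: {sorted(missing_cols)}")
    for geno in GENOTYPES:
        for treat in TREATMENTS:
            n = ((samples["genotype"] == geno) & (samples["treatment"] == treat)).sum()
            if n < 2:
                raise DataError(
                    f"design incomplete: {geno},{treat} has {n} replicate(s), need >= 2"
                )


def read_gmt(path) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT gene sets: term, description, members...; returns (sets, names)."""
    sets: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has < 3 fields")
            term, desc, members = fields[0], fields[1], fields[2:]
            if term in sets:
                raise DataError(f"{path}:{lineno}: duplicate term {term!r}")
            member_set = {m for m in members if m}
            if not member_set:
                raise DataError(f"{path}:{lineno}: term {term!r} has no members")
            sets[term] = member_set
            names[term] = desc
    return sets, names


def write_tsv(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
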