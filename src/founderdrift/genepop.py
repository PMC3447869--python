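"""Reading and writing genotype tables: Genepop and wide-CSV dialects.

Genepop files have a free-text title line, one locus name per line (or a
single comma-separated line), then ``Pop`` blocks of individuals::

    Finnish white-tailed deer
    Cervid1
    INRA011
    Pop
    ind_1 ,  001002 003003

Diploid genotypes are concatenated fixed-width allele codes (2 or 3 digits
per allele); ``00``/``000`` is missing. The wide CSV dialect has one row
per individual with two integer columns per locus (``<locus>_1``,
``<locus>_2``) and missing data coded 0.
"""
from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd

from .popgen import GenotypeTable

__all__ = ["read_genepop", "write_genepop", "read_wide_csv", "write_wide_csv", "read_table"]


class GenepopParseError(ValueError):
    """Malformed Genepop input; the message names the offending line."""


def read_genepop(path) -> GenotypeTable:
    """Parse the first population block of a Genepop file."""
    tables = read_genepop_all(path)
    return tables[0]


def read_genepop_all(path) -> list[GenotypeTable]:
    """Parse every ``Pop`` block of a Genepop file into genotype tables."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError(f"{path}: empty file")
    title = lines[0].strip()
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise GenepopParseError(f"{path}: no locus names before first 'Pop' (line {i + 1})")
    if i == len(lines):
        raise GenepopParseError(f"{path}: no 'Pop' line found")

    tables: list[GenotypeTable] = []
    block_rows: list[list[tuple[int, int]]] = []
    block_no = 0
    code_len: int | None = None  # allele-code width is fixed per file

    def flush() -> None:
        nonlocal block_rows
        if block_no:
            if not block_rows:
                raise GenepopParseError(f"{path}: empty Pop block #{block_no}")
            arr = np.array(block_rows, dtype=np.int64)
            tables.append(GenotypeTable(
                loci=list(loci), alleles=arr,
                population=f"{title} pop{block_no}" if len(tables) else title,
            ))
            block_rows = []

    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            flush()
            block_no += 1
            continue
        if "," not in line:
            raise GenepopParseError(
                f"{path}, line {lineno + 1}: expected '<id> , <genotypes>'"
            )
        _, geno_part = line.split(",", 1)
        codes = geno_part.split()
        if len(codes) != len(loci):
            raise GenepopParseError(
                f"{path}, line {lineno + 1}: {len(codes)} genotype fields for "
                f"{len(loci)} loci"
            )
        row = []
        for code in codes:
            if len(code) not in (4, 6) or not code.isdigit():
                raise GenepopParseError(
                    f"{path}, line {lineno + 1}: bad genotype code {code!r}"
                )
            if code_len is None:
                code_len = len(code)
            elif len(code) != code_len:
                raise GenepopParseError(
                    f"{path}, line {lineno + 1}: genotype code {code!r} has "
                    f"{len(code)} digits but the file uses {code_len}"
                )
            w = len(code) // 2
            row.append((int(code[:w]), int(code[w:])))
        block_rows.append(row)
    flush()
    if not tables:
        raise GenepopParseError(f"{path}: no individuals found")
    return tables


def write_genepop(table: GenotypeTable, path, title: str | None = None,
                  digits: int = 3) -> None:
    """Write one population as a Genepop file with fixed-width allele codes."""
    if digits not in (2, 3):
        raise ValueError("Genepop allele codes use 2 or 3 digits")
    if int(table.alleles.max(initial=0)) >= 10**digits:
        raise ValueError(f"allele labels too large for {digits}-digit Genepop codes")
    buf = io.StringIO()
    buf.write((title or table.population or "founderdrift export") + "\n")
    for locus in table.loci:
        buf.write(locus + "\n")
    buf.write("Pop\n")
    for i in range(table.n_individuals):
        codes = " ".join(
            f"{int(a):0{digits}d}{int(b):0{digits}d}"
            for a, b in table.alleles[i]
        )
        buf.write(f"ind_{i + 1} ,  {codes}\n")
    Path(path).write_text(buf.getvalue())


def write_wide_csv(table: GenotypeTable, path) -> None:
    """One row per individual; two integer columns per locus; 0 = missing."""
    df = table.to_dataframe()
    df.insert(0, "id", [f"ind_{i + 1}" for i in range(table.n_individuals)])
    df.to_csv(path, index=False)


def read_wide_csv(path, population: str = "") -> GenotypeTable:
    df = pd.read_csv(path)
    if "id" in df.columns:
        df = df.drop(columns=["id"])
    try:
        return GenotypeTable.from_dataframe(df, population=population or str(path))
    except ValueError as exc:
        raise GenepopParseError(f"{path}: {exc}") from exc


def read_table(path, fmt: str = "auto") -> GenotypeTable:
    """Read a genotype table, sniffing Genepop vs wide CSV when ``auto``."""
    path = Path(path)
    if fmt == "auto":
        fmt = "csv" if path.suffix.lower() == ".csv" else "genepop"
    if fmt == "csv":
        return read_wide_csv(path)
    if fmt == "genepop":
        return read_genepop(path)
    raise ValueError(f"unknown format {fmt!r}")
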