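"""Readers/writers for the genotype-matrix formats the pipeline touches.

Three dialects are supported:

* **genepop** — title line, one locus name per line, ``Pop`` separators,
  individual lines ``id , 0101 0202``.  Allele field width (2- or
  3-digit) is auto-detected from token length; ``00``/``000`` encodes a
  missing allele, and a genotype must be fully called or fully missing.
* **structure** — two rows per individual, one column per locus,
  ``-9`` for missing, optional integer population column, locus-name
  header row.
* **csv** — the canonical dialect of this package: one row per
  individual, two columns per locus named ``LOCUS.1``/``LOCUS.2``,
  metadata columns ``id, population, morphology, sex, x, y, material``;
  empty cell = missing.  Unlike the grid formats it is lossless for
  metadata.

Multiple sampling locations per individual do not fit a grid format and
live in a separate long-format CSV (``id, x, y, date``), see
:func:`read_coordinates` / :func:`write_coordinates`.
"""

from __future__ import annotations

import io
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset

FORMATS = ("genepop", "structure", "csv")


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def read_dataset(path: str | Path, format: str) -> Dataset:
    """Read a genotype file in the named dialect into a :class:`Dataset`."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    reader = {"genepop": read_genepop, "structure": read_structure, "csv": read_csv}[format]
    return reader(path)


def write_dataset(ds: Dataset, path: str | Path, format: str) -> None:
    """Write a :class:`Dataset` in the named dialect."""
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    writer = {"genepop": write_genepop, "structure": write_structure, "csv": write_csv}[format]
    writer(ds, path)


# ----------------------------------------------------------------------
# GenePop
# ----------------------------------------------------------------------

def read_genepop(path: str | Path) -> Dataset:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError("line 1: empty file (missing title line)")
    # locus names: one per line, or a single comma-separated line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = lines[i].strip()
        if chunk:
            loci.extend(name.strip() for name in chunk.split(",") if name.strip())
        i += 1
    if not loci:
        raise ParseError(f"line {i + 1}: no locus names before first 'Pop'")
    if len(set(loci)) != len(loci):
        raise ParseError("duplicated locus names in header")

    ids: list[str] = []
    pops: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    width: int | None = None
    pop_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            pop_idx += 1
            continue
        if pop_idx == 0:
            raise ParseError(f"line {i}: individual line before first 'Pop'")
        if "," not in line:
            raise ParseError(f"line {i}: expected 'id , genotypes'")
        ident, _, geno_part = line.partition(",")
        ident = ident.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise ParseError(
                f"line {i}: {len(tokens)} genotype tokens for {len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if not tok.isdigit() or len(tok) not in (4, 6):
                raise ParseError(f"line {i}: bad genotype token {tok!r}")
            w = len(tok) // 2
            if width is None:
                width = w
            elif w != width:
                raise ParseError(
                    f"line {i}: mixed allele field widths ({w}- vs {width}-digit)"
                )
            a, b = int(tok[:w]), int(tok[w:])
            if (a == 0) ^ (b == 0):
                raise ParseError(f"line {i}: half-missing genotype {tok!r}")
            row.append((MISSING, MISSING) if a == 0 else (a, b))
        if ident in ids:
            raise ParseError(f"line {i}: duplicated individual ID {ident!r}")
        ids.append(ident)
        pops.append(f"pop{pop_idx}")
        rows.append(row)

    geno = np.array(rows, dtype=np.int64).reshape(len(ids), len(loci), 2)
    meta = pd.DataFrame({"population": pops}, index=ids)
    return Dataset(ids=ids, loci=loci, genotypes=geno, meta=meta)


def write_genepop(ds: Dataset, path: str | Path, title: str = "wildhyb export") -> None:
    called = ds.genotypes[ds.genotypes != MISSING]
    max_code = int(called.max()) if called.size else 0
    if called.size and int(called.min()) < 1:
        raise ValueError("GenePop allele codes must be >= 1 (0 encodes missing)")
    if max_code > 999:
        raise ValueError(
            f"allele code {max_code} exceeds GenePop's 3-digit field width"
        )
    width = 2 if max_code <= 99 else 3
    out = [title]
    out.extend(ds.loci)
    for pop in ds.populations or []:
        out.append("Pop")
        for i in ds.population_indices(pop):
            toks = []
            for l in range(ds.n_loci):
                a, b = ds.genotypes[i, l]
                if a == MISSING:
                    a = b = 0
                toks.append(f"{a:0{width}d}{b:0{width}d}")
            out.append(f"{ds.ids[i]} ,  " + " ".join(toks))
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
# STRUCTURE (two-row)
# ----------------------------------------------------------------------

def read_structure(path: str | Path, pop_column: bool = True) -> Dataset:
    lines = [ln for ln in Path(path).read_text().splitlines()]
    body = [(n + 1, ln.split()) for n, ln in enumerate(lines) if ln.strip()]
    if not body:
        raise ParseError("empty STRUCTURE file")
    header = body[0][1]
    data = body[1:]
    n_loci = len(header)
    n_extra = 2 if pop_column else 1
    if len(data) % 2:
        raise ParseError("odd number of data rows (two rows per individual expected)")
    ids: list[str] = []
    pops: list[str] = []
    rows = []
    for (ln1, r1), (ln2, r2) in zip(data[::2], data[1::2]):
        for ln, r in ((ln1, r1), (ln2, r2)):
            if len(r) != n_loci + n_extra:
                raise ParseError(
                    f"line {ln}: {len(r)} columns, expected {n_loci + n_extra}"
                )
        if r1[0] != r2[0]:
            raise ParseError(f"line {ln2}: row pair IDs differ ({r1[0]!r} vs {r2[0]!r})")
        ident = r1[0]
        if ident in ids:
            raise ParseError(f"line {ln1}: duplicated individual ID {ident!r}")
        if pop_column and r1[1] != r2[1]:
            raise ParseError(f"line {ln2}: row pair population labels differ")
        try:
            a = [int(v) for v in r1[n_extra:]]
            b = [int(v) for v in r2[n_extra:]]
        except ValueError as exc:
            raise ParseError(f"line {ln1}: non-integer allele code ({exc})") from None
        row = []
        for ln, (x, y) in zip((ln1,) * n_loci, zip(a, b)):
            if (x == -9) ^ (y == -9):
                raise ParseError(f"line {ln}: half-missing genotype ({x},{y})")
            row.append((MISSING, MISSING) if x == -9 else (x, y))
        ids.append(ident)
        pops.append(f"pop{r1[1]}" if pop_column else "pop1")
        rows.append(row)
    geno = np.array(rows, dtype=np.int64).reshape(len(ids), n_loci, 2)
    meta = pd.DataFrame({"population": pops}, index=ids)
    return Dataset(ids=ids, loci=list(header), genotypes=geno, meta=meta)


def write_structure(ds: Dataset, path: str | Path, pop_column: bool = True) -> None:
    pop_code = {p: k + 1 for k, p in enumerate(ds.populations)}
    out = [" ".join(ds.loci)]
    for i, ident in enumerate(ds.ids):
        prefix = [ident]
        if pop_column:
            prefix.append(str(pop_code[ds.meta["population"].iloc[i]]))
        for copy in (0, 1):
            alleles = [
                "-9" if a == MISSING else str(a) for a in ds.genotypes[i, :, copy]
            ]
            out.append(" ".join(prefix + alleles))
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
# Canonical CSV
# ----------------------------------------------------------------------

_META_OUT = ["id", "population", "morphology", "sex", "x", "y", "material"]


def read_csv(path: str | Path) -> Dataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in _META_OUT:
        if col not in df.columns:
            raise ParseError(f"CSV missing required column {col!r}")
    locus_cols = [c for c in df.columns if c not in _META_OUT]
    loci: list[str] = []
    for c in locus_cols:
        if "." not in c or c.rsplit(".", 1)[1] not in ("1", "2"):
            raise ParseError(f"unexpected column {c!r}: locus columns are LOCUS.1/LOCUS.2")
        name = c.rsplit(".", 1)[0]
        if name not in loci:
            loci.append(name)
    for name in loci:
        if f"{name}.1" not in df.columns or f"{name}.2" not in df.columns:
            raise ParseError(f"locus {name!r} lacks one of its two allele columns")
    n = len(df)
    geno = np.full((n, len(loci), 2), MISSING, dtype=np.int64)
    for l, name in enumerate(loci):
        for copy, col in enumerate((f"{name}.1", f"{name}.2")):
            vals = df[col].str.strip()
            called = vals != ""
            try:
                geno[called.to_numpy(), l, copy] = vals[called].astype(int).to_numpy()
            except ValueError as exc:
                raise ParseError(f"column {col!r}: non-integer allele code ({exc})") from None
    ids = df["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ParseError("duplicated individual IDs in CSV")

    def _float(col: pd.Series) -> np.ndarray:
        return pd.to_numeric(col.mask(col == "", np.nan), errors="coerce").to_numpy()

    meta = pd.DataFrame(
        {
            "population": df["population"].tolist(),
            "morphology": df["morphology"].tolist(),
            "sex": df["sex"].tolist(),
            "x": _float(df["x"]),
            "y": _float(df["y"]),
            "material": df["material"].tolist(),
        },
        index=ids,
    )
    return Dataset(ids=ids, loci=loci, genotypes=geno, meta=meta)


def write_csv(ds: Dataset, path: str | Path) -> None:
    cols: dict[str, list] = {"id": ds.ids}
    for col in _META_OUT[1:]:
        vals = ds.meta[col]
        if col in ("x", "y"):
            cols[col] = ["" if (isinstance(v, float) and math.isnan(v)) else v for v in vals]
        else:
            cols[col] = list(vals)
    for l, name in enumerate(ds.loci):
        for copy in (0, 1):
            col = ds.genotypes[:, l, copy]
            cols[f"{name}.{copy + 1}"] = ["" if a == MISSING else int(a) for a in col]
    pd.DataFrame(cols).to_csv(path, index=False)


# ----------------------------------------------------------------------
# Long-format sampling coordinates
# ----------------------------------------------------------------------

def read_coordinates(path: str | Path) -> pd.DataFrame:
    """Read a long-format sampling-location table (id, x, y[, date])."""
    df = pd.read_csv(path)
    for col in ("id", "x", "y"):
        if col not in df.columns:
            raise ParseError(f"coordinates CSV missing column {col!r}")
    df["id"] = df["id"].astype(str)
    return df


def write_coordinates(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
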