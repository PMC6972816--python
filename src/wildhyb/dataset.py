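"""Core in-memory containers for multilocus codominant genotypes.

A genotype at one microsatellite locus is an *unordered* pair of integer
allele codes (fragment lengths or arbitrary labels).  Missing data is a
whole-genotype property: either both alleles are called or both are
missing — a half-called genotype is rejected on input.

The :class:`Dataset` is the common currency of the whole pipeline:
an individuals x loci grid of genotypes plus per-individual metadata
(population label, morphology-based subspecies, sex, sampling
coordinates, sample material).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Sentinel allele code for missing data (both alleles of a genotype).
MISSING: int = -1

META_COLUMNS = ["population", "morphology", "sex", "x", "y", "material"]


def normalize_genotypes(geno: np.ndarray) -> np.ndarray:
    """Canonicalize a (n, L, 2) genotype array.

    Sorts each allele pair ascending so that (a, b) == (b, a), and
    validates that alleles are either both present or both missing.
    """
    geno = np.asarray(geno, dtype=np.int64)
    if geno.ndim != 3 or geno.shape[2] != 2:
        raise ValueError("genotype array must have shape (n_individuals, n_loci, 2)")
    a, b = geno[..., 0], geno[..., 1]
    half = (a == MISSING) ^ (b == MISSING)
    if half.any():
        i, l = np.argwhere(half)[0]
        raise ValueError(
            f"half-missing genotype at individual {i}, locus {l}: "
            "both alleles must be present or both missing"
        )
    out = np.sort(geno, axis=2)
    # sorted order puts MISSING (-1) first; keep (-1,-1) canonical anyway
    return out


def is_missing(geno: np.ndarray) -> np.ndarray:
    """Boolean mask of missing genotypes, shape geno.shape[:-1]."""
    return np.asarray(geno)[..., 0] == MISSING


def is_het(geno: np.ndarray) -> np.ndarray:
    """Boolean mask of called heterozygous genotypes."""
    g = np.asarray(geno)
    return (g[..., 0] != g[..., 1]) & (g[..., 0] != MISSING)


@dataclass
class Dataset:
    """Individuals x loci genotype matrix with per-individual metadata.

    Parameters
    ----------
    ids:
        Unique individual identifiers, in row order.
    loci:
        Unique locus names, in column order.
    genotypes:
        Integer array of shape ``(len(ids), len(loci), 2)``; allele pairs
        are stored sorted ascending, missing cells are ``(-1, -1)``.
    meta:
        DataFrame indexed by individual id with columns
        ``population, morphology, sex, x, y, material`` (any subset;
        absent columns are filled with defaults).
    """

    ids: list[str]
    loci: list[str]
    genotypes: np.ndarray
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.loci = [str(l) for l in self.loci]
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate individual IDs")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate locus names")
        self.genotypes = normalize_genotypes(self.genotypes)
        if self.genotypes.shape[:2] != (len(self.ids), len(self.loci)):
            raise ValueError(
                f"genotype grid {self.genotypes.shape[:2]} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci"
            )
        if self.meta is None:
            self.meta = pd.DataFrame(index=pd.Index(self.ids, name="id"))
        else:
            self.meta = self.meta.copy()
            self.meta.index = pd.Index([str(i) for i in self.meta.index], name="id")
            if list(self.meta.index) != self.ids:
                self.meta = self.meta.reindex(self.ids)
        defaults = {
            "population": "pop1",
            "morphology": "unknown",
            "sex": "unknown",
            "x": np.nan,
            "y": np.nan,
            "material": "blood",
        }
        for col, default in defaults.items():
            if col not in self.meta.columns:
                self.meta[col] = default
        self.meta = self.meta[META_COLUMNS + [c for c in self.meta.columns if c not in META_COLUMNS]]

    # ------------------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.meta["population"]))

    def population_indices(self, population: str) -> np.ndarray:
        """Row indices of individuals in `population`."""
        return np.flatnonzero((self.meta["population"] == population).to_numpy())

    def subset(self, rows: Sequence[int] | np.ndarray) -> "Dataset":
        """New Dataset restricted to the given row indices (order kept)."""
        rows = np.asarray(rows, dtype=int)
        return Dataset(
            ids=[self.ids[i] for i in rows],
            loci=list(self.loci),
            genotypes=self.genotypes[rows].copy(),
            meta=self.meta.iloc[rows],
        )

    def subset_population(self, population: str) -> "Dataset":
        return self.subset(self.population_indices(population))

    def allele_counts(self, rows: np.ndarray | None = None) -> list[dict[int, int]]:
        """Per-locus observed allele counts among called genotypes."""
        g = self.genotypes if rows is None else self.genotypes[np.asarray(rows, int)]
        out: list[dict[int, int]] = []
        for l in range(self.n_loci):
            alleles = g[:, l, :].ravel()
            alleles = alleles[alleles != MISSING]
            vals, cnts = np.unique(alleles, return_counts=True)
            out.append(dict(zip(vals.tolist(), cnts.tolist())))
        return out

    def allele_freqs(self, rows: np.ndarray | None = None) -> list[dict[int, float]]:
        """Per-locus observed allele frequencies among called genotypes."""
        out = []
        for counts in self.allele_counts(rows):
            tot = sum(counts.values())
            out.append({a: c / tot for a, c in counts.items()} if tot else {})
        return out

    def equals(self, other: "Dataset", check_meta: bool = True) -> bool:
        if self.ids != other.ids or self.loci != other.loci:
            return False
        if not np.array_equal(self.genotypes, other.genotypes):
            return False
        if check_meta:
            a = self.meta[META_COLUMNS]
            b = other.meta[META_COLUMNS]
            for col in META_COLUMNS:
                if col in ("x", "y"):
                    xa = a[col].astype(float).to_numpy()
                    xb = b[col].astype(float).to_numpy()
                    same = (np.isnan(xa) & np.isnan(xb)) | (xa == xb)
                else:
                    same = a[col].astype(str).to_numpy() == b[col].astype(str).to_numpy()
                if not np.all(same):
                    return False
        return True


def concat_datasets(datasets: Iterable[Dataset]) -> Dataset:
    """Stack datasets sharing the same locus panel (row-wise)."""
    datasets = list(datasets)
    if not datasets:
        raise ValueError("no datasets to concatenate")
    loci = datasets[0].loci
    for ds in datasets[1:]:
        if ds.loci != loci:
            raise ValueError("datasets have differing locus panels")
    return Dataset(
        ids=[i for ds in datasets for i in ds.ids],
        loci=list(loci),
        genotypes=np.concatenate([ds.genotypes for ds in datasets], axis=0),
        meta=pd.concat([ds.meta for ds in datasets]),
    )
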