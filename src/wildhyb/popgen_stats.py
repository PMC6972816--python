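"""Diversity and differentiation statistics for microsatellite data.

Per-locus summaries (allele counts, observed and unbiased expected
heterozygosity), rarefied diversity at equalized sample size,
permutation tests of Hardy–Weinberg and linkage equilibrium,
Brookfield null-allele estimation with a binomial check, Weir &
Cockerham fixation indices with permutation significance, and a PCA of
allele-frequency indicators.

Expected heterozygosity uses the small-sample unbiased estimator
``(2n / (2n - 1)) * (1 - sum(p_i^2))``.  F-statistics follow the Weir &
Cockerham (1984) variance components a (among populations), b (among
individuals within populations) and c (within individuals), summed
over alleles and loci; per-locus sample sizes count called genotypes
only.  All permutation p-values use the plus-one estimator
``(b + 1) / (m + 1)`` so they are never exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataset import MISSING, Dataset, is_het, is_missing


# ----------------------------------------------------------------------
# Per-locus summaries
# ----------------------------------------------------------------------

def unbiased_he(freqs: np.ndarray, n: int) -> float:
    """Nei's unbiased expected heterozygosity for n diploid genotypes."""
    if n < 1:
        return float("nan")
    return float((2 * n / (2 * n - 1)) * (1.0 - np.sum(np.asarray(freqs) ** 2)))


def locus_summaries(
    ds: Dataset,
    populations: list[str] | None = None,
    rare_freq: float = 0.05,
    unbiased: bool = True,
) -> pd.DataFrame:
    """Na / Na_5pct / Ho / He per locus and population.

    Loci with no called genotype in a population get a flagged row with
    undefined statistics.
    """
    populations = populations or ds.populations
    rows = []
    for pop in populations:
        idx = ds.population_indices(pop)
        g = ds.genotypes[idx]
        for l, locus in enumerate(ds.loci):
            gl = g[:, l]
            called = gl[gl[:, 0] != MISSING]
            n = len(called)
            if n == 0:
                rows.append(
                    dict(locus=locus, population=pop, n=0, Na=np.nan, Na_5pct=np.nan,
                         Ho=np.nan, He=np.nan, null_freq=np.nan, flagged=True)
                )
                continue
            alleles, counts = np.unique(called.ravel(), return_counts=True)
            p = counts / counts.sum()
            ho = float(np.mean(called[:, 0] != called[:, 1]))
            he = unbiased_he(p, n) if unbiased else float(1.0 - np.sum(p ** 2))
            rows.append(
                dict(
                    locus=locus, population=pop, n=n,
                    Na=len(alleles), Na_5pct=int(np.sum(p > rare_freq)),
                    Ho=ho, He=he, null_freq=null_allele_freq(ho, he), flagged=False,
                )
            )
    return pd.DataFrame(rows)


def summarize_locus_table(table: pd.DataFrame, columns=("Na", "Ho", "He")) -> pd.DataFrame:
    """Mean and sample SD (ddof=1) of per-locus statistics per population
    — the summary rows of a diversity table."""
    out = []
    for pop, sub in table.groupby("population", sort=False):
        for stat, func in (("Mean", np.mean), ("SD", lambda v: np.std(v, ddof=1))):
            row = {"population": pop, "statistic": stat}
            for col in columns:
                row[col] = float(func(sub[col].to_numpy(dtype=float)))
            out.append(row)
    return pd.DataFrame(out)


def rarefied_diversity(
    ds: Dataset,
    n_individuals: int = 18,
    n_reps: int = 100,
    seed=0,
    populations: list[str] | None = None,
) -> pd.DataFrame:
    """Diversity at equalized sample size: draw `n_individuals` per
    population without replacement, `n_reps` times, and average the
    per-locus summaries over draws."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    populations = populations or ds.populations
    for pop in populations:
        if len(ds.population_indices(pop)) < n_individuals:
            raise ValueError(
                f"population {pop!r} has fewer than {n_individuals} individuals"
            )
    acc: list[pd.DataFrame] = []
    for _ in range(n_reps):
        keep: list[int] = []
        for pop in populations:
            idx = ds.population_indices(pop)
            keep.extend(rng.choice(idx, size=n_individuals, replace=False).tolist())
        acc.append(locus_summaries(ds.subset(keep), populations))
    stacked = pd.concat(acc)
    return (
        stacked.groupby(["locus", "population"], sort=False)[["Na", "Na_5pct", "Ho", "He"]]
        .mean()
        .reset_index()
    )


# ----------------------------------------------------------------------
# Weir & Cockerham variance components
# ----------------------------------------------------------------------

def _pop_allele_stats(g: np.ndarray) -> tuple[int, dict[int, float], dict[int, float]]:
    """(n called, allele freqs, per-allele heterozygote frequencies)."""
    called = g[g[:, 0] != MISSING]
    n = len(called)
    if n == 0:
        return 0, {}, {}
    alleles, counts = np.unique(called.ravel(), return_counts=True)
    p = dict(zip(alleles.tolist(), (counts / counts.sum()).tolist()))
    het = called[called[:, 0] != called[:, 1]]
    h = {
        int(a): float(np.mean((called[:, 0] == a) ^ (called[:, 1] == a)))
        for a in alleles
    }
    return n, p, h


def _wc_locus_components(pop_genos: list[np.ndarray]) -> tuple[float, float, float]:
    """Summed (a, b, c) over alleles at one locus, W&C (1984)."""
    stats_ = [_pop_allele_stats(g) for g in pop_genos]
    stats_ = [(n, p, h) for n, p, h in stats_ if n > 0]
    r = len(stats_)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array([s[0] for s in stats_], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - np.sum(ns ** 2) / (r * nbar)) / (r - 1)
    alleles = sorted({a for _, p, _ in stats_ for a in p})
    A = B = C = 0.0
    for al in alleles:
        p_i = np.array([p.get(al, 0.0) for _, p, _ in stats_])
        h_i = np.array([h.get(al, 0.0) for _, _, h in stats_])
        pbar = np.sum(ns * p_i) / (r * nbar)
        s2 = np.sum(ns * (p_i - pbar) ** 2) / ((r - 1) * nbar)
        hbar = np.sum(ns * h_i) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - ((r - 1) / r) * s2 - ((2 * nbar - 1) / (4 * nbar)) * hbar
        )
        c = hbar / 2
        A += a
        B += b
        C += c
    return A, B, C


def _theta(ds: Dataset, pops: list[str]) -> float:
    idx = {p: ds.population_indices(p) for p in pops}
    A = B = C = 0.0
    for l in range(ds.n_loci):
        a, b, c = _wc_locus_components([ds.genotypes[idx[p], l] for p in pops])
        A += a
        B += b
        C += c
    denom = A + B + C
    if denom == 0:
        raise ValueError("theta undefined: no polymorphic locus across these populations")
    return A / denom


def _fis_single_pop(g: np.ndarray) -> float:
    """W&C f for one population (components b and c only), one locus set.

    `g` has shape (n_individuals, n_loci, 2)."""
    B = C = 0.0
    for l in range(g.shape[1]):
        n, p, h = _pop_allele_stats(g[:, l])
        if n < 2 or len(p) < 2:
            continue
        for al, pa in p.items():
            ha = h[al]
            b = (n / (n - 1)) * (pa * (1 - pa) - ((2 * n - 1) / (4 * n)) * ha)
            c = ha / 2
            B += b
            C += c
    if B + C == 0:
        return float("nan")
    return 1.0 - C / (B + C)


@dataclass
class FstResult:
    fis: pd.Series  # per population, multilocus
    fst: pd.DataFrame  # pairwise theta, symmetric, NaN diagonal
    overall_theta: float


def wc_fstats(ds: Dataset, populations: list[str] | None = None) -> FstResult:
    """Multilocus Weir–Cockerham f (per population) and pairwise theta."""
    pops = populations or ds.populations
    if len(pops) < 2:
        raise ValueError("need at least two populations for theta")
    fis = pd.Series(
        {p: _fis_single_pop(ds.genotypes[ds.population_indices(p)]) for p in pops}
    )
    fst = pd.DataFrame(np.nan, index=pops, columns=pops)
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1:]:
            th = _theta(ds, [p1, p2])
            fst.loc[p1, p2] = fst.loc[p2, p1] = th
    return FstResult(fis=fis, fst=fst, overall_theta=_theta(ds, pops))


def fst_perm_test(
    ds: Dataset, pair: tuple[str, str], n_perm: int = 1000, seed=0
) -> tuple[float, float]:
    """Permutation significance of pairwise theta: shuffle individuals
    between the two populations.  Returns (theta, one-sided p)."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    i1, i2 = (ds.population_indices(p) for p in pair)
    sub = ds.subset(np.concatenate([i1, i2]))
    obs = _theta(sub, list(pair))
    n1 = len(i1)
    labels = np.array([pair[0]] * n1 + [pair[1]] * len(i2))
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        sub.meta["population"] = perm
        if _theta(sub, list(pair)) >= obs:
            exceed += 1
    sub.meta["population"] = labels
    return obs, (exceed + 1) / (n_perm + 1)


# ----------------------------------------------------------------------
# Hardy–Weinberg and linkage tests
# ----------------------------------------------------------------------

def hwe_test(
    ds: Dataset, locus: str, population: str, n_perm: int = 1000, seed=0
) -> dict:
    """Permutation HWE test at one locus in one population.

    Statistic: W&C f.  Null: shuffle the 2n allele copies and re-pair
    them into genotypes.  Two-sided p on |f|, plus-one corrected.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    l = ds.loci.index(locus)
    g = ds.genotypes[ds.population_indices(population), l]
    called = g[g[:, 0] != MISSING]
    n = len(called)
    if n < 5:
        raise ValueError(f"fewer than 5 called genotypes at {locus} in {population}")
    if len(np.unique(called.ravel())) < 2:
        return dict(f=float("nan"), p=1.0, monomorphic=True)
    f_obs = _fis_single_pop(called[:, None, :])
    copies = called.ravel()
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(copies).reshape(n, 2)
        f_star = _fis_single_pop(perm[:, None, :])
        if abs(f_star) >= abs(f_obs):
            exceed += 1
    return dict(f=float(f_obs), p=(exceed + 1) / (n_perm + 1), monomorphic=False)


def drop_hwe_deviating_loci(
    ds: Dataset, hwe_pvals: dict[str, float], alpha: float = 0.05
) -> tuple[Dataset, list[str]]:
    """Opt-in removal of loci whose (already corrected) HWE p-value
    falls below alpha; returns the reduced Dataset and the dropped
    locus names.  Not applied anywhere by default: retaining the full
    panel keeps analyses comparable across populations."""
    dropped = [l for l in ds.loci if hwe_pvals.get(l, 1.0) < alpha]
    if not dropped:
        return ds, []
    keep = [i for i, l in enumerate(ds.loci) if l not in dropped]
    out = Dataset(
        ids=list(ds.ids),
        loci=[ds.loci[i] for i in keep],
        genotypes=ds.genotypes[:, keep].copy(),
        meta=ds.meta,
    )
    return out, dropped


def bonferroni(pvals) -> np.ndarray:
    """Bonferroni-adjust a family of p-values (capped at 1)."""
    p = np.asarray(list(pvals), dtype=float)
    return np.minimum(p * len(p), 1.0)


def _g_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Log-likelihood G on the contingency table of two integer-coded
    categorical vectors."""
    kx, ky = x.max() + 1, y.max() + 1
    tab = np.bincount(x * ky + y, minlength=kx * ky).reshape(kx, ky).astype(float)
    total = tab.sum()
    expected = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / total
    mask = tab > 0
    return float(2.0 * np.sum(tab[mask] * np.log(tab[mask] / expected[mask])))


def ld_test(
    ds: Dataset, locus_a: str, locus_b: str, population: str, n_perm: int = 1000, seed=0
) -> dict:
    """Permutation test of genotypic linkage disequilibrium between two
    loci: log-likelihood G on the two-locus genotype table, null built
    by permuting one locus's genotypes across individuals."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    la, lb = ds.loci.index(locus_a), ds.loci.index(locus_b)
    g = ds.genotypes[ds.population_indices(population)]
    ok = (g[:, la, 0] != MISSING) & (g[:, lb, 0] != MISSING)
    if ok.sum() < 5:
        raise ValueError(
            f"fewer than 5 individuals called at both {locus_a} and {locus_b}"
        )
    ga = pd.factorize(np.array([f"{a}/{b}" for a, b in g[ok, la]]))[0]
    gb = pd.factorize(np.array([f"{a}/{b}" for a, b in g[ok, lb]]))[0]
    g_obs = _g_statistic(ga, gb)
    exceed = 0
    for _ in range(n_perm):
        if _g_statistic(ga, rng.permutation(gb)) >= g_obs:
            exceed += 1
    return dict(G=g_obs, p=(exceed + 1) / (n_perm + 1))


# ----------------------------------------------------------------------
# Null alleles
# ----------------------------------------------------------------------

def null_allele_freq(ho: float, he: float) -> float:
    """Brookfield estimator 1: r = (He - Ho) / (1 + He), clamped at 0."""
    return float(max(0.0, (he - ho) / (1.0 + he)))


def null_allele_test(ds: Dataset, locus: str, population: str) -> dict:
    """Binomial check of the null-allele explanation for a heterozygote
    deficit: under a null allele at frequency r, an expected fraction
    r^2 of individuals should be blank (non-amplifying) at the locus."""
    l = ds.loci.index(locus)
    g = ds.genotypes[ds.population_indices(population), l]
    n_total = len(g)
    blanks = int(np.sum(g[:, 0] == MISSING))
    called = g[g[:, 0] != MISSING]
    n = len(called)
    if n == 0:
        raise ValueError(f"no called genotypes at {locus} in {population}")
    alleles, counts = np.unique(called.ravel(), return_counts=True)
    p = counts / counts.sum()
    ho = float(np.mean(called[:, 0] != called[:, 1]))
    he = unbiased_he(p, n)
    r_null = null_allele_freq(ho, he)
    binom_p = stats.binomtest(blanks, n_total, r_null ** 2).pvalue if r_null > 0 else (
        1.0 if blanks == 0 else 0.0
    )
    return dict(r_null=r_null, n_blank=blanks, n_total=n_total, p=float(binom_p))


def null_allele_evidence(hwe_p: float, binom_p: float, alpha: float = 0.05) -> bool:
    """A locus shows evidence of null alleles *causing* HWE deviation
    when HWE is rejected while the binomial test cannot reject the
    null-allele explanation."""
    return (hwe_p < alpha) and (binom_p >= alpha)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

@dataclass
class PcaResult:
    scores: pd.DataFrame  # individuals x axes
    explained_variance: np.ndarray
    loadings: pd.DataFrame  # allele indicator columns x axes


def pca_genotypes(ds: Dataset, n_axes: int | None = None) -> PcaResult:
    """PCA of the individuals x allele-indicator matrix.

    Each observed allele contributes a column holding the within-
    individual frequency of that allele (0, 0.5 or 1); missing
    genotypes are imputed with the column mean; columns are centred.
    Axis signs follow a deterministic convention: the entry of largest
    magnitude in each loading vector is made positive.
    """
    if ds.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    cols, names = [], []
    for l, locus in enumerate(ds.loci):
        g = ds.genotypes[:, l]
        called = g[:, 0] != MISSING
        alleles = np.unique(g[called].ravel())
        if alleles.size == 0:
            continue  # all-missing column dropped
        for al in alleles:
            v = np.where(called, ((g[:, 0] == al).astype(float) + (g[:, 1] == al)) / 2.0, np.nan)
            mean = np.nanmean(v)
            cols.append(np.where(np.isnan(v), mean, v))
            names.append(f"{locus}:{al}")
    X = np.column_stack(cols)
    X -= X.mean(axis=0)
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    k = n_axes or len(s)
    scores = u[:, :k] * s[:k]
    load = vt[:k].T
    for j in range(min(k, load.shape[1])):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
            scores[:, j] = -scores[:, j]
    ev = s ** 2 / (ds.n_individuals - 1)
    return PcaResult(
        scores=pd.DataFrame(scores, index=ds.ids, columns=[f"PC{j+1}" for j in range(k)]),
        explained_variance=ev[:k],
        loadings=pd.DataFrame(load, index=names, columns=[f"PC{j+1}" for j in range(k)]),
    )
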