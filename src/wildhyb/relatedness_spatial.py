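"""Maximum-likelihood pairwise relatedness and spatial kin structure.

For a pair of diploid individuals the IBD-mode coefficients
(k0, k1, k2) are the probabilities that the pair shares 0, 1 or 2
alleles identical by descent at a locus; relatedness is
r = k2 + k1/2.  Given population allele frequencies, each locus
contributes a likelihood ``k0*S0 + k1*S1 + k2*S2`` where S0/S1/S2 are
the standard genotype-pair probabilities conditional on sharing 0/1/2
IBD alleles; the product over loci is maximized over the 2-simplex by
a deterministic coarse-to-fine grid search (final step 1e-3).

Spatial analysis: pairwise Euclidean distances (multi-sample
individuals use the mean over all cross-pairs of their sampling
locations) regressed on relatedness, per sex stratum or pooled with
the sex-pair class as a covariate, with an optional identity-
permutation p-value that respects the non-independence of pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .dataset import MISSING, Dataset


@dataclass
class KinshipCoefficients:
    pair: tuple[str, str]
    k0: float
    k1: float
    k2: float
    loglik: float
    n_loci: int

    @property
    def r(self) -> float:
        return self.k2 + self.k1 / 2.0


# ----------------------------------------------------------------------
# Likelihood machinery
# ----------------------------------------------------------------------

def _genotype_prob(g: tuple[int, int], p: dict[int, float]) -> float:
    a, b = g
    return p[a] ** 2 if a == b else 2.0 * p[a] * p[b]


def _ibd_components(
    g1: tuple[int, int], g2: tuple[int, int], p: dict[int, float]
) -> tuple[float, float, float]:
    """(S0, S1, S2): genotype-pair probabilities given 0/1/2 IBD alleles."""
    s0 = _genotype_prob(g1, p) * _genotype_prob(g2, p)
    s2 = _genotype_prob(g1, p) if g1 == g2 else 0.0
    a, b = g1
    c, d = g2
    if a == b:  # first is a homozygote
        if g1 == g2:
            s1 = p[a] ** 3
        elif c == d:
            s1 = 0.0
        elif a in (c, d):
            other = d if c == a else c
            s1 = p[a] ** 2 * p[other]
        else:
            s1 = 0.0
    else:
        if g1 == g2:
            s1 = p[a] * p[b] * (p[a] + p[b])
        elif c == d:
            s1 = p[c] ** 2 * p[b] if c == a else (p[c] ** 2 * p[a] if c == b else 0.0)
        else:
            shared = set(g1) & set(g2)
            if len(shared) == 1:
                i = shared.pop()
                j = b if a == i else a
                k = d if c == i else c
                s1 = p[i] * p[j] * p[k]
            else:
                s1 = 0.0
    return s0, s1, s2


def _simplex_grid(step: float, center=(None, None), halfwidth: float | None = None):
    """(k0, k2) grid points inside the 2-simplex."""
    if halfwidth is None:
        v0 = np.arange(0.0, 1.0 + step / 2, step)
        v2 = v0
    else:
        c0, c2 = center
        v0 = np.arange(max(0.0, c0 - halfwidth), min(1.0, c0 + halfwidth) + step / 2, step)
        v2 = np.arange(max(0.0, c2 - halfwidth), min(1.0, c2 + halfwidth) + step / 2, step)
    k0, k2 = (a.ravel() for a in np.meshgrid(v0, v2))
    ok = k0 + k2 <= 1.0 + 1e-12
    return np.column_stack([k0[ok], k2[ok]])


_COARSE_GRID = _simplex_grid(0.02)


def ml_relatedness(
    gi: np.ndarray,
    gj: np.ndarray,
    freqs: list[dict[int, float]],
    min_shared_loci: int = 5,
    feasible_only: bool = False,
) -> KinshipCoefficients:
    """Maximum-likelihood (k0, k1, k2) for one pair of genotype vectors.

    ``feasible_only`` restricts the search to the genetically feasible
    region k1^2 >= 4*k0*k2 (off by default).
    """
    gi = np.asarray(gi)
    gj = np.asarray(gj)
    comps = []
    for l in range(len(freqs)):
        if gi[l, 0] == MISSING or gj[l, 0] == MISSING:
            continue
        p = freqs[l]
        for allele in set(gi[l]) | set(gj[l]):
            if p.get(int(allele), 0.0) <= 0.0:
                raise ValueError(
                    f"allele {allele} observed at locus {l} has zero frequency"
                )
        comps.append(
            _ibd_components(tuple(int(v) for v in gi[l]), tuple(int(v) for v in gj[l]), p)
        )
    if len(comps) < min_shared_loci:
        raise ValueError(
            f"only {len(comps)} loci called in both individuals "
            f"(minimum {min_shared_loci})"
        )
    S = np.array(comps)  # (L, 3): S0, S1, S2

    def _best(points: np.ndarray) -> tuple[float, float, float]:
        k0 = points[:, 0]
        k2 = points[:, 1]
        k1 = 1.0 - k0 - k2
        if feasible_only:
            ok = k1 ** 2 >= 4 * k0 * k2 - 1e-12
            points, k0, k1, k2 = points[ok], k0[ok], k1[ok], k2[ok]
        lik = (
            np.log(
                np.maximum(
                    np.outer(k0, S[:, 0]) + np.outer(k1, S[:, 1]) + np.outer(k2, S[:, 2]),
                    1e-300,
                )
            ).sum(axis=1)
        )
        i = int(np.argmax(lik))
        return float(k0[i]), float(k2[i]), float(lik[i])

    b0, b2, _ = _best(_COARSE_GRID)
    b0, b2, ll = _best(_simplex_grid(0.001, center=(b0, b2), halfwidth=0.025))
    return KinshipCoefficients(
        pair=("i", "j"), k0=b0, k1=1.0 - b0 - b2, k2=b2, loglik=ll, n_loci=len(comps)
    )


def relatedness_matrix(
    ds: Dataset,
    population: str | None = None,
    leave_pair_out: bool = True,
    feasible_only: bool = False,
) -> pd.DataFrame:
    """All-pairs ML relatedness within one population.

    Frequencies default to leave-pair-out: the focal pair's own alleles
    are excluded from the frequency estimate (falling back to the full
    sample at loci where exclusion would empty an allele class).
    """
    sub = ds.subset_population(population) if population else ds
    n = sub.n_individuals
    counts = sub.allele_counts()
    totals = [sum(c.values()) for c in counts]
    rows = []
    for i, j in itertools.combinations(range(n), 2):
        freqs = []
        for l in range(sub.n_loci):
            c = dict(counts[l])
            tot = totals[l]
            if leave_pair_out:
                removed = 0
                for ind in (i, j):
                    g = sub.genotypes[ind, l]
                    if g[0] != MISSING:
                        for a in g:
                            c[int(a)] = c.get(int(a), 0) - 1
                            removed += 1
                tot -= removed
                needed = {
                    int(a)
                    for ind in (i, j)
                    for a in sub.genotypes[ind, l]
                    if sub.genotypes[ind, l][0] != MISSING
                }
                if tot <= 0 or any(c.get(a, 0) <= 0 for a in needed):
                    c = dict(counts[l])
                    tot = totals[l]
            freqs.append({a: v / tot for a, v in c.items() if v > 0})
        kc = ml_relatedness(
            sub.genotypes[i], sub.genotypes[j], freqs, feasible_only=feasible_only
        )
        rows.append(
            dict(
                id1=sub.ids[i], id2=sub.ids[j], k0=kc.k0, k1=kc.k1, k2=kc.k2,
                r=kc.r, n_loci=kc.n_loci,
            )
        )
    return pd.DataFrame(rows)


def relatedness_summary(table: pd.DataFrame) -> dict:
    r = table["r"].to_numpy()
    return dict(mean=float(r.mean()), sd=float(r.std(ddof=1)),
                min=float(r.min()), max=float(r.max()), n_pairs=len(r))


# ----------------------------------------------------------------------
# Distances and the distance ~ relatedness model
# ----------------------------------------------------------------------

def pair_distances(coords: pd.DataFrame) -> pd.DataFrame:
    """Mean Euclidean distance over all cross-pairs of two individuals'
    sampling locations; individuals without coordinates are excluded."""
    pts: dict[str, np.ndarray] = {}
    for ind, sub in coords.groupby("id"):
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        xy = xy[~np.isnan(xy).any(axis=1)]
        if len(xy):
            pts[ind] = xy
    ids = sorted(pts)
    rows = []
    for i1, i2 in itertools.combinations(ids, 2):
        d = np.linalg.norm(pts[i1][:, None, :] - pts[i2][None, :, :], axis=2)
        rows.append(dict(id1=i1, id2=i2, distance=float(d.mean())))
    return pd.DataFrame(rows)


def pair_table(
    distances: pd.DataFrame, relatedness: pd.DataFrame, sex: pd.Series
) -> pd.DataFrame:
    """Join distances and relatedness on the unordered pair key and
    attach the sex-pair class (FF/MM/FM)."""
    def _key(df):
        return df.apply(lambda row: tuple(sorted((row["id1"], row["id2"]))), axis=1)

    d = distances.copy()
    r = relatedness.copy()
    d["pair"] = _key(d)
    r["pair"] = _key(r)
    merged = d.merge(r[["pair", "r"]], on="pair", how="inner")
    merged["sex_pair"] = [
        "".join(sorted((str(sex.get(a, "U")), str(sex.get(b, "U")))))
        for a, b in merged["pair"]
    ]
    return merged.drop(columns="pair")


def distance_model(
    pairs: pd.DataFrame,
    stratum: str = "pooled",
    permutations: int = 0,
    seed=0,
    min_pairs: int = 10,
) -> dict:
    """OLS of pairwise distance on relatedness.

    ``stratum`` is "FF", "MM" (within-sex pairs only) or "pooled"
    (all pairs, sex-pair class as a covariate).  Reports the slope of
    relatedness, its F statistic and parametric p, and the model r^2.
    With ``permutations`` > 0, an identity-permutation p is added:
    individual labels are shuffled over the distance side, pairwise
    distances are re-keyed, and the F statistic recomputed.
    """
    if stratum == "pooled":
        sub = pairs.copy()
    else:
        sub = pairs[pairs["sex_pair"] == stratum].copy()
    if len(sub) < min_pairs:
        raise ValueError(f"fewer than {min_pairs} pairs in stratum {stratum!r}")
    if np.isclose(sub["r"].std(ddof=0), 0.0):
        raise ValueError(f"relatedness is constant in stratum {stratum!r}; slope undefined")

    def _fit(frame: pd.DataFrame):
        X = pd.DataFrame({"r": frame["r"].to_numpy()}, index=frame.index)
        if stratum == "pooled" and frame["sex_pair"].nunique() > 1:
            X = pd.concat([X, pd.get_dummies(frame["sex_pair"], drop_first=True, dtype=float)], axis=1)
        X = sm.add_constant(X)
        fit = sm.OLS(frame["distance"].to_numpy(), X).fit()
        t = fit.tvalues["r"]
        return fit, float(t ** 2), float(fit.pvalues["r"])

    fit, F, p = _fit(sub)
    out = dict(
        slope=float(fit.params["r"]), F=F, p=p, r2=float(fit.rsquared),
        df=int(fit.df_resid), n_pairs=len(sub),
    )
    if permutations > 0:
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        ids = sorted({i for pair in zip(sub["id1"], sub["id2"]) for i in pair})
        dist_lookup = {
            tuple(sorted((a, b))): d
            for a, b, d in zip(sub["id1"], sub["id2"], sub["distance"])
        }
        exceed = 0
        done = 0
        for _ in range(permutations):
            perm = dict(zip(ids, rng.permutation(ids)))
            new = sub.copy()
            keys = [tuple(sorted((perm[a], perm[b]))) for a, b in zip(sub["id1"], sub["id2"])]
            if any(k not in dist_lookup for k in keys):
                continue  # incomplete pair set; permutation not evaluable
            new["distance"] = [dist_lookup[k] for k in keys]
            _, F_star, _ = _fit(new)
            done += 1
            if F_star >= F:
                exceed += 1
        out["perm_p"] = (exceed + 1) / (done + 1) if done else float("nan")
    return out
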