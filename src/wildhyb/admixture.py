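"""Bayesian admixture inference and hybrid-class classification.

:func:`fit_admixture` is a Gibbs sampler over the standard admixture
model: every allele copy carries a latent cluster of origin; each
individual has an ancestry vector ``q`` with a symmetric Dirichlet(a)
prior whose concentration is itself sampled by a Metropolis step; each
cluster has per-locus allele frequencies with either a flat
Dirichlet(1) prior (independent model) or a correlated F-model prior
(per-cluster drift parameter around fixed empirical ancestral
frequencies).  Missing genotypes are simply skipped in the likelihood.
Posterior summaries are the mean ``q`` and the equal-tailed 90%
credibility interval (5th–95th percentiles of the retained draws).

:func:`evanno_delta_k` implements the second-order rate of change of
the data log-likelihood across K used to choose the cluster count, and
:func:`align_clusters` resolves label switching across repeated runs by
exhaustive permutation against reference individual subsets.

:func:`em_hybrid_classes` is a deterministic EM classifier over the six
early-generation genotype-frequency classes (pure A, pure B, F1, F2 and
the two first-generation backcrosses): a class fixes, per locus
independently, a distribution over the unordered pair of parental gene
pools the two allele copies originate from, and the genotype likelihood
mixes the pool allele frequencies accordingly.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset

CLASS_KERNELS: dict[str, dict[tuple[str, str], float]] = {
    "pureA": {("A", "A"): 1.0},
    "pureB": {("B", "B"): 1.0},
    "F1": {("A", "B"): 1.0},
    "F2": {("A", "A"): 0.25, ("A", "B"): 0.5, ("B", "B"): 0.25},
    "BC_A": {("A", "A"): 0.5, ("A", "B"): 0.5},
    "BC_B": {("B", "B"): 0.5, ("A", "B"): 0.5},
}


# ----------------------------------------------------------------------
# Data recoding
# ----------------------------------------------------------------------

def _recode(ds: Dataset):
    """Map allele codes to dense per-locus indices; flatten called copies."""
    L = ds.n_loci
    codes: list[np.ndarray] = []
    aidx = np.full((ds.n_individuals, L, 2), -1, dtype=np.int64)
    for l in range(L):
        g = ds.genotypes[:, l]
        called = g[:, 0] != MISSING
        alleles = np.unique(g[called].ravel())
        codes.append(alleles)
        lookup = {a: k for k, a in enumerate(alleles)}
        if called.any():
            flat = np.vectorize(lookup.get)(g[called])
            aidx[called, l] = flat
    amax = max((len(c) for c in codes), default=1) or 1
    ii, ll, cc = np.nonzero(aidx >= 0)
    return aidx, codes, amax, ii, ll, aidx[ii, ll, cc]


@dataclass
class AdmixtureResult:
    K: int
    ids: list[str]
    q: pd.DataFrame  # posterior mean, individuals x K
    cri_lo: pd.DataFrame  # 5th percentile
    cri_hi: pd.DataFrame  # 95th percentile
    draws: np.ndarray  # (n_draws, n_individuals, K)
    loglik_trace: np.ndarray
    alpha_trace: np.ndarray
    cluster_freqs: np.ndarray  # (K, L, amax) posterior mean, padded
    allele_codes: list[np.ndarray]
    loci: list[str]
    mean_loglik: float = float("nan")
    warnings: list[str] = field(default_factory=list)

    def relabel(self, perm: tuple[int, ...]) -> "AdmixtureResult":
        """Permute cluster labels: new column k = old column perm[k]."""
        perm = tuple(perm)
        cols = list(self.q.columns)
        new_cols = {cols[k]: self.q[cols[perm[k]]].to_numpy() for k in range(self.K)}
        def _reorder(df: pd.DataFrame) -> pd.DataFrame:
            return pd.DataFrame(
                {cols[k]: df[cols[perm[k]]].to_numpy() for k in range(self.K)},
                index=df.index,
            )
        return AdmixtureResult(
            K=self.K,
            ids=self.ids,
            q=pd.DataFrame(new_cols, index=self.q.index),
            cri_lo=_reorder(self.cri_lo),
            cri_hi=_reorder(self.cri_hi),
            draws=self.draws[:, :, list(perm)],
            loglik_trace=self.loglik_trace,
            alpha_trace=self.alpha_trace,
            cluster_freqs=self.cluster_freqs[list(perm)],
            allele_codes=self.allele_codes,
            loci=self.loci,
            mean_loglik=self.mean_loglik,
            warnings=list(self.warnings),
        )


def fit_admixture(
    ds: Dataset,
    K: int,
    burnin: int = 10_000,
    iters: int = 30_000,
    thin: int = 10,
    model: str = "independent",
    seed=0,
    alpha0: float = 1.0,
    alpha_max: float = 10.0,
    alpha_step: float = 0.05,
    lambda_prior: float = 1.0,
) -> AdmixtureResult:
    """Gibbs sampler for the admixture model; see module docstring.

    ``burnin`` sweeps are discarded, then every ``thin``-th of the
    ``iters`` post-burn-in sweeps is retained for posterior summaries.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > ds.n_individuals:
        raise ValueError(f"K={K} exceeds the number of individuals ({ds.n_individuals})")
    if iters <= 0:
        raise ValueError("iters must be > 0")
    if model not in ("independent", "correlated"):
        raise ValueError("model must be 'independent' or 'correlated'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    N, L = ds.n_individuals, ds.n_loci
    _, codes, amax, ii, ll, aa = _recode(ds)
    M = len(ii)
    valid = np.zeros((L, amax), dtype=bool)
    for l, c in enumerate(codes):
        valid[l, : len(c)] = True

    # empirical ancestral frequencies for the correlated model
    anc = np.zeros((L, amax))
    cnt = np.bincount(ll * amax + aa, minlength=L * amax).reshape(L, amax).astype(float)
    anc[valid] = (cnt[valid] + 0.5)
    anc /= np.maximum(anc.sum(axis=1, keepdims=True), 1e-300)

    q = rng.dirichlet(np.ones(K), size=N)
    p = np.zeros((K, L, amax))
    for k in range(K):
        raw = rng.gamma(1.0, size=(L, amax)) * valid
        p[k] = raw / raw.sum(axis=1, keepdims=True)
    alpha = alpha0
    Fdrift = np.full(K, 0.1)

    n_keep = iters // thin
    draws = np.empty((n_keep, N, K))
    ll_trace = np.empty(n_keep)
    alpha_trace = np.empty(n_keep)
    p_sum = np.zeros_like(p)
    kept = 0
    sum_log_q = 0.0  # updated lazily for the alpha step

    def _dirichlet_rows(shape: np.ndarray) -> np.ndarray:
        raw = rng.gamma(np.maximum(shape, 1e-9))
        raw *= shape > 0
        return raw / np.maximum(raw.sum(axis=-1, keepdims=True), 1e-300)

    total = burnin + iters
    for it in range(total):
        # latent origins
        probs = q[ii] * p[:, ll, aa].T  # (M, K)
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(M)
        z = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
        np.clip(z, 0, K - 1, out=z)

        # ancestry vectors
        counts_q = np.bincount(ii * K + z, minlength=N * K).reshape(N, K)
        q = _dirichlet_rows(alpha + counts_q.astype(float))

        # cluster allele frequencies
        counts_p = np.bincount(
            (z * L + ll) * amax + aa, minlength=K * L * amax
        ).reshape(K, L, amax).astype(float)
        if model == "independent":
            shape = (lambda_prior + counts_p) * valid
        else:
            conc = (1.0 - Fdrift) / Fdrift  # (K,)
            shape = (anc[None] * conc[:, None, None] + counts_p) * valid
        p = _dirichlet_rows(shape)

        if model == "correlated":
            # Metropolis update of each cluster's drift parameter
            for k in range(K):
                prop = Fdrift[k] + rng.normal(0, 0.02)
                if not (1e-3 < prop < 0.999):
                    continue
                logr = _fmodel_logpdf(p[k], anc, prop, valid) - _fmodel_logpdf(
                    p[k], anc, Fdrift[k], valid
                )
                if math.log(rng.random() + 1e-300) < logr:
                    Fdrift[k] = prop

        # Metropolis update of the ancestry concentration
        if K > 1:
            sum_log_q = float(np.log(np.maximum(q, 1e-300)).sum())
            prop = alpha + rng.normal(0, alpha_step)
            if 0.0 < prop <= alpha_max:
                logr = N * (
                    math.lgamma(K * prop) - K * math.lgamma(prop)
                    - math.lgamma(K * alpha) + K * math.lgamma(alpha)
                ) + (prop - alpha) * sum_log_q
                if math.log(rng.random() + 1e-300) < logr:
                    alpha = prop

        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            draws[kept] = q
            mix = (q[ii] * p[:, ll, aa].T).sum(axis=1)
            ll_trace[kept] = float(np.log(np.maximum(mix, 1e-300)).sum())
            alpha_trace[kept] = alpha
            p_sum += p
            kept += 1

    draws = draws[:kept]
    ll_trace = ll_trace[:kept]
    alpha_trace = alpha_trace[:kept]
    q_mean = draws.mean(axis=0)
    lo = np.percentile(draws, 5, axis=0)
    hi = np.percentile(draws, 95, axis=0)

    warnings: list[str] = []
    if kept >= 20:
        third = kept // 3
        a0, a1 = ll_trace[:third], ll_trace[-third:]
        pooled_se = np.sqrt((a0.var() + a1.var()) / third + 1e-300)
        if abs(a1.mean() - a0.mean()) > 4 * pooled_se:
            warnings.append("log-likelihood trend suggests the chain has not mixed")

    cols = [f"k{k+1}" for k in range(K)]
    return AdmixtureResult(
        K=K,
        ids=list(ds.ids),
        q=pd.DataFrame(q_mean, index=ds.ids, columns=cols),
        cri_lo=pd.DataFrame(lo, index=ds.ids, columns=cols),
        cri_hi=pd.DataFrame(hi, index=ds.ids, columns=cols),
        draws=draws,
        loglik_trace=ll_trace,
        alpha_trace=alpha_trace,
        cluster_freqs=p_sum / max(kept, 1),
        allele_codes=codes,
        loci=list(ds.loci),
        mean_loglik=float(ll_trace.mean()) if kept else float("nan"),
        warnings=warnings,
    )


def _fmodel_logpdf(p: np.ndarray, anc: np.ndarray, F: float, valid: np.ndarray) -> float:
    """Log density of cluster frequencies under the F-model Dirichlet."""
    from scipy.special import gammaln

    conc = (1.0 - F) / F
    a = np.where(valid, anc * conc, 0.0)
    x = np.maximum(np.where(valid, p, 1.0), 1e-12)
    per_locus = (
        gammaln(a.sum(axis=1))
        - np.where(valid, gammaln(np.maximum(a, 1e-12)), 0.0).sum(axis=1)
        + np.where(valid, (a - 1.0) * np.log(x), 0.0).sum(axis=1)
    )
    return float(per_locus.sum())


def data_loglik(result: AdmixtureResult) -> float:
    """Mean retained-draw data log-likelihood (input to Evanno's method)."""
    return result.mean_loglik


# ----------------------------------------------------------------------
# Evanno's method
# ----------------------------------------------------------------------

def evanno_delta_k(runs: dict[int, list[float]]) -> pd.DataFrame:
    """Second-order rate of change of L(K) across K.

    ``runs`` maps K to the mean data log-likelihoods of repeated runs.
    Returns a table with columns K, mean_L, sd_L, delta_K; delta_K is
    defined only at interior K values.  A zero SD yields an infinite
    delta_K (flagged upstream by the caller's warning).
    """
    ks = sorted(runs)
    if len(ks) < 3 or any(ks[i + 1] - ks[i] != 1 for i in range(len(ks) - 1)):
        raise ValueError("need at least three consecutive K values")
    if any(len(v) < 2 for v in runs.values()):
        raise ValueError("need at least two repeats per K")
    mean = {k: float(np.mean(runs[k])) for k in ks}
    sd = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        dk = np.nan
        if ks[0] < k < ks[-1]:
            curv = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1])
            dk = math.inf if sd[k] == 0 else curv / sd[k]
        rows.append(dict(K=k, mean_L=mean[k], sd_L=sd[k], delta_K=dk))
    return pd.DataFrame(rows)


def best_k(delta_table: pd.DataFrame) -> int:
    interior = delta_table.dropna(subset=["delta_K"])
    return int(interior.loc[interior["delta_K"].idxmax(), "K"])


# ----------------------------------------------------------------------
# Cluster alignment (label switching)
# ----------------------------------------------------------------------

def align_clusters(
    results: list[AdmixtureResult], reference: dict[int, list[str]]
) -> tuple[list[AdmixtureResult], list[bool]]:
    """Permute cluster labels of each run so that reference individuals
    load on their designated cluster.

    ``reference`` maps target cluster index (0-based) to a non-empty,
    disjoint list of individual IDs.  The permutation maximizing the
    summed mean q of each reference subset in its target cluster is
    found exhaustively over K! permutations.  Returns the relabeled
    runs and a per-run flag marking ambiguous (tied) optima, broken
    deterministically toward the identity-most permutation.
    """
    ids_sets = list(reference.values())
    if any(len(s) == 0 for s in ids_sets):
        raise ValueError("reference subsets must be non-empty")
    flat = [i for s in ids_sets for i in s]
    if len(set(flat)) != len(flat):
        raise ValueError("reference subsets must be disjoint")
    out, ties = [], []
    for res in results:
        K = res.K
        cols = list(res.q.columns)
        scores = {}
        for perm in itertools.permutations(range(K)):
            s = 0.0
            for target, members in reference.items():
                s += float(res.q.loc[members, cols[perm[target]]].mean())
            scores[perm] = s
        best = max(scores.values())
        winners = sorted(p for p, s in scores.items() if abs(s - best) < 1e-12)
        out.append(res.relabel(winners[0]))
        ties.append(len(winners) > 1)
    return out, ties


# ----------------------------------------------------------------------
# EM over hybrid genotype-frequency classes
# ----------------------------------------------------------------------

@dataclass
class HybridClassPosterior:
    classes: list[str]
    posterior: pd.DataFrame  # individuals x classes
    freqs_a: np.ndarray  # (L, amax)
    freqs_b: np.ndarray
    allele_codes: list[np.ndarray]
    loglik_trace: np.ndarray
    converged: bool

    @property
    def modal_class(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)


def _pool_freqs_from_rows(ds: Dataset, rows: np.ndarray, codes, amax: int) -> np.ndarray:
    out = np.zeros((ds.n_loci, amax))
    for l, alleles in enumerate(codes):
        g = ds.genotypes[rows, l]
        called = g[g[:, 0] != MISSING].ravel()
        lookup = {a: k for k, a in enumerate(alleles)}
        for a in called:
            out[l, lookup[int(a)]] += 1.0
        out[l, : len(alleles)] += 0.5  # half-count smoothing keeps support open
        out[l] /= out[l].sum()
    return out


def em_hybrid_classes(
    ds: Dataset,
    classes: list[str] = ("pureA", "pureB", "F1", "F2", "BC_A", "BC_B"),
    freq_mode: str = "joint",
    ref_a: list[str] | None = None,
    ref_b: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
    seed=0,
) -> HybridClassPosterior:
    """EM classifier over early-generation hybrid classes.

    Each class fixes a per-locus distribution over the unordered pair
    of parental gene pools of the two allele copies; given pool
    frequencies pA and pB, an origin pair (X, Y) gives genotype (i, j)
    probability ``pX_i pY_j + pX_j pY_i`` for i != j and ``pX_i pY_i``
    for i = j.  In ``fixed`` mode pool frequencies come from the
    reference individuals; in ``joint`` mode they are re-estimated each
    M-step from expected allele origins (initialised from the
    references when given, otherwise from a seeded random split).
    """
    classes = list(classes)
    unknown = set(classes) - set(CLASS_KERNELS)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    if "pureA" not in classes or "pureB" not in classes:
        raise ValueError("class set must include both pure classes")
    if freq_mode not in ("fixed", "joint"):
        raise ValueError("freq_mode must be 'fixed' or 'joint'")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    aidx, codes, amax, *_ = _recode(ds)
    N, L = ds.n_individuals, ds.n_loci
    a1, a2 = aidx[:, :, 0], aidx[:, :, 1]  # (N, L); -1 = missing
    called = a1 >= 0
    hom = called & (a1 == a2)
    a1c = np.where(called, a1, 0)
    a2c = np.where(called, a2, 0)
    rows_l = np.arange(L)[None, :].repeat(N, axis=0)

    id_pos = {i: k for k, i in enumerate(ds.ids)}
    if ref_a is not None and ref_b is not None:
        pa = _pool_freqs_from_rows(ds, np.array([id_pos[i] for i in ref_a]), codes, amax)
        pb = _pool_freqs_from_rows(ds, np.array([id_pos[i] for i in ref_b]), codes, amax)
    elif freq_mode == "fixed":
        raise ValueError("fixed mode requires non-empty reference sets for both pools")
    else:
        base = _pool_freqs_from_rows(ds, np.arange(N), codes, amax)
        jitter = rng.gamma(20.0, size=(2, L, amax))
        pa = base * jitter[0]
        pb = base * jitter[1]
        pa /= pa.sum(axis=1, keepdims=True)
        pb /= pb.sum(axis=1, keepdims=True)

    pi = np.full(len(classes), 1.0 / len(classes))
    pair_names = [("A", "A"), ("A", "B"), ("B", "B")]
    W = np.array([[CLASS_KERNELS[c].get(p, 0.0) for p in pair_names] for c in classes])

    ll_trace = []
    prev_resp = None
    converged = False
    for _ in range(max_iter):
        # per-pair genotype probabilities, (3, N, L)
        paa = pa[rows_l, a1c] * pa[rows_l, a2c]
        pbb = pb[rows_l, a1c] * pb[rows_l, a2c]
        t1 = pa[rows_l, a1c] * pb[rows_l, a2c]
        t2 = pa[rows_l, a2c] * pb[rows_l, a1c]
        pab = t1 + t2
        pair_p = np.stack([2 * paa, pab, 2 * pbb])
        pair_p[0][hom] = paa[hom]
        pair_p[2][hom] = pbb[hom]
        pair_p[1][hom] = t1[hom]
        pair_p = np.maximum(pair_p, 1e-300)

        # class log-likelihoods summed over called loci
        mix = np.einsum("cp,pnl->cnl", W, pair_p)
        logmix = np.where(called[None], np.log(np.maximum(mix, 1e-300)), 0.0)
        class_ll = logmix.sum(axis=2).T  # (N, C)

        logpost = class_ll + np.log(np.maximum(pi, 1e-300))
        m = logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost - m)
        norm = post.sum(axis=1, keepdims=True)
        post /= norm
        ll = float((np.log(norm[:, 0]) + m[:, 0]).sum())
        ll_trace.append(ll)

        if prev_resp is not None and np.max(np.abs(post - prev_resp)) < tol:
            prev_resp = post
            converged = True
            break
        prev_resp = post
        pi = post.mean(axis=0)

        if freq_mode == "joint":
            # per-locus pair posteriors weighted by class responsibilities
            class_mix = np.maximum(
                np.einsum("cp,pnl->cnl", W, pair_p), 1e-300
            )  # (C, N, L)
            pair_w = np.einsum(
                "nc,cp,pnl,cnl->pnl", post, W, pair_p, 1.0 / class_mix
            )
            s = t1 / np.maximum(t1 + t2, 1e-300)
            wAA, wAB, wBB = pair_w[0], pair_w[1], pair_w[2]
            cA = np.zeros((L, amax))
            cB = np.zeros((L, amax))
            msk = called
            for arr, wgt in (
                (a1c, wAA + wAB * s),
                (a2c, wAA + wAB * (1 - s)),
            ):
                np.add.at(cA, (rows_l[msk], arr[msk]), wgt[msk])
            for arr, wgt in (
                (a1c, wBB + wAB * (1 - s)),
                (a2c, wBB + wAB * s),
            ):
                np.add.at(cB, (rows_l[msk], arr[msk]), wgt[msk])
            valid = np.zeros((L, amax), dtype=bool)
            for l, c in enumerate(codes):
                valid[l, : len(c)] = True
            pa = (cA + 1e-6) * valid
            pb = (cB + 1e-6) * valid
            pa /= pa.sum(axis=1, keepdims=True)
            pb /= pb.sum(axis=1, keepdims=True)

    return HybridClassPosterior(
        classes=classes,
        posterior=pd.DataFrame(prev_resp, index=ds.ids, columns=classes),
        freqs_a=pa,
        freqs_b=pb,
        allele_codes=codes,
        loglik_trace=np.array(ll_trace),
        converged=converged,
    )
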