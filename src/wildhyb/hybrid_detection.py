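"""Simulation-calibrated detection of wildcat x domestic-cat hybrids.

Two complementary rules turn an admixture result into hybrid calls.
Let q be an individual's posterior mean ancestry toward its own
(majority) cluster and [lo, hi] the corresponding 90% credibility
interval.  Under the *conservative* rule the individual is a hybrid
when q < t; under the *relaxed* rule when lo < t.  Every conservative
hybrid is therefore also a relaxed hybrid: the two rules bracket the
hybridization rate from below and above.

The threshold t is either fixed (0.8 in the general analysis) or
calibrated per dataset: individuals assigned to a cluster with
q > 0.9 serve as reference parentals, parental and hybrid genotypes
are simulated from the reference allele frequencies, the simulants are
re-analysed with the same admixture model, and t is the lowest q
reached by a simulated parental.

The resampling procedure repeats this on datasets in which the
heavily over-sampled domestic population is subsampled (70 of 371 by
default, 30 datasets), yielding per-individual detection counts, a
>= 15-of-30 individual rule, and population-level rates with empirical
95% confidence intervals over datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .admixture import AdmixtureResult, em_hybrid_classes, fit_admixture
from .dataset import Dataset, concat_datasets
from .synthetic_data import simulate_hybrids, draw_genotypes_hwe


@dataclass
class DetectionConfig:
    """Knobs of the resampling detection procedure (defaults follow the
    study design the pipeline emulates)."""

    n_domestic_per_dataset: int = 70
    n_datasets: int = 30
    n_sim_parentals: int = 200
    n_sim_hybrids: int = 30  # per class: F1, BC toward each parental
    ref_q_cutoff: float = 0.9
    fixed_threshold: float = 0.8
    individual_call_min: int = 15
    ci_level: float = 95.0
    resample_population: str = "NE_domestic"
    wild_morphology: str = "silvestris"
    # MCMC settings for the per-dataset admixture fits
    burnin: int = 10_000
    iters: int = 30_000
    thin: int = 10
    model: str = "independent"

    def __post_init__(self) -> None:
        for name in ("n_domestic_per_dataset", "n_datasets", "n_sim_parentals",
                     "n_sim_hybrids", "individual_call_min"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("ref_q_cutoff", "fixed_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1)")


@dataclass
class HybridCallTable:
    per_individual: pd.DataFrame
    per_population: pd.DataFrame
    thresholds: list[float]
    n_datasets_run: int
    n_datasets_skipped: int
    dataset_rates: pd.DataFrame  # one row per dataset x population x mode


# ----------------------------------------------------------------------
# Building blocks
# ----------------------------------------------------------------------

def own_cluster_q(ar: AdmixtureResult) -> pd.DataFrame:
    """Per individual: majority cluster, its mean q and 90% CrI bounds."""
    qm = ar.q.to_numpy()
    own = qm.argmax(axis=1)
    rows = np.arange(len(own))
    return pd.DataFrame(
        {
            "cluster": [ar.q.columns[k] for k in own],
            "q": qm[rows, own],
            "lo": ar.cri_lo.to_numpy()[rows, own],
            "hi": ar.cri_hi.to_numpy()[rows, own],
        },
        index=ar.q.index,
    )


def select_reference_parentals(
    ar: AdmixtureResult, cutoff: float = 0.9
) -> dict[str, list[str]]:
    """Individuals with q strictly above `cutoff` toward a cluster, per
    cluster.  Raises when any cluster ends up without references."""
    if ar.K != 2:
        raise ValueError("reference selection expects a K=2 admixture result")
    out: dict[str, list[str]] = {c: [] for c in ar.q.columns}
    for ind in ar.q.index:
        for c in ar.q.columns:
            if float(ar.q.loc[ind, c]) > cutoff:
                out[c].append(ind)
    empty = [c for c, ids in out.items() if not ids]
    if empty:
        raise ValueError(
            f"no reference parentals above q={cutoff} for cluster(s) {empty}; "
            "threshold calibration impossible"
        )
    return out


def calibrate_threshold(sim_parental_q) -> float:
    """Detection threshold = lowest own-cluster q among simulated
    parental individuals."""
    q = np.asarray(list(sim_parental_q), dtype=float)
    if q.size == 0:
        raise ValueError("no simulated parental q-values")
    return float(q.min())


def classify(ar: AdmixtureResult, threshold: float, mode: str) -> pd.Series:
    """Boolean hybrid flag per individual under one rule."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    if mode not in ("conservative", "relaxed"):
        raise ValueError("mode must be 'conservative' or 'relaxed'")
    own = own_cluster_q(ar)
    stat = own["q"] if mode == "conservative" else own["lo"]
    return stat < threshold


# ----------------------------------------------------------------------
# General analysis (fixed threshold)
# ----------------------------------------------------------------------

@dataclass
class GeneralAnalysis:
    result: AdmixtureResult
    conservative: pd.Series
    relaxed: pd.Series
    threshold: float


def run_general_analysis(
    ds: Dataset,
    fixed_threshold: float = 0.8,
    cfg: DetectionConfig | None = None,
    seed=0,
) -> GeneralAnalysis:
    """Admixture at K=2 on the full dataset, classified against a fixed
    literature threshold under both rules."""
    cfg = cfg or DetectionConfig()
    ar = fit_admixture(
        ds, K=2, burnin=cfg.burnin, iters=cfg.iters, thin=cfg.thin,
        model=cfg.model, seed=seed,
    )
    return GeneralAnalysis(
        result=ar,
        conservative=classify(ar, fixed_threshold, "conservative"),
        relaxed=classify(ar, fixed_threshold, "relaxed"),
        threshold=fixed_threshold,
    )


# ----------------------------------------------------------------------
# Resampling procedure
# ----------------------------------------------------------------------

def resampling_inclusion_counts(
    n_pool: int, cfg: DetectionConfig, seed=0
) -> np.ndarray:
    """Bookkeeping only: how often each of `n_pool` domestic cats enters
    the `cfg.n_datasets` subsampled datasets of size
    `cfg.n_domestic_per_dataset` (drawn without replacement)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    counts = np.zeros(n_pool, dtype=int)
    for _ in range(cfg.n_datasets):
        counts[rng.choice(n_pool, size=cfg.n_domestic_per_dataset, replace=False)] += 1
    return counts


def _wild_cluster(ar: AdmixtureResult, ds: Dataset, morphology: str) -> str:
    wild_ids = [i for i, m in zip(ds.ids, ds.meta["morphology"]) if m == morphology]
    if not wild_ids:
        raise ValueError(f"no individuals with morphology {morphology!r} to anchor clusters")
    means = ar.q.loc[wild_ids].mean(axis=0)
    return str(means.idxmax())


@dataclass
class ResampleOutcome:
    subset_ids: list[str]
    threshold: float
    conservative: pd.Series
    relaxed: pd.Series
    reference_sets: dict[str, list[str]]


def resample_once(ds: Dataset, cfg: DetectionConfig, seed) -> ResampleOutcome:
    """One pass of the resampling procedure: subsample the domestic
    pool, fit admixture, pick references, simulate parentals and
    hybrids, calibrate the threshold on the simulants' own-cluster q,
    and classify the real individuals of this dataset."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dom_idx = ds.population_indices(cfg.resample_population)
    if len(dom_idx) < cfg.n_domestic_per_dataset:
        raise ValueError(
            f"population {cfg.resample_population!r} smaller than "
            f"n_domestic_per_dataset={cfg.n_domestic_per_dataset}"
        )
    keep_dom = rng.choice(dom_idx, size=cfg.n_domestic_per_dataset, replace=False)
    others = np.setdiff1d(np.arange(ds.n_individuals), dom_idx)
    rows = np.sort(np.concatenate([others, keep_dom]))
    sub = ds.subset(rows)

    ar = fit_admixture(
        sub, K=2, burnin=cfg.burnin, iters=cfg.iters, thin=cfg.thin,
        model=cfg.model, seed=int(rng.integers(2 ** 31)),
    )
    wild_col = _wild_cluster(ar, sub, cfg.wild_morphology)
    dom_col = [c for c in ar.q.columns if c != wild_col][0]
    refs = select_reference_parentals(ar, cfg.ref_q_cutoff)
    ref_wild, ref_dom = refs[wild_col], refs[dom_col]

    id_pos = {i: k for k, i in enumerate(sub.ids)}
    freqs_wild = sub.allele_freqs(np.array([id_pos[i] for i in ref_wild]))
    freqs_dom = sub.allele_freqs(np.array([id_pos[i] for i in ref_dom]))

    sim_seed = int(rng.integers(2 ** 31))
    sim_rng = np.random.default_rng(sim_seed)
    n_p = cfg.n_sim_parentals
    dom_ids = [f"simdom_{i+1:03d}" for i in range(n_p)]
    wild_ids = [f"simwild_{i+1:03d}" for i in range(n_p)]
    par_dom = Dataset(
        ids=dom_ids,
        loci=list(sub.loci),
        genotypes=draw_genotypes_hwe(freqs_dom, n_p, sim_rng),
        meta=pd.DataFrame({"population": "sim_dom"}, index=dom_ids),
    )
    par_wild = Dataset(
        ids=wild_ids,
        loci=list(sub.loci),
        genotypes=draw_genotypes_hwe(freqs_wild, n_p, sim_rng),
        meta=pd.DataFrame({"population": "sim_wild"}, index=wild_ids),
    )
    hybs = [
        simulate_hybrids(freqs_dom, freqs_wild, cls, cfg.n_sim_hybrids, sim_rng,
                         loci=list(sub.loci), id_prefix=f"sim{cls}")
        for cls in ("F1", "BC_A", "BC_B")  # BC_A: toward domestic; BC_B: toward wild
    ]
    sim_ds = concat_datasets([par_dom, par_wild] + hybs)
    ar_sim = fit_admixture(
        sim_ds, K=2, burnin=cfg.burnin, iters=cfg.iters, thin=cfg.thin,
        model=cfg.model, seed=int(rng.integers(2 ** 31)),
    )
    sim_wild_col = str(ar_sim.q.loc[par_wild.ids].mean(axis=0).idxmax())
    sim_dom_col = [c for c in ar_sim.q.columns if c != sim_wild_col][0]
    parental_q = np.concatenate(
        [
            ar_sim.q.loc[par_wild.ids, sim_wild_col].to_numpy(),
            ar_sim.q.loc[par_dom.ids, sim_dom_col].to_numpy(),
        ]
    )
    threshold = calibrate_threshold(parental_q)

    return ResampleOutcome(
        subset_ids=list(sub.ids),
        threshold=threshold,
        conservative=classify(ar, threshold, "conservative"),
        relaxed=classify(ar, threshold, "relaxed"),
        reference_sets={"wild": ref_wild, "domestic": ref_dom},
    )


def run_resampling(ds: Dataset, cfg: DetectionConfig | None = None, seed=0) -> HybridCallTable:
    """Full resampling detection: `cfg.n_datasets` independent passes of
    :func:`resample_once`, aggregated into per-individual detection
    counts with the >= `individual_call_min` rule and per-population
    rates with empirical percentile confidence intervals."""
    cfg = cfg or DetectionConfig()
    children = np.random.SeedSequence(seed).spawn(cfg.n_datasets)
    times_sampled = pd.Series(0, index=ds.ids, dtype=int)
    times_cons = pd.Series(0, index=ds.ids, dtype=int)
    times_rel = pd.Series(0, index=ds.ids, dtype=int)
    thresholds: list[float] = []
    rate_rows = []
    n_skipped = 0
    pop_by_id = ds.meta["population"]

    for d, child in enumerate(children):
        try:
            out = resample_once(ds, cfg, np.random.default_rng(child))
        except ValueError:
            n_skipped += 1
            continue
        thresholds.append(out.threshold)
        times_sampled[out.subset_ids] += 1
        times_cons[out.subset_ids] += out.conservative[out.subset_ids].astype(int)
        times_rel[out.subset_ids] += out.relaxed[out.subset_ids].astype(int)
        sub_pops = pop_by_id[out.subset_ids]
        for pop in sub_pops.unique():
            members = [i for i in out.subset_ids if pop_by_id[i] == pop]
            for mode, flags in (("conservative", out.conservative), ("relaxed", out.relaxed)):
                rate = 100.0 * float(flags[members].mean())
                rate_rows.append(dict(dataset=d, population=pop, mode=mode, rate=rate))

    dataset_rates = pd.DataFrame(rate_rows)
    lo_q, hi_q = (100 - cfg.ci_level) / 2, 100 - (100 - cfg.ci_level) / 2
    pop_rows = []
    if not dataset_rates.empty:
        for (pop, mode), sub in dataset_rates.groupby(["population", "mode"]):
            vals = sub["rate"].to_numpy()
            pop_rows.append(
                dict(
                    population=pop, mode=mode, mean_rate=float(vals.mean()),
                    ci_lo=float(np.percentile(vals, lo_q)),
                    ci_hi=float(np.percentile(vals, hi_q)),
                )
            )
    per_individual = pd.DataFrame(
        {
            "times_sampled": times_sampled,
            "times_hybrid_conservative": times_cons,
            "times_hybrid_relaxed": times_rel,
            "final_conservative": times_cons >= cfg.individual_call_min,
            "final_relaxed": times_rel >= cfg.individual_call_min,
        }
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        per_individual["frac_conservative"] = np.where(
            times_sampled > 0, times_cons / times_sampled.replace(0, 1), np.nan
        )
        per_individual["frac_relaxed"] = np.where(
            times_sampled > 0, times_rel / times_sampled.replace(0, 1), np.nan
        )
    return HybridCallTable(
        per_individual=per_individual,
        per_population=pd.DataFrame(pop_rows),
        thresholds=thresholds,
        n_datasets_run=cfg.n_datasets - n_skipped,
        n_datasets_skipped=n_skipped,
        dataset_rates=dataset_rates,
    )


# ----------------------------------------------------------------------
# Method agreement
# ----------------------------------------------------------------------

def consensus_calls(
    general: GeneralAnalysis,
    resampling: HybridCallTable,
    em_f1_only,
    em_with_backcrosses,
) -> pd.DataFrame:
    """Six-column agreement table: general conservative/relaxed,
    resampling conservative/relaxed (final >= min-count calls), and the
    modal class of the two EM classifiers (F1-only and with
    backcrosses), plus the count of detecting approaches."""
    ids = list(general.result.ids)

    def _em_hybrid(emres) -> pd.Series:
        modal = emres.modal_class
        return pd.Series(
            [modal.get(i, "pureA") not in ("pureA", "pureB") for i in ids], index=ids
        )

    table = pd.DataFrame(
        {
            "general_conservative": general.conservative.reindex(ids).fillna(False),
            "general_relaxed": general.relaxed.reindex(ids).fillna(False),
            "resampling_conservative": resampling.per_individual["final_conservative"]
            .reindex(ids)
            .fillna(False),
            "resampling_relaxed": resampling.per_individual["final_relaxed"]
            .reindex(ids)
            .fillna(False),
            "em_f1_only": _em_hybrid(em_f1_only),
            "em_backcrosses": _em_hybrid(em_with_backcrosses),
        }
    ).astype(bool)
    table["n_detections"] = table.sum(axis=1)
    return table
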