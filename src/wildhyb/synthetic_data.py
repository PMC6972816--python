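"""Generators for synthetic microsatellite datasets.

The generators emulate the statistical structure the downstream
analyses assume: two parental gene pools (domestic and wild) diverged
under pure drift, the four early-generation hybrid classes (F1, F2 and
both first-generation backcrosses), heavily unbalanced sampling across
two regions, full-sib family structure with optionally kin-clustered
sampling locations, and a noninvasive genotyping error model (allelic
dropout and whole-locus amplification failure over 2–4 PCR repeats).

Population differentiation uses the F-model: each population's
per-locus allele frequencies are drawn from a Dirichlet centred on the
ancestral frequencies with concentration ``(1 - F)/F``, so ``F`` is the
expected fixation index of each daughter population relative to the
ancestral pool.  Genotypes are then two independent draws per locus
(Hardy–Weinberg equilibrium within populations).

All generators are pure functions of their inputs and a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset, concat_datasets, is_het
from .genotyping_qc import ReplicateSet

HYBRID_CLASSES = ("F1", "F2", "BC_A", "BC_B")

#: Per-locus allele frequencies: one {allele code: frequency} dict per locus.
LocusFreqs = list


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class PopModel:
    """Drift model for parental populations.

    ``divergence`` is the F of the F-model, strictly inside (0, 1);
    driving it to 0 collapses every population onto the ancestor.
    ``ancestral_freqs`` defaults to uniform frequencies over
    ``alleles_per_locus`` allele codes 1..A at each locus.
    """

    n_loci: int = 22
    alleles_per_locus: int | list[int] = 8
    divergence: float = 0.15
    ancestral_freqs: LocusFreqs | None = None
    locus_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 < self.divergence < 1.0):
            raise ValueError("divergence F must lie strictly between 0 and 1")
        counts = (
            [self.alleles_per_locus] * self.n_loci
            if isinstance(self.alleles_per_locus, int)
            else list(self.alleles_per_locus)
        )
        if len(counts) != self.n_loci:
            raise ValueError("alleles_per_locus list length must equal n_loci")
        if self.ancestral_freqs is None:
            self.ancestral_freqs = [
                {a + 1: 1.0 / k for a in range(k)} for k in counts
            ]
        for freqs in self.ancestral_freqs:
            tot = sum(freqs.values())
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(f"ancestral frequency vector sums to {tot}, not 1")
        if not self.locus_names:
            self.locus_names = [f"L{l + 1:02d}" for l in range(self.n_loci)]


@dataclass
class ErrorModel:
    """Noninvasive genotyping error model.

    dropout_rate: per heterozygous genotype per repeat, probability that
        one (uniformly chosen) allele drops, leaving a false homozygote.
    failure_rate: per locus per repeat, probability of no amplification.
    n_repeats: PCR repeats per sample (first genotyping included).
    """

    dropout_rate: float = 0.2
    failure_rate: float = 0.15
    n_repeats: int = 3

    def __post_init__(self) -> None:
        for name in ("dropout_rate", "failure_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


# ----------------------------------------------------------------------
# Frequency and gamete primitives
# ----------------------------------------------------------------------

def draw_pop_freqs(ancestral: LocusFreqs, F: float, rng) -> LocusFreqs:
    """Draw one population's frequencies from the F-model Dirichlet."""
    rng = _rng(rng)
    conc = (1.0 - F) / F
    out = []
    for freqs in ancestral:
        alleles = sorted(freqs)
        alpha = np.array([freqs[a] for a in alleles]) * conc
        p = rng.dirichlet(alpha)
        out.append(dict(zip(alleles, p.tolist())))
    return out


def _freq_arrays(freqs: LocusFreqs) -> list[tuple[np.ndarray, np.ndarray]]:
    out = []
    for f in freqs:
        alleles = np.array(sorted(f), dtype=np.int64)
        p = np.array([f[a] for a in alleles], dtype=float)
        out.append((alleles, p / p.sum()))
    return out


def draw_gametes(freqs: LocusFreqs, n: int, rng) -> np.ndarray:
    """n haploid gametes (n, L) drawn locus-independently from freqs."""
    rng = _rng(rng)
    arrs = _freq_arrays(freqs)
    out = np.empty((n, len(arrs)), dtype=np.int64)
    for l, (alleles, p) in enumerate(arrs):
        out[:, l] = rng.choice(alleles, size=n, p=p)
    return out


def draw_genotypes_hwe(freqs: LocusFreqs, n: int, rng) -> np.ndarray:
    rng = _rng(rng)
    g = np.stack([draw_gametes(freqs, n, rng), draw_gametes(freqs, n, rng)], axis=2)
    return np.sort(g, axis=2)


def _gamete_from_parents(parents: np.ndarray, rng) -> np.ndarray:
    """One gamete per parent: one of the two alleles, per locus."""
    rng = _rng(rng)
    n, L, _ = parents.shape
    pick = rng.integers(0, 2, size=(n, L))
    return np.take_along_axis(parents, pick[:, :, None], axis=2)[:, :, 0]


# ----------------------------------------------------------------------
# Simulators
# ----------------------------------------------------------------------

def simulate_parental_pops(
    model: PopModel,
    n_per_pop: dict[str, int],
    seed,
    pop_freqs: dict[str, LocusFreqs] | None = None,
) -> tuple[Dataset, dict[str, LocusFreqs]]:
    """Simulate HWE genotypes for independently drifted populations.

    Each population's frequencies are drawn from the F-model Dirichlet
    around ``model.ancestral_freqs`` (or taken from ``pop_freqs`` when
    given, e.g. from :func:`draw_pop_freqs` with hierarchical drift).
    """
    rng = _rng(seed)
    if not any(n > 0 for n in n_per_pop.values()):
        raise ValueError("at least one population must have n > 0")
    if pop_freqs is None:
        pop_freqs = {
            name: draw_pop_freqs(model.ancestral_freqs, model.divergence, rng)
            for name in n_per_pop
        }
    parts = []
    for name, n in n_per_pop.items():
        if n == 0:
            continue
        geno = draw_genotypes_hwe(pop_freqs[name], n, rng)
        ids = [f"{name}_{i + 1:04d}" for i in range(n)]
        meta = pd.DataFrame({"population": name}, index=ids)
        parts.append(Dataset(ids=ids, loci=model.locus_names, genotypes=geno, meta=meta))
    return concat_datasets(parts), pop_freqs


def simulate_hybrids(
    freqs_a: LocusFreqs,
    freqs_b: LocusFreqs,
    hybrid_class: str,
    n: int,
    seed,
    loci: list[str] | None = None,
    id_prefix: str | None = None,
) -> Dataset:
    """Simulate hybrid genotypes of one class from two parental gene pools.

    F1: one gamete from A's frequencies, one from B's. F2: one gamete
    from each of two freshly simulated F1 parents.  BC_A / BC_B: one F1
    gamete plus one gamete from the named parental pool.
    """
    rng = _rng(seed)
    if hybrid_class not in HYBRID_CLASSES:
        raise ValueError(f"unknown hybrid class {hybrid_class!r}; expected {HYBRID_CLASSES}")
    if len(freqs_a) != len(freqs_b):
        raise ValueError("parental frequency sets cover different loci")

    def f1_parents(k: int) -> np.ndarray:
        return np.stack([draw_gametes(freqs_a, k, rng), draw_gametes(freqs_b, k, rng)], axis=2)

    if hybrid_class == "F1":
        g1 = draw_gametes(freqs_a, n, rng)
        g2 = draw_gametes(freqs_b, n, rng)
    elif hybrid_class == "F2":
        g1 = _gamete_from_parents(f1_parents(n), rng)
        g2 = _gamete_from_parents(f1_parents(n), rng)
    elif hybrid_class == "BC_A":
        g1 = _gamete_from_parents(f1_parents(n), rng)
        g2 = draw_gametes(freqs_a, n, rng)
    else:  # BC_B
        g1 = _gamete_from_parents(f1_parents(n), rng)
        g2 = draw_gametes(freqs_b, n, rng)

    geno = np.sort(np.stack([g1, g2], axis=2), axis=2)
    prefix = id_prefix or hybrid_class
    ids = [f"{prefix}_{i + 1:04d}" for i in range(n)]
    loci = loci or [f"L{l + 1:02d}" for l in range(len(freqs_a))]
    meta = pd.DataFrame({"population": hybrid_class}, index=ids)
    return Dataset(ids=ids, loci=loci, genotypes=geno, meta=meta)


def simulate_replicates(ds: Dataset, em: ErrorModel, seed) -> list[ReplicateSet]:
    """Corrupt each individual's true genotype into `em.n_repeats`
    observed repeats with amplification failure and allelic dropout."""
    rng = _rng(seed)
    out = []
    material = ds.meta["material"] if "material" in ds.meta else None
    for i, sid in enumerate(ds.ids):
        true = ds.genotypes[i]
        reps = np.repeat(true[None], em.n_repeats, axis=0).copy()
        fail = rng.random((em.n_repeats, ds.n_loci)) < em.failure_rate
        reps[fail] = MISSING
        het = is_het(reps)
        drop = het & (rng.random((em.n_repeats, ds.n_loci)) < em.dropout_rate)
        if drop.any():
            keep = rng.integers(0, 2, size=int(drop.sum()))
            kept_alleles = reps[drop][np.arange(len(keep)), keep]
            reps[drop] = kept_alleles[:, None]
        out.append(
            ReplicateSet(
                sample_id=sid,
                loci=list(ds.loci),
                repeats=reps,
                material=str(material.iloc[i]) if material is not None else "feces",
            )
        )
    return out


def simulate_families(
    pop_freqs: LocusFreqs,
    n_families: int,
    seed,
    family_sizes: tuple[int, int] = (2, 4),
    loci: list[str] | None = None,
    population: str = "pop1",
) -> Dataset:
    """Full-sib families: two HWE parents per family, 2–4 offspring each.

    The returned Dataset carries a ``family`` metadata column.
    """
    rng = _rng(seed)
    ids, rows, fams = [], [], []
    for f in range(n_families):
        parents = draw_genotypes_hwe(pop_freqs, 2, rng)
        size = int(rng.integers(family_sizes[0], family_sizes[1] + 1))
        for k in range(size):
            g1 = _gamete_from_parents(parents[:1], rng)[0]
            g2 = _gamete_from_parents(parents[1:], rng)[0]
            rows.append(np.sort(np.stack([g1, g2]), axis=0).T)
            ids.append(f"fam{f + 1:03d}_{k + 1}")
            fams.append(f"fam{f + 1:03d}")
    loci = loci or [f"L{l + 1:02d}" for l in range(len(pop_freqs))]
    meta = pd.DataFrame({"population": population, "family": fams}, index=ids)
    return Dataset(ids=ids, loci=loci, genotypes=np.stack(rows), meta=meta)


def simulate_coordinates(
    ds: Dataset,
    kin_clustering: bool,
    seed,
    extent: float = 20_000.0,
    family_sigma: float = 400.0,
    family_col: str = "family",
) -> pd.DataFrame:
    """Sampling coordinates on a square study area of side `extent` m.

    With ``kin_clustering`` on, members of a family share a uniformly
    placed centre and scatter around it with isotropic Gaussian noise of
    scale ``family_sigma``; off, every individual is uniform on the
    square regardless of family.
    """
    rng = _rng(seed)
    n = ds.n_individuals
    if kin_clustering:
        if family_col not in ds.meta:
            raise ValueError(f"kin clustering requires a {family_col!r} metadata column")
        fams = ds.meta[family_col].to_numpy()
        centers = {f: rng.uniform(0, extent, size=2) for f in dict.fromkeys(fams)}
        xy = np.stack([centers[f] for f in fams]) + rng.normal(0, family_sigma, size=(n, 2))
    else:
        xy = rng.uniform(0, extent, size=(n, 2))
    return pd.DataFrame({"id": ds.ids, "x": xy[:, 0], "y": xy[:, 1]})


# ----------------------------------------------------------------------
# Study-scale convenience design
# ----------------------------------------------------------------------

def simulate_study_design(
    seed,
    model: PopModel | None = None,
    n_ne_domestic: int = 371,
    n_ne_wild: int = 42,
    n_po_domestic: int = 21,
    n_po_wild: int = 18,
    regional_divergence_domestic: float = 0.02,
    regional_divergence_wild: float = 0.04,
    n_hybrids: dict[str, int] | None = None,
) -> tuple[Dataset, dict[str, LocusFreqs]]:
    """Two-subspecies, two-region sampling design with hierarchical drift.

    A domestic and a wild gene pool each drift from the ancestor with
    ``model.divergence``; each regional population then drifts a little
    further from its subspecies pool.  Morphology metadata mirrors the
    true subspecies; optional hybrids (classes among F1/F2/BC_A/BC_B
    with A = domestic) are appended to the wild northeastern population
    with wildcat morphology.
    """
    rng = _rng(seed)
    model = model or PopModel()
    pool = {
        "domestic": draw_pop_freqs(model.ancestral_freqs, model.divergence, rng),
        "wild": draw_pop_freqs(model.ancestral_freqs, model.divergence, rng),
    }
    freqs = {
        "NE_domestic": draw_pop_freqs(pool["domestic"], regional_divergence_domestic, rng),
        "PO_domestic": draw_pop_freqs(pool["domestic"], regional_divergence_domestic, rng),
        "NE_wild": draw_pop_freqs(pool["wild"], regional_divergence_wild, rng),
        "PO_wild": draw_pop_freqs(pool["wild"], regional_divergence_wild, rng),
    }
    n_per_pop = {
        "NE_domestic": n_ne_domestic,
        "NE_wild": n_ne_wild,
        "PO_domestic": n_po_domestic,
        "PO_wild": n_po_wild,
    }
    ds, _ = simulate_parental_pops(model, n_per_pop, rng, pop_freqs=freqs)
    morph = {
        "NE_domestic": "catus",
        "PO_domestic": "catus",
        "NE_wild": "silvestris",
        "PO_wild": "silvestris",
    }
    ds.meta["morphology"] = [morph[p] for p in ds.meta["population"]]
    ds.meta["material"] = [
        "blood" if p.startswith("NE") else ("hair" if "domestic" in p else "feces")
        for p in ds.meta["population"]
    ]
    parts = [ds]
    for cls, n in (n_hybrids or {}).items():
        hyb = simulate_hybrids(
            freqs["NE_domestic"], freqs["NE_wild"], cls, n, rng,
            loci=model.locus_names, id_prefix=f"NE_{cls}",
        )
        hyb.meta["population"] = "NE_wild"
        hyb.meta["morphology"] = "silvestris"
        hyb.meta["true_class"] = cls
        parts.append(hyb)
    full = concat_datasets(parts) if len(parts) > 1 else ds
    if "true_class" in full.meta:
        full.meta["true_class"] = full.meta["true_class"].fillna("parental")
    return full, freqs


def calibrate_divergence(
    model: PopModel,
    n_per_pop: int = 200,
    n_seeds: int = 10,
    seed: int = 0,
) -> float:
    """Empirical mean multilocus Weir–Cockerham F_ST between two
    populations generated at ``model.divergence`` (calibration helper
    mapping the drift parameter to realized differentiation)."""
    from .popgen_stats import wc_fstats

    vals = []
    for s in range(n_seeds):
        ds, _ = simulate_parental_pops(
            model, {"A": n_per_pop, "B": n_per_pop}, seed=seed * 1000 + s
        )
        vals.append(wc_fstats(ds).fst.loc["A", "B"])
    return float(np.mean(vals))
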