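"""Consensus genotyping and quality control for replicated samples.

Noninvasively collected material (feces, hair) yields unreliable PCR
amplifications: a heterozygote may lose one allele in a given repeat
(allelic dropout, producing a false homozygote) or a locus may fail to
amplify at all.  Each sample is therefore genotyped 2–4 times and the
repeats are reconciled into a consensus genotype.

Sample quality is summarised by a quality index (QI): at each locus,
each repeat scores 1 when it reproduces the consensus genotype, 0.5
when it is a homozygote while the consensus is heterozygous (the
dropout signature), and 0 when it is missing.  Scores are averaged
over repeats per locus, then over loci per sample.  Samples whose
first genotyping amplified fewer than five loci, or whose QI is not
strictly above 0.6, are discarded.

Samples are then matched into unique individuals: two consensus
genotypes represent the same individual when they are (a) identical,
(b) differ only by missing data spanning at most ten loci, or
(c) differ at exactly one called locus by a dropout-compatible
homozygote/heterozygote pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import MISSING, Dataset, is_het, is_missing, normalize_genotypes


@dataclass
class ReplicateSet:
    """Repeated genotypes of one physical sample over a fixed locus panel."""

    sample_id: str
    loci: list[str]
    repeats: np.ndarray  # (n_repeats, n_loci, 2); MISSING = -1
    material: str = "feces"

    def __post_init__(self) -> None:
        self.repeats = normalize_genotypes(self.repeats)
        if self.repeats.shape[0] < 1:
            raise ValueError(f"sample {self.sample_id}: at least one repeat required")
        if self.repeats.shape[1] != len(self.loci):
            raise ValueError(
                f"sample {self.sample_id}: repeats cover {self.repeats.shape[1]} "
                f"loci but the panel has {len(self.loci)}"
            )

    @property
    def n_repeats(self) -> int:
        return int(self.repeats.shape[0])


@dataclass
class QualityIndex:
    """Per-locus and per-sample quality index in [0, 1]."""

    sample_id: str
    per_locus: np.ndarray  # (n_loci,)
    single_repeat: bool = False

    @property
    def per_sample(self) -> float:
        return float(np.mean(self.per_locus))


@dataclass
class ConsensusResult:
    sample_id: str
    loci: list[str]
    consensus: np.ndarray  # (n_loci, 2)
    conflicts: list[int] = field(default_factory=list)  # locus indices set missing


def build_consensus(rs: ReplicateSet, min_het_repeats: int | None = None) -> ConsensusResult:
    """Reconcile the repeats of one sample into a consensus genotype.

    Per locus: a heterozygote seen in enough repeats wins (a homozygote
    in another repeat is explained by dropout); unanimously observed
    homozygotes stand; all-missing stays missing; three or more distinct
    alleles across repeats, or disagreeing calls that dropout cannot
    explain, yield a missing consensus with a conflict flag.

    ``min_het_repeats`` is the heterozygote confirmation rule: by
    default a heterozygote needs 1 supporting repeat at loci with at
    most two called repeats, and 2 where three or more repeats called
    (the usual multi-tube safeguard; failed amplifications carry no
    information and do not raise the bar).
    """
    n_rep, n_loci = rs.repeats.shape[:2]
    consensus = np.full((n_loci, 2), MISSING, dtype=np.int64)
    conflicts: list[int] = []
    for l in range(n_loci):
        calls = [tuple(g) for g in rs.repeats[:, l] if g[0] != MISSING]
        if not calls:
            continue
        need_het = min_het_repeats
        if need_het is None:
            need_het = 1 if len(calls) <= 2 else 2
        alleles = {a for g in calls for a in g}
        hets = [g for g in calls if g[0] != g[1]]
        homs = [g for g in calls if g[0] == g[1]]
        if len(alleles) > 2:
            conflicts.append(l)
            continue
        if hets:
            het = hets[0]  # with <=2 alleles all hets are the same pair
            if len(hets) >= need_het:
                consensus[l] = het
            elif homs and all(h == homs[0] for h in homs) and homs[0][0] in het:
                # unconfirmed heterozygote; agreeing contained homozygote stands
                consensus[l] = homs[0]
            else:
                conflicts.append(l)
        else:
            if all(g == homs[0] for g in homs):
                consensus[l] = homs[0]
            else:
                # two disagreeing homozygotes cannot both be dropout artefacts
                conflicts.append(l)
    return ConsensusResult(rs.sample_id, list(rs.loci), consensus, conflicts)


def quality_index(rs: ReplicateSet, consensus: np.ndarray) -> QualityIndex:
    """Score each repeat against the consensus: 1 match, 0.5 false
    homozygote at a heterozygous consensus, 0 missing (or otherwise
    unexplained mismatch)."""
    consensus = normalize_genotypes(consensus[None])[0]
    n_rep, n_loci = rs.repeats.shape[:2]
    scores = np.zeros((n_rep, n_loci))
    cons_het = is_het(consensus)
    for r in range(n_rep):
        rep = rs.repeats[r]
        match = np.all(rep == consensus, axis=1)
        rep_hom = ~is_het(rep) & ~is_missing(rep)
        false_hom = rep_hom & cons_het & ~match
        scores[r][match] = 1.0
        scores[r][false_hom] = 0.5
    return QualityIndex(rs.sample_id, scores.mean(axis=0), single_repeat=(n_rep == 1))


@dataclass
class FilterReport:
    n_input: int
    n_failed_first_pass: int
    n_failed_qi: int
    retained: list[str]


def filter_samples(
    samples: list[ReplicateSet],
    quality: dict[str, QualityIndex],
    min_first_pass_loci: int = 5,
    min_qi: float = 0.6,
) -> FilterReport:
    """Apply the two sample filters: a first genotyping that amplified at
    least `min_first_pass_loci` loci, and a QI strictly above `min_qi`."""
    retained = []
    n_fp = n_qi = 0
    for rs in samples:
        first_pass = int((~is_missing(rs.repeats[0])).sum())
        if first_pass < min_first_pass_loci:
            n_fp += 1
            continue
        if quality[rs.sample_id].per_sample <= min_qi:
            n_qi += 1
            continue
        retained.append(rs.sample_id)
    return FilterReport(len(samples), n_fp, n_qi, retained)


def match_genotypes(g1: np.ndarray, g2: np.ndarray, max_missing: int = 10) -> bool:
    """Decide whether two consensus genotype vectors represent the same
    individual.

    True when (a) the vectors are identical, (b) they differ only at
    loci where one is missing and at most `max_missing` loci are missing
    in either vector, or (c) exactly one called locus differs and the
    difference is a heterozygote versus a homozygote for one of its
    alleles (a dropout-compatible pair).
    """
    g1 = normalize_genotypes(np.asarray(g1)[None])[0]
    g2 = normalize_genotypes(np.asarray(g2)[None])[0]
    if g1.shape != g2.shape:
        raise ValueError("genotype vectors cover different locus panels")
    m1, m2 = is_missing(g1), is_missing(g2)
    if np.array_equal(g1, g2):
        return True
    both_called = ~m1 & ~m2
    diff_called = both_called & ~np.all(g1 == g2, axis=1)
    n_missing_union = int((m1 | m2).sum())
    if not diff_called.any():
        return n_missing_union <= max_missing
    if int(diff_called.sum()) == 1:
        (l,) = np.flatnonzero(diff_called)
        a, b = g1[l], g2[l]
        het, hom = (a, b) if a[0] != a[1] else (b, a)
        if het[0] != het[1] and hom[0] == hom[1] and hom[0] in het:
            return True
    return False


@dataclass
class CollapseReport:
    sample_to_individual: dict[str, str]
    samples_per_individual: dict[str, list[str]]
    nontransitive_groups: list[str]


def collapse_individuals(
    consensuses: list[ConsensusResult],
    meta: pd.DataFrame | None = None,
    max_missing: int = 10,
) -> tuple[Dataset, CollapseReport]:
    """Group matching samples into unique individuals by single linkage.

    Each group's genotype is the consensus of its samples' consensuses
    (same reconciliation rules).  Groups in which some sample pair does
    not match directly (a non-transitive triad) are kept but flagged.
    """
    if not consensuses:
        raise ValueError("no consensus genotypes to collapse")
    loci = consensuses[0].loci
    n = len(consensuses)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    pair_match = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if match_genotypes(consensuses[i].consensus, consensuses[j].consensus, max_missing):
                pair_match[i, j] = pair_match[j, i] = True
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    ids, rows, flagged = [], [], []
    sample_map: dict[str, str] = {}
    samples_per: dict[str, list[str]] = {}
    meta_rows = []
    for k, members in enumerate(sorted(groups.values(), key=lambda m: m[0])):
        ind_id = f"ind{k + 1:03d}"
        member_ids = [consensuses[i].sample_id for i in members]
        stacked = np.stack([consensuses[i].consensus for i in members])
        merged = build_consensus(
            ReplicateSet(ind_id, loci, stacked), min_het_repeats=1
        ).consensus
        ids.append(ind_id)
        rows.append(merged)
        samples_per[ind_id] = member_ids
        for sid in member_ids:
            sample_map[sid] = ind_id
        if len(members) > 2 or (len(members) == 2 and not pair_match[members[0], members[1]]):
            ok = all(
                pair_match[i, j] for i in members for j in members if i < j
            )
            if not ok:
                flagged.append(ind_id)
        if meta is not None:
            meta_rows.append(meta.loc[member_ids[0]])

    ds_meta = pd.DataFrame(meta_rows, index=ids) if meta is not None else None
    ds = Dataset(ids=ids, loci=list(loci), genotypes=np.stack(rows), meta=ds_meta)
    return ds, CollapseReport(sample_map, samples_per, flagged)
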