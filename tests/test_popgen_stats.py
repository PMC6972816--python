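import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wildhyb.dataset import MISSING, Dataset
from wildhyb.popgen_stats import (
    bonferroni,
    hwe_test,
    ld_test,
    locus_summaries,
    null_allele_evidence,
    null_allele_freq,
    null_allele_test,
    pca_genotypes,
    rarefied_diversity,
    summarize_locus_table,
    unbiased_he,
    wc_fstats,
    fst_perm_test,
)
from wildhyb.synthetic_data import PopModel, simulate_parental_pops


# ----------------------------------------------------------------------
# Independent brute-force implementation of the Weir & Cockerham (1984)
# variance components, written directly from the per-allele formulas.
# ----------------------------------------------------------------------

def wc_theta_oracle(pop_genos):
    """pop_genos: list of (n_i, L, 2) arrays. Returns (theta, f)."""
    A = B = C = 0.0
    L = pop_genos[0].shape[1]
    for l in range(L):
        per_pop = []
        for g in pop_genos:
            gl = g[:, l]
            gl = gl[gl[:, 0] != MISSING]
            if len(gl):
                per_pop.append(gl)
        r = len(per_pop)
        if r < 2:
            continue
        ns = [len(g) for g in per_pop]
        nbar = sum(ns) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(n * n for n in ns) / (r * nbar)) / (r - 1)
        alleles = sorted({int(a) for g in per_pop for a in g.ravel()})
        for al in alleles:
            p_i, h_i = [], []
            for g in per_pop:
                n = len(g)
                p_i.append(np.sum(g == al) / (2 * n))
                h_i.append(np.mean((g[:, 0] == al) != (g[:, 1] == al)))
            pbar = sum(n * p for n, p in zip(ns, p_i)) / (r * nbar)
            s2 = sum(n * (p - pbar) ** 2 for n, p in zip(ns, p_i)) / ((r - 1) * nbar)
            hbar = sum(n * h for n, h in zip(ns, h_i)) / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - ((r - 1) / r) * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar)
                - ((r - 1) / r) * s2
                - ((2 * nbar - 1) / (4 * nbar)) * hbar
            )
            c = hbar / 2
            A, B, C = A + a, B + b, C + c
    theta = A / (A + B + C)
    f = 1 - C / (B + C)
    return theta, f


def _dataset_from_pops(pop_genos):
    ids, pops, rows = [], [], []
    for k, g in enumerate(pop_genos):
        for i in range(len(g)):
            ids.append(f"p{k}_{i}")
            pops.append(f"P{k}")
            rows.append(g[i])
    meta = pd.DataFrame({"population": pops}, index=ids)
    loci = [f"L{l}" for l in range(pop_genos[0].shape[1])]
    return Dataset(ids=ids, loci=loci, genotypes=np.stack(rows), meta=meta)


class TestLocusSummaries:
    def test_monomorphic_locus(self):
        g = np.full((4, 1, 2), 7)
        ds = _dataset_from_pops([g])
        row = locus_summaries(ds, ["P0"]).iloc[0]
        assert row["Na"] == 1 and row["Ho"] == 0.0 and row["He"] == 0.0

    def test_unbiased_he_single_heterozygote(self):
        """n=1 individual (1,2): Ho = 1 and He = (2/1)(1 - 0.5) = 1."""
        ds = _dataset_from_pops([np.array([[[1, 2]]])])
        row = locus_summaries(ds, ["P0"]).iloc[0]
        assert row["Ho"] == 1.0
        assert row["He"] == pytest.approx(1.0)
        assert unbiased_he(np.array([0.5, 0.5]), 1) == pytest.approx(1.0)

    def test_all_missing_locus_flagged(self):
        g = np.array([[[1, 2], [-1, -1]], [[1, 1], [-1, -1]]])
        ds = _dataset_from_pops([g])
        table = locus_summaries(ds, ["P0"])
        assert bool(table.iloc[1]["flagged"])
        assert np.isnan(table.iloc[1]["He"])

    def test_summary_rows_are_mean_and_sample_sd(self):
        table = pd.DataFrame(
            {"population": "P", "locus": [f"L{i}" for i in range(4)],
             "Na": [2.0, 4.0, 6.0, 8.0], "Ho": 0.5, "He": 0.5}
        )
        out = summarize_locus_table(table)
        mean = out[out.statistic == "Mean"].iloc[0]
        sd = out[out.statistic == "SD"].iloc[0]
        assert mean["Na"] == pytest.approx(5.0)
        assert sd["Na"] == pytest.approx(np.std([2, 4, 6, 8], ddof=1))

    def test_he_ho_invariant_under_allele_relabeling(self, two_pop):
        ds, _ = two_pop
        relabeled = Dataset(
            ids=ds.ids, loci=ds.loci, genotypes=np.where(
                ds.genotypes == MISSING, MISSING, ds.genotypes * 13 + 5
            ),
            meta=ds.meta,
        )
        a = locus_summaries(ds)
        b = locus_summaries(relabeled)
        assert np.allclose(a["He"], b["He"]) and np.allclose(a["Ho"], b["Ho"])


class TestRarefaction:
    def test_population_of_exact_size_reproduces_full_summary(self):
        rng = np.random.default_rng(0)
        g = rng.integers(1, 5, size=(18, 3, 2))
        ds = _dataset_from_pops([g])
        rar = rarefied_diversity(ds, n_individuals=18, n_reps=5, seed=1)
        full = locus_summaries(ds)
        merged = rar.merge(full, on=["locus", "population"], suffixes=("_r", ""))
        assert np.allclose(merged["Na_r"], merged["Na"])
        assert np.allclose(merged["He_r"], merged["He"])

    def test_rarefied_na_never_exceeds_full_sample_na(self, two_pop):
        ds, _ = two_pop
        rar = rarefied_diversity(ds, n_individuals=18, n_reps=10, seed=2)
        full = locus_summaries(ds)
        merged = rar.merge(full, on=["locus", "population"], suffixes=("_r", ""))
        assert (merged["Na_r"] <= merged["Na"] + 1e-12).all()

    def test_small_population_error_names_population(self, two_pop):
        ds, _ = two_pop
        with pytest.raises(ValueError, match="'A'"):
            rarefied_diversity(ds, n_individuals=200, n_reps=2, seed=0)

    def test_allele_count_ordering_preserved(self):
        hits = 0
        for s in range(10):
            m_lo = PopModel(n_loci=10, alleles_per_locus=3, divergence=0.05)
            m_hi = PopModel(n_loci=10, alleles_per_locus=8, divergence=0.05)
            lo, _ = simulate_parental_pops(m_lo, {"LO": 40}, seed=500 + s)
            hi, _ = simulate_parental_pops(m_hi, {"HI": 40}, seed=800 + s)
            from wildhyb.dataset import concat_datasets

            ds = concat_datasets([lo, hi])
            rar = rarefied_diversity(ds, n_individuals=18, n_reps=20, seed=s)
            na = rar.groupby("population")["Na"].mean()
            if na["HI"] > na["LO"]:
                hits += 1
        assert hits >= 9


class TestHweAndLd:
    def test_all_heterozygote_sample_has_f_minus_one(self):
        g = np.tile(np.array([1, 2]), (30, 1, 1))
        ds = _dataset_from_pops([g])
        out = hwe_test(ds, "L0", "P0", n_perm=200, seed=1)
        assert out["f"] == pytest.approx(-1.0)
        assert out["p"] < 0.05

    def test_monomorphic_locus_flagged_p_one(self):
        ds = _dataset_from_pops([np.full((10, 1, 2), 3)])
        out = hwe_test(ds, "L0", "P0", n_perm=50, seed=0)
        assert out["monomorphic"] and out["p"] == 1.0

    def test_type_i_error_near_alpha(self):
        """HWE-simulated loci are rejected at ~ the nominal 5% rate."""
        model = PopModel(n_loci=100, alleles_per_locus=6, divergence=0.2)
        ds, _ = simulate_parental_pops(model, {"A": 60}, seed=9)
        rej = 0
        for l in ds.loci:
            if hwe_test(ds, l, "A", n_perm=199, seed=hash(l) % 2**31)["p"] < 0.05:
                rej += 1
        assert rej / 100 <= 0.12

    def test_bonferroni_arithmetic(self):
        adj = bonferroni([0.002] * 22)
        assert adj[0] == pytest.approx(0.044)
        assert bonferroni([0.5, 0.9])[1] == 1.0

    def test_duplicated_locus_maximal_dependence(self):
        rng = np.random.default_rng(3)
        g1 = rng.integers(1, 4, size=(40, 1, 2))
        ds = _dataset_from_pops([np.concatenate([g1, g1], axis=1)])
        out = ld_test(ds, "L0", "L1", "P0", n_perm=99, seed=4)
        assert out["p"] == pytest.approx(1 / 100)

    def test_independent_loci_type_i_error(self):
        model = PopModel(n_loci=40, alleles_per_locus=4, divergence=0.2)
        ds, _ = simulate_parental_pops(model, {"A": 50}, seed=11)
        rej = 0
        pairs = [(ds.loci[2 * i], ds.loci[2 * i + 1]) for i in range(20)]
        for la, lb in pairs:
            if ld_test(ds, la, lb, "A", n_perm=199, seed=5)["p"] < 0.05:
                rej += 1
        assert rej <= 4

    def test_zero_permutations_rejected(self, two_pop):
        ds, _ = two_pop
        with pytest.raises(ValueError):
            ld_test(ds, ds.loci[0], ds.loci[1], "A", n_perm=0)


class TestNullAlleles:
    def test_estimator_arithmetic(self):
        assert null_allele_freq(0.8, 0.8) == 0.0
        assert null_allele_freq(0.6, 0.8) == pytest.approx(0.2 / 1.8)
        assert null_allele_freq(0.9, 0.8) == 0.0  # clamped

    def test_recovery_of_simulated_null_allele(self):
        """A specific allele failing to amplify at frequency ~0.15 is
        recovered by the Brookfield estimator within +-0.05 (median)."""
        rng = np.random.default_rng(21)
        estimates = []
        for _ in range(50):
            # one locus, 8 alleles; allele 1 at freq 0.15 is the null
            p = np.array([0.15] + [0.85 / 7] * 7)
            g = rng.choice(np.arange(1, 9), size=(120, 2), p=p)
            null = g == 1
            geno = np.sort(g, axis=1)[:, None, :]
            both_null = null.all(axis=1)
            one_null = null.any(axis=1) & ~both_null
            # heterozygote with one null copy is mis-scored homozygote
            other = np.where(g[:, 0] == 1, g[:, 1], g[:, 0])
            geno[one_null, 0, 0] = other[one_null]
            geno[one_null, 0, 1] = other[one_null]
            geno[both_null, 0] = MISSING
            ds = _dataset_from_pops([geno])
            estimates.append(null_allele_test(ds, "L0", "P0")["r_null"])
        assert np.median(estimates) == pytest.approx(0.15, abs=0.05)

    def test_evidence_rule(self):
        assert null_allele_evidence(0.01, 0.5)
        assert not null_allele_evidence(0.20, 0.5)
        assert not null_allele_evidence(0.01, 0.01)


class TestWcFstats:
    def test_duplicated_population_halves_give_near_zero_theta(self):
        rng = np.random.default_rng(6)
        g = rng.integers(1, 6, size=(60, 8, 2))
        ds = _dataset_from_pops([g[:30], g[30:]])
        assert abs(wc_fstats(ds).fst.loc["P0", "P1"]) < 0.03

    def test_fixed_differences_give_theta_one(self):
        ds = _dataset_from_pops([np.full((10, 5, 2), 1), np.full((10, 5, 2), 2)])
        assert wc_fstats(ds).fst.loc["P0", "P1"] == pytest.approx(1.0)

    def test_monomorphic_pair_is_an_error(self):
        ds = _dataset_from_pops([np.full((4, 2, 2), 1), np.full((4, 2, 2), 1)])
        with pytest.raises(ValueError, match="theta undefined"):
            wc_fstats(ds)

    @settings(max_examples=40, deadline=None)
    @given(st.data())
    def test_matches_brute_force_oracle_on_random_instances(self, data):
        """theta and f from the vectorized implementation equal the
        per-allele brute-force formulas to 1e-12 on random 2x4x2 data."""
        draw = data.draw
        pops = []
        for _ in range(2):
            g = np.array(
                [
                    [
                        [draw(st.integers(1, 3)), draw(st.integers(1, 3))]
                        for _ in range(2)
                    ]
                    for _ in range(4)
                ]
            )
            pops.append(np.sort(g, axis=2))
        alleles = {int(a) for g in pops for a in g.ravel()}
        if len(alleles) < 2:
            return  # monomorphic overall: theta undefined
        ds = _dataset_from_pops(pops)
        res = wc_fstats(ds)
        theta_o, f_o = wc_theta_oracle(pops)
        assert res.fst.loc["P0", "P1"] == pytest.approx(theta_o, abs=1e-12)

    def test_permutation_p_detects_structure(self, two_pop):
        ds, _ = two_pop
        sub = ds.subset(list(range(30)) + list(range(100, 130)))
        theta, p = fst_perm_test(sub, ("A", "B"), n_perm=99, seed=7)
        assert theta > 0.08
        assert p == pytest.approx(1 / 100)

    def test_permutation_p_uniform_without_structure(self):
        rng = np.random.default_rng(8)
        g = rng.integers(1, 6, size=(40, 6, 2))
        ds = _dataset_from_pops([g[:20], g[20:]])
        _, p = fst_perm_test(ds, ("P0", "P1"), n_perm=99, seed=9)
        assert p > 0.05


class TestPca:
    def test_separates_diverged_populations(self, two_pop):
        ds, _ = two_pop
        res = pca_genotypes(ds, n_axes=2)
        labels = (ds.meta["population"] == "A").to_numpy(dtype=float)
        pc1 = res.scores["PC1"].to_numpy()
        corr = abs(np.corrcoef(pc1, labels)[0, 1])
        assert corr > 0.9

    def test_duplicated_dataset_gives_identical_scores(self, tiny_dataset):
        res1 = pca_genotypes(tiny_dataset)
        res2 = pca_genotypes(tiny_dataset)
        assert np.allclose(res1.scores, res2.scores)

    def test_explained_variance_sums_to_total(self, two_pop):
        ds, _ = two_pop
        res = pca_genotypes(ds)
        # rebuild the centred indicator matrix total variance
        total = res.explained_variance.sum()
        assert total == pytest.approx(
            np.var(res.scores.to_numpy(), axis=0, ddof=1).sum(), abs=1e-9
        )
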