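import numpy as np
import pandas as pd
import pytest

from wildhyb.admixture import (
    align_clusters,
    best_k,
    em_hybrid_classes,
    evanno_delta_k,
    fit_admixture,
)
from wildhyb.dataset import Dataset, concat_datasets
from wildhyb.synthetic_data import (
    PopModel,
    simulate_hybrids,
    simulate_parental_pops,
)

from conftest import fixed_difference_freqs

SHORT = dict(burnin=300, iters=1500, thin=5)


@pytest.fixture(scope="module")
def fitted_two_pop_f1(two_pop_with_f1):
    ds, freqs, f1_ids = two_pop_with_f1
    res = fit_admixture(ds, K=2, seed=42, **SHORT)
    return ds, res, f1_ids


def _own_cluster(res, ids):
    sub = res.q.loc[ids]
    return sub.mean(axis=0).idxmax()


class TestGibbsSampler:
    def test_k1_gives_degenerate_ancestry(self, tiny_dataset):
        res = fit_admixture(tiny_dataset, K=1, burnin=20, iters=100, thin=2, seed=0)
        assert np.allclose(res.q.to_numpy(), 1.0)
        assert np.allclose(res.cri_lo.to_numpy(), 1.0)
        assert np.allclose(res.cri_hi.to_numpy(), 1.0)

    def test_k_exceeding_individuals_rejected(self, tiny_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            fit_admixture(tiny_dataset, K=5, burnin=5, iters=10)

    def test_q_rows_sum_to_one(self, fitted_two_pop_f1):
        _, res, _ = fitted_two_pop_f1
        assert np.allclose(res.q.sum(axis=1), 1.0, atol=1e-9)
        assert (res.cri_lo.to_numpy() <= res.q.to_numpy() + 1e-9).all()
        assert (res.q.to_numpy() <= res.cri_hi.to_numpy() + 1e-9).all()

    def test_parental_recovery_and_f1_intermediacy(self, fitted_two_pop_f1):
        ds, res, f1_ids = fitted_two_pop_f1
        a_ids = [i for i in ds.ids if i.startswith("A_")]
        b_ids = [i for i in ds.ids if i.startswith("B_")]
        ka, kb = _own_cluster(res, a_ids), _own_cluster(res, b_ids)
        assert ka != kb
        assert res.q.loc[a_ids, ka].mean() > 0.9
        assert res.q.loc[b_ids, kb].mean() > 0.9
        qf1 = res.q.loc[f1_ids, ka].to_numpy()
        assert np.mean((qf1 > 0.25) & (qf1 < 0.75)) >= 0.9

    def test_fixed_seed_reproducible(self, tiny_dataset):
        r1 = fit_admixture(tiny_dataset, K=2, burnin=50, iters=200, thin=2, seed=3)
        r2 = fit_admixture(tiny_dataset, K=2, burnin=50, iters=200, thin=2, seed=3)
        assert np.array_equal(r1.draws, r2.draws)
        assert np.array_equal(r1.loglik_trace, r2.loglik_trace)

    def test_label_permutation_leaves_likelihood_unchanged(self, fitted_two_pop_f1):
        """Swapping cluster labels permutes q and the cluster frequencies
        consistently, so the mixture data likelihood is invariant."""
        ds, res, _ = fitted_two_pop_f1
        swapped = res.relabel((1, 0))

        def loglik(r):
            from wildhyb.admixture import _recode

            _, _, _, ii, ll, aa = _recode(ds)
            q = r.q.to_numpy()
            mix = (q[ii] * r.cluster_freqs[:, ll, aa].T).sum(axis=1)
            return float(np.log(np.maximum(mix, 1e-300)).sum())

        assert loglik(swapped) == pytest.approx(loglik(res), abs=1e-9)

    def test_correlated_model_runs_and_recovers(self, pop_model):
        ds, _ = simulate_parental_pops(pop_model, {"A": 40, "B": 40}, seed=77)
        res = fit_admixture(ds, K=2, model="correlated", burnin=200, iters=800, thin=4, seed=5)
        a_ids = ds.ids[:40]
        ka = _own_cluster(res, a_ids)
        assert res.q.loc[a_ids, ka].mean() > 0.85

    def test_f1_credibility_interval_coverage(self, pop_model, two_pop):
        """The true F1 ancestry (0.5) lies inside the 90% CrI for roughly
        90% of simulated F1s."""
        ds, freqs = two_pop
        f1 = simulate_hybrids(freqs["A"], freqs["B"], "F1", 200, 900, loci=pop_model.locus_names)
        full = concat_datasets([ds, f1])
        res = fit_admixture(full, K=2, seed=901, **SHORT)
        lo = res.cri_lo.loc[f1.ids].to_numpy()[:, 0]
        hi = res.cri_hi.loc[f1.ids].to_numpy()[:, 0]
        coverage = np.mean((lo < 0.5) & (0.5 < hi))
        assert 0.8 <= coverage <= 1.0


class TestEvanno:
    @staticmethod
    def _runs(means, sd=1.0):
        d = sd / np.sqrt(2)
        return {k + 1: [m - d, m + d] for k, m in enumerate(means)}

    def test_linear_likelihood_gives_zero_delta_k(self):
        table = evanno_delta_k(self._runs([-100, -80, -60, -40]))
        interior = table.dropna(subset=["delta_K"])
        assert np.allclose(interior["delta_K"], 0.0, atol=1e-9)

    def test_constructed_table_arithmetic(self):
        """L = (-100, -50, -48, -47), sd = 1: delta_K(2) = 48,
        delta_K(3) = 1, best K = 2."""
        table = evanno_delta_k(self._runs([-100, -50, -48, -47]))
        dk = dict(zip(table["K"], table["delta_K"]))
        assert dk[2] == pytest.approx(48.0)
        assert dk[3] == pytest.approx(1.0)
        assert np.isnan(dk[1]) and np.isnan(dk[4])
        assert best_k(table) == 2

    def test_zero_sd_gives_infinite_delta_k(self):
        runs = {1: [-100, -100], 2: [-50, -50], 3: [-48, -48]}
        table = evanno_delta_k(runs)
        assert np.isinf(table.set_index("K").loc[2, "delta_K"])

    def test_recovers_two_clusters_on_synthetic_data(self, two_pop):
        """Repeated short runs across K = 1..4 put the Evanno optimum at
        the true cluster count."""
        ds, _ = two_pop
        sub = ds.subset(list(range(0, 40)) + list(range(100, 140)))
        runs = {}
        for k in range(1, 5):
            runs[k] = [
                fit_admixture(sub, K=k, burnin=150, iters=600, thin=5, seed=10 * k + r).mean_loglik
                for r in range(3)
            ]
        assert best_k(evanno_delta_k(runs)) == 2

    def test_endpoint_and_repeat_validation(self):
        with pytest.raises(ValueError, match="consecutive"):
            evanno_delta_k({1: [0, 0], 3: [0, 0], 4: [0, 0]})
        with pytest.raises(ValueError, match="two repeats"):
            evanno_delta_k({1: [0.0], 2: [0.0], 3: [0.0]})


class TestAlignment:
    def test_identity_and_inversion(self, fitted_two_pop_f1):
        ds, res, _ = fitted_two_pop_f1
        a_ids = [i for i in ds.ids if i.startswith("A_")][:10]
        b_ids = [i for i in ds.ids if i.startswith("B_")][:10]
        ka = _own_cluster(res, a_ids)
        ref = {0: a_ids, 1: b_ids} if ka == "k1" else {1: a_ids, 0: b_ids}
        aligned, ties = align_clusters([res], ref)
        assert np.allclose(aligned[0].q.to_numpy(), res.q.to_numpy())
        swapped = res.relabel((1, 0))
        aligned2, _ = align_clusters([swapped], ref)
        assert np.allclose(aligned2[0].q.to_numpy(), res.q.to_numpy())

    def test_reference_validation(self, fitted_two_pop_f1):
        _, res, _ = fitted_two_pop_f1
        with pytest.raises(ValueError, match="non-empty"):
            align_clusters([res], {0: [], 1: ["A_0001"]})
        with pytest.raises(ValueError, match="disjoint"):
            align_clusters([res], {0: ["A_0001"], 1: ["A_0001"]})


class TestEmHybridClasses:
    def test_fully_heterozygous_individual_is_f1_at_diagnostic_loci(self):
        fa, fb = fixed_difference_freqs(n_loci=10)
        pa = simulate_hybrids(fa, fa, "F1", 5, 1, id_prefix="pa")  # pure A genotypes
        pb = simulate_hybrids(fb, fb, "F1", 5, 2, id_prefix="pb")
        f1 = simulate_hybrids(fa, fb, "F1", 1, 3, id_prefix="f1")
        full = concat_datasets([pa, pb, f1])
        em = em_hybrid_classes(
            full, classes=["pureA", "pureB", "F1"], freq_mode="fixed",
            ref_a=list(pa.ids), ref_b=list(pb.ids),
        )
        assert em.posterior.loc[f1.ids[0], "F1"] > 0.99

    def test_loglik_monotone_under_joint_em(self, two_pop_with_f1):
        ds, _, _ = two_pop_with_f1
        a = [i for i in ds.ids if i.startswith("A_")]
        b = [i for i in ds.ids if i.startswith("B_")]
        em = em_hybrid_classes(ds, freq_mode="joint", ref_a=a, ref_b=b, seed=1)
        assert np.all(np.diff(em.loglik_trace) > -1e-6)
        assert em.converged

    def test_posterior_rows_sum_to_one(self, two_pop_with_f1):
        ds, _, _ = two_pop_with_f1
        a = [i for i in ds.ids if i.startswith("A_")]
        b = [i for i in ds.ids if i.startswith("B_")]
        em = em_hybrid_classes(ds, freq_mode="joint", ref_a=a, ref_b=b, seed=1)
        assert np.allclose(em.posterior.sum(axis=1), 1.0, atol=1e-9)

    def test_backcross_recovery_rate(self, pop_model):
        """Modal class is the true backcross for >= 70% of simulated
        first-generation backcrosses at 22 loci, F_ST ~ 0.15."""
        ok = tot = 0
        for s in range(6):
            ds, freqs = simulate_parental_pops(pop_model, {"A": 100, "B": 100}, seed=100 + s)
            bca = simulate_hybrids(freqs["A"], freqs["B"], "BC_A", 30, 200 + s,
                                   loci=pop_model.locus_names)
            full = concat_datasets([ds, bca])
            em = em_hybrid_classes(
                full, classes=["pureA", "pureB", "F1", "BC_A", "BC_B"],
                freq_mode="joint", ref_a=list(ds.ids[:100]), ref_b=list(ds.ids[100:]),
                seed=0,
            )
            modal = em.modal_class[bca.ids]
            ok += int((modal == "BC_A").sum())
            tot += len(modal)
        assert ok / tot >= 0.7

    def test_class_set_validation(self, tiny_dataset):
        with pytest.raises(ValueError, match="unknown class"):
            em_hybrid_classes(tiny_dataset, classes=["pureA", "pureB", "F3"])
        with pytest.raises(ValueError, match="pure"):
            em_hybrid_classes(tiny_dataset, classes=["pureA", "F1"])
        with pytest.raises(ValueError, match="reference"):
            em_hybrid_classes(tiny_dataset, freq_mode="fixed")

    def test_agrees_with_gibbs_on_fixed_difference_cases(self):
        """Both routes call unambiguous pure and F1 individuals the same
        way when the parental pools share no alleles."""
        fa, fb = fixed_difference_freqs(n_loci=12)
        pa = simulate_hybrids(fa, fa, "F1", 20, 4, id_prefix="pa")
        pb = simulate_hybrids(fb, fb, "F1", 20, 5, id_prefix="pb")
        f1 = simulate_hybrids(fa, fb, "F1", 5, 6, id_prefix="f1")
        full = concat_datasets([pa, pb, f1])
        em = em_hybrid_classes(
            full, classes=["pureA", "pureB", "F1"], freq_mode="fixed",
            ref_a=list(pa.ids), ref_b=list(pb.ids),
        )
        res = fit_admixture(full, K=2, burnin=200, iters=800, thin=4, seed=7)
        ka = _own_cluster(res, list(pa.ids))
        for i in pa.ids:
            assert em.modal_class[i] == "pureA"
            assert res.q.loc[i, ka] > 0.9
        for i in f1.ids:
            assert em.modal_class[i] == "F1"
            assert 0.25 < res.q.loc[i, ka] < 0.75
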