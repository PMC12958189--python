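"""Synthetic-data generator: determinism, truth structure, marginal calibration."""

import numpy as np
import pytest
from scipy.stats import norm

from calvease.genomic import vanraden_g, GenotypeMatrix
from calvease.liability import category_probabilities
from calvease.simulate import (
    SimConfig,
    calibrated_intercept,
    default_comparison_scenario,
    simulate_genotypes,
    simulate_pedigree,
    simulate_records,
)

from conftest import SMALL_CFG

TINY = SimConfig(
    n_service_sires=20,
    n_mgs=15,
    n_dams=300,
    records_per_sire=20,
    n_founder_males=40,
    n_founder_females=100,
    n_snp=50,
    n_herds=8,
)


class TestPedigreeSimulation:
    def test_deterministic_under_seed(self):
        p1, t1 = simulate_pedigree(TINY, 3)
        p2, t2 = simulate_pedigree(TINY, 3)
        assert (p1.ids == p2.ids).all()
        assert (p1.sire == p2.sire).all() and (p1.dam == p2.dam).all()
        assert t1.u == pytest.approx(t2.u, abs=0)

    def test_different_seeds_differ(self):
        _, t1 = simulate_pedigree(TINY, 3)
        _, t2 = simulate_pedigree(TINY, 4)
        assert not np.allclose(t1.u, t2.u)

    def test_zero_genetic_variance_zero_breeding_values(self):
        cfg = SimConfig(**{**TINY.__dict__, "sigma2_s": 0.0, "cov_sm": 0.0, "sigma2_m": 0.0})
        _, truth = simulate_pedigree(cfg, 5)
        assert not truth.u.any()

    def test_founder_covariance_approaches_g0(self):
        cfg = SimConfig(
            n_service_sires=1, n_mgs=1, n_dams=1,
            n_founder_males=50_000, n_founder_females=10,
            records_per_sire=1, n_snp=1, n_herds=1,
        )
        ped, truth = simulate_pedigree(cfg, 11)
        founders = np.flatnonzero((ped.sire < 0) & (ped.dam < 0))
        u = truth.u[founders]
        emp = np.cov(u.T)
        g0 = cfg.g0
        n = founders.size
        for (i, j) in [(0, 0), (0, 1), (1, 1)]:
            se = np.sqrt((g0[i, i] * g0[j, j] + g0[i, j] ** 2) / n)
            assert abs(emp[i, j] - g0[i, j]) < 3 * se

    def test_descendants_regress_to_parent_average(self):
        ped, truth = simulate_pedigree(SMALL_CFG, 9)
        kids = np.flatnonzero((ped.sire >= 0) & (ped.dam >= 0))
        pa = 0.5 * (truth.u[ped.sire[kids]] + truth.u[ped.dam[kids]])
        dev = truth.u[kids] - pa
        # Mendelian deviations: mean 0, variance g0/2
        assert np.abs(dev.mean(axis=0)).max() < 0.02
        emp = np.cov(dev.T)
        assert emp == pytest.approx(0.5 * SMALL_CFG.g0, abs=0.01)


class TestGenotypeSimulation:
    def test_fixed_founder_frequency_gives_constant_dosage(self):
        ped, _ = simulate_pedigree(TINY, 2)
        g = simulate_genotypes(ped, 5, 2, founder_freq=1.0)
        assert (g.dosages == 2.0).all()

    def test_parent_offspring_share_an_allele(self):
        ped, _ = simulate_pedigree(TINY, 2)
        g = simulate_genotypes(ped, 40, 3)
        for i in range(len(ped)):
            s = ped.sire[i]
            if s < 0:
                continue
            # opposite homozygotes are impossible between parent and child
            assert not np.any((g.dosages[i] == 0) & (g.dosages[s] == 2))
            assert not np.any((g.dosages[i] == 2) & (g.dosages[s] == 0))

    def test_parent_offspring_genomic_relationship_near_half(self):
        cfg = SimConfig(**{**TINY.__dict__, "n_snp": 2000})
        ped, _ = simulate_pedigree(cfg, 6)
        g = simulate_genotypes(ped, cfg.n_snp, 6)
        G = vanraden_g(g)
        pairs = [(i, ped.sire[i]) for i in range(len(ped)) if ped.sire[i] >= 0]
        rel = np.mean([G[i, s] for i, s in pairs])
        assert rel == pytest.approx(0.5, abs=0.05)

    def test_deterministic_under_seed(self):
        ped, _ = simulate_pedigree(TINY, 2)
        g1 = simulate_genotypes(ped, 30, 5)
        g2 = simulate_genotypes(ped, 30, 5)
        assert (g1.dosages == g2.dosages).all()


class TestRecordSimulation:
    def test_degenerate_all_easy(self):
        cfg = SimConfig(
            **{
                **TINY.__dict__,
                "sigma2_s": 0.0,
                "cov_sm": 0.0,
                "sigma2_m": 0.0,
                "sigma2_hys": 1e-12,
                "fixed_effect_size": 0.0,
                "mu0": -10.0,
            }
        )
        ped, truth = simulate_pedigree(cfg, 1)
        rt = simulate_records(ped, truth, cfg, 1)
        assert (rt.df["score"] == 1).all()

    def test_every_mgs_is_pedigree_sire_of_dam(self):
        ped, truth = simulate_pedigree(TINY, 8)
        rt = simulate_records(ped, truth, TINY, 8)
        for _, row in rt.df.head(50).iterrows():
            di = ped.index_of([row["dam"]])[0]
            assert ped.ids[ped.sire[di]] == row["mgs"]

    def test_marginal_frequencies_match_analytic_oracle(self):
        # the liability is marginally N(mu0, sigma2_hys + sigma2_s + sigma2_m + 1);
        # category shares must match the probit integrals at any intercept
        cfg = SimConfig(
            n_service_sires=300,
            n_mgs=200,
            n_dams=5000,
            records_per_sire=20,
            n_founder_males=500,
            n_founder_females=2000,
            n_snp=1,
            n_herds=500,
            mu0=-1.5,
            fixed_effect_size=0.0,
        )
        ped, truth = simulate_pedigree(cfg, 13)
        rt = simulate_records(ped, truth, cfg, 13, n_records=400_000)
        sd = np.sqrt(cfg.sigma2_hys + cfg.sigma2_s + cfg.sigma2_m + 1.0)
        expected = np.diff(
            [0.0, *norm.cdf((np.array(cfg.cuts) - cfg.mu0) / sd), 1.0]
        )
        emp = (
            rt.df["score"].value_counts(normalize=True).reindex([1, 2, 3, 4]).fillna(0)
        )
        # herd/sire/dam level effects are shared across many records, so the
        # dominant Monte-Carlo error is level sampling (~0.006 per share here);
        # 0.02 is a ~3-sd bound, far below any scale or formula error
        assert emp.to_numpy() == pytest.approx(expected, abs=0.02)

    def test_default_calibration_hits_national_distribution(self):
        cfg = SimConfig(
            **{**TINY.__dict__, "n_service_sires": 300, "n_dams": 5000, "n_herds": 300}
        )
        ped, truth = simulate_pedigree(cfg, 17)
        rt = simulate_records(ped, truth, cfg, 17, n_records=1_000_000)
        emp = rt.df["score"].value_counts(normalize=True).sort_index().to_numpy()
        assert emp == pytest.approx([0.826, 0.091, 0.057, 0.026], abs=0.01)

    def test_intercept_calibration_closed_form(self):
        cfg = SimConfig()
        mu0 = calibrated_intercept(cfg)
        sd = np.sqrt(cfg.sigma2_hys + cfg.sigma2_s + cfg.sigma2_m + 1.0)
        assert norm.cdf((cfg.cuts[0] - mu0) / sd) == pytest.approx(0.826)


class TestScenario:
    def test_counts_and_coverage(self):
        sc = default_comparison_scenario(5, cfg=TINY)
        assert len(sc.records) == TINY.n_records
        sires = sc.records.phenotyped_sires()
        assert len(sires) == TINY.n_service_sires  # every sire phenotyped
        for m in sc.records.phenotyped_mgs():
            assert sc.ped.contains(m)

    def test_genotyped_set_is_male_layers(self):
        sc = default_comparison_scenario(5, cfg=TINY)
        assert sc.genos.n_animals == TINY.n_founder_males + TINY.n_service_sires + TINY.n_mgs

    def test_byte_identical_under_seed(self, tmp_path):
        a, b = tmp_path / "a", tmp_path / "b"
        default_comparison_scenario(5, cfg=TINY).write(a)
        default_comparison_scenario(5, cfg=TINY).write(b)
        for name in ("records.csv", "pedigree.csv", "genotypes.txt"):
            assert (a / name).read_bytes() == (b / name).read_bytes()
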