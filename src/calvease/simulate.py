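"""Synthetic calving-ease data with the structure of a national evaluation.

The generator emulates the record layout of the US calving-ease system: one
row per calving carrying the service sire, the dam, her sire (the maternal
grandsire), a herd-year-season contemporary group, and an ordinal score
1-4.  The truth model is the sire-dam (SMAT) structure -- every animal
carries a bivariate breeding value (u_s, u_m) for sire calving ease and
maternal calving ease distributed N(0, G0 kron A) -- so that the sire-dam
analysis is correctly specified and the sire-MGS analysis is its reduced
form, mirroring how the two models relate on real data.

Default parameters are the national liability-scale estimates on the dam
scale (G0 = [[0.0239, 0.0242], [0.0242, 0.0961]], sigma2_hys = 0.232,
cutpoints [-1.22, -0.67, 0]); the intercept is calibrated so the marginal
share of category-1 (easy) calvings is 82.6%, reproducing the national
score distribution (~82.6 / 9.1 / 5.7 / 2.6%).

The pedigree is three layers deep: founder males and females, a generation
of proven bulls (service sires and maternal grandsires), and a generation
of recorded dams.  Genotypes arise by gene dropping founder alleles drawn
at uniform frequencies; by default the male layers (founders plus proven
bulls) are the genotyped set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .genomic import GenotypeMatrix
from .liability import Thresholds
from .model import RecordTable, VarianceComponents
from .pedigree import PedigreeTable, build_pedigree

__all__ = [
    "SimConfig",
    "TruthSet",
    "Scenario",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_records",
    "default_comparison_scenario",
    "calibrated_intercept",
]

# printed national SMAT-scale truth
_DEFAULT_CUTS = (-1.22, -0.67, 0.0)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the national-evaluation conditions.

    Genetic and contemporary-group variances are on the liability scale
    with unit residual.  ``mu0=None`` calibrates the intercept so the
    marginal probability of score 1 equals ``p1_target`` given the total
    liability standard deviation.
    """

    n_service_sires: int = 300
    n_mgs: int = 200
    n_dams: int = 20000
    records_per_sire: int = 150
    n_founder_males: int = 1000
    n_founder_females: int = 5000
    n_snp: int = 1000
    n_herds: int = 150
    n_year_seasons: int = 6
    n_breeds: int = 2
    n_parities: int = 3
    n_sexes: int = 2
    fixed_effect_size: float = 0.1
    sigma2_s: float = 0.0239
    cov_sm: float = 0.0242
    sigma2_m: float = 0.0961
    sigma2_hys: float = 0.232
    cuts: tuple = _DEFAULT_CUTS
    p1_target: float = 0.826
    mu0: float | None = None

    @property
    def n_records(self) -> int:
        return self.n_service_sires * self.records_per_sire

    @property
    def g0(self) -> np.ndarray:
        return np.array([[self.sigma2_s, self.cov_sm], [self.cov_sm, self.sigma2_m]])

    @property
    def thresholds(self) -> Thresholds:
        return Thresholds(self.cuts)

    def variance_components(self) -> VarianceComponents:
        return VarianceComponents(
            model="smat",
            sigma2_s=self.sigma2_s,
            cov_sm=self.cov_sm,
            sigma2_m=self.sigma2_m,
            sigma2_hys=self.sigma2_hys,
        )


def calibrated_intercept(cfg: SimConfig) -> float:
    """Intercept putting the marginal category-1 share at ``p1_target``.

    Marginally the liability is N(mu0, sigma2_hys + sigma2_s + sigma2_m + 1)
    (fixed-effect draws are centred and small), so
    mu0 = t_1 - Phi^-1(p1) * sigma_lambda.
    """
    if cfg.mu0 is not None:
        return cfg.mu0
    sd = np.sqrt(cfg.sigma2_hys + cfg.sigma2_s + cfg.sigma2_m + 1.0)
    return cfg.cuts[0] - norm.ppf(cfg.p1_target) * sd


@dataclass
class TruthSet:
    """Simulated truth: breeding values, group effects, liabilities, roles."""

    u: np.ndarray  # (n_ped, 2) true (u_s, u_m) in pedigree order
    service_sires: np.ndarray
    mgs_bulls: np.ndarray
    dams: np.ndarray
    genotyped: np.ndarray = field(default_factory=lambda: np.array([], dtype=object))
    hys_effects: dict = field(default_factory=dict)
    liabilities: np.ndarray | None = None

    def u_of(self, ped: PedigreeTable, animal_ids, trait: int) -> np.ndarray:
        return self.u[ped.index_of(list(animal_ids)), trait]


def _mvn_pairs(rng, cov: np.ndarray, n: int) -> np.ndarray:
    vals, vecs = np.linalg.eigh(np.asarray(cov, float))
    root = vecs @ np.diag(np.sqrt(np.maximum(vals, 0.0)))
    return rng.standard_normal((n, 2)) @ root.T


def simulate_pedigree(cfg: SimConfig, seed: int) -> tuple[PedigreeTable, TruthSet]:
    """Three-layer pedigree plus true bivariate breeding values.

    Founders draw (u_s, u_m) ~ N(0, G0); descendants take the parent
    average plus a Mendelian deviation ~ N(0, G0/2) (parental inbreeding is
    ignored in the Mendelian variance -- founders are unrelated and the
    pedigree is shallow, so the approximation is negligible here).
    """
    rng = np.random.default_rng(seed)
    fm = [f"FM{i + 1:05d}" for i in range(cfg.n_founder_males)]
    ff = [f"FF{i + 1:05d}" for i in range(cfg.n_founder_females)]
    sires = [f"S{i + 1:05d}" for i in range(cfg.n_service_sires)]
    mgs = [f"G{i + 1:05d}" for i in range(cfg.n_mgs)]
    dams = [f"D{i + 1:06d}" for i in range(cfg.n_dams)]

    animal = fm + ff + sires + mgs + dams
    n_gen1 = cfg.n_service_sires + cfg.n_mgs
    gen1_sire = rng.choice(cfg.n_founder_males, size=n_gen1)
    gen1_dam = rng.choice(cfg.n_founder_females, size=n_gen1)
    dam_sire = rng.choice(cfg.n_mgs, size=cfg.n_dams)
    dam_dam = rng.choice(cfg.n_founder_females, size=cfg.n_dams)

    sire_col = (
        [None] * (cfg.n_founder_males + cfg.n_founder_females)
        + [fm[i] for i in gen1_sire]
        + [mgs[i] for i in dam_sire]
    )
    dam_col = (
        [None] * (cfg.n_founder_males + cfg.n_founder_females)
        + [ff[i] for i in gen1_dam]
        + [ff[i] for i in dam_dam]
    )
    ped = build_pedigree(animal, ["0" if s is None else s for s in sire_col],
                         ["0" if d is None else d for d in dam_col])

    n = len(ped)
    u = np.zeros((n, 2))
    founder_draws = _mvn_pairs(rng, cfg.g0, n)
    mend_draws = _mvn_pairs(rng, 0.5 * cfg.g0, n)
    for i in range(n):  # pedigree order: parents precede offspring
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            u[i] = founder_draws[i]
        else:
            pa = 0.5 * (u[s] if s >= 0 else 0.0) + 0.5 * (u[d] if d >= 0 else 0.0)
            u[i] = pa + mend_draws[i]
    return ped, TruthSet(
        u=u,
        service_sires=np.array(sires, dtype=object),
        mgs_bulls=np.array(mgs, dtype=object),
        dams=np.array(dams, dtype=object),
        genotyped=np.array(fm + sires + mgs, dtype=object),
    )


def simulate_genotypes(
    ped: PedigreeTable, n_snp: int, seed: int, founder_freq=None
) -> GenotypeMatrix:
    """Gene-drop biallelic genotypes through the pedigree.

    Founder allele frequencies are Uniform(0.05, 0.95) unless supplied;
    each non-founder gamete picks one parental allele per locus at random,
    and a gamete from an unknown parent is drawn at the founder frequency.
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    p = (
        np.full(n_snp, float(founder_freq))
        if np.isscalar(founder_freq)
        else np.asarray(founder_freq, float)
        if founder_freq is not None
        else rng.uniform(0.05, 0.95, size=n_snp)
    )
    hap = np.zeros((n, n_snp, 2), dtype=np.int8)
    for i in range(n):
        for slot, parent in enumerate((ped.sire[i], ped.dam[i])):
            if parent < 0:
                hap[i, :, slot] = rng.random(n_snp) < p
            else:
                pick = rng.integers(0, 2, size=n_snp)
                hap[i, :, slot] = hap[parent, np.arange(n_snp), pick]
    dosages = hap.sum(axis=2).astype(float)
    return GenotypeMatrix(ids=ped.ids.copy(), dosages=dosages, frequencies=None)


def simulate_records(
    ped: PedigreeTable, truth: TruthSet, cfg: SimConfig, seed: int,
    n_records: int | None = None,
) -> RecordTable:
    """Ordinal calving records under the sire-dam truth model.

    Each record pairs a dam (cycled so every dam is used) with a service
    sire (each sire receives ``records_per_sire`` matings, shuffled across
    dams and herds); its liability is

        lambda = mu0 + ys + breed.parity + breed.sex + hys + u_s(sire)
                 + u_m(dam) + e,   e ~ N(0, 1)

    and the score is 1 plus the number of cutpoints below lambda.  Herds
    belong to one breed; a dam's records stay in her herd.  Fixed-effect
    level values are Uniform(+/- ``fixed_effect_size``), centred.
    """
    rng = np.random.default_rng(seed)
    n_rec = cfg.n_records if n_records is None else int(n_records)
    t = cfg.thresholds
    mu0 = calibrated_intercept(cfg)

    n_sires = len(truth.service_sires)
    sire_idx = rng.permutation(np.arange(n_rec) % n_sires)
    dam_idx = rng.permutation(np.arange(n_rec) % len(truth.dams))

    dam_herd = rng.integers(0, cfg.n_herds, size=len(truth.dams))
    herd_breed = rng.integers(0, cfg.n_breeds, size=cfg.n_herds)
    ys_code = rng.integers(0, cfg.n_year_seasons, size=n_rec)
    parity = rng.integers(1, cfg.n_parities + 1, size=n_rec)
    sex = rng.integers(1, cfg.n_sexes + 1, size=n_rec)
    herd = dam_herd[dam_idx]
    breed = herd_breed[herd]

    def centred_effects(n_levels):
        e = rng.uniform(-cfg.fixed_effect_size, cfg.fixed_effect_size, size=n_levels)
        return e - e.mean()

    ys_eff = centred_effects(cfg.n_year_seasons)
    bp_eff = centred_effects(cfg.n_breeds * cfg.n_parities)
    bx_eff = centred_effects(cfg.n_breeds * cfg.n_sexes)

    hys_key = herd * cfg.n_year_seasons + ys_code
    uniq_hys, hys_codes = np.unique(hys_key, return_inverse=True)
    hys_eff = rng.normal(0.0, np.sqrt(cfg.sigma2_hys), size=uniq_hys.size)

    sire_ids = truth.service_sires[sire_idx]
    dam_ids = truth.dams[dam_idx]
    u_s = truth.u[ped.index_of(list(sire_ids)), 0]
    u_m = truth.u[ped.index_of(list(dam_ids)), 1]

    lam = (
        mu0
        + ys_eff[ys_code]
        + bp_eff[breed * cfg.n_parities + (parity - 1)]
        + bx_eff[breed * cfg.n_sexes + (sex - 1)]
        + hys_eff[hys_codes]
        + u_s
        + u_m
        + rng.standard_normal(n_rec)
    )
    score = 1 + (lam[:, None] > t.cuts[None, :]).sum(axis=1)

    dam_ped_idx = ped.index_of(list(dam_ids))
    mgs_idx = ped.sire[dam_ped_idx]
    mgs_ids = np.where(mgs_idx >= 0, ped.ids[np.maximum(mgs_idx, 0)], "0")

    df = pd.DataFrame(
        {
            "sire": sire_ids,
            "dam": dam_ids,
            "mgs": mgs_ids,
            "hys": [f"H{h:03d}Y{y}" for h, y in zip(herd, ys_code)],
            "ys": [f"Y{y}" for y in ys_code],
            "breed": [f"B{b}" for b in breed],
            "parity": parity,
            "sex": sex,
            "score": score,
        }
    )
    truth.hys_effects = dict(zip([f"H{k // cfg.n_year_seasons:03d}Y{k % cfg.n_year_seasons}"
                                  for k in uniq_hys], hys_eff))
    truth.liabilities = lam
    return RecordTable(df)


@dataclass
class Scenario:
    """One simulated evaluation data set plus its truth."""

    cfg: SimConfig
    seed: int
    records: RecordTable
    ped: PedigreeTable
    genos: GenotypeMatrix
    truth: TruthSet

    def write(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        self.records.write(os.path.join(outdir, "records.csv"))
        self.ped.write(os.path.join(outdir, "pedigree.csv"))
        self.genos.write(os.path.join(outdir, "genotypes.txt"))


def default_comparison_scenario(
    seed: int, cfg: SimConfig | None = None, with_genotypes: bool = True
) -> Scenario:
    """The standard solver/model comparison instance.

    Defaults: 300 service sires with 150 records each (45,000 records),
    200 maternal grandsires, 20,000 dams, and 1,000 SNP genotypes on the
    1,500 males of the founder and proven-bull layers.  Deterministic under
    ``seed``.
    """
    cfg = cfg or SimConfig()
    ped, truth = simulate_pedigree(cfg, seed)
    records = simulate_records(ped, truth, cfg, seed + 1)
    if with_genotypes and cfg.n_snp > 0:
        full = simulate_genotypes(ped, cfg.n_snp, seed + 2)
        idx = ped.index_of(list(truth.genotyped))
        genos = GenotypeMatrix(
            ids=truth.genotyped.copy(), dosages=full.dosages[idx], frequencies=None
        )
    else:
        genos = GenotypeMatrix(
            ids=np.array([], dtype=object),
            dosages=np.zeros((0, 0)),
            frequencies=np.zeros(0),
        )
    return Scenario(cfg=cfg, seed=seed, records=records, ped=ped, genos=genos, truth=truth)
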