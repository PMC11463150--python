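"""Generator contracts: determinism, HWE structure, moment recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dopascore.genotype import DEFAULT_LOCI, count_genotypes, allele_frequency, hwe_chi_square, parse_genotype
from dopascore.simulate import (
    ConfigError,
    GeneratorConfig,
    _draw_genotype_classes,
    gen_food_addiction,
    gen_genotypes,
    gen_phenotypes,
    generate_cohort,
)

OBESE_ONLY = {"normal": 0.0, "overweight": 0.0, "obese": 1.0}


def csv_bytes(df: pd.DataFrame) -> bytes:
    return df.to_csv(index=False).encode()


class TestConfig:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigError, match="empty cohort"):
            GeneratorConfig(seed=1, n_subjects=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"allele_freq_low": {"rs1800497": 1.2, "rs1799732": 0.5, "rs6277": 0.5, "rs4680": 0.5}},
            {"stratum_proportions": {"normal": 0.9, "overweight": 0.5, "obese": 0.5}},
            {"missing_rate": 1.0},
            {"fa_prevalence": {"normal": {"high": 2.0, "low": 0.1},
                               "overweight": {"high": 0.1, "low": 0.1},
                               "obese": {"high": 0.1, "low": 0.1}}},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=1, **kwargs)

    def test_from_dict_deep_merges_defaults(self):
        cfg = GeneratorConfig.from_dict(
            {"seed": 5, "fa_prevalence": {"obese": {"low": 0.6}}}
        )
        assert cfg.fa_prevalence["obese"]["low"] == 0.6
        assert cfg.fa_prevalence["obese"]["high"] == 0.23   # default retained
        with pytest.raises(ConfigError):
            GeneratorConfig.from_dict({"seed": 1, "bogus_option": 3})


class TestGenotypes:
    def test_fixed_allele(self):
        cfg = GeneratorConfig(
            seed=1, n_subjects=50,
            allele_freq_low={"rs1800497": 1.0, "rs1799732": 0.5,
                             "rs6277": 0.5, "rs4680": 0.5},
        )
        table = gen_genotypes(cfg, inject_missing=False)
        assert (table["rs1800497"] == "A1/A1").all()

    def test_hwe_proportions_at_large_n(self):
        cfg = GeneratorConfig(seed=2, n_subjects=100_000)
        table = gen_genotypes(cfg, inject_missing=False)
        p = 364 / 424
        frac_ins_ins = (table["rs1799732"] == "Ins/Ins").mean()
        assert frac_ins_ins == pytest.approx(p * p, abs=0.01)
        # allele-frequency recovery within ±0.02 at n = 10,000 (subsample)
        for rsid, target in cfg.allele_freq_low.items():
            locus = DEFAULT_LOCI[rsid]
            calls = [parse_genotype(g, locus) for g in table[rsid][:10_000]]
            assert allele_frequency(count_genotypes(calls, locus)) == pytest.approx(
                target, abs=0.02
            )

    def test_missing_injection_rate(self):
        cfg = GeneratorConfig(seed=3, n_subjects=20_000)
        table = gen_genotypes(cfg)
        frac = (table[list(cfg.allele_freq_low)] == "NA").any(axis=1).mean()
        assert frac == pytest.approx(17 / 221, abs=0.01)

    def test_generated_counts_pass_hwe(self):
        """Replicate cohorts pass the HWE test at alpha = 0.01 nearly always."""
        from dopascore.genotype import LocusCountTable

        cfg = GeneratorConfig(seed=4, n_subjects=1000)
        rng = np.random.default_rng(cfg.seed)
        passes = trials = 0
        for _ in range(300):
            dosages = _draw_genotype_classes(cfg, rng)
            for rsid, dose in dosages.items():
                c = np.bincount(dose, minlength=3)
                res = hwe_chi_square(
                    LocusCountTable(rsid, int(c[2]), int(c[1]), int(c[0]))
                )
                trials += 1
                passes += res.p_value > 0.01
        assert passes / trials >= 0.97

    def test_ld_coefficient_induces_haplotype_association(self):
        cfg = GeneratorConfig(seed=5, n_subjects=50_000, ld_rs1800497_rs6277=0.05)
        rng = np.random.default_rng(cfg.seed)
        dosages = _draw_genotype_classes(cfg, rng)
        r = stats.pearsonr(dosages["rs1800497"], dosages["rs6277"]).statistic
        assert r > 0.05
        with pytest.raises(ConfigError):
            GeneratorConfig(seed=5, ld_rs1800497_rs6277=0.5)


class TestPhenotypes:
    @pytest.fixture(scope="class")
    @staticmethod
    def big_obese_cohort():
        cfg = GeneratorConfig(seed=6, n_subjects=20_000, stratum_proportions=OBESE_ONLY)
        return cfg, generate_cohort(cfg)

    def test_group_conditional_ee_mean(self, big_obese_cohort):
        cfg, cohort = big_obese_cohort
        merged = cohort.truth.merge(cohort.phenotypes, on="subject_id")
        low = merged[merged["group"] == "low"]
        assert low["ee"].mean() == pytest.approx(2.9, abs=0.03)
        high = merged[merged["group"] == "high"]
        assert high["ee"].mean() == pytest.approx(2.5, abs=0.03)

    def test_moment_recovery(self, big_obese_cohort):
        cfg, cohort = big_obese_cohort
        merged = cohort.truth.merge(cohort.phenotypes, on="subject_id")
        for grp in ("high", "low"):
            sub = merged[merged["group"] == grp]
            for var in ("cr", "ue", "energy_kcal", "body_fat_pct", "trans_g"):
                mean, sd = cfg.phenotype_moments["obese"][grp][var]
                tol = 5 * sd / np.sqrt(len(sub))
                assert sub[var].mean() == pytest.approx(mean, abs=max(tol, 1e-3)), var

    def test_rank_correlation_calibrated(self, big_obese_cohort):
        cfg, cohort = big_obese_cohort
        merged = cohort.truth.merge(cohort.phenotypes, on="subject_id")
        r = stats.spearmanr(merged["mlgs_total"], merged["ee"]).statistic
        assert r == pytest.approx(0.21, abs=0.01)

    def test_zero_correlation_target(self):
        cfg = GeneratorConfig(
            seed=7, n_subjects=8000, stratum_proportions=OBESE_ONLY,
            ee_target_correlation={"obese": 0.0},
            phenotype_moments=_equal_ee_moments(),
        )
        cohort = generate_cohort(cfg)
        merged = cohort.truth.merge(cohort.phenotypes, on="subject_id")
        r = stats.spearmanr(merged["mlgs_total"], merged["ee"]).statistic
        assert abs(r) < 3 / np.sqrt(len(merged)) + 0.01

    def test_weight_class_consistent_with_stratum(self, big_obese_cohort):
        _, cohort = big_obese_cohort
        bmi = cohort.phenotypes["weight_kg"] / cohort.phenotypes["height_m"] ** 2
        assert (bmi >= 30.0).all()

    def test_fa_prevalence_recovery(self, big_obese_cohort):
        cfg, cohort = big_obese_cohort
        merged = cohort.truth.merge(cohort.phenotypes, on="subject_id")
        for grp, target in (("low", 0.53), ("high", 0.23)):
            sub = merged[merged["group"] == grp]
            tol = 4 * np.sqrt(target * (1 - target) / len(sub))
            assert sub["fa_diagnosis"].mean() == pytest.approx(target, abs=tol)

    def test_fa_consistent_with_diagnosis_rule(self, big_obese_cohort):
        _, cohort = big_obese_cohort
        ph = cohort.phenotypes
        rule = (ph["fa_symptoms"] >= 3) & (ph["fa_distress"] > 0)
        assert (rule == (ph["fa_diagnosis"] > 0)).all()

    def test_fa_extreme_prevalences(self):
        base = {"normal": {"high": 0.0, "low": 0.0},
                "overweight": {"high": 0.0, "low": 0.0},
                "obese": {"high": 0.0, "low": 0.0}}
        cfg = GeneratorConfig(seed=8, n_subjects=500, fa_prevalence=base)
        cohort = generate_cohort(cfg)
        ph = cohort.phenotypes
        assert (ph["fa_diagnosis"] == 0).all()
        assert not ((ph["fa_symptoms"] >= 3) & (ph["fa_distress"] > 0)).any()
        full = {s: {"high": 1.0, "low": 1.0} for s in base}
        cohort = generate_cohort(GeneratorConfig(seed=8, n_subjects=500, fa_prevalence=full))
        assert (cohort.phenotypes["fa_diagnosis"] == 1).all()


def _equal_ee_moments():
    import json
    from dopascore.simulate import DEFAULT_PHENOTYPE_MOMENTS

    moments = json.loads(json.dumps(DEFAULT_PHENOTYPE_MOMENTS))
    moments["obese"]["high"]["ee"] = [2.7, 0.7]
    moments["obese"]["low"]["ee"] = [2.7, 0.7]
    return moments


class TestDeterminism:
    def test_same_seed_identical_bytes(self):
        a = generate_cohort(GeneratorConfig(seed=9, n_subjects=400))
        b = generate_cohort(GeneratorConfig(seed=9, n_subjects=400))
        assert csv_bytes(a.genotypes) == csv_bytes(b.genotypes)
        assert csv_bytes(a.phenotypes) == csv_bytes(b.phenotypes)

    def test_different_seeds_differ_same_schema(self):
        a = generate_cohort(GeneratorConfig(seed=10, n_subjects=300))
        b = generate_cohort(GeneratorConfig(seed=11, n_subjects=300))
        assert csv_bytes(a.genotypes) != csv_bytes(b.genotypes)
        assert list(a.phenotypes.columns) == list(b.phenotypes.columns)

    def test_write_roundtrip(self, tmp_path):
        cohort = generate_cohort(GeneratorConfig(seed=12, n_subjects=100))
        paths = cohort.write(tmp_path)
        geno = pd.read_csv(paths["genotypes"], dtype=str, keep_default_na=False)
        assert len(geno) == 100
        assert list(geno.columns) == list(cohort.genotypes.columns)
        assert paths["provenance"].exists()


class TestStandaloneStages:
    def test_gen_phenotypes_from_table_with_missing(self):
        cfg = GeneratorConfig(seed=13, n_subjects=200)
        table = gen_genotypes(cfg)
        pheno = gen_phenotypes(cfg, table)
        assert len(pheno) == 200
        assert set(pheno["_group"].unique()) <= {"low", "high"}
        fa = gen_food_addiction(cfg, pheno)
        assert set(fa.columns) == {"fa_symptoms", "fa_distress", "fa_diagnosis"}
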