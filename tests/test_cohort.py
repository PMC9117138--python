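import numpy as np
import pandas as pd
import pytest

from hypermut.agemodel import build_design, fit_nb_identity
from hypermut.cohort import (AgeDistribution, InformativeSite,
                             SimulationConfig, inject_hypermutators,
                             inject_lota_artifact, read_cohort,
                             simulate_cohort, simulate_counts,
                             simulate_phasing_reads, write_cohort)


def fixed_age_config(**kw):
    """Ages pinned to 30/30 (degenerate distribution)."""
    ages = AgeDistribution(mother_mean=30.0, mother_sd=0.0,
                           father_offset=0.0, father_noise_sd=0.0)
    return SimulationConfig(age_distribution=ages, **kw)


def test_empty_cohort():
    co = simulate_cohort(SimulationConfig(n_trios=0))
    assert co.n_trios == 0 and len(co.dnms) == 0


def test_generative_mean_matches_closed_form():
    """At fixed ages 30/30 the NB mean is beta0 + 30*(b_pat + b_mat) = 68.9."""
    cfg = fixed_age_config(n_trios=5000, seed=21)
    tr = simulate_counts(cfg)
    expected = 20 + 1.28 * 30 + 0.35 * 30
    assert expected == pytest.approx(68.9)
    mc_se = tr["n_snv"].std() / np.sqrt(len(tr))
    assert abs(tr["n_snv"].mean() - expected) < 3 * mc_se


def test_poisson_limit_variance_ratio():
    cfg = fixed_age_config(n_trios=5000, seed=22, dispersion=np.inf)
    tr = simulate_counts(cfg)
    ratio = tr["n_snv"].var() / tr["n_snv"].mean()
    # Var/mean ratio concentrates around 1 with MC error ~ sqrt(2/n)
    assert abs(ratio - 1.0) < 4 * np.sqrt(2 / len(tr))


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(beta0=-1).validate()
    with pytest.raises(ValueError):
        SimulationConfig(dispersion=0).validate()
    with pytest.raises(ValueError):
        # paternal fraction exceeds 1 at high paternal ages
        SimulationConfig(paternal_fraction_slope=0.02).validate()
    with pytest.raises(ValueError):
        bad = SimulationConfig()
        bad.signature_mix["baseline"] = {"sig_cpg_deamination": 0.7}
        bad.validate()


def test_seed_reproducibility(tmp_path):
    """Fixed seed fixes every output byte."""
    for sub in ("a", "b"):
        co = simulate_cohort(SimulationConfig(n_trios=40, seed=9))
        write_cohort(co, tmp_path / sub)
    for name in ("dnms.tsv", "pedigree.tsv", "trio_truth.tsv",
                 "dnm_truth.tsv", "config.json"):
        assert (tmp_path / "a" / name).read_bytes() == \
            (tmp_path / "b" / name).read_bytes()


def test_roundtrip(tmp_path):
    co = simulate_cohort(SimulationConfig(n_trios=40, seed=9))
    co = inject_lota_artifact(co, "trio_00001", ("3", 10_000, 80_000), 50)
    write_cohort(co, tmp_path)
    back = read_cohort(tmp_path)
    pd.testing.assert_frame_equal(co.trios, back.trios, check_dtype=False,
                                  check_exact=False)
    pd.testing.assert_frame_equal(co.dnms, back.dnms, check_dtype=False,
                                  check_exact=False)
    # truth table covers every simulated DNM
    assert len(back.dnms) == co.trios["n_snv"].sum() + \
        co.trios["n_indel"].sum()


def test_parameter_recovery_via_age_model(big_counts):
    """Regressing simulated counts on ages recovers the generative betas."""
    X = build_design(big_counts, ["father_age", "mother_age"])
    fit = fit_nb_identity(big_counts["n_snv"].to_numpy(), X)
    for truth, est, se in zip((20.0, 1.28, 0.35), fit.params, fit.se):
        assert abs(est - truth) < 3 * se


def test_paternal_fraction_matches_configuration(big_counts):
    cfg = SimulationConfig()
    expect = cfg.paternal_fraction(big_counts["father_age"]).mean()
    n = big_counts["n_snv"].sum()
    frac = big_counts["n_paternal"].sum() / n
    assert abs(frac - expect) < 3 * np.sqrt(expect * (1 - expect) / n)


class TestInjections:
    def test_fold_one_is_identity(self):
        co = simulate_cohort(SimulationConfig(n_trios=20, seed=5))
        before = co.trios["n_snv"].sum()
        co = inject_hypermutators(
            co, [("trio_00002", "repair_defect", 1.0, "sig_repair_tc")])
        assert co.trios["n_snv"].sum() == before

    def test_repair_defect_fold_multiplies_paternal(self):
        """Fold 4 on paternal 50 / maternal 15 gives ~ 4*50 + 15 = 215."""
        totals = []
        for seed in range(12):
            # expectation pinned via the intercept: 65 SNVs, 50 paternal
            cfg = fixed_age_config(n_trios=30, seed=100 + seed, beta0=65.0,
                                   beta_pat=0.0, beta_mat=0.0,
                                   paternal_fraction_base=50 / 65,
                                   paternal_fraction_slope=0.0)
            co = simulate_cohort(cfg)
            co = inject_hypermutators(
                co, [("trio_00000", "repair_defect", 4.0, "sig_repair_tc")])
            totals.append(
                int(co.trios.set_index("trio_id").loc["trio_00000", "n_snv"]))
        mean = np.mean(totals)
        se = np.std(totals) / np.sqrt(len(totals))
        assert abs(mean - 215) < max(3 * se, 10)

    def test_postzygotic_vaf_below_04(self):
        co = simulate_cohort(SimulationConfig(n_trios=20, seed=6))
        co = inject_hypermutators(
            co, [("trio_00004", "postzygotic", 150, "sig_cpg_deamination")])
        inj = co.dnms[co.dnms["etiology"] == "postzygotic"]
        assert len(inj) == 150
        assert inj["true_vaf"].mean() < 0.4
        assert abs(
            (inj["true_parent"] == "father").mean() - 0.5) < 0.15

    def test_unknown_signature_rejected(self):
        co = simulate_cohort(SimulationConfig(n_trios=5, seed=6))
        with pytest.raises(ValueError, match="signature"):
            inject_hypermutators(
                co, [("trio_00000", "chemo_signature", 10, "sig_nope")])
        with pytest.raises(ValueError, match="etiology"):
            inject_hypermutators(
                co, [("trio_00000", "mystery", 10, "sig_repair_tc")])


class TestLotaInjection:
    def test_injected_calls_confined_to_region(self):
        co = simulate_cohort(SimulationConfig(n_trios=10, seed=8))
        co = inject_lota_artifact(co, "trio_00002", ("7", 50_000, 90_000),
                                  300)
        inj = co.dnms[co.dnms["etiology"] == "lota_artifact"]
        assert len(inj) == 300
        assert (inj["chrom"] == "7").all()
        assert inj["pos"].between(50_000, 90_000).all()

    def test_artifact_scale_possible(self):
        """1300 clustered pseudo-calls reach the published artifact scale."""
        co = simulate_cohort(SimulationConfig(n_trios=5, seed=8))
        co = inject_lota_artifact(co, "trio_00001", ("1", 1, 2_000_000),
                                  1300)
        total = co.trios.set_index("trio_id").loc["trio_00001", "n_snv"]
        assert total >= 1300

    def test_zero_calls_noop(self):
        co = simulate_cohort(SimulationConfig(n_trios=5, seed=8))
        before = co.trios["n_snv"].sum()
        co = inject_lota_artifact(co, "trio_00001", ("1", 1, 1000), 0)
        assert co.trios["n_snv"].sum() == before

    def test_unknown_chromosome_rejected(self):
        co = simulate_cohort(SimulationConfig(n_trios=5, seed=8))
        with pytest.raises(ValueError):
            inject_lota_artifact(co, "trio_00001", ("chrZ", 1, 1000), 10)


class TestPhasingReads:
    dnm = {"trio_id": "t", "dnm_id": "d", "chrom": "1", "pos": 5000,
           "ref": "C", "alt": "T"}
    site = InformativeSite(chrom="1", pos=5120, a1="A", a2="G",
                           parent_of={"A": "father", "G": "mother"},
                           distance=120)

    def test_noiseless_reads_carry_true_parent_allele(self):
        reads = simulate_phasing_reads(self.dnm, self.site, 10,
                                       error_rate=0.0, seed=1,
                                       true_parent="father")
        carrying = reads[reads["allele_a"] == "T"]
        assert len(carrying) > 0
        assert (carrying["allele_b"] == "A").all()

    def test_zero_reads_empty(self):
        reads = simulate_phasing_reads(self.dnm, self.site, 0, seed=1)
        assert len(reads) == 0

    def test_out_of_span_unphaseable(self):
        far = InformativeSite(chrom="1", pos=5000 + 700, a1="A", a2="G",
                              parent_of={"A": "father", "G": "mother"},
                              distance=700)
        reads = simulate_phasing_reads(self.dnm, far, 10, seed=1)
        assert len(reads) == 0

    def test_high_error_rate_creates_conflicts(self):
        """At error 0.5 site alleles are random, so DNM-carrying reads
        split between parents roughly half the time."""
        rng = np.random.default_rng(4)
        conflicts = 0
        trials = 200
        for _ in range(trials):
            reads = simulate_phasing_reads(self.dnm, self.site, 8,
                                           error_rate=0.5, rng=rng,
                                           true_parent="father")
            carrying = reads[reads["allele_a"] == "T"]
            votes = set(carrying["allele_b"])
            if {"A", "G"} <= votes:
                conflicts += 1
        # expected conflict prob: 1 - 2 * 0.5^m averaged over m carrying
        # reads; with ~4 carrying reads it is roughly 0.6-0.8
        assert 0.4 < conflicts / trials < 0.95
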