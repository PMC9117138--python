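import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hypermut.cohort import (SimulationConfig, inject_lota_artifact,
                             parental_genotype_bins, simulate_cohort,
                             simulate_counts)
from hypermut.detect import (CohortReference, artifact_screen,
                             characterize_hypermutator, cohort_reference,
                             detect_hypermutators, disease_risk,
                             excess_and_fold, iterative_detection,
                             multiple_testing_threshold)
from hypermut.stats import poisson_two_sided_p


class TestPoissonTwoSided:
    def test_matches_enumeration_oracle(self):
        """p equals the exact minimum-likelihood sum over Poisson(lam)."""
        for k, lam in [(10, 2.0), (0, 3.5), (7, 7.0), (2, 9.0), (40, 12.0)]:
            ks = np.arange(0, 500)
            pmf = sps.poisson.pmf(ks, lam)
            oracle = pmf[pmf <= pmf[k] * (1 + 1e-7)].sum()
            assert poisson_two_sided_p(k, lam) == pytest.approx(
                oracle, rel=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(st.integers(0, 60), st.floats(0.1, 30.0))
    def test_valid_probability(self, k, lam):
        p = poisson_two_sided_p(k, lam)
        assert 0.0 <= p <= 1.0
        # observed outcome always included: p >= pmf(k)
        assert p >= sps.poisson.pmf(k, lam) - 1e-12


class TestDetection:
    def test_bonferroni_denominator_counts_analysed_children(self,
                                                             big_counts):
        reports, _ = detect_hypermutators(big_counts)
        assert reports[0].threshold == pytest.approx(0.05 / 5000)
        excl = set(big_counts["child_id"].head(41))
        reports2, _ = detect_hypermutators(big_counts, exclusions=excl)
        assert reports2[0].threshold == pytest.approx(0.05 / 4959)
        assert len(reports2) == 4959

    def test_injected_fourfold_hypermutator_flagged(self, big_counts):
        tr = big_counts.copy()
        tr.loc[3, "n_snv"] = int(4 * tr.loc[3, "n_paternal"]
                                 + tr.loc[3, "n_maternal"])
        reports, _ = detect_hypermutators(tr)
        flagged = {r.child_id for r in reports if r.flagged}
        assert tr.loc[3, "child_id"] in flagged

    def test_null_cohort_rarely_flags(self):
        """Family-wise false-positive rate respects the Bonferroni bound
        (spot check on 25 null cohorts; the full 200-replicate run is in
        the acceptance suite)."""
        hits = 0
        for seed in range(25):
            tr = simulate_counts(SimulationConfig(n_trios=1000,
                                                  seed=500 + seed))
            reports, _ = detect_hypermutators(tr)
            hits += any(r.flagged for r in reports)
        assert hits <= 3

    def test_detection_monotone_in_fold(self):
        """Flag probability is non-decreasing in the injected fold."""
        folds = (1.0, 2.0, 4.0, 7.0)
        reps = 20
        rates = []
        for fold in folds:
            hits = 0
            for seed in range(reps):
                tr = simulate_counts(SimulationConfig(n_trios=1200,
                                                      seed=700 + seed))
                tr.loc[0, "n_snv"] = int(fold * tr.loc[0, "n_paternal"]
                                         + tr.loc[0, "n_maternal"])
                reports, _ = detect_hypermutators(tr)
                hits += tr.loc[0, "child_id"] in {
                    r.child_id for r in reports if r.flagged}
            rates.append(hits / reps)
        assert all(b >= a - 0.05 for a, b in zip(rates, rates[1:]))
        assert rates[0] < 0.2 and rates[-1] == 1.0

    def test_small_cohort_rejected(self):
        tr = simulate_counts(SimulationConfig(n_trios=3, seed=1))
        with pytest.raises(ValueError):
            detect_hypermutators(tr)


@pytest.fixture(scope="module")
def lota_cohort():
    co = simulate_cohort(SimulationConfig(n_trios=120, seed=77))
    co = inject_lota_artifact(co, "trio_00010", ("4", 200_000, 280_000), 600)
    return co


class TestArtifactScreenAndIteration:
    def test_lota_trio_raises_both_subflags(self, lota_cohort):
        bins = parental_genotype_bins(lota_cohort, ["child_00010"])
        calls = lota_cohort.dnms[lota_cohort.dnms["child_id"]
                                 == "child_00010"]
        res = artifact_screen(calls, bins)
        assert res["clustered"] and res["parental_loh"] and res["artifact"]
        assert res["chrom"] == "4" and res["parent"] == "father"

    def test_uniform_calls_not_flagged(self, lota_cohort):
        bins = parental_genotype_bins(lota_cohort, ["child_00011"])
        calls = lota_cohort.dnms[lota_cohort.dnms["child_id"]
                                 == "child_00011"]
        res = artifact_screen(calls, bins)
        assert not res["clustered"] and not res["artifact"]

    def test_cluster_without_loh_raises_cluster_subflag_only(self):
        co = simulate_cohort(SimulationConfig(n_trios=30, seed=78))
        # clustered calls but the parental bins show no LOH: build bins for
        # a clean trio and pair them with the artifact trio's calls
        co = inject_lota_artifact(co, "trio_00005",
                                  ("2", 100_000, 160_000), 400)
        clean_bins = parental_genotype_bins(co, ["child_00006"])
        calls = co.dnms[co.dnms["child_id"] == "child_00005"]
        res = artifact_screen(calls, clean_bins.assign(child_id="child_00005"))
        assert res["clustered"] and not res["parental_loh"]
        assert not res["artifact"]

    def test_iterative_detection_excludes_artifact_then_refits(self,
                                                               lota_cohort):
        trios = lota_cohort.trios

        def screen(flagged_ids):
            if not flagged_ids:
                return set()
            bins = parental_genotype_bins(lota_cohort, flagged_ids)
            out = set()
            for cid in flagged_ids:
                calls = lota_cohort.dnms[lota_cohort.dnms["child_id"] == cid]
                if artifact_screen(calls,
                                   bins[bins["child_id"] == cid])["artifact"]:
                    out.add(cid)
            return out

        reports, fit, excluded = iterative_detection(trios, screen)
        assert excluded == {"child_00010"}
        assert len(reports) == len(trios) - 1
        assert reports[0].threshold == pytest.approx(0.05 / (len(trios) - 1))


class TestCharacterization:
    def test_average_child_is_unremarkable(self, small_cohort):
        dnms = small_cohort.dnms
        phased = small_cohort.trios[["trio_id", "n_paternal", "n_maternal"]]
        ref = cohort_reference(dnms, phased, n_children=len(small_cohort.trios),
                               n_flagged=12)
        # build a pseudo-child whose counts equal the cohort means
        rng = np.random.default_rng(0)
        child = dnms.sample(int(len(dnms) / len(small_cohort.trios)),
                            random_state=1)
        from hypermut.detect import HypermutationReport
        rep = HypermutationReport(child_id="avg", observed=0, expected=0,
                                  residual=0, p=1, threshold=0, flagged=False)
        n_ph = int(round(ref.paternal_fraction * 20))
        rep = characterize_hypermutator(rep, child, n_ph, 20 - n_ph, ref)
        enr = [v["enrichment"] for v in rep.type_enrichment.values()
               if v["enrichment"] is not None]
        assert all(0.3 < e < 2.5 for e in enr)
        assert rep.phase_bias_p > 0.01
        assert rep.vaf_shift_p > 0.001

    def test_repair_defect_child_enriched_in_tc(self, small_cohort):
        import copy

        co = copy.deepcopy(small_cohort)
        from hypermut.cohort import inject_hypermutators

        co = inject_hypermutators(
            co, [("trio_00003", "repair_defect", 5.0, "sig_repair_tc")])
        dnms = co.dnms
        ref = cohort_reference(dnms, co.trios[["trio_id", "n_paternal",
                                               "n_maternal"]],
                               n_children=len(co.trios), n_flagged=1)
        calls = dnms[dnms["child_id"] == "child_00003"]
        from hypermut.detect import HypermutationReport
        rep = HypermutationReport(child_id="child_00003", observed=0,
                                  expected=0, residual=0, p=0, threshold=0,
                                  flagged=True)
        t = co.trios.set_index("child_id").loc["child_00003"]
        rep = characterize_hypermutator(
            rep, calls, int(t["n_paternal"]), int(t["n_maternal"]), ref)
        tc = rep.type_enrichment["T>C"]
        thr = multiple_testing_threshold(0.05, ref.n_flagged)
        assert tc["enrichment"] > 2.0
        assert tc["p"] < thr
        # paternal excess shows as phase bias against the cohort fraction
        assert rep.phase_bias_p < 0.05

    def test_zero_cohort_mean_reported_undefined(self):
        ref = CohortReference(type_means={t: 0.0 for t in
                                          ("C>A", "C>G", "C>T", "T>A",
                                           "T>C", "T>G", "indel")},
                              paternal_fraction=0.77,
                              vaf_low_proportion=0.05, n_flagged=1)
        from hypermut.detect import HypermutationReport
        rep = HypermutationReport(child_id="x", observed=0, expected=0,
                                  residual=0, p=0, threshold=0, flagged=True)
        calls = pd.DataFrame({"vartype": ["SNV"], "context96": ["A[C>T]A"],
                              "vaf_child": [0.5], "tx_strand": ["NA"]})
        rep = characterize_hypermutator(rep, calls, 1, 0, ref)
        assert rep.type_enrichment["C>T"]["enrichment"] is None
        assert "undefined" in rep.type_enrichment["C>T"]["note"]

    def test_multiple_testing_threshold(self):
        assert multiple_testing_threshold(0.05, 12) == pytest.approx(
            0.05 / 84)


class TestExcessFoldRisk:
    @pytest.mark.parametrize("observed,median,excess,fold", [
        (425, 65, 360, 6.5),
        (110, 65, 45, 1.7),
        (65, 65, 0, 1.0),
    ])
    def test_excess_and_fold(self, observed, median, excess, fold):
        e, f = excess_and_fold(observed, median)
        assert (e, f) == (excess, fold)
        assert e + median == observed  # integer conservation

    def test_disease_risk(self):
        assert disease_risk(4.0) == pytest.approx(4 / 300)
        assert disease_risk(4.0) > 0.01  # "just over 1%"
        assert disease_risk(1.0) == pytest.approx(1 / 300)
        assert disease_risk(0.0) == 0.0
        with pytest.raises(ValueError):
            disease_risk(-1.0)
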