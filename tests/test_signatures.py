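import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypermut.catalogue import (read_catalogue, synthetic_catalogue,
                                write_catalogue)
from hypermut.channels import CHANNELS
from hypermut.signatures import (build_spectrum, collapse_to_classes,
                                 compare_phased_spectra, cosine_similarity,
                                 extract_signatures_nmf, fit_exposures_nnls,
                                 match_signatures, nmf_multiplicative,
                                 sample_spectrum)


class TestSpectrum:
    def test_single_purine_mutation_folded_and_conserved(self):
        calls = pd.DataFrame([{"ref": "T", "alt": "C", "context96": "A[T>C]G"}])
        spec, excluded = build_spectrum(calls)
        assert spec.sum() == 1 and excluded == 0
        assert spec["A[T>C]G"] == 1
        # purine-reference input is reverse-complemented
        calls2 = pd.DataFrame([{"ref": "A", "alt": "G", "context": "CAT"}])
        spec2, _ = build_spectrum(calls2)
        assert spec2.sum() == 1
        assert spec2["A[T>C]G"] == 1  # revcomp(CAT)=ATG, T>C

    def test_empty_input(self):
        spec, excluded = build_spectrum(pd.DataFrame())
        assert spec.sum() == 0 and excluded == 0

    def test_ambiguous_context_excluded_with_tally(self):
        calls = pd.DataFrame([
            {"ref": "C", "alt": "T", "context": "NCA"},
            {"ref": "C", "alt": "T", "context": "ACA"}])
        spec, excluded = build_spectrum(calls)
        assert spec.sum() == 1 and excluded == 1

    def test_cohort_spectrum_conserves_counts(self, small_cohort):
        snv = small_cohort.dnms[small_cohort.dnms["vartype"] == "SNV"]
        spec, excluded = build_spectrum(snv)
        assert spec.sum() + excluded == len(snv)
        assert excluded == 0

    def test_pure_signature_sample_matches_source(self, catalogue):
        rng = np.random.default_rng(3)
        spec = sample_spectrum(catalogue["sig_platinum_like"], 10_000, rng)
        cos = cosine_similarity(spec, catalogue["sig_platinum_like"])
        assert cos >= 0.99

    def test_collapse_to_classes(self, catalogue):
        spec = 96 * catalogue["sig_cpg_deamination"]
        six = collapse_to_classes(spec)
        assert six.sum() == pytest.approx(96.0)
        assert six.idxmax() == "C>T"


class TestNnls:
    def test_exact_catalogue_member(self, catalogue):
        spec = 100.0 * catalogue["sig_clocklike_flat"]
        fit = fit_exposures_nnls(spec, catalogue)
        assert fit.exposures["sig_clocklike_flat"] == pytest.approx(100.0)
        assert fit.residual_norm < 1e-9
        others = fit.exposures.drop("sig_clocklike_flat")
        assert (others.abs() < 1e-9).all()

    def test_mixture_recovery(self, catalogue):
        rng = np.random.default_rng(8)
        mix = (0.7 * catalogue["sig_clocklike_flat"]
               + 0.3 * catalogue["sig_platinum_like"])
        spec = sample_spectrum(mix, 5000, rng)
        # sparsity pruning keeps collinear broad signatures from absorbing
        # mixture mass, which is how refitting is meant to be run
        fit = fit_exposures_nnls(spec, catalogue, prune_threshold=0.05)
        assert fit.proportions["sig_clocklike_flat"] == pytest.approx(
            0.7, abs=0.05)
        assert fit.proportions["sig_platinum_like"] == pytest.approx(
            0.3, abs=0.05)

    def test_cone_membership_zero_residual(self, catalogue):
        rng = np.random.default_rng(9)
        w = rng.uniform(10, 100, catalogue.shape[1])
        spec = pd.Series(catalogue.to_numpy() @ w, index=catalogue.index)
        fit = fit_exposures_nnls(spec, catalogue)
        assert fit.residual_norm < 1e-9

    def test_orthogonal_spectrum_reports_large_residual(self, catalogue):
        # mass on the channel the catalogue touches least
        weakest = catalogue.sum(axis=1).idxmin()
        spec = pd.Series(0.0, index=catalogue.index)
        spec[weakest] = 100.0
        fit = fit_exposures_nnls(spec, catalogue)
        assert fit.relative_residual > 0.5

    def test_pruning_refits(self, catalogue):
        rng = np.random.default_rng(10)
        spec = sample_spectrum(catalogue["sig_clocklike_flat"], 3000, rng)
        fit = fit_exposures_nnls(spec, catalogue, prune_threshold=0.05)
        kept = fit.proportions[fit.proportions > 0]
        assert (kept >= 0.05).all()

    def test_empty_spectrum_rejected(self, catalogue):
        with pytest.raises(ValueError):
            fit_exposures_nnls(pd.Series(0.0, index=catalogue.index),
                               catalogue)


class TestCosine:
    def test_identical_and_disjoint(self):
        a = np.array([1.0, 2.0, 0.0])
        b = np.array([0.0, 0.0, 3.0])
        assert cosine_similarity(a, a) == pytest.approx(1.0)
        assert cosine_similarity(a, b) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            cosine_similarity(a, np.zeros(3))

    @settings(derandomize=True, max_examples=40)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.random(96) + 1e-9, rng.random(96) + 1e-9
        direct = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
        assert abs(cosine_similarity(a, b) - direct) < 1e-12


class TestNmf:
    def planted(self, catalogue, rng, n_samples=24):
        names = ["sig_cpg_deamination", "sig_platinum_like",
                 "sig_alkylating_like"]
        S = catalogue[names].to_numpy().T
        W = rng.dirichlet([1.0] * 3, n_samples) * \
            rng.uniform(500, 2000, n_samples)[:, None]
        V = rng.poisson(W @ S)
        return pd.DataFrame(V, columns=CHANNELS), S

    def test_planted_signatures_recovered(self, catalogue):
        rng = np.random.default_rng(12)
        spectra, S = self.planted(catalogue, rng)
        result = extract_signatures_nmf(spectra, [3], restarts=20, seed=5)
        sol = result.best(3)
        _, cos = match_signatures(S, sol.signatures.to_numpy())
        assert (cos >= 0.95).all()
        assert sol.relative_error < 0.2
        assert (np.abs(sol.signatures.sum(axis=1) - 1.0) < 1e-9).all()

    def test_identical_samples_rank_one(self, catalogue):
        profile = catalogue["sig_clocklike_flat"].to_numpy()
        V = pd.DataFrame(np.tile(1000 * profile, (6, 1)), columns=CHANNELS)
        sol = extract_signatures_nmf(V, [1], restarts=5, seed=1).best(1)
        assert sol.relative_error < 1e-4
        assert cosine_similarity(sol.signatures.iloc[0], profile) > 0.9999

    def test_seeded_determinism(self, catalogue):
        rng = np.random.default_rng(13)
        spectra, _ = self.planted(catalogue, rng, n_samples=10)
        a = extract_signatures_nmf(spectra, [2], restarts=6, seed=3).best(2)
        b = extract_signatures_nmf(spectra, [2], restarts=6, seed=3).best(2)
        assert np.array_equal(a.signatures.to_numpy(),
                              b.signatures.to_numpy())

    def test_agrees_with_independent_nmf(self, catalogue):
        """Reconstruction quality and factors agree with an independent
        multiplicative-update implementation (scikit-learn)."""
        from sklearn.decomposition import NMF

        rng = np.random.default_rng(21)
        spectra, _ = self.planted(catalogue, rng, n_samples=12)
        sol = extract_signatures_nmf(spectra, [3], restarts=10,
                                     seed=2).best(3)
        sk = NMF(n_components=3, init="random", random_state=0,
                 solver="mu", max_iter=3000, tol=1e-9)
        Wsk = sk.fit_transform(spectra.to_numpy())
        err_sk = np.linalg.norm(spectra.to_numpy()
                                - Wsk @ sk.components_)
        assert np.sqrt(sol.objective) <= err_sk * 1.05
        Hsk = sk.components_ / sk.components_.sum(axis=1, keepdims=True)
        _, cos = match_signatures(sol.signatures.to_numpy(), Hsk)
        assert (cos >= 0.95).all()

    def test_k_exceeding_samples_rejected(self, catalogue):
        rng = np.random.default_rng(14)
        V = pd.DataFrame(rng.poisson(10.0, (3, 96)), columns=CHANNELS)
        with pytest.raises(ValueError):
            nmf_multiplicative(V.to_numpy(), 4, rng)


class TestComparePhasedSpectra:
    def test_identical_spectra_all_p_one(self, catalogue):
        spec = (1000 * catalogue["sig_clocklike_flat"]).round()
        out = compare_phased_spectra(spec, spec)
        assert (out["p"] > 0.99).all()

    def test_published_ct_difference_detected(self, catalogue):
        """A 0.27 vs 0.22 C>T excess at n=50k per side is flagged at the
        Bonferroni level over the six classes."""
        rng = np.random.default_rng(15)
        base = collapse_to_classes(catalogue["sig_clocklike_flat"])

        def spectrum(ct_prop, n):
            p = base.copy()
            p = p * (1 - ct_prop) / (p.sum() - p["C>T"])
            p["C>T"] = ct_prop
            draw = rng.multinomial(n, p.to_numpy())
            out = pd.Series(0.0, index=pd.Index(CHANNELS))
            for cls, k in zip(p.index, draw):
                out[f"A[{cls}]A"] = k
            return out

        hits = 0
        reps = 10
        for _ in range(reps):
            pat = spectrum(0.22, 50_000)
            mat = spectrum(0.27, 50_000)
            res = compare_phased_spectra(pat, mat)
            hits += res.loc["C>T", "p"] < 0.05 / 6
        assert hits >= int(0.95 * reps)

    def test_empty_class_on_both_sides(self):
        pat = pd.Series(0.0, index=pd.Index(CHANNELS))
        mat = pat.copy()
        pat["A[C>T]A"] = 100
        mat["A[C>T]A"] = 100
        out = compare_phased_spectra(pat, mat)
        assert out.loc["T>G", "p"] == pytest.approx(1.0)

    def test_empty_spectrum_rejected(self):
        zero = pd.Series(0.0, index=pd.Index(CHANNELS))
        with pytest.raises(ValueError):
            compare_phased_spectra(zero, zero)


def test_catalogue_roundtrip(tmp_path, catalogue):
    path = tmp_path / "catalogue.tsv"
    write_catalogue(catalogue, path)
    back = read_catalogue(path)
    assert list(back.columns) == list(catalogue.columns)
    assert np.allclose(back.to_numpy(), catalogue.to_numpy())
    assert np.allclose(back.sum(axis=0), 1.0)
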