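import warnings

import numpy as np
import pandas as pd
import pytest
import scipy.optimize

import cytomix as cm


@pytest.fixture(scope="module")
def true_signature(truth, signature):
    """The truth profiles restricted to the learned signature's gene set."""
    gene_pos = {g: i for i, g in enumerate(truth.gene_ids)}
    rows = [gene_pos[g] for g in signature.gene_ids]
    return cm.SignatureMatrix(truth.profiles[rows], signature.gene_ids,
                              truth.subpop_ids)


class TestArtificialMixtures:
    def test_fraction_rows_sum_to_one(self, cpm, true_labels):
        _, fr = cm.make_artificial_mixtures(cpm, true_labels, n_mixtures=10, seed=0)
        assert np.allclose(fr.sum(axis=1), 1.0, atol=1e-9)

    def test_one_hot_equals_sampled_mean_profile(self, cpm, true_labels):
        k = true_labels.nunique()
        F = np.zeros((1, k))
        F[0, 0] = 1.0
        mix, fr = cm.make_artificial_mixtures(cpm, true_labels, fractions=F,
                                              cells_per_mixture=2000, seed=3)
        sp = sorted(true_labels.unique(), key=str)[0]
        prof = cpm.counts[:, (true_labels == sp).to_numpy()].mean(axis=1)
        r = np.corrcoef(mix.values[:, 0], prof)[0, 1]
        assert r > 0.99

    def test_expectation_is_fraction_weighted_profile(self, cpm, true_labels):
        rng = np.random.default_rng(2)
        F = rng.dirichlet(np.ones(true_labels.nunique()), 5)
        mix, fr = cm.make_artificial_mixtures(cpm, true_labels, fractions=F,
                                              cells_per_mixture=1000, seed=4)
        subpops = sorted(true_labels.unique(), key=str)
        profiles = np.stack([
            cpm.counts[:, (true_labels == sp).to_numpy()].mean(axis=1)
            for sp in subpops], axis=1)
        expected = profiles @ F.T
        expected = expected * (1e6 / expected.sum(axis=0))
        rel = np.abs(mix.values - expected).sum(0) / expected.sum(0)
        assert rel.max() < 0.05

    def test_rank_deficiency_warning(self, cpm, true_labels):
        with pytest.warns(UserWarning, match="rank-deficient"):
            cm.make_artificial_mixtures(cpm, true_labels, n_mixtures=2, seed=0)


class TestSmodeAdjust:
    def test_no_shift_recovers_signature(self, truth, cpm, true_labels, signature):
        """With no platform shift and no noise the adjusted signature equals
        the original on shared genes (relative Frobenius < 0.05)."""
        rng = np.random.default_rng(5)
        F = rng.dirichlet(np.ones(truth.n_subpops), 20)
        bulk, _ = cm.mix_bulk(truth, F, noise_sd=0.0, apply_platform_shift=False, seed=6)
        # bulk mixes raw profiles; rescale to the signature's CPM convention
        bulk = cm.cpm_normalize(bulk)
        mix, fr = cm.make_artificial_mixtures(cpm, true_labels, n_mixtures=60,
                                              cells_per_mixture=1000, seed=7)
        adj = cm.smode_adjust(signature, mix, fr, bulk)
        pos = {g: i for i, g in enumerate(signature.gene_ids)}
        orig = signature.values[[pos[g] for g in adj.gene_ids]]
        # compare shapes: scale each matrix to unit Frobenius norm
        a = adj.values / np.linalg.norm(adj.values)
        o = orig / np.linalg.norm(orig)
        assert np.linalg.norm(a - o) < 0.05

    def test_known_shift_recovered(self, truth, cpm, true_labels, signature):
        """A known gene-wise multiplicative bulk shift is recovered in the
        adjusted signature (per-gene relative error < 0.1, noise off)."""
        rng = np.random.default_rng(8)
        F = rng.dirichlet(np.ones(truth.n_subpops), 20)
        bulk, _ = cm.mix_bulk(truth, F, noise_sd=0.0, apply_platform_shift=True, seed=9)
        bulk = cm.cpm_normalize(bulk)
        mix, fr = cm.make_artificial_mixtures(cpm, true_labels, n_mixtures=60,
                                              cells_per_mixture=1000, seed=10)
        adj = cm.smode_adjust(signature, mix, fr, bulk)
        gene_pos = {g: i for i, g in enumerate(truth.gene_ids)}
        sig_pos = {g: i for i, g in enumerate(signature.gene_ids)}
        shift = truth.platform_shift[[gene_pos[g] for g in adj.gene_ids]]
        target = signature.values[[sig_pos[g] for g in adj.gene_ids]] * shift[:, None]
        # compare after matching overall scale
        scale = np.sum(adj.values * target) / np.sum(adj.values**2)
        rel = np.abs(adj.values * scale - target) / np.maximum(target, 1e-9)
        assert np.median(rel) < 0.1

    def test_adjusted_signature_non_negative(self, truth, cpm, true_labels, signature,
                                             bulk20):
        bulk, _ = bulk20
        mix, fr = cm.make_artificial_mixtures(cpm, true_labels, n_mixtures=60, seed=11)
        adj = cm.smode_adjust(signature, mix, fr, bulk)
        assert (adj.values >= 0).all()

    def test_log2_bulk_refused(self, signature, cpm, true_labels):
        mix, fr = cm.make_artificial_mixtures(cpm, true_labels, n_mixtures=12, seed=0)
        bulk = cm.BulkMatrix(np.ones((3, 2)), ["a", "b", "c"], ["s1", "s2"],
                             scale="log2")
        with pytest.raises(ValueError, match="de-log"):
            cm.smode_adjust(signature, mix, fr, bulk)


class TestDeconvolve:
    def test_noiseless_exact_recovery(self, truth, true_signature):
        f = np.zeros((1, truth.n_subpops))
        f[0, :3] = [0.2, 0.3, 0.5]
        bulk, _ = cm.mix_bulk(truth, f, noise_sd=0, apply_platform_shift=False, seed=0)
        comps = cm.deconvolve(cm.cpm_normalize(bulk), true_signature)
        est = comps.fractions.to_numpy()[0]
        assert np.abs(est - f[0]).sum() < 0.02

    def test_signature_column_permutation_equivariance(self, truth, true_signature,
                                                       bulk20):
        bulk, _ = bulk20
        comps = cm.deconvolve(bulk, true_signature)
        perm = [3, 1, 5, 0, 2, 4]
        sig_p = cm.SignatureMatrix(true_signature.values[:, perm],
                                   true_signature.gene_ids,
                                   [true_signature.subpop_ids[i] for i in perm])
        comps_p = cm.deconvolve(bulk, sig_p)
        reordered = comps_p.fractions[comps.fractions.columns]
        assert np.allclose(comps.fractions.to_numpy(), reordered.to_numpy(),
                           atol=1e-6)

    def test_scale_invariance(self, truth, true_signature, bulk20):
        bulk, _ = bulk20
        scaled = cm.BulkMatrix(bulk.values * 37.0, bulk.gene_ids, bulk.sample_ids,
                               scale="linear")
        a = cm.deconvolve(bulk, true_signature).fractions.to_numpy()
        b = cm.deconvolve(scaled, true_signature).fractions.to_numpy()
        assert np.allclose(a, b, atol=1e-6)

    def test_matches_nnls_on_noiseless_mixtures(self, truth, true_signature):
        """On noiseless mixtures the SVR estimate agrees with the NNLS oracle
        within L1 0.02 per sample."""
        rng = np.random.default_rng(14)
        F = rng.dirichlet(np.ones(truth.n_subpops), 6)
        bulk, _ = cm.mix_bulk(truth, F, noise_sd=0, apply_platform_shift=False, seed=0)
        bulk = cm.cpm_normalize(bulk)
        comps = cm.deconvolve(bulk, true_signature)
        pos = {g: i for i, g in enumerate(bulk.gene_ids)}
        B = bulk.values[[pos[g] for g in true_signature.gene_ids]]
        for s in range(6):
            x, _ = scipy.optimize.nnls(true_signature.values, B[:, s])
            nnls_frac = x / x.sum()
            assert np.abs(comps.fractions.to_numpy()[s] - nnls_frac).sum() < 0.02

    def test_log2_refused(self, true_signature):
        bulk = cm.BulkMatrix(np.ones((3, 1)), true_signature.gene_ids[:3], ["s"],
                             scale="log2")
        with pytest.raises(ValueError, match="delog"):
            cm.deconvolve(bulk, true_signature)

    def test_missing_genes_warn(self, truth, true_signature, bulk20):
        bulk, _ = bulk20
        keep = [i for i, g in enumerate(bulk.gene_ids)
                if g not in set(true_signature.gene_ids[: len(true_signature.gene_ids) * 3 // 5])]
        small = cm.BulkMatrix(bulk.values[keep], [bulk.gene_ids[i] for i in keep],
                              bulk.sample_ids, scale=bulk.scale)
        with pytest.warns(UserWarning, match="signature genes"):
            cm.deconvolve(small, true_signature)


class TestPermutationSignificance:
    def test_p_bounds_and_noiseless_minimum(self, truth, true_signature):
        f = np.full((1, truth.n_subpops), 1 / truth.n_subpops)
        bulk, _ = cm.mix_bulk(truth, f, noise_sd=0, apply_platform_shift=False, seed=0)
        pos = {g: i for i, g in enumerate(bulk.gene_ids)}
        y = bulk.values[[pos[g] for g in true_signature.gene_ids], 0]
        p = cm.permutation_significance(y, true_signature, n_perm=100, seed=0)
        assert p == pytest.approx(1 / 101)

    def test_pure_noise_p_not_extreme(self, true_signature):
        rng = np.random.default_rng(3)
        ps = [cm.permutation_significance(
                rng.lognormal(3, 1, len(true_signature.gene_ids)),
                true_signature, n_perm=50, seed=s)
              for s in range(8)]
        assert 1 / 51 <= min(ps)
        assert np.median(ps) > 0.1

    def test_too_few_permutations_raise(self, true_signature):
        with pytest.raises(ValueError):
            cm.permutation_significance(np.ones(len(true_signature.gene_ids)),
                                        true_signature, n_perm=5)
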