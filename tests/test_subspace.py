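"""Subspace methods against linear-algebra oracles and planted ground truth."""

import numpy as np
import pytest
import scipy.linalg

from esgkit.recording import EpochSet, EventList, Recording, epoch
from esgkit.subspace import (CountSelection, apply_projection, beat_cca,
                             cca_average_regression, compute_ssp, dss,
                             dss_from_covariances, kneedle_elbow,
                             remove_components, select_component_count)


def _epochs(data):
    n_tr, n_ch, n_t = data.shape
    return EpochSet(data, -0.2, -0.2 + (n_t - 1) / 1000.0, 1000.0,
                    [f"ch{i}" for i in range(n_ch)])


def _recording(data, srate=1000.0, rpk=()):
    n_ch = data.shape[0]
    return Recording(data, srate, [f"ch{i}" for i in range(n_ch)],
                     ["esg_cervical"] * n_ch,
                     EventList.from_arrays(list(rpk), "r_peak"))


class TestSsp:
    def test_rank_one_artefact_removed_exactly(self, rng):
        u = rng.standard_normal(8)
        u /= np.linalg.norm(u)
        wave = np.sin(np.linspace(0, 4 * np.pi, 601))
        trials = np.stack([np.outer(u, wave)] * 10)
        f = compute_ssp(_epochs(trials), n_proj=1)
        rec = _recording(np.outer(u, np.tile(wave, 5)))
        out = apply_projection(rec, f, 1)
        assert np.sum(out.data ** 2) <= 1e-10 * np.sum(rec.data ** 2)

    def test_planted_rank3_subspace_recovered(self, rng):
        A = rng.standard_normal((8, 3))
        S = rng.standard_normal((3, 601))
        trials = np.stack([A @ S] * 6)
        f = compute_ssp(_epochs(trials), n_proj=3)
        # principal angles between estimated and true subspaces
        Qa, _ = np.linalg.qr(A)
        s = np.linalg.svd(f.filters @ Qa, compute_uv=False)
        angles = np.arccos(np.clip(s, -1, 1))
        assert np.max(angles) < 1e-6

    def test_projection_idempotent(self, rng):
        trials = rng.standard_normal((12, 6, 301))
        f = compute_ssp(_epochs(trials), n_proj=2)
        rec = _recording(rng.standard_normal((6, 2000)))
        once = apply_projection(rec, f, 2)
        twice = apply_projection(once, f, 2)
        assert np.max(np.abs(twice.data - once.data)) < 1e-10

    def test_k_zero_is_identity_and_complement_untouched(self, rng):
        trials = rng.standard_normal((12, 6, 301))
        f = compute_ssp(_epochs(trials), n_proj=3)
        rec = _recording(rng.standard_normal((6, 500)))
        np.testing.assert_array_equal(apply_projection(rec, f, 0).data, rec.data)
        # data in the orthogonal complement is unchanged
        U = f.filters[:3].T
        X = rec.data - U @ (U.T @ rec.data)
        rec2 = _recording(X)
        out = apply_projection(rec2, f, 3)
        assert np.max(np.abs(out.data - X)) < 1e-10
        # data entirely in span(U) is annihilated
        rec3 = _recording(U @ rng.standard_normal((3, 500)))
        out3 = apply_projection(rec3, f, 3)
        assert np.sum(out3.data ** 2) <= 1e-10 * np.sum(rec3.data ** 2)

    def test_too_many_projectors_rejected(self, rng):
        trials = rng.standard_normal((5, 4, 101))
        with pytest.raises(ValueError, match="n_proj"):
            compute_ssp(_epochs(trials), n_proj=4)


class TestCca:
    def test_self_correlation_is_one(self, rng):
        X = rng.standard_normal((4, 500))
        f = cca_average_regression(X, X)
        np.testing.assert_allclose(f.scores, 1.0, atol=1e-8)

    def test_matches_generalized_eigenproblem_oracle(self):
        # independent oracle: rho^2 from eigh(Cxy Cyy^-1 Cyx, Cxx)
        for seed in range(20):
            r = np.random.default_rng(seed)
            X = r.standard_normal((3, 400))
            Y = 0.5 * X + r.standard_normal((3, 400))
            f = cca_average_regression(X, Y, shrinkage=0.0)
            Xc = X - X.mean(1, keepdims=True)
            Yc = Y - Y.mean(1, keepdims=True)
            Cxx, Cyy = Xc @ Xc.T / 400, Yc @ Yc.T / 400
            Cxy = Xc @ Yc.T / 400
            lam = scipy.linalg.eigh(Cxy @ np.linalg.solve(Cyy, Cxy.T), Cxx,
                                    eigvals_only=True)[::-1]
            np.testing.assert_allclose(f.scores, np.sqrt(np.clip(lam, 0, 1)),
                                       atol=1e-8)

    def test_filters_unit_variance_and_patterns_invert(self, rng):
        X = rng.standard_normal((5, 800))
        Y = X + 0.1 * rng.standard_normal((5, 800))
        f = cca_average_regression(X, Y)
        np.testing.assert_allclose(f.patterns @ f.filters, np.eye(5), atol=1e-8)

    def test_planted_repeatable_source_found(self, small_uncleaned, small_sim):
        _, truth = small_sim
        f = beat_cca(small_uncleaned)
        # component 1 time course should track the dominant cardiac source
        rec = small_uncleaned
        idx = rec.esg_picks
        comp1 = f.filters[0] @ rec.data[idx]
        cardiac_sc6 = truth.cardiac[rec.channel_index("SC6")]
        n = min(len(comp1), len(cardiac_sc6))
        r = np.corrcoef(comp1[:n], cardiac_sc6[:n])[0, 1]
        assert abs(r) > 0.95

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            cca_average_regression(rng.standard_normal((3, 100)),
                                   rng.standard_normal((3, 99)))


class TestRemoveComponents:
    def test_k_zero_reconstructs_input(self, rng):
        X = rng.standard_normal((4, 600))
        f = cca_average_regression(X, X + 0.1 * rng.standard_normal((4, 600)))
        rec = _recording(X)
        out = remove_components(rec, f, 0)
        np.testing.assert_allclose(out.data, X, atol=1e-8 * np.abs(X).max())

    def test_k_all_zeroes_everything_but_the_mean(self, rng):
        X = rng.standard_normal((4, 600))
        f = cca_average_regression(X, X)
        out = remove_components(_recording(X), f, 4)
        # only the per-channel mean direction can survive
        assert np.abs(out.data - out.data.mean(axis=1, keepdims=True)).max() < 1e-6

    def test_planted_artefact_energy_removed(self, rng):
        # one strong repeatable source in 8 channels
        mix = rng.standard_normal(8)
        src = np.sin(2 * np.pi * 1.3 * np.arange(6000) / 1000.0) * 50
        noise = rng.standard_normal((8, 6000))
        X = np.outer(mix, src) + noise
        Y = np.outer(mix, src)  # the repeatable part
        f = cca_average_regression(X, Y)
        out = remove_components(_recording(X), f, 1)
        art_in = np.sum(np.outer(mix, src) ** 2)
        art_out = np.sum((out.data - noise) ** 2)
        assert art_out < 0.01 * art_in


class TestDss:
    def test_matches_generalized_eigendecomposition_oracle(self):
        for seed in range(20):
            r = np.random.default_rng(seed)
            B = r.standard_normal((4, 60))
            C1 = B @ B.T / 60
            W = r.standard_normal((4, 200))
            C0 = W @ W.T / 200 + 0.1 * np.eye(4)
            f = dss_from_covariances(C0, C1, shrinkage=0.0)
            lam = scipy.linalg.eigh(C1, C0, eigvals_only=True)[::-1]
            np.testing.assert_allclose(f.scores, np.clip(lam, 0, None), atol=1e-8)

    def test_joint_diagonalisation_property(self, rng):
        B = rng.standard_normal((5, 80))
        C1 = B @ B.T / 80
        W = rng.standard_normal((5, 300))
        C0 = W @ W.T / 300 + 0.1 * np.eye(5)
        f = dss_from_covariances(C0, C1, shrinkage=0.0)
        G = f.filters @ C0 @ f.filters.T
        off = G - np.diag(np.diag(G))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.abs(np.diag(G)))

    def test_degenerate_bias_gives_equal_ratios(self, rng):
        W = rng.standard_normal((4, 500))
        C0 = W @ W.T / 500
        f = dss_from_covariances(C0, C0, shrinkage=0.0)
        np.testing.assert_allclose(f.scores, 1.0, atol=1e-6)

    def test_repeatable_source_pattern_recovered(self, rng):
        mix = rng.standard_normal(8)
        mix /= np.linalg.norm(mix)
        srate, n = 1000.0, 60000
        peaks = np.arange(1000, n - 1000, 850)
        src = np.zeros(n)
        wave = np.sin(np.linspace(0, 2 * np.pi, 301)) * 30
        for p in peaks:
            src[p - 150:p + 151] += wave
        X = np.outer(mix, src) + rng.standard_normal((8, n))
        rec = _recording(X, rpk=peaks)
        ep = epoch(rec, "r_peak", -0.3, 0.3)
        f = dss(rec, ep)
        a1 = f.patterns[:, 0] / np.linalg.norm(f.patterns[:, 0])
        assert abs(np.dot(a1, mix)) > 0.99


class TestEnergyContraction:
    def test_no_method_adds_energy_to_pure_noise(self, rng):
        n = 20000
        peaks = np.arange(1000, n - 1000, 850)
        X = rng.standard_normal((6, n))
        rec = _recording(X, rpk=peaks)
        e_in = np.sum(X ** 2)
        ep_ssp = epoch(rec, "r_peak", -0.2, 0.4)
        out_ssp = apply_projection(rec, compute_ssp(ep_ssp, 3), 3)
        f_cca = beat_cca(rec)
        out_cca = remove_components(rec, f_cca, 3)
        ep_dss = epoch(rec, "r_peak", -0.4, 0.6)
        out_dss = remove_components(rec, dss(rec, ep_dss), 3)
        for out in (out_ssp, out_cca, out_dss):
            ratio = np.sum(out.data ** 2) / e_in
            assert 0.5 <= ratio <= 1.0 + 1e-9


class TestComponentCountSelection:
    def test_all_equal_indices(self):
        sel = CountSelection(idx_ri=4, idx_inpsr=4, idx_snr=4)
        assert sel.chosen == 4

    def test_weighted_formula_arithmetic(self):
        sel = CountSelection(idx_ri=2, idx_inpsr=4, idx_snr=5)
        assert sel.chosen == 4  # (0.5*2 + 0.5*4 + 1*5) / 2 = 4

    def test_half_ties_round_up(self):
        # (0.5*2 + 0.5*4 + 1*4) / 2 = 3.5 -> rounds up to 4
        assert CountSelection(idx_ri=2, idx_inpsr=4, idx_snr=4).chosen == 4
        # (0.5*1 + 0.5*2 + 1*3) / 2 = 2.25 -> 2
        assert CountSelection(idx_ri=1, idx_inpsr=2, idx_snr=3).chosen == 2

    def test_elbow_matches_curvature_oracle_on_exponential(self):
        k = np.arange(1, 21)
        y = np.exp(-k.astype(float))
        x = (k - k[0]) / (k[-1] - k[0])
        yn = (y - y.min()) / np.ptp(y)
        d1 = np.gradient(yn, x)
        d2 = np.gradient(d1, x)
        curv = np.abs(d2) / (1 + d1 ** 2) ** 1.5
        assert kneedle_elbow(k, y) == k[int(np.argmax(curv))]

    def test_constant_curve_raises_with_metric_name(self):
        k = np.arange(1, 21)
        with pytest.raises(ValueError, match="INPSR"):
            select_component_count(k, np.exp(-k.astype(float)),
                                   np.ones(20), np.exp(-k.astype(float)))

    def test_snr_index_is_argmax(self):
        k = np.arange(1, 21)
        snr = -((k - 7) ** 2).astype(float)
        sel = select_component_count(k, np.exp(-k.astype(float)),
                                     np.log(k.astype(float)), snr)
        assert sel.idx_snr == 7
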