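"""Heterogeneous-incomplete VAE: likelihoods, ELBO, training, grid search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ivambn.hivae as hv
from ivambn.hivae import (HivaeModel, ModalitySpec, elbo, encode, fit_hivae,
                          grid_search_cv, reconstruction_loglik,
                          thermometer_logprobs)


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class TestThermometer:
    def test_midpoint_splits_mass_evenly(self):
        logp = thermometer_logprobs(0.0, np.array([0.0]))
        assert np.exp(logp) == pytest.approx([0.5, 0.5])

    def test_extreme_latent_concentrates_mass(self):
        theta = np.array([-1.0, 0.0, 1.0])
        low = np.exp(thermometer_logprobs(-50.0, theta))
        high = np.exp(thermometer_logprobs(50.0, theta))
        assert low[0] == pytest.approx(1.0, abs=1e-12)
        assert high[-1] == pytest.approx(1.0, abs=1e-12)

    def test_hand_differencing_r4(self):
        theta = np.array([-1.0, 0.0, 2.0])
        h = 0.5
        probs = np.exp(thermometer_logprobs(h, theta))
        cdf = np.concatenate([[0.0], sigmoid(theta - h), [1.0]])
        assert probs == pytest.approx(np.diff(cdf), abs=1e-12)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_non_increasing_thresholds_rejected(self):
        with pytest.raises(ValueError):
            thermometer_logprobs(0.0, np.array([1.0, 0.5]))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(h=st.floats(-30, 30),
           start=st.floats(-10, 10),
           gaps=st.lists(st.floats(0.01, 5), min_size=1, max_size=8))
    def test_probabilities_sum_to_one_and_cdf_monotone(self, h, start, gaps):
        theta = start + np.cumsum([0.0] + gaps)
        logp = thermometer_logprobs(h, theta)
        probs = np.exp(logp)
        assert probs.min() >= 0.0
        assert abs(probs.sum() - 1.0) < 1e-12
        assert (np.diff(np.cumsum(probs)) >= -1e-12).all()


def tiny_model(specs, data, d_z=1, K=1, seed=0):
    rng = np.random.default_rng(seed)
    model = HivaeModel(specs=specs, latent_dim=d_z, K=K, params={},
                       norm_mean={}, norm_sd={})
    for s in specs:
        if s.kind == "categorical":
            continue
        v = pd.to_numeric(data[s.name], errors="coerce")
        model.norm_mean[s.name] = float(v.mean())
        sd = float(v.std(ddof=0))
        model.norm_sd[s.name] = sd if sd > 0 else 1.0
    model.params = hv._init_params(specs, model._input_dim(), d_z, K, rng)
    return model


class TestElbo:
    def test_regulariser_zero_at_prior(self):
        data = pd.DataFrame({"x": [0.3, -0.5, 1.0]})
        specs = [ModalitySpec("x", "real")]
        m = tiny_model(specs, data)
        # encoder pinned at mu(x)=0, sigma(x)=1
        m.params["enc_Wmu"][:] = 0.0
        m.params["enc_bmu"][:] = 0.0
        m.params["enc_Wsig"][:] = 0.0
        m.params["enc_bsig"][:] = 0.0
        total, reg, recon = elbo(data, None, m, L=1,
                                 rng=np.random.default_rng(0),
                                 return_parts=True)
        assert reg == pytest.approx(0.0, abs=1e-12)

    def test_identity_gaussian_decoder_closed_form(self):
        # decoder mean = z, unit decoder noise, collapsed posterior:
        # ELBO = reg - 1/2 (x_norm - mu(x))^2 - 1/2 log 2 pi per sample
        data = pd.DataFrame({"x": [1.0, -2.0, 0.5, 3.0]})
        specs = [ModalitySpec("x", "real")]
        m = tiny_model(specs, data)
        m.params["enc_Wmu"][:] = np.array([[0.7]])
        m.params["enc_bmu"][:] = 0.1
        m.params["enc_Wsig"][:] = 0.0
        m.params["enc_bsig"][:] = -40.0  # sigma(x) -> clipped tiny
        m.params["dec|x|w"][:] = 1.0
        m.params["dec|x|b"][:] = 0.0
        m.params["dec|x|rho"][:] = 0.0
        total, reg, recon = elbo(data, None, m, L=1,
                                 rng=np.random.default_rng(0),
                                 return_parts=True)
        xt, _, _ = m._prepare(data)
        mu = xt @ m.params["enc_Wmu"] + m.params["enc_bmu"]
        expect = float(np.mean(-0.5 * (xt[:, 0] - mu[:, 0]) ** 2
                               - 0.5 * np.log(2 * np.pi)))
        # sigma(x) is clipped at exp(-5), not exactly 0
        assert recon == pytest.approx(expect, abs=5e-3)

    def test_monte_carlo_estimates_agree(self):
        data = pd.DataFrame({"x": [0.7], "o": [2]})
        specs = [ModalitySpec("x", "real"), ModalitySpec("o", "ordinal", R=3)]
        m = tiny_model(specs, data, seed=3)
        big = elbo(data, None, m, L=10_000, rng=np.random.default_rng(1))
        singles = np.array([elbo(data, None, m, L=1,
                                 rng=np.random.default_rng(2_000 + i))
                            for i in range(3000)])
        se = singles.std(ddof=1) / np.sqrt(len(singles))
        assert abs(big - singles.mean()) < 3 * se

    def test_fully_missing_sample_keeps_regulariser_only(self):
        data = pd.DataFrame({"x": [np.nan]})
        specs = [ModalitySpec("x", "real")]
        m = tiny_model(specs, data)
        total, reg, recon = elbo(data, None, m, L=1,
                                 rng=np.random.default_rng(0),
                                 return_parts=True)
        assert recon == 0.0
        assert total == pytest.approx(reg)

    def test_full_mask_equals_unmasked(self):
        data = pd.DataFrame({"x": [0.5, 1.5], "o": [1, 3]})
        specs = [ModalitySpec("x", "real"), ModalitySpec("o", "ordinal", R=3)]
        m = tiny_model(specs, data, seed=5)
        mask = pd.DataFrame({"x": [True, True], "o": [True, True]})
        a = elbo(data, None, m, L=1, rng=np.random.default_rng(9))
        b = elbo(data, mask, m, L=1, rng=np.random.default_rng(9))
        assert a == b


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        n = 25
        data = pd.DataFrame({
            "x": rng.standard_normal(n),
            "o": rng.integers(1, 5, n),
            "c": rng.choice(["a", "b", "c"], n),
        })
        data.loc[2, "x"] = np.nan
        specs = [ModalitySpec("x", "real"), ModalitySpec("o", "ordinal", R=4),
                 ModalitySpec("c", "categorical", levels=["a", "b", "c"])]
        m = tiny_model(specs, data, d_z=2, K=3, seed=1)
        m.params["prior_means"] = rng.standard_normal((3, 2))
        for k in m.params:
            if k.endswith("|b"):
                m.params[k] = 0.3 * rng.standard_normal(m.params[k].shape)
        xt, targets, masks = m._prepare(data)
        eps = rng.standard_normal((2, n, 2))
        grads = {k: np.zeros_like(v) for k, v in m.params.items()}
        m._elbo_batch(xt, targets, masks, eps, grads=grads)
        h = 1e-6
        for key, arr in m.params.items():
            it = np.nditer(arr, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = arr[i]
                arr[i] = orig + h
                up, _ = m._elbo_batch(xt, targets, masks, eps)
                arr[i] = orig - h
                dn, _ = m._elbo_batch(xt, targets, masks, eps)
                arr[i] = orig
                numeric = (up - dn) / (2 * h) * n
                assert numeric == pytest.approx(grads[key][i], rel=1e-4,
                                                abs=1e-5), (key, i)


class TestFit:
    def test_recovers_1d_gaussian_module(self):
        rng = np.random.default_rng(1)
        n = 500
        z = rng.standard_normal(n)
        data = pd.DataFrame({"g": z + 0.2 * rng.standard_normal(n)})
        m = fit_hivae(data, [ModalitySpec("g", "real")],
                      {"seed": 3, "epochs": 200})
        z_hat = m.encode(data)[:, 0]
        assert abs(np.corrcoef(z_hat, z)[0, 1]) > 0.9
        rec = m.decode(m.encode(data), mode="mean")["g"].to_numpy()
        rmse = np.sqrt(np.mean((rec - data["g"].to_numpy()) ** 2))
        assert rmse < 0.2 * data["g"].std()

    def test_ordinal_module_frequencies(self):
        rng = np.random.default_rng(2)
        n = 500
        lat = rng.standard_normal(n)
        theta = np.array([-1.0, 0.0, 1.0])
        df = pd.DataFrame({
            f"o{j}": 1 + (theta[None, :]
                          < (1.5 * lat + rng.logistic(size=n))[:, None]
                          ).sum(axis=1)
            for j in range(2)})
        specs = [ModalitySpec(f"o{j}", "ordinal", R=4) for j in range(2)]
        m = fit_hivae(df, specs, {"seed": 4, "epochs": 300})
        dec = m.decode(m.sample_posterior(df, np.random.default_rng(5)),
                       rng=np.random.default_rng(6), mode="sample")
        for c in df.columns:
            emp = df[c].value_counts(normalize=True).sort_index()
            sim = pd.Series(dec[c]).value_counts(normalize=True).sort_index()
            assert float((emp - sim).abs().max()) < 0.05

    def test_constant_feature_decodes_constant(self):
        data = pd.DataFrame({"k": np.full(50, 7.0),
                             "x": np.random.default_rng(0).standard_normal(50)})
        specs = [ModalitySpec("k", "real"), ModalitySpec("x", "real")]
        m = fit_hivae(data, specs, {"seed": 0, "epochs": 100})
        dec = m.decode(m.encode(data), mode="mean")
        assert np.allclose(dec["k"], 7.0, atol=0.05)

    def test_training_is_bit_reproducible(self):
        rng = np.random.default_rng(7)
        data = pd.DataFrame({"a": rng.standard_normal(60),
                             "b": rng.standard_normal(60)})
        specs = [ModalitySpec("a", "real"), ModalitySpec("b", "real")]
        m1 = fit_hivae(data, specs, {"seed": 11, "epochs": 50})
        m2 = fit_hivae(data, specs, {"seed": 11, "epochs": 50})
        for k in m1.params:
            assert np.array_equal(m1.params[k], m2.params[k]), k

    def test_latent_correlates_despite_missingness(self):
        rng = np.random.default_rng(8)
        n = 400
        z = rng.standard_normal(n)
        data = pd.DataFrame({f"g{j}": z + 0.4 * rng.standard_normal(n)
                             for j in range(3)})
        mask = rng.random(data.shape) < 0.2
        vals = data.to_numpy()
        vals[mask] = np.nan
        data_miss = pd.DataFrame(vals, columns=data.columns)
        m = fit_hivae(data_miss, [ModalitySpec(c, "real")
                                  for c in data.columns],
                      {"seed": 2, "epochs": 200})
        assert abs(np.corrcoef(m.encode(data_miss)[:, 0], z)[0, 1]) > 0.9

    def test_too_few_samples_rejected(self):
        data = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            fit_hivae(data, [ModalitySpec("x", "real")], {"epochs": 1})


class TestEncodeDecode:
    def _fitted(self, seed=1, n=400):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        data = pd.DataFrame({f"g{j}": z + 0.1 * rng.standard_normal(n)
                             for j in range(2)})
        specs = [ModalitySpec(c, "real") for c in data.columns]
        return data, fit_hivae(data, specs, {"seed": seed, "epochs": 200})

    def test_autoencoding_fidelity(self):
        data, m = self._fitted()
        rec = m.decode(m.encode(data), mode="mean")
        for c in data.columns:
            rmse = np.sqrt(np.mean((rec[c] - data[c]) ** 2))
            assert rmse < 0.1 * data[c].std()

    def test_sample_posterior_collapses_with_tiny_sigma(self):
        data, m = self._fitted(seed=2)
        m.params["enc_Wsig"][:] = 0.0
        m.params["enc_bsig"][:] = -40.0
        z1 = m.encode(data)
        z2 = m.sample_posterior(data, np.random.default_rng(0))
        # sigma(x) floors at exp(-5) due to the log-sigma clip
        assert np.max(np.abs(z1 - z2)) < 0.05

    def test_ordinal_decode_modal_and_sampled(self):
        theta = np.array([-1.5, 1.5])
        spec = ModalitySpec("o", "ordinal", R=3)
        m = HivaeModel(specs=[spec], latent_dim=1, K=1,
                       params=hv._init_params([spec], 1, 1, 1,
                                              np.random.default_rng(0)),
                       norm_mean={"o": 2.0}, norm_sd={"o": 1.0})
        m.params["dec|o|w"][:] = 1.0
        m.params["dec|o|b"][:] = 0.0
        m.params["dec|o|theta1"][:] = theta[0]
        m.params["dec|o|deltas"][:] = np.log(np.expm1(theta[1] - theta[0]))
        z = np.zeros((10_000, 1))
        modal = m.decode(z, mode="mean")["o"]
        assert (modal == 2).all()  # middle category has the largest mass
        draws = m.decode(z, rng=np.random.default_rng(1), mode="sample")["o"]
        freq = pd.Series(draws).value_counts(normalize=True).sort_index()
        expect = np.exp(thermometer_logprobs(0.0, theta))
        assert freq.to_numpy() == pytest.approx(expect, abs=0.02)

    def test_save_load_roundtrip(self, tmp_path):
        data, m = self._fitted(seed=3)
        path = tmp_path / "model.npz"
        m.save(str(path))
        m2 = HivaeModel.load(str(path))
        assert np.array_equal(m.encode(data), m2.encode(data))
        assert m2.norm_mean == m.norm_mean


class TestGridSearch:
    def _unimodal(self, seed, n=200):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal(n)
        return pd.DataFrame({f"g{j}": z + 0.4 * rng.standard_normal(n)
                             for j in range(3)})

    def test_single_entry_grid_returned(self):
        data = self._unimodal(0)
        specs = [ModalitySpec(c, "real") for c in data.columns]
        best, table = grid_search_cv(data, specs, [{"epochs": 30}], seed=0)
        assert best == {"epochs": 30}
        assert len(table) == 1

    def test_learning_rate_grid_deterministic_winner(self):
        data = self._unimodal(1)
        specs = [ModalitySpec(c, "real") for c in data.columns]
        grid = {"lr": [0.001, 0.01], "epochs": [60]}
        best1, t1 = grid_search_cv(data, specs, grid, seed=3)
        best2, t2 = grid_search_cv(data, specs, grid, seed=3)
        assert best1 == best2
        pd.testing.assert_frame_equal(t1, t2)
        assert np.isfinite(t1["cv_reconstruction"]).all()

    def test_unimodal_data_makes_k_irrelevant(self):
        # with soft component responsibilities a K=3 model nests K=1, so on
        # unimodal data the held-out reconstruction difference is noise-level
        data = self._unimodal(2, n=300)
        specs = [ModalitySpec(c, "real") for c in data.columns]
        _, table = grid_search_cv(data, specs, {"K": [1, 3], "epochs": [120]},
                                  seed=2)
        vals = table.set_index("K")["cv_reconstruction"]
        assert abs(vals[1] - vals[3]) < 0.1

    def test_bimodal_data_selects_mixture(self):
        wins = 0
        for rep in range(3):
            rng = np.random.default_rng(200 + rep)
            n = 300
            comp = rng.integers(0, 2, n)
            z = np.where(comp == 1, 2.5, -2.5) + 0.5 * rng.standard_normal(n)
            data = pd.DataFrame({f"g{j}": z + 0.4 * rng.standard_normal(n)
                                 for j in range(3)})
            specs = [ModalitySpec(c, "real") for c in data.columns]
            best, _ = grid_search_cv(data, specs,
                                     {"K": [1, 2], "epochs": [120]}, seed=rep)
            wins += best["K"] == 2
        assert wins == 3

    def test_fewer_samples_than_folds_rejected(self):
        data = pd.DataFrame({"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            grid_search_cv(data, [ModalitySpec("x", "real")],
                           [{"epochs": 1}], folds=3)

    def test_empty_grid_rejected(self):
        data = self._unimodal(0)
        with pytest.raises(ValueError):
            grid_search_cv(data, [ModalitySpec("g0", "real")], [])


def test_encode_wrapper_keeps_index():
    rng = np.random.default_rng(0)
    data = pd.DataFrame({"x": rng.standard_normal(40)},
                        index=[f"p{i}" for i in range(40)])
    m = fit_hivae(data, [ModalitySpec("x", "real")], {"seed": 0, "epochs": 30})
    scores = encode(data, m)
    assert list(scores.index) == list(data.index)
    assert list(scores.columns) == ["z0"]
    # held-out objective is finite and reproducible
    r1 = reconstruction_loglik(m, data, rng=np.random.default_rng(5))
    r2 = reconstruction_loglik(m, data, rng=np.random.default_rng(5))
    assert r1 == r2 and np.isfinite(r1)
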