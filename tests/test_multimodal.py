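"""Feature assembly, standardisation, ridge vs normal equations, CV contract."""

import numpy as np
import pandas as pd
import pytest

from rair_axis import (CohortSpec, GeneModule, ScreenSpec, build_features,
                       compare_models, cross_validate, delta_r2,
                       generate_cell_panel, generate_screen, ridge_fit,
                       standardize)
from rair_axis.multimodal import Standardizer, cell_pc_scores, _summarise


def oracle_ridge(X, y, lam):
    """Closed-form normal equations on centred data; intercept unpenalised."""
    xm = X.mean(axis=0)
    ym = y.mean()
    Xc = X - xm
    yc = y - ym
    beta = np.linalg.solve(Xc.T @ Xc + lam * np.eye(X.shape[1]), Xc.T @ yc)
    return beta, ym - xm @ beta


def _panel_and_screen(seed=0, n_cells=18, n_drugs=40, interaction=None,
                      noise_sd=0.05):
    planted = frozenset(range(30))
    pspec = CohortSpec(n_genes=200, n_per_group=(1, n_cells - 1),
                       planted_up=planted, effect_size=2.0, noise_sd=0.3,
                       seed=seed)
    eng = np.linspace(0, 1, n_cells)
    panel = generate_cell_panel(pspec, eng)
    drugs = [f"D{i:03d}" for i in range(n_drugs)]
    class_map = {d: ("SENS" if i < n_drugs // 4 else "OTHER")
                 for i, d in enumerate(drugs)}
    rng = np.random.default_rng(seed + 1)
    potency = {d: float(rng.uniform(0.4, 1.0)) for d in drugs}
    sspec = ScreenSpec(n_cells=n_cells, n_drugs=n_drugs, class_map=class_map,
                       drug_potency=potency,
                       interaction_effect=interaction or {},
                       cell_effect_sd=0.0, noise_sd=noise_sd, seed=seed + 2)
    resp, _ = generate_screen(sspec, eng)
    module = GeneModule(name="planted", direction="up",
                        genes=frozenset(panel.gene_ids[sorted(planted)]))
    return panel, resp, module


class TestBuildFeatures:
    def test_drug_only_width_is_vocabulary_size(self):
        panel, resp, _ = _panel_and_screen()
        feats = build_features(panel, resp, "drug_only")
        assert feats.n_features == resp["drug_id"].nunique()
        onehot = feats.X[:, feats.blocks["drug_onehot"]]
        assert np.allclose(onehot.sum(axis=1), 1.0)

    def test_cell_only_with_signature_width(self):
        panel, resp, module = _panel_and_screen()
        feats = build_features(panel, resp, "cell_only", module=module)
        assert feats.n_features == 16 + 1
        assert "signature" in feats.blocks

    def test_multimodal_concatenates_blocks(self):
        panel, resp, module = _panel_and_screen()
        feats = build_features(panel, resp, "multimodal", module=module)
        assert feats.n_features == 16 + 1 + resp["drug_id"].nunique()
        assert set(feats.blocks) == {"cell_pcs", "signature", "drug_onehot"}

    def test_pc_scores_match_eigendecomposition(self, rng):
        genes = [f"g{i}" for i in range(50)]
        cells = [f"c{i}" for i in range(5)]
        from rair_axis.preprocess import ExpressionMatrix
        vals = pd.DataFrame(rng.normal(6, 1, size=(50, 5)), index=genes,
                            columns=cells)
        panel = ExpressionMatrix(values=vals, scale="log2p1")
        scores = cell_pc_scores(panel, n_components=4)
        # oracle: eigendecomposition of the cell-cell covariance
        X = vals.to_numpy().T
        Xc = X - X.mean(axis=0)
        cov = Xc @ Xc.T
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1][:4]
        for j, col in enumerate(scores.columns):
            expect = v[:, order[j]] * np.sqrt(w[order[j]])
            got = scores[col].to_numpy()
            assert (np.allclose(got, expect, atol=1e-8)
                    or np.allclose(got, -expect, atol=1e-8))

    def test_unknown_cells_dropped_with_warning(self):
        panel, resp, _ = _panel_and_screen()
        resp2 = pd.concat([resp, pd.DataFrame([
            {"cell_id": "GHOST", "drug_id": "D000", "auc": 0.5}])],
            ignore_index=True)
        feats = build_features(panel, resp2, "drug_only")
        assert feats.n_pairs == len(resp)

    def test_invalid_config_rejected(self):
        panel, resp, _ = _panel_and_screen()
        with pytest.raises(ValueError):
            build_features(panel, resp, "kitchen_sink")


class TestStandardize:
    def test_constant_column_zeroed_and_flagged(self):
        X = np.column_stack([np.ones(10), np.arange(10, dtype=float)])
        Z, st = standardize(X)
        assert np.allclose(Z[:, 0], 0.0)
        assert st.flagged[0] and not st.flagged[1]

    def test_two_point_column_fixed(self):
        X = np.array([[-1.0], [1.0]])
        Z, _ = standardize(X)
        assert np.allclose(Z, X)      # mu=0, population sd=1

    def test_population_convention(self, rng):
        X = rng.normal(2, 3, size=(200, 6))
        Z, _ = standardize(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-12
        assert np.abs(Z.std(axis=0, ddof=0) - 1).max() < 1e-12

    def test_params_reused_on_held_out_rows(self, rng):
        X = rng.normal(size=(50, 3))
        st = Standardizer.fit(X)
        held = rng.normal(10, 5, size=(5, 3))   # wildly different scale
        Z = st.transform(held)
        assert np.allclose(Z, (held - st.mu) / st.sigma)


class TestRidge:
    def test_small_lambda_approaches_ols(self, rng):
        X = rng.normal(size=(30, 4))
        y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + rng.normal(size=30)
        model = ridge_fit(X, y, lam=1e-10)
        beta_ols, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(30), X]), y, rcond=None)
        assert np.linalg.norm(model.beta - beta_ols[1:]) < 1e-6

    def test_huge_lambda_shrinks_to_intercept(self, rng):
        X = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        model = ridge_fit(X, y, lam=1e10)
        assert np.linalg.norm(model.beta) < 1e-6
        assert model.intercept == pytest.approx(y.mean(), abs=1e-6)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_normal_equation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        model = ridge_fit(X, y, lam=1.0)
        beta, intercept = oracle_ridge(X, y, 1.0)
        assert np.allclose(model.beta, beta, atol=1e-8)
        assert model.intercept == pytest.approx(intercept, abs=1e-8)

    def test_invalid_inputs_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        with pytest.raises(ValueError):
            ridge_fit(X, y, lam=0.0)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            ridge_fit(X, y, lam=1.0)


class TestCrossValidate:
    def test_fold_contract(self):
        panel, resp, _ = _panel_and_screen(n_cells=10, n_drugs=10)  # N=100
        feats = build_features(panel, resp, "drug_only")
        res = cross_validate(feats, k=5, seed=0)
        sizes = np.bincount(res.fold)
        assert sizes.tolist() == [20] * 5
        assert np.isfinite(res.y_hat_cv).all()

    def test_deterministic_given_seed(self):
        panel, resp, _ = _panel_and_screen()
        feats = build_features(panel, resp, "drug_only")
        a = cross_validate(feats, seed=7)
        b = cross_validate(feats, seed=7)
        assert np.array_equal(a.fold, b.fold)
        assert np.allclose(a.y_hat_cv, b.y_hat_cv)

    def test_perfect_predictor_metrics(self, rng):
        y = rng.normal(size=50)
        rmse, r, r2, r2p = _summarise(y, y.copy())
        assert rmse == 0.0 and r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0) and r2p == pytest.approx(1.0)

    def test_noiseless_linear_system_recovered(self, rng):
        X = rng.normal(size=(200, 5))
        y = X @ np.array([1.0, 2.0, -1.0, 0.5, 0.0]) + 3.0
        from rair_axis.multimodal import PairFeatureMatrix
        feats = PairFeatureMatrix(
            X=X, y=y,
            pairs=pd.DataFrame({"cell_id": ["c"] * 200,
                                "drug_id": [f"d{i}" for i in range(200)]}),
            feature_names=[f"f{i}" for i in range(5)],
            blocks={"all": slice(0, 5)}, config="cell_only")
        res = cross_validate(feats, k=5, lam=1e-8, seed=1)
        assert res.rmse < 1e-3 and res.pearson_r > 0.999999

    def test_drug_only_cv_r_matches_analytic_signal_to_noise(self):
        # y = potency + N(0, noise): CV r should approach
        # sqrt(var_potency / (var_potency + noise^2))
        panel, resp, _ = _panel_and_screen(seed=5, n_cells=18, n_drugs=100,
                                           noise_sd=0.05)
        feats = build_features(panel, resp, "drug_only")
        res = cross_validate(feats, k=5, seed=0)
        wide = resp.pivot(index="cell_id", columns="drug_id", values="auc")
        var_pot = wide.mean(axis=0).var(ddof=0)
        expect = np.sqrt(var_pot / (var_pot + 0.05 ** 2))
        assert res.pearson_r == pytest.approx(expect, abs=0.05)

    def test_training_fold_statistics_used_for_held_out_rows(self):
        # re-derive fold-0 predictions with train-only standardisation
        from sklearn.model_selection import KFold
        panel, resp, _ = _panel_and_screen(n_cells=6, n_drugs=10)
        feats = build_features(panel, resp, "drug_only")
        res = cross_validate(feats, k=3, lam=1.0, seed=11)
        kf = KFold(n_splits=3, shuffle=True, random_state=11)
        train, test = next(iter(kf.split(feats.X)))
        Ztr, st = standardize(feats.X[train])
        model = ridge_fit(Ztr, feats.y[train], 1.0)
        manual = model.predict(st.transform(feats.X[test]))
        assert np.allclose(res.y_hat_cv[test], manual, atol=1e-10)

    def test_bad_k_rejected(self):
        panel, resp, _ = _panel_and_screen(n_cells=4, n_drugs=2)
        feats = build_features(panel, resp, "drug_only")
        with pytest.raises(ValueError):
            cross_validate(feats, k=1)
        with pytest.raises(ValueError):
            cross_validate(feats, k=100)


class TestCompareModels:
    def test_identical_configs_give_zero_delta(self):
        panel, resp, module = _panel_and_screen()
        feats = build_features(panel, resp, "drug_only")
        a = cross_validate(feats, seed=3)
        b = cross_validate(feats, seed=3)
        assert delta_r2(a, b) == 0.0

    def test_fold_mismatch_rejected(self):
        panel, resp, _ = _panel_and_screen()
        feats = build_features(panel, resp, "drug_only")
        a = cross_validate(feats, seed=3)
        b = cross_validate(feats, seed=4)
        with pytest.raises(ValueError):
            delta_r2(a, b)
        with pytest.raises(ValueError):
            compare_models({"a": a, "b": b})

    def test_metric_table_layout(self):
        panel, resp, module = _panel_and_screen()
        results = {}
        for cfg in ("drug_only", "multimodal"):
            feats = build_features(panel, resp, cfg, module=module)
            results[cfg] = cross_validate(feats, seed=3)
        table = compare_models(results)
        assert list(table.index) == ["drug_only", "multimodal"]
        assert {"rmse", "pearson_r", "r2", "r2_pearson"} == set(table.columns)

    def test_noise_signature_adds_nothing(self):
        # signature column replaced by pure noise: delta_r2 ~ 0
        panel, resp, module = _panel_and_screen(seed=9, n_drugs=80)
        base = build_features(panel, resp, "drug_only")
        aug = build_features(panel, resp, "drug_only", module=module,
                             include_signature=True)
        rng = np.random.default_rng(0)
        aug.X[:, aug.blocks["signature"]] = rng.normal(size=(aug.n_pairs, 1))
        a = cross_validate(base, seed=3)
        b = cross_validate(aug, seed=3)
        assert abs(delta_r2(a, b)) < 0.01

    def test_planted_interaction_rewards_multimodal(self):
        panel, resp, module = _panel_and_screen(
            seed=13, n_drugs=80, interaction={"SENS": -0.3})
        results = {}
        for cfg in ("drug_only", "multimodal"):
            feats = build_features(panel, resp, cfg, module=module)
            results[cfg] = cross_validate(feats, seed=3)
        assert results["multimodal"].pearson_r > results["drug_only"].pearson_r
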