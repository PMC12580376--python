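"""Sample splitting, random-forest training, prediction and feature ranking."""

import numpy as np
import pandas as pd
import pytest

import earlycrop as ec
from earlycrop.classify import rank_features
from earlycrop.errors import ConfigurationError, SchemaError


def class_table(counts, seed=0, n_features=5, informative=False):
    """Random feature table; optionally append a class-coded feature."""
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n in counts.items():
        rows += [cls] * n
    table = pd.DataFrame({"crop_class": rows})
    for j in range(n_features):
        table[f"f{j}"] = rng.normal(size=len(table))
    if informative:
        code = {cls: i for i, cls in enumerate(counts)}
        table["leak"] = table["crop_class"].map(code).astype(float)
    return table


class TestSplitSamples:
    def test_default_counts_per_class(self):
        table = class_table({"soybean": 621, "maize": 588, "rice": 215})
        out = ec.split_samples(table, seed=1)
        train = out[out["split"] == "train"]["crop_class"].value_counts()
        assert train["soybean"] == 497
        assert train["maize"] == 470
        assert train["rice"] == 172

    def test_ratio_one_all_train(self):
        table = class_table({"soybean": 10, "maize": 10, "rice": 10})
        out = ec.split_samples(table, ratio=1.0, seed=1)
        assert (out["split"] == "train").all()

    def test_same_seed_identical_assignment(self):
        table = class_table({"soybean": 50, "maize": 40, "rice": 30})
        a = ec.split_samples(table, seed=9)
        b = ec.split_samples(table, seed=9)
        assert a["split"].equals(b["split"])

    def test_tiny_class_rejected(self):
        with pytest.raises(ConfigurationError):
            ec.split_samples(class_table({"soybean": 5, "maize": 1, "rice": 5}))


class TestTrainRF:
    def test_separable_classes_fit_near_perfectly(self):
        table = class_table({"soybean": 60, "maize": 60, "rice": 60},
                            informative=True)
        feats = table.drop(columns="crop_class")
        model = ec.train_rf(feats, table["crop_class"], seed=0)
        pred = model.predict(feats)
        assert (pred == table["crop_class"]).mean() >= 0.99

    def test_uninformative_features_score_near_majority_rate(self):
        """Null model: with label-independent features, validation OA stays
        within +/-0.1 of the majority-class rate on average over 20 seeds."""
        oas = []
        for seed in range(20):
            table = class_table({"soybean": 120, "maize": 50, "rice": 30},
                                seed=seed, n_features=8)
            table = ec.split_samples(table, seed=seed)
            train = table[table["split"] == "train"]
            val = table[table["split"] == "validation"]
            cols = [c for c in table.columns if c.startswith("f")]
            model = ec.train_rf(train[cols], train["crop_class"], seed=seed)
            oas.append((model.predict(val[cols]) == val["crop_class"]).mean())
        assert abs(np.mean(oas) - 0.6) < 0.1

    def test_same_seed_identical_predictions(self):
        table = class_table({"soybean": 40, "maize": 40, "rice": 40}, seed=2)
        feats = table.drop(columns="crop_class")
        a = ec.train_rf(feats, table["crop_class"], seed=7).predict(feats)
        b = ec.train_rf(feats, table["crop_class"], seed=7).predict(feats)
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        table = class_table({"soybean": 30})
        with pytest.raises(ConfigurationError):
            ec.train_rf(table.drop(columns="crop_class"), table["crop_class"])

    def test_missing_values_rejected(self):
        table = class_table({"soybean": 20, "maize": 20})
        feats = table.drop(columns="crop_class")
        feats.iloc[0, 0] = np.nan
        with pytest.raises(ConfigurationError):
            ec.train_rf(feats, table["crop_class"])


class TestPredictMap:
    @pytest.fixture()
    def fitted(self):
        table = class_table({"soybean": 40, "maize": 40, "rice": 40},
                            informative=True)
        feats = table.drop(columns="crop_class")
        return ec.train_rf(feats, table["crop_class"], seed=1), feats

    def test_all_masked_gives_nodata(self, fitted):
        model, feats = fitted
        out = ec.predict_map(model, feats, np.zeros(len(feats), bool))
        assert (out == "nodata").all()

    def test_unmasked_matches_model_predictions(self, fitted):
        model, feats = fitted
        out = ec.predict_map(model, feats, np.ones(len(feats), bool))
        assert np.array_equal(out, model.predict(feats))

    def test_schema_mismatch_names_missing_feature(self, fitted):
        model, feats = fitted
        with pytest.raises(SchemaError, match="leak"):
            model.predict(feats.drop(columns="leak"))


class TestRanking:
    def test_class_coded_feature_ranks_first(self):
        """A feature equal to the numeric label dominates MDI over pure noise
        (checked over 10 seeds)."""
        for seed in range(10):
            table = class_table({"soybean": 50, "maize": 50, "rice": 50},
                                seed=seed, informative=True)
            feats = table.drop(columns="crop_class")
            model = ec.train_rf(feats, table["crop_class"], seed=seed)
            assert rank_features(model)["feature"].iloc[0] == "leak"

    def test_importances_sum_to_one(self):
        table = class_table({"soybean": 30, "maize": 30, "rice": 30},
                            informative=True)
        feats = table.drop(columns="crop_class")
        model = ec.train_rf(feats, table["crop_class"], seed=3)
        assert model.importances.sum() == pytest.approx(1.0, abs=1e-9)

    def test_k_equal_all_is_identity(self):
        table = class_table({"soybean": 30, "maize": 30}, informative=True)
        feats = table.drop(columns="crop_class")
        model = ec.train_rf(feats, table["crop_class"], seed=3)
        _, reduced = ec.rank_and_select(model, table, k=len(model.feature_names))
        assert set(reduced.columns) == set(table.columns)

    def test_k_too_large_rejected(self):
        table = class_table({"soybean": 30, "maize": 30})
        feats = table.drop(columns="crop_class")
        model = ec.train_rf(feats, table["crop_class"], seed=3)
        with pytest.raises(ConfigurationError):
            ec.rank_and_select(model, table, k=99)


class TestLeakageAudit:
    def test_validation_rows_do_not_influence_pca(self, small_scene):
        """Perturbing validation samples must not change the fitted temporal
        PCA (it is fitted on training rows only)."""
        from earlycrop import pipeline
        from earlycrop.compositing import fill_gaps_matrix
        from earlycrop.sar import build_sar_features

        bundle = pipeline.composite_scene(small_scene)
        vv, _ = fill_gaps_matrix(bundle.sar["vv"])
        vh, _ = fill_gaps_matrix(bundle.sar["vh"])
        train_mask = np.zeros(len(vv), dtype=bool)
        train_mask[: len(vv) // 2] = True

        _, models_a = build_sar_features(vv, vh, train_mask=train_mask)
        vv2, vh2 = vv.copy(), vh.copy()
        vv2[~train_mask] += 25.0  # wreck the validation rows
        vh2[~train_mask] -= 25.0
        _, models_b = build_sar_features(vv2, vh2, train_mask=train_mask)
        for name in ("VV", "VH"):
            assert np.allclose(models_a[name].components_,
                               models_b[name].components_)
            assert np.allclose(models_a[name].mean_, models_b[name].mean_)
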