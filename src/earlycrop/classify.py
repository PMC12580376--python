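"""Random-forest classification, feature ranking and top-k selection.

The classifier follows the reference configuration: 100 trees, a minimum leaf
population of 10, all other hyperparameters at library defaults.  Feature
importance is the forest's Mean Decrease in Impurity (MDI), normalised to sum
to one.  Samples are split 8:2 into training and validation per class
(stratified) before any fitting, scaling or selection touches the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError, SchemaError

#: Default reproducibility seed recorded in run configs.
DEFAULT_SEED = 20190501

NODATA_CLASS = "nodata"


def split_samples(table: pd.DataFrame, ratio: float = 0.8, seed: int = DEFAULT_SEED,
                  class_column: str = "crop_class") -> pd.DataFrame:
    """Assign a stratified train/validation split.

    Per class, ``round(ratio * n)`` samples (round-half-up) go to training and
    the rest to validation.  Returns a copy with a ``split`` column.
    """
    if not 0.0 < ratio <= 1.0:
        raise ConfigurationError("ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    out["split"] = "validation"
    for cls, group in table.groupby(class_column, sort=True):
        n = len(group)
        if n < 2:
            raise ConfigurationError(f"class {cls!r} has fewer than 2 samples")
        n_train = int(np.floor(ratio * n + 0.5))
        order = rng.permutation(n)
        train_idx = group.index.to_numpy()[order[:n_train]]
        out.loc[train_idx, "split"] = "train"
    return out


@dataclass
class RFModel:
    """Fitted random forest plus its feature schema."""

    estimator: RandomForestClassifier
    feature_names: list[str]
    classes: list[str] = field(default_factory=list)

    @property
    def importances(self) -> pd.Series:
        """MDI importance per feature (sums to 1)."""
        return pd.Series(self.estimator.feature_importances_,
                         index=self.feature_names, name="importance")

    def _matrix(self, features: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in features.columns]
        if missing:
            raise SchemaError(f"missing feature(s): {missing[:5]}")
        return features[self.feature_names].to_numpy(dtype=float)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self._matrix(features))


def train_rf(features: pd.DataFrame, labels, trees: int = 100, min_leaf: int = 10,
             seed: int = DEFAULT_SEED) -> RFModel:
    """Fit the random forest on a feature table.

    Raises if the training labels contain a single class (nothing to separate)
    or the table contains missing values.
    """
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ConfigurationError("training data must contain at least two classes")
    X = features.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ConfigurationError("feature table contains missing values")
    clf = RandomForestClassifier(n_estimators=trees, min_samples_leaf=min_leaf,
                                 random_state=seed, n_jobs=1)
    clf.fit(X, labels)
    return RFModel(estimator=clf, feature_names=list(features.columns),
                   classes=list(clf.classes_))


def predict_map(model: RFModel, features: pd.DataFrame,
                cropland_mask: np.ndarray | None = None,
                nodata: str = NODATA_CLASS) -> np.ndarray:
    """Classify per-pixel features, assigning ``nodata`` outside the cropland mask."""
    n = len(features)
    out = np.full(n, nodata, dtype=object)
    if cropland_mask is None:
        mask = np.ones(n, dtype=bool)
    else:
        mask = np.asarray(cropland_mask, dtype=bool)
        if mask.shape != (n,):
            raise SchemaError("cropland_mask length must match feature rows")
    if mask.any():
        out[mask] = model.predict(features.loc[mask])
    return out


def rank_features(model: RFModel) -> pd.DataFrame:
    """MDI ranking: columns (rank, feature, importance), non-increasing scores.

    Ties are broken by lexicographic feature name, keeping rankings
    reproducible across runs.
    """
    imp = model.importances
    ranked = imp.to_frame().reset_index(names="feature")
    ranked = ranked.sort_values(["importance", "feature"],
                                ascending=[False, True], kind="mergesort")
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked.reset_index(drop=True)


def rank_and_select(model: RFModel, table: pd.DataFrame, k: int = 20
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k feature subset by MDI.

    Returns ``(ranking, reduced_table)`` where ``reduced_table`` keeps only the
    top-k feature columns of ``table`` (any non-feature columns such as id /
    crop_class / split are preserved).
    """
    if k > len(model.feature_names):
        raise ConfigurationError(
            f"k={k} exceeds the {len(model.feature_names)} available features"
        )
    ranking = rank_features(model)
    top = ranking["feature"].head(k).tolist()
    meta = [c for c in table.columns if c not in model.feature_names]
    return ranking, table[meta + top].copy()
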