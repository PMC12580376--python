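"""SAR feature extraction: polarimetric ratio indices, statistics and temporal PCA.

Backscatter composites are stored in dB, but ratio indices are physically
meaningful only on linear power, so the two index operations convert first:

* RVI (dual-pol Radar Vegetation Index) = 4 sVH / (sVH + sVV), range [0, 4)
* CPR (Cross-Polarization Ratio)        = sVH * sVV / (sVH + sVV)

Each of the four SAR parameters (sVV, sVH in dB; CPR, RVI on linear power) is
summarised by seven statistics (max, min, mean, std, 15/50/90th percentile)
and by the scores of a per-parameter temporal principal component analysis
(top three components of the across-window covariance, fitted on training
samples only), giving 28 + 12 = 40 SAR features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compositing import db_to_linear
from .errors import UndefinedValueError

SAR_PARAMS = ("VV", "VH", "CPR", "RVI")
SAR_STATS = ("max", "min", "mean", "stdDev", "p15", "p50", "p90")


@dataclass
class SarSample:
    """One dual-polarization backscatter observation, stored in dB."""

    vv_db: float
    vh_db: float

    @property
    def vv_linear(self) -> float:
        return float(db_to_linear(self.vv_db))

    @property
    def vh_linear(self) -> float:
        return float(db_to_linear(self.vh_db))

    def rvi(self) -> float:
        return float(rvi(self.vv_linear, self.vh_linear))

    def cpr(self) -> float:
        return float(cpr(self.vv_linear, self.vh_linear))


def rvi(vv, vh):
    """Dual-pol Radar Vegetation Index on *linear* power: 4 sVH / (sVH + sVV)."""
    vv, vh = np.asarray(vv, dtype=float), np.asarray(vh, dtype=float)
    den = vv + vh
    if np.any(den <= 0):
        raise UndefinedValueError("RVI: sVV + sVH must be > 0")
    return 4.0 * vh / den


def cpr(vv, vh):
    """Cross-Polarization Ratio on *linear* power: sVH sVV / (sVH + sVV)."""
    vv, vh = np.asarray(vv, dtype=float), np.asarray(vh, dtype=float)
    den = vv + vh
    if np.any(den <= 0):
        raise UndefinedValueError("CPR: sVV + sVH must be > 0")
    return vh * vv / den


def sar_stat_descriptors(series, stats: tuple[str, ...] = SAR_STATS) -> dict[str, float]:
    """Named summary statistics of one SAR parameter series.

    Same percentile and population-std conventions as the optical block.
    """
    from .optical import stat_matrix

    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    mat = stat_matrix(series[np.newaxis, :], stats)
    return {name: float(mat[name][0]) for name in stats}


@dataclass
class TemporalPCA:
    """Principal components of one parameter's time series across windows.

    Center-only standardisation (windows share units), eigendecomposition of
    the sample covariance, components ordered by descending eigenvalue, and a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """

    n_components: int = 3
    mean_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    components_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    eigenvalues_: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def fit(self, X: np.ndarray) -> "TemporalPCA":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        n, w = X.shape
        if n <= self.n_components:
            raise ValueError(
                f"need more than {self.n_components} samples to fit "
                f"{self.n_components} components, got {n}"
            )
        self.mean_ = X.mean(axis=0)
        centered = X - self.mean_
        cov = centered.T @ centered / (n - 1)
        vals, vecs = np.linalg.eigh(cov)
        order = np.argsort(vals)[::-1][: self.n_components]
        vals, vecs = vals[order], vecs[:, order]
        for j in range(vecs.shape[1]):
            if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
                vecs[:, j] = -vecs[:, j]
        self.components_ = vecs.T
        self.eigenvalues_ = np.maximum(vals, 0.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return (X - self.mean_) @ self.components_.T

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def sar_pca(train_matrix: np.ndarray, apply_matrix: np.ndarray | None = None,
            k: int = 3) -> tuple[np.ndarray, TemporalPCA]:
    """Fit a temporal PCA on training series and project (all) series onto it.

    Returns ``(scores, model)`` where ``scores`` has shape (n, k).
    """
    model = TemporalPCA(n_components=k).fit(train_matrix)
    X = train_matrix if apply_matrix is None else apply_matrix
    return model.transform(X), model


def sar_parameter_matrices(vv_db: np.ndarray, vh_db: np.ndarray) -> dict[str, np.ndarray]:
    """The four SAR parameter series: VV/VH kept in dB, CPR/RVI on linear power."""
    vv_db = np.atleast_2d(np.asarray(vv_db, dtype=float))
    vh_db = np.atleast_2d(np.asarray(vh_db, dtype=float))
    vv_lin, vh_lin = db_to_linear(vv_db), db_to_linear(vh_db)
    return {
        "VV": vv_db,
        "VH": vh_db,
        "CPR": cpr(vv_lin, vh_lin),
        "RVI": rvi(vv_lin, vh_lin),
    }


def build_sar_features(vv_db: np.ndarray, vh_db: np.ndarray,
                       train_mask: np.ndarray | None = None,
                       k: int = 3) -> tuple[pd.DataFrame, dict[str, TemporalPCA]]:
    """Full SAR feature block: 7 stats x 4 params + k PCA scores x 4 params.

    ``train_mask`` restricts PCA fitting to training samples (all samples are
    still projected); omitting it fits on everything, which is only
    appropriate for unsupervised use.
    """
    from .optical import stat_matrix

    params = sar_parameter_matrices(vv_db, vh_db)
    n, w = params["VV"].shape
    k = min(k, w)
    cols: dict[str, np.ndarray] = {}
    for name in SAR_PARAMS:
        stats = stat_matrix(params[name], SAR_STATS)
        for stat in SAR_STATS:
            cols[f"{name}_{stat}"] = stats[stat]
    models: dict[str, TemporalPCA] = {}
    for name in SAR_PARAMS:
        X = params[name]
        fit_on = X if train_mask is None else X[np.asarray(train_mask, dtype=bool)]
        scores, model = sar_pca(fit_on, X, k=k)
        models[name] = model
        for j in range(k):
            cols[f"{name}_pc{j + 1}"] = scores[:, j]
    return pd.DataFrame(cols), models
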