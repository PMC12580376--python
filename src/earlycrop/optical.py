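"""Optical feature extraction: vegetation indices and season-level descriptors.

Five vegetation indices are computed per composite window from surface
reflectance:

* EVI  = 2.5 (NIR - red) / (NIR + 6 red - 7.5 blue + 1)
* LSWI = (NIR - SWIR1) / (NIR + SWIR1)
* RENDVI = (NIR - RE2) / (NIR + RE2)
* NDSVI = (SWIR1 - red) / (SWIR1 + red)
* REPI = 705 + 35 * ((red + RE3)/2 - RE1) / (RE2 - RE1)   [nm]

and the season of each of 11 spectral parameters (6 bands: Blue, Green, Red,
RE2, SWIR1, SWIR2; plus the 5 indices) is summarised into:

* six statistical descriptors (min, max, std, 15/50/90th percentile),
* the "greenest" (peak-EVI window) and "wettest" (peak-LSWI window) snapshots,
* EVI harmonic-fit phase and amplitude (first-order terms of a least-squares
  Fourier series with frequency 1.5 cycles/year),
* median-threshold phenology (SOS/EOS/LOS) and the accumulated EVI between
  SOS and EOS as a biomass proxy,

for a canonical block of 94 named features per pixel.

All operations accept a single 1-D series or an (n_pixels, n_windows) matrix;
feature builders are vectorised over pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compositing import WINDOW_CENTERS
from .errors import DegeneratePhenologyError, UndefinedValueError

#: Parameters summarised by the optical feature block, in canonical order.
OPTICAL_PARAMS = ("Blue", "Green", "Red", "RE2", "SWIR1", "SWIR2",
                  "EVI", "LSWI", "RENDVI", "REPI", "NDSVI")
OPTICAL_STATS = ("min", "max", "stdDev", "p15", "p50", "p90")

#: Days used to express DOY as a fraction of the year in harmonic fitting.
DAYS_PER_YEAR = 365.0
HARMONIC_FREQ = 1.5


def _guard(den, what: str):
    if np.any(np.asarray(den) == 0):
        raise UndefinedValueError(f"{what}: zero denominator")
    return den


def evi(nir, red, blue):
    """Enhanced Vegetation Index (blue-corrected)."""
    nir, red, blue = (np.asarray(x, dtype=float) for x in (nir, red, blue))
    den = _guard(nir + 6.0 * red - 7.5 * blue + 1.0, "EVI")
    return 2.5 * (nir - red) / den


def lswi(nir, swir1):
    """Land Surface Water Index."""
    nir, swir1 = np.asarray(nir, dtype=float), np.asarray(swir1, dtype=float)
    return (nir - swir1) / _guard(nir + swir1, "LSWI")


def rendvi(nir, re2):
    """Red-edge NDVI (NIR vs second red-edge band)."""
    nir, re2 = np.asarray(nir, dtype=float), np.asarray(re2, dtype=float)
    return (nir - re2) / _guard(nir + re2, "RENDVI")


def ndsvi(swir1, red):
    """Normalized Difference Senescence Vegetation Index."""
    swir1, red = np.asarray(swir1, dtype=float), np.asarray(red, dtype=float)
    return (swir1 - red) / _guard(swir1 + red, "NDSVI")


def repi(red, re1, re2, re3):
    """Red Edge Position Index in nm (linear interpolation across the red edge)."""
    red, re1, re2, re3 = (np.asarray(x, dtype=float) for x in (red, re1, re2, re3))
    den = _guard(re2 - re1, "REPI")
    return 705.0 + 35.0 * ((red + re3) / 2.0 - re1) / den


def stat_descriptors(series, stats: tuple[str, ...] = OPTICAL_STATS) -> dict[str, float]:
    """Named summary statistics of one complete series.

    Percentiles use linear interpolation between order statistics; ``stdDev``
    is the population standard deviation.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("empty series")
    mat = stat_matrix(series[np.newaxis, :], stats)
    return {name: float(mat[name][0]) for name in stats}


def stat_matrix(matrix: np.ndarray, stats: tuple[str, ...] = OPTICAL_STATS
                ) -> dict[str, np.ndarray]:
    """Vectorised :func:`stat_descriptors` over rows of an (n, w) matrix."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if matrix.shape[1] == 0:
        raise ValueError("empty series")
    out = {}
    for name in stats:
        if name == "min":
            out[name] = matrix.min(axis=1)
        elif name == "max":
            out[name] = matrix.max(axis=1)
        elif name == "mean":
            out[name] = matrix.mean(axis=1)
        elif name == "stdDev":
            out[name] = matrix.std(axis=1)  # population form
        elif name.startswith("p"):
            out[name] = np.percentile(matrix, float(name[1:]), axis=1)
        else:
            raise ValueError(f"unknown statistic {name!r}")
    return out


@dataclass
class HarmonicFit:
    """Least-squares Fourier-series fit of a seasonal curve.

    ``f(t) = a0 + sum_k [a_k cos(2 pi k w t) + b_k sin(2 pi k w t)]`` with
    ``t = DOY / 365`` and frequency ``w``.  Phase and amplitude are taken from
    the first-order (k=1) pair.
    """

    a0: float
    a: np.ndarray
    b: np.ndarray
    order: int
    freq: float = HARMONIC_FREQ

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.a[0], self.b[0]))

    @property
    def phase(self) -> float:
        """atan2(b1, a1), in (-pi, pi]."""
        return float(np.arctan2(self.b[0], self.a[0]))

    def predict(self, doys) -> np.ndarray:
        X = _harmonic_design(np.asarray(doys, dtype=float), self.order, self.freq)
        coef = np.concatenate(([self.a0], np.ravel(np.column_stack([self.a, self.b]))))
        return X @ coef


def _harmonic_design(doys: np.ndarray, order: int, freq: float) -> np.ndarray:
    t = doys / DAYS_PER_YEAR
    cols = [np.ones_like(t)]
    for k in range(1, order + 1):
        ang = 2.0 * np.pi * k * freq * t
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
    return np.column_stack(cols)


def harmonic_fit_matrix(matrix: np.ndarray, doys, order: int = 2,
                        freq: float = HARMONIC_FREQ
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fit the harmonic model to every row; returns (a0, a, b) arrays."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    doys = np.asarray(doys, dtype=float)
    if matrix.shape[1] < 2 * order + 1:
        raise ValueError(
            f"harmonic order {order} needs >= {2 * order + 1} windows, "
            f"got {matrix.shape[1]}"
        )
    X = _harmonic_design(doys, order, freq)
    coef, *_ = np.linalg.lstsq(X, matrix.T, rcond=None)
    a0 = coef[0]
    a = coef[1::2].T
    b = coef[2::2].T
    return a0, a, b


def harmonic_fit(series, doys, order: int = 2, freq: float = HARMONIC_FREQ) -> HarmonicFit:
    """Fit one series; see :class:`HarmonicFit`."""
    a0, a, b = harmonic_fit_matrix(np.asarray(series, dtype=float)[np.newaxis, :],
                                   doys, order, freq)
    return HarmonicFit(a0=float(a0[0]), a=a[0], b=b[0], order=order, freq=freq)


@dataclass
class PhenoMetrics:
    """Median-threshold season timing extracted from an EVI series."""

    sos: float
    eos: float
    evi_at_sos: float
    evi_at_eos: float
    cum_evi: float

    @property
    def los(self) -> float:
        return self.eos - self.sos


def phenology_matrix(matrix: np.ndarray, doys,
                     degenerate: str = "raise") -> dict[str, np.ndarray]:
    """Vectorised median-threshold phenology.

    Threshold = median of each row; SOS/EOS are the DOYs of the first/last
    window whose value strictly exceeds the threshold; cum_evi sums windows in
    [SOS, EOS] inclusive.

    ``degenerate`` controls rows where nothing exceeds the median (flat or
    plateau-topped series, common on short truncated grids): ``"raise"``
    (default) raises :class:`DegeneratePhenologyError`; ``"plateau"`` collapses
    the season onto the maximal window(s): SOS / EOS become the first / last
    window attaining the row maximum.
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    doys = np.asarray(doys, dtype=float)
    thr = np.median(matrix, axis=1)
    above = matrix > thr[:, np.newaxis]
    flat = ~above.any(axis=1)
    if flat.any():
        if degenerate == "raise":
            raise DegeneratePhenologyError(
                f"{int(flat.sum())} series never exceed their own median "
                "(constant series?)"
            )
        # plateau rule: the season collapses onto the (first) maximum window
        above[flat] = matrix[flat] >= matrix[flat].max(axis=1, keepdims=True)
    first = np.argmax(above, axis=1)
    last = matrix.shape[1] - 1 - np.argmax(above[:, ::-1], axis=1)
    rows = np.arange(matrix.shape[0])
    idx = np.arange(matrix.shape[1])
    in_season = (idx >= first[:, np.newaxis]) & (idx <= last[:, np.newaxis])
    return {
        "SOS": doys[first],
        "EOS": doys[last],
        "LOS": doys[last] - doys[first],
        "evi_at_sos": matrix[rows, first],
        "evi_at_eos": matrix[rows, last],
        "cum_evi": np.where(in_season, matrix, 0.0).sum(axis=1),
    }


def phenology(evi_series, doys) -> PhenoMetrics:
    """Median-threshold phenology of one EVI series."""
    res = phenology_matrix(np.asarray(evi_series, dtype=float)[np.newaxis, :], doys)
    return PhenoMetrics(sos=float(res["SOS"][0]), eos=float(res["EOS"][0]),
                        evi_at_sos=float(res["evi_at_sos"][0]),
                        evi_at_eos=float(res["evi_at_eos"][0]),
                        cum_evi=float(res["cum_evi"][0]))


def optical_parameter_matrices(bands: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Derive the 11 spectral parameters from 9-band composite matrices.

    ``bands`` maps lowercase band keys (blue ... swir2) to (n, w) matrices.
    """
    b = {k: np.atleast_2d(np.asarray(v, dtype=float)) for k, v in bands.items()}
    return {
        "Blue": b["blue"], "Green": b["green"], "Red": b["red"],
        "RE2": b["re2"], "SWIR1": b["swir1"], "SWIR2": b["swir2"],
        "EVI": evi(b["nir"], b["red"], b["blue"]),
        "LSWI": lswi(b["nir"], b["swir1"]),
        "RENDVI": rendvi(b["nir"], b["re2"]),
        "REPI": repi(b["red"], b["re1"], b["re2"], b["re3"]),
        "NDSVI": ndsvi(b["swir1"], b["red"]),
    }


def peak_composites(params: dict[str, np.ndarray]) -> pd.DataFrame:
    """Greenest / wettest snapshots of all 11 parameters.

    The greenest (wettest) window is the argmax of EVI (LSWI) per pixel; ties
    resolve to the earliest window.  Features carry "_EVI" / "_LSWI" suffixes.
    """
    g = np.argmax(params["EVI"], axis=1)  # argmax takes the first maximum
    w = np.argmax(params["LSWI"], axis=1)
    rows = np.arange(params["EVI"].shape[0])
    cols = {}
    for name in OPTICAL_PARAMS:
        cols[f"{name}_EVI"] = params[name][rows, g]
    for name in OPTICAL_PARAMS:
        cols[f"{name}_LSWI"] = params[name][rows, w]
    return pd.DataFrame(cols)


def build_optical_features(bands: dict[str, np.ndarray], doys=None,
                           harmonic_order: int = 2,
                           include_pheno_evi: bool = False,
                           degenerate: str = "plateau") -> pd.DataFrame:
    """Full optical feature block (94 canonical features per pixel).

    Parameters
    ----------
    bands : dict band -> (n, w) gap-filled composite matrices (9 bands).
    doys : window-centre DOYs (defaults to the season grid centres).
    harmonic_order : Fourier order; phase/amplitude always come from k=1.
    include_pheno_evi : also emit EVI value at SOS and at EOS (-> 96 features).

    The harmonic pair is skipped (with the block reduced accordingly) only by
    the temporal-sweep driver when too few windows are available; here a short
    series raises instead.
    """
    params = optical_parameter_matrices(bands)
    n_windows = params["EVI"].shape[1]
    if doys is None:
        doys = WINDOW_CENTERS[:n_windows]
    doys = np.asarray(doys, dtype=float)

    cols: dict[str, np.ndarray] = {}
    for name in OPTICAL_PARAMS:
        stats = stat_matrix(params[name], OPTICAL_STATS)
        for stat in OPTICAL_STATS:
            cols[f"{name}_{stat}"] = stats[stat]
    peaks = peak_composites(params)
    for c in peaks.columns:
        cols[c] = peaks[c].to_numpy()

    pheno = phenology_matrix(params["EVI"], doys, degenerate=degenerate)
    cols["SOS"] = pheno["SOS"]
    cols["EOS"] = pheno["EOS"]
    cols["LOS"] = pheno["LOS"]

    a0, a, b = harmonic_fit_matrix(params["EVI"], doys, order=harmonic_order)
    cols["EVI_phase"] = np.arctan2(b[:, 0], a[:, 0])
    cols["EVI_amplitude"] = np.hypot(a[:, 0], b[:, 0])
    cols["EVI_cum"] = pheno["cum_evi"]

    if include_pheno_evi:
        cols["EVI_at_SOS"] = pheno["evi_at_sos"]
        cols["EVI_at_EOS"] = pheno["evi_at_eos"]
    return pd.DataFrame(cols)
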