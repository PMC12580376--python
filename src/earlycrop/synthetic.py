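"""Synthetic multi-sensor crop scenes for end-to-end pipeline testing.

Each crop (soybean, maize, rice) is described by per-band seasonal curves
built from a baseline plus one or more logistic "bell" components (a rising
logistic times a falling logistic) — the standard double-logistic phenology
model.  The default profiles encode the qualitative temporal signatures that
separate the three crops in the field:

* all crops show a bell-shaped canopy cycle in the red-edge/NIR bands and EVI,
  rising from green-up (~DOY 170) and senescing in September;
* rice is transplanted into flooded paddies: SWIR1/SWIR2 reflectance and
  VV/VH backscatter are depressed during the inundation window (DOY 120-200),
  and LSWI stays high season-long;
* soybean and maize are nearly indistinguishable until canopy closure:
  separability switches on around DOY 200, when soybean's VH (and weakly VV)
  backscatter rises above maize's as its canopy becomes structurally more
  complex and a milder SWIR / red-edge reflectance contrast emerges; soybean
  then senesces roughly 12 days earlier than maize, separating the optical
  curves further in September.

Observation noise is additive Gaussian for optical reflectance and
multiplicative gamma speckle (applied in linear power) for SAR.  Cloudy
optical acquisitions are flagged with a per-observation QA bit.  Per-sample
variability (sowing-date shifts, vigour differences) is modelled by jittering
curve timing and amplitudes, so classes overlap the way field samples do.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .compositing import db_to_linear, linear_to_db
from .errors import ConfigurationError

OPTICAL_BANDS = ("blue", "green", "red", "re1", "re2", "re3", "nir", "swir1", "swir2")
SAR_CHANNELS = ("vv", "vh")
CROP_CLASSES = ("soybean", "maize", "rice")

#: Default acquisition calendars: 5-day optical revisit, 12-day SAR revisit.
DEFAULT_OPTICAL_DOYS = tuple(range(121, 282, 5))
DEFAULT_SAR_DOYS = tuple(range(121, 282, 12))


@dataclass(frozen=True)
class LogisticBell:
    """One rise-and-fall seasonal component.

    ``amplitude * expit(rise_rate*(t-rise_doy)) * expit(-fall_rate*(t-fall_doy))``

    ``jitter_sd`` is the *relative* standard deviation of per-sample amplitude
    variability (0 disables it); it models sample-to-sample vigour differences
    that do not average out over time.
    """

    amplitude: float
    rise_doy: float
    fall_doy: float
    rise_rate: float = 0.12
    fall_rate: float = 0.12
    jitter_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.rise_doy >= self.fall_doy:
            raise ConfigurationError("green-up DOY must precede senescence DOY")

    def __call__(self, doy) -> np.ndarray:
        t = np.asarray(doy, dtype=float)
        return (self.amplitude
                * expit(self.rise_rate * (t - self.rise_doy))
                * expit(-self.fall_rate * (t - self.fall_doy)))


@dataclass(frozen=True)
class BandCurve:
    """Baseline plus seasonal components for one band or SAR channel."""

    base: float
    bells: tuple[LogisticBell, ...] = ()

    def __call__(self, doy) -> np.ndarray:
        t = np.asarray(doy, dtype=float)
        out = np.full(t.shape, self.base)
        for bell in self.bells:
            out = out + bell(t)
        return out


@dataclass
class CropProfileParams:
    """Noise-free per-band seasonal curves plus noise model for one crop."""

    crop_class: str
    curves: dict[str, BandCurve]
    flood_window: tuple[float, float] | None = None
    noise_sd: float | dict[str, float] = 0.01
    speckle_looks: int | None = 12

    def __post_init__(self) -> None:
        if self.crop_class not in CROP_CLASSES:
            raise ConfigurationError(f"unknown crop class {self.crop_class!r}")
        if self.speckle_looks is not None and self.speckle_looks < 1:
            raise ConfigurationError("speckle_looks must be >= 1")
        grid = np.arange(121, 282)
        for band in OPTICAL_BANDS:
            if band in self.curves:
                vals = self.curves[band](grid)
                if vals.min() < 0 or vals.max() > 1:
                    raise ConfigurationError(
                        f"{self.crop_class}/{band}: reflectance curve leaves [0, 1]"
                    )

    def band_noise_sd(self, band: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd.get(band, 0.0))
        return float(self.noise_sd)


@dataclass
class SceneConfig:
    """Sampling design of a synthetic scene.

    Default sample counts follow the reference field campaign (621 soybean,
    588 maize, 215 rice ground points).
    """

    n_soybean: int = 621
    n_maize: int = 588
    n_rice: int = 215
    optical_doys: tuple[int, ...] = DEFAULT_OPTICAL_DOYS
    sar_doys: tuple[int, ...] = DEFAULT_SAR_DOYS
    cloud_gap_prob: float = 0.3
    seed: int = 0
    doy_shift_sd: float = 3.0    # per-sample sowing-date jitter (days)
    amp_jitter_sd: float = 0.05  # per-sample, per-band amplitude jitter (relative)

    def __post_init__(self) -> None:
        for n in (self.n_soybean, self.n_maize, self.n_rice):
            if n < 0:
                raise ConfigurationError("sample counts must be >= 0")
        if not 0.0 <= self.cloud_gap_prob <= 1.0:
            raise ConfigurationError("cloud_gap_prob must be in [0, 1]")
        for doys in (self.optical_doys, self.sar_doys):
            arr = np.asarray(doys)
            if arr.size and (arr.min() < 121 or arr.max() > 281):
                raise ConfigurationError("observation DOYs must lie within [121, 281]")

    @property
    def counts(self) -> dict[str, int]:
        return {"soybean": self.n_soybean, "maize": self.n_maize, "rice": self.n_rice}


@dataclass
class Scene:
    """Generated labelled scene: per-sample observation matrices per sensor."""

    samples: pd.DataFrame            # columns: id, x, y, crop_class
    optical_doys: np.ndarray
    sar_doys: np.ndarray
    optical: dict[str, np.ndarray]   # band -> (n_samples, n_optical_obs) reflectance
    cloudy: np.ndarray               # (n_samples, n_optical_obs) QA cloud flags
    sar: dict[str, np.ndarray]       # channel -> (n_samples, n_sar_obs) dB
    config: SceneConfig

    @property
    def labels(self) -> np.ndarray:
        return self.samples["crop_class"].to_numpy()

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def stack(self, index: int) -> dict[str, "ObservationStack"]:
        """Single-pixel view as ObservationStacks (one per sensor)."""
        from .compositing import ObservationStack

        return {
            "optical": ObservationStack(
                doy=self.optical_doys,
                bands={b: self.optical[b][index] for b in self.optical},
                qa_cloud=self.cloudy[index],
                sensor="optical",
                pixel_id=self.samples["id"].iloc[index],
            ),
            "sar": ObservationStack(
                doy=self.sar_doys,
                bands={c: self.sar[c][index] for c in self.sar},
                qa_cloud=None,
                sensor="sar",
                pixel_id=self.samples["id"].iloc[index],
            ),
        }


def _bell(amp, rise, fall, kr=0.12, kf=0.12, jitter=0.0) -> LogisticBell:
    return LogisticBell(amp, rise, fall, kr, kf, jitter)


def default_profiles(noise_sd: float = 0.01,
                     speckle_looks: int | None = 12) -> dict[str, CropProfileParams]:
    """Default crop profiles encoding the orderings described in the module docstring.

    Soybean and maize share identical optical curves except for a
    class-specific divergence component switching on near DOY 200 (SAR) /
    DOY 215 (optical) and earlier soybean senescence; rice carries the flood
    depression on SWIR and SAR channels during DOY 120-200.
    """
    upland_optical = {
        "blue": BandCurve(0.060, (_bell(-0.025, 170, 255),)),
        "green": BandCurve(0.080, (_bell(-0.015, 170, 255),)),
        "red": BandCurve(0.090, (_bell(-0.055, 170, 255),)),
        "re1": BandCurve(0.110, (_bell(-0.020, 170, 255),)),
    }
    soy_optical = dict(
        upland_optical,
        re2=BandCurve(0.160, (_bell(0.180, 170, 250),)),
        re3=BandCurve(0.180, (_bell(0.190, 170, 250),)),
        nir=BandCurve(0.200, (_bell(0.220, 170, 250),)),
        # soybean keeps higher SWIR than maize during DOY 200-260
        swir1=BandCurve(0.260, (_bell(-0.070, 170, 255),
                                _bell(0.022, 197, 258, 0.25, 0.2, 0.15))),
        swir2=BandCurve(0.220, (_bell(-0.080, 170, 255),
                                _bell(0.018, 197, 258, 0.25, 0.2, 0.15))),
    )
    maize_optical = dict(
        upland_optical,
        re2=BandCurve(0.160, (_bell(0.180, 170, 262),
                              _bell(-0.018, 197, 262, 0.25, 0.2, 0.15))),
        re3=BandCurve(0.180, (_bell(0.190, 170, 262),)),
        nir=BandCurve(0.200, (_bell(0.220, 170, 262),)),
        swir1=BandCurve(0.260, (_bell(-0.070, 170, 262),)),
        swir2=BandCurve(0.220, (_bell(-0.080, 170, 262),)),
    )
    rice_optical = {
        "blue": BandCurve(0.055, (_bell(-0.020, 185, 268),)),
        "green": BandCurve(0.075, (_bell(-0.010, 185, 268),)),
        "red": BandCurve(0.085, (_bell(-0.050, 185, 268),)),
        "re1": BandCurve(0.105, (_bell(-0.015, 185, 268),)),
        "re2": BandCurve(0.150, (_bell(0.170, 185, 268),)),
        "re3": BandCurve(0.170, (_bell(0.180, 185, 268),)),
        "nir": BandCurve(0.190, (_bell(0.210, 185, 268),)),
        "swir1": BandCurve(0.210, (_bell(-0.050, 185, 268),
                                   _bell(-0.080, 118, 200, 0.25, 0.25))),
        "swir2": BandCurve(0.180, (_bell(-0.050, 185, 268),
                                   _bell(-0.060, 118, 200, 0.25, 0.25))),
    }

    upland_sar = {
        "vv": (BandCurve(-14.0, (_bell(4.0, 160, 265, 0.08, 0.2),)),),
        "vh": (BandCurve(-20.0, (_bell(5.0, 160, 265, 0.08, 0.2),)),),
    }
    soy_sar = {
        # canopy-structure divergence switching on near DOY 200
        "vv": BandCurve(-14.0, (_bell(4.0, 160, 265, 0.08, 0.2),
                                _bell(1.5, 197, 258, 0.5, 0.25, 0.30))),
        "vh": BandCurve(-20.0, (_bell(5.0, 160, 265, 0.08, 0.2),
                                _bell(3.0, 197, 258, 0.5, 0.25, 0.30))),
    }
    maize_sar = {
        "vv": BandCurve(-14.0, (_bell(4.0, 160, 265, 0.08, 0.2),
                                _bell(0.4, 197, 258, 0.5, 0.25, 0.30))),
        "vh": BandCurve(-20.0, (_bell(5.0, 160, 265, 0.08, 0.2),
                                _bell(0.7, 197, 258, 0.5, 0.25, 0.30))),
    }
    rice_sar = {
        "vv": BandCurve(-14.0, (_bell(3.0, 185, 268, 0.08, 0.2),
                                _bell(-5.0, 118, 205, 0.3, 0.3))),
        "vh": BandCurve(-20.0, (_bell(3.5, 185, 268, 0.08, 0.2),
                                _bell(-6.0, 118, 205, 0.3, 0.3))),
    }

    return {
        "soybean": CropProfileParams("soybean", {**soy_optical, **soy_sar},
                                     noise_sd=noise_sd, speckle_looks=speckle_looks),
        "maize": CropProfileParams("maize", {**maize_optical, **maize_sar},
                                   noise_sd=noise_sd, speckle_looks=speckle_looks),
        "rice": CropProfileParams("rice", {**rice_optical, **rice_sar},
                                  flood_window=(120.0, 200.0),
                                  noise_sd=noise_sd, speckle_looks=speckle_looks),
    }


def generate_crop_profile(params: CropProfileParams, doy_grid) -> dict[str, np.ndarray]:
    """Noise-free mean curve per band/channel sampled on ``doy_grid``."""
    grid = np.asarray(doy_grid, dtype=float)
    if np.any(np.diff(grid) < 0):
        raise ConfigurationError("doy_grid must be sorted ascending")
    return {name: curve(grid) for name, curve in params.curves.items()}


def inject_speckle(power, looks: int, rng) -> np.ndarray:
    """Multiply linear power by unit-mean gamma speckle with the given looks.

    ``rng`` may be a ``numpy.random.Generator`` or an integer seed.  The
    expected value is preserved: E[gamma(L, 1/L)] = 1.
    """
    power = np.asarray(power, dtype=float)
    if looks < 1:
        raise ConfigurationError("looks must be >= 1")
    if np.any(power <= 0):
        raise ConfigurationError("linear power must be > 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return power * rng.gamma(shape=looks, scale=1.0 / looks, size=power.shape)


def _sample_curves(curves: dict[str, BandCurve], names, doys, rng,
                   shift: np.ndarray, config: SceneConfig) -> dict[str, np.ndarray]:
    """Evaluate curves for n samples with per-sample timing/amplitude jitter.

    ``shift`` is the (n, 1) per-sample sowing-date offset, shared across
    sensors so a late-sown sample is late in both optical and SAR series.
    Setting ``config.amp_jitter_sd = 0`` disables *all* per-sample amplitude
    variability, including the per-component ``jitter_sd`` of the profiles,
    so fully deterministic (noise-free) scenes can be generated.
    """
    doys = np.asarray(doys, dtype=float)
    n = shift.shape[0]
    deterministic = config.amp_jitter_sd == 0
    out = {}
    for name in names:
        curve = curves[name]
        band_scale = (np.ones((n, 1)) if deterministic
                      else rng.normal(1.0, config.amp_jitter_sd, size=(n, 1)))
        vals = np.full((n, doys.size), curve.base)
        t = doys[np.newaxis, :] - shift
        for bell in curve.bells:
            bell_scale = (rng.normal(1.0, bell.jitter_sd, size=(n, 1))
                          if bell.jitter_sd > 0 and not deterministic else 1.0)
            vals = vals + band_scale * bell_scale * bell(t)
        out[name] = vals
    return out


def generate_scene(config: SceneConfig,
                   profiles: dict[str, CropProfileParams] | None = None) -> Scene:
    """Generate a labelled scene; identical config (incl. seed) gives identical output."""
    if profiles is None:
        profiles = default_profiles()
    counts = config.counts
    if sum(counts.values()) == 0:
        raise ConfigurationError("at least one sample is required")
    for crop, n in counts.items():
        if n > 0 and crop not in profiles:
            raise ConfigurationError(f"no profile supplied for {crop!r}")

    rng = np.random.default_rng(config.seed)
    opt_doys = np.asarray(config.optical_doys, dtype=int)
    sar_doys = np.asarray(config.sar_doys, dtype=int)

    rows = []
    optical = {b: [] for b in OPTICAL_BANDS}
    sar = {c: [] for c in SAR_CHANNELS}
    cloudy_parts = []
    idx0 = 0
    for crop in CROP_CLASSES:
        n = counts[crop]
        if n == 0:
            continue
        prof = profiles[crop]
        shift = (rng.normal(0.0, config.doy_shift_sd, size=(n, 1))
                 if config.doy_shift_sd > 0 else np.zeros((n, 1)))
        curves_opt = _sample_curves(prof.curves, OPTICAL_BANDS, opt_doys, rng,
                                    shift, config)
        for band in OPTICAL_BANDS:
            sd = prof.band_noise_sd(band)
            vals = curves_opt[band]
            if sd > 0:
                vals = vals + rng.normal(0.0, sd, size=vals.shape)
            optical[band].append(np.clip(vals, 0.0, 1.0))
        curves_sar = _sample_curves(prof.curves, SAR_CHANNELS, sar_doys, rng,
                                    shift, config)
        for ch in SAR_CHANNELS:
            db = curves_sar[ch]
            if prof.speckle_looks is not None:
                db = linear_to_db(inject_speckle(db_to_linear(db),
                                                 prof.speckle_looks, rng))
            sar[ch].append(db)
        cloudy_parts.append(rng.random((n, opt_doys.size)) < config.cloud_gap_prob)
        xy = rng.uniform(0.0, 10_000.0, size=(n, 2))
        for i in range(n):
            rows.append((idx0 + i, xy[i, 0], xy[i, 1], crop))
        idx0 += n

    samples = pd.DataFrame(rows, columns=["id", "x", "y", "crop_class"])
    return Scene(
        samples=samples,
        optical_doys=opt_doys,
        sar_doys=sar_doys,
        optical={b: np.vstack(optical[b]) for b in OPTICAL_BANDS},
        cloudy=np.vstack(cloudy_parts),
        sar={c: np.vstack(sar[c]) for c in SAR_CHANNELS},
        config=config,
    )
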