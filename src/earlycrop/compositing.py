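"""Ten-day median compositing and gap filling of irregular satellite time series.

Optical acquisitions arrive at irregular day-of-year (DOY) intervals, and cloud
masking removes an unpredictable subset of them.  SAR acquisitions are
cloud-insensitive but follow their own revisit cadence.  Both sensors are
brought onto a common regular grid of sixteen 10-day windows spanning the
growing season (DOY 121-280, i.e. May 1 to October 7): within each window the
median of all valid observations is taken, and windows left empty are filled by
linear interpolation between the nearest observed windows (nearest-value
extrapolation at the ends).

Backscatter conversion helpers (dB <-> linear power) live here as well since
compositing and speckle statistics need both representations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, UnusablePixelError

#: Number of 10-day windows in the season grid.
N_WINDOWS = 16

#: First DOY of each window: 121, 131, ..., 271 (May 1 anchor).
WINDOW_STARTS = np.arange(121, 121 + 10 * N_WINDOWS, 10)

#: Last DOY of each window: 130, 140, ..., 280.
WINDOW_ENDS = WINDOW_STARTS + 9

#: Window-center DOY used as the interpolation / fitting abscissa.
WINDOW_CENTERS = WINDOW_STARTS + 4.5


@dataclass
class ObservationStack:
    """Irregular timestamped observations for a single pixel.

    Parameters
    ----------
    doy : array of int
        Acquisition day-of-year per observation, sorted ascending.
    bands : dict of str -> array
        Per-band values aligned with ``doy`` (surface reflectance in [0, 1]
        for optical bands, backscatter in dB for SAR channels).
    qa_cloud : bool array or None
        Per-observation cloud flag (optical sensors only).
    sensor : {"optical", "sar"}
    pixel_id : hashable
    """

    doy: np.ndarray
    bands: dict[str, np.ndarray]
    qa_cloud: np.ndarray | None = None
    sensor: str = "optical"
    pixel_id: object = None

    def __post_init__(self) -> None:
        self.doy = np.asarray(self.doy, dtype=int)
        if np.any(np.diff(self.doy) < 0):
            raise ConfigurationError("observations must be sorted by DOY")
        self.bands = {k: np.asarray(v, dtype=float) for k, v in self.bands.items()}
        for name, vals in self.bands.items():
            if vals.shape != self.doy.shape:
                raise ConfigurationError(
                    f"band {name!r} has {vals.size} values for {self.doy.size} DOYs"
                )
        if self.qa_cloud is not None:
            self.qa_cloud = np.asarray(self.qa_cloud, dtype=bool)
            if self.qa_cloud.shape != self.doy.shape:
                raise ConfigurationError("qa_cloud length must match doy length")

    @property
    def n_obs(self) -> int:
        return int(self.doy.size)


@dataclass
class CompositeSeries:
    """One band's values on the regular 10-day grid.

    ``values`` holds NaN for windows with no valid observation until
    :func:`fill_gaps_linear` is applied; ``filled`` marks gap-filled windows.
    """

    band: str
    values: np.ndarray
    filled: np.ndarray = field(default=None)  # type: ignore[assignment]
    centers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.centers is None:
            self.centers = WINDOW_CENTERS[: self.values.size].copy()
        if self.filled is None:
            self.filled = np.zeros(self.values.size, dtype=bool)
        self.filled = np.asarray(self.filled, dtype=bool)

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)


def mask_clouds(stack: ObservationStack) -> ObservationStack:
    """Drop cloud-flagged observations from an optical stack.

    SAR stacks (or stacks without QA flags) pass through unchanged.
    """
    if stack.sensor != "optical" or stack.qa_cloud is None:
        return stack
    keep = ~stack.qa_cloud
    return replace(
        stack,
        doy=stack.doy[keep],
        bands={k: v[keep] for k, v in stack.bands.items()},
        qa_cloud=stack.qa_cloud[keep],
    )


def composite_matrix(
    doys: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray | None = None,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Median-composite many pixels at once.

    Parameters
    ----------
    doys : (n_obs,) int array
        Shared observation DOYs.
    values : (n_pixels, n_obs) array
    valid : optional bool array broadcastable to ``values``
        False marks observations to exclude (e.g. cloudy).
    grid : optional (starts, ends)
        Custom window bounds; defaults to the 16-window season grid.

    Returns
    -------
    (n_pixels, n_windows) array with NaN where a window has no valid data.
    """
    starts, ends = grid if grid is not None else (WINDOW_STARTS, WINDOW_ENDS)
    doys = np.asarray(doys)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    work = values.copy()
    if valid is not None:
        work[~np.broadcast_to(valid, work.shape)] = np.nan
    out = np.full((work.shape[0], len(starts)), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        for w, (lo, hi) in enumerate(zip(starts, ends)):
            sel = (doys >= lo) & (doys <= hi)
            if sel.any():
                out[:, w] = np.nanmedian(work[:, sel], axis=1)
    return out


def median_composite(
    stack: ObservationStack,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> dict[str, CompositeSeries]:
    """10-day median composite of a (cloud-masked) single-pixel stack.

    The median of an even observation count is the mean of the two middle
    values.  Windows with zero observations are NaN (``missing``).
    """
    starts, _ = grid if grid is not None else (WINDOW_STARTS, WINDOW_ENDS)
    centers = np.asarray(starts, dtype=float) + 4.5
    out = {}
    for name, vals in stack.bands.items():
        comp = composite_matrix(stack.doy, vals[np.newaxis, :], grid=grid)[0]
        out[name] = CompositeSeries(band=name, values=comp, centers=centers)
    return out


def fill_gaps_matrix(matrix: np.ndarray, centers: np.ndarray | None = None,
                     on_empty: str = "raise") -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate NaN windows row-wise; extrapolate ends by nearest value.

    Returns ``(filled_values, filled_mask)``.  Rows that are entirely NaN raise
    :class:`UnusablePixelError` (``on_empty="raise"``) or stay NaN
    (``on_empty="nan"``).
    """
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    if centers is None:
        centers = WINDOW_CENTERS[: matrix.shape[1]]
    out = matrix.copy()
    missing = np.isnan(matrix)
    empty_rows = missing.all(axis=1)
    if empty_rows.any() and on_empty == "raise":
        raise UnusablePixelError(
            f"{int(empty_rows.sum())} pixel(s) have no valid windows to interpolate from"
        )
    for i in np.nonzero(missing.any(axis=1) & ~empty_rows)[0]:
        obs = ~missing[i]
        # np.interp holds end values constant outside the observed range,
        # which is exactly the nearest-value extrapolation rule.
        out[i, missing[i]] = np.interp(centers[missing[i]], centers[obs], matrix[i, obs])
    return out, missing & ~empty_rows[:, None]


def fill_gaps_linear(series: CompositeSeries) -> CompositeSeries:
    """Gap-fill one composite series (see :func:`fill_gaps_matrix`).

    Observed windows are never modified; a series with no observed window at
    all raises :class:`UnusablePixelError`.
    """
    values, filled = fill_gaps_matrix(series.values[np.newaxis, :], series.centers)
    return replace(series, values=values[0], filled=filled[0])


def db_to_linear(x):
    """Convert backscatter from decibels to linear power: ``10**(x/10)``."""
    return np.power(10.0, np.asarray(x, dtype=float) / 10.0)


def linear_to_db(x):
    """Convert linear power to decibels: ``10*log10(x)``; requires ``x > 0``."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("linear power must be > 0 for dB conversion")
    return 10.0 * np.log10(x)
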