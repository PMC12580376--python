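"""Accuracy assessment: confusion matrix, OA/PA/UA/F1/Kappa, area accuracy, EIT.

Conventions (rows = reference, columns = prediction):

* OA = trace / n
* PA (producer's accuracy, omission side) = diagonal / reference row total
* UA (user's accuracy, commission side)   = diagonal / predicted column total
* F1 = 2 * UA * PA / (UA + PA)
* Kappa = (OA - p_e) / (1 - p_e) with chance agreement p_e from the marginals
* Area accuracy = 1 - |A_gt - A_rs| / A_gt (unclamped; negative when the
  mapped area is more than double the reference area)

The Earliest Identifiable Time (EIT) is the end DOY of the first temporal
round whose soybean F1 strictly exceeds 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASSES = ("soybean", "maize", "rice")


@dataclass
class ConfusionMatrix:
    """Square count matrix; ``counts[i, j]`` = reference class i predicted as j."""

    counts: np.ndarray
    classes: tuple[str, ...] = CLASSES

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square over the class set")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def index(self, cls: str) -> int:
        return self.classes.index(cls)


def confusion(reference, predicted, classes: tuple[str, ...] = CLASSES) -> ConfusionMatrix:
    """Count reference/prediction label pairs into a confusion matrix."""
    reference = np.asarray(reference)
    predicted = np.asarray(predicted)
    if reference.shape != predicted.shape:
        raise ValueError("label vectors must have equal length")
    lookup = {c: i for i, c in enumerate(classes)}
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    try:
        ref_idx = np.array([lookup[r] for r in reference])
        pred_idx = np.array([lookup[p] for p in predicted])
    except KeyError as exc:
        raise ValueError(f"unknown label {exc.args[0]!r}") from exc
    np.add.at(counts, (ref_idx, pred_idx), 1)
    return ConfusionMatrix(counts=counts, classes=tuple(classes))


@dataclass
class MetricsReport:
    """Per-class and overall accuracy metrics from one confusion matrix."""

    oa: float
    kappa: float
    pa: dict[str, float]
    ua: dict[str, float]
    f1: dict[str, float]
    n: int
    undefined: list[str] = field(default_factory=list)
    area_gt: float | None = None
    area_rs: float | None = None
    area_acc: float | None = None

    def f1_for(self, cls: str = "soybean") -> float:
        return self.f1[cls]

    def as_dict(self) -> dict:
        out = {"OA": self.oa, "Kappa": self.kappa, "n": self.n}
        for cls in self.pa:
            out[f"PA_{cls}"] = self.pa[cls]
            out[f"UA_{cls}"] = self.ua[cls]
            out[f"F1_{cls}"] = self.f1[cls]
        if self.area_acc is not None:
            out["area_gt_ha"] = self.area_gt
            out["area_rs_ha"] = self.area_rs
            out["area_accuracy"] = self.area_acc
        return out


def f1_score(pa: float, ua: float) -> float:
    """Harmonic mean of producer's and user's accuracy."""
    if pa + ua == 0:
        return 0.0
    return 2.0 * ua * pa / (ua + pa)


def metrics(cm: ConfusionMatrix, swap_pa_ua: bool = False,
            area_gt: float | None = None, area_rs: float | None = None
            ) -> MetricsReport:
    """Compute OA, Kappa and per-class PA/UA/F1 from a confusion matrix.

    ``swap_pa_ua=True`` divides PA by the predicted total and UA by the
    reference total instead (a non-standard variant seen in some reports).
    Classes with a zero row or column total get NaN for the affected rates and
    are listed in ``undefined``.
    """
    counts = cm.counts.astype(float)
    n = counts.sum()
    if n <= 0:
        raise ValueError("confusion matrix is empty")
    diag = np.diag(counts)
    row = counts.sum(axis=1)   # reference totals
    col = counts.sum(axis=0)   # predicted totals
    oa = diag.sum() / n
    pe = float(row @ col) / (n * n)
    kappa = (oa - pe) / (1.0 - pe) if pe < 1.0 else 1.0

    pa, ua, f1, undefined = {}, {}, {}, []
    for i, cls in enumerate(cm.classes):
        p = diag[i] / row[i] if row[i] > 0 else np.nan
        u = diag[i] / col[i] if col[i] > 0 else np.nan
        if swap_pa_ua:
            p, u = u, p
        if np.isnan(p) or np.isnan(u):
            undefined.append(cls)
            f1[cls] = np.nan
        else:
            f1[cls] = f1_score(p, u)
        pa[cls], ua[cls] = p, u

    report = MetricsReport(oa=float(oa), kappa=float(kappa), pa=pa, ua=ua, f1=f1,
                           n=int(n), undefined=undefined)
    if area_gt is not None and area_rs is not None:
        report.area_gt = float(area_gt)
        report.area_rs = float(area_rs)
        report.area_acc = area_accuracy(area_gt, area_rs)
    return report


def area_accuracy(area_gt: float, area_rs: float) -> float:
    """``1 - |A_gt - A_rs| / A_gt``; requires a positive reference area.

    Returned unclamped: values below zero indicate the mapped area differs
    from the reference by more than the reference area itself.
    """
    if area_gt <= 0:
        raise ValueError("reference area must be > 0")
    return 1.0 - abs(area_gt - area_rs) / area_gt


def aggregate_area(class_map, pixel_area: float = 0.01,
                   classes: tuple[str, ...] = CLASSES) -> dict[str, float]:
    """Per-class area in hectares: pixel count x pixel area (0.01 ha at 10 m).

    ``nodata`` pixels are ignored; classes absent from the map report 0.
    """
    flat = np.asarray(class_map).ravel()
    return {cls: float(np.count_nonzero(flat == cls) * pixel_area) for cls in classes}


def earliest_identifiable_time(f1_by_round: dict[int, float],
                               threshold: float = 0.9) -> int | None:
    """End DOY of the first round whose F1 strictly exceeds the threshold.

    ``f1_by_round`` maps round-end DOY -> soybean F1.  Returns None if the
    threshold is never exceeded.
    """
    for doy in sorted(f1_by_round):
        f1 = f1_by_round[doy]
        if f1 is not None and not np.isnan(f1) and f1 > threshold:
            return int(doy)
    return None
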