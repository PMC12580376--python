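"""Plain-text serialization of scenes, features, metrics and run manifests.

Everything is written as CSV / YAML / JSON so runs are portable and
diff-able: a scene directory holds one wide CSV per band (rows = samples,
columns = observation DOYs), the sample table, the cloud-flag matrix and a
YAML config capturing every generator parameter including the seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import OPTICAL_BANDS, SAR_CHANNELS, Scene, SceneConfig


def _doy_columns(doys) -> list[str]:
    return [f"doy_{int(d)}" for d in doys]


def write_scene(scene: Scene, directory) -> Path:
    """Write a scene to a directory of CSVs plus a YAML config; returns the path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scene.samples.to_csv(directory / "samples.csv", index=False)
    opt_cols = _doy_columns(scene.optical_doys)
    sar_cols = _doy_columns(scene.sar_doys)
    for band in OPTICAL_BANDS:
        pd.DataFrame(scene.optical[band], columns=opt_cols).to_csv(
            directory / f"optical_{band}.csv", index=False)
    pd.DataFrame(scene.cloudy.astype(int), columns=opt_cols).to_csv(
        directory / "optical_cloud.csv", index=False)
    for ch in SAR_CHANNELS:
        pd.DataFrame(scene.sar[ch], columns=sar_cols).to_csv(
            directory / f"sar_{ch}.csv", index=False)
    with open(directory / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(scene.config), fh, sort_keys=False)
    return directory


def read_scene(directory) -> Scene:
    """Load a scene written by :func:`write_scene`."""
    directory = Path(directory)
    with open(directory / "config.yaml") as fh:
        raw = yaml.safe_load(fh)
    raw["optical_doys"] = tuple(raw["optical_doys"])
    raw["sar_doys"] = tuple(raw["sar_doys"])
    config = SceneConfig(**raw)
    samples = pd.read_csv(directory / "samples.csv")
    optical = {band: pd.read_csv(directory / f"optical_{band}.csv").to_numpy(float)
               for band in OPTICAL_BANDS}
    cloudy = pd.read_csv(directory / "optical_cloud.csv").to_numpy(int).astype(bool)
    sar = {ch: pd.read_csv(directory / f"sar_{ch}.csv").to_numpy(float)
           for ch in SAR_CHANNELS}
    return Scene(samples=samples, optical_doys=np.asarray(config.optical_doys),
                 sar_doys=np.asarray(config.sar_doys), optical=optical,
                 cloudy=cloudy, sar=sar, config=config)


def write_manifest(path, **entries) -> None:
    """Record run configuration (parameters, seeds, package versions) as YAML."""
    import sklearn

    import earlycrop

    meta = {
        "earlycrop_version": earlycrop.__version__,
        "numpy_version": np.__version__,
        "sklearn_version": sklearn.__version__,
    }
    meta.update(entries)
    with open(path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def write_metrics(report_dict: dict, stem) -> None:
    """Write a metrics mapping as both JSON and a one-row CSV."""
    stem = Path(stem)
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(report_dict, fh, indent=2, default=float)
    pd.json_normalize(report_dict).to_csv(stem.with_suffix(".csv"), index=False)
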