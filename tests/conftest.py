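import numpy as np
import pytest

import earlycrop as ec


@pytest.fixture(scope="session")
def profiles():
    return ec.default_profiles()


@pytest.fixture(scope="session")
def small_scene():
    """Reduced scene with default noise/cloud conditions for fast tests."""
    return ec.generate_scene(
        ec.SceneConfig(n_soybean=60, n_maize=60, n_rice=30, seed=11)
    )


@pytest.fixture(scope="session")
def noisefree_scene():
    """Deterministic scene: no noise, no speckle, no clouds, no jitter.

    One observation per 10-day window (DOY 125, 135, ..., 275) so composites
    equal the profile curves sampled at the observation days exactly.
    """
    profs = ec.default_profiles(noise_sd=0.0, speckle_looks=None)
    cfg = ec.SceneConfig(
        n_soybean=4, n_maize=4, n_rice=4,
        optical_doys=tuple(range(125, 276, 10)),
        sar_doys=tuple(range(125, 276, 10)),
        cloud_gap_prob=0.0, seed=3, doy_shift_sd=0.0, amp_jitter_sd=0.0,
    )
    return ec.generate_scene(cfg, profs)


@pytest.fixture(scope="session")
def small_feature_table(small_scene):
    from earlycrop import classify, pipeline

    samples = classify.split_samples(small_scene.samples, seed=11)
    bundle = pipeline.composite_scene(small_scene)
    table, notes = pipeline.build_feature_table(bundle, samples)
    return table


def percentile_oracle(values, q):
    """Independent linear-interpolation percentile between order statistics."""
    v = np.sort(np.asarray(values, dtype=float))
    pos = q / 100.0 * (v.size - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac
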