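import numpy as np
import pytest

import gliohab as gh


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom (64 mm grid) used where full-size runs would be slow."""
    return gh.PhantomSpec(
        grid=gh.ImageGrid((64, 64, 64)),
        zone_radii=(12.0, 15.5, 18.0, 20.0, 21.8),
        halo_radius=25.0,
        speckle_fraction=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = gh.PhantomSpec(separation=0.0)
    return gh.generate_phantom(spec, seed=11)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Default-geometry phantom at 4-sigma class separation (no speckles)."""
    spec = gh.PhantomSpec(speckle_fraction=0.0)
    return gh.generate_phantom(spec, seed=42)


def dice_per_habitat(pred: np.ndarray, truth: np.ndarray) -> dict[int, float]:
    """Dice = 2|A&B| / (|A|+|B|) per habitat non-empty in the truth labels."""
    out = {}
    for h in range(1, 9):
        a, b = pred == h, truth == h
        if b.sum() == 0:
            continue
        out[h] = 2.0 * (a & b).sum() / (a.sum() + b.sum())
    return out


def between_class_variance(values: np.ndarray, t: float) -> float:
    """Data-based (not histogram) between-class variance of the split at t."""
    vals = np.asarray(values, dtype=float)
    lo, hi = vals[vals <= t], vals[vals > t]
    if lo.size == 0 or hi.size == 0:
        return -np.inf
    w0 = lo.size / vals.size
    return w0 * (1 - w0) * (lo.mean() - hi.mean()) ** 2


def assert_otsu_near_oracle(values: np.ndarray, threshold: float, n_bins: int) -> None:
    """The histogram threshold must classify like the exhaustive optimum up to
    one bin width — or sit on a variance plateau, achieving a between-class
    variance within discretization error of the exhaustive maximum."""
    values = np.asarray(values, dtype=float)
    oracle_t = brute_force_otsu(values)
    bin_w = (values.max() - values.min()) / n_bins
    disagree = (values <= threshold) != (values <= oracle_t)
    if np.all(np.abs(values[disagree] - threshold) <= bin_w + 1e-9):
        return
    achieved = between_class_variance(values, threshold)
    optimal = between_class_variance(values, oracle_t)
    assert achieved >= (1.0 - 1e-3) * optimal


def brute_force_otsu(values: np.ndarray) -> float:
    """Exhaustive between-class-variance maximization over distinct-value midpoints."""
    vals = np.sort(np.asarray(values, dtype=float))
    distinct = np.unique(vals)
    assert distinct.size >= 2
    best_t, best_s = None, -np.inf
    n = vals.size
    for a, b in zip(distinct[:-1], distinct[1:]):
        t = 0.5 * (a + b)
        lo = vals[vals <= t]
        hi = vals[vals > t]
        w0, w1 = lo.size / n, hi.size / n
        s = w0 * w1 * (lo.mean() - hi.mean()) ** 2
        if s > best_s + 1e-15:
            best_s, best_t = s, t
    return best_t
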