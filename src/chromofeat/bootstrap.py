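"""Percentile-bootstrap confidence intervals used across profile modules."""

from __future__ import annotations

import numpy as np


def percentile_ci(
    values: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
    chunk: int = 200,
) -> tuple[float, float, float]:
    """Mean of ``values`` with a (1-alpha) percentile bootstrap CI.

    Resamples the values with replacement ``n_boot`` times and takes the
    alpha/2 and 1-alpha/2 quantiles of the replicate means.  Deterministic
    for a fixed seed/Generator.  Returns ``(mean, lo, hi)``; NaNs when
    ``values`` is empty.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return float("nan"), float("nan"), float("nan")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    mean = float(values.mean())
    n = values.size
    reps = np.empty(n_boot)
    done = 0
    while done < n_boot:
        m = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(m, n))
        reps[done : done + m] = values[idx].mean(axis=1)
        done += m
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return mean, float(lo), float(hi)


def ratio_of_sums_ci(
    num: np.ndarray,
    den: np.ndarray,
    n_boot: int = 2000,
    alpha: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """Bootstrap CI for sum(num)/sum(den) resampling paired observations."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if num.size == 0:
        raise ValueError("empty scope: no observations to bootstrap")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    est = float(num.sum() / den.sum())
    n = num.size
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = num[idx].sum(axis=1) / den[idx].sum(axis=1)
    lo, hi = np.quantile(reps, [alpha / 2, 1 - alpha / 2])
    return est, float(lo), float(hi)
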