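"""Group-comparison statistics: pooled-variance two-sample t-tests, Cohen's
d effect sizes, and percentile bootstrap confidence intervals for means."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "two_sample_ttest", "cohens_d", "bootstrap_mean_ci"]


@dataclass
class StatResult:
    t: float
    p: float
    cohens_d: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def summary(self) -> str:
        return (
            f"a: {self.mean_a:.4g} ± {self.sd_a:.4g} (n={self.n_a}); "
            f"b: {self.mean_b:.4g} ± {self.sd_b:.4g} (n={self.n_b}); "
            f"t = {self.t:.3f}, p = {self.p:.3g}, d = {self.cohens_d:.3f}"
        )


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    return float(np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)))


def cohens_d(a, b) -> float:
    """Effect size (mean_b - mean_a) / pooled SD (n-weighted pooling).

    NaN when the pooled SD is zero.
    """

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    sd = _pooled_sd(a, b)
    if sd == 0:
        return float("nan")
    return float((b.mean() - a.mean()) / sd)


def two_sample_ttest(a, b) -> StatResult:
    """Standard pooled-variance two-sample t-test, two-sided p."""

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    if _pooled_sd(a, b) == 0:
        t, p = (0.0, 1.0) if a.mean() == b.mean() else (float("inf"), 0.0)
    else:
        t, p = sps.ttest_ind(b, a, equal_var=True)
    return StatResult(
        t=float(t),
        p=float(p),
        cohens_d=cohens_d(a, b),
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        n_b=int(b.size),
    )


def bootstrap_mean_ci(
    sample,
    n_boot: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Percentile bootstrap of the mean: (mean, lower, upper)."""

    x = np.asarray(sample, dtype=float)
    if x.size < 2:
        raise ValueError("need n >= 2")
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    means = x[idx].mean(axis=1)
    lo, hi = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(x.mean()), float(lo), float(hi)
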