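"""Cohort analysis: mean sensitivity, repeatability, bootstrap inference.

The analysis layer mirrors how a test-retest validation study of a
perimeter is analysed:

* **Mean sensitivity (MS)**: mean of the 44 test-point sensitivities,
  excluding the two blind-spot locations.
* **Bland-Altman repeatability** of paired runs: mean difference mu and
  the 95% coefficient of repeatability CoR95 = 1.96 x SD of the paired
  differences (sample SD); the 95% limits of agreement are mu +/- CoR95.
* **BCa bootstrap confidence intervals** (bias-corrected and accelerated
  percentile, default N = 20,000 resamples) for arbitrary statistics.
* **CoR difference test** between two devices: a nonparametric
  within-observer device-label permutation builds the null for
  Delta = CoR_A - CoR_B, two-sided, with add-one smoothing.
* **Pointwise paired comparisons** between devices with Bonferroni
  control (default alpha = 0.01 over the full grid).
* **Normative tables**: per-location mean and 2.5th/97.5th percentiles
  pooled over all tests, right-eye format, linear-interpolation
  percentile convention.
* **Minimum detectable difference** for a paired design (post hoc power):
  ``(t_{1-alpha/2, n-1} + t_{power, n-1}) * sd / sqrt(n)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .grid import ROLE_TEST, TestGrid, to_right_eye_format

__all__ = [
    "CohortResults",
    "RepeatabilitySummary",
    "mean_sensitivity",
    "bland_altman",
    "bca_bootstrap_ci",
    "cor95",
    "cor_difference_test",
    "pointwise_comparison",
    "normative_table",
    "min_detectable_difference",
]


@dataclass
class CohortResults:
    """Paired pointwise results: per device, (n_observers, n_runs, n_locations).

    Observers index identically across devices and runs; values are on the
    screen's attenuation-dB scale.
    """

    values: dict[str, np.ndarray]
    grid: TestGrid

    def __post_init__(self) -> None:
        shapes = {k: np.asarray(v).shape for k, v in self.values.items()}
        n_obs = {s[0] for s in shapes.values()}
        if len(n_obs) > 1:
            raise ValueError(f"devices must share observers, got shapes {shapes}")
        for k, v in self.values.items():
            self.values[k] = np.asarray(v, dtype=float)

    @property
    def devices(self) -> list[str]:
        return list(self.values)

    def ms(self, device: str) -> np.ndarray:
        """(n_observers, n_runs) mean-sensitivity array for one device."""
        vals = self.values[device]
        return np.apply_along_axis(lambda v: mean_sensitivity(v, self.grid),
                                   -1, vals)


@dataclass(frozen=True)
class RepeatabilitySummary:
    mean_difference: float
    cor95: float
    limits_of_agreement: tuple[float, float]
    n: int
    ci_mean_difference: tuple[float, float] | None = None
    ci_cor95: tuple[float, float] | None = None


def mean_sensitivity(values, grid: TestGrid) -> float:
    """MS: mean of test-role values; blind-spot locations are excluded."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(grid):
        raise ValueError("values must align with grid locations")
    mask = np.array([l.role == ROLE_TEST for l in grid])
    return float(np.mean(values[mask]))


def cor95(differences) -> float:
    """95% coefficient of repeatability: 1.96 x sample SD of differences."""
    d = np.asarray(differences, dtype=float)
    if len(d) < 2:
        raise ValueError("need at least two paired differences")
    return float(1.96 * np.std(d, ddof=1))


def bland_altman(run1, run2, *, n_boot: int = 0, seed: int | None = None,
                 ) -> RepeatabilitySummary:
    """Bland-Altman test-retest analysis of paired summary values.

    Differences are run2 - run1.  With ``n_boot > 0``, BCa bootstrap CIs
    are attached for the mean difference and CoR95.
    """
    run1 = np.asarray(run1, dtype=float)
    run2 = np.asarray(run2, dtype=float)
    if run1.shape != run2.shape or run1.ndim != 1:
        raise ValueError("runs must be paired 1-d arrays of equal length")
    if len(run1) < 2:
        raise ValueError("need at least two paired observations")
    d = run2 - run1
    mu = float(np.mean(d))
    cor = cor95(d)
    ci_mu = ci_cor = None
    if n_boot > 0:
        ci_mu = bca_bootstrap_ci(np.mean, d, n_boot=n_boot, seed=seed)
        ci_cor = bca_bootstrap_ci(cor95, d, n_boot=n_boot, seed=seed)
    return RepeatabilitySummary(mu, cor, (mu - cor, mu + cor), len(d),
                                ci_mu, ci_cor)


def bca_bootstrap_ci(statistic, data, n_boot: int = 20000, level: float = 0.95,
                     seed: int | None = None) -> tuple[float, float]:
    """Bias-corrected and accelerated percentile bootstrap CI.

    ``statistic`` maps a 1-d sample to a scalar.  Data are sorted
    internally, which makes the interval invariant to the input ordering
    (statistics are assumed exchangeable).  Falls back to the plain
    percentile interval, with a warning, when the bootstrap distribution
    is degenerate.
    """
    data = np.sort(np.asarray(data, dtype=float))
    if data.ndim != 1 or len(data) < 2:
        raise ValueError("data must be a 1-d sample with >= 2 values")
    if np.ptp(data) == 0.0:
        v = float(statistic(data))
        return (v, v)
    rng = np.random.default_rng(seed)
    res = sps.bootstrap((data,), statistic, n_resamples=n_boot,
                        confidence_level=level, method="BCa",
                        vectorized=False, rng=rng)
    lo, hi = float(res.confidence_interval.low), float(res.confidence_interval.high)
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn("degenerate bootstrap distribution; "
                      "falling back to the percentile interval")
        dist = np.asarray(res.bootstrap_distribution, dtype=float)
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(dist, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


def cor_difference_test(device_a_runs, device_b_runs, n_boot: int = 20000,
                        seed: int | None = None) -> tuple[float, float]:
    """Permutation test for a difference in CoR95 between two devices.

    Inputs are (n_observers, 2) paired-run arrays per device over the same
    observers.  The null resamples under within-observer exchangeability
    of device labels; returns (observed Delta = CoR_A - CoR_B, two-sided
    p with add-one smoothing), so p is always in (0, 1].
    """
    a = np.asarray(device_a_runs, dtype=float)
    b = np.asarray(device_b_runs, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("each device needs an (n_observers, 2) paired-run array")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two observers")
    da = a[:, 1] - a[:, 0]
    db = b[:, 1] - b[:, 0]
    observed = cor95(da) - cor95(db)
    rng = np.random.default_rng(seed)
    swap = rng.random((n_boot, n)) < 0.5
    pa = np.where(swap, db[None, :], da[None, :])
    pb = np.where(swap, da[None, :], db[None, :])
    null = 1.96 * (np.std(pa, axis=1, ddof=1) - np.std(pb, axis=1, ddof=1))
    p = (1.0 + np.sum(np.abs(null) >= abs(observed))) / (n_boot + 1.0)
    return float(observed), float(p)


def pointwise_comparison(device_a, device_b, grid: TestGrid,
                         alpha: float = 0.01,
                         correction: str = "bonferroni") -> pd.DataFrame:
    """Per-location paired comparison between devices.

    Inputs are (n_observers, n_locations) arrays aligned with the grid.
    Returns a frame with the mean difference (A - B), t, raw p, and a
    verdict per location: ``"a_higher"``, ``"b_higher"``, or ``"ns"``.
    Bonferroni divides by the number of comparable (test-role) locations
    -- alpha/44 on the full grid; blind-spot rows are reported but never
    flagged.  Undefined p-values (zero-variance differences) are not
    significant.
    """
    a = np.asarray(device_a, dtype=float)
    b = np.asarray(device_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != len(grid):
        raise ValueError("device arrays must be (n_observers, n_locations) and paired")
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    test_mask = np.array([l.role == ROLE_TEST for l in grid])
    m = int(test_mask.sum()) or a.shape[1]
    threshold = alpha / m if correction == "bonferroni" else alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_rel(a, b, axis=0)
    diff = np.mean(a - b, axis=0)
    sig = (np.asarray(p) < threshold) & test_mask  # nan compares False
    verdict = np.where(~sig, "ns", np.where(diff > 0, "a_higher", "b_higher"))
    return pd.DataFrame({
        "x_deg": [l.x for l in grid],
        "y_deg": [l.y for l in grid],
        "role": [l.role for l in grid],
        "mean_difference_db": diff,
        "t": t,
        "p": p,
        "verdict": verdict,
    })


def normative_table(values, grid: TestGrid,
                    percentiles: tuple[float, float] = (2.5, 97.5)) -> pd.DataFrame:
    """Per-location mean and population percentiles, right-eye format.

    ``values`` is (n_tests, n_locations) pooled over observers and runs.
    Percentiles use linear interpolation between order statistics (the
    convention is recorded in the frame's ``attrs``).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != len(grid):
        raise ValueError("values must be (n_tests, n_locations)")
    re_grid = to_right_eye_format(grid)
    lo, hi = np.percentile(values, percentiles, axis=0)
    out = pd.DataFrame({
        "x_deg": [l.x for l in re_grid],
        "y_deg": [l.y for l in re_grid],
        "role": [l.role for l in re_grid],
        "mean_db": np.mean(values, axis=0),
        f"p{percentiles[0]:g}_db": lo,
        f"p{percentiles[1]:g}_db": hi,
    })
    out.attrs["percentile_convention"] = "linear interpolation between order statistics"
    return out


def min_detectable_difference(n: int, sd_paired_diff: float,
                              alpha: float = 0.05, power: float = 0.80) -> float:
    """Smallest mean paired difference detectable at the given alpha/power.

    Central-t approximation for a two-tailed paired design:
    ``(t_{1-alpha/2, n-1} + t_{power, n-1}) * sd / sqrt(n)``.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_paired_diff < 0:
        raise ValueError("sd must be non-negative")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    df = n - 1
    crit = sps.t.ppf(1.0 - alpha / 2.0, df) + sps.t.ppf(power, df)
    return float(crit * sd_paired_diff / np.sqrt(n))
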