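"""Circular statistics and the hypothesis-testing schemes of the validation.

Single-trial SSVEP phases are compared between conditions with the Wallraff
test: within each sample, angular distances to the sample's circular median
are computed, and the two distance samples are compared with a rank test.
Amplitudes are compared with t-tests (one-sided where the artifact has a
known direction), and the group level uses Wilcoxon rank-sum tests.  A
noncentral-t power analysis reports the minimal detectable effect size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sst

from .exceptions import DegenerateDataError

__all__ = [
    "TestResult",
    "wrap_angles",
    "plv",
    "circular_mean",
    "circular_median",
    "angular_distance",
    "circular_correlation",
    "wallraff_test",
    "amplitude_tests",
    "min_detectable_d",
    "group_tests",
    "stars",
]


def wrap_angles(angles) -> np.ndarray:
    """Wrap to (-pi, pi]."""
    a = np.angle(np.exp(1j * np.asarray(angles, dtype=float)))
    return np.where(a == -np.pi, np.pi, a)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one" or "two"
    paired: bool
    n1: int
    n2: int
    degenerate: bool = False

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")

    @property
    def stars(self) -> str:
        return stars(self.p_value)


def stars(p: float) -> str:
    """Significance coding: thresholds 0.05 / 0.01 / 0.001 / 0.0001."""
    for n, thr in ((4, 1e-4), (3, 1e-3), (2, 1e-2), (1, 5e-2)):
        if p < thr:
            return "*" * n
    return "ns"


def plv(angles) -> float:
    """Phase-locking value: modulus of the mean unit phasor, in [0, 1]."""
    a = np.asarray(angles, dtype=float)
    if a.size == 0:
        raise DegenerateDataError("PLV of an empty sample")
    return float(np.abs(np.mean(np.exp(1j * a))))


def circular_mean(angles) -> float:
    return float(np.angle(np.mean(np.exp(1j * np.asarray(angles, dtype=float)))))


def angular_distance(angles, reference) -> np.ndarray:
    """Unsigned circular distance ``pi - |pi - |theta - ref||`` in [0, pi]."""
    d = np.abs(wrap_angles(np.asarray(angles) - reference))
    return np.pi - np.abs(np.pi - d)


def circular_median(angles) -> float:
    """Data-point minimizer of the mean angular distance.

    Ties between candidate medians are broken toward the candidate closest
    to the circular mean.
    """
    a = wrap_angles(angles)
    if a.size == 0:
        raise DegenerateDataError("circular median of an empty sample")
    mean_dist = np.array([angular_distance(a, c).mean() for c in a])
    best = mean_dist.min()
    cand = a[mean_dist <= best + 1e-12]
    if cand.size == 1:
        return float(cand[0])
    cm = circular_mean(a)
    return float(cand[np.argmin(angular_distance(cand, cm))])


def circular_correlation(a, b) -> float:
    """Circular-circular association (Jammalamadaka-SenGupta), in [-1, 1]."""
    a, b = wrap_angles(a), wrap_angles(b)
    sa = np.sin(a - circular_mean(a))
    sb = np.sin(b - circular_mean(b))
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)


def wallraff_test(a, b, paired: bool = False, sided: str = "two",
                  alternative: str = None) -> TestResult:
    """Wallraff test of circular dispersion.

    Angular distances of each sample to its own circular median are compared
    with a Wilcoxon rank-sum test (independent samples) or a Wilcoxon
    signed-rank test on paired distances (dependent samples).  With
    ``sided='one'`` the alternative is that sample ``b`` is more dispersed
    than ``a`` unless ``alternative`` overrides it (scipy semantics on the
    distances of ``a`` versus ``b``).
    """
    a, b = wrap_angles(a), wrap_angles(b)
    if a.size < 2 or b.size < 2:
        raise DegenerateDataError("Wallraff test needs at least 2 angles per sample")
    if paired and a.size != b.size:
        raise DegenerateDataError("paired Wallraff test needs equal sample sizes")
    da = angular_distance(a, circular_median(a))
    db = angular_distance(b, circular_median(b))
    if np.all(da == 0) and np.all(db == 0):
        return TestResult(0.0, 1.0, sided, paired, a.size, b.size, degenerate=True)
    if alternative is None:
        alternative = "two-sided" if sided == "two" else "less"
    if paired:
        diff = da - db
        if np.all(diff == 0):
            return TestResult(0.0, 1.0, sided, paired, a.size, b.size, degenerate=True)
        res = sst.wilcoxon(da, db, alternative=alternative)
    else:
        method = "exact" if max(a.size, b.size) <= 25 else "asymptotic"
        res = sst.mannwhitneyu(da, db, alternative=alternative, method=method)
    return TestResult(float(res.statistic), float(res.pvalue), sided, paired,
                      a.size, b.size)


def amplitude_tests(no_stim, stim_raw, stim_sass) -> dict:
    """The three-condition amplitude comparison scheme.

    * no-stim vs stim-without-SASS: one-sided independent t (artifact
      inflates amplitudes);
    * stim-without-SASS vs stim-with-SASS: one-sided paired t (same trials);
    * no-stim vs stim-with-SASS: two-sided independent t (residual artifact
      could fall either way).
    """
    no_stim = np.asarray(no_stim, float)
    stim_raw = np.asarray(stim_raw, float)
    stim_sass = np.asarray(stim_sass, float)
    if stim_raw.size != stim_sass.size:
        raise DegenerateDataError("paired comparison requires equal trial counts")
    out = {}
    r = sst.ttest_ind(stim_raw, no_stim, alternative="greater")
    out["no_stim_vs_stim_raw"] = TestResult(
        float(r.statistic), float(r.pvalue), "one", False, no_stim.size, stim_raw.size
    )
    diff = stim_raw - stim_sass
    if np.all(diff == 0):
        out["stim_raw_vs_stim_sass"] = TestResult(
            0.0, 1.0, "one", True, stim_raw.size, stim_sass.size, degenerate=True
        )
    else:
        r = sst.ttest_rel(stim_raw, stim_sass, alternative="greater")
        out["stim_raw_vs_stim_sass"] = TestResult(
            float(r.statistic), float(r.pvalue), "one", True, stim_raw.size, stim_sass.size
        )
    r = sst.ttest_ind(no_stim, stim_sass, alternative="two-sided")
    out["no_stim_vs_stim_sass"] = TestResult(
        float(r.statistic), float(r.pvalue), "two", False, no_stim.size, stim_sass.size
    )
    return out


def min_detectable_d(
    n_per_group: int,
    alpha: float = 0.05,
    power: float = 0.80,
    sided: str = "two",
) -> float:
    """Smallest Cohen's d a two-sample t-test can detect at the target power.

    Power is computed from the noncentral t distribution with
    ``df = 2n - 2`` and noncentrality ``d * sqrt(n/2)``; the effect size is
    found by bisection to 1e-6.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 observations per group")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie strictly in (0, 1)")
    df = 2 * n_per_group - 2
    tcrit = sst.t.ppf(1 - alpha / 2, df) if sided == "two" else sst.t.ppf(1 - alpha, df)

    from scipy.special import nctdtr  # stable noncentral-t CDF for large df

    def attained(d):
        ncp = d * np.sqrt(n_per_group / 2.0)
        p = 1.0 - nctdtr(df, ncp, tcrit)
        if sided == "two":
            lower = nctdtr(df, ncp, -tcrit)
            p += 0.0 if np.isnan(lower) else lower  # far-left tail underflow
        return p

    if power <= attained(0.0):
        return 0.0
    hi = 0.5
    while attained(hi) < power:
        hi *= 2
        if hi > 1e3:
            raise DegenerateDataError("target power unattainable")
    return float(optimize.brentq(lambda d: attained(d) - power, 0.0, hi, xtol=1e-6))


_GROUP_DIRECTIONS = {
    # alternative for (first, second): does the metric rise or fall with artifact?
    "plv": {"no_stim_vs_stim_raw": "greater", "stim_sass_vs_stim_raw": "greater"},
    "amplitude": {"no_stim_vs_stim_raw": "less", "stim_sass_vs_stim_raw": "less"},
}


def group_tests(values_by_condition: dict, metric: str = "plv") -> dict:
    """Group-level rank-sum comparisons between the three conditions.

    ``values_by_condition`` maps ``no_stim`` / ``stim_raw`` / ``stim_sass``
    to per-participant values.  One-sided tests are used where the artifact
    direction is known (uncleaned stimulation scrambles phase, hence lowers
    PLV, and inflates amplitude); no-stim vs stim-with-SASS is two-sided.
    """
    dirs = _GROUP_DIRECTIONS[metric]
    vals = {k: np.asarray(v, float) for k, v in values_by_condition.items()}

    def ranksum(x, y, alternative, sided):
        method = "exact" if max(x.size, y.size) <= 25 else "asymptotic"
        r = sst.mannwhitneyu(x, y, alternative=alternative, method=method)
        return TestResult(float(r.statistic), float(r.pvalue), sided, False,
                          x.size, y.size)

    out = {
        "no_stim_vs_stim_raw": ranksum(
            vals["no_stim"], vals["stim_raw"], dirs["no_stim_vs_stim_raw"], "one"
        ),
        "stim_sass_vs_stim_raw": ranksum(
            vals["stim_sass"], vals["stim_raw"], dirs["stim_sass_vs_stim_raw"], "one"
        ),
        "no_stim_vs_stim_sass": ranksum(
            vals["no_stim"], vals["stim_sass"], "two-sided", "two"
        ),
    }
    return out
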