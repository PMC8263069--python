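"""Burst-duration non-linearity measures and the supporting statistics.

BDDLS ("burst duration distance to linear surrogate") summarizes how far a
signal's average burst duration profile departs from the profile of its
linear surrogates: the sum of squared profile differences, scaled by the
squared mean of the surrogate profile (which makes the measure invariant to
an overall amplitude scale). The module also provides the contrasts between
two conditions (BDDLSdiff, DURdiff, PSDdiff) and the statistical machinery
used alongside: adaptive FDR control, cluster-based permutation testing for
paired amplitude PDFs, per-threshold t-tests, rank tests, a binomial tail
test, and Barnard's unconditional exact test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import AmplitudePDF, SpectralDensity, ThresholdProfile

__all__ = [
    "NonlinearityReport",
    "StatResult",
    "bddls",
    "contrasts",
    "adaptive_fdr",
    "cluster_permutation_test",
    "paired_profile_tests",
    "rank_tests",
    "binomial_tail_test",
    "barnard_test",
    "bddls_rank_test",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n: int
    method: str
    sidedness: str

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class NonlinearityReport:
    bddls_on: float
    bddls_off: float
    bddls_diff: float
    dur_diff: float
    psd_diff: float
    rho: float

    def __post_init__(self):
        if self.bddls_on < 0 or self.bddls_off < 0:
            raise ValueError("BDDLS is non-negative by construction")


def _shared_durations(a: ThresholdProfile, b: ThresholdProfile):
    if not a.same_grid(b):
        raise ValueError("profiles must share the same percentile grid")
    da, db = a.mean_duration, b.mean_duration
    if np.any(~np.isfinite(da)) or np.any(~np.isfinite(db)):
        raise ValueError("profiles carry missing entries on the shared grid")
    return da, db


def bddls(data_profile: ThresholdProfile, surrogate_profile: ThresholdProfile) -> float:
    """Burst duration distance to linear surrogate.

    Sum over thresholds of squared differences between data and surrogate
    mean burst durations, divided by the squared mean of the surrogate
    profile. Dimensionless and invariant to a common amplitude scaling.
    """
    d, s = _shared_durations(data_profile, surrogate_profile)
    scale = np.mean(s) ** 2
    if scale == 0:
        raise ValueError("surrogate profile has zero mean")
    return float(np.sum((d - s) ** 2) / scale)


def contrasts(profile_on: ThresholdProfile, profile_off: ThresholdProfile,
              surr_on: ThresholdProfile, surr_off: ThresholdProfile,
              psd_on: SpectralDensity, psd_off: SpectralDensity,
              band: tuple | None = None, rho: float = 0.0,
              psd_mode: str = "band_integral") -> NonlinearityReport:
    """ON/OFF condition contrasts.

    DURdiff = sum over thresholds of (tau_OFF - tau_ON), in seconds.
    PSDdiff = relative difference of band-integrated power,
    (P_OFF - P_ON) / P_ON; ``psd_mode='per_frequency'`` instead averages the
    per-frequency relative difference over the band.
    BDDLSdiff = BDDLS_OFF - BDDLS_ON.
    """
    d_on, d_off = _shared_durations(profile_on, profile_off)
    dur_diff = float(np.sum(d_off - d_on))
    b_on = bddls(profile_on, surr_on)
    b_off = bddls(profile_off, surr_off)
    if band is None:
        band = (psd_on.freqs[1], psd_on.freqs[-1])
    if psd_mode == "band_integral":
        p_on = psd_on.band_power(*band)
        p_off = psd_off.band_power(*band)
        psd_diff = (p_off - p_on) / p_on
    elif psd_mode == "per_frequency":
        mask = (psd_on.freqs >= band[0]) & (psd_on.freqs <= band[1])
        ratio = (psd_off.power[mask] - psd_on.power[mask]) / psd_on.power[mask]
        psd_diff = float(np.mean(ratio))
    else:
        raise ValueError("psd_mode must be 'band_integral' or 'per_frequency'")
    return NonlinearityReport(b_on, b_off, b_off - b_on, dur_diff,
                              float(psd_diff), rho)


def adaptive_fdr(p_values, q: float = 0.05, method: str = "two_stage") -> np.ndarray:
    """Adaptive linear step-up FDR control.

    The default estimates the number of true null hypotheses with the
    two-stage linear step-up procedure and re-runs the step-up at the
    adjusted level; ``method='bh'`` is the non-adaptive original.
    Returns a boolean rejection mask.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"two_stage": "fdr_tsbky", "bh": "fdr_bh"}[method]
    reject, *_ = multipletests(p, alpha=q, method=sm_method)
    return reject


def _paired_t(diff: np.ndarray) -> np.ndarray:
    """Paired t statistic per column of an (n_pairs, n_bins) difference array."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(sd == 0, 0.0, t)


def cluster_permutation_test(group_a, group_b, n_perm: int = 10**6,
                             cluster_alpha: float = 0.05, seed: int = 0):
    """Cluster-based permutation test on paired amplitude PDFs.

    A paired t statistic is computed per histogram bin; contiguous bins
    exceeding the two-sided critical t at ``cluster_alpha`` form clusters
    scored by their summed t. The null distribution of the maximum cluster
    mass is built by sign-flipping pairs (exhaustively when 2^n_pairs is
    within the permutation budget, sampled otherwise).

    Returns a list of ``(bin_slice, cluster_mass, p_value)`` tuples and the
    smallest cluster p (1.0 when no cluster forms).
    """
    a = np.array([g.density for g in group_a]) if not isinstance(group_a, np.ndarray) else group_a
    b = np.array([g.density for g in group_b]) if not isinstance(group_b, np.ndarray) else group_b
    if a.shape != b.shape:
        raise ValueError("paired groups need identical bin grids and sizes")
    if not isinstance(group_a, np.ndarray):
        e0 = group_a[0].bin_edges
        for g in list(group_a) + list(group_b):
            if not np.allclose(g.bin_edges, e0):
                raise ValueError("all PDFs must share the bin grid")
    diff = a - b
    n_pairs = diff.shape[0]
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n_pairs - 1)

    def cluster_masses(tvals):
        supra = np.abs(tvals) > t_crit
        masses, spans = [], []
        i = 0
        while i < len(supra):
            if supra[i]:
                j = i
                while j < len(supra) and supra[j] and np.sign(tvals[j]) == np.sign(tvals[i]):
                    j += 1
                masses.append(np.abs(tvals[i:j]).sum())
                spans.append(slice(i, j))
                i = j
            else:
                i += 1
        return masses, spans

    t_obs = _paired_t(diff)
    obs_masses, obs_spans = cluster_masses(t_obs)
    if not obs_masses:
        return [], 1.0

    if 2 ** n_pairs <= n_perm:
        signs = np.array(np.meshgrid(*[[-1, 1]] * n_pairs)).T.reshape(-1, n_pairs)
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(n_perm, n_pairs))
    null_max = np.zeros(len(signs))
    for k, s in enumerate(signs):
        t_perm = _paired_t(diff * s[:, None])
        masses, _ = cluster_masses(t_perm)
        null_max[k] = max(masses) if masses else 0.0
    results = []
    for mass, span in zip(obs_masses, obs_spans):
        p = (1.0 + np.sum(null_max >= mass)) / (len(signs) + 1.0)
        results.append((span, float(mass), float(p)))
    return results, min(r[2] for r in results)


def paired_profile_tests(on_segments, off_segments, q: float = 0.05):
    """Per-threshold two-sample t-tests between segment profiles, with FDR.

    With 5 segments per condition each test has 8 degrees of freedom.
    Thresholds where either group has a missing mean get p = NaN and are
    excluded from the FDR step; zero variance in both groups gives p = 1.

    Returns ``(p_values, rejection_mask)``.
    """
    on = np.array([p.mean_duration for p in on_segments])
    off = np.array([p.mean_duration for p in off_segments])
    n_thr = on.shape[1]
    p_values = np.full(n_thr, np.nan)
    for k in range(n_thr):
        x, y = on[:, k], off[:, k]
        if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
            continue
        if np.ptp(x) == 0 and np.ptp(y) == 0:
            p_values[k] = 1.0
            continue
        p_values[k] = stats.ttest_ind(x, y).pvalue
    reject = np.zeros(n_thr, dtype=bool)
    ok = np.isfinite(p_values)
    if ok.any():
        reject[ok] = adaptive_fdr(p_values[ok], q=q)
    return p_values, reject


def rank_tests(x, y, kind: str = "wilcoxon_one_tailed") -> StatResult:
    """Wilcoxon signed-rank (one-tailed, x > y) or Spearman correlation.

    The Wilcoxon test uses the exact small-sample distribution when there
    are no ties in the differences; all-zero differences give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "wilcoxon_one_tailed":
        if x.shape != y.shape:
            raise ValueError("paired samples required")
        d = x - y
        if np.all(d == 0):
            return StatResult(0.0, 1.0, len(x), "wilcoxon", "greater")
        res = stats.wilcoxon(x, y, alternative="greater", method="auto")
        return StatResult(float(res.statistic), float(res.pvalue), len(x),
                          "wilcoxon", "greater")
    if kind == "spearman":
        if len(x) < 3:
            raise ValueError("need n >= 3 for Spearman correlation")
        res = stats.spearmanr(x, y)
        return StatResult(float(res.statistic), float(res.pvalue), len(x),
                          "spearman", "two-sided")
    raise ValueError(f"unknown rank test {kind!r}")


def binomial_tail_test(k: int, n: int, p0: float) -> StatResult:
    """Upper-tail binomial test: P(X >= k), X ~ Binomial(n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("require 0 <= p0 <= 1")
    p = float(stats.binom.sf(k - 1, n, p0))
    return StatResult(float(k), min(p, 1.0), n, "binomial_tail", "greater")


def barnard_test(table, alternative: str = "greater", pooled: bool = True,
                 n_grid: int = 64) -> StatResult:
    """Barnard's unconditional exact test for a 2x2 table.

    Columns are the two fixed-size groups (e.g. conditions); rows are the
    outcome. The tail probability of the Wald statistic (pooled variance by
    default) is maximized over a grid of the nuisance success probability.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if t.sum() == 0:
        raise ValueError("zero-total table")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    res = stats.barnard_exact(t, alternative=alternative, pooled=pooled, n=n_grid)
    return StatResult(float(res.statistic), float(res.pvalue), int(t.sum()),
                      "barnard", alternative)


def bddls_rank_test(data_profile: ThresholdProfile, surrogate_profiles) -> StatResult:
    """Surrogate rank test of burst-duration non-linearity.

    The data BDDLS (against the mean surrogate profile) is ranked among the
    leave-one-out BDDLS of each surrogate (against the mean of the others).
    With n surrogates, p = (1 + #{surrogate >= data}) / (n + 1); n = 19
    gives a minimum attainable p of 0.05.
    """
    profs = list(surrogate_profiles)
    n = len(profs)
    grid = profs[0].percentiles
    durs = np.array([p.mean_duration for p in profs])

    def mean_profile(rows):
        return ThresholdProfile(grid, profs[0].thresholds, rows.mean(axis=0))

    d_stat = bddls(data_profile, mean_profile(durs))
    null = np.empty(n)
    for i in range(n):
        others = np.delete(durs, i, axis=0)
        null[i] = bddls(profs[i], mean_profile(others))
    p = (1.0 + np.sum(null >= d_stat)) / (n + 1.0)
    return StatResult(float(d_stat), float(p), n, "bddls_rank", "greater")
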