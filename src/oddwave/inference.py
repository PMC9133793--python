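"""Nonparametric group inference for decoding time courses.

Implements the sign-permutation cluster machinery used throughout the study:

* one-sample tests that flip each participant's whole accuracy (or accuracy-
  difference) series about the null value (50% for accuracies, 0 for
  differences), with familywise error across time points controlled by
  cluster-based inference (cluster mass = sum of the group-mean deviation
  within a contiguous suprathreshold run);
* two-sample tests between groups, with the null built by random reassignment
  of participants to groups (a paired sign-flip variant is provided for
  within-subject comparisons);
* onset latency (first time point of the earliest significant cluster) and
  peak latency (argmax of the group mean), compared between conditions or
  groups by bootstrapping participants with replacement;
* pooled-variance two-sample t and Cohen's d for behavioral tables.

The observed statistic is always counted as one sample of its own null
distribution, so the smallest attainable p-value is 1/n_permutations
(0.0002 at the default 5,000 permutations).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "ClusterTestConfig",
    "Cluster",
    "ClusterTestResult",
    "LatencyEstimate",
    "LatencyResult",
    "sign_permutation_cluster_test",
    "two_sample_cluster_test",
    "paired_difference_cluster_test",
    "onset_and_peak_latency",
    "bootstrap_latency_test",
    "pooled_t_and_d",
]


@dataclass(frozen=True)
class ClusterTestConfig:
    n_permutations: int = 5000
    cluster_alpha: float = 0.05  # corrected significance level for a cluster
    cluster_defining_alpha: float = 0.05  # pointwise threshold that forms clusters
    alternative: str = "greater"  # "greater" or "two-sided"
    null_value: float = 0.5  # 0.5 for accuracies, 0.0 for accuracy differences
    analysis_window: tuple[float, float] = (0.0, 550.0)
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0 < self.cluster_alpha < 1 and 0 < self.cluster_defining_alpha < 1):
            raise ValueError("alphas must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("need at least 1 permutation")
        if self.alternative not in ("greater", "two-sided"):
            raise ValueError("alternative must be 'greater' or 'two-sided'")


@dataclass(frozen=True)
class Cluster:
    start_ms: float
    end_ms: float
    start_idx: int
    end_idx: int  # inclusive
    mass: float
    corrected_p: float


@dataclass
class ClusterTestResult:
    statistic_map: np.ndarray  # group-mean deviation from the null, per time point
    pointwise_p: np.ndarray
    clusters: list[Cluster]
    significant_mask: np.ndarray  # True where a corrected-significant cluster lies
    null_max_mass: np.ndarray  # empirical max-cluster-mass distribution
    times: np.ndarray  # analysis-window time grid

    @property
    def min_corrected_p(self) -> float:
        return min((c.corrected_p for c in self.clusters), default=1.0)


def _restrict_window(series: np.ndarray, times: np.ndarray, window: tuple[float, float]):
    t0, t1 = window
    mask = (times >= t0) & (times <= t1)
    if not mask.any():
        raise ValueError("analysis window contains no time points")
    return series[..., mask], times[mask]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal contiguous runs of True, as (start, end) inclusive."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _cluster_inference(M: np.ndarray, times: np.ndarray, config: ClusterTestConfig) -> ClusterTestResult:
    """Shared cluster machinery.

    ``M`` is (n_permutations, n_times); row 0 is the observed statistic map
    and the remaining rows are permutation samples.  Pointwise p-values are
    empirical ranks within each column (observed included); clusters are
    contiguous runs with pointwise p <= cluster_defining_alpha, with mass the
    sum of the map's values inside the run, corrected against the empirical
    distribution of per-permutation maximal cluster masses.
    """
    n_perm, _ = M.shape
    two_sided = config.alternative == "two-sided"
    V = np.abs(M) if two_sided else M
    # empirical pointwise p of every row at once: count of rows >= value,
    # computed per column by sorting (exact under ties)
    Vs = np.sort(V, axis=0)
    count_lt = np.empty_like(V, dtype=int)
    for t in range(V.shape[1]):
        count_lt[:, t] = np.searchsorted(Vs[:, t], V[:, t], side="left")
    P = (n_perm - count_lt) / n_perm

    thresh_mask = P <= config.cluster_defining_alpha
    masses = np.zeros(n_perm)
    observed_clusters: list[tuple[int, int, float]] = []
    for r in range(n_perm):
        best = 0.0
        for s, e in _runs(thresh_mask[r]):
            mass = float(M[r, s : e + 1].sum())
            size = abs(mass) if two_sided else mass
            if size > best:
                best = size
            if r == 0:
                observed_clusters.append((s, e, mass))
        masses[r] = best

    clusters = []
    sig = np.zeros(M.shape[1], dtype=bool)
    for s, e, mass in observed_clusters:
        size = abs(mass) if two_sided else mass
        p = float((masses >= size).sum() / n_perm)
        p = max(p, 1.0 / n_perm)
        clusters.append(
            Cluster(
                start_ms=float(times[s]),
                end_ms=float(times[e]),
                start_idx=int(s),
                end_idx=int(e),
                mass=mass,
                corrected_p=p,
            )
        )
        if p <= config.cluster_alpha:
            sig[s : e + 1] = True
    return ClusterTestResult(
        statistic_map=M[0].copy(),
        pointwise_p=P[0].copy(),
        clusters=clusters,
        significant_mask=sig,
        null_max_mass=masses,
        times=times.copy(),
    )


def sign_permutation_cluster_test(
    subject_series: np.ndarray, times: np.ndarray, config: ClusterTestConfig | None = None
) -> ClusterTestResult:
    """One-sample cluster-corrected sign-permutation test.

    ``subject_series`` is (n_subjects, n_times).  Permutation samples flip
    each subject's whole series by +-1 about ``config.null_value``
    independently, then average across subjects; the observed average is
    counted in the null distribution, so corrected p-values are floored at
    1/n_permutations.
    """
    config = config if config is not None else ClusterTestConfig()
    series = np.asarray(subject_series, float)
    if series.ndim != 2 or series.shape[0] < 2:
        raise ValueError("need a (n_subjects >= 2, n_times) array")
    dev, wtimes = _restrict_window(series - config.null_value, np.asarray(times, float),
                                   config.analysis_window)
    rng = np.random.default_rng(config.seed)
    n_sub = dev.shape[0]
    signs = rng.choice([-1.0, 1.0], size=(config.n_permutations - 1, n_sub))
    M = np.vstack([dev.mean(axis=0), signs @ dev / n_sub])
    return _cluster_inference(M, wtimes, config)


def two_sample_cluster_test(
    group_a: np.ndarray,
    group_b: np.ndarray,
    times: np.ndarray,
    config: ClusterTestConfig | None = None,
) -> ClusterTestResult:
    """Two-sample cluster test by random reassignment of subjects to groups.

    The observed statistic is the difference of group means per time point;
    the null is built by shuffling the pooled subjects into groups of the
    original sizes.
    """
    config = config if config is not None else ClusterTestConfig(null_value=0.0)
    A = np.asarray(group_a, float)
    B = np.asarray(group_b, float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] < 2 or B.shape[0] < 2:
        raise ValueError("need >= 2 subjects per group")
    if A.shape[1] != B.shape[1]:
        raise ValueError("groups must share the time grid")
    times = np.asarray(times, float)
    A, wtimes = _restrict_window(A, times, config.analysis_window)
    B, _ = _restrict_window(B, times, config.analysis_window)
    na = A.shape[0]
    pooled = np.vstack([A, B])
    rng = np.random.default_rng(config.seed)
    M = np.empty((config.n_permutations, pooled.shape[1]))
    M[0] = A.mean(axis=0) - B.mean(axis=0)
    for r in range(1, config.n_permutations):
        perm = rng.permutation(pooled.shape[0])
        M[r] = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
    return _cluster_inference(M, wtimes, config)


def paired_difference_cluster_test(
    series_a: np.ndarray,
    series_b: np.ndarray,
    times: np.ndarray,
    config: ClusterTestConfig | None = None,
) -> ClusterTestResult:
    """Sign-flip test on per-subject difference series (paired designs).

    Equivalent to the one-sample test on ``series_a - series_b`` with null 0;
    this is the variant used for the ordered repetition contrasts (e.g.
    1sts-vs-4ths accuracy > 1sts-vs-2nds accuracy within participants).
    """
    config = config if config is not None else ClusterTestConfig(null_value=0.0)
    A = np.asarray(series_a, float)
    B = np.asarray(series_b, float)
    if A.shape != B.shape:
        raise ValueError("paired series must share subjects and time grid")
    return sign_permutation_cluster_test(A - B, times, replace(config, null_value=0.0))


@dataclass(frozen=True)
class LatencyEstimate:
    onset_ms: float  # nan when no significant cluster
    peak_ms: float
    onset_defined: bool


@dataclass
class LatencyResult:
    latency_kind: str
    latency_a: float
    latency_b: float
    bootstrap_differences: np.ndarray  # defined draws only
    n_undefined: int
    p_two_sided: float
    reliable: bool


def onset_and_peak_latency(
    group_series: np.ndarray, cluster_result: ClusterTestResult
) -> LatencyEstimate:
    """Onset = first time point of the earliest significant cluster; peak =
    argmax of the group mean within the analysis window."""
    mean = np.asarray(group_series, float).mean(axis=0)
    if mean.size != cluster_result.times.size:
        raise ValueError("series and cluster result are on different grids")
    peak = float(cluster_result.times[int(np.argmax(mean))])
    sig = cluster_result.significant_mask
    if sig.any():
        onset = float(cluster_result.times[int(np.argmax(sig))])
        return LatencyEstimate(onset_ms=onset, peak_ms=peak, onset_defined=True)
    return LatencyEstimate(onset_ms=float("nan"), peak_ms=peak, onset_defined=False)


def _bootstrap_latency(
    series: np.ndarray, times: np.ndarray, kind: str, config: ClusterTestConfig, seed
) -> tuple[float, bool]:
    dev, wtimes = _restrict_window(series, times, config.analysis_window)
    mean = dev.mean(axis=0)
    if kind == "peak":
        return float(wtimes[int(np.argmax(mean))]), True
    res = sign_permutation_cluster_test(series, times, replace(config, seed=seed))
    est = onset_and_peak_latency(dev, res)
    return est.onset_ms, est.onset_defined


def bootstrap_latency_test(
    series_set_a: np.ndarray,
    series_set_b: np.ndarray,
    times: np.ndarray,
    latency_kind: str = "onset",
    n_boot: int = 1000,
    paired: bool = False,
    cluster_config: ClusterTestConfig | None = None,
    seed: int | None = None,
) -> LatencyResult:
    """Bootstrap test for a latency difference between two series sets.

    Per draw, subjects are resampled with replacement (jointly for paired
    comparisons of the same subjects' two condition series), the group
    latency is recomputed (onsets require re-running the sign-permutation
    cluster test on the resampled set) and the latency difference recorded.
    The two-sided p is ``2 * min(P(diff <= 0), P(diff >= 0))`` over defined
    draws, capped at 1.  Draws where either onset is undefined are dropped;
    the result is flagged unreliable when more than half the draws are
    undefined.
    """
    if latency_kind not in ("onset", "peak"):
        raise ValueError("latency_kind must be 'onset' or 'peak'")
    config = cluster_config if cluster_config is not None else ClusterTestConfig()
    A = np.asarray(series_set_a, float)
    B = np.asarray(series_set_b, float)
    times = np.asarray(times, float)
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired comparison needs the same subjects in both sets")
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    inner_seeds = ss.generate_state(2 * n_boot + 2) % (2**31)

    lat_a, _ = _bootstrap_latency(A, times, latency_kind, config, int(inner_seeds[-2]))
    lat_b, _ = _bootstrap_latency(B, times, latency_kind, config, int(inner_seeds[-1]))

    diffs = []
    n_undef = 0
    for d in range(n_boot):
        idx_a = rng.integers(A.shape[0], size=A.shape[0])
        idx_b = idx_a if paired else rng.integers(B.shape[0], size=B.shape[0])
        la, ok_a = _bootstrap_latency(A[idx_a], times, latency_kind, config, int(inner_seeds[2 * d]))
        lb, ok_b = _bootstrap_latency(B[idx_b], times, latency_kind, config, int(inner_seeds[2 * d + 1]))
        if ok_a and ok_b:
            diffs.append(la - lb)
        else:
            n_undef += 1
    diffs = np.asarray(diffs, float)
    if diffs.size == 0:
        p = float("nan")
    else:
        p = 2.0 * min(float((diffs <= 0).mean()), float((diffs >= 0).mean()))
        p = min(p, 1.0)
    return LatencyResult(
        latency_kind=latency_kind,
        latency_a=lat_a,
        latency_b=lat_b,
        bootstrap_differences=diffs,
        n_undefined=n_undef,
        p_two_sided=p,
        reliable=n_undef <= n_boot / 2,
    )


def pooled_t_and_d(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> tuple[float, float, float]:
    """Two-sample pooled-variance t, two-sided p, and Cohen's d (pooled SD)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need n >= 2 per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("SDs must be positive")
    df = n_a + n_b - 2
    sp = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df)
    diff = mean_a - mean_b
    t = diff / (sp * np.sqrt(1.0 / n_a + 1.0 / n_b))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    d = diff / sp
    return float(t), p, float(d)
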