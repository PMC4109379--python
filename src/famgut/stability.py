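"""Temporal stability of within-individual community structure.

Stability is summarized as similarity (1 - theta-YC dissimilarity) between
pairs of samples from the same individual, grouped by the number of days
separating them.  Group contrasts (child-child, child-mother, ...) are
summarized at the *individual* level — one average similarity per anchor
individual — and compared with exact nonparametric tests; pooling all
sample pairs would pseudo-replicate.

The exact Wilcoxon tests enumerate the permutation null over midranks via a
dynamic program, which is mathematically identical to enumerating all
C(n+m, n) group labelings (rank-sum) or all 2^n sign assignments
(signed-rank) and handles ties exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .diversity import DistanceMatrix
from .tables import SampleMetadata

__all__ = [
    "StabilityCurve",
    "GroupComparison",
    "stability_curve",
    "stability_slope",
    "group_similarity",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
]


@dataclass
class StabilityCurve:
    """Mean within-subject similarity per sampling lag (days apart)."""

    subject_id: str
    curve: pd.DataFrame  # columns: lag, mean_similarity, n_pairs

    def __post_init__(self) -> None:
        if (self.curve["lag"] < 1).any():
            raise ValueError("lags must be positive")
        sims = self.curve["mean_similarity"]
        if ((sims < -1e-9) | (sims > 1 + 1e-9)).any():
            raise ValueError("similarities must lie in [0, 1]")


@dataclass
class GroupComparison:
    """Per-individual average similarities for one contrast, plus a test."""

    label: str
    values_a: pd.Series
    values_b: pd.Series
    statistic: float
    p_value: float
    paired: bool

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def stability_curve(
    dist: DistanceMatrix,
    meta: SampleMetadata,
    subject: str,
    bin_width: int | None = None,
) -> StabilityCurve:
    """Similarity between a subject's sample pairs as a function of lag.

    For every within-subject pair, lag = |day_i - day_j| and similarity =
    1 - dissimilarity; pairs are averaged per lag (or per lag bin when
    ``bin_width`` is given).  Invariant to shifting all days by a constant.
    """
    samples = [s for s in meta.samples_of(subject) if s in set(dist.ids)]
    if len(samples) < 2:
        raise ValueError(f"subject {subject!r} has fewer than 2 samples in the matrix")
    days = {s: meta.day_of(s) for s in samples}
    records = []
    for i, si in enumerate(samples):
        for sj in samples[i + 1 :]:
            lag = abs(days[si] - days[sj])
            records.append((lag, 1.0 - dist[si, sj]))
    df = pd.DataFrame(records, columns=["lag", "similarity"])
    if bin_width is not None:
        if bin_width < 1:
            raise ValueError("bin_width must be >= 1")
        df["lag"] = ((df["lag"] - 1) // bin_width) * bin_width + 1
    grouped = (
        df.groupby("lag")["similarity"]
        .agg(mean_similarity="mean", n_pairs="size")
        .reset_index()
        .sort_values("lag", ignore_index=True)
    )
    return StabilityCurve(subject, grouped)


def _lag_slope(sim_pairs: np.ndarray, lags: np.ndarray) -> float:
    """OLS slope of per-lag mean similarity against lag."""
    sums = np.bincount(lags, weights=sim_pairs)
    counts = np.bincount(lags)
    present = counts > 0
    x = np.flatnonzero(present).astype(float)
    y = sums[present] / counts[present]
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("need at least two distinct lags to fit a slope")
    return float((x @ (y - y.mean())) / denom)


def stability_slope(
    dist: DistanceMatrix,
    meta: SampleMetadata,
    subject: str,
    method: str = "permutation",
    n_permutations: int = 999,
    seed=None,
) -> tuple[float, tuple[float, float]]:
    """Slope of within-subject similarity against sampling lag, with 95% CI.

    The slope is the OLS fit of per-lag mean similarity on lag.  Because
    lag-mean points share samples, iid OLS intervals under-cover; the
    default CI therefore comes from permuting the subject's day labels
    (exact under day-exchangeability): basic interval
    ``[slope - q97.5(perm), slope - q2.5(perm)]``.  ``method="ols"`` gives
    the naive textbook interval instead.
    """
    from .tables import as_rng

    samples = [s for s in meta.samples_of(subject) if s in set(dist.ids)]
    if len(samples) < 3:
        raise ValueError(f"subject {subject!r} needs >= 3 samples for a slope")
    days = np.array([meta.day_of(s) for s in samples])
    index = {s: i for i, s in enumerate(dist.ids)}
    idx = [index[s] for s in samples]
    sim = 1.0 - dist.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(samples), k=1)
    sim_pairs = sim[iu]

    def lags_for(day_vec: np.ndarray) -> np.ndarray:
        return np.abs(day_vec[iu[0]] - day_vec[iu[1]])

    observed = _lag_slope(sim_pairs, lags_for(days))
    if method == "ols":
        import statsmodels.api as sm

        lags = lags_for(days)
        sums = np.bincount(lags, weights=sim_pairs)
        counts = np.bincount(lags)
        present = counts > 0
        x = sm.add_constant(np.flatnonzero(present).astype(float))
        y = sums[present] / counts[present]
        fit = sm.OLS(y, x).fit()
        lo, hi = fit.conf_int(alpha=0.05)[1]
        return observed, (float(lo), float(hi))
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    rng = as_rng(seed)
    perm_slopes = np.empty(n_permutations)
    for i in range(n_permutations):
        perm_slopes[i] = _lag_slope(sim_pairs, lags_for(rng.permutation(days)))
    q_lo, q_hi = np.quantile(perm_slopes, [0.025, 0.975])
    return observed, (observed - float(q_hi), observed - float(q_lo))


def group_similarity(
    dist: DistanceMatrix,
    meta: SampleMetadata,
    anchors: list[str],
    targets: list[str] | None = None,
    intra: bool = False,
) -> pd.Series:
    """Average similarity per anchor individual against a target group.

    For each anchor subject the value is the mean of ``1 - d`` over all
    pairs of that subject's samples with the target subjects' samples
    (excluding the anchor's own samples).  With ``intra=True`` the target is
    the anchor itself and the mean runs over its n(n-1)/2 distinct sample
    pairs.
    """
    present = set(dist.ids)
    sim = 1.0 - dist.values
    index = {s: i for i, s in enumerate(dist.ids)}
    out = {}
    for anchor in anchors:
        a_samples = [s for s in meta.samples_of(anchor) if s in present]
        if not a_samples:
            raise ValueError(f"anchor {anchor!r} has no samples in the matrix")
        a_idx = [index[s] for s in a_samples]
        if intra:
            if len(a_idx) < 2:
                raise ValueError(f"anchor {anchor!r} needs >= 2 samples for intra similarity")
            block = sim[np.ix_(a_idx, a_idx)]
            iu = np.triu_indices(len(a_idx), k=1)
            out[anchor] = float(block[iu].mean())
        else:
            if targets is None:
                raise ValueError("targets required unless intra=True")
            t_subjects = [t for t in targets if t != anchor]
            if not t_subjects:
                raise ValueError(
                    f"target group for anchor {anchor!r} is empty after removing the anchor"
                )
            t_samples = [
                s for t in t_subjects for s in meta.samples_of(t) if s in present
            ]
            if not t_samples:
                raise ValueError(f"no target samples in the matrix for anchor {anchor!r}")
            t_idx = [index[s] for s in t_samples]
            out[anchor] = float(sim[np.ix_(a_idx, t_idx)].mean())
    return pd.Series(out, name="mean_similarity")


# ---------------------------------------------------------------------------
# exact nonparametric tests
# ---------------------------------------------------------------------------

def _doubled_midranks(values: np.ndarray) -> np.ndarray:
    """Midranks scaled by 2 so ties (.5 ranks) become exact integers."""
    ranks = scipy.stats.rankdata(values)
    doubled = np.round(ranks * 2).astype(np.int64)
    return doubled


def wilcoxon_rank_sum(x, y, mode: str = "exact") -> tuple[float, float]:
    """Two-sample Wilcoxon/Mann-Whitney rank-sum test (two-sided).

    ``exact`` enumerates the full permutation null of the rank sum of ``x``
    over all C(n+m, n) labelings (via a subset-sum dynamic program over
    midranks, so ties are handled exactly); it is used automatically for
    n + m <= 20 and on request otherwise.  ``normal_approx`` uses the
    continuity-corrected normal approximation.  Returns (rank sum of x,
    two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if mode == "exact":
        r2 = np.round(ranks * 2).astype(np.int64)
        n1, total_sum = x.size, int(r2.sum())
        # f[k, s] = number of size-k subsets of the midrank multiset with sum s
        f = np.zeros((n1 + 1, total_sum + 1))
        f[0, 0] = 1.0
        for r in r2:
            for k in range(n1, 0, -1):
                f[k, r:] += f[k - 1, : total_sum + 1 - r]
        dist = f[n1]
        n_subsets = dist.sum()
        w2 = int(round(2 * w))
        lower = dist[: w2 + 1].sum() / n_subsets
        upper = dist[w2:].sum() / n_subsets
        p = min(1.0, 2.0 * min(lower, upper))
        return w, float(p)
    if mode == "normal_approx":
        res = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        return w, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")


def wilcoxon_signed_rank(a, b=None, mode: str = "exact") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test (two-sided).

    Accepts either paired vectors ``a, b`` or a single vector of
    differences.  Zeros are dropped; with no non-zero differences the test
    degenerates (warning, p = 1).  ``exact`` enumerates all 2^n sign
    assignments of the midranked absolute differences via a dynamic
    program.  Returns (W+, two-sided p).
    """
    a = np.asarray(a, dtype=float)
    d = a if b is None else a - np.asarray(b, dtype=float)
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; signed-rank test is degenerate")
        return 0.0, 1.0
    if d.size < 2:
        warnings.warn("fewer than 2 non-zero differences; signed-rank test has no power")
    ranks = scipy.stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if mode == "exact":
        r2 = np.round(ranks * 2).astype(np.int64)
        total_sum = int(r2.sum())
        # g[s] = number of sign assignments whose positive-rank sum is s
        g = np.zeros(total_sum + 1)
        g[0] = 1.0
        for r in r2:
            g[r:] += g[: total_sum + 1 - r]
        n_assignments = g.sum()  # = 2 ** n
        w2 = int(round(2 * w_plus))
        lower = g[: w2 + 1].sum() / n_assignments
        upper = g[w2:].sum() / n_assignments
        p = min(1.0, 2.0 * min(lower, upper))
        return w_plus, float(p)
    if mode == "normal_approx":
        res = scipy.stats.wilcoxon(d, correction=True, method="approx")
        return w_plus, float(res.pvalue)
    raise ValueError(f"unknown mode {mode!r}")
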