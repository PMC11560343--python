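"""Group disparity and hypothesis tests.

Disparity of a group is the sum over ordination axes of the sample
variance (n-1 denominator) of the group's scores — the usual
sum-of-variances morphospace-volume proxy, which is relatively robust to
sample-size differences. Distributions are obtained by bootstrapping
group rows with replacement at constant n, and group pairs are compared
with two-sided Mann-Whitney tests on the bootstrap replicate vectors,
Bonferroni-corrected over the number of pairs.

Caveat, by design: replicates of a bootstrap distribution are not
independent samples, so the Wilcoxon p-values are to be read as a ranking
device over replicate distributions (mirroring common disparity-testing
practice), not as exact frequentist error rates.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

__all__ = [
    "DisparityResult",
    "sum_of_variances",
    "bootstrap_disparity",
    "mann_whitney_u",
    "bonferroni_adjust",
    "compare_disparities",
    "pairwise_group_means",
    "pearson_correlation",
]

#: groups smaller than this are summarized but excluded from pair tests
MIN_TEST_GROUP_SIZE = 3


def _subset_scores(scores: pd.DataFrame, subset) -> np.ndarray:
    subset = list(subset)
    missing = [s for s in subset if s not in scores.index]
    if missing:
        raise InputError(f"species absent from scores: {missing}")
    return scores.loc[subset].to_numpy(dtype=float)


def sum_of_variances(scores: pd.DataFrame, subset=None) -> float:
    """Sum over axes of the subset's per-axis sample variance.

    A subset with fewer than two members has undefined variance and
    returns 0.0 with a warning.
    """
    x = (
        scores.to_numpy(dtype=float)
        if subset is None
        else _subset_scores(scores, subset)
    )
    if x.shape[0] < 2:
        warnings.warn("subset has < 2 members; sum of variances set to 0", stacklevel=2)
        return 0.0
    return float(np.var(x, axis=0, ddof=1).sum())


def bootstrap_disparity(
    scores: pd.DataFrame, subset, n_boot: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Bootstrap the sum of variances of one group.

    Each replicate resamples the group's rows with replacement at the
    group's own n (no rarefaction) and recomputes the metric.
    """
    if not isinstance(n_boot, (int, np.integer)) or n_boot < 1:
        raise InputError(f"n_boot must be a positive integer, got {n_boot!r}")
    x = _subset_scores(scores, subset)
    n = x.shape[0]
    if n < 2:
        raise InputError("bootstrap needs a subset of >= 2 members")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    reps = np.empty(n_boot)
    for b in range(n_boot):
        reps[b] = np.var(x[idx[b]], axis=0, ddof=1).sum()
    return reps


# ---------------------------------------------------------------------------
# Mann-Whitney


def _exact_mann_whitney_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Two-sided exact p by full enumeration of rank labelings.

    The doubled one-tail convention is used: p = min(1, 2 * min(P(U <= u),
    P(U >= u))) over all C(nx+ny, nx) equally likely assignments.
    """
    nx = len(x)
    pooled = np.sort(np.concatenate([x, y]))
    n = len(pooled)
    offset = nx * (nx + 1) / 2
    lower = higher = total = 0
    for positions in itertools.combinations(range(n), nx):
        u_perm = sum(positions) + nx - offset  # ranks are positions+1
        total += 1
        if u_perm <= u:
            lower += 1
        if u_perm >= u:
            higher += 1
    return min(1.0, 2 * min(lower, higher) / total)


def _normal_mann_whitney_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Two-sided normal approximation with tie and continuity corrections."""
    nx, ny = len(x), len(y)
    n = nx + ny
    mu = nx * ny / 2
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = nx * ny / 12 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return math.nan  # all pooled values identical: test degenerate
    z = (abs(u - mu) - 0.5) / math.sqrt(sigma2)
    z = max(z, 0.0)
    return min(1.0, 2 * stats.norm.sf(z))


def mann_whitney_u(x, y, exact_limit: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney (Wilcoxon rank-sum) test.

    Returns ``(U, p)`` where U is the rank-sum statistic of ``x``
    (U = R_x - n_x(n_x+1)/2, midranks for ties). The p-value is exact by
    full enumeration when the pooled sample is small (n_x + n_y <=
    ``exact_limit``) and tie-free; otherwise the normal approximation with
    tie and continuity corrections is used. A degenerate comparison (all
    pooled values identical) yields ``p = nan``.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise InputError("Mann-Whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2)
    has_ties = np.unique(pooled).size < pooled.size
    if x.size + y.size <= exact_limit and not has_ties:
        p = _exact_mann_whitney_p(x, y, u)
    else:
        p = _normal_mann_whitney_p(x, y, u)
    return u, p


def bonferroni_adjust(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni correction: p_adj = min(1, p * m). NaNs pass through."""
    p = np.asarray(pvals, dtype=float)
    finite = p[np.isfinite(p)]
    if np.any((finite < 0) | (finite > 1)):
        raise InputError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise InputError(f"m={m} is smaller than the number of p-values ({p.size})")
    return np.minimum(1.0, p * m)


# ---------------------------------------------------------------------------
# group comparisons


@dataclass
class DisparityResult:
    """Per-group disparity estimates plus the pairwise test table.

    ``groups`` columns: group, n, disparity, boot_mean, boot_q025,
    boot_q975, tested. ``pairs`` columns: group_a, group_b, W, p_raw,
    p_adj, degenerate.
    """

    groups: pd.DataFrame
    pairs: pd.DataFrame
    replicates: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    n_boot: int = 0
    seed: int | None = None


def compare_disparities(
    scores: pd.DataFrame,
    grouping: pd.Series,
    n_boot: int = 100,
    seed: int = 0,
    min_group_size: int = MIN_TEST_GROUP_SIZE,
) -> DisparityResult:
    """Bootstrap sum-of-variances comparison across the levels of one
    grouping scheme.

    ``grouping`` maps species id -> group label and must cover the score
    rows it references. Groups need n >= 2 for a point estimate and
    bootstrap; groups below ``min_group_size`` are reported but excluded
    from the pairwise tests (with a warning). Pairwise two-sided
    Mann-Whitney tests run on the replicate vectors and are Bonferroni
    adjusted over the number of pairs tested.
    """
    grouping = grouping.dropna()
    levels = sorted(grouping.unique())
    members = {g: grouping.index[grouping == g].tolist() for g in levels}
    usable = [g for g in levels if len(members[g]) >= 2]
    if len(usable) < 2:
        raise InputError(
            f"need >= 2 groups with >= 2 members, got {len(usable)} of {len(levels)}"
        )

    rng = np.random.default_rng(seed)
    rows, replicates = [], {}
    for g in levels:
        n = len(members[g])
        tested = n >= min_group_size
        if n >= 2:
            point = sum_of_variances(scores, members[g])
            reps = bootstrap_disparity(scores, members[g], n_boot, rng)
            replicates[g] = reps
            if not tested:
                warnings.warn(
                    f"group {g!r} has n={n} < {min_group_size}; reported but "
                    "excluded from pairwise tests",
                    stacklevel=2,
                )
            rows.append(
                {
                    "group": g,
                    "n": n,
                    "disparity": point,
                    "boot_mean": reps.mean(),
                    "boot_q025": np.quantile(reps, 0.025),
                    "boot_q975": np.quantile(reps, 0.975),
                    "tested": tested,
                }
            )
        else:
            warnings.warn(f"group {g!r} has n={n} < 2; no disparity estimate", stacklevel=2)
            rows.append(
                {
                    "group": g,
                    "n": n,
                    "disparity": np.nan,
                    "boot_mean": np.nan,
                    "boot_q025": np.nan,
                    "boot_q975": np.nan,
                    "tested": False,
                }
            )
    group_table = pd.DataFrame(rows)

    tested_groups = group_table.loc[group_table["tested"], "group"].tolist()
    pair_rows = []
    pairs = list(itertools.combinations(tested_groups, 2))
    for ga, gb in pairs:
        ra, rb = replicates[ga], replicates[gb]
        degenerate = np.unique(np.concatenate([ra, rb])).size == 1
        if degenerate:
            w, p = float(len(ra) * len(rb)) / 2, math.nan
        else:
            w, p = mann_whitney_u(ra, rb)
        pair_rows.append(
            {"group_a": ga, "group_b": gb, "W": w, "p_raw": p, "degenerate": degenerate}
        )
    pair_table = pd.DataFrame(
        pair_rows, columns=["group_a", "group_b", "W", "p_raw", "degenerate"]
    )
    if len(pair_table):
        pair_table["p_adj"] = bonferroni_adjust(pair_table["p_raw"], m=len(pairs))
    else:
        pair_table["p_adj"] = pd.Series(dtype=float)
    pair_table = pair_table[["group_a", "group_b", "W", "p_raw", "p_adj", "degenerate"]]

    return DisparityResult(
        groups=group_table,
        pairs=pair_table,
        replicates=replicates,
        n_boot=n_boot,
        seed=seed if isinstance(seed, int) else None,
    )


def pairwise_group_means(
    values, groups, welch: bool = False, min_group_size: int = 2
) -> pd.DataFrame:
    """Bonferroni-corrected pairwise t-tests of group means.

    By default the pooled standard deviation is estimated from *all*
    groups (df = N - k), matching the classical pairwise procedure;
    ``welch=True`` switches to per-pair Welch tests instead.
    """
    values = pd.Series(np.asarray(values, dtype=float))
    groups = pd.Series(np.asarray(groups)).reset_index(drop=True)
    if len(values) != len(groups):
        raise InputError("values and groups have different lengths")

    by_group = {}
    for g in pd.unique(groups):
        x = values[groups == g].to_numpy()
        if len(x) < min_group_size:
            warnings.warn(f"group {g!r} has n={len(x)} < {min_group_size}; excluded", stacklevel=2)
            continue
        by_group[g] = x
    if len(by_group) < 2:
        raise InputError("need >= 2 groups with enough members for t-tests")

    n_total = sum(len(x) for x in by_group.values())
    k = len(by_group)
    pooled_df = n_total - k
    pooled_var = sum(((len(x) - 1) * np.var(x, ddof=1)) for x in by_group.values()) / pooled_df
    pooled_sd = math.sqrt(pooled_var)

    rows = []
    pairs = list(itertools.combinations(by_group, 2))
    for ga, gb in pairs:
        xa, xb = by_group[ga], by_group[gb]
        if welch:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
            df = np.nan
        else:
            se = pooled_sd * math.sqrt(1 / len(xa) + 1 / len(xb))
            if se == 0:
                t, p, df = 0.0, 1.0, pooled_df
            else:
                t = (xa.mean() - xb.mean()) / se
                df = pooled_df
                p = 2 * stats.t.sf(abs(t), df)
        rows.append({"group_a": ga, "group_b": gb, "t": float(t), "df": df, "p_raw": float(p)})
    table = pd.DataFrame(rows)
    table["p_adj"] = bonferroni_adjust(table["p_raw"], m=len(pairs))
    return table


def pearson_correlation(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the two-sided t-distribution p-value.

    p is derived from t = R * sqrt((n-2) / (1-R^2)) on n-2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise InputError("x and y must have the same length")
    n = x.size
    if n < 3:
        raise InputError("Pearson correlation needs n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InputError("Pearson correlation undefined for constant input")
    xc, yc = x - x.mean(), y - y.mean()
    r = float((xc @ yc) / math.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return r, float(p)
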