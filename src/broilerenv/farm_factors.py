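"""Farm-factor analysis: 1-D k-means clustering and one-way ANOVA.

Continuous farm attributes (altitude, litter-reuse cycles, downtime,
transport distance) are clustered per variable with k-means (solved exactly
in one dimension via dynamic programming over contiguous sorted runs); the
number of clusters is chosen by an information criterion.  For a one-dimensional
k-means with within-cluster sum of squares ``wss`` on ``n`` points,

    AIC = n*ln(wss/n) + 2k        BIC = n*ln(wss/n) + k*ln(n)

and the model with the lowest BIC is selected (ties toward smaller k); both
criteria are reported.  Cluster (or categorical factor) membership then
enters a one-way ANOVA on 35-d performance, with least-squares mean
separation by Tukey's HSD (more than two groups) or Student's t (exactly
two), summarised as a compact letter display at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClusterModel",
    "AnovaResult",
    "kmeans_fit",
    "select_k",
    "one_way_anova",
    "mean_separation",
    "factor_analysis",
]

_WSS_FLOOR = 1e-12  # avoid ln(0) for degenerate (zero-variance) fits


@dataclass
class ClusterModel:
    """One k-means fit of a single continuous variable."""

    variable: str
    k: int
    centers: np.ndarray          # sorted ascending
    center_sd: np.ndarray        # per-cluster SD of members
    assignments: np.ndarray      # cluster index per observation (center order)
    wss: float
    aic: float
    bic: float
    n_iter: int


def _information_criteria(wss: float, n: int, k: int) -> tuple[float, float]:
    w = max(wss, _WSS_FLOOR)
    base = n * np.log(w / n)
    return base + 2 * k, base + k * np.log(n)


def _dp_segment_cost(x_sorted: np.ndarray) -> callable:
    s1 = np.concatenate([[0.0], np.cumsum(x_sorted)])
    s2 = np.concatenate([[0.0], np.cumsum(x_sorted ** 2)])

    def cost(i: int, j: int) -> float:
        # within-SS of x_sorted[i:j] around its mean
        m = j - i
        s = s1[j] - s1[i]
        return max((s2[j] - s2[i]) - s * s / m, 0.0)

    return cost


def kmeans_fit(values, k: int, seed: int = 0, n_starts: int = 20,
               variable: str = "x") -> ClusterModel:
    """Globally optimal k-means of a 1-D variable.

    In one dimension the optimal clusters are contiguous runs of the sorted
    values, so the exact within-cluster-SS optimum is found by dynamic
    programming over split points — equivalent to multi-start Lloyd
    iterations run to the best possible convergence, without the risk of a
    local optimum.  ``seed`` and ``n_starts`` are accepted for interface
    compatibility but the solution is deterministic and exact.  Clusters
    are labelled so centers are ascending.  Raises when ``k`` exceeds the
    number of distinct values (centers would collide).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("no values to cluster")
    distinct = np.unique(x).size
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > distinct:
        raise ValueError(f"k={k} exceeds the {distinct} distinct values")
    order = np.argsort(x, kind="stable")
    xs = x[order]
    n = xs.size
    cost = _dp_segment_cost(xs)
    # dp[c][j]: best WSS splitting the first j sorted points into c clusters
    dp = np.full((k + 1, n + 1), np.inf)
    split = np.zeros((k + 1, n + 1), dtype=int)
    dp[0][0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = np.inf, c - 1
            for i in range(c - 1, j):
                v = dp[c - 1][i] + cost(i, j)
                if v < best:
                    best, arg = v, i
            dp[c][j] = best
            split[c][j] = arg
    # Recover cluster boundaries and labels in original order
    bounds = [n]
    j = n
    for c in range(k, 0, -1):
        j = split[c][j]
        bounds.append(j)
    bounds = bounds[::-1]
    labels_sorted = np.empty(n, dtype=int)
    for c in range(k):
        labels_sorted[bounds[c]:bounds[c + 1]] = c
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    centers = np.array([x[labels == j].mean() for j in range(k)])
    sd = np.array([x[labels == j].std(ddof=0) for j in range(k)])
    wss = float(dp[k][n])
    aic, bic = _information_criteria(wss, n, k)
    return ClusterModel(
        variable=variable, k=k, centers=centers, center_sd=sd,
        assignments=labels, wss=wss, aic=aic, bic=bic, n_iter=1,
    )


def select_k(values, k_range=(1, 2, 3, 4), seed: int = 0, n_starts: int = 20,
             variable: str = "x") -> ClusterModel:
    """Fit each k in ``k_range`` and return the lowest-BIC model.

    Ties are broken toward smaller k.  Candidate k larger than the number of
    distinct values are skipped.
    """
    k_range = sorted(set(int(k) for k in k_range))
    if not k_range:
        raise ValueError("k_range must be nonempty")
    x = np.asarray(values, dtype=float).ravel()
    distinct = np.unique(x).size
    best = None
    for k in k_range:
        if k > distinct:
            continue
        model = kmeans_fit(x, k, seed=seed, n_starts=n_starts, variable=variable)
        if best is None or model.bic < best.bic - 1e-12:
            best = model
    if best is None:
        raise ValueError("no feasible k in k_range for these values")
    return best


@dataclass
class AnovaResult:
    """One-way ANOVA of a response over factor levels, with LS-mean summary."""

    factor: str
    response: str
    levels: list
    group_n: np.ndarray
    group_means: np.ndarray
    sem: float           # sqrt(MS_within / harmonic mean n)
    cv_pct: float        # 100 * sqrt(MS_within) / grand mean
    f: float
    p: float
    df_between: int
    df_within: int
    ms_within: float
    ss_between: float
    ss_within: float
    letters: list[str] = field(default_factory=list)
    _groups: list = field(default_factory=list, repr=False)


def one_way_anova(groups: dict, factor: str = "factor",
                  response: str = "response") -> AnovaResult:
    """Fixed-effects one-way ANOVA from a mapping {level: values}.

    F = MS_between / MS_within on (g-1, N-g) degrees of freedom; the pooled
    SEM uses the harmonic mean of the group sizes.
    """
    levels = list(groups)
    data = [np.asarray(groups[lv], dtype=float).ravel() for lv in levels]
    if len(data) < 2:
        raise ValueError("need at least two groups")
    for lv, arr in zip(levels, data):
        if arr.size < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 observations")
    ns = np.array([a.size for a in data])
    means = np.array([a.mean() for a in data])
    allvals = np.concatenate(data)
    grand = allvals.mean()
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((a - m) ** 2).sum() for a, m in zip(data, means)))
    df_b = len(data) - 1
    df_w = allvals.size - len(data)
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w == 0:
        f = np.inf if ms_b > 0 else 0.0
        p = 0.0 if ms_b > 0 else 1.0
    else:
        f = ms_b / ms_w
        p = float(stats.f.sf(f, df_b, df_w))
    harm_n = len(ns) / (1.0 / ns).sum()
    sem = float(np.sqrt(ms_w / harm_n))
    cv = float(100.0 * np.sqrt(ms_w) / grand) if grand != 0 else np.nan
    return AnovaResult(
        factor=factor, response=response, levels=levels,
        group_n=ns, group_means=means, sem=sem, cv_pct=cv,
        f=float(f), p=p, df_between=df_b, df_within=df_w,
        ms_within=ms_w, ss_between=ss_between, ss_within=ss_within,
        _groups=data,
    )


def pairwise_p(anova: AnovaResult, i: int, j: int, method: str) -> float:
    """P-value of the (i, j) LS-mean comparison with the pooled variance.

    ``tukey`` uses the studentized range (Tukey-Kramer for unequal n);
    ``student_t`` an unadjusted two-sided t-test.
    """
    ni, nj = anova.group_n[i], anova.group_n[j]
    diff = abs(anova.group_means[i] - anova.group_means[j])
    msw, dfw = anova.ms_within, anova.df_within
    if msw == 0:
        return 0.0 if diff > 0 else 1.0
    if method == "tukey":
        se = np.sqrt(msw / 2.0 * (1.0 / ni + 1.0 / nj))
        q = diff / se
        return float(stats.studentized_range.sf(q, len(anova.levels), dfw))
    if method == "student_t":
        se = np.sqrt(msw * (1.0 / ni + 1.0 / nj))
        t = diff / se
        return float(2.0 * stats.t.sf(t, dfw))
    raise ValueError(f"unknown method {method!r}")


def mean_separation(anova: AnovaResult, method: str | None = None,
                    alpha: float = 0.05) -> list[str]:
    """Compact letter display for the group means at level ``alpha``.

    When ``method`` is None, Tukey's HSD is used for more than two groups
    and Student's t for exactly two.  Letters are assigned by the
    insert-and-absorb algorithm, then renamed so that 'a' labels the highest
    mean; groups sharing no letter differ significantly, groups sharing a
    letter do not.  The letters are also stored on ``anova.letters``.
    """
    g = len(anova.levels)
    if method is None:
        method = "tukey" if g > 2 else "student_t"
    sig = {(i, j): pairwise_p(anova, i, j, method) < alpha
           for i in range(g) for j in range(i + 1, g)}
    # Insert-and-absorb: start with one letter covering everything; split on
    # each significant pair; drop letters that become subsets of another.
    letters: list[set[int]] = [set(range(g))]
    for (i, j), is_sig in sig.items():
        if not is_sig:
            continue
        expanded: list[set[int]] = []
        for s in letters:
            if i in s and j in s:
                expanded.extend([s - {i}, s - {j}])
            else:
                expanded.append(s)
        uniq: list[set[int]] = []
        for a in expanded:
            if a and a not in uniq:
                uniq.append(a)
        letters = [a for a in uniq if not any(a < b for b in uniq)]
    # Order letters by the highest mean they contain, name a, b, c, ...
    order = np.argsort(-anova.group_means)
    rank = {int(gi): r for r, gi in enumerate(order)}
    letters.sort(key=lambda s: min(rank[m] for m in s) if s else g)
    names = "abcdefghijklmnopqrstuvwxyz"
    display = ["" for _ in range(g)]
    for name, s in zip(names, letters):
        for m in sorted(s):
            display[m] += name
    # Per-group letters sorted alphabetically for stable output
    display = ["".join(sorted(d)) for d in display]
    anova.letters = display
    return display


def factor_analysis(
    data: pd.DataFrame,
    factors: dict[str, str],
    responses: tuple[str, ...] = ("bw", "fcr", "cum_mortality"),
    k_range=(2, 3, 4),
    seed: int = 0,
    alpha: float = 0.05,
    min_group_n: int = 2,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cluster-and-ANOVA over many factors at once.

    ``factors`` maps column name -> 'continuous' (clustered first via
    :func:`select_k`) or 'categorical' (levels used as-is).  Rows with
    missing factor values are dropped per factor; levels with fewer than
    ``min_group_n`` rows are excluded.  Returns ``(cluster_report,
    anova_report)`` frames shaped like a means-and-letters table.
    """
    cluster_rows = []
    anova_rows = []
    for col, kind in factors.items():
        sub = data.dropna(subset=[col])
        if kind == "continuous":
            model = select_k(sub[col].to_numpy(), k_range=k_range, seed=seed,
                             variable=col)
            labels = [
                f"{model.centers[a]:.1f}" for a in model.assignments
            ]
            sub = sub.assign(_level=labels)
            for j in range(model.k):
                cluster_rows.append({
                    "variable": col, "k": model.k, "cluster": j,
                    "center": model.centers[j], "sd": model.center_sd[j],
                    "n": int((model.assignments == j).sum()),
                    "wss": model.wss, "aic": model.aic, "bic": model.bic,
                })
        elif kind == "categorical":
            sub = sub.assign(_level=sub[col].astype(str))
        else:
            raise ValueError(f"unknown factor kind {kind!r}")
        counts = sub["_level"].value_counts()
        keep_levels = counts[counts >= min_group_n].index
        sub = sub[sub["_level"].isin(keep_levels)]
        if sub["_level"].nunique() < 2:
            continue
        for resp in responses:
            groups = {lv: grp[resp].dropna().to_numpy()
                      for lv, grp in sub.groupby("_level", sort=True)}
            groups = {lv: v for lv, v in groups.items() if v.size >= min_group_n}
            if len(groups) < 2:
                continue
            res = one_way_anova(groups, factor=col, response=resp)
            letters = mean_separation(res, alpha=alpha)
            for lv, n, m, letter in zip(res.levels, res.group_n,
                                        res.group_means, letters):
                anova_rows.append({
                    "factor": col, "response": resp, "level": lv,
                    "n": int(n), "mean": m, "letter": letter,
                    "sem": res.sem, "cv_pct": res.cv_pct,
                    "F": res.f, "p": res.p,
                })
    return pd.DataFrame(cluster_rows), pd.DataFrame(anova_rows)
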