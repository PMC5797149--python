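"""Group-comparison statistics for per-animal metrics.

The battery mirrors standard practice in telemetric phenotyping:
normality screening routes each metric to a parametric or nonparametric
branch; one-way ANOVA with a Student-Newman-Keuls (SNK) step-down
post-hoc compares strains, two-way ANOVA with Sidak-adjusted pairwise
comparisons handles strain x day/night layouts, and Kruskal-Wallis with
Dunn's rank post-hoc covers skewed event counts.  Alpha is 0.05
throughout; studentized-range tail probabilities come from numerical
integration (``scipy.stats.studentized_range``), not tables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sstats

ALPHA = 0.05


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    statistic: float
    p_adjusted: float
    significant: bool
    note: str = ""


@dataclass
class ComparisonResult:
    test: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    adjustment: str = ""
    extra: dict = field(default_factory=dict)

    def pairwise_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"group_a": c.pair[0], "group_b": c.pair[1], "statistic": c.statistic,
             "p_adjusted": c.p_adjusted, "significant": c.significant, "note": c.note}
            for c in self.pairwise
        ])


def stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------- normality

def normality_check(values, alpha: float = ALPHA) -> tuple[bool, float]:
    """Shapiro-Wilk screen; returns (looks_normal, W statistic).

    Fewer than 3 observations or a degenerate (constant) sample cannot be
    assessed and force the nonparametric branch (False).
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 3 or np.ptp(x) == 0:
        return False, np.nan
    w, p = sstats.shapiro(x)
    return bool(p >= alpha), float(w)


# ------------------------------------------------------------ one-way + SNK

def one_way_anova_snk(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> ComparisonResult:
    """One-way ANOVA with the SNK studentized-range step-down post-hoc.

    SNK orders the group means and tests each pair with the studentized
    range at the span (number of means enclosed by the pair); a pair
    inside a span already declared non-significant is blocked: declared
    non-significant without testing (its reported p is floored at the
    blocking span's p).
    """
    groups = list(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in groups]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")

    f_stat, f_p = sstats.f_oneway(*arrays)
    n_total = sum(len(a) for a in arrays)
    k = len(groups)
    df_err = n_total - k
    grand_means = np.array([a.mean() for a in arrays])
    mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df_err

    order = np.argsort(grand_means)  # ascending
    ranked = [groups[i] for i in order]
    means = {g: float(np.asarray(samples[g]).mean()) for g in groups}
    ns = {g: len(samples[g]) for g in groups}

    # step-down over spans, widest first, with blocking
    nonsig_spans: list[tuple[int, int, float]] = []  # (lo, hi, p of the span test)
    results: dict[tuple[str, str], PairwiseComparison] = {}
    for span in range(k, 1, -1):
        for lo in range(0, k - span + 1):
            hi = lo + span - 1
            ga, gb = ranked[lo], ranked[hi]
            pair = tuple(sorted((ga, gb)))
            block = next((s for s in nonsig_spans if s[0] <= lo and hi <= s[1]), None)
            if block is not None:
                results[pair] = PairwiseComparison(
                    pair=pair, statistic=np.nan, p_adjusted=max(block[2], 0.0),
                    significant=False, note="blocked by enclosing span")
                continue
            diff = abs(means[ga] - means[gb])
            if mse == 0:
                q = np.inf if diff > 0 else 0.0
                p = 0.0 if diff > 0 else 1.0
            else:
                se = np.sqrt(mse / 2.0 * (1.0 / ns[ga] + 1.0 / ns[gb]))
                q = diff / se
                p = float(sstats.studentized_range.sf(q, span, df_err))
            sig = p < alpha
            results[pair] = PairwiseComparison(pair=pair, statistic=float(q),
                                               p_adjusted=p, significant=sig)
            if not sig:
                nonsig_spans.append((lo, hi, p))

    ordered_pairs = [results[tuple(sorted(p))] for p in itertools.combinations(groups, 2)]
    return ComparisonResult(
        test="one-way ANOVA + SNK", statistic=float(f_stat), p_value=float(f_p),
        pairwise=ordered_pairs, adjustment="studentized range (SNK step-down)",
        extra={"df": (k - 1, df_err), "mse": float(mse)},
    )


# ------------------------------------------------------- two-way + Sidak

def sidak_adjust(p: float, m: int) -> float:
    """Family-wise Sidak correction: 1 - (1 - p)^m."""
    if m < 1:
        raise ValueError("family size must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def two_way_anova_sidak(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "group",
    factor_b: str = "factor",
    alpha: float = ALPHA,
    compare: str = "b_within_a",
) -> ComparisonResult:
    """Two-way fixed-effects ANOVA on a complete layout with Sidak post-hoc.

    Sums of squares are computed in closed form for the (possibly
    unbalanced-in-n but complete) two-factor layout using cell means
    (type II equivalent for complete crossed designs with proportional
    emphasis on cells).  Pairwise comparisons (default: factor-B levels
    within each factor-A level, e.g. day vs night within each strain) use
    the residual MSE with a Sidak family of the comparisons reported.
    Missing cells are rejected.
    """
    a_levels = sorted(data[factor_a].unique())
    b_levels = sorted(data[factor_b].unique())
    cells: dict[tuple, np.ndarray] = {}
    for ai in a_levels:
        for bi in b_levels:
            v = data.loc[(data[factor_a] == ai) & (data[factor_b] == bi), value].to_numpy(float)
            if len(v) == 0:
                raise ValueError(f"missing cell: {factor_a}={ai!r}, {factor_b}={bi!r}")
            cells[(ai, bi)] = v

    # balanced-design sums of squares from cell means (exact for equal n;
    # the layouts this battery serves are complete and near-balanced)
    n_cell = {k: len(v) for k, v in cells.items()}
    cell_mean = {k: v.mean() for k, v in cells.items()}
    N = sum(n_cell.values())
    grand = sum(v.sum() for v in cells.values()) / N
    a_mean = {ai: np.mean([cell_mean[(ai, bi)] for bi in b_levels]) for ai in a_levels}
    b_mean = {bi: np.mean([cell_mean[(ai, bi)] for ai in a_levels]) for bi in b_levels}
    cg = np.mean(list(cell_mean.values()))
    nh = len(cells) / sum(1.0 / n for n in n_cell.values())  # harmonic cell n

    ss_a = nh * len(b_levels) * sum((a_mean[ai] - cg) ** 2 for ai in a_levels)
    ss_b = nh * len(a_levels) * sum((b_mean[bi] - cg) ** 2 for bi in b_levels)
    ss_ab = nh * sum(
        (cell_mean[(ai, bi)] - a_mean[ai] - b_mean[bi] + cg) ** 2
        for ai in a_levels for bi in b_levels
    )
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    df_a = len(a_levels) - 1
    df_b = len(b_levels) - 1
    df_ab = df_a * df_b
    df_err = N - len(cells)
    ms_err = ss_err / df_err

    def ftest(ss, df):
        if ms_err == 0:
            return np.inf if ss > 0 else 0.0, 0.0 if ss > 0 else 1.0
        f = (ss / df) / ms_err
        return float(f), float(sstats.f.sf(f, df, df_err))

    f_a, p_a = ftest(ss_a, df_a)
    f_b, p_b = ftest(ss_b, df_b)
    f_ab, p_ab = ftest(ss_ab, df_ab)

    if compare == "b_within_a":
        todo = [((ai, b1), (ai, b2)) for ai in a_levels
                for b1, b2 in itertools.combinations(b_levels, 2)]
    elif compare == "a_within_b":
        todo = [((a1, bi), (a2, bi)) for bi in b_levels
                for a1, a2 in itertools.combinations(a_levels, 2)]
    else:
        raise ValueError("compare must be 'b_within_a' or 'a_within_b'")
    m = len(todo)
    pairwise = []
    for ca, cb in todo:
        se = np.sqrt(ms_err * (1.0 / n_cell[ca] + 1.0 / n_cell[cb]))
        if se == 0:
            t = np.inf if cell_mean[ca] != cell_mean[cb] else 0.0
            p_raw = 0.0 if t else 1.0
        else:
            t = (cell_mean[ca] - cell_mean[cb]) / se
            p_raw = 2.0 * float(sstats.t.sf(abs(t), df_err))
        p_adj = sidak_adjust(min(p_raw, 1.0), m)
        name_a = f"{ca[0]}:{ca[1]}"
        name_b = f"{cb[0]}:{cb[1]}"
        pairwise.append(PairwiseComparison(
            pair=(name_a, name_b), statistic=float(t), p_adjusted=p_adj,
            significant=p_adj < alpha))

    return ComparisonResult(
        test="two-way ANOVA + Sidak", statistic=f_ab, p_value=p_ab,
        pairwise=pairwise, adjustment=f"Sidak, m={m}",
        extra={
            "F_a": f_a, "p_a": p_a, "F_b": f_b, "p_b": p_b,
            "F_interaction": f_ab, "p_interaction": p_ab,
            "df_err": df_err, "ms_err": float(ms_err),
        },
    )


# --------------------------------------------------- Kruskal-Wallis + Dunn

def kruskal_dunn(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> ComparisonResult:
    """Kruskal-Wallis H (tie-corrected) with Dunn's pairwise z post-hoc.

    Dunn's z compares mean ranks with the tie-corrected variance; the
    multiplicity adjustment is family-wise Sidak over all pairs.
    """
    groups = list(samples)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(samples[g], dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    N = len(pooled)
    if np.ptp(pooled) == 0:
        h, h_p = 0.0, 1.0
    else:
        h, h_p = sstats.kruskal(*arrays)

    ranks = sstats.rankdata(pooled)
    idx = np.cumsum([0] + [len(a) for a in arrays])
    mean_ranks = {g: ranks[idx[i]:idx[i + 1]].mean() for i, g in enumerate(groups)}
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (N - 1)) if N > 1 else 0.0
    base_var = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    pairwise = []
    for ga, gb in pairs:
        na, nb = len(samples[ga]), len(samples[gb])
        se = np.sqrt(base_var * (1.0 / na + 1.0 / nb))
        if se == 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[ga] - mean_ranks[gb]) / se
            p_raw = 2.0 * float(sstats.norm.sf(abs(z)))
        p_adj = sidak_adjust(min(p_raw, 1.0), m)
        pairwise.append(PairwiseComparison(
            pair=(ga, gb), statistic=float(z), p_adjusted=p_adj,
            significant=p_adj < alpha))
    return ComparisonResult(
        test="Kruskal-Wallis + Dunn", statistic=float(h), p_value=float(h_p),
        pairwise=pairwise, adjustment=f"Sidak, m={m}",
        extra={"mean_ranks": mean_ranks, "tie_term": tie_term},
    )


# ------------------------------------------------------------- descriptives

@dataclass(frozen=True)
class Descriptives:
    n: int
    mean: float
    sem: float
    median: float
    q1: float
    q3: float
    p5: float
    p95: float


def describe(values) -> Descriptives:
    """Descriptive set used in figures: median with 5-95 percentile /
    interquartile range, and mean +/- SEM."""
    x = np.asarray(values, dtype=float)
    if len(x) < 1:
        raise ValueError("need at least one value")
    sem = float(x.std(ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0
    return Descriptives(
        n=len(x), mean=float(x.mean()), sem=sem,
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)), q3=float(np.percentile(x, 75)),
        p5=float(np.percentile(x, 5)), p95=float(np.percentile(x, 95)),
    )


def route_and_compare(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> ComparisonResult:
    """Normality-screened routing: parametric (ANOVA+SNK) when every group
    passes Shapiro-Wilk, otherwise Kruskal-Wallis + Dunn."""
    normal = all(normality_check(v, alpha)[0] for v in samples.values())
    if normal:
        return one_way_anova_snk(samples, alpha)
    return kruskal_dunn(samples, alpha)
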