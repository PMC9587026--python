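"""Cohort validation statistics for biomarker panels.

Non-parametric group comparisons (Kruskal-Wallis with post-hoc pairwise
Mann-Whitney U and Benjamini-Hochberg correction), Spearman rank
correlations with Zou's confidence interval for comparing two dependent
overlapping correlations, Bland-Altman method agreement, and the
repeatability ("ergodicity") statistic

    e = Var_inter / (Var_intra + Var_inter)

which contrasts between-subject variance of subject means with pooled
within-subject variance over repeated visits.  e near 1 means subjects
occupy individual set points (high intra-individual clustering, low
ergodicity of the cohort as a whole).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "spearman_rho",
    "zou_ci_difference",
    "group_comparison",
    "bland_altman",
    "ergodicity",
    "correlation_edge_list",
    "BlandAltmanResult",
    "ErgodicityResult",
]


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midrank ties) with its p-value.

    Pairs with a missing value in either vector are dropped; at least three
    complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    if keep.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, got {int(keep.sum())}")
    rho, p = sps.spearmanr(x[keep], y[keep])
    return float(rho), float(p)


def zou_ci_difference(
    rho_1: float, rho_2: float, rho_overlap: float, n: int, alpha: float = 0.05
) -> tuple[float, float, bool]:
    """Zou's CI for the difference of two dependent overlapping correlations.

    ``rho_1`` = corr(x, y) and ``rho_2`` = corr(x, z) share the variable x;
    ``rho_overlap`` = corr(y, z).  Individual Fisher-z confidence limits are
    combined using the asymptotic correlation between the two estimates.
    Returns (low, high, different) where ``different`` flags 0 outside the CI.
    """
    for name, r in (("rho_1", rho_1), ("rho_2", rho_2), ("rho_overlap", rho_overlap)):
        if not -1 < r < 1:
            raise ValueError(f"{name} must be strictly inside (-1, 1), got {r!r}")
    if n < 4:
        raise ValueError("n must be >= 4")
    z = sps.norm.ppf(1 - alpha / 2)
    se = 1.0 / np.sqrt(n - 3)
    l1, u1 = np.tanh(np.arctanh(rho_1) - z * se), np.tanh(np.arctanh(rho_1) + z * se)
    l2, u2 = np.tanh(np.arctanh(rho_2) - z * se), np.tanh(np.arctanh(rho_2) + z * se)
    # asymptotic correlation between the two correlation estimates
    c = (
        (rho_overlap - 0.5 * rho_1 * rho_2)
        * (1 - rho_1**2 - rho_2**2 - rho_overlap**2)
        + rho_overlap**3
    ) / ((1 - rho_1**2) * (1 - rho_2**2))
    low = rho_1 - rho_2 - np.sqrt(
        (rho_1 - l1) ** 2 + (u2 - rho_2) ** 2 - 2 * c * (rho_1 - l1) * (u2 - rho_2)
    )
    high = rho_1 - rho_2 + np.sqrt(
        (u1 - rho_1) ** 2 + (rho_2 - l2) ** 2 - 2 * c * (u1 - rho_1) * (rho_2 - l2)
    )
    return float(low), float(high), not (low <= 0.0 <= high)


def group_comparison(values, groups) -> dict:
    """Kruskal-Wallis plus BH-corrected pairwise Mann-Whitney U tests.

    Returns a dict with the tie-corrected H statistic and p-value, and a
    list of pairwise records (group_a, group_b, U, p, p_adjusted).  The U
    test uses the exact null distribution for small tie-free samples and
    the tie/continuity-corrected normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    keep = ~np.isnan(values)
    values, groups = values[keep], groups[keep]
    labels = pd.unique(groups)
    samples = {lab: values[groups == lab] for lab in labels}
    small = [lab for lab, v in samples.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 observations: {list(map(str, small))}")
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    H, p_kw = sps.kruskal(*samples.values())
    pairs = list(itertools.combinations(labels, 2))
    raw_p, records = [], []
    for a, b in pairs:
        res = sps.mannwhitneyu(samples[a], samples[b], alternative="two-sided",
                               method="auto")
        raw_p.append(res.pvalue)
        records.append({"group_a": a, "group_b": b, "U": float(res.statistic),
                        "p": float(res.pvalue)})
    _, p_adj, _, _ = multipletests(raw_p, method="fdr_bh")
    for rec, adj in zip(records, p_adj):
        rec["p_adjusted"] = float(min(adj, 1.0))
    return {"H": float(H), "p": float(p_kw), "pairwise": records,
            "groups": [str(lab) for lab in labels]}


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement between two paired measurement methods."""

    bias: float
    loa_low: float
    loa_high: float
    proportional_bias_slope: float
    slope_ci: tuple[float, float]
    n: int


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland-Altman agreement of paired methods a and b.

    Differences d = a - b; bias = mean(d); limits of agreement
    bias +/- 1.96*sd(d); proportional bias as the least-squares slope of d
    on the pair means with its 95% CI.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("a and b must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(a)}")
    d = a - b
    means = (a + b) / 2.0
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if np.ptp(means) == 0 or sd == 0:
        slope, ci = 0.0, (0.0, 0.0)
    else:
        fit = sps.linregress(means, d)
        tcrit = sps.t.ppf(0.975, len(a) - 2)
        slope = float(fit.slope)
        ci = (slope - tcrit * fit.stderr, slope + tcrit * fit.stderr)
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
        proportional_bias_slope=slope,
        slope_ci=(float(ci[0]), float(ci[1])),
        n=len(a),
    )


@dataclass(frozen=True)
class ErgodicityResult:
    """Repeatability decomposition of repeated-visit measurements."""

    var_inter: float
    var_intra: float
    e: float
    n_subjects: int
    n_excluded: int


def ergodicity(measurements) -> ErgodicityResult:
    """Repeatability e = Var_inter/(Var_intra + Var_inter).

    ``measurements`` is a long-format DataFrame with columns ``subject``
    and ``value`` (or any 2-column frame in that order).  Var_intra is the
    unweighted mean of unbiased within-subject variances; Var_inter is the
    unbiased variance of subject means.  Subjects with fewer than two
    non-missing repeats are excluded with a warning.
    """
    df = pd.DataFrame(measurements)
    if "subject" not in df.columns or "value" not in df.columns:
        df = df.iloc[:, :2].set_axis(["subject", "value"], axis=1)
    df = df.dropna(subset=["value"])
    counts = df.groupby("subject")["value"].count()
    excluded = counts[counts < 2]
    if len(excluded):
        warnings.warn(
            f"excluding {len(excluded)} subject(s) with < 2 repeats",
            stacklevel=2,
        )
    kept = counts[counts >= 2].index
    if len(kept) < 2:
        raise ValueError("need >= 2 subjects with >= 2 repeats each")
    sub = df[df["subject"].isin(kept)]
    within = sub.groupby("subject")["value"].var(ddof=1)
    means = sub.groupby("subject")["value"].mean()
    var_intra = float(within.mean())
    var_inter = float(means.var(ddof=1))
    total = var_intra + var_inter
    e = var_inter / total if total > 0 else float("nan")
    return ErgodicityResult(
        var_inter=var_inter,
        var_intra=var_intra,
        e=float(e),
        n_subjects=len(kept),
        n_excluded=len(excluded),
    )


def correlation_edge_list(frame: pd.DataFrame, columns=None) -> pd.DataFrame:
    """All pairwise Spearman correlations among numeric columns.

    Returns an edge list (marker_a, marker_b, rho, p, p_adjusted) with
    Benjamini-Hochberg adjusted p-values, suitable for correlation-network
    maps.
    """
    cols = list(columns) if columns is not None else [
        c for c in frame.columns if pd.api.types.is_numeric_dtype(frame[c])
    ]
    rows = []
    for a, b in itertools.combinations(cols, 2):
        rho, p = spearman_rho(frame[a], frame[b])
        rows.append({"marker_a": a, "marker_b": b, "rho": rho, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        _, p_adj, _, _ = multipletests(out["p"], method="fdr_bh")
        out["p_adjusted"] = p_adj
    return out
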