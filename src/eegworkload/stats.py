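"""Statistical battery for workload contrasts.

Paired t with Cohen's d, one-way repeated-measures ANOVA with partial
eta squared, Fisher protected LSD, Pearson correlation with strength
categories, and Benjamini-Hochberg FDR.

Cohen's d uses the pooled-SD-of-conditions form
|mean(x) - mean(y)| / sqrt((sd(x)^2 + sd(y)^2) / 2) with sample SDs
(n - 1); this convention reproduces published worked examples computed
from condition means and SDs alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "PairedTestResult",
    "AnovaResult",
    "CorrelationResult",
    "paired_t",
    "cohen_d_from_summary",
    "rm_anova_one_way",
    "fisher_plsd",
    "pearson",
    "fdr_bh",
    "electrode_wise_contrast",
]


@dataclass(frozen=True)
class PairedTestResult:
    t: float
    df: int
    p: float
    d: float
    n: int


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float
    ms_error: float
    n_subjects: int


@dataclass(frozen=True)
class CorrelationResult:
    R: float
    p: float
    n: int
    strength: str


def cohen_d_from_summary(
    mean_x: float, sd_x: float, mean_y: float, sd_y: float
) -> float:
    """|mean difference| over the pooled SD of the two conditions."""
    return abs(mean_x - mean_y) / np.sqrt((sd_x**2 + sd_y**2) / 2.0)


def paired_t(x: np.ndarray, y: np.ndarray) -> PairedTestResult:
    """Two-sided paired t-test on differences x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    d = x - y
    sd_d = d.std(ddof=1)
    if sd_d == 0:
        raise ValueError("zero-variance differences")
    t = d.mean() / (sd_d / np.sqrt(n))
    p = 2.0 * sstats.t.sf(abs(t), df=n - 1)
    effect = cohen_d_from_summary(x.mean(), x.std(ddof=1), y.mean(), y.std(ddof=1))
    return PairedTestResult(t=float(t), df=n - 1, p=float(p), d=float(effect), n=n)


def rm_anova_one_way(data: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA on a (subjects x levels) matrix.

    SS_total = SS_subjects + SS_effect + SS_error;
    F = MS_effect / MS_error; partial eta^2 = SS_effect/(SS_effect+SS_error).
    No sphericity correction.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be subjects x levels")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing or non-finite cells")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 levels")
    grand = data.mean()
    ss_effect = n * np.sum((data.mean(axis=0) - grand) ** 2)
    ss_subjects = k * np.sum((data.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subjects
    df_effect = k - 1
    df_error = (n - 1) * (k - 1)
    ms_error = ss_error / df_error
    if ms_error <= 0:
        F, p = np.inf if ss_effect > 0 else 0.0, 0.0 if ss_effect > 0 else 1.0
    else:
        F = (ss_effect / df_effect) / ms_error
        p = float(sstats.f.sf(F, df_effect, df_error))
    denom = ss_effect + ss_error
    eta = float(ss_effect / denom) if denom > 0 else 0.0
    return AnovaResult(
        F=float(F),
        df_effect=df_effect,
        df_error=df_error,
        p=float(p),
        partial_eta_sq=eta,
        ms_error=float(ms_error),
        n_subjects=n,
    )


def fisher_plsd(
    data: np.ndarray,
    pairs: list[tuple[int, int]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher protected LSD pairwise comparisons after a RM-ANOVA.

    Pairwise t uses the ANOVA error term:
    t = (mean_i - mean_j) / sqrt(2 * MS_error / n), df = df_error.
    If the omnibus test is not significant at ``alpha`` the pairs are
    flagged unprotected and no p-values are reported.
    """
    data = np.asarray(data, dtype=float)
    omnibus = rm_anova_one_way(data)
    n, k = data.shape
    if pairs is None:
        pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    protected = omnibus.p < alpha
    rows = []
    means = data.mean(axis=0)
    se = np.sqrt(2.0 * omnibus.ms_error / n)
    for i, j in pairs:
        row: dict = {"level_i": i, "level_j": j, "protected": protected}
        if protected:
            t = (means[i] - means[j]) / se
            row["t"] = float(t)
            row["df"] = omnibus.df_error
            row["p"] = float(2.0 * sstats.t.sf(abs(t), df=omnibus.df_error))
        else:
            row["t"] = np.nan
            row["df"] = omnibus.df_error
            row["p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def _strength(r: float) -> str:
    a = abs(r)
    if a > 0.70:
        return "strong"
    if a >= 0.50:
        return "moderate"
    if a >= 0.30:
        return "weak"
    return "negligible"


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Product-moment correlation with two-sided p and a strength category."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be 1-D, equal length, n >= 3")
    r, p = sstats.pearsonr(x, y)
    return CorrelationResult(R=float(r), p=float(p), n=x.size, strength=_strength(r))


def fdr_bh(
    pvalues: np.ndarray, q: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (adjusted p-values, reject mask at q)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted <= q


def electrode_wise_contrast(
    table: pd.DataFrame, band: str, q: float = 0.05
) -> pd.DataFrame:
    """Per-channel paired contrast (high - low) of band power with FDR.

    ``table`` is a tidy band-power table with columns subject, condition
    ('low'/'high'), channel, band, power (blocks averaged first if
    present).  Positive t means higher power under high workload.  FDR
    is applied across channels within the band only.
    """
    sub = table[table["band"] == band]
    if sub.empty:
        raise ValueError(f"band {band!r} not in table")
    cell = sub.groupby(["subject", "condition", "channel"], as_index=False)[
        "power"
    ].mean()
    wide = cell.pivot_table(
        index="subject", columns=["condition", "channel"], values="power"
    )
    channels = sorted(cell["channel"].unique())
    rows = []
    for ch in channels:
        res = paired_t(wide[("high", ch)].to_numpy(), wide[("low", ch)].to_numpy())
        rows.append({"channel": ch, "t": res.t, "p": res.p, "d": res.d})
    out = pd.DataFrame(rows)
    adjusted, reject = fdr_bh(out["p"].to_numpy(), q=q)
    out["p_fdr"] = adjusted
    out["significant"] = reject
    out["direction"] = np.sign(out["t"]).astype(int)
    return out
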