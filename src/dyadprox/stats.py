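"""Descriptive and inferential reporting for the proximity study.

Paired mother-vs-father comparisons use the Wilcoxon signed-rank test with
zero differences dropped and a tie-corrected normal approximation for the
signed z statistic (exact sign-assignment enumeration below 6 informative
pairs).  Correlations are Pearson with pairwise-complete observations and a
per-cell n.  ``study_report`` renders deterministic summary tables and the
hourly proximity profile plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .proximity import hourly_profile  # noqa: F401  (re-exported for reports)


@dataclass(frozen=True)
class PairedComparison:
    n_pairs: int
    n_informative: int
    z: float
    p: float
    median_x: float
    median_y: float
    method: str


def _signed_rank_stat(d: np.ndarray) -> tuple[float, np.ndarray]:
    """W+ (sum of ranks of positive differences) and the midranks of |d|."""
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided p of the signed-rank statistic under sign flips.

    Dynamic programming over the distribution of W+ across all 2^n sign
    assignments of the |d| midranks (midranks are doubled to stay on an
    integer lattice, so ties are handled exactly).
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    _, ranks = _signed_rank_stat(d)
    r2 = np.round(2 * ranks).astype(int)  # midranks are multiples of 1/2
    total = int(r2.sum())
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[: total + 1 - r]
        pmf = 0.5 * (pmf + shifted)
    w2_obs = float(r2[d > 0].sum())
    mu2 = total / 2.0
    dev = abs(w2_obs - mu2)
    support = np.arange(total + 1)
    return float(pmf[np.abs(support - mu2) >= dev - 1e-9].sum())


def paired_signed_rank(
    x, y, continuity: bool = False, zero_method: str = "drop"
) -> PairedComparison:
    """Wilcoxon signed-rank test of paired samples x vs y.

    Pairs with a missing member are excluded before testing; zero differences
    are dropped (classic Wilcoxon).  The signed statistic is
    z = (W+ - n(n+1)/4) / sigma with the tie correction in sigma, so a
    negative z means x tends below y.  Up to 25 informative pairs the p-value
    is exact (sign-flip null distribution); beyond that the normal
    approximation is used.  All differences zero -> NaN result.
    """
    if zero_method != "drop":
        raise ValueError("only zero_method='drop' is implemented")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n_pairs = len(x)
    d = x - y
    d = d[d != 0]
    n = len(d)
    med_x = float(np.median(x)) if n_pairs else math.nan
    med_y = float(np.median(y)) if n_pairs else math.nan
    if n == 0:
        return PairedComparison(n_pairs, 0, math.nan, math.nan, med_x, med_y, "degenerate")

    w_plus, ranks = _signed_rank_stat(d)
    mu = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var <= 0:
        return PairedComparison(n_pairs, n, math.nan, math.nan, med_x, med_y, "degenerate")
    dev = w_plus - mu
    if continuity:
        dev = math.copysign(max(abs(dev) - 0.5, 0.0), dev)
    z = dev / math.sqrt(var)
    if n <= 25:
        p = exact_signed_rank_p(d)
        method = "exact"
    else:
        p = 2.0 * sps.norm.sf(abs(z))
        method = "normal"
    return PairedComparison(n_pairs, n, float(z), float(p), med_x, med_y, method)


def correlation_matrix(df: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Pearson correlations with pairwise-complete observations.

    Long output: variable_1, variable_2, r, n, p for each unordered pair of
    numeric columns.  Cells with fewer than ``min_n`` complete pairs or a
    constant variable report NaN.
    """
    cols = list(df.columns)
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = df[[a, b]].dropna()
            n = len(sub)
            if n < min_n or sub[a].nunique() < 2 or sub[b].nunique() < 2:
                r, p = math.nan, math.nan
            else:
                r, p = sps.pearsonr(sub[a], sub[b])
            rows.append({"variable_1": a, "variable_2": b, "r": r, "n": n, "p": p})
    return pd.DataFrame(rows, columns=["variable_1", "variable_2", "r", "n", "p"])


def _skewed_descriptives(values: pd.Series) -> dict:
    v = values.dropna()
    if len(v) == 0:
        return {"N": 0, "Mdn": math.nan, "Min": math.nan, "Max": math.nan, "M": math.nan}
    return {
        "N": int(len(v)),
        "Mdn": float(v.median()),
        "Min": float(v.min()),
        "Max": float(v.max()),
        "M": float(v.mean()),
    }


def proximity_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Frequency/duration descriptives with the paired mother-father test.

    Median/Min/Max are reported because frequency and duration are typically
    non-normal; pairing is within family across the mother and father dyads.
    """
    rows = []
    for var in ("freq_total", "dur_total_min"):
        by_role = {}
        for role in ("mother", "father"):
            sub = metrics[metrics["parent_role"] == role]
            by_role[role] = sub.set_index("family_id")[var]
            rows.append({"variable": var, "dyad": f"adolescent-{role}", **_skewed_descriptives(sub[var])})
        paired = pd.concat([by_role["mother"], by_role["father"]], axis=1, keys=["m", "f"]).dropna()
        cmp = paired_signed_rank(paired["f"], paired["m"])
        rows[-1].update({"z": cmp.z, "p": cmp.p, "n_pairs": cmp.n_pairs})
    return pd.DataFrame(rows)


def study_report(
    metrics: pd.DataFrame,
    events: pd.DataFrame,
    scores: pd.DataFrame,
    outdir: str | Path,
    profile: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Render the study-style tables (and the hourly profile plot) to disk.

    Deterministic: identical inputs produce byte-identical tables.  Returns
    the paths written, keyed by artifact name.  Empty inputs yield empty but
    valid tables.
    """
    from .scoring import summary_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    tab2 = proximity_table(metrics) if len(metrics) else pd.DataFrame()
    written["proximity_descriptives"] = outdir / "proximity_descriptives.csv"
    tab2.to_csv(written["proximity_descriptives"], index=False)

    tab3 = summary_table(scores) if len(scores) else pd.DataFrame()
    written["interaction_quality"] = outdir / "interaction_quality.csv"
    tab3.to_csv(written["interaction_quality"], index=False)

    if len(metrics) and len(scores):
        from .scoring import person_means

        pm = person_means(scores)
        wide = pm.pivot_table(index="person_id", columns="scale", values="mean", aggfunc="first")
        quant = metrics.groupby("adolescent_id")[["freq_total", "dur_total_min"]].mean()
        merged = wide.join(quant, how="outer")
        corr = correlation_matrix(merged)
    else:
        corr = pd.DataFrame()
    written["correlations"] = outdir / "correlations.csv"
    corr.to_csv(written["correlations"], index=False)

    if len(events):
        written["events"] = outdir / "events.csv"
        events.to_csv(written["events"], index=False)

    if profile is not None and len(profile):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 7, figsize=(18, 3), sharey=True)
        days = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat", "Sun"]
        for wd, ax in enumerate(axes):
            for role, color in (("mother", "tab:blue"), ("father", "tab:orange")):
                sub = profile[(profile["weekday"] == wd) & (profile["parent_role"] == role)]
                ax.plot(sub["hour"], sub["total"], color=color, label=role)
            ax.set_title(days[wd])
            ax.set_xlabel("hour")
        axes[0].set_ylabel("occurrences")
        axes[0].legend()
        fig.tight_layout()
        written["hourly_profile"] = outdir / "hourly_profile.png"
        fig.savefig(written["hourly_profile"], dpi=100)
        plt.close(fig)
        written["hourly_profile_table"] = outdir / "hourly_profile.csv"
        profile.to_csv(written["hourly_profile_table"], index=False)

    return written
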