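"""Group-level statistics for chromatin-domain feature tables.

Two families of comparison are provided, matching how imaging features are
analysed per modality:

* **SIM features** — one-sided two-sample t-tests (Welch by default)
  between conditions, plus a per-batch t-statistic summary: one t value
  per (batch, comparison), signed so that positive means the reference
  condition exceeds the other.
* **Feature-table cascades** — a normality gate (Shapiro-Wilk and
  Kolmogorov-Smirnov), then a Kruskal-Wallis omnibus test whose
  significance (p < alpha) unlocks pairwise Mann-Whitney U tests with
  Bonferroni correction over the pairs actually tested.

Significance stars are configurable; the default map is * p<0.05,
** p<0.01, *** p<0.001, with an alternative stricter map
(* p<0.01, ** p<0.001, *** p<0.0001) used by some figure conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

logger = logging.getLogger(__name__)

#: star maps as ascending (cutoff, label) pairs
METHODS_STAR_MAP = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
STRICT_STAR_MAP = ((0.0001, "***"), (0.001, "**"), (0.01, "*"))


@dataclass
class StatResult:
    test: str
    groups: tuple[str, ...]
    statistic: float
    pvalue: float
    sidedness: str = "two-sided"
    n_per_group: tuple[int, ...] = ()
    correction: str | None = None
    stars: str = ""


def significance_stars(
    p: float, threshold_map: tuple[tuple[float, str], ...] = METHODS_STAR_MAP
) -> str:
    """Label for a p value: the most extreme satisfied cutoff, else "ns"."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p value {p} outside [0, 1]")
    cutoffs = [c for c, _ in threshold_map]
    if cutoffs != sorted(cutoffs):
        raise ValueError("threshold map must be ordered by ascending cutoff")
    for cutoff, label in threshold_map:
        if p < cutoff:
            return label
    return "ns"


def one_sided_t(
    a: np.ndarray | list[float],
    b: np.ndarray | list[float],
    direction: str = "greater",
    equal_var: bool = False,
    star_map: tuple[tuple[float, str], ...] = METHODS_STAR_MAP,
) -> StatResult:
    """One-sided two-sample t-test of ``a`` versus ``b``.

    ``direction="greater"`` tests mean(a) > mean(b). Welch's unequal
    variance form is the default; ``equal_var=True`` selects the pooled
    form. Degenerate zero-variance inputs resolve by the sign of the mean
    difference (p = 0.5 at equality).
    """
    if direction not in ("greater", "less"):
        raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        diff = a.mean() - b.mean()
        if diff == 0:
            t, p = 0.0, 0.5
        else:
            favored = (diff > 0) == (direction == "greater")
            t = np.inf if diff > 0 else -np.inf
            p = 0.0 if favored else 1.0
    else:
        res = sp_stats.ttest_ind(a, b, equal_var=equal_var, alternative=direction)
        t, p = float(res.statistic), float(res.pvalue)
    return StatResult(
        test="t" if equal_var else "welch-t",
        groups=("a", "b"),
        statistic=t,
        pvalue=p,
        sidedness=direction,
        n_per_group=(len(a), len(b)),
        stars=significance_stars(p, star_map),
    )


def batch_t_summary(
    records: pd.DataFrame,
    feature: str,
    ref: str,
    others: list[str] | None = None,
    condition_col: str = "condition",
    batch_col: str = "batch",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-batch t statistics of ``ref`` against each other condition.

    The t statistic is signed positive when the reference condition's mean
    exceeds the other's within that batch. Batches missing either
    condition are skipped (logged). Returns columns batch, comparison, t,
    n_ref, n_other.
    """
    if others is None:
        others = [c for c in records[condition_col].unique() if c != ref]
    rows = []
    for batch, grp in records.groupby(batch_col):
        ref_vals = grp.loc[grp[condition_col] == ref, feature].dropna().to_numpy()
        for other in others:
            other_vals = grp.loc[grp[condition_col] == other, feature].dropna().to_numpy()
            if len(ref_vals) < 2 or len(other_vals) < 2:
                logger.info(
                    "batch %s skipped for %s vs %s: missing condition data",
                    batch, ref, other,
                )
                continue
            res = one_sided_t(ref_vals, other_vals, "greater", equal_var=equal_var)
            rows.append(
                {
                    "batch": batch,
                    "comparison": f"{ref} vs {other}",
                    "feature": feature,
                    "t": res.statistic,
                    "n_ref": len(ref_vals),
                    "n_other": len(other_vals),
                }
            )
    if not rows:
        raise ValueError(f"no batch contains both {ref} and {others}")
    return pd.DataFrame(rows)


@dataclass
class NormalityReport:
    shapiro_p: float
    ks_p: float
    verdict: str                      # "normal" | "non-normal"
    reason: str = ""
    alpha: float = 0.05


def normality_gate(values: np.ndarray | list[float], alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk plus Kolmogorov-Smirnov normality screen.

    The KS test compares against a normal with the sample's own mean and
    standard deviation. The verdict is "non-normal" if either test
    rejects at ``alpha``; non-normal data route to the non-parametric
    cascade. A constant sample is non-normal by convention.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise ValueError("normality tests need at least 3 observations")
    if np.ptp(x) == 0:
        return NormalityReport(
            shapiro_p=float("nan"), ks_p=float("nan"),
            verdict="non-normal", reason="constant sample", alpha=alpha,
        )
    sw_p = float(sp_stats.shapiro(x).pvalue)
    ks_p = float(sp_stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).pvalue)
    verdict = "non-normal" if (sw_p < alpha or ks_p < alpha) else "normal"
    return NormalityReport(shapiro_p=sw_p, ks_p=ks_p, verdict=verdict, alpha=alpha)


def kruskal_then_pairwise(
    groups: dict[str, np.ndarray | list[float]],
    alpha: float = 0.05,
    star_map: tuple[tuple[float, str], ...] = METHODS_STAR_MAP,
) -> list[StatResult]:
    """Kruskal-Wallis omnibus test, gated pairwise Mann-Whitney follow-up.

    Pairwise two-sided Mann-Whitney U tests run only when the omnibus
    p < alpha; their p values are Bonferroni-multiplied by the number of
    pairs tested (capped at 1). Returns the omnibus result first.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} has fewer than 2 observations")
    kw = sp_stats.kruskal(*arrays.values())
    results = [
        StatResult(
            test="kruskal-wallis",
            groups=tuple(arrays),
            statistic=float(kw.statistic),
            pvalue=float(kw.pvalue),
            n_per_group=tuple(v.size for v in arrays.values()),
            stars=significance_stars(float(kw.pvalue), star_map),
        )
    ]
    if kw.pvalue >= alpha:
        logger.info("omnibus p=%.3g >= %.2g: pairwise tests not run", kw.pvalue, alpha)
        return results
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    for ga, gb in pairs:
        mw = sp_stats.mannwhitneyu(arrays[ga], arrays[gb], alternative="two-sided")
        p_adj = min(1.0, float(mw.pvalue) * m)
        results.append(
            StatResult(
                test="mann-whitney",
                groups=(ga, gb),
                statistic=float(mw.statistic),
                pvalue=p_adj,
                n_per_group=(arrays[ga].size, arrays[gb].size),
                correction=f"bonferroni x{m}",
                stars=significance_stars(p_adj, star_map),
            )
        )
    return results
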