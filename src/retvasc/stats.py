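"""Two-group statistics: pooled-variance Student's t-tests (from raw
samples or printed summaries), noncentral-t power, and minimal sample-size
search for a two-sided two-sample design."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FEATURE_NAMES


@dataclass(frozen=True)
class TestResult:
    feature: str
    t: float
    df: int
    p: float
    significant: bool
    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def caption(self) -> str:
        """Figure-caption style summary with p to 4 decimals."""
        return (
            f"{self.feature}: {self.mean1:g} ± {self.sd1:g} vs "
            f"{self.mean2:g} ± {self.sd2:g} (P = {self.p:.4f})"
        )


def ttest_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    alpha: float = 0.05,
    feature: str = "",
) -> TestResult:
    """Unpaired two-tailed Student's t-test from group summaries.

    Uses the pooled variance sp^2 = ((n1-1)sd1^2 + (n2-1)sd2^2) / (n1+n2-2)
    and df = n1 + n2 - 2. Both SDs zero with equal means gives t=0, p=1;
    with unequal means the p-value underflows to the machine floor.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = mean1 - mean2
    if se == 0:
        if diff == 0:
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, diff)
            p = np.nextafter(0.0, 1.0)
    else:
        t = diff / se
        p = 2 * sps.t.sf(abs(t), df)
    return TestResult(
        feature=feature,
        t=t,
        df=df,
        p=float(p),
        significant=bool(p < alpha),
        mean1=mean1,
        sd1=sd1,
        n1=n1,
        mean2=mean2,
        sd2=sd2,
        n2=n2,
    )


def ttest_from_samples(
    samples1, samples2, alpha: float = 0.05, feature: str = ""
) -> TestResult:
    """Pooled t-test on raw values; identical to the summary form applied
    to the groups' own means/SDs/ns."""
    x = np.asarray(samples1, dtype=float)
    y = np.asarray(samples2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    return ttest_from_summary(
        float(x.mean()),
        float(x.std(ddof=1)),
        int(x.size),
        float(y.mean()),
        float(y.std(ddof=1)),
        int(y.size),
        alpha=alpha,
        feature=feature,
    )


def power_two_sample_t(d: float, n1: int, n2: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided pooled t-test via the noncentral t.

    Noncentrality delta = d * sqrt(n1*n2/(n1+n2)), df = n1+n2-2; power is
    the probability that |T'| exceeds the central-t critical value.
    """
    if d < 0:
        raise ValueError("effect size must be >= 0")
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    df = n1 + n2 - 2
    delta = d * math.sqrt(n1 * n2 / (n1 + n2))
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(t_crit, df, delta) + sps.nct.cdf(-t_crit, df, delta))


def required_sample_size(
    d: float,
    alpha: float = 0.05,
    target_power: float = 0.8,
    ratio: float = 1.0,
    max_n: int = 1_000_000,
) -> tuple[int, int, float]:
    """Smallest n1 (n2 = round(ratio * n1)) achieving the target power.

    Returns (n1, n2, achieved_power).
    """
    if d <= 0:
        raise ValueError("no finite sample size for a zero effect")
    if not (alpha < target_power < 1):
        raise ValueError("target_power must lie in (alpha, 1)")
    if ratio <= 0:
        raise ValueError("allocation ratio must be > 0")
    n1 = 2
    while n1 <= max_n:
        n2 = max(2, round(ratio * n1))
        achieved = power_two_sample_t(d, n1, n2, alpha=alpha)
        if achieved >= target_power:
            return n1, n2, achieved
        n1 += 1
    raise RuntimeError("sample-size search exceeded max_n")


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default)."""
    p = np.asarray(pvalues, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


def compare_feature_tables(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    holm: bool = False,
) -> dict:
    """Per-feature pooled t-tests between two feature tables.

    No multiple-testing correction is applied unless ``holm=True``.
    Returns a report dict with one TestResult-shaped entry per feature.
    """
    for table in (table_a, table_b):
        missing = [c for c in FEATURE_NAMES if c not in table.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
    results = {}
    for name in FEATURE_NAMES:
        res = ttest_from_samples(
            table_a[name].to_numpy(),
            table_b[name].to_numpy(),
            alpha=alpha,
            feature=name,
        )
        results[name] = res
    if holm:
        adj = holm_adjust([results[n].p for n in FEATURE_NAMES])
        for name, p_adj in zip(FEATURE_NAMES, adj):
            r = results[name]
            results[name] = TestResult(
                feature=r.feature,
                t=r.t,
                df=r.df,
                p=float(p_adj),
                significant=bool(p_adj < alpha),
                mean1=r.mean1,
                sd1=r.sd1,
                n1=r.n1,
                mean2=r.mean2,
                sd2=r.sd2,
                n2=r.n2,
            )
    return {
        "alpha": alpha,
        "holm": holm,
        "n1": int(len(table_a)),
        "n2": int(len(table_b)),
        "features": {
            name: {
                "t": results[name].t,
                "df": results[name].df,
                "p": round(results[name].p, 4),
                "significant": results[name].significant,
                "group1": {
                    "mean": results[name].mean1,
                    "sd": results[name].sd1,
                    "n": results[name].n1,
                },
                "group2": {
                    "mean": results[name].mean2,
                    "sd": results[name].sd2,
                    "n": results[name].n2,
                },
                "caption": results[name].caption(),
            }
            for name in FEATURE_NAMES
        },
    }
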