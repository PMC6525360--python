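"""Replicate-level statistical comparisons of outcrossing estimates.

Welch's unequal-variance two-sample t-test (Satterthwaite degrees of
freedom) compares treatments; a paired t-test compares the two maternal
genotypes within a treatment, paired by replicate.  Both statistics are
computed here from their defining formulas; tail probabilities come from
the exact Student t distribution.  Both tests are scale-invariant, so they
give identical results on outcrossing rates and on mean non-parental
frequencies (which differ by the constant factor 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from scipy.stats import t as t_dist


@dataclass
class TTestResult:
    test: str
    t: float
    df: float
    p: float  # two-sided
    n1: int
    n2: int
    flags: list[str] = field(default_factory=list)


def _mean_var(values: Sequence[float]) -> tuple[float, float]:
    n = len(values)
    m = sum(values) / n
    if len(set(values)) == 1:  # exactly constant, no float residue
        return m, 0.0
    v = sum((x - m) ** 2 for x in values) / (n - 1) if n > 1 else 0.0
    return m, v


def welch_t_test(group_a: Sequence[float], group_b: Sequence[float]) -> TTestResult:
    """Welch two-sample t-test, two-sided.

    t = (m_a - m_b) / sqrt(v_a/n_a + v_b/n_b); df by Welch–Satterthwaite.
    With both variances zero the test is degenerate: p = 1 if the means are
    equal, else p = 0, flagged.
    """
    na, nb = len(group_a), len(group_b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 values")
    ma, va = _mean_var(group_a)
    mb, vb = _mean_var(group_b)
    sa, sb = va / na, vb / nb
    if sa + sb == 0:
        equal = math.isclose(ma, mb)
        return TTestResult(
            "welch",
            0.0 if equal else math.inf,
            float(na + nb - 2),
            1.0 if equal else 0.0,
            na,
            nb,
            ["degenerate_zero_variance"],
        )
    t = (ma - mb) / math.sqrt(sa + sb)
    denom = sa**2 / (na - 1) + sb**2 / (nb - 1)
    # squares of subnormal variances can underflow to 0; fall back to the
    # pooled df, where t is effectively infinite anyway
    df = (sa + sb) ** 2 / denom if denom > 0 else float(na + nb - 2)
    p = 2.0 * t_dist.sf(abs(t), df)
    return TTestResult("welch", t, df, p, na, nb)


def paired_t_test(pairs: Sequence[tuple[float, float]]) -> TTestResult:
    """One-sample t-test on paired differences, df = n - 1, two-sided.

    All-zero differences give p = 1 by convention, flagged.
    """
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    diffs = [x - y for x, y in pairs]
    md, vd = _mean_var(diffs)
    df = float(n - 1)
    if vd == 0:
        if md == 0:
            return TTestResult(
                "paired", 0.0, df, 1.0, n, n, ["degenerate_zero_variance"]
            )
        return TTestResult(
            "paired", math.inf, df, 0.0, n, n, ["degenerate_zero_variance"]
        )
    t = md / math.sqrt(vd / n)
    p = 2.0 * t_dist.sf(abs(t), df)
    return TTestResult("paired", t, df, p, n, n)


def run_stats(
    estimates: pd.DataFrame,
    value_col: str = "outcrossing_rate",
    treatment_col: str = "treatment",
    genotype_col: str = "genotype",
    replicate_col: str = "replicate",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """The study's comparisons on an estimates table.

    Within each treatment: paired t-test between the two genotypes, paired
    by replicate.  Across treatments (when exactly two): Welch t-test on
    all values.  Raw p-values by default; ``bonferroni`` multiplies them by
    the number of tests for users who want a family-wise correction.
    """
    rows = []
    treatments = sorted(estimates[treatment_col].unique())
    for treat in treatments:
        sub = estimates[estimates[treatment_col] == treat]
        genos = sorted(sub[genotype_col].unique())
        if len(genos) != 2:
            rows.append(
                {
                    "test": "paired",
                    "comparison": f"{treat}: genotypes",
                    "note": f"skipped ({len(genos)} genotype(s))",
                }
            )
            continue
        a = sub[sub[genotype_col] == genos[0]].set_index(replicate_col)[value_col]
        b = sub[sub[genotype_col] == genos[1]].set_index(replicate_col)[value_col]
        common = sorted(set(a.index) & set(b.index))
        if len(common) < 2:
            rows.append(
                {
                    "test": "paired",
                    "comparison": f"{treat}: {genos[0]} vs {genos[1]}",
                    "note": "skipped (<2 complete pairs)",
                }
            )
            continue
        res = paired_t_test([(a[r], b[r]) for r in common])
        rows.append(
            {
                "test": "paired",
                "comparison": f"{treat}: {genos[0]} vs {genos[1]}",
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "n": len(common),
                "note": ";".join(res.flags),
            }
        )
    if len(treatments) == 2:
        ga = estimates[estimates[treatment_col] == treatments[0]][value_col].tolist()
        gb = estimates[estimates[treatment_col] == treatments[1]][value_col].tolist()
        if len(ga) >= 2 and len(gb) >= 2:
            res = welch_t_test(ga, gb)
            rows.append(
                {
                    "test": "welch",
                    "comparison": f"{treatments[0]} vs {treatments[1]}",
                    "t": res.t,
                    "df": res.df,
                    "p": res.p,
                    "n": len(ga) + len(gb),
                    "note": ";".join(res.flags),
                }
            )
        else:
            rows.append(
                {
                    "test": "welch",
                    "comparison": f"{treatments[0]} vs {treatments[1]}",
                    "note": "skipped (group size < 2)",
                }
            )
    report = pd.DataFrame(rows)
    if bonferroni and "p" in report:
        n_tests = report["p"].notna().sum()
        report["p_bonferroni"] = (report["p"] * n_tests).clip(upper=1.0)
    return report
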