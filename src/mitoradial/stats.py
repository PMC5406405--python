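"""Group inference on per-cell measurements.

Conditions are compared by a two-tailed unpaired Student's t-test
(pooled variance) at alpha = 0.05, with each cell contributing one data
point; condition summaries report mean ± sample SD.  A Welch option
exists for sensitivity analysis but is not the default.  No
multiple-testing correction is applied; raw p-values are reported with
the alpha used.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

P_FLOOR = float(np.nextafter(0, 1))


@dataclass
class GroupComparison:
    condition_a: str
    condition_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    significant: bool
    alpha: float = 0.05
    flagged: str = ""

    def to_dict(self) -> dict:
        return {
            "condition_a": self.condition_a,
            "condition_b": self.condition_b,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value": self.p_value,
            "significant": self.significant,
            "alpha": self.alpha,
            "flagged": self.flagged,
        }


def ttest_unpaired(
    a: Sequence[float],
    b: Sequence[float],
    alpha: float = 0.05,
    labels: tuple[str, str] = ("a", "b"),
    welch: bool = False,
) -> GroupComparison:
    """Two-tailed unpaired Student's t-test (pooled variance by default).

    Degenerate samples are handled explicitly: two identical constant
    groups give t = 0, p = 1; zero pooled variance with unequal means is
    reported at the machine-precision p floor and flagged.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError(f"need at least 2 values per group (got {a.size} and {b.size})")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    sd_a = float(a.std(ddof=1))
    sd_b = float(b.std(ddof=1))
    df = float(a.size + b.size - 2)
    flagged = ""

    pooled_sq = (np.sum((a - mean_a) ** 2) + np.sum((b - mean_b) ** 2)) / df
    if pooled_sq == 0.0 and not welch:
        if mean_a == mean_b:
            t, p = 0.0, 1.0
            flagged = "identical constant groups"
        else:
            t = float(np.sign(mean_a - mean_b)) * np.inf
            p = P_FLOOR
            flagged = "zero pooled variance with unequal means"
    else:
        res = sps.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
        if welch:
            df = float(res.df)
        if np.isnan(t):  # welch with two zero-variance groups
            t, p = 0.0, 1.0
            flagged = "identical constant groups"
    return GroupComparison(
        condition_a=labels[0],
        condition_b=labels[1],
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=mean_a,
        mean_b=mean_b,
        sd_a=sd_a,
        sd_b=sd_b,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
        flagged=flagged,
    )


def summarize_condition(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean ± sample SD (n−1 denominator) per condition; SD absent at n = 1."""
    rows = []
    for cond, values in groups.items():
        v = np.asarray(values, dtype=np.float64)
        if v.size < 1:
            raise ValueError(f"condition {cond!r} has no values")
        rows.append(
            {
                "condition": cond,
                "n": int(v.size),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["condition", "n", "mean", "sd"])


def compare_all_pairs(
    groups: Mapping[str, Sequence[float]],
    metric: str,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """t-test every pair of conditions on one per-cell metric."""
    conds = sorted(groups)
    rows = []
    for i, ca in enumerate(conds):
        for cb in conds[i + 1 :]:
            cmp_ = ttest_unpaired(groups[ca], groups[cb], alpha=alpha, labels=(ca, cb), welch=welch)
            row = {"metric": metric, **cmp_.to_dict()}
            rows.append(row)
    return pd.DataFrame(rows)
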