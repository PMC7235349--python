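"""Two-group statistics on cluster abundances.

Mirrors the conventional analysis of such experiments: per-cluster group
means with SEM, KO/WT fold change, and a two-sided pooled-variance Student
t-test with significance called at p < alpha (default 0.01).  No
multiple-testing correction is applied; a Welch variant is available behind
a flag.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import betainc

from .errors import DataError

__all__ = ["GroupComparison", "sem", "students_t", "compare_groups", "compare_all", "comparisons_frame"]


@dataclass
class GroupComparison:
    """Result of one per-cluster WT-vs-KO comparison (percent units)."""

    cluster_id: int
    n_wt: int
    n_ko: int
    mean_wt: float
    sem_wt: float
    mean_ko: float
    sem_ko: float
    fold_change: float
    t_stat: float
    df: int
    p_value: float
    significant: bool
    alpha: float = 0.01


def sem(values: Sequence[float]) -> float:
    """Standard error of the mean: sample sd (n-1 denominator) / sqrt(n)."""
    v = np.asarray(values, dtype=np.float64)
    if v.size < 2:
        raise DataError("SEM needs at least 2 values")
    return float(np.std(v, ddof=1) / math.sqrt(v.size))


def students_t(
    group_a: Sequence[float], group_b: Sequence[float], welch: bool = False
) -> tuple[float, float, float]:
    """Two-sample t-test, two-sided.

    Default is the classic pooled-variance Student test with
    ``df = n_a + n_b - 2``; ``welch=True`` switches to unequal-variance
    Welch-Satterthwaite.  The p-value comes from the regularized incomplete
    beta function, ``p = I(df/2, 1/2; df/(df + t^2))``.

    Zero-variance degenerate inputs return ``(0, df, 1)`` when the means are
    equal, and ``(+/-inf, df, 0)`` with a warning otherwise.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise DataError("non-finite values in a group")
    ma, mb = float(a.mean()), float(b.mean())
    va, vb = float(a.var(ddof=1)), float(b.var(ddof=1))
    na, nb = a.size, b.size
    if welch:
        se2 = va / na + vb / nb
        if se2 > 0:
            df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
        else:
            df = float(na + nb - 2)
    else:
        df = float(na + nb - 2)
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se2 = sp2 * (1.0 / na + 1.0 / nb)
    if se2 == 0.0:
        if ma == mb:
            return 0.0, df, 1.0
        warnings.warn(
            "zero pooled variance with unequal means: degenerate t-test (p=0)",
            stacklevel=2,
        )
        return math.copysign(math.inf, ma - mb), df, 0.0
    t = (ma - mb) / math.sqrt(se2)
    p = float(betainc(df / 2.0, 0.5, df / (df + t * t)))
    return t, df, p


def compare_groups(
    table: pd.DataFrame, cluster_id: int, alpha: float = 0.01
) -> GroupComparison:
    """Assemble the WT-vs-KO comparison for one cluster of an abundance table.

    ``table`` is long-format with columns image_id, group (WT|KO),
    cluster_id, percent.  Fold change is defined KO/WT.
    """
    sub = table[table["cluster_id"] == cluster_id]
    wt = sub.loc[sub["group"] == "WT", "percent"].to_numpy(dtype=float)
    ko = sub.loc[sub["group"] == "KO", "percent"].to_numpy(dtype=float)
    if wt.size < 2 or ko.size < 2:
        raise DataError(
            f"cluster {cluster_id}: need >= 2 images per group "
            f"(got WT={wt.size}, KO={ko.size})"
        )
    mean_wt = float(wt.mean())
    if mean_wt == 0.0:
        raise DataError(f"cluster {cluster_id}: WT mean is zero; fold change undefined")
    t, df, p = students_t(ko, wt)
    return GroupComparison(
        cluster_id=int(cluster_id),
        n_wt=int(wt.size),
        n_ko=int(ko.size),
        mean_wt=mean_wt,
        sem_wt=sem(wt),
        mean_ko=float(ko.mean()),
        sem_ko=sem(ko),
        fold_change=float(ko.mean()) / mean_wt,
        t_stat=float(t),
        df=int(round(df)),
        p_value=float(p),
        significant=bool(p < alpha),
        alpha=float(alpha),
    )


def compare_all(table: pd.DataFrame, alpha: float = 0.01) -> list[GroupComparison]:
    """One :class:`GroupComparison` per cluster id, in ascending order."""
    return [
        compare_groups(table, int(cid), alpha=alpha)
        for cid in sorted(table["cluster_id"].unique())
    ]


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparisons to a DataFrame with exactly the result fields."""
    return pd.DataFrame([vars(c) for c in comparisons])
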