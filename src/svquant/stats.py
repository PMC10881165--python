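"""Group comparison statistics used by the reporting stage.

EM morphometry groups are compared by one-way ANOVA with Tukey post hoc
pairwise tests; mobile-puncta counts by pairwise t tests with Bonferroni
correction; decay-constant heterogeneity by the variance tests in
:mod:`svquant.kinetics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .kinetics import decay_variance_test

__all__ = ["GroupComparison", "group_compare", "fold_change", "percent_change"]


@dataclass
class GroupComparison:
    groups: list[str]
    means: dict[str, float]
    sems: dict[str, float]
    ns: dict[str, int]
    test: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame | None = None


def fold_change(numerator: float, denominator: float) -> float:
    """Fold change = B / A."""
    return float(numerator) / float(denominator)


def percent_change(reference: float, value: float) -> float:
    """Percent change relative to the reference: (A - B) / A × 100."""
    return (float(reference) - float(value)) / float(reference) * 100.0


def group_compare(
    values_by_group: dict[str, np.ndarray],
    test: str = "one_way_anova_tukey",
) -> GroupComparison:
    """Compare groups with the named procedure.

    ``test`` is one of ``one_way_anova_tukey``, ``t_bonferroni``, or
    ``f_variance``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    if len(groups) < 2:
        raise ValueError("group comparison needs >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group '{name}' has n < 2")
    names = list(groups)
    means = {k: float(np.mean(v)) for k, v in groups.items()}
    sems = {k: float(sps.sem(v)) for k, v in groups.items()}
    ns = {k: int(len(v)) for k, v in groups.items()}

    if test == "one_way_anova_tukey":
        F, p = sps.f_oneway(*groups.values())
        values = np.concatenate(list(groups.values()))
        labels = np.concatenate([[k] * len(v) for k, v in groups.items()])
        tk = pairwise_tukeyhsd(values, labels)
        pw = pd.DataFrame(
            tk.summary().data[1:], columns=tk.summary().data[0]
        )
        return GroupComparison(names, means, sems, ns, test, float(F), float(p), pw)

    if test == "t_bonferroni":
        rows = []
        raw_p = []
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                t, p = sps.ttest_ind(groups[a], groups[b])
                rows.append({"group1": a, "group2": b, "t": float(t), "p_raw": float(p)})
                raw_p.append(p)
        _, p_adj, _, _ = multipletests(raw_p, method="bonferroni")
        pw = pd.DataFrame(rows).assign(p_adj=p_adj)
        best = pw.loc[pw["p_adj"].idxmin()]
        return GroupComparison(
            names, means, sems, ns, test, float(best["t"]), float(best["p_adj"]), pw
        )

    if test == "f_variance":
        res = decay_variance_test(groups)
        return GroupComparison(
            names, means, sems, ns, test, res.statistic, res.p_value, None
        )

    raise ValueError(f"unknown test '{test}'")
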