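"""Drug-induced IR recovery across three ordered groups.

A locus shows reverse-V recovery when its intron ratio rises from control
to pre-treatment (IncIR) and falls back after treatment (DecIR between the
pre and post arms); V recovery is the mirror image.  Classification is the
Venn intersection of two two-group differential-IR runs; each trajectory
can additionally be tested by one-way ANOVA with Tukey HSD pairwise
comparisons.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, tukey_hsd

from .containers import IRCountTable, PsiMatrix
from .diff_ir import diff_ir
from .ir_quant import psi_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "venn_recovery",
    "anova_trajectory",
    "recovery_summary",
    "recovery_analysis",
    "AnovaResult",
]


def venn_recovery(diff_pre_vs_control: pd.DataFrame, diff_post_vs_pre: pd.DataFrame) -> pd.DataFrame:
    """Classify each event by intersecting the calls of the two legs.

    reverse_V = IncIR in (control vs pre) and DecIR in (pre vs post);
    V = the converse; anything else is none. Operates on the common event
    universe of the two result tables (warns when they differ).
    """
    a = diff_pre_vs_control.set_index("event_id")
    b = diff_post_vs_pre.set_index("event_id")
    common = a.index.intersection(b.index)
    if len(common) < len(a) or len(common) < len(b):
        warnings.warn(
            f"event universes differ ({len(a)} vs {len(b)}); "
            f"classifying the {len(common)} common events",
            stacklevel=2,
        )
    call_a = a.loc[common, "call"]
    call_b = b.loc[common, "call"]
    pattern = np.where(
        (call_a == "IncIR") & (call_b == "DecIR"),
        "reverse_V",
        np.where((call_a == "DecIR") & (call_b == "IncIR"), "V", "none"),
    )
    return pd.DataFrame({"event_id": common, "pattern": pattern}).reset_index(drop=True)


class AnovaResult(NamedTuple):
    F: float
    p: float
    tukey: pd.DataFrame


def anova_trajectory(psi_row, group_labels) -> AnovaResult:
    """One-way ANOVA across the (>=2 per-group) psi values of one event.

    Returns the omnibus F and p plus a Tukey HSD table of pairwise mean
    differences and studentized-range adjusted p-values.
    """
    psi_row = np.asarray(psi_row, dtype=float)
    group_labels = np.asarray(group_labels)
    order: list = []
    for g in group_labels:
        if g not in order:
            order.append(g)
    samples = []
    for g in order:
        vals = psi_row[(group_labels == g) & ~np.isnan(psi_row)]
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 non-missing psi values")
        samples.append(vals)
    F, p = f_oneway(*samples)
    hsd = tukey_hsd(*samples)
    rows = []
    for i, j in combinations(range(len(order)), 2):
        rows.append(
            (
                order[i],
                order[j],
                float(np.mean(samples[j]) - np.mean(samples[i])),
                float(hsd.pvalue[i, j]),
            )
        )
    tukey = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p_adj"])
    return AnovaResult(float(F), float(p), tukey)


def recovery_summary(calls: pd.DataFrame, psi: PsiMatrix | None = None) -> dict:
    """Tabulate recovery patterns; optionally add group-mean psi trajectories.

    Returns a dict with ``counts`` (per pattern), ``fractions``, and — when a
    psi matrix with group labels is supplied — ``mean_psi``: the per-group
    mean intron ratio of every recovered (reverse_V or V) event.
    """
    patterns = ["reverse_V", "V", "none"]
    counts = {pat: int((calls["pattern"] == pat).sum()) for pat in patterns}
    total = max(len(calls), 1)
    out = {
        "counts": counts,
        "n_events": len(calls),
        "fractions": {pat: counts[pat] / total for pat in patterns},
    }
    if psi is not None and psi.groups is not None:
        recovered = calls.loc[calls["pattern"] != "none", "event_id"]
        recovered = [e for e in recovered if e in psi.values.index]
        means = psi.values.loc[recovered].T.groupby(psi.groups).mean().T
        out["mean_psi"] = means
    return out


def recovery_analysis(
    table: IRCountTable,
    groups: tuple[str, str, str] | None = None,
    anova_p_max: float = 0.05,
    **diff_kwargs,
) -> dict:
    """Full recovery pipeline from a three-group count table.

    Runs differential IR on both legs (control vs pre, pre vs post),
    intersects the calls, then ANOVA-tests recovered trajectories with
    Tukey HSD applied when the omnibus p < ``anova_p_max``.
    """
    if groups is None:
        groups = tuple(table.groups)
    if len(groups) != 3:
        raise ValueError("recovery needs exactly three ordered groups")
    control, pre, post = groups
    leg1 = diff_ir(table, control, pre, **diff_kwargs)
    leg2 = diff_ir(table, pre, post, **diff_kwargs)
    calls = venn_recovery(leg1, leg2)

    psi = psi_matrix(table, coverage_min=diff_kwargs.get("coverage_min", 10))
    labels = table.samples.to_numpy()
    anova_rows = []
    for event_id in calls.loc[calls["pattern"] != "none", "event_id"]:
        if event_id not in psi.values.index:
            continue
        row = psi.values.loc[event_id].to_numpy()
        try:
            res = anova_trajectory(row, labels)
        except ValueError as exc:
            logger.info("recovery: ANOVA skipped for %s (%s)", event_id, exc)
            continue
        anova_rows.append(
            {
                "event_id": event_id,
                "F": res.F,
                "p": res.p,
                "tukey": res.tukey if res.p < anova_p_max else None,
            }
        )
    return {
        "leg1": leg1,
        "leg2": leg2,
        "calls": calls,
        "anova": anova_rows,
        "summary": recovery_summary(calls, psi),
    }
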