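"""Reporting layer: paired contrasts with Holm-Bonferroni adjustment.

The study design behind this package compares a within-subject condition
effect (control vs drug) between two groups (actuator-expressing vs
wild-type). The full analysis uses a mixed model with subject as a random
effect; the reduced mode replaces it with paired t statistics. In both modes
the gating rule holds: simple per-group contrasts are computed (and
Holm-adjusted) only when the interaction stage is significant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["paired_t", "holm_bonferroni", "contrast_report", "significance_stars"]


def paired_t(values_a, values_b) -> dict:
    """Two-tailed paired t-test; raises on zero variance of the differences."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("values_a and values_b must be equal-length 1-d vectors")
    if a.size < 2:
        raise ValueError("need n >= 2 pairs")
    d = a - b
    if np.std(d, ddof=1) == 0:
        raise ValueError("zero variance of the paired differences; "
                         "t statistic undefined")
    t, p = sps.ttest_rel(a, b)
    return {"t": float(t), "df": int(a.size - 1), "p": float(p)}


def holm_bonferroni(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values, order-preserving and monotone.

    The i-th smallest p-value is multiplied by (m - i), running maxima enforce
    monotonicity, and the result is clipped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a non-empty 1-d vector")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    m = p.size
    stepdown = p[order] * (m - np.arange(m))
    adjusted_sorted = np.minimum(np.maximum.accumulate(stepdown), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted


def significance_stars(p: float, ns_label: str = "ns") -> str:
    """Figure annotation at the 0.05 / 0.01 / 0.001 cutoffs."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ns_label


def _paired_table(table: pd.DataFrame, conditions: tuple[str, str]) -> pd.DataFrame:
    wide = table.pivot_table(index=["subject_id", "group"], columns="condition",
                             values="value", aggfunc="first")
    missing = wide[list(conditions)].isna().any(axis=1)
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} unpaired subject(s)",
                      stacklevel=3)
    return wide.loc[~missing].reset_index()


def _interaction_mixed(table: pd.DataFrame) -> float:
    import statsmodels.formula.api as smf
    data = table.rename(columns={"subject_id": "subject"}).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm("value ~ C(condition) * C(group)", data,
                            groups=data["subject"]).fit(reml=False)
    names = [n for n in model.params.index if ":" in n]
    return float(model.pvalues[names[0]])


def contrast_report(table: pd.DataFrame, conditions: tuple[str, str] = ("control", "drug"),
                    mode: str = "paired", alpha: float = 0.05) -> dict:
    """Interaction-gated per-group simple contrasts with Holm adjustment.

    ``table`` is long-format with columns subject_id, group, condition, value
    (paired design: each subject appears once per condition; unpaired subjects
    are dropped with a warning). The interaction stage tests whether the
    condition effect differs between groups: a two-sample Welch t-test on the
    within-subject differences in the reduced (``paired``) mode, or the Wald
    test of the condition x group term of a random-intercept mixed model
    (``mixed``). Only when the interaction is significant at ``alpha`` are the
    per-group paired contrasts computed, Holm-adjusted and annotated.
    """
    required = {"subject_id", "group", "condition", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = _paired_table(table, conditions)
    groups = sorted(wide["group"].unique())
    diffs = {g: (wide.loc[wide["group"] == g, conditions[1]].to_numpy()
                 - wide.loc[wide["group"] == g, conditions[0]].to_numpy())
             for g in groups}

    if mode == "mixed":
        long = table[table["subject_id"].isin(wide["subject_id"])]
        interaction_p = _interaction_mixed(long)
    elif mode == "paired":
        if len(groups) == 2:
            _, interaction_p = sps.ttest_ind(diffs[groups[0]], diffs[groups[1]],
                                             equal_var=False)
            interaction_p = float(interaction_p)
        else:
            interaction_p = np.nan
    else:
        raise ValueError("mode must be 'paired' or 'mixed'")

    report = {"interaction_p": interaction_p,
              "gated": bool(np.isfinite(interaction_p) and interaction_p < alpha),
              "contrasts": {}}
    if not report["gated"]:
        return report

    raw = []
    for g in groups:
        sub = wide[wide["group"] == g]
        res = paired_t(sub[conditions[1]].to_numpy(), sub[conditions[0]].to_numpy())
        raw.append((g, res))
    adjusted = holm_bonferroni([r["p"] for _, r in raw])
    for (g, res), p_adj in zip(raw, adjusted):
        report["contrasts"][g] = {**res, "p_adjusted": float(p_adj),
                                  "stars": significance_stars(float(p_adj))}
    return report


def report_markdown(report: dict, metric: str = "value") -> str:
    """Render a contrast report as a small Markdown table."""
    lines = [f"| stage | statistic | p | annotation |",
             f"|---|---|---|---|",
             f"| interaction ({metric}) | - | {report['interaction_p']:.3g} | "
             f"{significance_stars(report['interaction_p'])} |"]
    for g, c in report.get("contrasts", {}).items():
        lines.append(f"| {g} | t={c['t']:.3g} (df={c['df']}) | "
                     f"{c['p_adjusted']:.3g} | {c['stars']} |")
    if not report["gated"]:
        lines.append("| simple contrasts | not evaluated (interaction ns) | - | - |")
    return "\n".join(lines)
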