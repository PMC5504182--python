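"""Univariate statistics: fold changes, normality-routed two-sample tests,
Benjamini-Hochberg correction, color tables, and lesion-summary arithmetic.

Fold changes are ratios of group means computed on the normalized (pre-glog)
intensity scale; the significance tests run on the variance-stabilized glog
branch.  Each metabolite is routed to a Student/Welch t-test when both
groups pass a Shapiro-Wilk normality check, otherwise to a two-sided
Mann-Whitney test with tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import FeatureMatrix

__all__ = [
    "fold_change",
    "route_and_test",
    "bh_adjust",
    "fold_change_table",
    "LesionSummary",
    "lesion_summary",
    "render_color_table",
]

SIGNIFICANCE_LEVELS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))
_LOG_FC_SATURATION = np.log(4.0)  # |log FC| at which cell color saturates


def fold_change(fm: FeatureMatrix, group_a: str, group_b: str) -> pd.Series:
    """Per-feature ratio of group means, FC = mean(A) / mean(B)."""
    if fm.glog or fm.pareto:
        raise ValueError("fold changes need normalized, untransformed intensities")
    mean_a = fm.group_values(group_a).mean(axis=0)
    mean_b = fm.group_values(group_b).mean(axis=0)
    if (mean_b == 0).any():
        zero = list(mean_b.index[mean_b == 0])
        raise ValueError(f"zero group-{group_b} mean for features: {zero[:5]}")
    fc = mean_a / mean_b
    fc.name = f"FC({group_a}/{group_b})"
    return fc


def _is_normal(values: np.ndarray, alpha: float) -> bool:
    if np.ptp(values) == 0:  # Shapiro-Wilk undefined for constant data
        return False
    return stats.shapiro(values).pvalue > alpha


def route_and_test(
    values_a,
    values_b,
    normality_alpha: float = 0.05,
    pooled_t: bool = False,
) -> tuple[float, str]:
    """Two-sided two-sample test with normality routing.

    Both groups Shapiro-Wilk normal at ``normality_alpha`` -> t-test (Welch
    by default, pooled-variance with ``pooled_t``); otherwise Mann-Whitney
    with tie correction.  Returns ``(p_value, "parametric" | "non-parametric")``.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 samples")
    if _is_normal(a, normality_alpha) and _is_normal(b, normality_alpha):
        res = stats.ttest_ind(a, b, equal_var=pooled_t)
        return float(res.pvalue), "parametric"
    if np.ptp(np.concatenate([a, b])) == 0:  # everything tied
        return 1.0, "non-parametric"
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.pvalue), "non-parametric"


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fold_change_table(
    fm_fc: FeatureMatrix,
    fm_test: FeatureMatrix,
    comparisons: list[tuple[str, str]],
    normality_alpha: float = 0.05,
    pooled_t: bool = False,
) -> pd.DataFrame:
    """FC + routed test + BH adjustment for each (group_a, group_b) comparison.

    ``fm_fc`` supplies the normalized intensities for the ratios; ``fm_test``
    (typically the glog branch of the same matrix) supplies the test values.
    BH correction is applied per comparison across features.
    """
    if list(fm_fc.feature_names) != list(fm_test.feature_names):
        raise ValueError("fold-change and test matrices must share features")
    blocks = {}
    for a, b in comparisons:
        fc = fold_change(fm_fc, a, b)
        va = fm_test.group_values(a)
        vb = fm_test.group_values(b)
        raw, routes = [], []
        for feat in fm_test.feature_names:
            p, route = route_and_test(
                va[feat].to_numpy(), vb[feat].to_numpy(), normality_alpha, pooled_t
            )
            raw.append(p)
            routes.append(route)
        adj = bh_adjust(raw)
        blocks[f"{a} vs. {b}"] = pd.DataFrame(
            {
                "FC": fc.to_numpy(),
                "log_FC": np.log(fc.to_numpy()),
                "p_raw": raw,
                "p_adj": adj,
                "test": routes,
            },
            index=fm_fc.feature_names,
        )
    return pd.concat(blocks, axis=1)


@dataclass
class LesionSummary:
    """Per-group neoplastic-lesion arithmetic (incidence %, average/mouse)."""

    table: pd.DataFrame

    def __getitem__(self, group: str) -> pd.Series:
        return self.table.loc[group]


def lesion_summary(counts: dict[str, tuple[int, int, int]]) -> LesionSummary:
    """Incidence and average lesions from (sacrificed, with_lesions, total) counts.

    incidence = 100 * with_lesions / sacrificed (2 dp);
    average = total_lesions / sacrificed (2 dp).
    """
    rows = {}
    for group, (sacrificed, with_lesions, total) in counts.items():
        if sacrificed == 0:
            raise ValueError(f"group {group!r}: no sacrificed mice")
        if min(sacrificed, with_lesions, total) < 0:
            raise ValueError(f"group {group!r}: counts must be non-negative")
        if with_lesions > sacrificed:
            raise ValueError(f"group {group!r}: with_lesions exceeds sacrificed")
        rows[group] = {
            "sacrificed": sacrificed,
            "with_lesions": with_lesions,
            "incidence_pct": round(100.0 * with_lesions / sacrificed, 2),
            "total_lesions": total,
            "avg_lesions": round(total / sacrificed, 2),
        }
    return LesionSummary(table=pd.DataFrame(rows).T)


def _stars(p_adj: float) -> str:
    for level, marker in SIGNIFICANCE_LEVELS:
        if p_adj < level:
            return marker
    return ""


def _cell_color(log_fc: float) -> str:
    """White->red for increases, white->blue for decreases; |log FC| sets depth."""
    intensity = min(abs(log_fc) / _LOG_FC_SATURATION, 1.0)
    fade = int(round(255 * (1 - intensity)))
    if log_fc > 0:
        r, g, b = 255, fade, fade
    elif log_fc < 0:
        r, g, b = fade, fade, 255
    else:
        r = g = b = 255
    return f"#{r:02x}{g:02x}{b:02x}"


def render_color_table(fct: pd.DataFrame) -> pd.DataFrame:
    """Annotate a fold-change table with cell colors and significance stars.

    Expects the two-level-column output of :func:`fold_change_table`; returns
    a same-shaped table with ``color`` (hex) and ``stars`` columns added per
    comparison.  Red cells mark increases, blue decreases, color depth scales
    with |log FC| and saturates at FC 4 (or 1/4); stars follow the
    * p<0.05 / ** p<0.01 / *** p<0.001 convention on adjusted p-values.
    """
    out = {}
    for comp in fct.columns.get_level_values(0).unique():
        block = fct[comp].copy()
        block["color"] = [_cell_color(v) for v in block["log_FC"]]
        block["stars"] = [_stars(v) for v in block["p_adj"]]
        out[comp] = block
    return pd.concat(out, axis=1)
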