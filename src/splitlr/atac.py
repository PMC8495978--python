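"""Integration of TSS-level expression with chromatin accessibility.

Given a TSS x cell expression matrix (long-read derived) and a TSS x cell
normalized accessibility matrix over the same TSS set, this module compares
the two modalities per cell group: group means, pairwise log2 fold changes
with a pseudocount of 1, a two-standard-deviation specificity call requiring
agreement of both modalities, a binary expressed/accessible state with fixed
cutoffs, the concordance of each multi-TSS gene's strongest TSS across
modalities, and Pearson/Spearman correlation summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


class Specificity(str, Enum):
    GROUP_A_SPECIFIC = "GROUP_A_SPECIFIC"
    GROUP_B_SPECIFIC = "GROUP_B_SPECIFIC"
    NONE = "NONE"


def group_means(matrix: pd.DataFrame, cell_groups: Mapping[str, str]) -> pd.DataFrame:
    """Arithmetic mean per TSS per group; every group must have >= 1 cell."""
    groups = pd.Series({c: cell_groups[c] for c in matrix.columns})
    labels = sorted(set(cell_groups.values()))
    empty = [g for g in labels if (groups == g).sum() == 0]
    if empty:
        raise ValueError(f"empty group(s): {empty}")
    return matrix.T.groupby(groups).mean().T[labels]


def lfc(mean_a, mean_b, pseudocount: float = 1.0):
    """log2((a + pc) / (b + pc)); finite for non-negative means, antisymmetric
    under swapping a and b, and exactly 0 at a = b (including 0, 0)."""
    return np.log2((np.asarray(mean_a, dtype=float) + pseudocount) /
                   (np.asarray(mean_b, dtype=float) + pseudocount))


def classify_specific(
    lfc_expr: pd.Series, lfc_acc: pd.Series, k: float = 2.0
) -> pd.Series:
    """Two-SD specificity call requiring agreement of both modalities.

    Thresholds are k standard deviations of each LFC vector, computed
    independently over all TSSs of the comparison. A TSS is group-A specific
    when both LFCs exceed +threshold, group-B specific when both fall below
    -threshold, else unspecific.
    """
    if len(lfc_expr) < 2 or len(lfc_acc) < 2:
        raise ValueError("need >= 2 TSSs to estimate a standard deviation")
    if not lfc_expr.index.equals(lfc_acc.index):
        lfc_acc = lfc_acc.reindex(lfc_expr.index)
    thr_e = k * float(np.std(lfc_expr, ddof=1))
    thr_a = k * float(np.std(lfc_acc, ddof=1))
    if k > 0 and (thr_e == 0 or thr_a == 0):
        raise ValueError("degenerate zero-variance LFC vector")
    out = pd.Series(Specificity.NONE.value, index=lfc_expr.index, dtype=object)
    out[(lfc_expr > thr_e) & (lfc_acc > thr_a)] = Specificity.GROUP_A_SPECIFIC.value
    out[(lfc_expr < -thr_e) & (lfc_acc < -thr_a)] = Specificity.GROUP_B_SPECIFIC.value
    return out


def binary_state(
    expr_reads: float, acc_value: float, expr_cut: float = 2.0, acc_cut: float = 1000.0
) -> Tuple[bool, bool]:
    """(expressed, accessible) with inclusive cutoffs."""
    return bool(expr_reads >= expr_cut), bool(acc_value >= acc_cut)


def binary_agreement(
    expr: pd.Series, acc: pd.Series, expr_cut: float = 2.0, acc_cut: float = 1000.0
) -> dict:
    """2x2 expressed-by-accessible table and the percent of TSSs on which
    the two binary states agree."""
    e = expr >= expr_cut
    a = acc.reindex(expr.index) >= acc_cut
    table = {
        "expressed_accessible": int((e & a).sum()),
        "expressed_only": int((e & ~a).sum()),
        "accessible_only": int((~e & a).sum()),
        "neither": int((~e & ~a).sum()),
    }
    n = len(expr)
    concordant = table["expressed_accessible"] + table["neither"]
    return {**table, "n": n, "percent_concordant": 100.0 * concordant / n if n else float("nan")}


def top_tss_concordance(
    expr_means: pd.Series, acc_means: pd.Series, tss_genes: Mapping[str, str]
) -> float:
    """Fraction of multi-TSS genes whose most expressed TSS is also the most
    accessible one; argmax ties count as concordant when the tied sets
    intersect. NaN when no gene has more than one TSS."""
    genes = pd.Series({t: tss_genes[t] for t in expr_means.index})
    acc_means = acc_means.reindex(expr_means.index)
    n_multi = 0
    n_concordant = 0
    for gene, idx in genes.groupby(genes).groups.items():
        if len(idx) < 2:
            continue
        n_multi += 1
        e = expr_means[idx]
        a = acc_means[idx]
        top_e = set(e.index[e == e.max()])
        top_a = set(a.index[a == a.max()])
        if top_e & top_a:
            n_concordant += 1
    return n_concordant / n_multi if n_multi else float("nan")


def expr_acc_correlation(expr: Sequence[float], acc: Sequence[float]) -> Tuple[float, float]:
    """(Pearson r, Spearman rho) between TSS expression and accessibility;
    NaN for degenerate (constant) vectors."""
    x = np.asarray(expr, dtype=float)
    y = np.asarray(acc, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    return float(stats.pearsonr(x, y)[0]), float(stats.spearmanr(x, y)[0])


def integrate(
    expr: pd.DataFrame,
    acc: pd.DataFrame,
    cell_groups_expr: Mapping[str, str],
    cell_groups_acc: Mapping[str, str],
    pairs: Sequence[Tuple[str, str]],
    tss_genes: Optional[Mapping[str, str]] = None,
    k: float = 2.0,
    expr_cut: float = 2.0,
    acc_cut: float = 1000.0,
    pseudocount: float = 1.0,
) -> Tuple[pd.DataFrame, dict]:
    """Full integration pass over a list of group pairs.

    Returns a long table with one row per TSS per comparison (group means,
    LFCs, specificity, binary states) and a summary dict with per-pair
    correlations, binary agreement and top-TSS concordance.
    """
    common = expr.index.intersection(acc.index)
    expr = expr.loc[common]
    acc = acc.loc[common]
    em = group_means(expr, cell_groups_expr)
    am = group_means(acc, cell_groups_acc)
    rows: List[dict] = []
    summary: dict = {}
    for ga, gb in pairs:
        lfc_e = pd.Series(lfc(em[ga], em[gb], pseudocount), index=common)
        lfc_a = pd.Series(lfc(am[ga], am[gb], pseudocount), index=common)
        spec = classify_specific(lfc_e, lfc_a, k=k)
        for t in common:
            e_state, a_state = binary_state(em.loc[t, ga], am.loc[t, ga], expr_cut, acc_cut)
            rows.append(
                {
                    "tss_name": t,
                    "gene_id": tss_genes.get(t) if tss_genes else None,
                    "pair": f"{ga}_vs_{gb}",
                    f"expr_mean_a": em.loc[t, ga],
                    f"expr_mean_b": em.loc[t, gb],
                    f"acc_mean_a": am.loc[t, ga],
                    f"acc_mean_b": am.loc[t, gb],
                    "lfc_expr": lfc_e[t],
                    "lfc_acc": lfc_a[t],
                    "specificity": spec[t],
                    "expressed": e_state,
                    "accessible": a_state,
                }
            )
        pair_summary = {
            "n_a_specific": int((spec == Specificity.GROUP_A_SPECIFIC.value).sum()),
            "n_b_specific": int((spec == Specificity.GROUP_B_SPECIFIC.value).sum()),
        }
        r, rho = expr_acc_correlation(em[ga], am[ga])
        pair_summary["pearson_r"] = r
        pair_summary["spearman_rho"] = rho
        pair_summary["binary_agreement"] = binary_agreement(em[ga], am[ga], expr_cut, acc_cut)
        if tss_genes:
            pair_summary["top_tss_concordance"] = top_tss_concordance(em[ga], am[ga], tss_genes)
        summary[f"{ga}_vs_{gb}"] = pair_summary
    return pd.DataFrame(rows), summary
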