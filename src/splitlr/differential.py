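"""Differential isoform / TSS usage testing between two cell groups.

For each gene, reads are pooled over the cells of each group and laid out in
an n x 2 contingency table of per-feature counts (isoforms or TSSs), capped
at 11 rows by pooling the most lowly expressed features into an "other" row.
A gene is testable when both groups contribute at least 10 reads and at
least two features are observed. Testable genes get a Pearson chi-squared
test of homogeneity (no continuity correction) and an effect size
``dpi`` (delta-pi): the summed absolute change in percent usage of the two
most-expressed features, in percent points (range 0-200). Raw p-values are
Benjamini-Hochberg corrected per pairwise comparison; a gene is called
significant when adjusted p <= alpha and dpi >= dpi_min.

The same machinery serves isoform switching (features = transcripts) and
differential TSS usage (features = TSS peaks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

OTHER_ROW = "other"


@dataclass
class UsageTestConfig:
    alpha: float = 0.05
    dpi_min: float = 10.0
    min_reads: int = 10
    max_rows: int = 11
    #: whether the pooled "other" row may rank among the top-two for dpi
    other_in_top: bool = True


@dataclass
class ContingencyTable:
    """Feature-by-condition counts for one gene (conditions A, B)."""

    gene_id: str
    features: List[str]
    counts: np.ndarray  # shape (n_rows, 2), non-negative ints
    collapsed: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[1] != 2:
            raise ValueError("counts must be an n x 2 array")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.features) != self.counts.shape[0]:
            raise ValueError("feature list and count rows disagree")

    @property
    def column_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def usage(self) -> np.ndarray:
        """Percent usage pi per feature per condition; columns sum to 100."""
        sums = self.column_sums.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(sums > 0, 100.0 * self.counts / sums, np.nan)


@dataclass
class UsageTestResult:
    gene_id: str
    n_rows: int
    colsum_a: int
    colsum_b: int
    testable: bool
    chi2: float = float("nan")
    df: int = 0
    p_raw: float = float("nan")
    p_adj: float = float("nan")
    dpi: float = float("nan")
    significant: bool = False


def build_contingency(
    counts_a: Mapping[str, int],
    counts_b: Mapping[str, int],
    gene_id: str = "",
    max_rows: int = 11,
) -> ContingencyTable:
    """Lay out per-feature counts of two conditions as an n x 2 table.

    Features are ranked by total count across conditions (descending, ties
    broken lexicographically by feature id); when more than ``max_rows``
    features exist, the lowest-ranked ones are pooled into a final "other"
    row so the table never exceeds ``max_rows`` rows.
    """
    features = sorted(set(counts_a) | set(counts_b))
    if not features:
        raise ValueError("no features")
    totals = {f: counts_a.get(f, 0) + counts_b.get(f, 0) for f in features}
    ranked = sorted(features, key=lambda f: (-totals[f], f))
    collapsed = len(ranked) > max_rows
    if collapsed:
        head, tail = ranked[: max_rows - 1], ranked[max_rows - 1 :]
        rows = [(f, counts_a.get(f, 0), counts_b.get(f, 0)) for f in head]
        rows.append(
            (OTHER_ROW, sum(counts_a.get(f, 0) for f in tail), sum(counts_b.get(f, 0) for f in tail))
        )
    else:
        rows = [(f, counts_a.get(f, 0), counts_b.get(f, 0)) for f in ranked]
    return ContingencyTable(
        gene_id=gene_id,
        features=[r[0] for r in rows],
        counts=np.array([[r[1], r[2]] for r in rows]),
        collapsed=collapsed,
    )


def is_testable(table: ContingencyTable, min_reads: int = 10) -> bool:
    """Both conditions must contribute >= min_reads reads and the gene must
    express >= 2 distinct features (otherwise df = 0)."""
    nonzero_rows = int((table.counts.sum(axis=1) > 0).sum())
    return bool((table.column_sums >= min_reads).all() and nonzero_rows >= 2)


def chi_squared(table: ContingencyTable) -> Tuple[float, int, float]:
    """Pearson chi-squared statistic, degrees of freedom and upper-tail p.

    Expected counts come from the row/column marginals; rows with zero
    counts in both conditions are dropped before computing df; no continuity
    correction is applied.
    """
    obs = table.counts[table.counts.sum(axis=1) > 0]
    if obs.shape[0] < 2:
        raise ValueError("chi-squared requires >= 2 non-empty feature rows")
    col = obs.sum(axis=0).astype(float)
    if (col == 0).any():
        raise ValueError("zero column sum; gene should have failed testability")
    row = obs.sum(axis=1).astype(float)
    n = col.sum()
    expected = np.outer(row, col) / n
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    df = obs.shape[0] - 1
    return chi2, df, float(stats.chi2.sf(chi2, df))


def delta_pi(table: ContingencyTable, other_in_top: bool = True) -> float:
    """Summed absolute change in percent usage over the top-two features.

    Features are ranked by total count across both conditions; with
    ``other_in_top`` false, a pooled "other" row is excluded from ranking.
    Result is in percent points within [0, 200].
    """
    if (table.column_sums == 0).any():
        raise ValueError("delta-pi requires reads in both conditions")
    usage = table.usage
    totals = table.counts.sum(axis=1)
    order = sorted(
        range(len(table.features)),
        key=lambda i: (-totals[i], table.features[i]),
    )
    if not other_in_top:
        order = [i for i in order if table.features[i] != OTHER_ROW] or order
    top = order[:2]
    return float(sum(abs(usage[i, 0] - usage[i, 1]) for i in top))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_usage_tests(
    matrix: pd.DataFrame,
    feature_genes: Mapping[str, str],
    cell_groups: Mapping[str, str],
    group_pair: Tuple[str, str],
    config: UsageTestConfig = UsageTestConfig(),
) -> pd.DataFrame:
    """Test every gene for differential feature usage between two groups.

    ``matrix`` is features x cells; ``cell_groups`` maps cell -> group label;
    reads are pooled over the cells of each group. Returns one row per gene
    with the chi-squared statistic, raw and BH-adjusted p, dpi and the
    significance call.
    """
    group_a, group_b = group_pair
    cells_a = [c for c in matrix.columns if cell_groups.get(c) == group_a]
    cells_b = [c for c in matrix.columns if cell_groups.get(c) == group_b]
    if not cells_a or not cells_b:
        raise ValueError(f"both groups need cells; got {len(cells_a)} vs {len(cells_b)}")
    sum_a = matrix[cells_a].sum(axis=1)
    sum_b = matrix[cells_b].sum(axis=1)
    genes = pd.Series({f: feature_genes[f] for f in matrix.index})
    results: List[UsageTestResult] = []
    for gene in sorted(genes.unique()):
        feats = genes.index[genes == gene]
        table = build_contingency(
            {f: int(sum_a[f]) for f in feats},
            {f: int(sum_b[f]) for f in feats},
            gene_id=gene,
            max_rows=config.max_rows,
        )
        testable = is_testable(table, config.min_reads)
        res = UsageTestResult(
            gene_id=gene,
            n_rows=len(table.features),
            colsum_a=int(table.column_sums[0]),
            colsum_b=int(table.column_sums[1]),
            testable=testable,
        )
        if testable:
            res.chi2, res.df, res.p_raw = chi_squared(table)
            res.dpi = delta_pi(table, other_in_top=config.other_in_top)
        results.append(res)
    out = pd.DataFrame([r.__dict__ for r in results]).set_index("gene_id")
    testable_mask = out["testable"].to_numpy()
    if testable_mask.any():
        out.loc[testable_mask, "p_adj"] = bh_adjust(out.loc[testable_mask, "p_raw"])
    out["significant"] = (
        out["testable"]
        & (out["p_adj"] <= config.alpha)
        & (out["dpi"] >= config.dpi_min)
    )
    return out
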