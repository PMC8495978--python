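"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the libraries and algorithms the package itself
uses (edlib, the chained peak caller, statsmodels) so agreement is a real
cross-check rather than a tautology.
"""

from typing import Dict, List, Sequence, Tuple

import numpy as np


def levenshtein(a: str, b: str) -> int:
    """Textbook dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_matrix(queries: Sequence[str], refs: Sequence[str]) -> np.ndarray:
    """All-pairs edit distances, vectorized over both axes.

    Standard DP over character positions; the table is materialized per
    (query, ref) pair as a numpy array so large batches stay fast.
    """
    qa = np.array([list(q) for q in queries])
    ra = np.array([list(r) for r in refs])
    nq, lq = qa.shape
    nr, lr = ra.shape
    D = np.zeros((nq, nr, lq + 1, lr + 1), dtype=np.int32)
    D[:, :, :, 0] = np.arange(lq + 1)[None, None, :]
    D[:, :, 0, :] = np.arange(lr + 1)[None, None, :]
    for i in range(1, lq + 1):
        for j in range(1, lr + 1):
            sub = (qa[:, None, i - 1] != ra[None, :, j - 1]).astype(np.int32)
            D[:, :, i, j] = np.minimum(
                np.minimum(D[:, :, i - 1, j] + 1, D[:, :, i, j - 1] + 1),
                D[:, :, i - 1, j - 1] + sub,
            )
    return D[:, :, lq, lr]


def correct_barcode_oracle(raw: str, whitelist: Sequence[str], max_edit: int):
    """Exhaustive minimum-distance correction mirroring the stated contract."""
    dists = {w: levenshtein(raw, w) for w in whitelist}
    m = min(dists.values())
    winners = [w for w, d in dists.items() if d == m]
    if m > max_edit:
        return None, "UNCORRECTABLE"
    if len(winners) > 1:
        return None, "AMBIGUOUS"
    return winners[0], "OK"


def cluster_positions_oracle(
    counts: Dict[int, int], window: int, min_reads: int, strand: str = "+"
) -> List[dict]:
    """Exhaustive gap-chaining: walk sorted positions, cut where the gap
    exceeds the window, then derive summit/wide/narrow per cluster."""
    positions = sorted(counts)
    clusters: List[List[int]] = []
    for p in positions:
        if clusters and p - clusters[-1][-1] <= window:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    out = []
    for cl in clusters:
        total = sum(counts[p] for p in cl)
        if total < min_reads:
            continue
        best = max(counts[p] for p in cl)
        tied = [p for p in cl if counts[p] == best]
        summit = min(tied) if strand == "+" else max(tied)
        wide = (cl[0], cl[-1] + 1)
        half = window // 2
        narrow = (max(wide[0], summit - half), min(wide[1], summit + half + 1))
        out.append(
            {"wide": wide, "narrow": narrow, "summit": summit, "count": total}
        )
    return out


def bh_oracle(pvals: Sequence[float]) -> np.ndarray:
    """Step-up BH from the definition: adj_i = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        adj_sorted[i] = min(adj_sorted[i], adj_sorted[i + 1])
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def pearson_chi2_oracle(table: np.ndarray) -> Tuple[float, int]:
    """Pearson statistic from first principles (cell-by-cell loop)."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    chi2 = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / n
            chi2 += (table[i, j] - e) ** 2 / e
    return chi2, (table.shape[0] - 1) * (table.shape[1] - 1)
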