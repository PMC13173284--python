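"""Independent brute-force oracles used only by the tests.

Every function here recomputes a quantity by the most direct method
available (exhaustive enumeration, closed forms, O(n^3) clustering, full
eigendecomposition) without touching the package's own implementations.
"""

from __future__ import annotations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def hamming_hits(read: str, references: dict[str, str], budget: int):
    """All ungapped hits within `budget` mismatches, scanning every offset
    of both strands in pure Python; N never matches. Returns a set of
    (ref_id, forward_position, strand, mismatches) in the best stratum."""
    L = len(read)
    all_hits = []
    for rid, ref in references.items():
        for strand, seq in (("+", ref), ("-", revcomp(ref))):
            n = len(seq)
            for off in range(n - L + 1):
                mm = 0
                for a, b in zip(read, seq[off : off + L]):
                    if a != b or a == "N" or b == "N":
                        mm += 1
                        if mm > budget:
                            break
                else:
                    fpos = off if strand == "+" else n - off - L
                    all_hits.append((rid, fpos, strand, mm))
    if not all_hits:
        return set()
    best = min(h[3] for h in all_hits)
    return {h for h in all_hits if h[3] == best}


def best_adapter_occurrence(seq: str, adapter: str, max_error_rate: float,
                            min_overlap: int):
    """Exhaustive semi-global search for the adapter: every start position,
    prefix-overhang at the 3' end, ranked by matched columns then errors
    then 5'-most start. Returns the truncation index or None."""
    n, m = len(seq), len(adapter)
    candidates = []
    for start in range(n):
        overlap = min(m, n - start)
        if overlap < min_overlap:
            continue
        errors = sum(
            1 for a, b in zip(seq[start : start + overlap], adapter[:overlap])
            if a != b or a == "N" or b == "N"
        )
        if errors <= max_error_rate * overlap:
            candidates.append((-(overlap - errors), errors, start))
    if not candidates:
        return None
    return min(candidates)[2]


def bh_closed_form(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values from the textbook definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running_min = 1.0
    for rank in range(n - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, p[i] * n / (rank + 1))
        adj[i] = running_min
    return adj


def quantile_scan_counts(p: np.ndarray, abundance: np.ndarray, alpha: float,
                         grid) -> list[int]:
    """Independent per-grid-point recomputation of the filtering scan."""
    counts = []
    for theta in grid:
        thr = np.quantile(abundance, theta)
        keep = (abundance >= thr) & ~np.isnan(p)
        if keep.sum() == 0:
            counts.append(0)
            continue
        adj = bh_closed_form(p[keep])
        counts.append(int((adj <= alpha).sum()))
    return counts


def complete_linkage_heights(points: np.ndarray) -> list[float]:
    """Merge heights of naive O(n^3) complete-linkage clustering on
    Euclidean distances."""
    n = len(points)
    clusters = [[i] for i in range(n)]
    d = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(-1))
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if best is None or h < best[0]:
                    best = (h, i, j)
        h, i, j = best
        heights.append(h)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return heights


def pca_scores_eig(x: np.ndarray, ncomp: int) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores via a full eigendecomposition of the feature covariance
    (x: samples x features, already on the analysis scale)."""
    centered = x - x.mean(axis=0, keepdims=True)
    cov = centered.T @ centered
    vals, vecs = np.linalg.eigh(cov)
    idx = np.argsort(vals)[::-1][:ncomp]
    scores = centered @ vecs[:, idx]
    evr = vals[idx] / vals.sum()
    return scores, evr
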