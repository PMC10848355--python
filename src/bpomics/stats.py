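"""Shared statistical primitives.

The Benjamini-Hochberg step-up is authored here (rather than delegated)
because downstream modules assert its exact adjusted-p contract against a
brute-force reference, and because the same routine is reused across the
RNA, protein and enrichment layers.
"""

from __future__ import annotations

import numpy as np

__all__ = ["bh_adjust", "benjamini_hochberg_brute"]


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR).

    Parameters
    ----------
    p
        Raw p-values in (0, 1]. NaNs are propagated and excluded from the
        number of tests.

    Returns
    -------
    Adjusted p-values, same shape: ``p_adj[(i)] = min_{j: p_(j) >= p_(i)}
    m * p_(j) / rank(j)``, clipped to 1.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = ~np.isnan(p)
    pv = p[mask]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest p downwards
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    res = np.empty(m)
    res[order] = adj
    out[mask] = res
    return out


def benjamini_hochberg_brute(p: list[float]) -> list[float]:
    """Literal O(m^2) BH definition, used as an independent oracle.

    ``p_adj_i`` is the smallest FDR level q at which hypothesis i would be
    rejected by the step-up rule: reject all hypotheses with rank <= k where
    k = max{ j : p_(j) <= j*q/m }.
    """
    m = len(p)
    out = []
    for pi in p:
        best = 1.0
        for pj in p:
            if pj >= pi:
                rank = sum(1 for pk in p if pk <= pj)
                best = min(best, pj * m / rank)
        out.append(min(best, 1.0))
    return out
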