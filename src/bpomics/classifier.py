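"""PCA-loading classifier-gene selection.

The signature pipeline: principal component analysis of normalized
log-expression (samples as observations), selection of genes whose
loadings fall in the top or bottom 20% of each of the top six PCs' loading
ranges, intersection of that union with the dual-method consensus DEGs,
and projection of samples onto the resulting signature with a silhouette
score quantifying group separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

from .rnaseq import ConsensusDEGSet, CountMatrix, size_factors

__all__ = [
    "PCAResult",
    "LoadingSelection",
    "ClassifierSet",
    "log_normalized_expression",
    "pca",
    "select_by_loading_range",
    "derive_classifier",
    "combine_signatures",
    "project_and_separate",
]

N_PCS = 6
LOADING_FRAC = 0.2


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # features x PCs, orthonormal columns
    scores: pd.DataFrame  # samples x PCs
    explained_variance: np.ndarray  # non-increasing

    @property
    def n_pcs(self) -> int:
        return self.loadings.shape[1]


@dataclass
class LoadingSelection:
    per_pc: dict[int, frozenset[str]]  # PC index (0-based) -> selected features
    n_pcs: int
    frac: float

    @property
    def union(self) -> set[str]:
        out: set[str] = set()
        for s in self.per_pc.values():
            out |= s
        return out


@dataclass
class ClassifierSet:
    features: list[str]  # deterministic lexicographic order
    contrast: str = ""

    def __len__(self) -> int:
        return len(self.features)


def log_normalized_expression(counts: CountMatrix) -> pd.DataFrame:
    """log2(median-of-ratios normalized count + 1), features x samples."""
    norm = counts.counts / size_factors(counts)
    return np.log2(norm + 1.0)


def pca(expr: pd.DataFrame, center: bool = True, scale: bool = False) -> PCAResult:
    """PCA of an expression matrix (rows = features, columns = samples).

    Samples are the observations; features the variables.  Columns of the
    loading matrix are orthonormal right singular vectors; scores are the
    projections of the (centered) sample vectors.  Signs are fixed so each
    PC's largest-magnitude loading is positive.
    """
    if expr.isna().to_numpy().any():
        raise ValueError("expression matrix contains missing values")
    if expr.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples")
    x = expr.to_numpy(dtype=float).T  # samples x features
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        x = x / sd
    if not np.any(x != 0):
        raise ValueError("matrix has no variance; PCA undefined")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros_like(s, dtype=bool)
    u, s, vt = u[:, keep], s[keep], vt[keep]
    # deterministic orientation
    for i in range(vt.shape[0]):
        j = np.argmax(np.abs(vt[i]))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    cols = [f"PC{i + 1}" for i in range(s.size)]
    loadings = pd.DataFrame(vt.T, index=expr.index, columns=cols)
    scores = pd.DataFrame(u * s, index=expr.columns, columns=cols)
    explained = s**2 / (x.shape[0] - 1)
    return PCAResult(loadings=loadings, scores=scores, explained_variance=explained)


def select_by_loading_range(
    loadings: pd.DataFrame, n_pcs: int = N_PCS, frac: float = LOADING_FRAC
) -> LoadingSelection:
    """Features in the top or bottom ``frac`` of each PC's loading range.

    For PC k with loading span [lo, hi], a feature is selected when its
    loading is >= hi - frac*(hi-lo) or <= lo + frac*(hi-lo) (boundaries
    inclusive); the selection is taken over the first ``n_pcs`` PCs, capped
    at the number available (with a warning).  A zero-range PC selects
    nothing.  The rule is invariant to a global sign flip of any PC.
    """
    if not 0 < frac < 0.5:
        raise ValueError("frac must lie in (0, 0.5)")
    avail = loadings.shape[1]
    if n_pcs > avail:
        warnings.warn(
            f"requested {n_pcs} PCs but only {avail} exist; using all {avail}",
            stacklevel=2,
        )
        n_pcs = avail
    per_pc: dict[int, frozenset[str]] = {}
    for k in range(n_pcs):
        col = loadings.iloc[:, k]
        lo, hi = float(col.min()), float(col.max())
        span = hi - lo
        if span == 0:
            per_pc[k] = frozenset()
            continue
        sel = col[(col >= hi - frac * span) | (col <= lo + frac * span)]
        per_pc[k] = frozenset(sel.index)
    return LoadingSelection(per_pc=per_pc, n_pcs=n_pcs, frac=frac)


def derive_classifier(
    selection: LoadingSelection, degs: ConsensusDEGSet | set, contrast: str = ""
) -> ClassifierSet:
    """Classifier genes = PCA loading-range union intersected with consensus DEGs."""
    deg_set = degs.all if isinstance(degs, ConsensusDEGSet) else set(degs)
    return ClassifierSet(features=sorted(selection.union & deg_set), contrast=contrast)


def combine_signatures(*signatures: ClassifierSet | set | list) -> ClassifierSet:
    """Union of classifier sets (deduplicated, lexicographic order)."""
    union: set[str] = set()
    for sig in signatures:
        union |= set(sig.features if isinstance(sig, ClassifierSet) else sig)
    return ClassifierSet(features=sorted(union))


def project_and_separate(
    expr: pd.DataFrame, classifier: ClassifierSet, labels: dict[str, str]
) -> tuple[pd.DataFrame, float]:
    """PCA restricted to the classifier genes plus a silhouette of the labels.

    The silhouette is computed on the first two score dimensions (or one,
    for a single-PC projection) and quantifies how cleanly the labelled
    groups separate; it requires >= 2 distinct labels.
    """
    if not classifier.features:
        raise ValueError("classifier set is empty")
    missing = [f for f in classifier.features if f not in expr.index]
    if missing:
        raise ValueError(f"classifier features missing from expression matrix: {missing}")
    res = pca(expr.loc[classifier.features])
    lab = [labels[s] for s in res.scores.index]
    if len(set(lab)) < 2:
        raise ValueError("need >= 2 distinct labels for separation scoring")
    dims = min(2, res.scores.shape[1])
    sil = float(silhouette_score(res.scores.iloc[:, :dims].to_numpy(), lab))
    return res.scores, sil
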