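"""Transcription-factor regulon analysis across before/after contrasts.

Maps differentially expressed genes onto TF->target databases (TRED, ITFP,
TRRUST, Marbach or synthetic stand-ins), classifies each regulated TF's
trajectory across the four "versus control" contrasts (persistent,
normalized after surgery, de novo, unchanged), clusters the fold-change
profiles of a TF's targets with 1 - Pearson distance and average linkage,
and summarises each cluster's trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "TFRegulonDB",
    "TFExpressionPattern",
    "TargetClusterSet",
    "categorize_tf",
    "regulated_tfs",
    "target_matrix",
    "cluster_targets",
    "cluster_trajectory_report",
    "fisher_overlap",
]

KNOWN_SOURCES = ("TRED", "ITFP", "TRRUST", "Marbach", "synthetic")
DEFAULT_K = 5  # target-profile cluster count observed for the SOX21 regulon


@dataclass
class TFRegulonDB:
    """TF -> target map with per-source provenance."""

    table: pd.DataFrame  # columns: tf, target, source

    def __post_init__(self) -> None:
        need = {"tf", "target", "source"}
        if not need <= set(self.table.columns):
            raise ValueError(f"TF table needs columns {sorted(need)}")
        self.table = self.table.drop_duplicates(subset=["tf", "target", "source"])
        sizes = self.table.groupby("tf")["target"].nunique()
        if (sizes == 0).any():
            raise ValueError("every TF must have a nonempty target set")

    @property
    def tfs(self) -> list[str]:
        return sorted(self.table["tf"].unique())

    def regulon(self, tf: str, sources: list[str] | None = None) -> set[str]:
        sub = self.table[self.table["tf"] == tf]
        if sources is not None:
            sub = sub[sub["source"].isin(sources)]
        return set(sub["target"])

    def merged(self, other: "TFRegulonDB") -> "TFRegulonDB":
        """Union of two databases; duplicate (tf, target) pairs keep both sources."""
        return TFRegulonDB(pd.concat([self.table, other.table], ignore_index=True))


@dataclass
class TFExpressionPattern:
    tf: str
    lfc: dict[str, float]  # contrast -> log2fc
    category: str  # persistent | normalized_after | de_novo | unchanged


@dataclass
class TargetClusterSet:
    clusters: list[frozenset[str]]  # index = cluster id
    linkage: np.ndarray | None
    k: int
    flat: frozenset[str]  # constant-profile targets, bucketed separately

    def labels(self) -> dict[str, int]:
        return {t: i for i, members in enumerate(self.clusters) for t in members}


def _split_contrast(name: str) -> tuple[str, str]:
    group, _, timepoint = name.rpartition("_")
    if timepoint not in ("before", "after") or not group:
        raise ValueError(f"contrast name {name!r} must look like '<group>_before' or '<group>_after'")
    return group, timepoint


def categorize_tf(before_de: dict[str, bool], after_de: dict[str, bool]) -> str:
    """Trajectory category from per-group before/after DE booleans.

    persistent       — some group is DE both before and after;
    normalized_after — DE before in >= 1 group and, in every such group, no
                       longer DE after (takes precedence over de_novo);
    de_novo          — DE only in after contrasts;
    unchanged        — DE nowhere.
    """
    groups = set(before_de) | set(after_de)
    b = {g: bool(before_de.get(g, False)) for g in groups}
    a = {g: bool(after_de.get(g, False)) for g in groups}
    if any(b[g] and a[g] for g in groups):
        return "persistent"
    if any(b.values()):
        return "normalized_after"
    if any(a.values()):
        return "de_novo"
    return "unchanged"


def regulated_tfs(
    de_sets: dict[str, set[str]],
    lfc_tables: dict[str, pd.Series],
    db: TFRegulonDB,
) -> list[TFExpressionPattern]:
    """TFs present in the database and DE in at least one contrast.

    ``de_sets`` maps contrast names ('HP_before', 'HP_after', ...) to the
    significant feature sets of that contrast versus control; ``lfc_tables``
    carries the matching per-feature log2 fold changes.
    """
    if db.table.empty:
        raise ValueError("TF database is empty")
    contrasts = sorted(de_sets)
    for c in contrasts:
        _split_contrast(c)
    known_tfs = set(db.table["tf"])
    hits = known_tfs & set().union(*de_sets.values()) if de_sets else set()
    out = []
    for tf in sorted(hits):
        before = {}
        after = {}
        lfc = {}
        for c in contrasts:
            group, timepoint = _split_contrast(c)
            de = tf in de_sets[c]
            if timepoint == "before":
                before[group] = de
            else:
                after[group] = de
            series = lfc_tables.get(c)
            lfc[c] = float(series.get(tf, np.nan)) if series is not None else np.nan
        out.append(TFExpressionPattern(tf=tf, lfc=lfc, category=categorize_tf(before, after)))
    return out


def target_matrix(
    tf: str,
    db: TFRegulonDB,
    lfc_tables: dict[str, pd.Series],
    sources: list[str] | None = None,
) -> pd.DataFrame:
    """Log2 fold changes of a TF's targets across all contrasts.

    Rows are the database targets measured in every contrast table; targets
    absent from any table are dropped (their ids are recorded in
    ``attrs['dropped']``).
    """
    if tf not in set(db.table["tf"]):
        raise ValueError(f"TF {tf!r} not in database")
    targets = sorted(db.regulon(tf, sources=sources))
    contrasts = sorted(lfc_tables)
    measured = [t for t in targets if all(t in lfc_tables[c].index for c in contrasts)]
    dropped = [t for t in targets if t not in measured]
    mat = pd.DataFrame(
        {c: lfc_tables[c].loc[measured].astype(float) for c in contrasts}, index=measured
    )
    mat.attrs["dropped"] = dropped
    return mat


def cluster_targets(matrix: pd.DataFrame, k: int = DEFAULT_K) -> TargetClusterSet:
    """Agglomerative clustering of target profiles, d = 1 - Pearson, average linkage.

    Constant rows have no defined correlation and go to a separate ``flat``
    bucket before clustering.  ``k`` caps the cluster count; with fewer
    usable rows than ``k`` each row becomes its own cluster.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    variable = matrix.std(axis=1, ddof=0) > 0
    flat = frozenset(matrix.index[~variable])
    sub = matrix.loc[variable]
    if sub.shape[0] == 0:
        return TargetClusterSet(clusters=[], linkage=None, k=k, flat=flat)
    if sub.shape[0] == 1:
        return TargetClusterSet(
            clusters=[frozenset(sub.index)], linkage=None, k=k, flat=flat
        )
    dist = pdist(sub.to_numpy(dtype=float), metric="correlation")
    z = hierarchy.linkage(np.clip(dist, 0.0, None), method="average")
    assign = hierarchy.fcluster(z, t=min(k, sub.shape[0]), criterion="maxclust")
    clusters = [
        frozenset(sub.index[assign == c]) for c in sorted(np.unique(assign))
    ]
    return TargetClusterSet(clusters=clusters, linkage=z, k=k, flat=flat)


def cluster_trajectory_report(
    clusters: TargetClusterSet, matrix: pd.DataFrame
) -> pd.DataFrame:
    """Per-cluster mean fold change per contrast plus a down-after flag.

    ``down_after`` is true when the cluster's mean fold change drops from
    before to after surgery in every group present.
    """
    contrasts = list(matrix.columns)
    groups = sorted({_split_contrast(c)[0] for c in contrasts})
    rows = []
    for ci, members in enumerate(clusters.clusters):
        sub = matrix.loc[sorted(members)]
        means = {c: float(sub[c].mean()) for c in contrasts}
        down = True
        for g in groups:
            b, a = f"{g}_before", f"{g}_after"
            if b in means and a in means:
                down &= means[a] < means[b]
        rows.append({"cluster": ci, "n_targets": len(members), **means, "down_after": down})
    return pd.DataFrame(rows)


def fisher_overlap(set_a: set[str], set_b: set[str], universe: set[str]) -> float:
    """One-sided Fisher exact p for over-enrichment of the overlap of two sets."""
    a = set_a & universe
    b = set_b & universe
    k = len(a & b)
    table = [
        [k, len(a) - k],
        [len(b) - k, len(universe) - len(a) - len(b) + k],
    ]
    return float(sps.fisher_exact(table, alternative="greater")[1])
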