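"""Synthetic data generators emulating the study design.

Every generator is deterministic under a fixed seed and returns ground
truth alongside the data, so the analysis modules can be exercised as
parameter-recovery tests.  The emulated design: six controls and two
patient groups of three (high-pressure HP and medium-pressure MP), each
sampled before and three months after surgical de-obstruction.

Model choices (documented constants, not fitted to any dataset):

* counts are negative binomial, var = mu + alpha*mu^2, with per-sample
  library-size factors drawn log-normal(0, 0.2) and gene baseline means
  log-normal around 150; per-gene dispersions are log-normal around the
  requested mean with sigma 0.3;
* planted fold changes have magnitude exactly ``lfc_scale`` with signs
  split 50/50 up/down;
* LFQ log2 intensities are normal per protein (between-protein SD 2.0,
  replicate SD 0.3 around a grand mean of 23) and are censored below each
  sample's ``censor_quantile`` quantile, plus a 2% missing-completely-at-
  random background so both imputation tiers are exercised;
* identifiers are synthetic (g0001, p0001, T0001, tf01) — never real
  symbols.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import OntologyDAG
from .proteomics import LFQMatrix
from .rnaseq import CountMatrix
from .tfreg import TFRegulonDB
from .urodynamics import UrodynamicRecord

__all__ = [
    "SyntheticTruth",
    "gen_counts",
    "gen_lfq",
    "gen_ontology",
    "gen_tf_db",
    "gen_urodynamics",
    "gen_study_counts",
]

LIBSIZE_SIGMA = 0.2  # log-normal spread of per-sample depth factors
BASELINE_LOG_MEAN = np.log(150.0)
BASELINE_LOG_SD = 1.0
DISPERSION_LOG_SD = 0.3
LFQ_GRAND_MEAN = 23.0  # log2 of ~8e6, a typical LFQ scale
LFQ_BETWEEN_SD = 2.0
LFQ_WITHIN_SD = 0.3
LFQ_MCAR = 0.02

#: printed PdetQmax group means/SDs (cmH2O): (before mean, before SD, after mean, after SD)
PDETQMAX_PARAMS = {
    "HP": (107.0, 20.4, 40.6, 5.5),
    "MP": (55.0, 21.7, 22.0, 2.64),
}
AGE_PARAMS = {"HP": (71.0, 2.6), "MP": (68.0, 9.0)}
#: plausible flow/residual configurations (mean, SD) per timepoint
QMAX_PARAMS = {"before": (7.0, 2.0), "after": (16.0, 4.0)}
RV_PARAMS = {"before": (150.0, 60.0), "after": (25.0, 12.0)}


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset."""

    de_features: dict[str, set[str]]  # contrast name -> planted features
    effect_log2fc: dict[str, float]  # feature -> planted log2fc (0 if not planted)
    dispersion: dict[str, float] = field(default_factory=dict)
    missing_mechanism: dict[str, float] = field(default_factory=dict)  # sample -> censor threshold
    group_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def planted(self) -> set[str]:
        out: set[str] = set()
        for s in self.de_features.values():
            out |= s
        return out


def _check_group_sizes(group_sizes: dict[str, int]) -> None:
    for g, n in group_sizes.items():
        if not isinstance(n, (int, np.integer)) or n < 2:
            raise ValueError(f"group {g!r} size must be an integer >= 2, got {n!r}")


def _reference_group(group_sizes: dict[str, int]) -> str:
    return "control" if "control" in group_sizes else next(iter(group_sizes))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB with var = mu + alpha*mu^2 via gamma-Poisson mixing."""
    shape = 1.0 / alpha
    lam = rng.gamma(shape, mu * alpha)
    return rng.poisson(lam)


def _counts_from_effects(
    n_genes: int,
    group_sizes: dict[str, int],
    effects: pd.DataFrame,  # genes x groups, log2 units
    dispersion_mean: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict[str, str], np.ndarray]:
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    base_mu = np.exp(rng.normal(BASELINE_LOG_MEAN, BASELINE_LOG_SD, size=n_genes))
    disp = np.exp(rng.normal(np.log(dispersion_mean), DISPERSION_LOG_SD, size=n_genes))
    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    for g, n in group_sizes.items():
        mult = 2.0 ** effects[g].to_numpy()
        for r in range(n):
            sample = f"{g}_{r + 1}"
            lib = np.exp(rng.normal(0.0, LIBSIZE_SIGMA))
            cols[sample] = _nb_draw(rng, base_mu * mult * lib, disp)
            groups[sample] = g
    counts = pd.DataFrame(cols, index=genes)
    return counts, groups, disp


def gen_counts(
    n_genes: int,
    group_sizes: dict[str, int],
    frac_de: float = 0.1,
    lfc_scale: float = 1.5,
    dispersion_mean: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Negative-binomial count matrix with planted group effects.

    ``floor(frac_de * n_genes)`` genes receive a log2 fold change of
    magnitude ``lfc_scale`` (sign split 50/50) in every non-reference group
    relative to the reference ('control' when present, else the first
    group).  Truth records the planted set per contrast.
    """
    if n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")
    _check_group_sizes(group_sizes)
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    ref = _reference_group(group_sizes)

    n_de = int(np.floor(frac_de * n_genes))
    planted = sorted(rng.choice(n_genes, size=n_de, replace=False)) if n_de else []
    # exact 50/50 up/down split (odd counts leave the extra on +)
    signs = np.ones(n_de)
    signs[n_de - n_de // 2:] = -1.0
    signs = rng.permutation(signs)

    effects = pd.DataFrame(0.0, index=genes, columns=list(group_sizes))
    for idx, sign in zip(planted, signs):
        for g in group_sizes:
            if g != ref:
                effects.iloc[idx, effects.columns.get_loc(g)] = sign * lfc_scale

    counts, groups, disp = _counts_from_effects(n_genes, group_sizes, effects, dispersion_mean, rng)
    planted_ids = {genes[i] for i in planted}
    truth = SyntheticTruth(
        de_features={f"{g}_vs_{ref}": set(planted_ids) for g in group_sizes if g != ref},
        effect_log2fc={
            genes[i]: float(s * lfc_scale) for i, s in zip(planted, signs)
        } | {g: 0.0 for g in genes if g not in planted_ids},
        dispersion=dict(zip(genes, disp)),
        group_sizes=dict(group_sizes),
    )
    return CountMatrix(counts=counts, groups=groups), truth


def gen_study_counts(
    n_genes: int = 1200,
    n_control: int = 6,
    n_per_patient_group: int = 3,
    frac_de: float = 0.15,
    lfc_scale: float = 1.5,
    dispersion_mean: float = 0.05,
    seed: int = 0,
) -> tuple[CountMatrix, SyntheticTruth]:
    """Five-group study design with before/after effect trajectories.

    Groups: control, HP_before, HP_after, MP_before, MP_after.  Planted
    genes are split across trajectories — 40% persistent (DE before and
    after), 40% normalized (before only) and 20% de novo (after only) — and
    across group scopes — 60% affect both patient groups, 20% only HP, 20%
    only MP — so the bookkeeping, group-classifier and TF-trajectory layers
    all see signal.
    """
    group_sizes = {
        "control": n_control,
        "HP_before": n_per_patient_group,
        "HP_after": n_per_patient_group,
        "MP_before": n_per_patient_group,
        "MP_after": n_per_patient_group,
    }
    _check_group_sizes(group_sizes)
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]

    n_de = int(np.floor(frac_de * n_genes))
    planted = rng.choice(n_genes, size=n_de, replace=False)
    signs = np.ones(n_de)
    signs[n_de // 2:] = -1.0
    signs = rng.permutation(signs)
    trajectories = rng.choice(
        ["persistent", "normalized", "de_novo"], size=n_de, p=[0.4, 0.4, 0.2]
    )
    scopes = rng.choice(["both", "HP", "MP"], size=n_de, p=[0.6, 0.2, 0.2])

    effects = pd.DataFrame(0.0, index=genes, columns=list(group_sizes))
    de_features: dict[str, set[str]] = {f"{g}_vs_control": set() for g in group_sizes if g != "control"}
    effect_lfc = {g: 0.0 for g in genes}
    for idx, sign, traj, scope in zip(planted, signs, trajectories, scopes):
        gene = genes[idx]
        lfc = float(sign * lfc_scale)
        effect_lfc[gene] = lfc
        timepoints = {
            "persistent": ["before", "after"],
            "normalized": ["before"],
            "de_novo": ["after"],
        }[traj]
        pgroups = ["HP", "MP"] if scope == "both" else [scope]
        for pg in pgroups:
            for tp in timepoints:
                g = f"{pg}_{tp}"
                effects.loc[gene, g] = lfc
                de_features[f"{g}_vs_control"].add(gene)

    counts, groups, disp = _counts_from_effects(n_genes, group_sizes, effects, dispersion_mean, rng)
    truth = SyntheticTruth(
        de_features=de_features,
        effect_log2fc=effect_lfc,
        dispersion=dict(zip(genes, disp)),
        group_sizes=group_sizes,
    )
    return CountMatrix(counts=counts, groups=groups), truth


def gen_lfq(
    n_proteins: int,
    group_sizes: dict[str, int],
    frac_de: float = 0.1,
    censor_quantile: float = 0.3,
    delta: float = 2.0,
    seed: int = 0,
) -> tuple[LFQMatrix, SyntheticTruth]:
    """Log-normal LFQ intensities with left-censored (MNAR) missingness.

    Each sample censors values below its own ``censor_quantile`` quantile
    (deterministically) and additionally loses a 2% random background.
    Planted proteins shift by ``delta`` log2 units (sign split 50/50) in
    every non-reference group.  Truth records per-sample censoring
    thresholds in ``missing_mechanism``.
    """
    if not 0 < censor_quantile < 1:
        raise ValueError("censor_quantile must lie in (0, 1)")
    if not 0 <= frac_de <= 1:
        raise ValueError("frac_de must lie in [0, 1]")
    _check_group_sizes(group_sizes)
    rng = np.random.default_rng(seed)
    prots = [f"p{i + 1:04d}" for i in range(n_proteins)]
    ref = _reference_group(group_sizes)

    base = rng.normal(LFQ_GRAND_MEAN, LFQ_BETWEEN_SD, size=n_proteins)
    n_de = int(np.floor(frac_de * n_proteins))
    planted = sorted(rng.choice(n_proteins, size=n_de, replace=False)) if n_de else []
    signs = np.ones(n_de)
    signs[n_de // 2:] = -1.0
    signs = rng.permutation(signs)

    effect = np.zeros(n_proteins)
    for idx, s in zip(planted, signs):
        effect[idx] = s * delta

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, str] = {}
    order = []
    for g, n in group_sizes.items():
        mu = base + (effect if g != ref else 0.0)
        for r in range(n):
            sample = f"{g}_{r + 1}"
            cols[sample] = rng.normal(mu, LFQ_WITHIN_SD)
            groups[sample] = g
            order.append(sample)
    full = pd.DataFrame(cols, index=prots, columns=order)

    thresholds: dict[str, float] = {}
    masked = full.copy()
    for s in order:
        thr = float(np.quantile(full[s].to_numpy(), censor_quantile))
        thresholds[s] = thr
        censored = full[s] < thr
        mcar = pd.Series(rng.random(n_proteins) < LFQ_MCAR, index=full.index)
        masked.loc[censored | mcar, s] = np.nan

    planted_ids = {prots[i] for i in planted}
    truth = SyntheticTruth(
        de_features={f"{g}_vs_{ref}": set(planted_ids) for g in group_sizes if g != ref},
        effect_log2fc={prots[i]: float(s * delta) for i, s in zip(planted, signs)}
        | {p: 0.0 for p in prots if p not in planted_ids},
        missing_mechanism=thresholds,
        group_sizes=dict(group_sizes),
    )
    return LFQMatrix.from_intensities(masked, groups), truth


def gen_ontology(
    n_terms: int,
    max_children: int = 3,
    n_genes: int = 50,
    seed: int = 0,
    focus_genes: set[str] | None = None,
    n_focus_terms: int = 3,
) -> tuple[OntologyDAG, dict[str, set[str]]]:
    """Random rooted is_a DAG with true-path-closed annotations.

    Terms may have multiple parents.  Every gene is directly annotated to
    at least one non-root term, so the root's closed annotation set equals
    the gene universe.  When ``focus_genes`` is given, ``n_focus_terms``
    terms draw ~70% of their direct annotations from that set, planting
    enrichable structure.  Returns the DAG and the *direct* annotations.
    """
    if n_terms < 3:
        raise ValueError("n_terms must be >= 3")
    rng = np.random.default_rng(seed)
    terms = [f"T{i + 1:04d}" for i in range(n_terms)]
    root = terms[0]
    edges: list[tuple[str, str]] = []
    children_of = {t: 0 for t in terms}
    for i, t in enumerate(terms[1:], start=1):
        # primary parent among earlier terms with spare child slots
        candidates = [u for u in terms[:i] if children_of[u] < max_children] or [root]
        parent = candidates[rng.integers(len(candidates))]
        edges.append((t, parent))
        children_of[parent] += 1
        # occasional second parent -> genuine DAG, not a tree
        if i > 1 and rng.random() < 0.25:
            others = [u for u in terms[:i] if u != parent]
            if others:
                edges.append((t, others[rng.integers(len(others))]))

    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    non_root = terms[1:]
    direct: dict[str, set[str]] = {t: set() for t in terms}
    for g in genes:
        n_annot = 1 + rng.integers(0, 3)
        for t in rng.choice(non_root, size=min(n_annot, len(non_root)), replace=False):
            direct[str(t)].add(g)
    if focus_genes:
        focus = sorted(set(focus_genes) & set(genes))
        if focus:
            focus_terms = rng.choice(non_root, size=min(n_focus_terms, len(non_root)), replace=False)
            for t in focus_terms:
                size = max(5, len(focus) // max(1, n_focus_terms))
                n_from_focus = int(round(0.7 * size))
                picked = rng.choice(focus, size=min(n_from_focus, len(focus)), replace=False)
                background = rng.choice(genes, size=max(0, size - len(picked)), replace=False)
                direct[str(t)] |= set(picked) | set(background)
    dag = OntologyDAG.from_edges(edges, direct)
    return dag, direct


def gen_tf_db(
    n_tfs: int,
    targets_per_tf: int = 20,
    overlap: float = 0.0,
    seed: int = 0,
    target_pool: list[str] | None = None,
    tf_pool: list[str] | None = None,
) -> TFRegulonDB:
    """TF->target table with controllable regulon overlap.

    Each regulon holds exactly ``targets_per_tf`` targets, of which
    ``floor(overlap * targets_per_tf)`` are drawn from a shared pool common
    to all TFs (overlap = 0 gives pairwise-disjoint regulons).  Source tags
    cycle through the four public database names.  TF identifiers default
    to tf01, tf02, ...; pass ``tf_pool`` (e.g. gene ids measured in the
    expression data) to name them from a universe instead, so the TFs
    themselves can appear in DE results.
    """
    if n_tfs < 1:
        raise ValueError("n_tfs must be >= 1")
    if not 0 <= overlap <= 1:
        raise ValueError("overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_shared = int(np.floor(overlap * targets_per_tf))
    n_own = targets_per_tf - n_shared
    if target_pool is None:
        need = n_shared + n_own * n_tfs
        target_pool = [f"g{i + 1:04d}" for i in range(need)]
    pool = list(target_pool)
    if len(pool) < n_shared + n_own * n_tfs:
        raise ValueError("target pool too small for the requested regulons")
    pool = [str(x) for x in rng.permutation(pool)]
    shared, rest = pool[:n_shared], pool[n_shared:]
    if tf_pool is not None:
        if len(tf_pool) < n_tfs:
            raise ValueError("tf_pool too small for the requested number of TFs")
        tf_names = [str(x) for x in rng.choice(sorted(tf_pool), size=n_tfs, replace=False)]
    else:
        tf_names = [f"tf{i + 1:02d}" for i in range(n_tfs)]
    sources = ["TRED", "ITFP", "TRRUST", "Marbach"]
    rows = []
    for i, tf in enumerate(tf_names):
        own = rest[i * n_own: (i + 1) * n_own]
        for t in shared + own:
            if t == tf:
                continue  # a regulon never lists its own TF
            rows.append({"tf": tf, "target": t, "source": sources[i % len(sources)]})
    return TFRegulonDB(pd.DataFrame(rows, columns=["tf", "target", "source"]))


def gen_urodynamics(n_per_group: int, seed: int = 0) -> list[UrodynamicRecord]:
    """Before/after pressure-flow records for HP and MP patients.

    PdetQmax is drawn per group/timepoint from normals with the study's
    group means and SDs (HP 107+-20.4 -> 40.6+-5.5; MP 55+-21.7 ->
    22+-2.64 cmH2O), truncated at 0 by resampling; Qmax and RV come from
    plausible configured ranges (module constants).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)

    def truncated_normal(mean: float, sd: float, lo: float = 0.0) -> float:
        for _ in range(1000):
            v = rng.normal(mean, sd)
            if v >= lo:
                return float(v)
        return lo

    records = []
    for group in ("HP", "MP"):
        mb, sb, ma, sa = PDETQMAX_PARAMS[group]
        age_m, age_s = AGE_PARAMS[group]
        for i in range(n_per_group):
            pid = f"{group}{i + 1:02d}"
            age = truncated_normal(age_m, age_s, lo=40.0)
            for timepoint, (m, s) in (("before", (mb, sb)), ("after", (ma, sa))):
                qm, qs = QMAX_PARAMS[timepoint]
                rm, rs = RV_PARAMS[timepoint]
                records.append(
                    UrodynamicRecord(
                        patient_id=pid,
                        timepoint=timepoint,
                        pdet_qmax=truncated_normal(m, s),
                        qmax=truncated_normal(qm, qs, lo=0.5),
                        rv=truncated_normal(rm, rs),
                        age=age,
                    )
                )
    return records
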