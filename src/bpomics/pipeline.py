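"""End-to-end orchestration of the analysis on a (synthetic or read) bundle.

The run order mirrors the study: urodynamic grouping -> dual-method RNA DE
versus control -> before/after bookkeeping -> PCA classifier selection ->
ontology enrichment with semantic clustering -> repeated-imputation
proteomics DE -> TF regulon analysis.  Everything is deterministic given
the config seed; per-stage seeds are fixed offsets of it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classifier as clf
from . import enrichment as enr
from . import io as bio
from . import proteomics as prot
from . import rnaseq as rna
from . import synthetic as syn
from . import tfreg
from .urodynamics import compute_indices

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger("bpomics")

PATIENT_GROUPS = ("HP", "MP")
CONTRAST_GROUPS = ("HP_before", "HP_after", "MP_before", "MP_after")

# per-stage seed offsets (all randomness flows from config.seed)
_SEED_COUNTS = 0
_SEED_LFQ = 1
_SEED_ONTOLOGY = 2
_SEED_TFDB = 3
_SEED_URO = 4
_SEED_IMPUTE = 10


@dataclass
class RunConfig:
    """Pipeline parameters; the defaults are the study's printed values."""

    alpha_rna: float = 0.1
    alpha_ora: float = 0.1
    n_pcs: int = 6
    loading_frac: float = 0.2
    impute_shift: float = 2.5
    impute_width: float = 0.3
    impute_cycles: int = 20
    curve_fc_min: float = 1.0
    curve_alpha: float = 0.05
    curve_curvature: float = 0.5
    sim_threshold: float = 0.7
    cluster_k: int = 5
    seed: int = 0
    # synthetic-bundle sizes (used when no input paths are given)
    n_genes: int = 1200
    n_proteins: int = 400
    n_terms: int = 40
    n_tfs: int = 8
    n_urodyn_per_group: int = 3
    # optional real inputs; when set, generation of that layer is skipped
    counts_path: str | None = None
    counts_meta_path: str | None = None
    lfq_path: str | None = None
    lfq_meta_path: str | None = None
    obo_path: str | None = None
    gmt_path: str | None = None
    tf_path: str | None = None
    urodyn_path: str | None = None

    def __post_init__(self) -> None:
        for name in ("alpha_rna", "alpha_ora", "loading_frac", "curve_alpha", "sim_threshold"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)


def _load_or_generate(config: RunConfig, outdir: Path):
    seed = config.seed
    if config.counts_path:
        counts = bio.read_counts(config.counts_path, config.counts_meta_path)
        truth = None
    else:
        counts, truth = syn.gen_study_counts(n_genes=config.n_genes, seed=seed + _SEED_COUNTS)
        bio.write_counts(counts, outdir / "counts.tsv", outdir / "counts_meta.tsv")
        bio.write_truth(truth, outdir / "truth_counts.json")
    if config.lfq_path:
        lfq = bio.read_lfq(config.lfq_path, config.lfq_meta_path)
    else:
        group_sizes = {"control": 6, "HP_before": 3, "HP_after": 3, "MP_before": 3, "MP_after": 3}
        lfq, lfq_truth = syn.gen_lfq(
            config.n_proteins, group_sizes, frac_de=0.15, delta=2.0, seed=seed + _SEED_LFQ
        )
        bio.write_lfq(lfq, outdir / "lfq.tsv", outdir / "lfq_meta.tsv")
        bio.write_truth(lfq_truth, outdir / "truth_lfq.json")
    if config.obo_path:
        annotations = bio.read_gmt(config.gmt_path)
        dag = bio.read_obo(config.obo_path, annotations)
    else:
        focus = truth.de_features.get("HP_before_vs_control") if truth else None
        dag, direct = syn.gen_ontology(
            config.n_terms, n_genes=config.n_genes, seed=seed + _SEED_ONTOLOGY,
            focus_genes=focus,
        )
        bio.write_obo(dag, outdir / "ontology.obo")
        bio.write_gmt(direct, outdir / "annotations.gmt")
    if config.tf_path:
        db = bio.read_tf(config.tf_path)
    else:
        db = syn.gen_tf_db(
            config.n_tfs,
            targets_per_tf=25,
            overlap=0.1,
            seed=seed + _SEED_TFDB,
            target_pool=[f"g{i + 1:04d}" for i in range(config.n_genes)],
            tf_pool=sorted(truth.planted) if truth else None,
        )
        bio.write_tf(db, outdir / "tf.tsv")
    if config.urodyn_path:
        records = bio.read_urodyn(config.urodyn_path)
    else:
        records = syn.gen_urodynamics(config.n_urodyn_per_group, seed=seed + _SEED_URO)
        bio.write_urodyn(records, outdir / "urodynamics.csv")
    return counts, truth, lfq, dag, db, records


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, write all tables under ``outdir``, return the summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts, truth, lfq, dag, db, records = _load_or_generate(config, outdir)
    summary: dict = {"seed": config.seed, "parameters": {
        "alpha_rna": config.alpha_rna, "alpha_ora": config.alpha_ora,
        "n_pcs": config.n_pcs, "loading_frac": config.loading_frac,
        "impute_cycles": config.impute_cycles, "sim_threshold": config.sim_threshold,
        "cluster_k": config.cluster_k,
    }}

    # -- urodynamics --------------------------------------------------------
    log.info("stage: urodynamic indices")
    idx_rows = [asdict(compute_indices(r)) for r in records]
    indices = pd.DataFrame(idx_rows)
    indices.to_csv(outdir / "urodynamic_indices.csv", index=False)
    summary["urodynamics"] = {
        "n_records": len(records),
        "hp_fraction_before": float(
            (indices.query("timepoint == 'before'")["pressure_group"] == "HP").mean()
        ),
        "unobstructed_fraction_after": float(
            (indices.query("timepoint == 'after'")["obstruction_class"] == "unobstructed").mean()
        ),
    }

    # -- RNA DE versus control ----------------------------------------------
    cons: dict[str, rna.ConsensusDEGSet] = {}
    lfc_tables: dict[str, pd.Series] = {}
    summary["rnaseq"] = {}
    for group in CONTRAST_GROUPS:
        log.info("stage: RNA DE %s vs control", group)
        res_e = rna.de_test(counts, (group, "control"), method="nb_exact", alpha=config.alpha_rna)
        res_w = rna.de_test(counts, (group, "control"), method="nb_wald", alpha=config.alpha_rna)
        res_e.table.rename_axis("feature").to_csv(outdir / f"de_{group}_nb_exact.tsv", sep="\t")
        res_w.table.rename_axis("feature").to_csv(outdir / f"de_{group}_nb_wald.tsv", sep="\t")
        c = rna.consensus(res_e, res_w, alpha=config.alpha_rna)
        cons[group] = c
        lfc_tables[group] = res_w.table["log2fc"]
        summary["rnaseq"][group] = {
            "nb_exact": rna.de_counts(res_e),
            "nb_wald": rna.de_counts(res_w),
            "mean_of_methods": {
                k: (rna.de_counts(res_e)[k] + rna.de_counts(res_w)[k]) / 2
                for k in ("up", "down", "total")
            },
            "consensus": rna.de_counts(c),
        }

    # -- bookkeeping ---------------------------------------------------------
    summary["bookkeeping"] = {}
    for g in PATIENT_GROUPS:
        book = rna.bookkeeping(cons[f"{g}_before"], cons[f"{g}_after"])
        summary["bookkeeping"][g] = book.counts
        pd.DataFrame(
            [(f, cat) for cat in ("normalized", "persistent", "de_novo")
             for f in sorted(getattr(book, cat))],
            columns=["feature", "category"],
        ).to_csv(outdir / f"bookkeeping_{g}.tsv", sep="\t", index=False)

    # -- classifier selection ------------------------------------------------
    log.info("stage: classifier selection")
    expr = clf.log_normalized_expression(counts)

    def signature(contrast: tuple[str, str], name: str) -> clf.ClassifierSet:
        samples = counts.samples_of(contrast[0]) + counts.samples_of(contrast[1])
        res_e = rna.de_test(counts, contrast, method="nb_exact", alpha=config.alpha_rna)
        res_w = rna.de_test(counts, contrast, method="nb_wald", alpha=config.alpha_rna)
        degs = rna.consensus(res_e, res_w, alpha=config.alpha_rna)
        pcares = clf.pca(expr[samples])
        sel = clf.select_by_loading_range(pcares.loadings, n_pcs=config.n_pcs, frac=config.loading_frac)
        return clf.derive_classifier(sel, degs, contrast=name)

    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # <6 PCs with n=3+3 samples is expected
        sig_group = signature(("HP_before", "MP_before"), "HP_vs_MP_before")
        sig_deob = signature(("HP_after", "HP_before"), "HP_after_vs_before")
    combined = clf.combine_signatures(sig_group, sig_deob)
    pd.DataFrame({
        "feature": sig_group.features + sig_deob.features,
        "signature": ["HP_vs_MP_before"] * len(sig_group) + ["HP_after_vs_before"] * len(sig_deob),
    }).to_csv(outdir / "classifier_genes.tsv", sep="\t", index=False)
    summary["classifier"] = {
        "group_signature_size": len(sig_group),
        "deobstruction_signature_size": len(sig_deob),
        "combined_size": len(combined),
    }
    if combined.features:
        labels = {s: counts.groups[s] for s in counts.samples}
        scores, sil = clf.project_and_separate(expr, combined, labels)
        scores.rename_axis("sample").to_csv(outdir / "classifier_scores.tsv", sep="\t")
        summary["classifier"]["silhouette_all_groups"] = round(float(sil), 6)

    # -- enrichment ----------------------------------------------------------
    log.info("stage: ontology enrichment")
    universe = set(counts.counts.index[(counts.counts > 0).any(axis=1)])
    query = cons["HP_before"].all & universe
    lfc_map = lfc_tables["HP_before"].to_dict()
    results = enr.ora(query, universe, dag, p_max=config.alpha_ora, log2fc=lfc_map)
    summary["enrichment"] = {"n_enriched_terms": len(results)}
    if results:
        terms = [r.term for r in results]
        sim = enr.similarity_matrix(dag, terms)
        kept = enr.prune_redundant({r.term: r.p for r in results}, sim, threshold=config.sim_threshold)
        clusters = enr.binary_cut(
            sim.loc[kept, kept],
            term_p={r.term: r.p for r in results},
            term_size={r.term: r.K for r in results},
        )
        tables = enr.display_tables([r for r in results if r.term in set(kept)], clusters, lfc_map)
        for name, df in tables.items():
            df.to_csv(outdir / f"enrichment_{name}.tsv", sep="\t", index=False)
        summary["enrichment"].update(
            {"n_after_pruning": len(kept), "n_clusters": len(clusters.clusters)}
        )

    # -- proteomics ----------------------------------------------------------
    summary["proteomics"] = {}
    for i, group in enumerate(CONTRAST_GROUPS):
        log.info("stage: proteomics DE %s vs control", group)
        dep = prot.repeated_imputation_de(
            lfq, (group, "control"),
            n_cycles=config.impute_cycles,
            base_seed=config.seed + _SEED_IMPUTE + 100 * i,
            fc_min=config.curve_fc_min,
            curve_alpha=config.curve_alpha,
            curvature=config.curve_curvature,
            shift=config.impute_shift,
            width=config.impute_width,
        )
        dep.table.rename_axis("protein").to_csv(outdir / f"dep_{group}.tsv", sep="\t")
        summary["proteomics"][group] = {
            "significant": prot.dep_counts(dep, "significant"),
            "consistent": prot.dep_counts(dep, "consistent"),
        }

    # -- TF regulons ---------------------------------------------------------
    log.info("stage: TF regulons")
    de_sets = {g: cons[g].all for g in CONTRAST_GROUPS}
    patterns = tfreg.regulated_tfs(de_sets, lfc_tables, db)
    pd.DataFrame(
        [{"tf": p.tf, "category": p.category, **p.lfc} for p in patterns]
    ).to_csv(outdir / "tf_patterns.tsv", sep="\t", index=False)
    summary["tf"] = {
        "n_regulated": len(patterns),
        "categories": {
            cat: sum(1 for p in patterns if p.category == cat)
            for cat in ("persistent", "normalized_after", "de_novo", "unchanged")
        },
    }
    focus = next((p for p in patterns if p.category == "normalized_after"), None) or (
        patterns[0] if patterns else None
    )
    if focus is not None:
        mat = tfreg.target_matrix(focus.tf, db, lfc_tables)
        if mat.shape[0] >= 2:
            tclust = tfreg.cluster_targets(mat, k=config.cluster_k)
            report = tfreg.cluster_trajectory_report(tclust, mat)
            report.to_csv(outdir / f"tf_{focus.tf}_clusters.tsv", sep="\t", index=False)
            summary["tf"]["focus"] = {
                "tf": focus.tf,
                "category": focus.category,
                "n_targets_measured": int(mat.shape[0]),
                "n_clusters": len(tclust.clusters),
                "n_down_after": int(report["down_after"].sum()),
            }

    # -- ground-truth cross-checks ------------------------------------------
    if truth is not None:
        planted_before = truth.de_features.get("HP_before_vs_control", set())
        detected = cons["HP_before"].all
        summary["truth_check"] = {
            "hp_before_planted": len(planted_before),
            "hp_before_detected": len(detected),
            "hp_before_recall": round(
                len(planted_before & detected) / max(1, len(planted_before)), 6
            ),
        }

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
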