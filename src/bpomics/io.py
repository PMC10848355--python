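"""Readers and writers for the pipeline's plain-text formats.

Every writer emits exactly what the matching reader consumes, and
round-trip write->read is an identity (exact for counts and annotations,
floating-point-tolerant for LFQ intensities which are stored on the raw
scale and log2-transformed on load).

Formats: counts TSV (feature id column + one column per sample) with a
sample,group metadata TSV; MatrixMarket with .rows/.cols name sidecars;
MaxQuant proteinGroups-like TSV with 'LFQ intensity <sample>' columns
(blank or 0 = missing); OBO subset (id/name/is_a stanzas); GMT and
2-column TSV annotations; TF TSV (tf, target, source); urodynamics CSV;
truth JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import obonet
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .enrichment import OntologyDAG
from .proteomics import LFQMatrix
from .rnaseq import CountMatrix
from .synthetic import SyntheticTruth
from .tfreg import TFRegulonDB
from .urodynamics import UrodynamicRecord

__all__ = [
    "read_counts", "write_counts", "read_counts_mtx", "write_counts_mtx",
    "read_metadata", "write_metadata", "read_lfq", "write_lfq",
    "read_obo", "write_obo", "read_gmt", "write_gmt", "read_annotations_tsv",
    "read_tf", "write_tf", "read_urodyn", "write_urodyn",
    "read_truth", "write_truth",
]


# -- sample metadata --------------------------------------------------------

def write_metadata(groups: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"sample": list(groups), "group": [groups[s] for s in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: metadata needs 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


# -- counts -----------------------------------------------------------------

def write_counts(cm: CountMatrix, counts_path: str | Path, meta_path: str | Path) -> None:
    cm.counts.rename_axis("feature").to_csv(counts_path, sep="\t")
    write_metadata(cm.groups, meta_path)


def read_counts(counts_path: str | Path, meta_path: str | Path) -> CountMatrix:
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{counts_path}: duplicate feature id {dup!r}")
    bad = df.columns[df.isna().any()]
    if len(bad):
        raise ValueError(f"{counts_path}: non-numeric or missing entries in {list(bad)}")
    return CountMatrix(counts=df.astype(np.int64), groups=read_metadata(meta_path))


def write_counts_mtx(cm: CountMatrix, mtx_path: str | Path, meta_path: str | Path) -> None:
    """MatrixMarket coordinate file plus .rows/.cols name sidecars."""
    mtx_path = Path(mtx_path)
    spio.mmwrite(str(mtx_path), sparse.csr_matrix(cm.counts.to_numpy()))
    mtx_path.with_suffix(".rows").write_text("\n".join(cm.features) + "\n")
    mtx_path.with_suffix(".cols").write_text("\n".join(cm.samples) + "\n")
    write_metadata(cm.groups, meta_path)


def read_counts_mtx(mtx_path: str | Path, meta_path: str | Path) -> CountMatrix:
    mtx_path = Path(mtx_path)
    mat = spio.mmread(str(mtx_path))
    rows = mtx_path.with_suffix(".rows").read_text().splitlines()
    cols = mtx_path.with_suffix(".cols").read_text().splitlines()
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.int64)
    df = pd.DataFrame(dense, index=rows, columns=cols)
    return CountMatrix(counts=df, groups=read_metadata(meta_path))


# -- LFQ --------------------------------------------------------------------

_LFQ_PREFIX = "LFQ intensity "
_LFQ_ID = "Protein IDs"


def write_lfq(lfq: LFQMatrix, path: str | Path, meta_path: str | Path) -> None:
    """proteinGroups-like TSV; intensities written on the raw (2**x) scale,
    missing entries as blanks."""
    out = pd.DataFrame({_LFQ_ID: lfq.proteins})
    for s in lfq.samples:
        raw = np.power(2.0, lfq.intensities[s].to_numpy(dtype=float))
        col = [("" if np.isnan(v) else f"{v:.10g}") for v in raw]
        out[_LFQ_PREFIX + s] = col
    out.to_csv(path, sep="\t", index=False)
    write_metadata(lfq.groups, meta_path)


def read_lfq(path: str | Path, meta_path: str | Path) -> LFQMatrix:
    df = pd.read_csv(path, sep="\t", dtype={_LFQ_ID: str})
    if _LFQ_ID not in df.columns:
        raise ValueError(f"{path}: missing {_LFQ_ID!r} column")
    lfq_cols = [c for c in df.columns if c.startswith(_LFQ_PREFIX)]
    if not lfq_cols:
        raise ValueError(f"{path}: no '{_LFQ_PREFIX}<sample>' columns")
    ids = df[_LFQ_ID]
    if ids.duplicated().any():
        raise ValueError(f"{path}: duplicate protein id {ids[ids.duplicated()].iloc[0]!r}")
    mat = df[lfq_cols].apply(pd.to_numeric, errors="coerce")
    mat = mat.where(mat > 0)  # zeros and blanks are both missing
    mat = np.log2(mat)
    mat.columns = [c[len(_LFQ_PREFIX):] for c in lfq_cols]
    mat.index = ids
    mat.index.name = None
    return LFQMatrix.from_intensities(mat, read_metadata(meta_path))


# -- ontology ---------------------------------------------------------------

def write_obo(dag: OntologyDAG, path: str | Path) -> None:
    """Minimal OBO subset: id, name and is_a tags only."""
    lines = ["format-version: 1.2", ""]
    for term in dag.terms:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.names.get(term, term)}")
        for parent in sorted(dag.graph.successors(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def read_obo(path: str | Path, direct_annotations: dict[str, set[str]]) -> OntologyDAG:
    """Read an OBO subset and attach (then propagate) direct annotations."""
    g = obonet.read_obo(str(path))
    edges = [(c, p) for c, p, key in g.edges(keys=True) if key == "is_a"]
    names = {t: data.get("name", t) for t, data in g.nodes(data=True)}
    return OntologyDAG.from_edges(edges, direct_annotations, names=names)


def write_gmt(annotations: dict[str, set[str]], path: str | Path,
              descriptions: dict[str, str] | None = None) -> None:
    lines = []
    for term in sorted(annotations):
        genes = sorted(annotations[term])
        if not genes:
            continue
        desc = (descriptions or {}).get(term, "na")
        lines.append("\t".join([term, desc] + genes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description and >=1 gene")
        out[parts[0]] = set(parts[2:])
    return out


def read_annotations_tsv(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV: term <tab> gene."""
    out: dict[str, set[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected exactly 2 tab-separated columns")
        out.setdefault(parts[0], set()).add(parts[1])
    return out


# -- TF database ------------------------------------------------------------

def write_tf(db: TFRegulonDB, path: str | Path) -> None:
    db.table.sort_values(["tf", "target", "source"]).to_csv(path, sep="\t", index=False)


def read_tf(path: str | Path) -> TFRegulonDB:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return TFRegulonDB(df)


# -- urodynamics ------------------------------------------------------------

_URO_COLS = ["patient_id", "timepoint", "pdet_qmax", "qmax", "rv", "age"]


def write_urodyn(records: list[UrodynamicRecord], path: str | Path) -> None:
    pd.DataFrame([
        {c: getattr(r, c) for c in _URO_COLS} for r in records
    ]).to_csv(path, index=False, float_format="%.17g")


def read_urodyn(path: str | Path) -> list[UrodynamicRecord]:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in _URO_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        UrodynamicRecord(
            patient_id=str(row.patient_id),
            timepoint=str(row.timepoint),
            pdet_qmax=float(row.pdet_qmax),
            qmax=float(row.qmax),
            rv=float(row.rv),
            age=float(row.age),
        )
        for row in df.itertuples()
    ]


# -- truth ------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    payload = {
        "de_features": {c: sorted(s) for c, s in truth.de_features.items()},
        "effect_log2fc": truth.effect_log2fc,
        "dispersion": truth.dispersion,
        "missing_mechanism": truth.missing_mechanism,
        "group_sizes": truth.group_sizes,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    return SyntheticTruth(
        de_features={c: set(v) for c, v in payload["de_features"].items()},
        effect_log2fc=payload["effect_log2fc"],
        dispersion=payload.get("dispersion", {}),
        missing_mechanism=payload.get("missing_mechanism", {}),
        group_sizes=payload.get("group_sizes", {}),
    )
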