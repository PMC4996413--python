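"""Readers and writers for the on-disk formats shared by every stage.

Formats are deliberately plain text: intensity tables as TSV with two
columns per sample (``<id>.meth`` / ``<id>.unmeth``), the sample sheet
as CSV, probe annotations as TSV with semicolon-joined gene lists, the
ontology as an OBO subset (parsed via :mod:`obonet`, ``is_a`` edges
only, obsolete terms skipped), gene annotations as two-column TSV, and
reports/configs as JSON with sorted keys so identical runs produce
identical bytes.  Readers validate and reject malformed input rather
than coercing it.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .normalize import MethylationDataset
from .semantic import AnnotationCorpus, validate_dag
from .simulate import IntensityDataset, PlantedTruth, ProbeAnnotation, SampleSheet


def write_intensity_table(ds: IntensityDataset, path) -> None:
    data = {}
    for j, sid in enumerate(ds.samples):
        data[f"{sid}.meth"] = ds.meth[:, j]
        data[f"{sid}.unmeth"] = ds.unmeth[:, j]
    frame = pd.DataFrame(data, index=pd.Index(ds.probes, name="probe"))
    frame.to_csv(path, sep="\t")


def read_intensity_table(path, sheet: SampleSheet) -> IntensityDataset:
    """Read a paired-channel TSV; errors name the offending sample."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col="probe", float_precision="round_trip")
    meth_cols = [c for c in frame.columns if c.endswith(".meth")]
    unmeth_cols = [c for c in frame.columns if c.endswith(".unmeth")]
    samples = [c[: -len(".meth")] for c in meth_cols]
    missing = [s for s in samples if f"{s}.unmeth" not in unmeth_cols]
    orphan = [c[: -len(".unmeth")] for c in unmeth_cols if f"{c[:-len('.unmeth')]}.meth" not in meth_cols]
    if missing or orphan:
        bad = (missing + orphan)[0]
        raise ValueError(f"mismatched channel columns for sample {bad!r}")
    meth = frame[[f"{s}.meth" for s in samples]].to_numpy(dtype=float)
    unmeth = frame[[f"{s}.unmeth" for s in samples]].to_numpy(dtype=float)
    if (meth < 0).any() or (unmeth < 0).any():
        raise ValueError("negative intensity in table")
    return IntensityDataset(
        probes=list(frame.index.astype(str)),
        samples=samples,
        meth=meth,
        unmeth=unmeth,
        sheet=sheet,
    )


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.frame.to_csv(path, index=False)


def read_sample_sheet(path) -> SampleSheet:
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    return SampleSheet(frame)


def write_m_matrix(ds: MethylationDataset, path) -> None:
    frame = pd.DataFrame(ds.M, index=pd.Index(ds.probes, name="probe"), columns=ds.samples)
    frame.to_csv(path, sep="\t")


def read_m_matrix(path, sheet: SampleSheet) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe", float_precision="round_trip")


def write_probe_annotation(annot: ProbeAnnotation, path) -> None:
    frame = annot.frame.copy()
    frame["genes"] = frame["genes"].map(";".join)
    frame.to_csv(path, sep="\t", index=False)


def read_probe_annotation(path) -> ProbeAnnotation:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame["genes"] = frame["genes"].map(lambda s: tuple(s.split(";")))
    return ProbeAnnotation(frame[["probe", "genes", "region"]])


def write_obo_subset(graph: nx.DiGraph, path) -> None:
    """Serialize the term DAG as a minimal OBO file (is_a edges only)."""
    lines = ["format-version: 1.2", ""]
    for term in sorted(graph.nodes):
        attrs = graph.nodes[term]
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {attrs.get('name', term)}")
        ns = attrs.get("aspect", "BP")
        namespace = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}.get(ns, ns)
        lines.append(f"namespace: {namespace}")
        for parent in sorted(graph.successors(term)):
            lines.append(f"is_a: {parent}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


_NAMESPACE_TO_ASPECT = {
    "biological_process": "BP",
    "molecular_function": "MF",
    "cellular_component": "CC",
}


def parse_obo_subset(path) -> nx.DiGraph:
    """Parse an OBO file into a child→parent is_a DAG; obsolete terms
    are skipped; a cycle raises with the offending edges listed."""
    multi = obonet.read_obo(path)  # skips obsolete stanzas by default
    g = nx.DiGraph()
    for term, attrs in multi.nodes(data=True):
        ns = attrs.get("namespace", "biological_process")
        g.add_node(term, name=attrs.get("name", term), aspect=_NAMESPACE_TO_ASPECT.get(ns, ns))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent, relation="is_a")
    validate_dag(g)
    return g


def write_gene_annotation(corpus: AnnotationCorpus, path) -> None:
    lines = ["gene\tterm"]
    for gene in sorted(corpus.gene2terms):
        for term in sorted(corpus.gene2terms[gene]):
            lines.append(f"{gene}\t{term}")
    Path(path).write_text("\n".join(lines) + "\n")


def parse_gene_annotation(path, graph: nx.DiGraph | None = None) -> AnnotationCorpus:
    """Two-column gene↔term TSV → corpus; associations to terms missing
    from the graph (when given) are dropped with a warning."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    if frame.empty:
        raise ValueError(f"empty gene annotation file: {path}")
    frame = frame.drop_duplicates()
    dropped = 0
    g2t: dict[str, set[str]] = {}
    for gene, term in zip(frame["gene"], frame["term"]):
        if graph is not None and term not in graph:
            dropped += 1
            continue
        g2t.setdefault(gene, set()).add(term)
    if dropped:
        warnings.warn(f"dropped {dropped} association(s) to unknown terms", stacklevel=2)
    return AnnotationCorpus.from_gene2terms(g2t)


def write_truth(truth: PlantedTruth, path) -> None:
    payload = {
        "dm_probes": {d: sorted(s) for d, s in sorted(truth.dm_probes.items())},
        "true_beta": {p: float(b) for p, b in truth.true_beta.items()},
        "chip_bias": {c: list(b) for c, b in sorted(truth.chip_bias.items())},
    }
    write_report(payload, path)


def read_truth(path) -> PlantedTruth:
    payload = json.loads(Path(path).read_text())
    return PlantedTruth(
        dm_probes={d: frozenset(s) for d, s in payload["dm_probes"].items()},
        true_beta=pd.Series(payload["true_beta"], name="true_beta"),
        chip_bias={c: (b[0], b[1]) for c, b in payload["chip_bias"].items()},
    )


def _sanitize(obj):
    """JSON-ready copy: NaN → null (with warning), numpy scalars → python."""
    if isinstance(obj, dict):
        return {str(k): _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        seq = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_sanitize(v) for v in seq]
    if isinstance(obj, np.ndarray):
        return [_sanitize(v) for v in obj.tolist()]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        if math.isnan(v):
            warnings.warn("NaN metric serialized as null", stacklevel=4)
            return None
        return v
    return obj


def write_report(report: dict, path) -> None:
    """Deterministic JSON: sorted keys, fixed separators, NaN → null."""
    Path(path).write_text(
        json.dumps(_sanitize(report), sort_keys=True, indent=2, allow_nan=False) + "\n"
    )


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())


def read_config(path) -> dict:
    """Flat key=value or JSON run configuration."""
    text = Path(path).read_text()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return json.loads(text)
    out = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = json.loads(value.strip()) if value.strip() else ""
    return out
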