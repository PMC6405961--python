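"""End-to-end annotation pipeline and machine-readable report.

Stages: sequence input -> ORF/protein -> signal peptide -> B/C segmentation
-> class call -> splice version -> gene grouping -> nomenclature, with
optional similarity/tree and read-quantification stages.  All randomness
flows from the single config seed; identical config + inputs give a
byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from . import classify as _classify
from . import isoform as _isoform
from . import nomen as _nomen
from . import quantify as _quantify
from . import segment as _segment
from . import seqio as _seqio
from . import simtree as _simtree

logger = logging.getLogger("seroinkit")


@dataclass
class PipelineConfig:
    """All pipeline inputs and parameter overrides, with module defaults."""

    input_fasta: Optional[str] = None
    molecule: str = "dna"  # dna | protein
    species_table: Optional[str] = None  # TSV: id, genus, species
    reads_fasta: Optional[str] = None
    output_dir: str = "seroinkit-out"
    seed: int = 0
    # segmentation
    pro_threshold: float = _segment.PRO_THRESHOLD
    profile_window: int = _segment.PROFILE_WINDOW
    min_run: int = _segment.MIN_RUN
    smooth_window: int = _segment.SMOOTH_WINDOW
    # classification
    min_score: float = _classify.MIN_SCORE
    min_margin: float = _classify.MIN_MARGIN
    # gene grouping
    nterm_k: int = 25
    id_threshold: float = 0.95
    # alignment / quantification
    gap_open: float = _simtree.GAP_OPEN
    gap_extend: float = _simtree.GAP_EXTEND
    evalue_max: float = _quantify.DEFAULT_EVALUE
    query_len: int = _quantify.QUERY_LEN
    # optional stages
    run_similarity: bool = False
    run_tree: bool = False
    run_quantify: bool = False

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


#: structural schema of the report JSON (shipped with the package)
REPORT_SCHEMA: dict = {
    "type": "object",
    "required": ["provenance", "records", "summaries"],
    "properties": {
        "provenance": {
            "type": "object",
            "required": ["config_digest", "seed", "version"],
        },
        "records": {"type": "array"},
        "summaries": {
            "type": "object",
            "required": ["n_records", "class_counts"],
        },
    },
}


def validate_report(report: dict) -> None:
    """Minimal structural validation of a report against REPORT_SCHEMA."""

    def check(obj, schema, path="report"):
        t = schema.get("type")
        if t == "object":
            if not isinstance(obj, dict):
                raise ValueError(f"{path}: expected object")
            for key in schema.get("required", []):
                if key not in obj:
                    raise ValueError(f"{path}: missing required key {key!r}")
            for key, sub in schema.get("properties", {}).items():
                if key in obj:
                    check(obj[key], sub, f"{path}.{key}")
        elif t == "array" and not isinstance(obj, list):
            raise ValueError(f"{path}: expected array")

    check(report, REPORT_SCHEMA)


@dataclass
class Report:
    rows: pd.DataFrame
    summaries: dict
    provenance: dict
    similarity: Optional[pd.DataFrame] = None
    newick: Optional[str] = None
    read_counts: Optional[dict] = None

    def to_json(self) -> str:
        payload = {
            "provenance": self.provenance,
            "records": self.rows.to_dict(orient="records"),
            "summaries": self.summaries,
        }
        if self.similarity is not None:
            payload["summaries"]["similarity"] = self.similarity.to_dict(orient="records")
        if self.newick is not None:
            payload["summaries"]["newick"] = self.newick
        if self.read_counts is not None:
            payload["summaries"]["read_counts"] = self.read_counts
        validate_report(payload)
        return json.dumps(payload, indent=2, sort_keys=True, default=_json_default)


def _json_default(obj):
    import numpy as np

    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return None if pd.isna(obj) else float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _load_species_table(path: Optional[str]) -> dict[str, tuple[str, str]]:
    if not path:
        return {}
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"id", "genus", "species"}
    if not required <= set(df.columns):
        raise ValueError(f"species table needs columns {sorted(required)}")
    return {row["id"]: (row["genus"], row["species"]) for _, row in df.iterrows()}


def annotate_protein(protein: str, config: PipelineConfig) -> dict:
    """Run signal detection, segmentation, classification and version call
    on one protein; returns a flat result row (never raises on rule
    failures - problems land in the 'flags' field)."""
    row: dict = {"protein_length": len(protein), "flags": ""}
    try:
        a_mod = _segment.detect_signal(protein)
    except (_segment.NoInitiatorMet, ValueError) as exc:
        row.update({"seroin_class": "unclassified", "version": "n/a",
                    "flags": str(exc), "module_spans": ""})
        return row
    call = _classify.assign_class(protein, config.min_score, config.min_margin)
    row["seroin_class"] = call.seroin_class
    row.update({f"score_{c}": round(s, 4) for c, s in call.scores.items()})
    row["margin"] = round(call.margin, 4)
    row["satisfied_clauses"] = ";".join(call.satisfied_clauses)
    try:
        arch = _segment.segment_modules(
            protein, a_mod.end, config.pro_threshold, config.profile_window,
            config.min_run, config.smooth_window,
            class_hint=None if call.seroin_class == "unclassified" else call.seroin_class,
        )
    except ValueError as exc:
        row.update({"version": "n/a", "flags": str(exc), "module_spans": ""})
        return row
    if call.seroin_class == "unclassified":
        row["version"] = "n/a"
        row["module_spans"] = ";".join(
            f"{m.label}:{m.start}-{m.end}" for m in arch.modules)
        return row
    version = _isoform.call_version(arch, call.seroin_class)
    row["version"] = version.code
    spans = version.canonical_modules or arch.modules
    row["module_spans"] = ";".join(
        f"{m.label}{'' if m.complete else '*'}:{m.start}-{m.end}" for m in spans)
    return row


def run(config: PipelineConfig, records: Optional[list[_seqio.SeqRecordLite]] = None
        ) -> Report:
    """Execute the pipeline and build the report.

    ``records`` may be passed directly (e.g. synthetic data); otherwise
    they are read from ``config.input_fasta``.
    """
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(name)s %(message)s")
    if records is None:
        if not config.input_fasta:
            raise ValueError("config.input_fasta is required when no records given")
        logger.info("stage seqio: reading %s", config.input_fasta)
        records = _seqio.read_sequences(config.input_fasta, config.molecule)
    species_map = _load_species_table(config.species_table)

    rows = []
    proteins: dict[str, str] = {}
    for rec in records:
        if config.molecule == "dna" and rec.molecule == "dna":
            orf = _seqio.longest_orf(rec.sequence) if len(rec.sequence) >= 6 else None
            if orf is None:
                rows.append({"id": rec.id, "seroin_class": "unclassified",
                             "version": "n/a", "flags": "no ORF", "module_spans": ""})
                continue
            protein = orf.protein
        else:
            protein = rec.sequence
        proteins[rec.id] = protein
        row = annotate_protein(protein, config)
        row["id"] = rec.id
        genus, species = species_map.get(rec.id, ("Unknown", "sp"))
        row["genus"], row["species"] = genus, species
        rows.append(row)

    df = pd.DataFrame(rows)
    logger.info("stage classify: %d records annotated", len(df))

    # gene grouping + naming per species x class
    if not df.empty:
        df["gene_number"] = 1
        df["n_genes"] = 1
        grouped = df[df["seroin_class"].isin(("Sn1", "Sn2", "Sn3"))]
        registry = _nomen.AbbrevRegistry()
        name_rows = []
        for (genus, species, cls), sub in grouped.groupby(["genus", "species", "seroin_class"]):
            members = [_GeneRecord(r["id"], proteins[r["id"]], (genus, species), cls)
                       for _, r in sub.iterrows() if r["id"] in proteins]
            if not members:
                continue
            groups = _isoform.group_genes(members, config.nterm_k, config.id_threshold)
            n_genes = len(groups)
            for grp in groups:
                for rid in grp.member_ids:
                    df.loc[df["id"] == rid, "gene_number"] = grp.gene_number
                    df.loc[df["id"] == rid, "n_genes"] = n_genes
            for _, r in df[df["id"].isin(sub["id"])].iterrows():
                name_rows.append({
                    "id": r["id"], "genus": genus, "species": species,
                    "seroin_class": cls, "version": r["version"],
                    "gene_number": int(r["gene_number"]), "n_genes": int(r["n_genes"]),
                })
        names = _nomen.assign_names(name_rows, registry) if name_rows else {}
        df["name"] = df["id"].map(names).fillna("")

    class_counts = (df["seroin_class"].value_counts().to_dict() if not df.empty else {})
    summaries: dict = {"n_records": int(len(df)), "class_counts": class_counts}
    report = Report(
        rows=df,
        summaries=summaries,
        provenance={"config_digest": config.digest(), "seed": config.seed,
                    "version": __version__},
    )

    classified = ([] if df.empty else
                  [r for r in records if r.id in proteins and
                   df.set_index("id").loc[r.id, "seroin_class"] in ("Sn1", "Sn2", "Sn3")])
    calls = ({} if df.empty else
             {r.id: df.set_index("id").loc[r.id, "seroin_class"] for r in classified})

    if config.run_similarity and len(classified) >= 2:
        logger.info("stage similarity: %d records", len(classified))
        prot_records = [_GeneRecord(r.id, proteins[r.id], ("", ""), calls[r.id])
                        for r in classified]
        report.similarity = _simtree.class_similarity_summary(prot_records, calls)

    if config.run_tree and len(classified) >= 3:
        logger.info("stage tree: %d leaves", len(classified))
        prot_records = [_GeneRecord(r.id, proteins[r.id], ("", ""), calls[r.id])
                        for r in classified]
        dm = _simtree.distance_matrix(prot_records)
        tree = _simtree.nj_tree(dm)
        report.newick = tree.to_newick()
        report.summaries["monophyly"] = _simtree.is_class_monophyletic(tree, calls)

    if config.run_quantify and config.reads_fasta:
        logger.info("stage quantify: reads from %s", config.reads_fasta)
        reads = _seqio.read_sequences(config.reads_fasta, "dna")
        queries = {}
        for cls in ("Sn1", "Sn2", "Sn3"):
            members = [rid for rid, c in calls.items() if c == cls]
            if members:
                queries[cls] = _quantify.cterm_query(
                    proteins[sorted(members)[0]], config.query_len)
        if queries:
            counts = _quantify.count_class_reads(reads, queries, config.evalue_max)
            report.read_counts = {"counts": counts.counts, "total": counts.total,
                                  "unassigned": counts.unassigned,
                                  "threshold": counts.evalue_max}
    return report


@dataclass
class _GeneRecord:
    id: str
    protein: str
    species: tuple[str, str]
    seroin_class: str


def write_report(report: Report, output_dir: str | Path) -> Path:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.rows.to_csv(out / "records.tsv", sep="\t", index=False)
    (out / "report.json").write_text(report.to_json())
    if report.newick:
        (out / "tree.nwk").write_text(report.newick + "\n")
    if report.similarity is not None:
        report.similarity.to_csv(out / "similarity.tsv", sep="\t", index=False)
    return out / "report.json"
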