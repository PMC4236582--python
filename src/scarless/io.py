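"""Readers and writers: GenBank, FASTA + feature tables, design bundles.

All file formats carry 1-based inclusive coordinates (the GenBank
convention); conversion to the internal 0-based half-open convention
happens here and only here.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from pydantic import BaseModel, Field

from .config import DesignConfig
from .errors import ParseError
from .seq_core import ElementLibrary, Feature, GenomeRecord, NucSeq, Part, Region


# --- machine-readable report schema ----------------------------------------


class CheckModel(BaseModel):
    name: str
    status: str = Field(pattern="^(pass|warn|fail)$")
    detail: str = ""


class PrimerModel(BaseModel):
    name: str
    sequence: str = Field(pattern="^[ACGT]+$")
    length: int = Field(ge=4)
    tm_anneal: float


class ReportModel(BaseModel):
    """Validation model for the JSON design report (the shipped schema)."""

    checks: list[CheckModel]
    p_desired_integration: float | None = Field(default=None, ge=0.0, le=1.0)
    p_desired_native: float | None = Field(default=None, ge=0.0, le=1.0)
    recoding: list[dict]
    rbs_scores: dict
    primers: list[PrimerModel]
    provenance: dict


def report_json_schema() -> dict:
    """JSON Schema for design reports (generated from :class:`ReportModel`)."""
    return ReportModel.model_json_schema()

_FEATURE_COLUMNS = ["feature_id", "contig", "start_1based", "end_1based", "strand", "kind"]


def _feature_id_from_qualifiers(feat, index: int) -> str:
    for key in ("locus_tag", "gene", "label", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return f"feature_{index}"


def read_genome(path, fmt: str = "genbank", features_path=None) -> GenomeRecord:
    """Load a genome from GenBank or FASTA (+ TSV feature table).

    The TSV columns are ``feature_id  contig  start_1based  end_1based
    strand  kind`` with an optional ``product`` column and an optional
    header row.
    """
    path = Path(path)
    contigs: dict = {}
    features: list = []
    if fmt == "genbank":
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:
            raise ParseError(f"cannot parse GenBank file {path}: {exc}") from exc
        if not records:
            raise ParseError(f"no records in {path}")
        for rec in records:
            contigs[rec.id] = NucSeq(str(rec.seq))
            idx = 0
            for feat in rec.features:
                if feat.type == "source":
                    continue
                kind = feat.type if feat.type in ("CDS", "gene") else "misc"
                idx += 1
                features.append(
                    Feature(
                        feature_id=_feature_id_from_qualifiers(feat, idx),
                        region=Region(
                            rec.id,
                            int(feat.location.start),
                            int(feat.location.end),
                            "-" if feat.location.strand == -1 else "+",
                        ),
                        kind=kind,
                        product=str(feat.qualifiers.get("product", [""])[0]),
                    )
                )
    elif fmt == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            contigs[rec.id] = NucSeq(str(rec.seq))
        if not contigs:
            raise ParseError(f"no FASTA records in {path}")
        if features_path is not None:
            features = _read_feature_table(features_path, contigs)
    else:
        raise ValueError(f"unknown genome format {fmt!r}")
    try:
        return GenomeRecord(contigs=contigs, features=features)
    except ValueError as exc:
        raise ParseError(str(exc)) from exc


def _read_feature_table(path, contigs: dict) -> list:
    features = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh, delimiter="\t") if r and not r[0].startswith("#")]
    if rows and rows[0][0] == "feature_id":
        rows = rows[1:]
    for lineno, row in enumerate(rows, start=1):
        if len(row) < 6:
            raise ParseError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
        fid, contig, start, end, strand, kind = row[:6]
        product = row[6] if len(row) > 6 else ""
        try:
            region = Region(contig, int(start) - 1, int(end), strand)
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        if contig not in contigs or region.end > len(contigs[contig]):
            raise ParseError(f"{path}:{lineno}: feature {fid!r} outside contig {contig!r}")
        features.append(Feature(fid, region, kind, product))
    return features


def write_genome(genome: GenomeRecord, path, fmt: str = "genbank", features_path=None) -> None:
    path = Path(path)
    if fmt == "genbank":
        records = []
        for cid, seq in genome.contigs.items():
            rec = SeqRecord(Seq(str(seq)), id=cid, name=cid[:16], description="")
            rec.annotations["molecule_type"] = "DNA"
            rec.annotations["topology"] = "linear"
            for f in genome.features:
                if f.region.contig_id != cid:
                    continue
                loc = FeatureLocation(f.region.start, f.region.end, strand=-1 if f.region.strand == "-" else 1)
                sf = SeqFeature(loc, type=f.kind if f.kind in ("CDS", "gene") else "misc_feature")
                sf.qualifiers["label"] = [f.feature_id]
                if f.product:
                    sf.qualifiers["product"] = [f.product]
                rec.features.append(sf)
            records.append(rec)
        SeqIO.write(records, str(path), "genbank")
    elif fmt == "fasta":
        records = [SeqRecord(Seq(str(s)), id=cid, description="") for cid, s in genome.contigs.items()]
        SeqIO.write(records, str(path), "fasta")
        if features_path is not None:
            with open(features_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t", lineterminator="\n")
                w.writerow(_FEATURE_COLUMNS + ["product"])
                for f in genome.features:
                    w.writerow(
                        [f.feature_id, f.region.contig_id, f.region.start + 1, f.region.end,
                         f.region.strand, f.kind, f.product]
                    )
    else:
        raise ValueError(f"unknown genome format {fmt!r}")


# --- element libraries ------------------------------------------------------


def read_library(path, table=None) -> ElementLibrary:
    """Element library from multi-FASTA with ``role=`` / ``name=`` header tags.

    Example header: ``>part1 name=BBa_B1006 role=terminator``.
    """
    from .seq_core import default_table

    parts: dict = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        tags = dict(
            kv.split("=", 1) for kv in rec.description.split() if "=" in kv
        )
        name = tags.get("name", rec.id)
        role = tags.get("role")
        if role is None:
            raise ParseError(f"library record {rec.id!r} lacks a role= tag")
        parts[name] = Part(name=name, seq=NucSeq(str(rec.seq)), role=role, notes=tags.get("notes", ""))
    return ElementLibrary(parts=parts, table=table or default_table())


def write_library(library: ElementLibrary, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(library.parts):
            p = library.parts[name]
            fh.write(f">{name} name={name} role={p.role}\n{p.seq}\n")


# --- design bundles ---------------------------------------------------------


@dataclass
class DesignBundle:
    """Everything a design run produces, ready to be written as files."""

    cassette: object  # MutationCassette
    template_fragments: object
    report: object  # DesignReport
    config: DesignConfig
    name: str = "design"


def _cassette_record(bundle: DesignBundle) -> SeqRecord:
    cas = bundle.cassette
    rec = SeqRecord(Seq(str(cas.sequence)), id=bundle.name[:16] or "cassette", description="mutation cassette")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "linear"
    for label, start, end, strand in sorted(cas.annotations, key=lambda a: (a[1], a[2])):
        sf = SeqFeature(
            FeatureLocation(start, end, strand=-1 if strand == "-" else 1),
            type="CDS" if label.startswith("marker:") else "misc_feature",
        )
        sf.qualifiers["label"] = [label]
        rec.features.append(sf)
    return rec


def write_design(bundle: DesignBundle, outdir) -> dict:
    """Emit GenBank + FASTA + primer TSV + JSON report; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    gb = outdir / f"{bundle.name}.gb"
    SeqIO.write([_cassette_record(bundle)], str(gb), "genbank")
    files["genbank"] = gb

    fa = outdir / f"{bundle.name}_template_fragments.fasta"
    tf = bundle.template_fragments
    with open(fa, "w") as fh:
        fh.write(f">fragment5_with_overlaps backbone={tf.backbone_label}\n{tf.fragment5_with_overlaps}\n")
        fh.write(f">fragment3_with_overlaps backbone={tf.backbone_label}\n{tf.fragment3_with_overlaps}\n")
    files["fasta"] = fa

    tsv = outdir / f"{bundle.name}_primers.tsv"
    with open(tsv, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["name", "sequence", "length", "tm_anneal_C", "purpose"])
        for p in bundle.report.primers:
            purpose = "cassette amplification" if p.name in ("MF", "MR") else "selection-cassette amplification"
            w.writerow([p.name, str(p.sequence), len(p.sequence), f"{p.tm_anneal:.1f}", purpose])
    files["primers"] = tsv

    js = outdir / f"{bundle.name}_report.json"
    with open(js, "w") as fh:
        json.dump(bundle.report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["report"] = js

    cfgf = outdir / f"{bundle.name}_config.toml"
    cfgf.write_text(bundle.config.to_toml())
    files["config"] = cfgf
    return files
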