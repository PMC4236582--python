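"""Turn an edit specification into a validated mutation cassette.

A mutation cassette is the linear editing fragment

    HR1 - 5' fragment (ends with HR3 copy 1) - [restoring fragment] -
    selection core - [restoring fragment] - 3' fragment (starts with
    HR3 copy 2) - HR2

where the selection core is (terminators +) I-SceI site + marker.  The
two identical HR3 windows span the desired modification; excision of
everything between them after I-SceI cleavage leaves the edited locus
with no scar.  Essential-gene designs add a synonymously recoded
fragment that reconstitutes a complete open reading frame in the
*intermediate* genome -- before the core on the gene's 5' side when the
gene keeps its own promoter, after the core (read from the marker's
promoter) otherwise, or a wild-type-restoring copy when gene function
must stay wild type until the final step.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .config import DesignConfig
from .errors import DesignError, LibraryError
from .homology import (
    IdentityMask,
    cleave_and_resolve,
    integrate_in_silico,
    p_desired_integration,
)
from .recode import (
    RbsModel,
    RecodeOptions,
    hairpin_screen,
    max_shared_window,
    recode_synonymous,
    silent_rbs_boost,
)
from .seq_core import (
    CodonTable,
    ElementLibrary,
    Feature,
    GenomeRecord,
    NucSeq,
    Region,
    default_table,
    revcomp,
    scan_motif,
    translate,
)

# ---------------------------------------------------------------------------
# edit specification


class CodonChange(BaseModel):
    """A single-codon replacement, 1-based residue index on the gene."""

    residue_index: int = Field(ge=1)
    new_codon: str = Field(min_length=3, max_length=3)


class EditSpec(BaseModel):
    """Declarative description of a genomic change.

    Coordinates (``start``/``end``) are 1-based inclusive, matching
    GenBank and every other user-facing surface of the package; the
    library converts internally.  ``payload`` is given on the plus
    strand for coordinate edits and as gene-frame codons for
    essential-gene edits.
    """

    kind: Literal["point_mutation", "insertion", "deletion", "essential_gene"]
    contig: Optional[str] = None
    start: Optional[int] = Field(default=None, ge=1)
    end: Optional[int] = Field(default=None, ge=1)
    payload: Optional[str] = None
    feature_id: Optional[str] = None
    variant: Optional[Literal["own_promoter", "marker_promoter", "wt_restoring"]] = None
    mutations: Optional[list[CodonChange]] = None
    rbs_boost: bool = False

    @model_validator(mode="after")
    def _check_kind(self) -> "EditSpec":
        if self.kind == "point_mutation":
            if self.start is None or self.end is None or not self.payload:
                raise ValueError("point_mutation needs start, end and payload")
            if len(self.payload) != self.end - self.start + 1:
                raise ValueError("point_mutation payload must match the replaced span length")
        elif self.kind == "insertion":
            if self.start is None or not self.payload:
                raise ValueError("insertion needs start (insertion point) and payload")
        elif self.kind == "deletion":
            if self.start is None or self.end is None:
                raise ValueError("deletion needs start and end")
        elif self.kind == "essential_gene":
            if not self.feature_id or self.variant is None or not self.mutations:
                raise ValueError("essential_gene needs feature_id, variant and mutations")
        if self.payload is not None:
            NucSeq(self.payload)  # alphabet check
        return self


@dataclass(frozen=True)
class ResolvedEdit:
    """Plus-strand, 0-based form of an edit: replace [cut_start, cut_end) by replacement."""

    contig: str
    cut_start: int
    cut_end: int
    replacement: NucSeq
    gene: Region | None = None  # target CDS span for essential designs


def resolve_edit(edit: EditSpec, genome: GenomeRecord, table: CodonTable | None = None) -> ResolvedEdit:
    tab = table or default_table()
    if edit.kind == "essential_gene":
        feat = genome.feature_by_id(edit.feature_id)
        if feat.kind != "CDS":
            raise DesignError(f"essential_gene target {edit.feature_id!r} is not a CDS feature")
        g = feat.region
        cds = genome.extract(g)
        muts = sorted(edit.mutations, key=lambda m: m.residue_index)
        lo, hi = muts[0].residue_index, muts[-1].residue_index
        if 3 * hi > len(cds):
            raise DesignError(f"residue {hi} beyond CDS of {len(cds) // 3} codons")
        edited_cds = list(str(cds))
        for m in muts:
            old = cds[3 * (m.residue_index - 1) : 3 * m.residue_index]
            new = NucSeq(m.new_codon)
            if tab.aa(old) != tab.aa(new):
                warnings.warn(
                    f"codon change {old}->{new} at residue {m.residue_index} is not synonymous"
                )
            edited_cds[3 * (m.residue_index - 1) : 3 * m.residue_index] = str(new)
        # gene-frame window covering all changed codons -> plus-strand coords
        gf_start, gf_end = 3 * (lo - 1), 3 * hi
        repl_gene = NucSeq("".join(edited_cds[gf_start:gf_end]))
        if g.strand == "+":
            cut_start, cut_end = g.start + gf_start, g.start + gf_end
            repl = repl_gene
        else:
            cut_start, cut_end = g.end - gf_end, g.end - gf_start
            repl = revcomp(repl_gene)
        return ResolvedEdit(g.contig_id, cut_start, cut_end, repl, gene=g)

    contig = edit.contig or genome.single_contig_id()
    if edit.kind == "point_mutation":
        return ResolvedEdit(contig, edit.start - 1, edit.end, NucSeq(edit.payload))
    if edit.kind == "insertion":
        p = edit.start - 1
        return ResolvedEdit(contig, p, p, NucSeq(edit.payload))
    # deletion
    return ResolvedEdit(contig, edit.start - 1, edit.end, NucSeq(""))


def apply_edit(genome: GenomeRecord, edit: EditSpec, table: CodonTable | None = None) -> GenomeRecord:
    """The intended final genome: the edit applied directly, no cassette."""
    res = resolve_edit(edit, genome, table)
    seq = genome.contigs[res.contig]
    new_seq = NucSeq(seq[: res.cut_start] + res.replacement + seq[res.cut_end :])
    delta = len(res.replacement) - (res.cut_end - res.cut_start)
    features = []
    for f in genome.features:
        r = f.region
        if r.contig_id != res.contig or r.end <= res.cut_start or delta == 0:
            features.append(f)
        elif r.start >= res.cut_end:
            features.append(
                Feature(f.feature_id, Region(res.contig, r.start + delta, r.end + delta, r.strand), f.kind, f.product)
            )
        # length-changing edits drop overlapped features
    contigs = dict(genome.contigs)
    contigs[res.contig] = new_seq
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GenomeRecord(contigs=contigs, features=features)


# ---------------------------------------------------------------------------
# selection cassette


@dataclass
class SelectionCassette:
    """Terminator block + I-SceI site + marker: the excisable, selectable core."""

    sequence: NucSeq
    n_terminators: int
    marker_name: str
    layout: list  # (label, start, end) tiling the sequence
    isceI_span: tuple
    marker_orf: tuple  # ORF coordinates within `sequence`
    rbs_mutations: list = field(default_factory=list)

    def span(self, label: str) -> tuple:
        for lab, s, e in self.layout:
            if lab == label:
                return (s, e)
        raise KeyError(label)


def build_selection_cassette(
    marker_name: str,
    n_terminators: int,
    library: ElementLibrary,
    rbs_boost_tail: int | None = None,
    config: DesignConfig | None = None,
) -> SelectionCassette:
    """Compose [terminator block] + I-SceI site + marker from library parts.

    ``n_terminators`` of 0/1/2 reproduce the published pAS / pTS / pT2S
    cassette layouts; 2 is the recommended default because read-through
    transcription otherwise blocks I-SceI cleavage.  With
    ``rbs_boost_tail`` set, the marker's last codons receive silent
    mutations that sculpt a consensus-like ribosome binding site for a
    gene fragment placed immediately downstream (the pT2SCb behaviour).
    """
    cfg = config or DesignConfig()
    if n_terminators not in (0, 1, 2):
        raise ValueError("n_terminators must be 0, 1 or 2")
    marker = library[marker_name]
    if marker.role != "marker":
        raise LibraryError(f"part {marker_name!r} has role {marker.role!r}, not 'marker'")

    pieces: list = []  # (label, seq)
    if n_terminators >= 1:
        spacers = library.by_role("spacer")
        if len(spacers) < 2:
            raise LibraryError("terminator block needs at least two spacer parts")
        terms = {p.name: p for p in library.by_role("terminator")}
        order = ["BBa_B1006"] if n_terminators == 1 else ["BBa_B1002", "BBa_B1006"]
        chosen = [terms[n] for n in order if n in terms]
        if len(chosen) < n_terminators:  # fall back to whatever the library offers
            chosen = library.by_role("terminator")[:n_terminators]
        if len(chosen) < n_terminators:
            raise LibraryError(f"library offers fewer than {n_terminators} terminator parts")
        s1, s2 = spacers[0], spacers[1]
        pieces.append((f"spacer:{s1.name}", s1.seq))
        pieces.append((f"terminator:{chosen[0].name}", chosen[0].seq))
        pieces.append((f"spacer:{s2.name}", s2.seq))
        if n_terminators == 2:
            pieces.append((f"terminator:{chosen[1].name}", chosen[1].seq))
            # reuse part of the first spacer, as in the published STTS fragment
            pieces.append((f"spacer:{s1.name}_3p", NucSeq(s1.seq[len(s1.seq) // 2 :])))
    site = library.isceI_site
    pieces.append(("I-SceI_site", site.seq))

    marker_seq = marker.seq
    orf = library.marker_orf(marker)
    rbs_mutations: list = []
    if rbs_boost_tail:
        orf_start, orf_end = orf
        tail_len = 3 * int(rbs_boost_tail)
        tail_len = min(tail_len, orf_end - orf_start)
        tail = marker_seq[orf_end - tail_len : orf_end]
        model = RbsModel(
            consensus=NucSeq(cfg.rbs_consensus),
            spacer_min=cfg.rbs_spacer_min,
            spacer_max=cfg.rbs_spacer_max,
        )
        boosted, muts, _before, _after = silent_rbs_boost(tail, library.table, model)
        marker_seq = NucSeq(marker_seq[: orf_end - tail_len] + boosted + marker_seq[orf_end:])
        rbs_mutations = [(orf_end - tail_len + p, a, b) for p, a, b in muts]
    pieces.append((f"marker:{marker.name}", marker_seq))

    seq, layout, pos = "", [], 0
    for label, s in pieces:
        layout.append((label, pos, pos + len(s)))
        seq += str(s)
        pos += len(s)
    core = SelectionCassette(
        sequence=NucSeq(seq),
        n_terminators=n_terminators,
        marker_name=marker.name,
        layout=layout,
        isceI_span=next((s, e) for lab, s, e in layout if lab == "I-SceI_site"),
        marker_orf=None,
        rbs_mutations=rbs_mutations,
    )
    m_start = core.span(f"marker:{marker.name}")[0]
    core.marker_orf = (m_start + orf[0], m_start + orf[1])
    # invariant: terminator block strictly upstream of the recognition site
    assert all(e <= core.isceI_span[0] for lab, s, e in layout if lab.startswith(("terminator", "spacer")))
    orf_seq = core.sequence[core.marker_orf[0] : core.marker_orf[1]]
    prot = translate(orf_seq, library.table)
    if "*" in prot[:-1] or prot[-1] != "*":
        raise LibraryError(f"marker ORF of {marker.name!r} does not translate start->stop")
    return core


# ---------------------------------------------------------------------------
# mutation cassette


@dataclass
class RestoringFragment:
    """A synonymously recoded ORF-restoring segment and its native original."""

    side: str  # '5' (before the core) or '3' (after the core)
    recoded: NucSeq
    native: NucSeq
    report: object = None


@dataclass
class Hr3Choice:
    seq: NucSeq
    placement: str  # inside_hr3 | after_hr3
    start: int  # edited-genome coordinates, 0-based half-open
    end: int
    mut_offsets: tuple  # edited base offsets relative to `start`


@dataclass
class MutationCassette:
    """The full linear editing fragment plus everything needed to audit it."""

    hr1: NucSeq
    fragment5: NucSeq  # ends with HR3 copy 1
    core: SelectionCassette
    fragment3: NucSeq  # starts with HR3 copy 2
    hr2: NucSeq
    hr3: NucSeq
    placement: str
    restoring5: NucSeq = NucSeq("")
    restoring3: NucSeq = NucSeq("")
    restoring: list = field(default_factory=list)  # RestoringFragment records
    hr3_mut_offsets: tuple = ()
    after_mut_offsets: tuple = ()  # edited offsets within fragment3, after_hr3 designs
    variant: str | None = None
    target_strand: str = "+"
    intermediate_orf: NucSeq | None = None
    intermediate_protein: str | None = None  # 'wild_type' | 'edited'
    annotations: list = field(default_factory=list)  # (label, start, end, strand)

    @property
    def sequence(self) -> NucSeq:
        return NucSeq(
            self.hr1
            + self.fragment5
            + self.restoring5
            + self.core.sequence
            + self.restoring3
            + self.fragment3
            + self.hr2
        )

    def __post_init__(self) -> None:
        if not self.fragment5.endswith(self.hr3) or not self.fragment3.startswith(self.hr3):
            raise DesignError("HR3 copies must terminate fragment5 and open fragment3")
        if not self.annotations:
            self.annotations = self._tile()
        spans = sorted((s, e) for _, s, e, _ in self.annotations)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise DesignError("annotation spans overlap")

    def _tile(self) -> list:
        tiles = []
        pos = 0

        def add(label, length, strand="+"):
            nonlocal pos
            if length:
                tiles.append((label, pos, pos + length, strand))
                pos += length

        L = len(self.hr3)
        add("HR1", len(self.hr1))
        add("target_5prime", len(self.fragment5) - L)
        add("HR3_copy1", L)
        add("recoded_fragment_5", len(self.restoring5))
        for label, s, e in self.core.layout:
            tiles.append((label, pos + s, pos + e, "+"))
        pos += len(self.core.sequence)
        add("recoded_fragment_3", len(self.restoring3))
        add("HR3_copy2", L)
        add("target_3prime", len(self.fragment3) - L)
        add("HR2", len(self.hr2))
        return tiles


def choose_hr3(genome: GenomeRecord, edit: EditSpec, config: DesignConfig | None = None,
               table: CodonTable | None = None) -> Hr3Choice:
    """Pick the duplicated homology window that spans the modification.

    Point mutations sit centred inside HR3 (ties toward the 5' side);
    deletions get the junction fusion of the two flanks; insertions are
    carried inside HR3 when insert-plus-context fits within the maximum
    HR3 length and placed immediately after HR3 otherwise; the
    wild-type-restoring essential variant keeps HR3 wild type with the
    mutation immediately following it.  Essential-gene windows are
    snapped to codon boundaries so restoring fragments stay in frame.
    """
    cfg = config or DesignConfig()
    tab = table or default_table()
    if edit.kind == "essential_gene":
        feat = genome.feature_by_id(edit.feature_id)
        if feat.region.strand == "-":
            # work in gene orientation; returned coordinates refer to the
            # reverse-complemented contig (design() does the same flip)
            return choose_hr3(_flip_genome(genome, feat.region.contig_id), edit, cfg, tab)
    res = resolve_edit(edit, genome, tab)
    g_seq = genome.contigs[res.contig]
    edited = NucSeq(g_seq[: res.cut_start] + res.replacement + g_seq[res.cut_end :])

    e5 = res.cut_start
    e3 = res.cut_start + len(res.replacement)
    if edit.kind == "deletion":
        diff = [e5]  # junction sentinel: first base 3' of the fused joint
    elif edit.kind == "insertion":
        diff = list(range(e5, e3))
    else:
        diff = [i for i in range(e5, e3) if edited[i] != g_seq[res.cut_end - (e3 - i)]] or [e5]

    L = cfg.hr3_len
    placement = "inside_hr3"
    wt_restoring = edit.kind == "essential_gene" and edit.variant == "wt_restoring"

    if edit.kind == "insertion":
        min_context = 6
        if len(res.replacement) + 2 * min_context > cfg.hr3_max:
            placement = "after_hr3"
        else:
            L = min(max(cfg.hr3_len, len(res.replacement) + 2 * min_context), cfg.hr3_max)
    if wt_restoring:
        placement = "after_hr3"

    if placement == "after_hr3":
        h3 = e5  # window of wild-type sequence ending at the edit
        if wt_restoring:
            # snap to a codon boundary at or before the first edit
            h3 = res.gene.start + 3 * ((e5 - res.gene.start) // 3)
            L = 3 * (L // 3)
        h5 = h3 - L
        if h5 < 0:
            raise DesignError("not enough 5' context for an HR3 window")
        mut_off = tuple(d - h5 for d in diff)
        return Hr3Choice(NucSeq(edited[h5:h3]), "after_hr3", h5, h3, mut_off)

    width = diff[-1] - diff[0] + 1
    if edit.kind == "essential_gene":
        L = 3 * (L // 3)
    if width > cfg.hr3_max:
        raise DesignError(
            f"edited span of {width} bp exceeds the maximum HR3 length {cfg.hr3_max}; "
            "consider an after_hr3 design"
        )
    L = max(L, width)
    if edit.kind == "deletion":
        h5 = diff[0] - L // 2
    else:
        h5 = diff[0] - (L - width) // 2
    if edit.kind == "essential_gene":
        gene = res.gene  # plus strand after the flip above
        h5 = gene.start + 3 * max(0, (h5 - gene.start) // 3)
        h3 = h5 + L
        over = h3 - gene.end
        if over > 0:
            shift = 3 * ((over + 2) // 3)
            h5, h3 = h5 - shift, h3 - shift
        if h5 < gene.start or h3 > gene.end or h3 < diff[-1] + 1 or h5 > diff[0]:
            raise DesignError("cannot fit a codon-aligned HR3 inside the gene around the edit")
    else:
        h3 = h5 + L
    if h5 < 0 or h3 > len(edited):
        raise DesignError("HR3 window extends beyond the contig")
    mut_off = tuple(d - h5 for d in diff)
    return Hr3Choice(NucSeq(edited[h5:h3]), "inside_hr3", h5, h3, mut_off)


# ---------------------------------------------------------------------------
# design


@dataclass
class TemplateFragments:
    """Gibson-ready 5'/3' mutation fragments for the template plasmid."""

    fragment5_with_overlaps: NucSeq
    fragment3_with_overlaps: NucSeq
    overlap_len: int
    backbone_label: str


@dataclass
class CheckResult:
    name: str
    status: str  # pass | warn | fail
    detail: str = ""


@dataclass
class DesignReport:
    checks: list = field(default_factory=list)
    p_desired_integration: float | None = None
    p_desired_native: float | None = None
    recoding: list = field(default_factory=list)
    rbs_scores: dict = field(default_factory=dict)
    primers: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def check(self, name: str) -> CheckResult:
        for c in self.checks:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def ok(self) -> bool:
        return all(c.status != "fail" for c in self.checks)

    def to_json_dict(self) -> dict:
        return {
            "checks": [{"name": c.name, "status": c.status, "detail": c.detail} for c in self.checks],
            "p_desired_integration": self.p_desired_integration,
            "p_desired_native": self.p_desired_native,
            "recoding": self.recoding,
            "rbs_scores": self.rbs_scores,
            "primers": [
                {
                    "name": p.name,
                    "sequence": str(p.sequence),
                    "length": len(p.sequence),
                    "tm_anneal": round(p.tm_anneal, 2),
                }
                for p in self.primers
            ],
            "provenance": self.provenance,
        }


def _flip_genome(genome: GenomeRecord, contig_id: str) -> GenomeRecord:
    seq = genome.contigs[contig_id]
    n = len(seq)
    contigs = dict(genome.contigs)
    contigs[contig_id] = revcomp(seq)
    feats = []
    for f in genome.features:
        r = f.region
        if r.contig_id != contig_id:
            feats.append(f)
        else:
            strand = "+" if r.strand == "-" else "-"
            feats.append(Feature(f.feature_id, Region(contig_id, n - r.end, n - r.start, strand), f.kind, f.product))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return GenomeRecord(contigs=contigs, features=feats)


def design(
    edit: EditSpec,
    genome: GenomeRecord,
    library: ElementLibrary,
    config: DesignConfig | None = None,
) -> tuple:
    """Design a mutation cassette; returns (cassette, template_fragments, report).

    Deterministic: identical inputs give byte-identical output.  For an
    essential gene annotated on the minus strand the cassette is emitted
    in gene orientation (its reverse complement relative to the plus
    strand); integration handles either orientation.
    """
    cfg = config or DesignConfig()
    tab = library.table

    if edit.kind == "essential_gene":
        feat = genome.feature_by_id(edit.feature_id)
        if feat.region.strand == "-":
            flipped = _flip_genome(genome, feat.region.contig_id)
            cassette, frags, _ = design(edit, flipped, library, cfg)
            cassette.target_strand = "-"
            report = validate_design(cassette, genome, library, cfg, edit=edit)
            return cassette, frags, report

    res = resolve_edit(edit, genome, tab)
    edited_genome = apply_edit(genome, edit, tab)
    edited = edited_genome.contigs[res.contig]
    choice = choose_hr3(genome, edit, cfg, tab)
    h5, h3, L = choice.start, choice.end, len(choice.seq)

    flen5 = max(cfg.fragment_len, L + 10)
    flen3 = max(cfg.fragment_len, L + 10)
    if choice.placement == "after_hr3":
        last_edit = h5 + max(choice.mut_offsets)
        flen3 = max(flen3, (last_edit - h5) + 20)
    f5_start = h3 - flen5
    f3_end = h5 + flen3
    if f5_start - cfg.hr_len < 0:
        raise DesignError("insufficient 5' genomic context for fragment5 + HR1")
    if f3_end + cfg.hr_len > len(edited):
        raise DesignError("insufficient 3' genomic context for fragment3 + HR2")

    hr1 = NucSeq(edited[f5_start - cfg.hr_len : f5_start])
    fragment5 = NucSeq(edited[f5_start:h3])
    fragment3 = NucSeq(edited[h5:f3_end])
    hr2 = NucSeq(edited[f3_end : f3_end + cfg.hr_len])
    if cfg.hr_len < 100:
        warnings.warn(f"{cfg.hr_len} bp homology regions: generally sufficient, but 100 bp is more reliable")

    site = library.isceI_site.seq
    restoring: list = []
    restoring5 = restoring3 = NucSeq("")
    intermediate_orf = None
    protein_kind = None
    if edit.kind == "essential_gene":
        gene = res.gene
        opts = RecodeOptions(w_max=cfg.w_max, forbidden_motifs=(site,))
        if edit.variant in ("own_promoter", "wt_restoring"):
            source = genome.contigs[res.contig] if edit.variant == "wt_restoring" else edited
            native = NucSeq(source[h3 : gene.end])
            if native:
                restoring5, rep = recode_synonymous(native, tab, opts)
                restoring.append(RestoringFragment("5", restoring5, native, rep))
            intermediate_orf = NucSeq(source[gene.start : h3] + restoring5)
            protein_kind = "wild_type" if edit.variant == "wt_restoring" else "edited"
        else:  # marker_promoter
            native = NucSeq(edited[gene.start : h5])
            if native:
                restoring3, rep = recode_synonymous(native, tab, opts)
                restoring.append(RestoringFragment("3", restoring3, native, rep))
            intermediate_orf = NucSeq(restoring3 + edited[h5 : gene.end])
            protein_kind = "edited"

    rbs_tail = cfg.rbs_boost_codons if (edit.rbs_boost and edit.kind == "essential_gene") else None
    core = build_selection_cassette(cfg.marker, cfg.n_terminators, library, rbs_boost_tail=rbs_tail, config=cfg)

    cassette = MutationCassette(
        hr1=hr1,
        fragment5=fragment5,
        core=core,
        fragment3=fragment3,
        hr2=hr2,
        hr3=choice.seq,
        placement=choice.placement,
        restoring5=restoring5,
        restoring3=restoring3,
        restoring=restoring,
        hr3_mut_offsets=choice.mut_offsets if choice.placement == "inside_hr3" else (),
        after_mut_offsets=tuple(o for o in choice.mut_offsets) if choice.placement == "after_hr3" else (),
        variant=edit.variant,
        intermediate_orf=intermediate_orf,
        intermediate_protein=protein_kind,
    )

    backbone = (library.by_role("backbone") or [None])[0]
    ov = cfg.overlap_len
    vec = backbone.seq if backbone else NucSeq("")
    frags = TemplateFragments(
        fragment5_with_overlaps=NucSeq(
            (vec[-ov:] if backbone else "") + hr1 + fragment5 + restoring5 + core.sequence[:ov]
        ),
        fragment3_with_overlaps=NucSeq(
            core.sequence[-ov:] + restoring3 + fragment3 + hr2 + (vec[:ov] if backbone else "")
        ),
        overlap_len=ov,
        backbone_label=backbone.name if backbone else "(none)",
    )

    report = validate_design(cassette, genome, library, cfg, edit=edit)
    return cassette, frags, report


# ---------------------------------------------------------------------------
# integration-outcome mask


def integration_identity_mask(cassette: MutationCassette, recoded: bool = True) -> tuple:
    """(IdentityMask, mutation positions) for the crossover-position model.

    The mask covers the homology arm whose crossover decides whether the
    mutations are transferred, oriented so that desired crossovers lie
    3' of the last mutation: the 3' arm as-is when the restoring
    fragment follows the core (marker-promoter designs and every
    non-essential design), the 5' arm reversed when it precedes the core
    (own-promoter and wild-type-restoring designs).  ``recoded=False``
    rebuilds the arm as if the restoring fragment had been left native
    (the failure-prone geometry the synonymous-codon strategy replaces).
    """
    L = len(cassette.hr3)

    def seg_identity(rf: RestoringFragment) -> np.ndarray:
        if not recoded:
            return np.ones(len(rf.native), dtype=bool)
        a, b = str(rf.recoded), str(rf.native)
        return np.array([x == y for x, y in zip(a, b)], dtype=bool)

    hr3_ident = np.ones(L, dtype=bool)
    for o in cassette.hr3_mut_offsets:
        hr3_ident[o] = False

    if cassette.restoring5 or (cassette.variant in ("own_promoter", "wt_restoring")):
        # 5' arm, reversed: [restoring5][HR3 copy1][target_5prime][HR1] read 3'->5'
        rf = next((r for r in cassette.restoring if r.side == "5"), None)
        parts = []
        muts = []
        pos = 0
        if rf is not None:
            ident = seg_identity(rf)[::-1]
            if cassette.placement == "after_hr3":
                # wild-type-restoring: any crossover inside a native restoring
                # fragment strands the mutation; sentinel at the arm boundary
                ident = ident.copy()
                ident[-1] = False
                muts.append(pos + len(ident) - 1)
            parts.append(ident)
            pos += len(ident)
        h = hr3_ident[::-1]
        muts.extend(pos + i for i in np.flatnonzero(~h))
        parts.append(h)
        pos += L
        body = np.ones(len(cassette.fragment5) - L, dtype=bool)
        parts.append(body)
        pos += len(body)
        parts.append(np.ones(len(cassette.hr1), dtype=bool))
        mask = IdentityMask("arm5_reversed", np.concatenate(parts))
        if not muts:
            muts = [int(np.flatnonzero(~mask.identity)[0])] if (~mask.identity).any() else []
        return mask, sorted(int(m) for m in muts)

    # 3' arm as-is: [restoring3][HR3 copy2][target_3prime][HR2]
    rf = next((r for r in cassette.restoring if r.side == "3"), None)
    parts = []
    muts = []
    pos = 0
    if rf is not None:
        parts.append(seg_identity(rf))
        pos += len(rf.native)
    muts.extend(pos + i for i in np.flatnonzero(~hr3_ident))
    parts.append(hr3_ident)
    pos += L
    tail = np.ones(len(cassette.fragment3) - L, dtype=bool)
    for o in cassette.after_mut_offsets:
        if 0 <= o - L < len(tail):
            tail[o - L] = False
            muts.append(pos + (o - L))
    # an insertion's bases are novel sequence: identity false across them
    parts.append(tail)
    pos += len(tail)
    parts.append(np.ones(len(cassette.hr2), dtype=bool))
    mask = IdentityMask("arm3", np.concatenate(parts))
    return mask, sorted(int(m) for m in muts)


# ---------------------------------------------------------------------------
# validation


def _digest(data: str) -> str:
    return hashlib.sha256(data.encode()).hexdigest()[:16]


def validate_design(
    cassette: MutationCassette,
    genome: GenomeRecord,
    library: ElementLibrary,
    config: DesignConfig | None = None,
    edit: EditSpec | None = None,
) -> DesignReport:
    """Run every design check and collect the results; never raises.

    Soft failures (integration probability below threshold, hairpins in
    spacers) are warnings by default; structural failures (non-identical
    HR3 copies, ambiguous targeting, scar left behind) are failures.
    """
    cfg = config or DesignConfig()
    tab = library.table
    report = DesignReport()
    soft = "warn" if cfg.severity == "warn" else "fail"

    def add(name, ok, detail="", failure="fail"):
        report.checks.append(CheckResult(name, "pass" if ok else failure, detail))

    seq = cassette.sequence
    site = library.isceI_site.seq

    for label, hr in (("HR1", cassette.hr1), ("HR2", cassette.hr2)):
        hits = sum(
            len(scan_motif(c, hr, both_strands=True)) for c in genome.contigs.values()
        )
        add(f"{label}_unique_in_genome", hits == 1, f"{hits} hit(s)")

    cassette_sites = scan_motif(seq, site, both_strands=True)
    add("single_isceI_site_in_cassette", len(cassette_sites) == 1, f"{len(cassette_sites)} site(s)")
    genome_sites = sum(len(scan_motif(c, site, both_strands=True)) for c in genome.contigs.values())
    add("isceI_site_absent_from_genome", genome_sites == 0, f"{genome_sites} site(s)", failure="warn")

    add(
        "hr3_copies_identical",
        cassette.fragment5.endswith(cassette.hr3) and cassette.fragment3.startswith(cassette.hr3),
        "",
    )
    add(
        "hr3_length_in_bounds",
        cfg.hr3_min <= len(cassette.hr3) <= cfg.hr3_max,
        f"{len(cassette.hr3)} bp",
    )
    add(
        "hr_lengths_equal",
        len(cassette.hr1) == len(cassette.hr2) == cfg.hr_len,
        f"{len(cassette.hr1)}/{len(cassette.hr2)} bp",
    )

    orf_s, orf_e = cassette.core.marker_orf
    prot = translate(cassette.core.sequence[orf_s:orf_e], tab)
    add("marker_orf_intact", "*" not in prot[:-1] and prot.endswith("*"), "")

    ok_w = True
    detail = []
    for rf in cassette.restoring:
        w = max_shared_window(rf.recoded, rf.native)
        detail.append(f"side{rf.side}: {w} bp")
        ok_w &= w <= cfg.w_max
        report.recoding.append(
            {
                "side": rf.side,
                "length": len(rf.recoded),
                "max_shared_window": w,
                "codons_changed": rf.report.n_changed if rf.report else None,
                "codons_unchangeable": rf.report.n_unchangeable if rf.report else None,
            }
        )
    add("recoded_shared_window", ok_w, "; ".join(detail) or "no restoring fragment")

    spacer_hits = []
    for label, s, e in cassette.core.layout:
        if label.startswith("spacer"):
            spacer_hits += hairpin_screen(
                cassette.core.sequence[s:e], cfg.hairpin_min_stem, cfg.hairpin_loop_min, cfg.hairpin_loop_max
            )
    add("spacer_hairpin_screen", not spacer_hits, f"{len(spacer_hits)} hairpin(s)", failure="warn")

    try:
        mask, muts = integration_identity_mask(cassette)
        p = p_desired_integration(mask, muts, cfg.pairing_window) if muts else 1.0
        report.p_desired_integration = p
        if cassette.restoring:
            mask_n, muts_n = integration_identity_mask(cassette, recoded=False)
            report.p_desired_native = (
                p_desired_integration(mask_n, muts_n, cfg.pairing_window) if muts_n else 1.0
            )
        add("integration_probability", p >= cfg.p_threshold, f"p={p:.3f}", failure=soft)
    except Exception as exc:  # infeasible masks are reported, not raised
        add("integration_probability", False, str(exc), failure=soft)

    if edit is not None:
        try:
            intended = apply_edit(genome, edit, tab)
            resolved = cleave_and_resolve(integrate_in_silico(genome, cassette), library)
            same = all(
                resolved.contigs.get(c) == intended.contigs.get(c) for c in intended.contigs
            ) and set(resolved.contigs) == set(intended.contigs)
            add("scarless_round_trip", same, "")
        except Exception as exc:
            add("scarless_round_trip", False, str(exc))
    if cassette.intermediate_orf is not None:
        try:
            inter = integrate_in_silico(genome, cassette)
            found = any(
                scan_motif(c, cassette.intermediate_orf, both_strands=True)
                for c in inter.contigs.values()
            )
            prot_i = translate(cassette.intermediate_orf, tab)
            if cassette.intermediate_protein == "wild_type" and edit is not None:
                res = resolve_edit(edit, genome, tab)
                expect = translate(genome.extract(res.gene), tab)
            elif edit is not None:
                res = resolve_edit(edit, genome, tab)
                expect = translate(apply_edit(genome, edit, tab).extract(res.gene), tab)
            else:
                expect = prot_i
            add(
                "intermediate_orf_reconstituted",
                found and prot_i == expect,
                f"protein={cassette.intermediate_protein}",
            )
        except Exception as exc:
            add("intermediate_orf_reconstituted", False, str(exc))

    from .primers import design_amplification_primers

    try:
        mf, mr = design_amplification_primers(
            seq, Region("cassette", 0, len(seq)), cfg, "MF", "MR", template_label="mutation_cassette"
        )
        core_start = len(cassette.hr1) + len(cassette.fragment5) + len(cassette.restoring5)
        markerf, markerr = design_amplification_primers(
            seq,
            Region("cassette", core_start, core_start + len(cassette.core.sequence)),
            cfg,
            "MarkerF",
            "MarkerR",
            template_label="mutation_cassette",
        )
        report.primers = [mf, mr, markerf, markerr]
        add("primers_designed", True, "")
    except Exception as exc:
        add("primers_designed", False, str(exc), failure=soft)

    if cassette.core.rbs_mutations:
        orf_s, orf_e = cassette.core.marker_orf
        tail_len = 3 * cfg.rbs_boost_codons
        model = RbsModel(NucSeq(cfg.rbs_consensus), cfg.rbs_spacer_min, cfg.rbs_spacer_max)
        from .recode import rbs_score

        report.rbs_scores = {
            "marker_tail_after": rbs_score(cassette.core.sequence[orf_e - tail_len : orf_e], model)[0],
            "n_silent_mutations": len(cassette.core.rbs_mutations),
        }

    report.provenance = {
        "config_digest": cfg.digest(),
        "config": cfg.to_dict(),
        "library_digest": _digest(json.dumps({n: str(p.seq) for n, p in sorted(library.parts.items())})),
        "cassette_digest": _digest(str(seq)),
        "cassette_length": len(seq),
        "variant": cassette.variant,
        "placement": cassette.placement,
    }
    return report
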