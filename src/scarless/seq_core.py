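"""Nucleotide sequence primitives, coordinates, codon arithmetic and parts.

This module holds the low-level vocabulary the rest of the package is
built on: validated DNA strings (:class:`NucSeq`), 0-based half-open
genomic intervals (:class:`Region`), genomes with annotated features
(:class:`GenomeRecord`), the codon table that defines synonymy
(:class:`CodonTable`), and the library of reusable cassette parts
(:class:`ElementLibrary`).

Coordinate convention: everything in memory is 0-based half-open.
User-facing surfaces (GenBank output, TSV feature tables, the CLI and
JSON edit specifications) use 1-based inclusive coordinates, matching
GenBank; conversion happens at the I/O boundary only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable as _BioCodonTable

from .errors import AlphabetError, CodingFrameError, LibraryError

_ALPHABET = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Canonical 18 bp I-SceI recognition sequence.  The default element
#: library ships this as an external-knowledge default; every operation
#: that needs a recognition site reads it from the library, so a user
#: library can override it freely.
CANONICAL_ISCEI_SITE = "TAGGGATAACAGGGTAAT"


class NucSeq(str):
    """An uppercase DNA string over {A, C, G, T}.

    Lowercase input and RNA-style ``U`` are normalised on construction;
    ambiguity codes are rejected outright because a design tool must not
    emit ambiguous synthesis orders.
    """

    def __new__(cls, value: str = "") -> "NucSeq":
        s = str(value).upper().replace("U", "T")
        if not _ALPHABET.issuperset(s):
            bad = sorted(set(s) - _ALPHABET)
            raise AlphabetError(f"non-ACGT characters in sequence: {bad}")
        return super().__new__(cls, s)


def revcomp(seq: str) -> NucSeq:
    """Reverse complement.  An involution: ``revcomp(revcomp(x)) == x``."""
    return NucSeq(str(NucSeq(seq)).translate(_COMPLEMENT)[::-1])


@dataclass(frozen=True)
class Region:
    """0-based half-open interval on a named contig."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.end < self.start:
            raise ValueError(f"bad region bounds [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Feature:
    feature_id: str
    region: Region
    kind: str = "misc"  # CDS | gene | misc
    product: str = ""


@dataclass(frozen=True)
class CodonTable:
    """64-entry codon -> amino-acid map; STOP is rendered as ``*``.

    Defines the synonymy relation used throughout: two codons are
    synonymous iff they map to the same single-letter symbol (stop
    codons form their own family).
    """

    forward: dict
    start_codons: tuple
    id: str = "11"

    def __post_init__(self) -> None:
        if len(self.forward) != 64:
            raise ValueError(f"codon table must have 64 entries, got {len(self.forward)}")
        if "*" not in self.forward.values():
            raise ValueError("codon table has no stop codon")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 11) -> "CodonTable":
        bio = _BioCodonTable.unambiguous_dna_by_id[table_id]
        fwd = dict(bio.forward_table)
        for stop in bio.stop_codons:
            fwd[stop] = "*"
        return cls(forward=fwd, start_codons=tuple(bio.start_codons), id=str(table_id))

    def aa(self, codon: str) -> str:
        return self.forward[str(codon).upper()]

    def synonyms(self, codon: str) -> tuple:
        """All codons encoding the same residue, sorted, including ``codon``."""
        target = self.aa(codon)
        return tuple(sorted(c for c, a in self.forward.items() if a == target))

    def is_stop(self, codon: str) -> bool:
        return self.aa(codon) == "*"


_DEFAULT_TABLE: CodonTable | None = None


def default_table() -> CodonTable:
    """The bacterial/archaeal codon table (NCBI table 11), cached."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = CodonTable.from_ncbi_id(11)
    return _DEFAULT_TABLE


def translate(seq: str, table: CodonTable | None = None, require_start: bool = False) -> str:
    """Translate an in-frame DNA string to a protein string.

    STOP codons are rendered as ``*``.  ``require_start`` additionally
    demands that the first codon is a valid initiation codon under the
    table (it is still translated by plain lookup, so GTG yields V).
    """
    s = NucSeq(seq)
    if len(s) % 3 != 0:
        raise CodingFrameError(f"length {len(s)} is not divisible by 3")
    tab = table or default_table()
    if require_start and s and s[:3] not in tab.start_codons:
        raise CodingFrameError(f"{s[:3]} is not a start codon in table {tab.id}")
    return "".join(tab.forward[str(s[i : i + 3])] for i in range(0, len(s), 3))


def scan_motif(seq: str, motif: str, both_strands: bool = False) -> list:
    """All exact, possibly overlapping occurrences of ``motif`` in ``seq``.

    Returns ``(position, strand)`` pairs, 0-based, sorted by position.
    A ``-`` hit at position p means the reverse complement of the motif
    occupies ``seq[p : p + len(motif)]``.
    """
    s, m = NucSeq(seq), NucSeq(motif)
    if len(m) == 0:
        raise ValueError("motif must be nonempty")

    def _forward(text: str, pat: str, strand: str) -> list:
        hits, i = [], text.find(pat)
        while i != -1:
            hits.append((i, strand))
            i = text.find(pat, i + 1)
        return hits

    hits = _forward(s, m, "+")
    if both_strands:
        rc = revcomp(m)
        if rc != m:  # palindromes would double-report the same occupancy
            hits += _forward(s, rc, "-")
    return sorted(hits)


def codon_window(residue_index: int) -> tuple:
    """1-based inclusive CDS coordinates occupied by codon ``n``: (3n-2, 3n)."""
    if residue_index < 1:
        raise ValueError(f"residue index must be >= 1, got {residue_index}")
    return (3 * residue_index - 2, 3 * residue_index)


@dataclass
class GenomeRecord:
    """Contigs plus CDS/gene/misc features; the substrate edited in silico."""

    contigs: dict
    features: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contigs = {k: NucSeq(v) for k, v in self.contigs.items()}
        table = default_table()
        for f in self.features:
            if f.region.contig_id not in self.contigs:
                raise ValueError(f"feature {f.feature_id} on unknown contig {f.region.contig_id}")
            if f.region.end > len(self.contigs[f.region.contig_id]):
                raise ValueError(
                    f"feature {f.feature_id} ends at {f.region.end}, beyond contig "
                    f"{f.region.contig_id} length {len(self.contigs[f.region.contig_id])}"
                )
            if f.kind == "CDS":
                cds = self.extract(f.region)
                if len(cds) % 3 != 0:
                    warnings.warn(f"CDS {f.feature_id} length {len(cds)} not divisible by 3")
                else:
                    if cds[:3] not in table.start_codons:
                        warnings.warn(f"CDS {f.feature_id} does not begin with a start codon")
                    if not table.is_stop(cds[-3:]):
                        warnings.warn(f"CDS {f.feature_id} does not end with a stop codon")

    def extract(self, region: Region) -> NucSeq:
        """Feature-strand sequence of ``region`` (reverse-complemented for '-')."""
        raw = NucSeq(self.contigs[region.contig_id][region.start : region.end])
        return revcomp(raw) if region.strand == "-" else raw

    def feature_by_id(self, feature_id: str) -> Feature:
        for f in self.features:
            if f.feature_id == feature_id:
                return f
        raise KeyError(f"no feature named {feature_id!r}")

    def single_contig_id(self) -> str:
        if len(self.contigs) != 1:
            raise ValueError("genome has multiple contigs; name one explicitly")
        return next(iter(self.contigs))


PART_ROLES = ("isceI_site", "terminator", "spacer", "marker", "promoter", "tag", "backbone")


@dataclass(frozen=True)
class Part:
    name: str
    seq: NucSeq
    role: str
    notes: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", NucSeq(self.seq))
        if self.role not in PART_ROLES:
            raise LibraryError(f"unknown part role {self.role!r} for part {self.name!r}")


def _find_orf(seq: str, table: CodonTable) -> tuple | None:
    """Longest in-frame start..stop span in ``seq`` (0-based half-open), or None."""
    s = NucSeq(seq)
    best = None
    for i in range(len(s) - 5):
        if s[i : i + 3] not in table.start_codons:
            continue
        for j in range(i + 3, len(s) - 2, 3):
            codon = s[j : j + 3]
            if table.is_stop(codon):
                if best is None or (j + 3 - i) > (best[1] - best[0]):
                    best = (i, j + 3)
                break
    return best


@dataclass
class ElementLibrary:
    """Named cassette parts with roles.

    Invariants enforced on construction: exactly one ``isceI_site`` part;
    every ``marker`` part contains a complete open reading frame; every
    ``terminator`` part is nonempty.
    """

    parts: dict
    table: CodonTable = field(default_factory=default_table)

    def __post_init__(self) -> None:
        sites = [p for p in self.parts.values() if p.role == "isceI_site"]
        if len(sites) != 1:
            raise LibraryError(f"library must contain exactly one isceI_site part, found {len(sites)}")
        for p in self.parts.values():
            if p.role == "terminator" and len(p.seq) == 0:
                raise LibraryError(f"terminator part {p.name!r} is empty")
            if p.role == "marker" and self.marker_orf(p) is None:
                raise LibraryError(f"marker part {p.name!r} contains no complete ORF")

    @property
    def isceI_site(self) -> Part:
        return next(p for p in self.parts.values() if p.role == "isceI_site")

    def __getitem__(self, name: str) -> Part:
        try:
            return self.parts[name]
        except KeyError:
            raise LibraryError(f"library has no part named {name!r}") from None

    def by_role(self, role: str) -> list:
        return [p for p in self.parts.values() if p.role == role]

    def marker_orf(self, part: Part) -> tuple | None:
        """(start, end) of the marker ORF within the part, 0-based half-open."""
        if "orf" in part.meta:
            return tuple(part.meta["orf"])
        return _find_orf(part.seq, self.table)


# --- default library -------------------------------------------------------
#
# The published construct descriptions give part names and composition order
# (iGEM terminators BBa_B1006/BBa_B1002, spacers BBa_K259002/BBa_B0040, cat/
# kan/dfrA markers with a shared 16 bp 3' tail) but not the sequences, so the
# default library ships deterministic synthetic stand-ins under those names,
# each flagged provisional.  Correctness of every design operation depends
# only on the invariants (one recognition site, intact marker ORFs, nonempty
# terminators), never on these literal bases; supply a real part library for
# wet-lab use.

_PROMOTER = NucSeq("TTGACAGCTAGCTCAGTCCTAGGTATAATGCTAGCACGA")  # -35/-10 style
_RBS = NucSeq("TAGGAGATATACC")
#: 16 bp 3' tail shared by every default marker so one common reverse primer
#: can amplify any selection cassette (the common-primer-tail behaviour).
COMMON_MARKER_TAIL = NucSeq("CGGCAGTTTCTACACA")


def _synth_orf(rng: np.random.Generator, n_codons: int, table: CodonTable) -> NucSeq:
    sense = sorted(c for c, a in table.forward.items() if a != "*" and c != "ATG")
    body = "".join(rng.choice(sense) for _ in range(n_codons))
    return NucSeq("ATG" + body + "TAA")


def _synth_terminator(rng: np.random.Generator, stem: int = 12) -> NucSeq:
    arm = "".join(rng.choice(list("GC"), size=stem - 3)) + "".join(rng.choice(list("ACGT"), size=3))
    return NucSeq(arm + "TTCG" + revcomp(arm) + "TTTTTTTT")


def default_library(table: CodonTable | None = None, seed: int = 7) -> ElementLibrary:
    """Deterministic synthetic part library (see module comment above)."""
    tab = table or default_table()
    rng = np.random.default_rng(seed)
    parts = {}

    def add(name, seq, role, notes="", meta=None):
        parts[name] = Part(name=name, seq=NucSeq(seq), role=role, notes=notes, meta=meta or {})

    add(
        "I-SceI_site",
        CANONICAL_ISCEI_SITE,
        "isceI_site",
        "canonical 18 bp recognition site (external-knowledge default; override via library file)",
    )
    add("BBa_B1006", _synth_terminator(rng), "terminator", "provisional synthetic stand-in for iGEM part")
    add("BBa_B1002", _synth_terminator(rng), "terminator", "provisional synthetic stand-in for iGEM part")
    # low-structure spacers: alternating-purine/pyrimidine biased draws
    add("BBa_K259002", "".join(rng.choice(list("ACAT"), size=11)) + "".join(rng.choice(list("GTCA"), size=11)),
        "spacer", "provisional synthetic stand-in for iGEM part")
    add("BBa_B0040", "".join(rng.choice(list("AGAC"), size=10)) + "".join(rng.choice(list("TCTG"), size=10)),
        "spacer", "provisional synthetic stand-in for iGEM part")

    for name, ncod in (("cat_syn", 80), ("kan_syn", 92), ("dfrA_syn", 70)):
        orf = _synth_orf(rng, ncod, tab)
        seq = _PROMOTER + _RBS + orf + COMMON_MARKER_TAIL
        orf_start = len(_PROMOTER) + len(_RBS)
        add(
            name,
            seq,
            "marker",
            "synthetic selection-marker stand-in (promoter + RBS + ORF + common 16 bp tail)",
            meta={"orf": (orf_start, orf_start + len(orf))},
        )

    # 3xFLAG epitope tag, back-translated with fixed codons (synthetic DNA,
    # canonical peptide DYKDHDGDYKDHDIDYKDDDDK)
    _bt = {
        "D": "GAT", "Y": "TAT", "K": "AAA", "H": "CAT", "G": "GGT", "I": "ATT",
    }
    add("3xFLAG", "".join(_bt[a] for a in "DYKDHDGDYKDHDIDYKDDDDK"), "tag",
        "synthetic back-translation of the 3xFLAG peptide")
    add("pHA_syn", "".join(rng.choice(list("ACGT"), size=300)), "backbone",
        "synthetic stand-in for the pUC19-derived assembly backbone")

    lib = ElementLibrary(parts=parts, table=tab)
    # guard against pathological collisions in the fixed synthetic sequences
    for p in lib.parts.values():
        if p.role != "isceI_site" and scan_motif(p.seq, CANONICAL_ISCEI_SITE, both_strands=True):
            raise LibraryError(f"default part {p.name} accidentally contains the I-SceI site")
    return lib
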