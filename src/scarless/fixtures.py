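"""Synthetic toy-genome generator for tests, examples and benchmarks.

Generates small bacterial-style contigs: protein-coding genes (proper
start codon, sense codons only, stop codon) separated by random
intergenic stretches, on either strand, fully deterministic under a
seed.  Optional planted pathologies (a stray I-SceI site, a duplicated
repeat) exercise the negative paths of the validator.  These genomes
stand in for real loci; they reproduce the *structural* properties the
design procedure depends on (unique homology anchors, intact reading
frames, realistic gene/intergenic geometry), not real codon usage,
GC skew or regulatory sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .seq_core import (
    CANONICAL_ISCEI_SITE,
    CodonTable,
    Feature,
    GenomeRecord,
    NucSeq,
    Region,
    default_table,
    revcomp,
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a generated toy genome; same spec -> same genome."""

    seed: int = 0
    n_genes: int = 4
    gene_len: tuple = (300, 600)        # bp, floored to a codon multiple
    intergenic_len: tuple = (260, 420)  # bp; generous so 100 bp arms always fit
    gc: float = 0.5                     # intergenic GC fraction
    minus_strand_fraction: float = 0.3
    contig_id: str = "chr"
    plant_isceI_site: bool = False      # negative-control: site already in genome
    plant_repeat: int = 0               # bp of duplicated sequence planted twice

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.gene_len[0] < 60 or self.intergenic_len[0] < 1:
            raise ValueError("infeasible fixture ranges")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("gc must be in (0, 1)")


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _random_cds(rng: np.random.Generator, n_codons: int, table: CodonTable) -> NucSeq:
    sense = sorted(c for c, a in table.forward.items() if a != "*")
    body = "".join(rng.choice(sense, size=n_codons - 2))
    stop = rng.choice(sorted(c for c, a in table.forward.items() if a == "*"))
    return NucSeq("ATG" + body + stop)


def generate_fixture(spec: FixtureSpec, table: CodonTable | None = None) -> GenomeRecord:
    """Build a toy genome from a :class:`FixtureSpec`."""
    tab = table or default_table()
    rng = np.random.default_rng(spec.seed)
    chunks: list = []
    features: list = []
    pos = 0

    def emit_intergenic() -> None:
        nonlocal pos
        n = int(rng.integers(spec.intergenic_len[0], spec.intergenic_len[1] + 1))
        chunks.append(_random_dna(rng, n, spec.gc))
        pos += n

    emit_intergenic()
    for i in range(spec.n_genes):
        n_codons = int(rng.integers(spec.gene_len[0] // 3, spec.gene_len[1] // 3 + 1))
        cds = _random_cds(rng, n_codons, tab)
        strand = "-" if rng.random() < spec.minus_strand_fraction else "+"
        placed = revcomp(cds) if strand == "-" else cds
        features.append(
            Feature(
                feature_id=f"gene_{i + 1}",
                region=Region(spec.contig_id, pos, pos + len(placed), strand),
                kind="CDS",
                product=f"synthetic protein {i + 1}",
            )
        )
        chunks.append(str(placed))
        pos += len(placed)
        emit_intergenic()

    seq = "".join(chunks)
    if spec.plant_isceI_site:
        # drop the site into the middle of the final intergenic stretch
        tail = len(chunks[-1])
        at = len(seq) - tail // 2
        seq = seq[:at] + CANONICAL_ISCEI_SITE + seq[at:]
    if spec.plant_repeat:
        unit = _random_dna(rng, spec.plant_repeat, spec.gc)
        seq = unit + seq + unit

    if spec.plant_repeat:  # features shifted by the leading repeat copy
        features = [
            Feature(
                f.feature_id,
                Region(spec.contig_id, f.region.start + spec.plant_repeat, f.region.end + spec.plant_repeat, f.region.strand),
                f.kind,
                f.product,
            )
            for f in features
        ]
    return GenomeRecord(contigs={spec.contig_id: NucSeq(seq)}, features=features)


_EDIT_KINDS = ("point_mutation", "insertion", "deletion", "essential_gene")
_VARIANTS = ("own_promoter", "marker_promoter", "wt_restoring")


def random_edit(
    genome: GenomeRecord,
    rng: np.random.Generator,
    table: CodonTable | None = None,
    kind: str | None = None,
    variant: str | None = None,
    insert_seq: str | None = None,
):
    """A random well-posed edit on a fixture genome, for randomised suites.

    Kinds and essential-gene variants are drawn uniformly unless pinned.
    Edits keep enough flanking context for the 100 bp homology arms and
    ~200 bp mutation fragments; essential-gene edits pick a degenerate
    mid-gene codon and swap it for a random synonym.
    """
    from .design import EditSpec  # local import to keep module layers acyclic

    tab = table or default_table()
    kind = kind or _EDIT_KINDS[int(rng.integers(len(_EDIT_KINDS)))]
    contig_id = next(iter(genome.contigs))
    seq = genome.contigs[contig_id]
    margin = 360  # fragment + homology arm + slack

    if kind == "essential_gene":
        variant = variant or _VARIANTS[int(rng.integers(len(_VARIANTS)))]
        for _ in range(50):
            feat = genome.features[int(rng.integers(len(genome.features)))]
            if feat.kind != "CDS":
                continue
            cds = genome.extract(feat.region)
            n = len(cds) // 3
            r = int(rng.integers(max(2, n // 5), min(n - 1, 4 * n // 5)))
            cod = cds[3 * (r - 1) : 3 * r]
            syn = [c for c in tab.synonyms(cod) if c != cod]
            if not syn:
                continue
            return EditSpec(
                kind=kind,
                feature_id=feat.feature_id,
                variant=variant,
                mutations=[{"residue_index": r, "new_codon": syn[int(rng.integers(len(syn)))]}],
                rbs_boost=bool(variant == "marker_promoter" and rng.random() < 0.5),
            )
        raise RuntimeError("no degenerate codon found in 50 draws")

    if kind == "point_mutation":
        width = int(rng.integers(1, 4))
        p = int(rng.integers(margin, len(seq) - margin - width))
        old = seq[p : p + width]
        new = "".join(
            str(rng.choice([b for b in "ACGT" if b != o])) for o in old
        )
        return EditSpec(kind=kind, contig=contig_id, start=p + 1, end=p + width, payload=new)

    if kind == "insertion":
        p = int(rng.integers(margin, len(seq) - margin))
        if insert_seq is None:
            n = int(rng.integers(6, 80))
            insert_seq = "".join(rng.choice(list("ACGT"), size=n))
        return EditSpec(kind=kind, contig=contig_id, start=p + 1, payload=str(insert_seq))

    # deletion
    span = int(rng.integers(30, 400))
    p = int(rng.integers(margin, len(seq) - margin - span))
    return EditSpec(kind=kind, contig=contig_id, start=p + 1, end=p + span)
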