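"""In-silico execution of the editing steps and the crossover-position model.

Two things live here.  First, a quantitative model of where the second
lambda-Red crossover can land during cassette integration: crossovers
require a minimal pairing window ``w`` of perfect donor/target identity,
and within the identity segments that remain the crossover position is
taken as uniform per base.  A crossover is *desired* when it lies 3' of
the last mutated base, so that every mutation travels into the genome;
this is the arithmetic that makes synonymous recoding pay off, because
recoding deletes the identity segments 5' of the mutation.  Second,
deterministic simulation of the two editing steps themselves:
integration of a mutation cassette between its HR1/HR2 anchors, then
I-SceI cleavage and HR3-mediated resolution that excises the selection
core scarlessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CleavageError, DesignInfeasibleError, ResolutionError, TargetingError
from .seq_core import Feature, GenomeRecord, NucSeq, Region, revcomp, scan_motif

#: feature-id prefix used to annotate cassette anatomy in the intermediate
EDIT_PREFIX = "edit:"


@dataclass
class IdentityMask:
    """Per-base donor/target identity over one homology arm.

    The donor is designed from the target, so the alignment is purely
    positional; the edit itself is masked ``False``.
    """

    label: str
    identity: np.ndarray

    def __post_init__(self) -> None:
        self.identity = np.asarray(self.identity, dtype=bool)

    def __len__(self) -> int:
        return int(self.identity.size)


@dataclass(frozen=True)
class IntegrationOutcomeModel:
    """Minimal pairing window and the uniform-per-base crossover density."""

    w: int = 20

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("pairing window must be >= 1")


def eligible_segments(mask: IdentityMask, w: int) -> list:
    """Maximal runs of identity with length >= w, in coordinate order."""
    if w < 1:
        raise ValueError("w must be >= 1")
    ident = mask.identity
    segments = []
    start = None
    for i in range(len(ident) + 1):
        on = i < len(ident) and ident[i]
        if on and start is None:
            start = i
        elif not on and start is not None:
            if i - start >= w:
                segments.append(Region(contig_id=mask.label, start=start, end=i))
            start = None
    return segments


def p_desired_integration(mask: IdentityMask, mutation_positions: list, w: int) -> float:
    """Probability that a uniform crossover transfers every mutation.

    Eligible crossover positions are the bases of :func:`eligible_segments`;
    desired ones lie strictly 3' of the last mutation position.  No
    eligible base at all means integration is impossible under the
    model, which is an error rather than probability zero.
    """
    if not mutation_positions:
        raise ValueError("at least one mutation position is required")
    positions = sorted(int(p) for p in mutation_positions)
    if positions[0] < 0 or positions[-1] >= len(mask):
        raise ValueError("mutation positions outside mask coordinates")
    if any(mask.identity[p] for p in positions):
        raise ValueError("mask must be False at every mutation position")
    eligible = [i for seg in eligible_segments(mask, w) for i in range(seg.start, seg.end)]
    if not eligible:
        raise DesignInfeasibleError(
            f"no identity segment of length >= {w} in arm {mask.label!r}; "
            "integration is impossible under the pairing model"
        )
    last = positions[-1]
    desired = sum(1 for i in eligible if i > last)
    return desired / len(eligible)


def _shift_features(features: list, contig_id: str, cut_start: int, cut_end: int, delta: int) -> list:
    """Keep features clear of [cut_start, cut_end); shift downstream ones."""
    out = []
    for f in features:
        r = f.region
        if r.contig_id != contig_id:
            out.append(f)
        elif r.end <= cut_start:
            out.append(f)
        elif r.start >= cut_end:
            out.append(
                Feature(
                    f.feature_id,
                    Region(contig_id, r.start + delta, r.end + delta, r.strand),
                    f.kind,
                    f.product,
                )
            )
        # features overlapping the replaced span are dropped
    return out


def integrate_in_silico(genome: GenomeRecord, cassette) -> GenomeRecord:
    """Lambda-Red integration: replace the HR1..HR2 span with the cassette.

    HR1 and HR2 must each occur exactly once in the target genome, on the
    plus strand (cassettes are emitted in plus-strand orientation), in
    order.  The returned intermediate genome carries ``edit:``-prefixed
    features marking the cassette anatomy, which the resolution step and
    the validator consume.
    """
    hr1, hr2 = NucSeq(cassette.hr1), NucSeq(cassette.hr2)
    cassette_seq = NucSeq(cassette.sequence)

    def find(pattern):
        return [(cid, pos) for cid, s in genome.contigs.items() for pos, _ in scan_motif(s, pattern)]

    # a cassette may be emitted in either orientation relative to the genome
    # plus strand (essential genes annotated on the minus strand): try the
    # as-given orientation first, then the reverse complement
    plus1, plus2 = find(hr1), find(hr2)
    minus1, minus2 = find(revcomp(hr2)), find(revcomp(hr1))
    flipped = False
    if plus1 or plus2:
        hits1, hits2 = plus1, plus2
    else:
        hits1, hits2, flipped = minus1, minus2, True
        cassette_seq = revcomp(cassette_seq)
    if len(hits1) != 1 or len(hits2) != 1 or hits1[0][0] != hits2[0][0]:
        raise TargetingError(
            f"homology arms must anchor uniquely on one contig: "
            f"left-anchor hits={len(hits1)}, right-anchor hits={len(hits2)}"
        )
    contig_id = hits1[0][0]
    p1, p2 = hits1[0][1], hits2[0][1]
    if p1 + len(hr1 if not flipped else hr2) > p2:
        raise TargetingError(f"homology anchors (at {p1}, {p2}) are out of order or overlap")

    seq = genome.contigs[contig_id]
    cut_start = p1
    cut_end = p2 + (len(hr2) if not flipped else len(hr1))
    new_seq = NucSeq(seq[:cut_start] + cassette_seq + seq[cut_end:])
    delta = len(cassette_seq) - (cut_end - cut_start)

    features = _shift_features(genome.features, contig_id, cut_start, cut_end, delta)
    n_cas = len(cassette_seq)
    for label, start, end, strand in cassette.annotations:
        if flipped:
            start, end = n_cas - end, n_cas - start
            strand = "+" if strand == "-" else "-"
        features.append(
            Feature(
                feature_id=EDIT_PREFIX + label,
                region=Region(contig_id, cut_start + start, cut_start + end, strand),
                kind="misc",
                product=label,
            )
        )
    contigs = dict(genome.contigs)
    contigs[contig_id] = new_seq
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # interrupted CDS features were dropped above
        return GenomeRecord(contigs=contigs, features=features)


def _edit_feature(genome: GenomeRecord, label: str) -> Feature:
    try:
        return genome.feature_by_id(EDIT_PREFIX + label)
    except KeyError:
        raise ResolutionError(
            f"intermediate genome lacks the {EDIT_PREFIX}{label} annotation; "
            "resolve only genomes produced by integrate_in_silico"
        ) from None


def cleave_and_resolve(intermediate: GenomeRecord, library) -> GenomeRecord:
    """I-SceI cleavage followed by recombination between the HR3 copies.

    Requires exactly one recognition site in the whole genome and two
    byte-identical HR3 copies flanking the excisable core; returns the
    resolved genome with one HR3 copy retained and the core (terminators,
    recognition site, marker, any restoring fragment) removed.  Verifies
    that no marker, terminator, or recognition-site sequence survives.
    """
    site = library.isceI_site.seq
    site_hits = [
        (cid, pos, strand)
        for cid, seq in intermediate.contigs.items()
        for pos, strand in scan_motif(seq, site, both_strands=True)
    ]
    if len(site_hits) != 1:
        raise CleavageError(f"expected exactly one I-SceI site, found {len(site_hits)}")

    c1 = _edit_feature(intermediate, "HR3_copy1")
    c2 = _edit_feature(intermediate, "HR3_copy2")
    if c2.region.start < c1.region.start:  # cassette was integrated flipped
        c1, c2 = c2, c1
    contig_id = c1.region.contig_id
    seq = intermediate.contigs[contig_id]
    copy1 = seq[c1.region.start : c1.region.end]
    copy2 = seq[c2.region.start : c2.region.end]
    if copy1 != copy2:
        raise ResolutionError("the two HR3 copies are not identical; cannot resolve")

    cut_start, cut_end = c1.region.end, c2.region.end  # drop copy2 + everything between
    new_seq = NucSeq(seq[:cut_start] + seq[cut_end:])
    delta = -(cut_end - cut_start)
    features = [
        f
        for f in _shift_features(intermediate.features, contig_id, cut_start, cut_end, delta)
        if not f.feature_id.startswith(EDIT_PREFIX)
    ]
    contigs = dict(intermediate.contigs)
    contigs[contig_id] = new_seq
    resolved = GenomeRecord(contigs=contigs, features=features)

    leftovers = []
    for part in library.parts.values():
        if part.role not in ("marker", "terminator", "isceI_site"):
            continue
        for cid, cseq in resolved.contigs.items():
            if scan_motif(cseq, part.seq, both_strands=True):
                leftovers.append(part.name)
    if leftovers:
        raise ResolutionError(f"resolved genome still contains parts: {sorted(set(leftovers))}")
    return resolved
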