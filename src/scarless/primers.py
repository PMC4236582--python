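"""Primer design, melting temperatures, and Gibson-style assembly planning."""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.SeqUtils import MeltingTemp as _mt

from .errors import AssemblyAmbiguityError, PrimerError
from .seq_core import NucSeq, Region, revcomp, scan_motif


@dataclass(frozen=True)
class Primer:
    """An oligo with an annealing 3' portion and an optional 5' tail."""

    name: str
    sequence: NucSeq
    anneal_len: int
    tail_len: int
    tm_anneal: float
    binds: tuple  # (template label, Region, strand)

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", NucSeq(self.sequence))
        if self.anneal_len + self.tail_len != len(self.sequence):
            raise ValueError("anneal_len + tail_len must equal the primer length")

    @property
    def anneal_seq(self) -> NucSeq:
        return NucSeq(self.sequence[self.tail_len :])


def tm(seq: str, method: str = "auto", na_mM: float = 50.0, dnac_nM: float = 250.0) -> float:
    """Melting temperature in degrees C.

    ``wallace``: the 2*(A+T) + 4*(G+C) rule.  ``nn``: nearest-neighbor
    thermodynamics (SantaLucia unified parameters, monovalent-salt
    entropy correction) at the given Na+ and oligo concentrations.
    ``auto`` selects wallace below 14 nt and nearest-neighbor otherwise.
    """
    s = NucSeq(seq)
    if len(s) < 4:
        raise ValueError(f"sequence too short for a melting temperature: {len(s)} nt")
    if method == "auto":
        method = "wallace" if len(s) < 14 else "nn"
    if method == "wallace":
        at = s.count("A") + s.count("T")
        gc = s.count("G") + s.count("C")
        return float(2 * at + 4 * gc)
    if method == "nn":
        return float(
            _mt.Tm_NN(str(s), nn_table=_mt.DNA_NN3, Na=na_mM, K=0, Tris=0, Mg=0,
                      dnac1=dnac_nM, dnac2=0, saltcorr=5)
        )
    raise ValueError(f"unknown tm method {method!r}")


def design_amplification_primers(
    template: str,
    region: Region,
    config=None,
    name_forward: str = "F",
    name_reverse: str = "R",
    tail_forward: str = "",
    tail_reverse: str = "",
    template_label: str = "template",
) -> tuple:
    """Forward/reverse primer pair amplifying ``region`` from ``template``.

    The forward primer starts exactly at the region start; the reverse is
    the reverse complement anchored at the region end.  Annealing length
    grows from the configured minimum until the target melting
    temperature is reached, then the cooler primer is extended until the
    pair differs by at most the configured delta.
    """
    from .config import DesignConfig

    cfg = config or DesignConfig()
    t = NucSeq(template)
    if not (0 <= region.start < region.end <= len(t)):
        raise ValueError("region outside template")

    def grow(anchor_fwd: bool, min_len: int) -> tuple:
        length = min_len
        while True:
            if anchor_fwd:
                if region.start + length > region.end:
                    raise PrimerError("forward primer cannot reach target Tm within the region")
                seq = t[region.start : region.start + length]
            else:
                if region.end - length < region.start:
                    raise PrimerError("reverse primer cannot reach target Tm within the region")
                seq = revcomp(t[region.end - length : region.end])
            temp = tm(seq, cfg.tm_method)
            if temp >= cfg.tm_target or length >= cfg.primer_max_len:
                if temp < cfg.tm_target:
                    raise PrimerError(
                        f"cannot reach Tm {cfg.tm_target} within {cfg.primer_max_len} nt "
                        f"({'forward' if anchor_fwd else 'reverse'} primer, Tm {temp:.1f})"
                    )
                return seq, length, temp
            length += 1

    fseq, flen, ftm = grow(True, cfg.primer_min_len)
    rseq, rlen, rtm = grow(False, cfg.primer_min_len)
    # equalise: extend the cooler primer (extension can only raise Tm)
    while abs(ftm - rtm) > cfg.tm_delta:
        if ftm < rtm:
            if flen >= cfg.primer_max_len:
                raise PrimerError(f"primer pair Tm difference {abs(ftm - rtm):.1f} irreducible")
            fseq, flen, ftm = grow(True, flen + 1)
        else:
            if rlen >= cfg.primer_max_len:
                raise PrimerError(f"primer pair Tm difference {abs(ftm - rtm):.1f} irreducible")
            rseq, rlen, rtm = grow(False, rlen + 1)

    fwd = Primer(
        name=name_forward,
        sequence=NucSeq(tail_forward) + fseq,
        anneal_len=flen,
        tail_len=len(tail_forward),
        tm_anneal=ftm,
        binds=(template_label, Region(template_label, region.start, region.start + flen), "+"),
    )
    rev = Primer(
        name=name_reverse,
        sequence=NucSeq(tail_reverse) + rseq,
        anneal_len=rlen,
        tail_len=len(tail_reverse),
        tm_anneal=rtm,
        binds=(template_label, Region(template_label, region.end - rlen, region.end), "-"),
    )
    return fwd, rev


@dataclass
class AssemblyPlan:
    """Ordered fragments joined by shared terminal overlaps."""

    fragments: list
    junctions: list  # overlap sequences between consecutive fragments
    total_length: int
    circular: bool = False

    @property
    def assembled(self) -> NucSeq:
        seq = str(self.fragments[0])
        for frag, j in zip(self.fragments[1:], self.junctions[: len(self.fragments) - 1]):
            seq += str(frag)[len(j) :]
        if self.circular and self.junctions:
            seq = seq[: len(seq) - len(self.junctions[-1])]
        return NucSeq(seq)


def assembly_length(segment_lengths, overlap_lengths=()) -> int:
    """Total length of a junction-resolved assembly: sum of segments minus overlaps."""
    return int(sum(segment_lengths) - sum(overlap_lengths))


def plan_assembly(fragments, overlap_len: int = 20, backbone=None, circular: bool = False) -> AssemblyPlan:
    """Join fragments end-to-end via ``overlap_len`` bp shared junctions.

    Fragments whose ends already agree are validated as-is; otherwise the
    junction is injected by rewriting the first ``overlap_len`` bases of
    each following fragment to the preceding fragment's terminal bases
    (what happens physically when overlaps are added as primer tails).
    A junction sequence occurring more than once across the assembly is
    a mis-assembly risk and raises an error.
    """
    frags = [NucSeq(f) for f in fragments]
    if backbone is not None:
        frags = [NucSeq(backbone)] + frags
    if len(frags) < 2:
        raise ValueError("an assembly needs at least two fragments")
    if not (15 <= overlap_len <= 40):
        raise ValueError("overlap_len must lie in [15, 40]")
    if any(len(f) <= overlap_len for f in frags):
        raise ValueError("every fragment must be longer than the overlap")

    out = [frags[0]]
    junctions = []
    pairs = list(range(1, len(frags))) + ([0] if circular else [])
    for i in pairs:
        prev = out[-1] if i != 0 else out[-1]
        junction = NucSeq(prev[-overlap_len:])
        junctions.append(junction)
        if i != 0:
            nxt = frags[i]
            if not nxt.startswith(junction):
                nxt = NucSeq(junction + nxt[overlap_len:])
            out.append(nxt)
        else:  # circular closure: first fragment must begin with the junction
            if not out[0].startswith(junction):
                out[0] = NucSeq(junction + out[0][overlap_len:])

    seen = {}
    for j in junctions:
        seen[j] = seen.get(j, 0) + 1
    dups = [j for j, n in seen.items() if n > 1]
    if dups:
        raise AssemblyAmbiguityError(f"{len(dups)} junction sequence(s) occur more than once")
    total = assembly_length([len(f) for f in out], [overlap_len] * len(junctions))
    plan = AssemblyPlan(fragments=out, junctions=junctions, total_length=total, circular=circular)
    # overlaps occurring elsewhere in the assembled product are also a risk
    for j in junctions:
        if len(scan_motif(plan.assembled, j)) > 1:
            raise AssemblyAmbiguityError(f"junction {j[:8]}... recurs outside its joint")
    return plan
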