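"""Synonymous-codon recoding, RBS scoring/boosting, and structure screens.

The recoder destroys nucleotide identity between a coding fragment and
its genomic original while preserving the encoded protein.  This is the
device that makes essential-gene editing reliable: a restoring fragment
composed of synonymous codons cannot pair with the chromosomal copy, so
homologous recombination is confined to the short HR3 window that
actually carries the desired mutation.

Objective: per-codon maximal Hamming distance from the original codon,
ties broken by (1) higher codon-usage frequency when a usage table is
supplied, then (2) lexicographic order.  Constraints (forbidden motifs,
a cap ``w_max`` on the longest exact window shared with the original)
are repaired by local re-choice at offending codons, scanning left to
right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import CodingFrameError, RecodeInfeasibleError
from .seq_core import CodonTable, NucSeq, default_table, revcomp, scan_motif, translate


@dataclass(frozen=True)
class RecodeOptions:
    """Tunables for :func:`recode_synonymous`.

    w_max is the longest exact window (bp) the recoded fragment may
    share with the original.  The default of 14 bp sits well below the
    30 bp lower bound of an HR3 window, i.e. below the scale at which
    RecA-mediated pairing becomes efficient, with margin.
    """

    w_max: int = 14
    forbidden_motifs: tuple = ()
    objective: str = "max_hamming"
    codon_usage: dict | None = None

    def __post_init__(self) -> None:
        if self.w_max < 3:
            raise ValueError("w_max below one codon is meaningless")
        if any(len(m) == 0 for m in self.forbidden_motifs):
            raise ValueError("forbidden motifs must be nonempty")


@dataclass(frozen=True)
class RbsModel:
    """Shine-Dalgarno consensus and admissible spacer range.

    ``spacer`` counts the nucleotides between the 3' end of the
    consensus match and the first base of the start codon.  AGGAGG with
    a 4-13 nt spacer is the conventional bacterial consensus; both are
    configurable and nothing downstream depends on the defaults.
    """

    consensus: NucSeq = NucSeq("AGGAGG")
    spacer_min: int = 4
    spacer_max: int = 13

    def __post_init__(self) -> None:
        if not (0 < self.spacer_min <= self.spacer_max):
            raise ValueError("need 0 < spacer_min <= spacer_max")
        if len(self.consensus) < 4:
            raise ValueError("consensus must be at least 4 nt")


@dataclass
class CodonChoice:
    index: int
    original: str
    chosen: str
    changeable: bool
    deviated: bool = False  # constraint repair displaced the objective-optimal codon


@dataclass
class RecodeReport:
    choices: list = field(default_factory=list)

    @property
    def n_changed(self) -> int:
        return sum(1 for c in self.choices if c.chosen != c.original)

    @property
    def n_unchangeable(self) -> int:
        return sum(1 for c in self.choices if not c.changeable)


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _ranked_candidates(codon: str, table: CodonTable, opts: RecodeOptions) -> list:
    """Synonyms of ``codon`` other than itself, best first; [codon] if unique."""
    family = table.synonyms(codon)
    if len(family) == 1:
        return [codon]
    usage = opts.codon_usage or {}
    alts = [c for c in family if c != codon]
    return sorted(alts, key=lambda c: (-_hamming(c, codon), -usage.get(c, 0.0), c))


def max_shared_window(a: str, b: str) -> int:
    """Length of the longest exact substring common to ``a`` and ``b``.

    Suffix-automaton traversal: O(len(a)) states, O(len(b)) matching.
    """
    a, b = str(NucSeq(a)), str(NucSeq(b))
    if not a or not b:
        return 0
    # build suffix automaton of a
    nxt = [{}]
    link = [-1]
    length = [0]
    last = 0
    for ch in a:
        cur = len(nxt)
        nxt.append({})
        length.append(length[last] + 1)
        link.append(-1)
        p = last
        while p != -1 and ch not in nxt[p]:
            nxt[p][ch] = cur
            p = link[p]
        if p == -1:
            link[cur] = 0
        else:
            q = nxt[p][ch]
            if length[p] + 1 == length[q]:
                link[cur] = q
            else:
                clone = len(nxt)
                nxt.append(dict(nxt[q]))
                length.append(length[p] + 1)
                link.append(link[q])
                while p != -1 and nxt[p].get(ch) == q:
                    nxt[p][ch] = clone
                    p = link[p]
                link[q] = clone
                link[cur] = clone
        last = cur
    # run b through it
    best = cur_len = 0
    v = 0
    for ch in b:
        while v != 0 and ch not in nxt[v]:
            v = link[v]
            cur_len = length[v]
        if ch in nxt[v]:
            v = nxt[v][ch]
            cur_len += 1
            best = max(best, cur_len)
    return best


def _longest_common_window(a: str, b: str) -> tuple:
    """(length, end_in_a) of one longest common substring; DP, repair helper."""
    n, m = len(a), len(b)
    best, end_a = 0, 0
    prev = [0] * (m + 1)
    for i in range(1, n + 1):
        cur = [0] * (m + 1)
        ai = a[i - 1]
        for j in range(1, m + 1):
            if ai == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best, end_a = cur[j], i
        prev = cur
    return best, end_a


def recode_synonymous(
    cds_fragment: str,
    table: CodonTable | None = None,
    opts: RecodeOptions | None = None,
) -> tuple:
    """Replace every degenerate codon with a synonym; return (recoded, report).

    Postconditions: the protein is unchanged; every codon whose amino
    acid has more than one codon differs from the original; no forbidden
    motif occurs in the output (either strand); the longest window
    shared with the input is at most ``opts.w_max``.
    """
    frag = NucSeq(cds_fragment)
    tab = table or default_table()
    opts = opts or RecodeOptions()
    if len(frag) % 3 != 0:
        raise CodingFrameError(f"fragment length {len(frag)} not divisible by 3")
    codons = [str(frag[i : i + 3]) for i in range(0, len(frag), 3)]
    for k, c in enumerate(codons[:-1]):
        if tab.is_stop(c):
            raise CodingFrameError(f"internal stop codon {c} at codon {k + 1}")

    ranked = [_ranked_candidates(c, tab, opts) for c in codons]
    pointer = [0] * len(codons)  # index into ranked[k] currently chosen
    exhausted_baseline = [len(r) == 1 and r[0] == codons[k] for k, r in enumerate(ranked)]

    # infeasibility pre-check: a run of single-codon families yields an
    # unavoidable identical window of 3 * run_length bp
    run_start = None
    for k in range(len(codons) + 1):
        unchangeable = k < len(codons) and exhausted_baseline[k]
        if unchangeable and run_start is None:
            run_start = k
        if not unchangeable and run_start is not None:
            if 3 * (k - run_start) > opts.w_max:
                raise RecodeInfeasibleError(
                    f"codons {run_start + 1}..{k} have single-codon families; the "
                    f"{3 * (k - run_start)} bp span they fix exceeds w_max={opts.w_max}",
                    span=(3 * run_start, 3 * k),
                )
            run_start = None

    def build() -> str:
        return "".join(ranked[k][pointer[k]] for k in range(len(codons)))

    deviated = set()

    def violation_span(seq: str) -> tuple | None:
        """A (start, end) span in ``seq`` witnessing a constraint violation."""
        for motif in opts.forbidden_motifs:
            for pat in (NucSeq(motif), revcomp(motif)):
                hits = scan_motif(seq, pat)
                if hits:
                    return (hits[0][0], hits[0][0] + len(pat))
        if max_shared_window(seq, frag) > opts.w_max:  # cheap O(n) test first
            w, end_a = _longest_common_window(seq, frag)
            return (end_a - w, end_a)
        return None

    max_rounds = 12 * max(1, len(codons))
    for _ in range(max_rounds):
        seq = build()
        span = violation_span(seq)
        if span is None:
            break
        s, e = span
        lo, hi = s // 3, (e - 1) // 3
        mid = (lo + hi) // 2
        # advance the alternative pointer at a codon inside the window,
        # starting from the middle and spiralling outward
        order = sorted(range(lo, hi + 1), key=lambda k: (abs(k - mid), k))
        for k in order:
            if pointer[k] + 1 < len(ranked[k]):
                pointer[k] += 1
                deviated.add(k)
                break
        else:
            raise RecodeInfeasibleError(
                f"constraints unsatisfiable over fragment span {s}..{e} "
                f"(all synonymous alternatives exhausted)",
                span=(s, e),
            )
    else:
        raise RecodeInfeasibleError("constraint repair did not converge", span=(0, len(frag)))

    recoded = NucSeq(build())
    assert translate(recoded, tab) == translate(frag, tab)
    report = RecodeReport(
        choices=[
            CodonChoice(
                index=k,
                original=codons[k],
                chosen=ranked[k][pointer[k]],
                changeable=not exhausted_baseline[k],
                deviated=k in deviated,
            )
            for k in range(len(codons))
        ]
    )
    return recoded, report


def rbs_score(upstream_window: str, model: RbsModel | None = None) -> tuple:
    """Best consensus match over all admissible placements: (score, spacer).

    ``upstream_window`` is the sequence ending immediately before a start
    codon.  For spacer ``s`` the consensus is aligned so that its 3' end
    sits ``s`` nt before the window's 3' end; placements truncated by the
    window's 5' edge are scored over the available bases only, so a
    short window is never an error.  Ties break toward the smallest
    spacer; a window with no overlapping placement scores (0, None).
    """
    w = NucSeq(upstream_window)
    model = model or RbsModel()
    cons = model.consensus
    best_score, best_spacer = 0, None
    for s in range(model.spacer_min, model.spacer_max + 1):
        end = len(w) - s
        if end <= 0:
            continue
        start = end - len(cons)
        cstart = max(0, -start)  # consensus bases cut off by the 5' edge
        seg = w[max(0, start) : end]
        score = sum(x == y for x, y in zip(seg, cons[cstart:]))
        if best_spacer is None or score > best_score:
            best_score, best_spacer = score, s
    return best_score, best_spacer


def silent_rbs_boost(
    upstream_cds_tail: str,
    table: CodonTable | None = None,
    model: RbsModel | None = None,
) -> tuple:
    """Silent mutations in a CDS tail that maximise the downstream RBS score.

    The tail is in-frame coding sequence whose last base immediately
    precedes the downstream gene's start codon (the marker->essential-
    gene junction of a marker-promoter design).  Returns ``(modified_tail, mutations, score_before,
    score_after)`` with ``mutations`` a list of 0-based ``(position,
    from, to)`` tuples.  The achieved score is the maximum over all
    fully-silent variants of the tail: for a fixed consensus placement
    the consensus positions partition by codon, so optimising each
    overlapping codon independently is exact, and maximising over
    placements then equals maximising over (variant, placement) pairs.
    """
    tail = NucSeq(upstream_cds_tail)
    tab = table or default_table()
    model = model or RbsModel()
    if len(tail) % 3 != 0:
        raise CodingFrameError(f"tail length {len(tail)} not divisible by 3")
    codons = [str(tail[i : i + 3]) for i in range(0, len(tail), 3)]
    cons = model.consensus
    score_before, _ = rbs_score(tail, model)

    best = None  # (score, spacer, codon_assignment)
    for s in range(model.spacer_min, model.spacer_max + 1):
        end = len(tail) - s
        if end <= 0:
            continue
        start = end - len(cons)
        assignment = list(codons)
        total = 0
        for k in range(len(codons)):
            c0, c1 = 3 * k, 3 * k + 3  # codon span in tail coordinates
            positions = [p for p in range(max(start, c0, 0), min(end, c1)) if p >= 0]
            if not positions:
                continue

            def matches(codon: str) -> int:
                return sum(codon[p - c0] == cons[p - start] for p in positions)

            fam = tab.synonyms(codons[k])
            cand = max(fam, key=lambda c: (matches(c), c == codons[k], _neg_lex(c)))
            assignment[k] = cand
            total += matches(cand)
        key = (total, -s)
        if best is None or key > (best[0], -best[1]):
            best = (total, s, assignment)

    if best is None:  # window shorter than any spacer: nothing to do
        return tail, [], score_before, score_before

    modified = NucSeq("".join(best[2]))
    score_after, _ = rbs_score(modified, model)
    if score_after < score_before:  # never regress (defensive; should not occur)
        return tail, [], score_before, score_before
    mutations = [(i, tail[i], modified[i]) for i in range(len(tail)) if tail[i] != modified[i]]
    if score_after == score_before:
        return tail, [], score_before, score_before
    assert translate(modified, tab) == translate(tail, tab)
    return modified, mutations, score_before, score_after


class _neg_lex(str):
    """Sort key wrapper: lexicographically *smaller* strings rank higher."""

    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)


_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def hairpin_screen(seq: str, min_stem: int = 8, loop_min: int = 3, loop_max: int = 10) -> list:
    """Maximal inverted repeats: hairpins with stem >= min_stem, loop in range.

    A hit ``(stem_len, pos5, pos3)`` means ``seq[pos5 : pos5+stem]`` pairs
    with the reverse complement of ``seq[pos3 : pos3+stem]`` around a loop
    of ``pos3 - (pos5 + stem)`` unpaired bases.  Used as a quick screen
    for unwanted secondary structure in spacer regions; it is a
    sequence-level surrogate, not a thermodynamic fold.
    """
    s = NucSeq(seq)
    if min_stem < 3:
        raise ValueError("min_stem must be >= 3")
    hits = []
    n = len(s)
    for loop in range(loop_min, loop_max + 1):
        for i in range(1, n):  # i = first base of the loop
            j = i + loop  # first base of the 3' arm
            if j >= n:
                break
            k = 0
            while i - 1 - k >= 0 and j + k < n and s[i - 1 - k] == _PAIR[s[j + k]]:
                k += 1
            if k >= min_stem:
                hits.append((k, i - k, j))
    return sorted(set(hits), key=lambda h: (h[1], h[2]))
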