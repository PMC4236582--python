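"""Recoding engine: synonymy, divergence windows, RBS scoring, hairpins."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarless import (
    NucSeq,
    RbsModel,
    RecodeInfeasibleError,
    RecodeOptions,
    hairpin_screen,
    max_shared_window,
    rbs_score,
    recode_synonymous,
    silent_rbs_boost,
    translate,
)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def random_cds_fragment(rng, n_codons, table, allow_stop_tail=False):
    sense = sorted(c for c, a in table.forward.items() if a != "*")
    codons = [str(rng.choice(sense)) for _ in range(n_codons)]
    if allow_stop_tail and rng.random() < 0.3:
        codons[-1] = str(rng.choice(sorted(c for c, a in table.forward.items() if a == "*")))
    return NucSeq("".join(codons))


def hamming(a, b):
    return sum(x != y for x, y in zip(a, b))


def brute_force_recode(fragment, table, usage=None):
    """Exhaustive enumeration over all synonymous combinations, max total
    Hamming distance, ties broken per codon by (usage desc, lexicographic)."""
    codons = [fragment[i : i + 3] for i in range(0, len(fragment), 3)]
    usage = usage or {}
    choices = []
    for c in codons:
        fam = table.synonyms(c)
        choices.append([x for x in fam if x != c] if len(fam) > 1 else [c])
    best = None
    for combo in itertools.product(*choices):
        score = sum(hamming(x, c) for x, c in zip(combo, codons))
        key = tuple((-usage.get(x, 0.0), x) for x in combo)
        if best is None or score > best[0] or (score == best[0] and key < best[1]):
            best = (score, key, combo)
    return "".join(best[2])


class TestRecodeSynonymous:
    def test_single_codon_family_unchanged(self, table):
        recoded, report = recode_synonymous("ATG", table)
        assert recoded == "ATG"
        assert not report.choices[0].changeable

    def test_serine_swap_reaches_max_divergence(self, table):
        # AGC -> TCT is the published silent serine mutation; it attains the
        # maximal Hamming distance within the serine family
        recoded, _ = recode_synonymous("AGC", table)
        best = max(hamming(c, "AGC") for c in table.synonyms("AGC"))
        assert hamming("TCT", "AGC") == best
        assert hamming(recoded, "AGC") == best
        assert translate(recoded, table) == "S"

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed, table):
        rng = np.random.default_rng(seed)
        frag = random_cds_fragment(rng, int(rng.integers(2, 7)), table, allow_stop_tail=True)
        opts = RecodeOptions(w_max=10_000)  # objective only, no window constraint
        recoded, _ = recode_synonymous(frag, table, opts)
        assert str(recoded) == brute_force_recode(frag, table)

    def test_usage_table_breaks_ties(self, table):
        # Leu family: vs CTA both TTA and TTG... pick codon where several
        # synonyms attain max Hamming and check usage steers the choice
        frag = "AGC"  # Ser: TCT/TCA/TCG all at Hamming 3 from AGC
        usage = {"TCG": 0.9, "TCT": 0.1, "TCA": 0.1}
        recoded, _ = recode_synonymous(frag, table, RecodeOptions(codon_usage=usage))
        assert recoded == "TCG"

    @pytest.mark.parametrize("seed", range(20))
    def test_invariants_on_random_fragments(self, seed, table):
        rng = np.random.default_rng(100 + seed)
        frag = random_cds_fragment(rng, int(rng.integers(10, 60)), table)
        opts = RecodeOptions(w_max=14)
        recoded, report = recode_synonymous(frag, table, opts)
        assert translate(recoded, table) == translate(frag, table)
        assert max_shared_window(recoded, frag) <= 14
        for k, choice in enumerate(report.choices):
            if choice.changeable:
                assert choice.chosen != choice.original

    def test_repeated_recoding_preserves_protein(self, table):
        rng = np.random.default_rng(5)
        frag = random_cds_fragment(rng, 30, table)
        prot = translate(frag, table)
        current = frag
        for _ in range(3):
            current, _ = recode_synonymous(current, table)
            assert translate(current, table) == prot

    def test_forbidden_motif_avoided(self, table):
        rng = np.random.default_rng(8)
        frag = random_cds_fragment(rng, 40, table)
        motif = NucSeq("GGATCC")
        opts = RecodeOptions(forbidden_motifs=(motif,))
        recoded, _ = recode_synonymous(frag, table, opts)
        from scarless import revcomp, scan_motif

        assert not scan_motif(recoded, motif)
        assert not scan_motif(recoded, revcomp(motif))

    def test_met_run_is_infeasible(self, table):
        with pytest.raises(RecodeInfeasibleError) as err:
            recode_synonymous("ATG" * 6, table, RecodeOptions(w_max=14))
        assert err.value.span is not None

    def test_internal_stop_rejected(self, table):
        with pytest.raises(Exception):
            recode_synonymous("TAAATG", table)


class TestMaxSharedWindow:
    def test_identical_and_disjoint(self):
        assert max_shared_window("A" * 30, "A" * 30) == 30
        assert max_shared_window("AAAA", "TTTT") == 0
        assert max_shared_window("", "ACGT") == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, derandomize=True)
    def test_matches_dp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 120))
        a = "".join(rng.choice(list("ACGT"), size=n))
        b = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 120))))
        # O(n*m) dynamic-programming longest-common-substring oracle
        best = 0
        prev = [0] * (len(b) + 1)
        for i in range(1, len(a) + 1):
            cur = [0] * (len(b) + 1)
            for j in range(1, len(b) + 1):
                if a[i - 1] == b[j - 1]:
                    cur[j] = prev[j - 1] + 1
                    best = max(best, cur[j])
            prev = cur
        assert max_shared_window(a, b) == best

    def test_500mer_pair(self):
        rng = np.random.default_rng(77)
        a = "".join(rng.choice(list("ACGT"), size=500))
        b = a[200:260] + "".join(rng.choice(list("ACGT"), size=440))
        assert max_shared_window(a, b) >= 60


def exhaustive_rbs_score(window, model):
    best, best_s = 0, None
    for s in range(model.spacer_min, model.spacer_max + 1):
        end = len(window) - s
        if end <= 0:
            continue
        start = end - len(model.consensus)
        seg = window[max(0, start) : end]
        cons = model.consensus[max(0, -start) :]
        score = sum(x == y for x, y in zip(seg, cons))
        if best_s is None or score > best:
            best, best_s = score, s
    return best, best_s


class TestRbsScore:
    def test_perfect_consensus(self):
        model = RbsModel()
        window = "C" * 20 + "AGGAGG" + "C" * 6  # spacer 6
        assert rbs_score(window, model) == (6, 6)

    def test_all_c_scores_zero(self):
        assert rbs_score("C" * 30, RbsModel())[0] == 0

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, derandomize=True)
    def test_matches_placement_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        window = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 40))))
        model = RbsModel()
        assert rbs_score(window, model) == exhaustive_rbs_score(window, model)


def exhaustive_silent_best(tail, table, model):
    codons = [tail[i : i + 3] for i in range(0, len(tail), 3)]
    best = 0
    for combo in itertools.product(*(table.synonyms(c) for c in codons)):
        score, _ = rbs_score("".join(combo), model)
        best = max(best, score)
    return best


class TestSilentRbsBoost:
    def test_already_optimal_is_untouched(self, table):
        # Arg-Arg (AGG AGG) forms a perfect consensus; with a matching spacer
        # the tail is already maximal and must come back untouched
        model = RbsModel(spacer_min=6, spacer_max=6)
        tail = "GCT" + "AGG" + "AGG" + "ACT" + "CTA"  # consensus ends 6 nt before the end
        assert exhaustive_silent_best(tail, table, model) == rbs_score(tail, model)[0]
        mod, muts, before, after = silent_rbs_boost(tail, table, model)
        assert muts == [] and mod == tail and after == before

    def test_met_trp_tail_has_no_freedom(self, table):
        tail = "ATGTGGATGTGGATG"
        mod, muts, before, after = silent_rbs_boost(tail, table, model=RbsModel())
        assert mod == tail and muts == [] and after == before

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_exhaustive_silent_search(self, seed, table):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        sense = sorted(c for c, a in table.forward.items() if a != "*")
        tail = "".join(str(rng.choice(sense)) for _ in range(n))
        model = RbsModel()
        mod, muts, before, after = silent_rbs_boost(tail, table, model)
        assert translate(mod, table) == translate(tail, table)
        assert after >= before
        assert after == exhaustive_silent_best(tail, table, model)
        for pos, old, new in muts:
            assert tail[pos] == old and mod[pos] == new

    def test_eight_codon_tails(self, table):
        # longer tails, constructed from low-degeneracy residues to keep the
        # exhaustive oracle enumerable
        rng = np.random.default_rng(42)
        lowdeg = [c for c, a in sorted(table.forward.items()) if len(table.synonyms(c)) <= 4 and a != "*"]
        for _ in range(5):
            tail = "".join(str(rng.choice(lowdeg)) for _ in range(8))
            model = RbsModel()
            mod, _, before, after = silent_rbs_boost(tail, table, model)
            assert after == exhaustive_silent_best(tail, table, model)
            assert translate(mod, table) == translate(tail, table)


def brute_force_hairpins(seq, min_stem, loop_min, loop_max):
    hits = set()
    n = len(seq)
    for p5 in range(n):
        for p3 in range(p5 + 1, n):
            for k in range(min_stem, n):
                if p5 + k > p3 or p3 + k > n:
                    break
                loop = p3 - (p5 + k)
                if not (loop_min <= loop <= loop_max):
                    continue
                if all(seq[p5 + u] == _COMP[seq[p3 + k - 1 - u]] for u in range(k)):
                    # outward-maximal for this loop
                    ext = (
                        p5 - 1 >= 0
                        and p3 + k < n
                        and seq[p5 - 1] == _COMP[seq[p3 + k]]
                    )
                    inner_growth = (
                        p5 + k < p3 and loop - 2 >= loop_min
                        and seq[p5 + k] == _COMP[seq[p3 - 1]]
                    )
                    if not ext and not inner_growth:
                        hits.add((k, p5, p3))
    return hits


class TestHairpinScreen:
    def test_planted_hairpin_found(self):
        rng = np.random.default_rng(4)
        from scarless import revcomp

        stem = "".join(rng.choice(list("ACGT"), size=10))
        seq = stem + "TTTT" + str(revcomp(stem))
        hits = hairpin_screen(seq, min_stem=8, loop_min=3, loop_max=6)
        assert any(h[0] == 10 and h[1] == 0 and h[2] == 14 for h in hits)

    def test_homopolymer_has_none(self):
        assert hairpin_screen("A" * 20, min_stem=3, loop_min=3, loop_max=6) == []

    @pytest.mark.parametrize("seed", range(6))
    def test_against_brute_force(self, seed):
        rng = np.random.default_rng(200 + seed)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        mine = set(hairpin_screen(seq, min_stem=4, loop_min=3, loop_max=8))
        brute = brute_force_hairpins(seq, 4, 3, 8)
        # every brute-force maximal hairpin must be reported (the screen may
        # additionally list sub-maximal stems at shifted loop positions)
        assert brute <= mine
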