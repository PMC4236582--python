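# Methods

This note records the models, defaults and design choices behind the
package, in the order a designed cassette encounters them.

## Cassette geometry

A design replaces the genomic span between two unique 100 bp anchors
(HR1/HR2) with

```
HR1 · fragment5(…HR3₁) · [restoring5] · core · [restoring3] · fragment3(HR3₂…) · HR2
```

where `core = [spacer·terminator·spacer(·terminator·spacer)] · I-SceI
site · marker`. The two HR3 copies are byte-identical; the excision
step removes everything strictly between them (one HR3 copy plus the
core and any restoring fragment), so the resolved locus is exactly
`fragment5 + fragment3[len(HR3):]` — which is constructed to equal the
edited genome. This identity is what the scarless round-trip tests
assert byte-for-byte.

Mutation fragments carry ~200 bp of target sequence each (configurable
`fragment_len`); HR1/HR2 default to 100 bp (50 bp is accepted with a
warning: shorter arms integrate, just less reliably); HR3 defaults to
40 bp within enforced bounds [30, 50] — long enough for RecA pairing,
short enough to limit unproductive crossovers. Edits are centred in
HR3 with the tie toward the 5' side; deletions get the junction fusion
of the two flanks (20 bp + 20 bp at the default length); inserts ride
inside HR3 only when insert + 6 bp context per side fits within 50 bp,
otherwise they are placed immediately after HR3₂.

### Essential-gene variants

HR3 windows in coding sequence are snapped to codon boundaries (and the
default 40 trimmed to 39 bp) so restoring fragments stay in frame.

* `own_promoter` — `restoring5` is a recoded copy of the gene from the
  HR3 3' boundary to the stop codon, appended after HR3₁; the
  intermediate genome carries a complete ORF (edited protein) under the
  native promoter.
* `marker_promoter` — `restoring3` is a recoded copy from the start
  codon to the HR3 5' boundary, placed directly after the marker
  (default 0 nt junction gap, configurable; the published junction
  geometry is not printed, so the gap is flagged in reports). The
  intermediate ORF reads `recoded-prefix + HR3 + native rest` from the
  marker's promoter. Optionally, silent mutations in the last marker
  codons sculpt a Shine-Dalgarno consensus for this ORF (below).
* `wt_restoring` — HR3 is wild type, the mutations sit immediately 3'
  of HR3₂, and `restoring5` recodes the *wild-type* gene tail: the
  intermediate keeps the wild-type protein until resolution installs
  the edit. Used when gene function must persist to the last step
  (e.g. editing the recombination machinery itself).

Genes annotated on the minus strand are handled by designing in gene
orientation (the contig is reverse-complemented internally); the
emitted cassette is then in gene orientation and the integration
simulator accepts either orientation. Features spanning a replaced
region are dropped from derived genomes rather than remapped.

## Synonymous recoding

Objective: per codon, the synonym with maximal Hamming distance to the
original; ties broken by higher codon-usage frequency (if a usage table
is supplied), then lexicographically. Because the objective is
separable per codon, the greedy choice equals the global optimum — the
test suite checks this against exhaustive enumeration on short
fragments. Two constraints are then repaired by local re-choice,
scanning violations left to right and spiralling outward from the
middle codon of the offending window: no forbidden motif (either
strand; the I-SceI site is always forbidden in designs), and no shared
window with the original longer than `w_max`.

`w_max` defaults to 14 bp: comfortably below the 30 bp lower bound that
the HR3 length bounds treat as sufficient for RecA-mediated pairing.
Longest-common-substring queries run on a suffix automaton (O(n));
an O(n²) dynamic program locates windows during repair and serves as
the independent oracle in tests. Fragments whose single-codon families
(Met/Trp) fix an identical run longer than `w_max` raise an
infeasibility error naming the span.

## Crossover-position model

The second λ-Red crossover is modelled as uniform per base over
"eligible" bases: positions where donor and target are identical and
that lie in an identity run of at least `pairing_window` bp (default
20 bp, a conventional minimal efficient pairing length; configurable).
A crossover is *desired* iff it lies 3' of the last mutated base — any
other eligible crossover strands at least one mutation outside the
genome, and later resolution regenerates the wild type. The alignment
between donor arm and target is positional (the donor is designed from
the target); the edit itself is masked non-identical, and an insertion
contributes its full length of non-identity.

The mask covers the arm whose crossover decides the outcome: the 3'
arm for marker-promoter and all non-essential designs, the 5' arm
(reversed, so "3' of the mutation" keeps one meaning) for own-promoter
and wild-type-restoring designs. For wild-type-restoring designs the
arm carries no mutated base, so a sentinel non-identity base at the
restoring/HR3 boundary stands for the failure mode — any crossover
inside a *native* restoring fragment re-installs wild type.

`validate_design` computes P(desired) for the as-designed (recoded)
arm and, for comparison, the same arm with the restoring fragment left
native; designs below `p_threshold` (default 0.9) warn. Under the
default geometry recoded essential designs score ≈ 0.92–1.0 versus
≈ 0.45–0.65 for their native counterparts; the strict dominance is a
tested invariant. Uniformity per base is the minimal assumption — the
underlying argument is purely geometric — and colony counts or
cleavage efficiencies are deliberately not simulated.

## RBS scoring and silent boosting

`rbs_score` counts matches to a consensus (default `AGGAGG`) over all
placements whose spacer to the downstream start codon lies in a window
(default 4–13 nt), tie toward the smallest spacer; placements truncated
by the 5' edge score over the available bases, so short windows never
error. `silent_rbs_boost` maximises this score over all fully silent
variants of a CDS tail. For a fixed placement the consensus positions
partition by codon, so per-codon optimisation is exact, and maximising
over placements equals maximising over (variant, placement) pairs —
the test suite confirms equality with exhaustive silent-variant search
on tails up to 8 codons. Ties prefer the original codon, so an
already-optimal tail returns zero mutations.

## Secondary-structure screen

Spacer regions are screened with a maximal inverted-repeat search
(stem ≥ 8 bp, loop 3–10 nt by default) rather than thermodynamic
folding: the screen is a sequence-level surrogate that flags the
hairpins capable of pairing at all; free energies are out of scope.

## Primers and assembly

Melting temperatures: the Wallace 2/4 rule below 14 nt, nearest-
neighbour thermodynamics above (unified parameters, entropic
monovalent-salt correction, 50 mM Na⁺, 250 nM oligo — conventional
values, not protocol-specified; the tests re-derive one value by an
independent hand-computed parameter sum). Amplification primers grow
from 18 nt until they reach the 60 °C target, then the cooler primer is
extended until the pair agrees within 3 °C; every primer exact-matches
its template at its recorded coordinates. Assembly plans join
fragments via 20 bp terminal overlaps (published designs used
20–22 bp), count every overlap once in the total length, and refuse
junction sequences that recur anywhere in the assembled product.
Every default marker part ends in one shared 16 bp tail so a single
common reverse primer amplifies any selection cassette.

## Element library

The published construct descriptions give part names and composition
order, not sequences, so the default library ships deterministic
synthetic stand-ins under those names (terminators, spacers, markers,
backbone), each flagged provisional; the 18 bp canonical I-SceI
recognition sequence is an external-knowledge default. No operation's
correctness depends on these literal bases — only on the library
invariants (exactly one recognition site, intact marker ORFs, nonempty
terminators) — and a user library file overrides everything.

## Synthetic genomes and what passing tests show

The fixture generator emits genomes with clean CDS features (start
codon, sense codons, stop) on both strands, separated by 260–420 bp
intergenic stretches so that 100 bp arms and 200 bp fragments always
find context, at sizes (4 genes of 300–600 bp) chosen to keep the
randomized suites fast: the randomized acceptance suites run 100
round-trip designs and 50 matched probability comparisons in seconds.
These genomes reproduce the structural properties the designer relies
on — unique homology anchors, intact frames, no pre-existing
recognition site (unless planted for negative tests) — but not real
codon usage, GC skew, repeats, or regulatory context. Passing tests
therefore demonstrate the correctness of the design arithmetic and the
simulated recombination logic, not wet-lab efficiency on any real
genome; repetitive genomic neighbourhoods in particular can defeat the
unique-anchor assumption and are only detected, not resolved.

## Known limitations

* Circular topologies are not modelled: plasmid maps are emitted
  linearized, and origin-spanning features are unsupported.
* Integration requires exact full-length HR1/HR2 matches; mismatched
  homology is out of scope.
* Resolution is deterministic single-crossover between the HR3 copies;
  alternative resolutions via residual homology elsewhere are reported
  as warnings, not simulated.
* No promoter-strength or polar-effect prediction: "expression" of a
  restored ORF is represented structurally (contiguity + RBS score).
* No primer-dimer/off-target thermodynamics beyond exact-match
  multiplicity checks; no ΔG-based RBS strength calculation; no codon
  harmonization.
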