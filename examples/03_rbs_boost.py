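"""Sculpt a ribosome binding site out of silent marker mutations.

When a recoded essential-gene fragment is translated from the marker's
promoter, its expression can be too weak to keep the cell alive.  The
fix: silent mutations in the 3' end of the marker ORF that shape an
AGGAGG-like Shine-Dalgarno consensus just upstream of the downstream
start codon -- the marker protein is untouched.
"""

from scarless import RbsModel, build_selection_cassette, default_library, rbs_score, translate

library = default_library()
model = RbsModel()  # AGGAGG consensus, 4-13 nt spacer

plain = build_selection_cassette("cat_syn", n_terminators=2, library=library)
boosted = build_selection_cassette("cat_syn", n_terminators=2, library=library, rbs_boost_tail=8)

for name, core in (("plain", plain), ("boosted", boosted)):
    s, e = core.marker_orf
    tail = core.sequence[e - 24 : e]  # last 8 codons, ending right before the junction
    score, spacer = rbs_score(tail, model)
    print(f"{name:8s} marker tail {tail}  RBS score {score}/6 (spacer {spacer})")

s, e = plain.marker_orf
same = translate(plain.sequence[s:e]) == translate(
    boosted.sequence[boosted.marker_orf[0] : boosted.marker_orf[1]]
)
print(f"marker protein unchanged by the boost: {same}")
print(f"silent mutations applied: {[(p, a, b) for p, a, b in boosted.rbs_mutations]}")
# Score is matches to the 6 nt consensus at the best legal spacer; the
# boost finds the maximum achievable over all fully-silent tail variants.
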