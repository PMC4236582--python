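"""Amplification primers and Gibson-style template assembly.

Designs the cassette amplification primers (MF/MR, plus the MarkerF/
MarkerR pair for the selection core), plans the three-fragment template
plasmid assembly, and reruns the length arithmetic of a classic
overlap-assembled repair fragment.
"""

from scarless import (
    DesignConfig,
    EditSpec,
    FixtureSpec,
    assembly_length,
    default_library,
    design,
    generate_fixture,
    plan_assembly,
    scan_motif,
)

genome = generate_fixture(FixtureSpec(seed=11))
library = default_library()
config = DesignConfig()

pos = genome.features[1].region.start + 40
base = genome.contigs["chr"][pos]
edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1,
                payload="A" if base != "A" else "G")
cassette, frags, report = design(edit, genome, library, config)

print("primers (annealing Tm targets 60 C, pair within 3 C):")
for p in report.primers:
    print(f"  {p.name:8s} {p.sequence}  {p.tm_anneal:.1f} C")

plan = plan_assembly(
    [frags.fragment5_with_overlaps, cassette.core.sequence, frags.fragment3_with_overlaps],
    overlap_len=frags.overlap_len,
    backbone=library["pHA_syn"].seq,
    circular=True,
)
print(f"template assembly: {len(plan.fragments)} fragments, "
      f"{len(plan.junctions)} x {frags.overlap_len} bp junctions, "
      f"{plan.total_length} bp plasmid")
print("cassette present once in the assembled template:",
      len(scan_motif(plan.assembled, cassette.sequence)) == 1)

# length accounting for an overlap assembly: a 610 bp synthetic fragment
# from five segments (21 + 405 + 81 + 81 + 22) replacing a 555 bp span
# (405 + 81 + 69)
print("repair fragment:", assembly_length([21, 405, 81, 81, 22]), "bp")
print("replaced span:  ", assembly_length([405, 81, 69]), "bp")
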