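# scarless

Design automation for **scarless two-step genome editing** in bacteria
(*E. coli* / *Salmonella*-style recombineering with I-SceI
counter-selection). Given a genome, an edit, and a library of parts,
the package designs the full mutation cassette, verifies it by
simulating both editing steps in silico, and emits synthesis- and
bench-ready files.

## Who this is for

Strain engineers and molecular biologists building chromosomal point
mutations, insertions (e.g. epitope tags), deletions, and — the hard
case — edits in **essential genes**, where the reading frame must stay
intact through every step of the procedure.

## The method

A mutation cassette is the linear fragment

```
HR1 — 5' fragment (…HR3) — [recoded fragment] — TT·TT — I-SceI site — marker — [recoded fragment] — 3' fragment (HR3…) — HR2
```

* **HR1/HR2** (100 bp) target λ-Red-mediated integration of the whole
  cassette into the chromosome; the marker selects integrants.
* Two identical **HR3** windows (30–50 bp) span the desired edit. After
  I-SceI introduces a double-strand break at its 18 bp site, RecA-mediated
  recombination between the HR3 copies excises everything in between —
  terminators, site, marker — leaving only the edited locus. No scar.
* A **double transcription terminator** (TT·TT) upstream of the I-SceI
  site insulates it from read-through transcription, which otherwise
  blocks cleavage in highly transcribed loci.
* For essential genes, a **synonymously recoded** copy of part of the
  gene reconstitutes a complete ORF in the intermediate genome (under
  the gene's own promoter, under the marker's promoter, or restoring
  the wild type until the final step). Because every degenerate codon
  is changed, the recoded fragment cannot recombine with the
  chromosome.

The package also quantifies *why* the recoding matters. Model the
second integration crossover as uniform over every donor/target
identity base lying in a run of at least *w* bp (default *w* = 20):

```
P(desired) = (# eligible bases 3' of the last mutated base) / (# eligible bases)
```

Only those crossovers carry every mutation into the genome. Recoding
deletes the eligible bases 5' of the mutation and drives P(desired)
from ≈ 0.5 toward 1.

## Worked example

```python
from scarless import (DesignConfig, EditSpec, FixtureSpec, apply_edit,
                      cleave_and_resolve, default_library, design,
                      generate_fixture, integrate_in_silico)

genome  = generate_fixture(FixtureSpec(seed=11))       # toy genome, 4 CDS
library = default_library()                            # parts: terminators, I-SceI site, markers…
pos = genome.features[1].region.start + 40
edit = EditSpec(kind="point_mutation", start=pos + 1, end=pos + 1, payload="A")

cassette, fragments, report = design(edit, genome, library, DesignConfig())
final = cleave_and_resolve(integrate_in_silico(genome, cassette), library)
print(len(cassette.sequence), report.ok,
      final.contigs == apply_edit(genome, edit).contigs)
```

prints

```
1057 True True
```

— a 1057 bp cassette, every validation check green, and the resolved
genome byte-identical to the intended edit (the scarlessness
guarantee). `examples/` contains one narrative script per capability
(point mutation, essential-gene recoding, RBS boosting, the
integration-probability model, primers/assembly); each prints the
numbers it computes and says what they mean.

A thin CLI wraps the same functions:

```
scarless fixture --seed 3 --out toy.gb
scarless design point-mutation --genome toy.gb --start 1072 --end 1072 --payload A --out out/
scarless simulate --genome toy.gb --edit-json edit.json --out sim/
```

## Layout

```
src/scarless/
  seq_core.py   sequences, coordinates, codon table, element library
  recode.py     synonymous recoding, RBS scoring/boosting, hairpin screen
  homology.py   crossover-position model; in-silico integrate/cleave/resolve
  design.py     EditSpec -> MutationCassette + template fragments + report
  primers.py    Tm, amplification primers, Gibson-style assembly plans
  io.py         GenBank/FASTA/TSV/JSON readers and writers
  fixtures.py   deterministic toy-genome generator
  cli.py        click command-line layer
```

See `docs/methods.md` for the model assumptions, defaults, and known
limitations.
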