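# tolorf

Design and audit of scrambled multi-reporter chimeric open reading frames.

## The problem

Reporter proteins (fluorescent proteins, luciferases) and modifier proteins
(recombinases such as Cre) are foreign to the mouse, so cells engineered to
express them risk T-cell-mediated rejection. A transgenic line that
constitutively expresses *all* the peptides of a reporter panel — without
expressing any functional reporter — induces central tolerance: thymocytes
recognizing those peptides are deleted, and transferred reporter-bearing
cells engraft cleanly.

`tolorf` builds such a "tolerogenic" transgene. Given a panel of parental
coding sequences, it:

1. **splits** every gene on a codon boundary into an N- and a C-terminal
   fragment (no parent is expressed intact);
2. **patches** each split with the parental region of *h* codons on either
   side of the breakpoint, so peptides straddling the split are not lost;
3. **scrambles** fragments and patches under the constraint that no two
   consecutive elements share a parent (no partial reconstitution);
4. **assembles** one single ORF — start codon, codon-aligned elements, a
   C-terminal control epitope (HPV16 E7 49–57, `RAHYNIVTF`, by default) and
   one terminal stop;
5. **audits** the result: it proves, by exhaustive scan, that every parental
   peptide of length *k* (default 8 ≤ k ≤ 11, the MHC class I range) occurs
   contiguously in the chimeric protein.

The central guarantee is combinatorial: a length-*k* peptide destroyed by a
split at codon *s* must start in `[s−k+1, s−1]`, so it lies entirely within
the patch `[s−h, s+h)` whenever `h ≥ k−1`. With the defaults
(`k_max = 11 ⇒ h = 10`) each patch is 60 nt of parental context and coverage
is complete for all k ≤ 11. Because every element is codon-aligned, junctions
can never create a novel codon — in particular never a premature stop — so
the full-length protein is always translatable.

## Worked example

```python
from tolorf import DesignConfig, design, tol_scale_panel

panel = tol_scale_panel(seed=1)          # 8 synthetic genes, 218-550 codons
construct, coverage, report = design(panel, DesignConfig(seed=1))

print(len(construct.elements))           # 25   (16 fragments + 8 patches + epitope)
print(len(construct.nt))                 # 7320 (nucleotides, single ORF)
print(len(construct.protein))            # 2439 (amino acids)
print(construct.protein[-9:])            # RAHYNIVTF (control epitope, C-terminal)
print(coverage.complete)                 # True (every parental 8..11-mer preserved)
```

Eight genes give 16 fragments; each of the 8 patches is exactly 60 nt; the
assembled ORF is a single-start, single-stop sequence in the several-kilobase
range whose protein ends with the control epitope, and the coverage report
confirms that no parental MHC-I-length peptide was lost.

The same pipeline from the shell:

```
tolorf synth -o panel.fasta --n-genes 8 --codons 240 --seed 1
tolorf design panel.fasta -o out/ --seed 1
tolorf audit panel.fasta out/construct.fasta -o audit/
```

`design` writes the construct (FASTA, GenBank, GFF3 — one feature per
element with parent-of-origin coordinates), a design report, the coverage
audit (TSV + JSON), a predictor-ready peptide list and a JSON run manifest.
It exits non-zero if any parental k-mer is missing (override with
`--allow-incomplete`). All outputs are byte-reproducible from the input and
the seed.

## Scope

The tool designs and audits the construct and exports peptide lists for
external MHC-binding predictors. It does not perform binding prediction,
codon-usage optimization, or any downstream molecular-biology steps.
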