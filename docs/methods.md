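# Methods

## The design procedure

Input is a panel of parental coding sequences, each a complete ORF (ATG,
in-frame sense codons, one terminal stop). Validation is strict: ambiguity
codes are rejected outright rather than translated, because the design must
be deterministic at nucleotide level; internal stops, missing starts,
frameshifted lengths and duplicate ids are each a distinct error naming the
offending record. All internal coordinates are 0-based half-open; only the
GFF3/GenBank writers convert to 1-based inclusive.

For each gene of protein length *L* (stop excluded):

* **Split.** The stop-stripped CDS is cut at codon *s* into an N-fragment
  `[0, s)` and a C-fragment `[s, L)`. The default `s = floor(L/2)` is a
  design choice — the midpoint disrupts both halves of the protein
  symmetrically — and can be overridden per gene.
* **Patch.** The parental slice `[max(0, s−h), min(L, s+h))` is extracted,
  with `h = k_max − 1` codons by default (10 codons each side, 60 nt total
  at `k_max = 11`). Near a terminus the span is clamped; the clamped context
  does not exist in the parent either, so truncation cannot lose a parental
  peptide (it is logged, not fatal).
* **Scramble.** The 2N fragments and N patches are shuffled by a seeded
  uniform shuffle with rejection until no two consecutive elements share a
  parent. Rejection sampling keeps the distribution uniform over valid
  permutations; infeasibility is detected immediately by pigeonhole (a
  parent owning more than `ceil(n/2)` of the n elements) and otherwise after
  `max_shuffle_attempts` (default 10 000) rejections. Patches take part in
  the shuffle as ordinary elements; the adjacency constraint then also
  prevents a patch from seamlessly extending its own gene's fragment. A
  weaker `minimal` mode (only forbidding a gene's N-half immediately before
  its own C-half) is available but not the default.
* **Assemble.** Elements are concatenated; the control epitope is appended
  last so tolerance at the extreme C-terminus — and hence full-length
  translation — can be probed experimentally; a configurable stop codon
  (default TAA) terminates the ORF. An ATG is prepended only when the first
  element does not already begin with one. Because every element is a whole
  number of codons, the construct's codon multiset is exactly the union of
  the element codons plus this bookkeeping — junctions cannot create novel
  codons, so a premature stop is impossible (asserted, not handled). When a
  start codon is prepended, the boundary after it is recorded as a junction
  like any element boundary, so the audit can attribute novel peptides
  arising there.

## The coverage guarantee

A length-*k* peptide of a parent is destroyed by a split at *s* only if it
straddles *s*, i.e. starts in `[s−k+1, s−1]`; such a window lies inside
`[s−h, s+h)` whenever `h ≥ k−1`. The auditor does not trust this argument:
it scans every parent, every `k ∈ [k_min, k_max]`, every position, and looks
the window up in the construct protein. Coverage is judged on amino acids —
epitopes are peptides — and nucleotide-level identity is neither required
nor claimed. The test suite proves both directions on a grid of gene
lengths, split positions and half-widths against an independent plain
substring scan: complete whenever `h ≥ k−1`, and incomplete with every miss
straddling the split whenever `h < k−1` with at least `k−1` residues on both
flanks.

Defaults `k_min = 8, k_max = 11` cover MHC class I ligand lengths. An MHC
class II audit (k up to 15) can be requested, but patches sized for
`k_max = 11` will not guarantee it; the auditor reports such misses rather
than silencing them, and the `design` command then exits non-zero unless
`--allow-incomplete` is given.

## Audits beyond coverage

* **Junctional peptides** — construct k-mers absent from every parent —
  are enumerated per k as a set difference. They are reported, not
  forbidden: they too are expressed (hence tolerized) wherever the construct
  is expressed. K-mers wholly inside the control epitope fall in this set by
  definition, since the epitope has no parent gene.
* **Longest parental run**, the longest substring of a parent protein
  surviving in the construct, proxies how thoroughly function was disrupted.
  It is computed with a suffix automaton over the construct protein
  (linear-time streaming match) and validated against a quadratic
  dynamic-programming oracle in the tests. Under strict adjacency it equals
  the parent's largest single element.
* **Peptide export** writes the construct's unique k-mers, uppercase, one
  per line, lexicographically sorted — the plain list dialect MHC-binding
  predictors accept. Prediction itself is out of scope.

## Reverse translation

When the control epitope is given only as amino acids, its codons come from
a fixed one-codon-per-residue table (part of the tool's stable contract;
`translate(reverse_translate(x)) == x` always). The table makes no
codon-usage claims.

## Synthetic panels

The generator emits ORFs of `ATG + (codons − 1)` random sense codons `+
stop`, drawing from the 61 sense codons so internal stops are impossible by
construction; an optional GC bias reweights the draw. The eight-gene
"reporter-scale" panel uses protein lengths 233, 229, 225, 218, 233, 239
(fluorescent-protein-sized), 550 (luciferase-sized) and 343 codons
(recombinase-sized modifier) — the size profile of a typical
seven-reporter-plus-one-modifier cassette. These are synthetic stand-ins:
random codons share no homology with real reporters, so passing tests
demonstrate the combinatorial and coordinate logic of the method, not
behaviour on biologically realistic sequence composition (which the method
does not depend on — its guarantees are position arithmetic, valid for any
sequence). Real parental CDSs are supplied by the user as FASTA.

## Numerical and degenerate-input choices

* Determinism everywhere: `(genes, config)` fully determines every output
  byte (GenBank's mandatory date field is pinned for this reason); the run
  manifest records the seed, input digests and real timestamps.
* A seed left unset is drawn from system entropy once and recorded in the
  design report, never silently defaulted.
* Splits may sit anywhere in `[1, L−1]`; the degenerate one-element
  assembly (a full unsplit gene) is supported as a pass-through and embeds
  the parent protein intact.
* Duplicate missing peptides occurring at several parent positions are
  reported once per distinct peptide with all source positions attached;
  position counts (not distinct peptides) are what `preserved + missing =
  total` conserves.
* An audited construct supplied externally is wrapped as a single-element
  ORF; it must itself pass full ORF validation.

## Problem sizes

The default test suite and the acceptance script run on the eight-gene
panel (~2.4 kaa construct) and on grids of 15–300-codon genes — sizes at
which every brute-force oracle (substring scan, quadratic DP, exhaustive
permutation enumeration) is exact and fast. Nothing in the implementation
is size-limited beyond memory; the suffix automaton and set-based k-mer
audits scale linearly in construct length.

## Known limitations

* Exactly two fragments per gene; no multi-way splitting, introns, 2A or
  IRES architectures.
* No codon-usage optimization or GenBank vector-map input.
* Strand is always `+`: constructs are synthesized, not mined from genomes.
* The epitope-coverage guarantee is exact for the amino-acid k-mer range it
  is configured for and says nothing about longer (e.g. MHC II) peptides
  unless the patch width is raised accordingly.
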