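# Methods

## The editing model

`mitostop` designs double-stranded-DNA cytosine base editors (DdCBEs)
that knock out mitochondrial protein-coding genes by installing
premature stop codons. A DdCBE is a pair of TALE proteins binding
opposite strands of mtDNA, each fused to one half of a split
double-stranded-DNA cytosine deaminase; where the two halves meet over
the spacer between the binding sites, C:G pairs are converted to T:A.
Three facts of mitochondrial biology shape the search space:

1. **Genetic code.** Vertebrate mitochondria translate with NCBI table
   2: TGA encodes tryptophan and the stop set is {TAA, TAG, AGA, AGG}.
   A Trp TGA codon is therefore one G→A edit away from a TAA stop.
2. **Sequence context.** The deaminase edits a C only when it is
   immediately preceded by T on its own strand (5′-TC-3′; the relaxed
   `HC` motif of engineered variants is available as an option).
   Because the edit converts C to T, runs of consecutive Cs can be
   edited in **cascade**: editing the 5′ C creates the TC context for
   the next one. This is how a GTC·CAA dicodon becomes GTT·TAA — a
   stop at the Gln codon with a silent Val bystander.
3. **Complementarity.** The template-strand triplet of any TGA codon is
   5′-TCA-3′, so the C opposite the G always carries a valid TC
   context. Every in-frame TGA is editable; this "TGA theorem" is
   exercised exhaustively in the tests. Conversely TGG→TAG is never
   reachable (the middle-position C on the template strand is preceded
   by C), although TGG→TAA is reachable through a two-step cascade when
   the next codon begins with A — the intermediate TGG→TGA change is
   itself synonymous. The enumerator reports such routes with their
   origin codon so users can restrict to classical TGA targets.

## Candidate enumeration

For each gene the coding sequence is extracted (reverse-complemented
for heavy-strand genes; origin-spanning features are handled on the
circular coordinate ring) and the cascade closure of editable Cs is
computed on both strands, reading one context base beyond each CDS
boundary from the genome. Cascade chains are bounded at 4 consecutive
Cs and plans at 4 total edits — one beyond the deepest case used in
practice, keeping enumeration finite. For every combination of
closure edits inside one codon, plus the prerequisite edits their
contexts require, the CDS is mutated in silico and translated; plans
whose codon lands in the stop set are kept. Every other changed codon
is classified (synonymous / missense / nonsense / stop-loss); the
default policy discards plans with any non-synonymous bystander.
Plans touching the start codon or the natural stop, and codons
containing N, are excluded. Candidates are deduplicated on (gene,
stop codon, primary edit positions) and ordered by stop codon index,
then bystander count. The test suite proves the enumerator equal to a
brute-force oracle that applies every reachable edit subset
sequentially and translates with Biopython.

## TALE pair design

Windows are placed around each candidate under the geometry the
editors tolerate: binding sites of `tale_length` (default 16 nt,
configurable 14–18), a spacer of 14–20 bp containing every primary
edit at least `min_edge_offset` (default 4) nt from both edges
(editing efficiency drops at spacer edges), and by default a T
immediately 5′ of each binding site (the canonical TALE "T0"
requirement; relax with `--no-t0` — on A/T-poor targets T0 is often
the binding constraint that decides feasibility). Two placements per
strand are chosen deterministically — the shortest-feasible (L1, H1)
and the most-bracketing distinct (L2, H2), with all four combinations
inside the spacer bounds — and expanded into the eight pair
configurations: four TALE pairings × two split orientations, each
with exactly one N-terminal and one C-terminal deaminase half.

The recommended split orientation follows a single empirical rule:
the C-terminal half goes on the TALE bound to the strand *opposite*
the edited C. This reproduces the observed optima for light-strand
genes (edited C on the heavy strand), for the heavy-strand gene
(edited C on the light strand), and for the coding-strand dicodon
route.

Each spacer is profiled by re-running the cascade closure over both
of its strands: every editable C is labelled intended, synonymous,
missense/nonsense, or noncoding (outside the CDS; counted as
non-synonymous — conservative, since the consequence of editing
tRNA/rRNA/regulatory positions is unknown). Designs are ranked by
(non-synonymous editable bystanders, total editable Cs, stop codon
index, spacer length), a stable deterministic sort favouring spacers
with a single correctly-contexted cytosine.

## Heteroplasmy and off-target scoring

Scoring consumes per-base count tables (`contig pos ref A C G T`,
1-based positions), the standard digest of `samtools mpileup` output.
All frequencies are percentages of read depth. On-target heteroplasmy
is the variant allele frequency of the stop-creating edit, with
cascade prerequisites reported alongside. Genome-wide C:G→T:A
variants are filtered by two rules, order-independent by
construction: depth must exceed 30 in *every* sample (configurable),
and variants at ≥ 45% in any control are treated as strain
differences rather than induced edits. Each call carries its
deaminase context (TC / TCC / other, read on the strand carrying the
edited C — for a reference G>A the context is evaluated on the
complement).

Editor pairs are compared with the penalty score

    ( Σ f>5% f  +  25 · Σ f>20% f ) / (on-target %)²

which is zero when no off-target exceeds 5%, weights high-frequency
off-targets 26-fold, and rewards on-target efficiency quadratically;
thresholds are strict inequalities and frequencies above 20%
contribute to both sums. The mtDNA-wide burden is additionally
summarized as the mean C:G→T:A frequency over *all* C/G reference
positions (not only called variants) outside the on-target spacer
± 5 bp, and as its fold change over an untreated control.

## Synthetic data

The generator emulates the structure of the mouse mtDNA coding
complement, not its sequence: 13 ORFs with planted target codons
(earliest Trp-TGA at codon 6, latest at 146, one heavy-strand gene,
one GTC-CAA dicodon gene at codons 90–91), random codons drawn from a
pool excluding the stop set and TGA so planted targets are unique,
ATG starts and TAA stops, and uniform-random intergenic spacers.
Count tables are sampled binomially at a stated depth with 0.02%
background C:G→T:A heteroplasmy at every C/G site (the level reported
for untreated cultured cells), 50% planted on-target heteroplasmy
(mid-range of reported editor performance) and, for fold-change
exercises, a 0.29% treated off-target mean (the upper end of the
reported range, giving the worked 14.5-fold example). Everything is
reproducible bit-exactly from an explicit seed; no global random
state is touched.

What the synthetic data does **not** emulate: real mtDNA base
composition and strand asymmetry, TALE binding-affinity differences,
position-dependent editing efficiency within the spacer, alignment
artifacts, strand-biased sequencing error, or NUMT contamination.
Passing tests therefore demonstrate correctness of the combinatorics,
the context model and the estimators — not predictions of wet-lab
editing efficiency, which this package deliberately measures rather
than models.

## Numerical and design choices

* Coordinates are 0-based half-open internally; all reports use the
  1-based `m.N` convention. The light strand is mapped to the
  reference (+) strand (configurable, since L/H conventions vary).
* Frequencies are percent throughout; penalty thresholds strict.
* Problem sizes in the test suite and acceptance script (10⁴ random
  ORFs of 25 codons for the TGA theorem, 1,000 random targets for
  spacer geometry, oracle equivalence on CDSs ≤ 300 nt, depth 10⁴
  count tables) were chosen to make binomial standard errors small
  relative to the tolerances while keeping a default run fast.
* Ties in ranking preserve input order (stable sort); window search
  order is fixed, so designs are reproducible run to run.
* Degenerate inputs: zero read depth raises an error rather than
  returning 0%; a zero control mean reports an infinite fold change
  explicitly; N-containing codons and windows are excluded from
  enumeration and placement rather than guessed at.

## Mouse reference checks

The canonical targets of the package are the 13 ORFs of the mouse
mtDNA reference NC_005089 (GRCm38 ChrM). The reference sequence is
not redistributed; `mitostop fetch-reference` downloads it once and
the reference-dependent tests (earliest/latest truncation codons,
the Atp6 m.8069 site, the Nd4l dicodon, 13/13 gene coverage) run
against that file. Without it those tests fail with instructions;
all synthetic-data tests are self-contained.

## Known limitations

* Editing efficiency is not predicted; the ranking is a specificity
  heuristic, not an activity model.
* The off-target analysis is mtDNA-wide only; nuclear off-target
  assessment needs genome-scale variant calling outside this scope.
* The L1/L2/H1/H2 placement convention (shortest/most-bracketing
  feasible) is a declared convention, one of several defensible ways
  to pick two windows per strand.
* tRNA/rRNA genes and regulatory regions are not annotated; spacer
  bystanders outside CDSs are flagged but not interpreted.
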