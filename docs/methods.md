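# Methods

This note records the models implemented in `polyarch`, the numerical
and design choices made where more than one convention exists, and what
the synthetic test genome does and does not establish about behaviour
on real data.

## The genome model

The package targets assemblies of interspecific hybrid polyploids in
which (i) every region descends from one of two progenitor species
diverged at roughly the percent level; (ii) homologous chromosome
copies vary in number and some copies are *exactly* identical
(identical by descent through a shared ancestor), so an assembler
represents them once — "collapsed" haplotypes; and (iii) some
chromosomes are interspecific recombinants switching progenitor at
breakpoints. All coordinates are 0-based half-open; conversions to
1-based conventions (GFF3) happen only in the readers.

## Synthetic generator (`polyarch.simulate`)

`simulate_progenitors` draws a uniform-random ancestor and derives the
second progenitor by independent substitutions at a given per-site rate
(default fixture: 0.012, matching the synonymous divergence used in the
dating module). Substitution-only divergence keeps oracle read
placements exact; there is no indel model. `build_hybrid_assembly`
emits one sequence per unique copy and one per IBD group (the collapsed
representation); private mutations are drawn once per emitted sequence
(default 0.01/site), so IBD copies are byte-identical by construction
while distinct copies are distinguishable by k = 27 painting and unique
read placement.

`simulate_reads` draws reads per *underlying* copy, so a region
collapsed from c copies receives ≈ c × coverage. Fragment start
positions are uniform over [−(read_len − 1), L) and reads are clipped
at sequence ends; this keeps expected depth uniform along the
chromosome. On a 200 kb test chromosome the alternative (starts
confined to [0, L − read_len]) depresses depth over a ±15 kb margin —
about 10% of all windows — whereas on a full-size genome the same edge
effect is negligible; the clipped model reproduces the large-genome
behaviour at fixture scale. Reads are forward-strand and error-free by
default (an error rate is supported); the oracle PAF places each read
at its true span with a `tp:A:P` primary tag. Painting and dosage are
strand-insensitive (canonical k-mers, base-overlap depth), so
single-strand simulation loses no test power.

Default fixture scale: 3 basic chromosomes × 200 kb; copies spanning
dosage ×1–×4 including IBD groups of 2, 3 and 4 and one recombinant
with a mid-chromosome breakpoint; 15 kb reads at 30× per copy. This
runs in seconds on one CPU while leaving ≥ 100 single-copy windows for
the depth normaliser (below).

`simulate_selfed_progeny` unites two gametes per progeny, each a
uniform draw of ploidy/2 copies without replacement (random bivalent
pairing, no double reduction); `simulate_ortholog_pairs` builds CDS
pairs from codon families whose synonymous-site count is exactly one
per codon (GGN, GCN, CCN, ACN, GTN), mutating third positions with
probability p = ¾(1 − e^(−4d/3)) so the Jukes–Cantor-corrected Ks has
expectation d.

What the generator does **not** emulate: sequencing-error profiles,
chimeric or reverse-strand reads, indels, structural variation,
repeats, aneuploidy. Passing tests therefore demonstrate correctness of
the algorithms under the stated model, not robustness to real-data
artefacts; on real data the alignment, repeat annotation and pileup
inputs should come from the standard external tools.

## Progenitor painting (`polyarch.painting`)

K-mers are canonical (lexicographic minimum of the k-mer and its
reverse complement, computed on 2-bit integer codes where the numeric
and lexicographic orders coincide), since assembly strand is arbitrary.
A k-mer is diagnostic for a progenitor if its canonical form occurs in
that genome and never in the other; k-mers touching non-ACGT symbols
are skipped. k must be odd (unambiguous canonicalisation) and ≤ 31 so
codes fit 64-bit integers; the default is 27.

Windows (default 10 kb, shared with the depth analysis) count
diagnostic hits by k-mer start position; the label is the argmax of the
two counts when the larger reaches `min_hits` (default 2) and the
counts differ, else unassigned. Segmentation merges same-label runs,
absorbs runs of ≤ `max_gap` (default 2) unassigned windows flanked by
one label, and drops blocks shorter than `min_block` (default 20 kb).
These four defaults are robustness choices on the fixture, exposed as
configuration; real-repeat-derived diagnostic sequence is generalised
here to any diagnostic k-mer (on synthetic data all diagnostic k-mers
are substitution-derived).

## Dosage classification (`polyarch.dosage`)

Window depth is mean aligned-base coverage (total aligned bases
overlapping the window over window length) from primary PAF records
only (`tp:A:P` or untagged); read-start counting was rejected because
the bins are calibrated on coverage ratios. Classes come from
median-normalised relative depth with half-open bins
[0, 0.25) → ×0, [0.25, 1.4) → ×1, [1.4, 2.3) → ×2, [2.3, 3.5) → ×3,
[3.5, 5.0] → ×4, and > 5 masked as repetitive. Bin closure at the
boundaries is a documented convention (the printed ranges do not state
it); boundary behaviour is tested explicitly.

**Normaliser.** The estimand is single-copy depth. The plain
genome-wide median overestimates it whenever a sizeable minority of
windows is collapsed: the median then sits in the upper tail of the
single-copy peak and pushes true ×4 windows against the 3.5 edge (on
the fixture, bias ≈ +11%, dropping window accuracy from ~97% to ~93%).
`estimate_single_copy_depth` therefore refines the median once: windows
falling in the ×1 bin relative to the initial median are kept and their
median returned. This is the programmatic analogue of anchoring the
bins on the depth-histogram peak with a fixed constant, which is how
the bins are calibrated on real data; `classify_depth` still accepts a
plain median or an explicit `median_override`.

Masking: a window is repeat-masked when ≥ 95% of bases are
repeat-masked or > 90% retrotransposon-annotated; outlier masking
excludes windows outside the inclusive 10th–90th percentile depth range
of the not-repeat-masked windows. Percentile exclusion belongs to the
*collapse validation* step (coverage adequacy), not to the ×0–4
classification, and the pipeline wires it accordingly. The normalising
median is computed after repeat masking and before outlier masking.

Collapse validation lays each primary read gaplessly over its target
span (substitution-only model; indel-containing alignments are
rejected) and flags sites where the second-most-common base strictly
exceeds 20% of coverage, reporting flagged sites as run-length
intervals; zero-coverage regions are reported unevaluable. At 60×
combined coverage a wrongly merged pair of ~1%-diverged copies yields
~50% alternate-allele sites, far above threshold, while truly identical
IBD copies yield none — both constructions are tested. On the
160-window fixture, per-window depth CV is ~8–12% (15 kb reads over
10 kb windows), so a small fraction of ×2/×4 windows unavoidably cross
the narrow 2.3/3.5 bin edges; accuracy statements are therefore
evaluated over several hundred pooled windows.

## Divergence (`polyarch.divergence`)

Peptide pairs are aligned globally with BLOSUM62 and affine gap
penalties (open 10, extend 1); among co-optimal alignments the first
reported is used deterministically. PID2 counts exact-match columns
over all columns including terminal gaps; `X` never matches.
Back-translation expands each peptide column to a codon column
(`---` for gaps), trims terminal stops, and verifies translation,
naming the first offending codon on mismatch.

Ka/Ks is Nei–Gojobori (1986): fractional synonymous sites per codon
(each of the nine single-base changes weighs 1/3 of a site), S and N
averaged over the two sequences; observed differences counted over all
minimal mutation pathways with equal weights, pathways through stop
codons excluded (with an equal-weight fallback over all pathways when
every pathway hits a stop); Jukes–Cantor correction, with p ≥ 3/4
reported as missing (NaN) rather than raised. Single-base changes that
*create* a stop codon count as nonsynonymous in site counting; gapped
or ambiguous codon columns are excluded. NG86 was chosen over the
LWL-family estimators because it is fully specified and testable
against a brute-force counting oracle; for data diverged ~1% at
synonymous sites the estimator family makes no practical difference,
and correctness is asserted by parameter recovery rather than
estimator-for-estimator identity.

The Ks peak is the midpoint of the modal histogram bin (default width
0.002, bins centred on multiples of the width so concentrated samples
report their value exactly; ties resolve to the lowest bin; ≥ 30 finite
values required). Kernel density estimation was rejected as an
unnecessary bandwidth choice. Dating is T = Ks_peak/(2µ) with µ in
substitutions/site/year.

## Architecture statistics (`polyarch.stats`)

Intersection uses interval trees with BEDtools semantics and is checked
against a quadratic all-pairs oracle. Feature assignment labels a
feature by the block class covering the strict plurality of its length
(ties and no overlap → unassigned); an any-overlap rule is available.
Fisher's exact test takes the two-sided p from the hypergeometric
distribution (tables with probability ≤ observed); the odds ratio is
the cross-product ad/bc with a 0.5 Haldane correction on zero cells
(flagged), and fold enrichment compares the first-row rate with the
overall first-column rate. Raw p-values are reported (one test per
question); a Benjamini–Hochberg helper exists but is off by default.
The collapsed fraction is classified length at class ≥ 2 over all
integer-classified length.

## Pedigree genetics (`polyarch.pedigree`)

Inbreeding uses Wright's path counting: over common ancestors A and
pairs of ancestor paths from sire and dam meeting only at A,
F = Σ (½)^(n₁+n₂+1)(1 + F_A), with F memoised and founders at 0; a
recursive-kinship oracle validates it in tests. Pedigrees are
3-column TSV (individual, sire, dam; `0` = founder), validated acyclic.

Segregation ratios use exact rational arithmetic: with random bivalent
pairing the null-gamete frequency for dose d in a p-copy homology group
is hypergeometric, q = C(p−d, p/2)/C(p, p/2); selfed absence is q², and
the presence:absence ratio (1−q²)/q² prints literally as `3:1`
(simplex, any even ploidy) or `143:1` (triplex, p = 10). Double
reduction is deliberately excluded: it would make the ratio depend on a
quadrivalent-formation parameter, whereas the bivalent model is exact
and matches the textbook ratios. An exhaustive gamete-enumeration
oracle must agree with the closed form for every dose at all ploidies
≤ 12. Doses above p/2 give q = 0 (marker in every gamete); the ratio is
then reported as undefined (`all-present`) rather than infinite.

## Problem sizes and determinism

All stochastic components take an integer seed and are byte-stable
across runs. The test suite runs the fixture at 3 × 200 kb with ~6,000
reads; dosage recovery is scored over four pooled fixture replicates
(~640 windows); Ks parameter recovery uses 2,000 pairs × 1,000 codons.
These sizes keep the full suite to a few minutes on one CPU while
leaving the statistical margins described above.

## Known limitations

- Two progenitors only; no probabilistic/HMM painting.
- Substitution-only pileup; real-data collapse validation should use an
  external indel-aware pileup.
- PAF is the only alignment format consumed (convert BAM with
  `paftools`/`minimap2` conventions upstream).
- The k-mer index is in-memory (fine to tens of megabases per genome;
  genome-scale painting would need a disk-backed counter).
- No confidence intervals on the divergence date; the Ks peak is a
  point estimate.
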