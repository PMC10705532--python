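# Methods

## Problem and approach

The two common alpha-thalassemia deletions arise by non-allelic homologous
recombination between nearly identical repeat pairs in the alpha-globin
locus: Z boxes ~3.8 kb apart (the rightward -α3.7 deletion) and X boxes
~4.2 kb apart (the leftward -α4.2 deletion). Reads from the locus misalign
because the repeats are as long as the reads, so `svkg` never aligns:
genotype signal is read off raw-read k-mer counts, and a supervised
classifier trained purely on simulated reads maps count vectors to one of
the six diploid genotypes over {wild type, del3.7, del4.2}.

The pipeline is: haplotype panel → deletion alleles → diploid genomes →
simulated paired-end reads → k-mer feature vectors → random forest.
Each stage is importable on its own and the whole chain is a deterministic
function of a master seed.

## Synthetic haplotype panel

Real assembled haplotypes can be supplied as FASTA plus a box-coordinate
table, but the default panel is generated. The generator does not imitate
the locus base-by-base; it reproduces the architectural features the method
actually senses:

- a 40 kb region; all coordinates 0-based, half-open, forward strand;
- two identical 3.9 kb gene cassettes, with the X-box pair (300 bp, 100%
  identity) flanking the second copy exactly, so collapsing the X pair
  removes precisely one cassette's worth of duplicated sequence
  (4,200 bp) — a pure copy-number change with no junction-specific or
  private k-mers. The first cassette copy lies upstream of both deletion
  spans, so it survives every genotype and anchors the depth contrast;
- a Z-box pair (300 bp, 97% identity) whose collapse removes 3,800 bp
  crossing ~3 kb of single-copy sequence. The Z paralogous variants and
  the unique span give the rightward deletion presence/absence k-mers,
  making it detectable at any practical coverage;
- a decayed pseudogene paralog of the cassette (98% identity) further
  upstream, which flattens the leftward deletion's depth contrast the way
  additional paralogs do in segmentally duplicated loci;
- inter-haplotype diversity as i.i.d. substitutions at `snp_rate`
  (default 1e-3/bp — a stand-in, exposed in the blueprint) relative to a
  common ancestor; no indels between haplotypes, so box coordinates are
  shared panel-wide (per-haplotype coordinates are supported via the box
  table when loading real assemblies).

This division of labour — leftward deletion detectable only through read
depth, rightward deletion carrying sequence-level markers — makes the
panel's hardest decision "does an otherwise wild-type sample carry one
leftward allele?", which is where genotyping errors concentrate at low
coverage. With 14 haplotypes the defaults produce held-out accuracies of
~0.99 at 10x and ~1.00 at 30-40x, with the residual 10x errors almost all
confusing wild type with the heterozygous leftward deletion.

What the generator does not model: GC-dependent or otherwise non-uniform
coverage, indel and adapter artefacts, platform error profiles, background
genome k-mer collisions (an optional background-FASTA filter can drop
non-unique keys), structural polymorphism among templates beyond the two
deletions, and library-to-library depth overdispersion. Passing tests on
this panel therefore validate the method's signal model and code paths,
not the error rate of any particular real cohort.

## Deletions and diploid genomes

A deletion is specified by a box pair and a breakpoint offset into the box
(default: the midpoint; any offset in [0, box length] yields the same
deletion size, which is the genotype-discriminating quantity). Applying it
keeps the prefix up to `copy1.start + offset` and the suffix from
`copy2.start + offset`, shortening the haplotype by exactly
`copy2.start − copy1.start` and leaving a hybrid box (copy 1's 5' side,
copy 2's 3' side). Box pairs that lose a copy are dropped from the result,
so re-applying a deletion — or stacking the second deletion on an allele
that has lost the other pair's copy — is rejected; exactly six diploid
classes exist. `build_genotype_panel` enumerates ordered template pairs ×
six genotypes (7 × 7 × 6 = 294 genomes for a seven-template panel).
Reciprocal duplication products (anti-3.7) are out of scope.

## Read simulation

Paired-end fragments are drawn uniformly per haplotype (half of the pairs
from each), lengths Normal(insert_mean, insert_sd) truncated to
[read length, haplotype length] by redrawing, strand Bernoulli(1/2), and
every base substituted independently at `error_rate`. Defaults: 150 bp
reads, 400 ± 50 bp inserts, 0.2% substitutions, constant Q30 qualities —
typical 30x-era short-read WGS geometry. Pair count is
`round(coverage × mean haplotype length / (2 × read_length))`, i.e. fold
coverage counts sequenced bases per reference position with both
haplotypes piling onto the shared coordinate. Constant quality and
substitution-only errors are deliberate simplifications: the classifier
consumes k-mer counts, for which the error *rate* matters but the
per-cycle quality profile does not. No indel errors, adapters, duplicates
or circularization.

## K-mer features

The full k-mer list is every canonical 21-mer (lexicographic minimum of a
k-mer and its reverse complement; k configurable, 21 being the
conventional WGS choice) of every genotype-template haplotype — wild type
and both deletion alleles of each panel haplotype, scanned left-to-right
in fixed template order and deduplicated at first occurrence. Features are
every 30th element of that list (positional, not lexicographic,
subsampling: neighbouring features remain neighbouring loci, and
subsampling thins the strong dependence between overlapping k-mers). The
default panel yields ~45,000 k-mers → ~1,500 features. Counting is over
raw read sequences only, never alignments, and an identical brute-force
scan serves as the oracle in the test suite. Implementation detail:
k-mers are packed 2 bits/base into uint64, reverse complements derived by
bitwise reversal, and membership is resolved by a 16-bit prefilter table
plus binary search, which keeps per-sample featurization at tens of
milliseconds without changing any count.

Control k-mers (up to 2,000, evenly thinned) lie outside every deletable
span and occur exactly once per haplotype in every genotype template;
half the median control count estimates per-haploid-copy depth. In
`per-haploid-copy` mode counts are divided by this normalizer (single-copy
k-mer ≈ 2.0 in a wild-type diploid), enabling a single cross-coverage
model; the default pipeline instead trains coverage-matched models on raw
counts, which is also how the accuracy-versus-coverage surfaces are built.
Both modes are provided because depth-matched training and explicit
normalization are both defensible; matched-coverage raw counts are the
default since they preserve the absolute-depth signal the six classes
differ in.

## Classifier

A scikit-learn random forest. Hyperparameters are chosen by stratified
5-fold cross-validation (fixed seed, default 42) over a small grid —
trees ∈ {100, 300}, depth ∈ {20, unbounded}, features per split ∈
{√p, 0.3p} — with ties resolved toward fewer trees, then shallower depth;
the winner is refit on all training data. The grid is config-overridable;
a 4-point `FAST_GRID` (100 trees only) is used by the bundled evaluation
scripts because on this panel at these sample sizes the 300-tree
configurations triple cross-validation cost without changing held-out
accuracy. Every prediction is one of the six classes; calls with top
probability below 0.5, or all-zero feature vectors, are flagged
"uncertain" rather than withheld. Models persist as a joblib payload plus
a JSON sidecar (index hash, class labels, CV report); predictions refuse
feature vectors whose index hash differs from the model's.

## Evaluation surfaces

- `accuracy_grid`: per (coverage, n_train) cell, simulate train and
  held-out sets, train, and report mean ± standard error of held-out
  accuracy across independent seed replicates; degenerate cells (a class
  missing) are marked invalid without aborting the run.
- `confusion_and_accuracy`: truth × predicted counts with an optional
  per-sample exclusion list; accuracy = trace / total. Percentages are
  displayed to one decimal; stored values stay exact.
- `mendelian_check`: a child is consistent when some assignment sends one
  of its alleles into each parent's allele set; symmetric under parent
  swap and child-allele order, and verified in tests against exhaustive
  enumeration of all 216 trio combinations.
- `allele_frequencies`: per-population and overall allele counts over the
  unrelated samples with calls (het carriers count once, homozygotes
  twice; denominators are two alleles per counted sample).

## Reported problem sizes

The bundled evaluation (`scripts/acceptance.py`) uses the default panel
and three coverage-matched conditions — 240 training samples at 30x, 360
at 10x, 240 at 40x — each with 100 held-out samples and five seed
replicates, `FAST_GRID` model selection, and balanced genotype classes.
These sizes complete in minutes on a single CPU while keeping the
binomial uncertainty of each accuracy estimate near half a percentage
point.

## Numerical and degenerate-input choices

All randomness flows from `numpy.random.default_rng`; pipeline stages
derive their seeds as SHA-256 of (master seed, stage name) reduced below
2^31, so reruns are byte-identical and stage results are independent of
execution order. K-mers containing N are skipped and counted in logs;
N bases are rejected inside box intervals (junction k-mers would be
ambiguous) but tolerated elsewhere on load. Reads shorter than k are
skipped with a warning. Truncated-normal sampling falls back to clamping
only if rejection fails 1,000 times (pathological parameters). Class
probability ties break by the fixed class order (wild type first).
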