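# Methods

This note records the model, the conventions the implementation freezes
where the problem is genuinely underdetermined, the defaults and why, and
what the synthetic data does and does not emulate.

## Model and assumptions

A canonical animal microRNA locus is a ~70 nt stem-loop: Drosha cuts the
base of the hairpin, Dicer cuts the loop side, and the resulting miR:miR*
duplex (2 nt 3′ overhangs) releases two ~22 nt matures, one per arm. In
aligned small RNA-seq this leaves a characteristic signature: a tight read
stack with a precise modal 5′ end on the dominant arm, a weaker stack on
the opposite arm at the duplex register, occasional moR (offset) and loop
fragments, and — decisively — a near-reverse-complement of the mature
within a few tens of nucleotides.

mirstack assumes reads are already adapter-trimmed and aligned (bowtie-style
input; multi-mapped records present, NH tags optional since hit counts are
recomputed from read-id multiplicity). It makes no assumption about read
abundance: single-read stacks flow through both classifier layers.

The two-layer design separates two questions with different evidence. *Is
this stack shaped like a mature product?* (MPRF: stack geometry, sequence
composition, product:flank duplex energy.) *Is the best surrounding span a
plausible precursor?* (HPRF: fold structure, duplex geometry, product
arrangement, expression.) The first layer's decision value is itself a
feature of the second (stacking).

## Precursor span detection

Whole-window MFE folding is sensitive to the window choice; a few shifted
nucleotides can fold away the hairpin entirely. The duplex-focused method
avoids this by asking a more robust question: where, in the 70 nt on either
side of the product, is the minimum-energy RNA:RNA duplex with the
product's most frequent read? The span from product to duplexed
subsequence (± 5 nt pad) is then folded. Product-focused spans (between
the product and any other passing product with a gap ≥ 5 nt) are generated
in parallel; all candidates compete only through their HPRF score.
Spans above 250 nt are rejected (precursors are ~70 nt; the cap prevents
pathological folds).

Two implementation choices here were made after the naive versions failed
on simulated data and are deliberate:

* **Windows anchor on the major read, not the region.** Loop and moR
  fragments can bridge both arms of a well-expressed hairpin into one
  maximal read region; a window anchored on the region's outer edges then
  excludes the partner arm. All 70 nt windows therefore surround the span
  of the region's most abundant read.
* **Score ties at overlap resolution prefer duplex-focused spans.** On
  clean loci both span types can reach identical forest votes; the duplex
  span localizes the partner arm explicitly and orients the fold more
  reliably, so it wins ties (then the smaller genomic start).

## Products within a candidate

Read regions are maximal overlap components and by construction can never
overlap one another — but real products (miR and an abutting moR, miR and
loop) do overlap. Inside a candidate, each member region is therefore
decomposed into *cut products*: greedy groups seeded by the most abundant
remaining read, absorbing reads whose 5′ ends lie within 3 nt. Products
are named by position relative to the fold's main loop and the duplex
register: the most abundant product is the miR of its arm; the opposite-arm
product overlapping the duplexed target interval (± 2 nt) is the partner
miR; same-arm products outside a miR are moRs; products centered in the
loop are loop products; the rest are out-5p/out-3p/other. Exactly one
product is the major.

## Hairpin anatomy conventions

The feature set needs "the loop", "bulges", "interior loops" and
"offshoots" to be well-defined on arbitrary MFE folds, including
multibranch cases the vocabulary does not naturally cover. Frozen
conventions (tested against an independent recursive oracle):

* The **main stem** starts at the outermost base pair enclosing or touching
  the anchor (major product) and walks inward, passing through bulges and
  interior loops; at a multibranch loop it descends into the branch
  containing the anchor, else the branch with the most pairs (ties 5′-most).
* The **main loop** is the hairpin loop the walk ends in. **Offshoots** are
  hairpin loops other than the main loop under the anchor's enclosing pair.
* **innerLoopGapCount** counts maximal runs of ≥ 3 unpaired positions lying
  directly in the loop closed by the *first* branching pair met on the walk
  (the hairpin loop itself when there is no branching); a value above 1
  flags a multibranched loop.
* maxBulge/maxInteriorLoop are restricted to stem elements overlapping the
  interval from the miR 5′ end to the star 3′ end (the miR span alone when
  no duplex exists); missing-duplex features are 0 with a flag that is not
  part of the feature vector.
* Position classes (paired / loop / bulge / interior / exterior) partition
  the fold; multibranch-loop interiors count as loop.

Folding is delegated to ViennaRNA (MFE, 37 °C, default parameters; engine
version recorded in run provenance). T→U normalization on input;
structures are reported in the RNA alphabet, genomic coordinates in DNA.

## Classifiers, training and tuning

Both layers are scikit-learn random forests: 500 trees, √p features per
split, no depth cap, single-thread, seeded; decision value = positive-class
vote fraction. These hyperparameters are conventional defaults — the
method's contribution is the stacking and the features, not the forest.

Training labels come from annotations: MPRF positives are regions
overlapping an annotated mature on the same strand; HPRF positives are, per
annotated precursor, the candidate with the greatest reciprocal overlap.
Negatives overlap no annotation on either strand (keeping antisense loci
out of the negative pool, consistent with the antisense false-positive
rule) and are sampled at 1:X — X = 1 for the product layer (letting as many
products as possible reach the hairpin phase), X = 25 for the hairpin layer.

Three parameters are tuned by exhaustive grid search on a sample disjoint
from the training sample: the HPRF decision threshold y, the expression
threshold E_th (ARPM), and X. Shipped defaults are y = 0.28, E_th = 0.11
ARPM, X = 25. Ties prefer smaller X, then larger y. The tuning objective
is configurable between the two F statistics below (default f1).

## The two F statistics

The F-score proper is the harmonic mean f1 = 2PR/(P+R). Published
comparison tables in this area sometimes print PR/(P+R) — exactly half the
harmonic mean — under the name "F-score" (e.g. precision 0.727 and recall
0.501 tabulated as 0.296). `evaluation.f_scores` returns both, labeled
`f1` and `f_paper`, rather than silently picking one; nothing downstream
conflates them. One further wrinkle: 0.727·0.501/1.228 = 0.29660, whose
third decimal *truncates* (not rounds) to the printed 0.296; the worked
examples accept either.

## Synthetic data: what it emulates, and what it does not

The generator plants hairpins `mature + loop + revcomp(mature) + 2 nt` on
random strands of a random-GC background, and emits read stacks with the
biogenesis signature: mature reads at the planted cut (90 % 5′ precision,
±1 nt length jitter), star reads at a quarter of mature depth, moR (10 %)
and loop (5 %) fragments, plus unstructured noise stacks (ragged 5′ ends,
precision 0.4, depth 1–10) whose flanks carry no planted complement.
Multi-mapping is realized by physically duplicating a locus at a decoy
position appended to the genome and emitting its reads at both, so
recomputed hit counts are consistent without an aligner. Defaults: mature
21–23 nt, loop 8–20 nt, depth 5–50, GC 0.42, 50 hairpins + 500 noise loci
per 300 kb genome — a clean, moderately expressed library.

What passing tests on this data show: the feature pipeline, span detection,
naming, training and thresholds work end-to-end, and the duplex-energy axis
separates planted from unstructured loci. What they do not show: robustness
to sequencing error, adapter artifacts, isomiR biology, repeat-derived
hairpins (other structured ncRNAs folding hairpin-like), or realistic
expression distributions. The noise model is intentionally the pipeline's
statistical null, not transcriptome realism — real-data precision will be
lower than the synthetic numbers.

Test problem sizes were chosen to exercise the study conditions at desk
scale: module tests use 10–20 hairpin libraries; the parameter-recovery
acceptance test trains, tunes and tests on three disjoint 50-hairpin /
500-noise fixtures with a 3×1×2 tuning grid.

## Numerical and degenerate-input choices

* Population (not sample) variance for the read-count/start variances.
* Weighted medians for read length; 5′-position modal ties break to the
  smaller genomic coordinate.
* Duplexes with energy ≥ 0 are "no duplex"; duplex spans trim to the paired
  extent. Flanks shorter than 10 nt are skipped; no usable flank gives a
  0.0 duplex-energy sentinel.
* fivePrimeHet = 1 − modal-5′ dup-weighted fraction (the simplest statistic
  matching the name; the literature variant is not uniquely specified).
* Offset profile entries are fractions (scale-invariant), denominated over
  all reads, so the 15 entries sum to ≤ 1.
* PR curves use the trapezoid over recall with the curve anchored at recall
  0 at the highest-threshold precision; single-class inputs are an error,
  not NaN.
* Homology E-values come from a Karlin–Altschul formula (λ = 0.625,
  K = 0.41 for match 2 / mismatch −3, gap 5/2) over a deterministic local
  aligner; the engine is pluggable and its identity is recorded on every
  call. The built-in E-values are approximate — adequate for the
  known/homolog/novel verdicts, not for publication-grade E-value claims.
* Clusters require ≥ 2 members; the 10 kbp chaining distance is inclusive,
  measured between precursor span edges. A cluster is "annotated"-sourced
  iff ≥ 2 annotated members already chained without any novel predictions.

## Known limitations

* Mirtron detection is emergent (a span matching an intron is found only
  because the duplex method finds it); splice junctions are never consulted.
* The product-naming concretization (register tolerance 2 nt, cut tolerance
  3 nt, the 11 overlap pairs and 8 count classes) is this package's
  convention, recorded in the feature manifest; other reasonable
  conventions exist.
* Strand-specific regions are assumed throughout; antisense evidence enters
  only through features (totalAntisenseRPM, tapd, aapd).
* No suboptimal folds, partition-function pairing, or pseudoknots.
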