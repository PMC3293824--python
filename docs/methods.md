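# Methods

## The problem

Environmental 16S rRNA surveys contain many reads from organisms whose 16S
gene has never been sequenced. A closed-set classifier will still assign
every such read to its best match in the reference, silently mislabelling
reads of novel taxonomic origin. `taxonovel` implements (i) a word-based
naive Bayes genus classifier with a per-rank bootstrap confidence, and
(ii) an *open-set detector*: a trained score threshold that separates reads
from database-represented ("known") taxa from reads of novel origin, so the
candidate-novel pool can be isolated before further analysis.

## Classifier model

A query read is decomposed into all overlapping `w`-mers (default `w = 8`)
containing only A/C/G/T; windows touching an ambiguity code are dropped.
Training records word *presence* per reference sequence — a word counts at
most once per sequence. With `N` training sequences of which `n(w)` contain
word `w`:

    P(w) = (n(w) + 0.5) / (N + 1)                      (corpus prior)
    P(w|g) = (m_g(w) + P(w)) / (M_g + 1)               (genus conditional)

where genus `g` holds `M_g` sequences, `m_g(w)` of which contain `w`. A read
is assigned to the genus maximising `Σ ln P(w|g)` over its *distinct* valid
words. Genus priors are taken as equiprobable, so this maximum-likelihood
assignment coincides with the maximum-posterior one. Exact ties break toward
the earlier genus in reference insertion order, making runs reproducible.
All arithmetic is in log space; the smoothing keeps every probability
strictly inside (0, 1), so no score is ever degenerate.

Two detector scores are derived per read:

* **Bootstrap confidence** — each of `bootstrap_trials` (default 100) trials
  draws `⌈W/8⌉` of the read's `W` word occurrences (without replacement by
  default; the policy is configurable because either convention is
  defensible), classifies the subsample, and records the assigned genus.
  The confidence at rank `r` is the fraction of trials whose assignment
  shares the full-read assignment's ancestor at `r`. It is by construction
  a multiple of `1/trials`, lies in [0, 1], and is non-decreasing from genus
  toward kingdom. Reads with fewer than 8 valid words are refused (a 1/8
  subsample would be empty). Because 1/8 of a longer read contains more
  words, the score is read-length dependent; the fixed-word variant
  (`bootstrap_fixed_words`) draws a constant number of words per trial and
  refuses reads shorter than twice that span, giving a length-independent
  score at the cost of a minimum read length.
* **Normalised log likelihood** — the best-genus joint log score divided by
  the number of distinct valid words, making scores comparable across read
  lengths.

## Detector training (half-fold + 5-fold design)

A random half of the reference *sequences* (not stratified by genus, so some
genera fall entirely into the held-out half and become genuinely novel test
taxa) forms the detector-training half. Its genera are partitioned into five
near-equal groups; for detectors at ranks above genus the partition groups
genera by their ancestor at the target rank, so a fold never splits a higher
taxon between known and novel. Fold `i`:

1. trains the classifier on group `i`'s sequences only (≈1/5 of the genera
   known, the other 4/5 novel — emulating a diverse sample in which ~20% of
   reads have database representatives);
2. simulates fixed-length reads from the *whole* training half (defaults:
   5 reads/sequence at 100 bp, 2 at 250 bp and 500 bp, error-free random
   windows; windows above 20% ambiguity codes are redrawn, then skipped);
3. scores the reads and labels each known/novel at the target rank;
4. builds an ROC (decision rule `score ≥ t ⇒ known`, thresholds swept over
   every distinct score, AUC by trapezoid) and selects the threshold
   maximising the f-measure `2·sens·spec/(sens+spec)`; among ties the
   smallest threshold wins, which avoids giving up further sensitivity —
   the bootstrap detector is already conservative.

The final threshold is the unweighted mean of the five fold thresholds. A
fold whose labels collapse to a single class raises an error naming the
fold rather than producing a silent degenerate ROC. Testing retrains the
classifier on the full training half, scores reads from the held-out half,
and reports sensitivity, specificity, f-measure, AUC and (for known reads)
assignment accuracy. Metrics whose denominator class is empty are reported
as absent, never as 0 — at phylum level a test set can contain almost no
novel reads.

With known-read fraction `k` and sensitivity `s`, the detector passes
`1 − k·s` of all reads on to the candidate-novel pool (the search-space
-reduction identity); `EvalReport.novel_pool_fraction()` computes this.

## Defection analysis

When a reference database grows, reads that were forced onto a poor best
match tend to "defect" to newly added, better-matching taxa. For each taxon
the analysis takes the reads assigned under a half-size database (`n_half`),
the subset passing the detector (`n_passed`), and the reads retained under
the full database (`n_full`), and correlates the predicted novelty fraction
`x = 1 − n_passed/n_half` with the observed relative decrease
`y = (n_half − n_full)/n_half` (Pearson). Relative, not absolute, decreases
are used; negative decreases (taxa that grow) are retained, and taxa that
vanish entirely under the full database are included with `y = 1` (a flag
drops them). Low-abundance taxa make `y` noisy — one read leaving a 3-read
bin is a 33% drop — so correlations are reported at abundance floors
{0, 50, 100, 500}. The packaged cohort simulator draws log-normal taxon
abundances, a uniform per-taxon novel fraction, a detector with 0.95
sensitivity / 0.05 false-pass rate, and a 0.8 per-read defection
probability; recovering a rising correlation across abundance floors checks
the analysis end to end.

## Synthetic data: what it does and does not emulate

The generator builds a random six-rank taxonomy with exact per-rank node
counts, then evolves sequences from a single root ancestor by i.i.d.
substitutions down each rank edge (defaults: phylum 0.35 — near-saturating,
so phyla are almost mutually random — class 0.10, order 0.08, family 0.06,
genus 0.08, within-genus 0.02; all rates validated to [0, 0.5)). Genus sizes
follow the imbalance of real reference sets: 50% singletons and a geometric
tail capped at 50 sequences. Evolution is substitution-only; indels would
add no behaviour the alignment-free classifier tests. The generator does
*not* reproduce real 16S base composition, conserved/variable region
structure, or chimeras — passing tests demonstrate correctness of the
machinery under a known hierarchical divergence model, not performance on
real amplicon data, where anomalously labelled intermediate ranks and
uneven phylogenetic coherence reduce separability.

Benchmark construction withholds a nested set of taxa (novel at family ⇒
novel at genus) and emits reads at a configured known/novel mix, with a
manifest sufficient to recompute every label.

Two named presets define the study conditions used by the acceptance
script and tests, chosen once:

* **easy** — 20 genera, genus-edge divergence 0.15, within-genus 0.01,
  1200 bp references, 500 bp reads, 8 reads/sequence, test mix 20% known /
  80% novel. Sister genera are ~26% diverged while a read matches its own
  genus near-perfectly, so a correct implementation should reach AUC ≈ 1.
* **null** — every divergence rate 0: all sequences identical, every score
  ties, and AUC is 0.5 exactly. This is the no-structure control; any AUC
  away from chance indicates an implementation artifact.

Problem sizes throughout (20 genera, ~50 sequences, a few hundred reads per
experiment) are chosen so the full workflow remains a seconds-to-minutes
computation while every statistic stays far from its decision boundary.

## Numerical and design notes

* Word indices are base-4 packed integers; `word_size ≤ 12` keeps the
  4^w-sized prior table small. Per-genus presence counts are stored sparse.
* All randomness flows through `numpy` generators seeded from explicit
  integers; batch bootstrap seeds are spawned per read, so batch scoring is
  deterministic and independent of read order.
* The smoothing formulas above are the standard trainset conventions for
  word-presence naive Bayes 16S classifiers; the bootstrap subsampling unit
  (words vs. base pairs) and replacement policy are exposed as parameters
  because published descriptions are ambiguous; defaults are
  word-subsampling without replacement.
* Thresholds serialise to JSON with rank, read length, score kind, fold
  thresholds, seed and a config hash; applying a threshold to reads of a
  different length is refused at the CLI.
* External score tables (read_id, score TSV) can be thresholded with the
  same detector machinery, so third-party classifiers' scores can be used
  without reimplementing them here.

## Known limitations

* No reverse-strand handling: queries are assumed to be oriented.
* The detector threshold is trained per read length; no interpolation
  between trained lengths is attempted.
* Taxon priors are equiprobable; heavily represented genera are not
  up-weighted.
* Bootstrap cost is `O(trials × words)` per read; classification of very
  large read sets is linear but unparallelised.
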