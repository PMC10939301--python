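# Methods

## Overview

`cormit` detects miRNA–target gene pairs (mTPs) from paired gene and miRNA
expression matrices measured on the same samples. Seven Pearson-correlation
strategies are evaluated over a threshold grid; every (strategy, threshold)
combination is scored against a database of predicted/validated pairs with
an odds ratio and a one-sided exact test; the per-miRNA best significant
combination is selected and its detections integrated into the final pair
set. The package assumes the upstream work — quantification, normalization
inputs, differential expression, co-expression module detection — has been
done; module assignments and DEG/DEM lists are inputs, not products.

## Representatives and strategies

Each strategy pairs a *gene representative* with a *miRNA representative*:

- **C (CPM profile)** — the feature's own counts-per-million profile,
  `cpm[i,j] = counts[i,j] / colsum[j] × 1e6`.
- **E (module eigengene)** — first principal component of the module's
  member × sample matrix after per-feature standardization (mean 0, sd 1
  across samples, population divisor *n*). Returned with unit Euclidean
  norm and sign oriented so its correlation with the mean standardized
  member profile is non-negative; an exact-zero correlation (only possible
  in contrived balanced modules) is resolved by making the first non-zero
  entry positive, so recomputation is bit-identical. Constant members are
  dropped from the PCA with a warning; a module whose members are all
  constant has no representative and its members are excluded from the
  module-strategy maps.
- **H (module hub)** — the CPM profile of the member with maximal |kME|,
  kME being the Pearson correlation of the member profile with the module
  eigengene. Ties take the lexicographically smallest feature id.

The eigengene and hub definitions follow the WGCNA conventions, which is
the clustering framework these module assignments typically come from;
"hub" in particular has no single field-wide definition (max-kME vs max
intramodular connectivity), so the max-|kME| convention is stated here
prominently rather than left implicit.

Seven combinations are valid — `Cg_Cm, Eg_Cm, Hg_Cm, Eg_Em, Eg_Hm, Hg_Em,
Hg_Hm` — in this canonical order. The two combinations that would
correlate a miRNA-module representative against individual gene CPM
profiles (`Cg_Em`, `Cg_Hm`) are excluded; no prior work motivates them.

Module-level correlations are broadcast: the pair (g, m) under a module
strategy receives the correlation of g's module representative with m's
representative, so every strategy yields pair-level detections. Features
in the unassigned module ("0", the WGCNA grey equivalent, which also
absorbs any feature missing from the assignment file) have no module
representative, and their pairs get NA under module strategies; NA is
never detected.

## Detection and scoring

Candidate pairs default to DEMs × all expressed genes (flags widen the
miRNA side to all expressed miRNAs or narrow the gene side to DEGs).
Detection keeps pairs with r strictly below the threshold (anti mode,
grid −0.90 … −0.50 step 0.05) or strictly above it (positive mode,
+0.50 … +0.90); detection sets are therefore nested across the grid.

For a detection set and database S over a pair universe the 2×2 table is
a (detected ∩ S), b (detected only), S_d (S only), R (neither); database
pairs involving unexpressed features fall outside the universe and are
excluded before counting. Scores:

- **odds ratio** OR = a·R / (b·S_d). When reporting (and ranking), a
  Haldane–Anscombe 0.5 is added to every cell if any cell is zero — strict
  thresholds routinely give b = 0 and the ranking needs finite values. The
  exact test always uses the uncorrected table. OR is NA when the universe
  or S ∩ universe is empty.
- **one-sided Fisher exact test** P(X ≥ a) under the hypergeometric null
  with the table margins (scipy's `fisher_exact`, alternative `greater`;
  over-representation is the question, so depletion is not penalized).
  A property worth noting: both OR and this p-value are invariant under
  swapping b ↔ S_d, because the hypergeometric law is symmetric in its
  two margins — table orientation cannot be distinguished statistically.
- **benchmark metrics** precision a/(a+b), recall a/(a+S_d), specificity
  R/(b+R), accuracy (a+R)/N, with 0/0 → NA.

The *overall* scope pools all expressed-miRNA × expressed-gene pairs; the
*specific* scope uses {m} × expressed genes for each candidate miRNA m,
which keeps the same miRNA in numerator and denominator and so removes the
bias from miRNAs being unevenly represented in databases.

## Selection-integration

Per miRNA, combinations with finite OR and p < α (default 0.05, no
multiple-testing correction — a deliberate caveat, `--fdr`-style
correction is left to downstream filtering of `specific_eval.tsv`) are
ranked by descending specific OR. Ties are broken by stricter threshold
first, then canonical strategy order, then smaller p — an invented but
total and therefore deterministic order. The top combination's detected
pairs, annotated with r and a database flag, form the integrated set;
miRNAs with no significant combination contribute nothing ("no targets
found"). `db_only` restricts the output to database hits, the subset a
functional analysis would use.

## Robustness protocol

To measure sensitivity to database composition, a uniform
without-replacement sample of ⌊fraction × |S|⌋ pairs (default 75%) is
drawn, the specific evaluations and rankings recomputed — correlations
and detections are unchanged, only the database varies — and the rank of
the full-database top combination recorded; NA if it fell below
significance. Repeated n_reps times (default 40) with seed
`base_seed + replicate`, so any replicate can be reproduced alone and
replicates can run in parallel. All combinations are re-ranked, not just
per-strategy bests (the stricter reading). Subsample size uses floor
rounding.

## Synthetic data generator

The generator emulates the structure the method assumes — nothing more:

- **modules** via shared latent Gaussian sample factors: member profile
  = √w·z + √(1−w)·ε with background coherence w = 0.7; ~10% of genes and
  ~20% of background miRNAs stay unassigned.
- **planted regulation**: the first `n_regulator_mirnas` miRNAs (default
  3) are the DEM set; each gets `targets_per_regulator` (default 15)
  genes coupled at Pearson `coupling` (default −0.9) on the latent scale.
  Two architectures: *individual* couples each target's own profile to the
  regulator and leaves targets unassigned, so individual-CPM strategies
  carry the signal; *module* couples one dedicated gene module's latent to
  the regulator while members attach to the module latent at
  `target_module_corr` = 0.55, so the eigengene tracks the regulator
  better than any single member and module strategies win. The member
  coherence default was calibrated once for the default 12 samples:
  substantially weaker coherence makes the eigengene itself unestimable
  (15 members > 12 samples, first-PC noise swamps the factor), which would
  defeat the preset's purpose rather than test it.
- **counts**: latent profiles are exponentiated around per-feature
  log-normal baselines (log-sd 1 around ~200) with log-scale dispersion
  0.3 (~31% CV, typical for within-condition bulk RNA-seq). The
  exponentiation attenuates Pearson correlations modestly (planted −0.9
  on the latent scale measures about −0.75 to −0.8 in CPM), which is part
  of what makes the exercise non-trivial. No negative-binomial read-level
  simulation: the method consumes CPM correlations, so correlation
  structure matters and the marginal count family does not.
- **database**: `db_truth_fraction` (default 0.8) of the planted pairs
  plus `db_decoy_count` (default 150) uniformly random non-planted pairs.
- **defaults**: 12 samples, 500 genes, 60 miRNAs, 6 gene / 4 miRNA
  background modules — a full pipeline run takes well under a second, and
  the whole acceptance recomputation a few seconds.

Module assignments reflect the generative truth exactly; upstream
clustering error is deliberately out of scope so tests isolate the
detection/selection logic. Passing tests on this generator therefore say
nothing about clustering quality, miRNA identifier reconciliation across
database releases, or count overdispersion beyond log-normal — all
properties of real data the generator does not emulate.

## Numerical and interface choices

- ID matching is exact and case-sensitive; `--lowercase-ids` normalizes
  all inputs at load time. miRNA nomenclature differs across databases and
  miRBase releases; normalization must be explicit, never silent.
- Expression matrices require ≥ 3 samples (Pearson is degenerate below),
  unique ids, finite non-negative values; CPM rejects zero-sum columns.
- TSV dialect everywhere: tab-separated, UTF-8, `#` comments, no quoting.
- All randomness (generator, subsampling) uses numpy `default_rng` with
  explicit seeds; outputs are written with sorted iteration orders and a
  fixed float format, so identical config + seed gives byte-identical
  files.

## Known limitations

- Pearson only; no Spearman, partial or lagged association.
- No consensus/voting integration across strategies — the per-miRNA top
  combination takes all.
- The significance filter is uncorrected for multiple testing across the
  63 combinations per miRNA.
- Small detection sets with zero cells get large Haldane-corrected odds
  ratios and can win a ranking on thin evidence; the reported
  `n_detected` / `n_overlap_db` columns expose this, and the robustness
  protocol is the designed check against it.
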