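# Methods

## Taxonomic resolution of shared peptides

A taxonomy is a rooted tree whose nodes carry one of the named ranks
(superkingdom, phylum, class, order, family, genus, species) or `no_rank`.
Unranked nodes participate fully in lineage and LCA computations but are
never reported when a named rank is requested, so an unranked clade
between a phylum and its genera does not break rank-level aggregation.

Peptide annotation proceeds in two layers. Within a subpeptide, the taxa
of all database hits are collapsed by lowest common ancestor — the
standard conservative choice for peptides shared across genomes. Across
subpeptides of one observed peptide the *branch rule* applies: when all
per-subpeptide taxa lie on one root-to-leaf path the deepest (most
specific) taxon is kept, because the shallower assignments are consistent
coarsenings of it; when they disagree across branches a broad consensus is
kept. "Broad" is genuinely ambiguous in that situation: the literal
shallowest member of the conflict set still belongs to one of the
conflicting lineages, so the default broad mode is the LCA of the set
(which is neutral between branches), with `literal_broadest` retained
behind a flag and its ties broken by smallest taxon id for
reproducibility.

Subpeptides with no database hit are ignored rather than vetoing the
peptide: an absent peptide is evidence about database coverage, not about
taxonomy. A subpeptide matching any human protein is treated as
host-derived and contributes no taxonomic evidence (host-first rule);
this deliberately sacrifices a little microbial sensitivity to avoid
counting shared host/microbe sequence as microbial signal.

## Digestion and canonicalization

Trypsin cleaves C-terminal to K or R but not before proline. The proline
exception is the standard convention and is configurable, since some
search engines disable it. Fragments with up to `max_missed` internal
cleavage sites are enumerated in order of start position; `max_missed=2`
is the index default, matching common search settings. Canonicalization
rewrites L as I (keeping canonical strings inside the 20-letter alphabet,
rather than introducing a 21st symbol) and the length filter keeps 5–50
residues inclusive.

## Quantification conventions

Missing intensity means "not identified"; identification counts use
non-missing (not non-zero) values because DIA reports leave absent
features blank. Ratios and aggregation operate on the native linear
scale; log2 transforms happen only inside the statistics layer.
Aggregation to a rank or category sums member intensities per sample,
dropping (and counting) features whose lineage lacks the requested rank;
a group with no identified member in a sample stays missing rather than
becoming zero. The cross-cohort sharing percentage uses the union as the
denominator — the fraction of everything identified in either cohort that
was identified in both — which is the reading that makes the published
worked examples internally consistent.

Sample QC keeps samples with at least `min_human` and at least
`min_microbial` identified proteins. The full-scale survey thresholds are
800 and 2000; the synthetic pipeline defaults scale these to 60 and 600
because its default database is about a tenth of survey scale.

## Statistics

Differential abundance uses the two-sided Wilcoxon rank-sum test: exact
null distribution when the combined n is at most 20 and untied, otherwise
the normal approximation with tie correction. Fold change is the ratio of
linear-scale group means (offset by +1 only when a group mean is zero);
the significance rule is |log2FC| > 1 together with p < 0.05. Raw p is
the default because that matches how the threshold is commonly applied in
practice; Benjamini–Hochberg adjustment is available via `adjust="bh"`,
and the adjusted column is always reported. Enrichment is the two-sided
Fisher exact test on the in/out-foreground × in/out-category table over
the background.

Species risk is a univariate logistic regression per species. The
predictor coding is a design choice: z-scored log2(intensity + 1), so the
odds ratio reads "per SD of log abundance" and is comparable across
species with different dynamic ranges. Estimates are Wald (OR, 95% CI,
p); fits that fail to converge — e.g. quasi-separated species — are
flagged and carry no estimate rather than reporting a degenerate CI.

Stability is the Spearman correlation of feature abundances between
sample pairs on pairwise-complete features (pairs with fewer than three
shared features are dropped and counted), stratified into same-subject
and different-subject pairs and summarized as mean ± sd.

## Screening model

The classifier is a stochastic gradient boosting machine with Bernoulli
deviance loss, interaction depth 3, 150 trees, shrinkage 0.1 and minimum
node size 10 — the classic gbm-style parameterization. Feature selection
fits the full ensemble on training data only (a stratified 3:1 split;
cross-validated accuracy is estimated with stratified k-fold when
`cv_folds > 0`) and ranks features by reduction-in-loss importance
normalized to sum 100, ties broken by feature id. The top 50 are refit
into the final model. The selected list is fixed before any test data is
scored; a property test verifies that perturbing test intensities cannot
change the selection.

Evaluation reports accuracy with an exact binomial (Clopper–Pearson) 95%
CI — chosen over the normal approximation because test sets can be small
— plus sensitivity and specificity at a fixed 0.5 probability cutoff (no
threshold tuning) and trapezoidal AUC. The t-SNE diagnostic uses
perplexity 30 (clamped for small n) with a fixed seed and PCA
initialization; Euclidean distances are computed on z-scored log2(x+1)
features, and mean control-to-stratum distances are reported for
gastritis, stage I–II and stage III–IV strata.

## Synthetic data generator

The generator defines the study conditions everything is tested under.

*Designs.* Time series: 5 healthy subjects × days 0/3/6/9 × 3 replicates
with one subject missing the final visit → 57 samples. Single-center
case–control: 120 cancer (stages I–IV balanced) vs 120 non-cancer (a
third with gastritis). Multi-center: 60/60 across three centers.
Together: 417 samples.

*Reference.* A balanced root → phylum → genus → species taxonomy
(default 4 × 3 × 3 = 36 species), 30 random proteins of length 80–400 per
species and 120 human proteins — about a tenth of a real tongue-coating
survey while preserving the ~9:1 microbial:human protein ratio. Each
microbial protein gets one COG and one KO from 40-term vocabularies.
Baseline log2 abundances are hierarchical and belong to the reference:
species biomass ~ N(20, 2), protein offsets ~ N(0, 0.5) within a species,
so a species' proteins rise and fall together, as biomass dictates.

*Intensity model.* log2 intensity = baseline + subject effect + planted
effects + noise, with subject effects ~ N(0, 0.8) shared by all samples
of a subject (producing the intra > inter individual correlation the
pipeline's stability analysis must detect), observation noise ~ N(0, 1),
and 10% missing-at-random masking. Planted differential and
discriminative features get a +2 log2 shift (4-fold) in cancer samples;
discriminative shifts are scaled per stage (gastritis 0.25, stage I–II
1.0, stage III–IV 1.25) so late-stage samples sit farther from controls.

*Risk species.* One species' abundance is coupled to the outcome through
a logistic link. With per-group predictor means ±m and within-group sd s
chosen so that 2m/s² = log(OR) and s² + m² = 1, the log-odds are linear
in the predictor with slope log(OR) per pooled SD; scaling both m and s
by a common factor (default 2.5 log2 units, a realistic inter-individual
abundance swing for an oral species) leaves that slope unchanged while
letting the planted signal dominate protein-level measurement noise in
the species aggregate. The risk species' proteins are excluded from the
differential/discriminative pools so its odds ratio is not confounded by
an extra cancer fold change.

*Truth ledger.* Every planted effect (features, fold changes, risk
species and predictor values, protein→taxon map) is recorded at
generation time; recovery tests read only the ledger, never a re-draw.

*What the generator does not emulate:* spectrum-level noise, ionization
or retention-time effects, batch/center effects, compositionality
constraints, correlated co-occurrence between species, and realistic
protein sequence homology (random sequences make nearly all peptides
proteotypic, so annotation rates here are upper bounds). Passing
recovery tests therefore demonstrate the pipeline's correctness under a
known generative model, not its field performance on deposited cohorts.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale versions of each analysis:
recovery suites use references of 16–432 microbial proteins, 50–100
simulation replicates, and skip the cross-validated error estimate
(`cv_folds=0`) during repeated feature-ranking runs, since CV informs the
analyst but does not enter the ranking. The single-pass pipeline default
keeps the full 10-fold CV. Stage seeds are derived from the global seed
by a fixed stage-name hash so stages can be toggled without shifting each
other's random streams. Ties in feature influence are broken by feature
id; q-value filtering is row-level; FASTA merge output is sorted by
accession so record order never depends on input order.

## Known limitations

- The branch rule's `literal_broadest` mode is retained for fidelity
  experiments but the LCA default is the defensible choice; results can
  differ when subpeptides disagree across branches.
- Protein inference is taken at face value from PSM accession lists; no
  parsimony re-grouping is attempted.
- The logistic risk model is univariate; confounders (center, age) are
  not modelled.
- Wald CIs undercover slightly when species aggregates carry heavy
  measurement noise; the generator's conditions keep this effect small
  but real-data use should prefer profile-likelihood or Firth CIs for
  rare species.
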