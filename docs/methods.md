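# Methods

## Scope and data model

The package analyses annotated BCR heavy-chain rearrangement tables (AIRR
Rearrangement TSV dialect: one row per UMI-consensus sequence with V/D/J
calls, junction nucleotides and amino acids, isotype, observed and
germline alignments of equal length, a productive flag and a consensus
count). Raw-read processing, V(D)J annotation and germline inference are
upstream concerns: alignments arrive precomputed, either from an external
annotator or from the built-in simulator. Unproductive rows are filtered
on read (the standard analysis mode); rows violating invariants
(alignment length mismatch, consensus count below 1, productive junction
not a multiple of 3) are rejected with their file line numbers rather
than silently dropped. Sub-isotype constant-region calls collapse to the
five classes IgM/IgD/IgG/IgE/IgA, the resolution at which all downstream
isotype analyses run.

## Clonal inference

Two clone definitions are implemented and each report records the mode
used:

* **Identity mode (default).** Two sequences are clonal iff they share the
  V gene, the J gene and the exact CDR3 amino-acid junction. Gene-level
  grouping: allele suffixes (`*01`) are stripped and, for multi-gene call
  strings, the first listed gene is used — deterministic and standard
  practice. Clone ids are stable hashes of the defining triple.
* **Threshold mode.** Within (V gene, J gene, junction length) groups,
  single-linkage clustering of junction nucleotide sequences at normalized
  Hamming distance ≤ t. The sample-specific t is the density minimum
  between the two largest modes of a Gaussian-KDE fit to the
  distance-to-nearest distribution (each sequence's minimal distance to
  another group member). Distributions without two modes fall back to a
  configured default (0.1) with a warning flag; fewer than 50 finite
  distances is an error directing the user to identity mode.

Records with an empty junction (e.g. frameshifted, non-translatable) are
excluded from partitioning and reported.

## Diversity, clonal expansion

Hill numbers are computed on clone relative abundances, with q = 1
evaluated as the entropy exponential limit. Cross-sample comparisons use
uniform-depth subsampling without replacement: the depth is the minimum
sample size within each tissue (computed once per run and logged in the
manifest), the default bootstrap count is 200 and the band is the 2.5/97.5
percentile across replicates. Raw Shannon entropy and the Simpson
concentration are exposed separately for users who want the classical
indices rather than their Hill transforms. Clone size counts distinct
consensus sequences by default; consensus-count weighting is a flag, since
either convention is defensible for UMI-consensus data.

P20 sums the relative frequencies of the 20 largest clones; ranking ties
at the boundary are broken by clone id so results are reproducible.
Per-isotype diversity and P20 slice the records by isotype before
recomputing clone abundances (a clone may appear in several slices).

## Repertoire dissimilarity index

For each sample pair, per repeat: subsample both to a common depth,
count V/D/J gene-segment usage over a fixed shared feature space,
normalize, take the Euclidean distance; report the mean over 100 repeats
(the default repeat count of the procedure this implements). Design
choices where the procedure is underdetermined:

* **Normalization** defaults to within-segment proportions (V, D and J
  blocks each sum to 1); a centered log2 variant with a half-count
  pseudocount — the transformation of the original RDI formulation — is
  available by configuration, and the choice is recorded in the output.
* **Missing D calls**: the D block is computed over records with a D call
  and renormalized, so "no D" never acts as a spurious dominant feature.
* The feature space spans V, D and J segments by default and is
  configurable to subsets.
* Subsampling streams are keyed by sample id, making the pair value
  symmetric in argument order under a shared seed. When the depth equals
  both sample sizes the subsample is the whole sample and the average
  collapses to a single exact distance.

The per-mouse dissimilarity covariate used in correlation analyses is the
mean RDI of a sample to the other samples of its own age × diet group — a
per-individual reduction of the group-level quantity, needed because
morbidity is a per-mouse outcome.

## Somatic hypermutation and class-switch staging

Mutations are counted over the alignment excluding the junction (junction
identity defines clones, and CDR3 properties are analysed separately).
Positions with gaps or ambiguous bases in either string are not
informative. Each mismatch is classified by translating the germline
codon with and without the observed substitution, the other codon
positions taken from germline; multi-hit codons are therefore classified
per position against the germline context (the common single-substitution
approximation — a documented limitation), and stop-gaining changes count
as non-synonymous. Frequencies divide by informative positions. Both
per-sequence means and per-clone aggregates can be formed from the
per-sequence table, since field practice varies.

Clones are staged by class-switch status: any IgM or IgD member ⇒
IgM+IgD+, split into SHM− / SHM+ by whether any member carries at least
`shm_min_mutations` (default 1) total mutations; no naive isotype left ⇒
IgM−IgD− (post-antigenic). CDR3 lengths (amino acids) are summarised by a
Gaussian location/scale fit; the deviation uses the n−1 denominator by
default with the convention recorded on the result object.

## Macromorbidity index

Neoplasia grade: 0 (tumor-free), 1 (one organ affected), 2 (two or more
organs, metastatic disease). Each macroscopic non-neoplastic finding at
necropsy adds one point; findings come from a closed seven-label
vocabulary (kyphosis/bad habitus, enlarged spleen, WAT discoloration,
granular pancreas, uterine cysts, enlarged kidneys, enlarged adrenal
glands), with bilateral organs counted once at the label level. The index
is grade + burden, bounded by 0 and 2 + vocabulary size.

## Cohort statistics

Per-diet OLS of each metric on age (two-sided slope test); fixed-effects
two-way ANOVA with interaction (type-II sums of squares via statsmodels)
between diet pairs; two-sided Mann-Whitney U between diets at each time
point — exact enumeration when both groups have ≤ 8 observations and no
cross-group ties (mandatory fidelity for an n = 5 design), tie-corrected
normal approximation otherwise; and Spearman correlation (mid-rank ties)
of each metric against macromorbidity, neoplasia grade and non-neoplastic
burden separately. Bonferroni families: all timepoint tests of a run form
one family; correlations are corrected within one outcome panel, with
undefined tests (constant metric or outcome, or fewer than 5 pairs)
flagged and excluded from the family count. Because "variance explained"
is ambiguous between ρ² and a linear R², both are emitted and neither is
privileged.

## Synthetic cohort generator

The generator emulates the statistical structure of a cross-sectional
aging cohort under ad libitum (AL) feeding, chronic dietary restriction
(DR, from 3 months) and a mid-life switch group (AL_DR16M, AL until 16
months then DR):

* **Clone sizes.** Per sample, clone relative sizes are a symmetric
  Dirichlet draw over `n_clones_base` = 1000 clones with per-clone
  concentration α(age, diet) = α₀ · exp(−Σ_d s_d · m_d), where m_d are the
  months spent under regime d since randomisation at 3 months and s_d is
  the regime's expansion slope. Sequences are multinomial draws from the
  clone law. One parameter per diet thus controls how fast the size
  distribution skews with age. Defaults α₀ = 0.135, s_AL = 0.097/mo,
  s_DR = 0.059/mo are illustrative effect sizes chosen so clonal abundance
  (P20) rises from roughly a third of the repertoire at 5 months to about
  80% (AL) versus 60% (DR) at 24 months — the qualitative trajectory of an
  aging DR cohort, not an estimate from any dataset.
* **Usage idiosyncrasy.** Each mouse's V/D/J usage is Dirichlet-resampled
  around fixed population vectors with precision κ(age, diet) =
  κ₀ · exp(−u_d · m_d) (κ₀ = 800, u_AL = 0.12/mo, u_DR = 0.05/mo), so
  repertoires drift apart with age, faster under AL — the mechanism that
  produces growing inter-individual RDI without bespoke machinery.
* **Sequences.** The germline reference is random: V segments 252–300 nt
  and J segments 42–60 nt built from sense codons in a fixed frame, D
  segments 10–30 nt. Junctions are in-frame random codon strings flanked
  by the conserved Cys and Trp; D genes are call labels only and are not
  embedded in the assembled V–junction–J sequence. Isotypes are drawn per
  tissue (spleen 61/23/13/2/1% IgM/IgG/IgA/IgD/IgE; ileum IgA-dominant),
  and SHM is planted as Poisson-distributed independent substitutions
  outside the junction at isotype-dependent expected counts (IgM 1.5,
  IgD 1, IgG 8, IgE 5, IgA 8 per sequence), each recorded as synonymous or
  non-synonymous at planting time.
* **Clone identity is exact by construction**: junctions never mutate by
  default, so the identity rule recovers the planted partition with Rand
  index 1 — the key end-to-end validation hook. A junction-mutation switch
  exists to exercise threshold mode under junction noise.
* **Morbidity.** A latent score couples each mouse's planted expansion
  (the true top-20 clone mass of its primary-tissue sample) to pathology:
  score = coupling · z(expansion) + Gaussian noise (defaults 1.5 and 0.5),
  mapped monotonically to a tumor-organ count and a nested finding list,
  so planted expansion and the macromorbidity index share rank order up to
  noise and discretisation.
* **Design.** The default pipeline cohort is 3 diets × ages 16/20/24 × 5
  mice, spleen only (45 samples): with the switch at 16 months this is the
  largest balanced design in which all three diet groups exist at every
  age. The 5-month time point is available for AL/DR-only analyses.

What the generator does **not** emulate: sequencing error, chimeras, UMI
artefacts, lineage trees within clones, biologically structured V–D–J
pairing preferences, mutation hot/cold spots, and unequal sample sizes
(all samples share one depth, so subsampling machinery is exercised by
explicit-depth analyses rather than by the default end-to-end run).
Passing tests therefore validate the pipeline's arithmetic, invariants
and sensitivity to planted effects — not the biological realism of any
particular dataset.

## Determinism and numerics

A single run seed is expanded into independent named substreams (SHA-256
of the label path as a SeedSequence spawn key), one per stage × sample,
so changing the draw count of one stage never perturbs another. Pipeline
reruns with the same config and seed are byte-identical, including the
manifest (which therefore records no wall-clock times). KDE threshold
detection evaluates on a 512-point grid over [0, max distance] with
Scott's bandwidth; boundary grid points count as modes so a spike at zero
distance is detected. Diversity at full depth short-circuits the
bootstrap (all subsamples are the whole sample), as does RDI when the
depth equals both sample sizes.

## Problem sizes used in validation

The test suite validates oracles on 100–200-sequence samples, calibrates
type-I error on 500 synthetic null replicates, checks planted-effect
recovery on 100 scaled cohorts (2 diets × ages 5/20/24 × 5 mice × 600
sequences), and runs the default 45 × 5000 cohort end to end once. These
sizes were chosen as the smallest at which the respective statistical
checks are informative.

## Known limitations

* Threshold detection assumes an approximately bimodal distance-to-nearest
  distribution; heavily mutated junctions blur the valley.
* The exact Mann-Whitney test at n = 5 per group has attainable size
  8/252 ≈ 0.032, not 0.05: discreteness makes it conservative.
* Cross-sample clone tracking, lineage trees, selection-strength and
  mutation-targeting analyses are out of scope.
* The per-mouse RDI covariate depends on group definitions; singleton
  groups yield a missing value.
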