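# Methods

This note documents the models and procedures implemented in
`genecentric`, the parameters that matter, the design decisions taken
where the procedure was genuinely open, and what the synthetic-data
tests do and do not demonstrate about real data.

## Study design and bookkeeping

`genecentric.study` encodes the three-cohort comparison design the
pipeline targets: per cohort, two phenotypic groups ("control" and
"disease" roles) of stool metagenomes. The bundled table carries both
sample and patient counts per (cohort, group, source study) because one
source contributed 48 samples from 10 patients; totals computed from it
(554 samples overall, 83 disease patients in cohort 1, 230 individuals
in cohort 3) are used as a bookkeeping check.

## RPKSM

For family *f* and sample *s*,

RPKSM = count / (L̄_kb · S · lib/10⁶),

with L̄_kb the mean member gene length in kilobases and S the member
count. Two open points were resolved as follows:

- **Length basis.** "Per kilobase per family size" does not pin down
  whether the kilobase term is the mean or the summed member length.
  The default uses the mean: with the summed length the family size
  would effectively be charged twice (sum = S·mean). The summed-basis
  alternative is exposed as `basis="total"`.
- **One read, one family.** A retained read increments exactly one
  family — the family of its single globally best gene — never several.
  This prevents double counting when families share sequence
  similarity. Best-hit selection is lowest E-value, ties broken by
  highest bit score, then lexicographically smallest gene id (a total
  order, so results are reproducible).
- Gene lengths are nucleotide-based; amino-acid inputs are converted
  ×3. The read E-value cutoff is a strict inequality (E < 10⁻¹⁰): a hit
  at exactly 10⁻¹⁰ is discarded.

## Family building

- **Header matching** is case-insensitive regular-expression search
  (plain substrings work unchanged); exclude patterns take precedence
  over includes, implementing negative matching for spurious
  annotations ("… kinase 2").
- **Length filter** defaults to [0.5, 1.5] × the reference enzyme's
  length, bounds inclusive. The symmetric fractional window is a
  configurable default, not a claim about any particular upstream
  pipeline.
- **Gap filter**: alignment rows with gap fraction ≥ 0.30 are removed
  (boundary excluded by construction of the rule).
- **Reference anchoring** threads the validated reference into the
  existing alignment columns by globally aligning it to the column
  consensus; reference insertions become new all-gap columns. For
  equal-length member sets (the synthetic generator's point-substituted
  families) this reduces to appending the reference row.
- **Tree and delimitation.** Pairwise p-distances over gap-free column
  pairs feed a neighbor-joining tree (negative branches clamped to
  zero), midpoint-rooted. The family is the largest clade containing
  the reference in which every leaf's path distance to the reference is
  ≤ d_max (default 0.6). NJ on p-distances deliberately replaces
  maximum-likelihood reconstruction: the delimitation contract is
  distance-based, and at the scale of one family the ML machinery adds
  runtime without changing the clustering decision. d_max = 0.6 sits
  far above the within-family divergence the generator emulates (~0.1
  substitutions/site) and far below the distance of unrelated proteins
  (p ≈ 0.95), so delimitation is insensitive to d_max over a wide
  range.
- The reference enzyme never counts toward S.

## Differential testing

- **Mann-Whitney U**, two-sided, U = min(U_a, U_b) with midranks.
  Exact enumeration is used when the pooled sample size is ≤ 12 with no
  ties; otherwise the normal approximation with tie correction and
  continuity correction. The switchover keeps exact computation cheap
  while all real group sizes use the approximation.
- **Benjamini-Hochberg** within each (cohort × feature-table) batch.
  Per-cohort batching is the conservative reading when the adjustment
  family is not otherwise specified.
- **Fold change** is the ratio of group medians (disease/control); 0/0
  is flagged flat, x/0 as infinite — flagged, not dropped.
- **Consistency rule**: direction identical (and non-flat) in every
  cohort, q < α in ≥ 2 cohorts. The exemption list removes named
  cohorts from the significance count only (their direction still must
  agree); the natural use is a cohort whose two arms are both diseased,
  where demanding significance would obscure genuine trends.
- α = 0.05 throughout, matching the usual single-star convention.
- Both raw p and q are reported for every test.

### Calibration of the USCG negative control

The control passes a run when none of the five single-copy genes
reaches q < α in any cohort. Under the global null with independent,
continuous p-values, BH makes at least one false rejection with
probability exactly α per batch (Simes' identity), so a three-cohort
run passes with probability at most (1 − α)³ ≈ 0.857. Discreteness of
the Mann-Whitney null distribution at moderate group sizes makes BH
conservative and raises the observed pass rate (≈ 0.88–0.93 at
n = 20/group over 100 runs), but no faithful multi-cohort simulation
can push the expected pass rate to 0.95 at α = 0.05. The validation
suite asserts the stricter bound regardless and is expected to flag
this; the control itself, on a single real study, is simply a
low-probability-of-false-alarm check, exactly as intended.

## Taxon-table post-processing

- Cleaning drops "unclassified" rows (any rank prefix) and clades whose
  mean abundance is zero across all samples of at least one cohort,
  *unless* the clade is present in exactly one comparison group of some
  cohort. The retention clause deliberately overrides cross-cohort
  zero-mean removal: a clade confined to one arm of one cohort is kept
  as a potential exclusive marker.
- Abundance thresholds (genus > 0.5%, species > 0.2%, strict) use the
  unweighted mean over all samples of a cohort, both groups pooled.
  Per-cohort means (rather than pooled across cohorts) match the
  per-cohort phrasing of the zero-mean rule.
- Both filters are idempotent; the shared-clade set is invariant to
  cohort ordering. Clade names are compared after stripping rank
  prefixes (g__, s__, …).

## Genome/plasmid screen

- Presence: coverage (hmm_to − hmm_from + 1)/profile_length > 0.90
  (strict), E < 0.01 and independent E < 0.01 (strict); any passing ORF
  hit makes the replicon carry the profile.
- Genome filter: completeness > 95 (strict; 95.0 is dropped) and all
  five USCG flags true. Clades require > 100 retained genomes (strict;
  100 is dropped). Prevalence is computed at genus and species rank
  from the same presence calls.
- Classes: core p > 0.80; accessory 0.20 ≤ p ≤ 0.80 (closed at both
  ends); highly accessory 0 < p < 0.20; absent p = 0. The closed
  accessory interval is the only reading consistent with three printed
  brackets plus a separate absent class.
- Plasmid curation keeps records that are non-partial, non-control and
  host-assigned; a plasmid counts once per gene regardless of copy
  number.
- ORF ids are `<replicon>_<serial>`; the replicon is recovered by
  splitting on the last underscore.

## Synthetic data: what it emulates and what it does not

The generator produces every input shape the pipeline consumes —
annotated protein FASTA pangenomes, per-sample 12-column tabular
alignment files, merged clade × sample percentage tables, HMMER3-style
per-domain scan tables, genome and plasmid metadata — with explicit
ground truth. The analyzed study provides no generative model (it
analyzes real data), so all distributional choices here are stand-ins,
chosen to be the simplest that make the recovery contracts sharp:

- **Hit counts** are Poisson with mean a_fs · S_f · L̄_f(kb) · lib_s/10⁶,
  so E[RPKSM] = a_fs exactly. An optional Gamma multiplier adds
  overdispersion; the default is pure Poisson. Disease effects are
  per-family fold changes on the baseline concentration a_f, covering
  depletion through ~10-fold enrichment — the effect-size range
  reported for real metabolic gene families.
- **Noise** is injected at stated rates, never learned: sub-threshold
  alignment rows (E ≥ 10⁻¹⁰, must be removed by the E-value filter),
  strictly worse secondary hits per read (must be removed by best-hit
  filtering), scan hits violating the coverage or E-value rules, and
  genome/plasmid records that must fall to the metadata filters.
- **Families** are derived from a random reference protein by
  independent point substitutions (divergence 0.10 by default), with
  three decoy types per family: spurious near-miss annotations,
  fragments at 40% of the reference length, and random sequences under
  the true annotation.
- **Taxon tables** are Dirichlet compositions (concentration 200 around
  fixed base proportions) normalized to 100% per sample, with an
  unclassified row, per-cohort-specific clades and one group-exclusive
  clade built in so every cleaning rule is exercised.
- **Screen carriers** are a fixed-size random subset of round(p·n)
  genomes rather than independent Bernoulli draws. This makes the
  configured prevalence sharp: recovered class labels can be checked
  exactly even for truths two binomial standard errors from a class
  boundary, while binomial-CI checks remain trivially valid.
- The default cohort design is the published three-cohort layout
  (117/121, 72/14, 105/125 samples); library sizes are uniform over
  0.5–2 million reads.

Not emulated: read-level sequences (FASTQ), sequencing-error models,
host contamination, phylogenetic correlation between families, and
compositional coupling between gene families. Passing the synthetic
suite therefore demonstrates correctness of the bookkeeping,
filtering, normalization and statistical machinery under a known
model — not robustness to the full messiness of real metagenomes.

## Validation problem sizes

The validation script (`scripts/acceptance.py`) uses: 20 families ×
10 samples with per-family expected read targets drawn log-uniformly in
[500, 1000] at the minimum library size (RPKSM rank recovery is a
statement about adequately covered families; below ~tens of reads
Poisson noise dominates ranks for trivial reasons); all 140 group-size
/ replicate combinations with pooled n ≤ 8 for the exact-test oracle;
1,000 null features at n = 20/group and 500 shifted features (σ = 1
log-normal, 4-fold shift) at n = 50/group for calibration and power;
10,000 random vectors for BH equivalence; two 200-genome clades with
truths {0, 0.05, 0.5, 0.85} for prevalence recovery; 100 simulated
pangenome families for builder recovery; and 100 replicate three-cohort
runs at n = 20/group for the USCG control. Numerical tolerances: exact
agreements are asserted to 10⁻¹², the calibration band is
[0.035, 0.065] on the raw rejection rate, and recovery thresholds are
Spearman ≥ 0.95 and ≥ 95% exact family recovery.

## Known limitations

- The alignment-stacking step requires equal-length sequences (true for
  the generator's point-substituted families); externally aligned FASTA
  must be supplied for real, indel-containing families.
- p-distances with pairwise gap deletion can be non-additive for very
  gappy alignments; delimitation is robust to this only because within-
  family distances are small.
- `compare_groups` tests features independently; no covariate
  adjustment or count-model shrinkage is provided (the statistical
  contract is the rank test, by design).
- The exact Mann-Whitney path requires tie-free data; tied small
  samples fall back to the corrected normal approximation.
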