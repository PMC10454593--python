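# Methods

This note documents the statistical model, the algorithmic and numerical
choices, and the synthetic-data generator behind `clonevo`, in the order
the pipeline runs.

## Inputs and conventions

The pipeline consumes, per patient: a multi-sample VCF of somatic variant
calls (tumor samples plus one matched normal, AD-style allelic depths
required), a tab-separated table of allele-specific copy-number segments
per sample (`sample, chrom, start, end, nMajor, nMinor` — the shape an
ASCAT-class caller emits), and a sample panel (`sample, purity, date,
sex`). All genomic coordinates are 1-based inclusive throughout. Copy
number is *not* inferred here; integer allele-specific states are trusted
as given. Purity is required as an explicit input because downstream CCF
correction is undefined without it. Non-PASS VCF rows are skipped by
default (upstream somatic filtering is assumed done); indels are parsed
and flagged but excluded from CCF estimation and clustering, which
operate on SNVs only. The patient's sex determines normal copy number on
the sex chromosomes (chrX: 1 in males, 2 in females) — this matters
because AR, a recurrent driver in prostate cancer, is X-linked.

## CCF estimation

Model: a variant carried by a fraction `ccf` of tumor cells on `m` of the
locus's `cn = n_major + n_minor` tumor copies has expected VAF

    E[vaf] = ccf · ρ · m / (ρ · cn + (1 − ρ) · n_normal)

with `ρ` the sample purity. Multiplicity is estimated per variant *and
per sample* (copy number can differ between samples, e.g. at an
amplified locus) as the `m ∈ {1..n_major}` minimizing
`|vaf − E[vaf | ccf = 1, m]|`, ties to the smaller `m`; the cap at
`n_major` encodes that a point mutation arises on one parental haplotype
and can only be multiplied up to that haplotype's copy number. The CCF
then inverts the formula.

Identifiability: from a single VAF only the product `m · ccf` is
identified; a subclonal variant at `m = 2` is indistinguishable from one
at `m = 1` with twice the CCF. The smaller-`m` convention resolves this
deterministically, and the property tests assert exact inversion where
the model is identifiable (clonal variants at any multiplicity, and
subclonal variants at `m = 1`) plus the product identity everywhere.

Raw CCFs slightly above 1 arise from binomial noise; they are reported
raw, clipped to 1.0 for clustering, and flagged above a cap of 1.2.
Variants with depth below 10 in any sample, in regions uncovered by
segments, or at zero tumor copies in any sample are excluded with a
logged reason (the pipeline was designed against ~100× exomes, where a
depth-10 floor removes only unusable sites).

## Dirichlet-process clustering

The clustering stage is a from-scratch binomial-emission Dirichlet-
process mixture, in the DPClust tradition. Published multi-sample
analyses of this kind often name only "a Dirichlet process algorithm",
leaving model and hyperparameters unstated; this module fixes an
explicit, reproducible reference semantics:

- Emission: `alt_is ~ Binomial(depth_is, φ_ks · c_is)` for variant `i` in
  cluster `k`, sample `s`, where `c_is` is the purity/copy-number/
  multiplicity conversion factor above. Counts, not point CCFs, enter the
  likelihood, so depth differences are weighted correctly.
- Cluster CCFs `φ_ks` live on a grid over [0, 1] with step 0.01
  (configurable) — fine enough relative to binomial noise at ~100×,
  cheap enough that the per-variant grid log-likelihood table
  (N × S × 101) is precomputed once; the Gibbs inner loop then only
  indexes it.
- Prior: Chinese restaurant process; the concentration `α` is resampled
  every sweep by the standard auxiliary-variable update under a
  Gamma(1, 1) hyperprior.
- Sampling: collapsed Gibbs over assignments with `φ` instantiated
  per cluster per sample from its grid posterior each sweep; a new
  cluster's marginal uses a uniform grid prior, independent across
  samples. Defaults: 2000 sweeps, 500 burn-in, trace thinned every 5.
- Hard assignment: posterior co-clustering frequencies, average-linkage
  hierarchical clustering on `1 − frequency`, cut at 0.5 — this damps
  Monte-Carlo noise relative to reading off the final sweep. Clusters
  smaller than `max(5, 2% of SNVs)` are folded into the nearest center
  (Euclidean over per-sample centers) to suppress spurious singleton
  clones from over-dispersed counts.
- Centers are posterior means of `φ` on the grid given the final hard
  memberships; clusters are labelled A, B, C… in descending order of
  total CCF, so the truncal clone is canonically "A".

All randomness flows through one integer seed; runs are bit-reproducible
for fixed inputs and config. The inner loop is numba-compiled, which
keeps the default 2000-sweep run on a few hundred SNVs under a second.

## Ploidy, WGD and copy-number events

Ploidy is the segment-length-weighted mean total copy number,
`Σ len_i (n_major_i + n_minor_i) / Σ len_i`, and WGD is declared when
ploidy exceeds 3 — a strict inequality, so ploidy exactly 3 is not WGD.

Event calling is relative to each sample's own ploidy, scaled by the
locus's normal copy number: the expected copies of a locus are
`ploidy · n_normal / 2`, so a hemizygous male chrX locus is expected at
half ploidy and is not miscalled as lost after WGD. Per gene (which must
be fully covered by segments; uncovered genes are no-calls):

- **LOH**: minor allele count exactly 0 over the whole span (integer
  input, so no tolerance), called only where the normal genome is
  heterozygous (`n_normal = 2`);
- **loss**: minimum total copies below `round(expected)` — relative to
  ploidy, so one copy in a tetraploid genome is a loss;
- **focal amplification**: any overlapping segment no longer than 10 Mb
  with total copies ≥ 2 × expected. The focality threshold and factor
  are configurable; there is no community-standard numeric rule, and a
  narrow high-copy spike against the genome background is the pattern
  being operationalized.

A gene straddling segments of different states takes the most extreme
state per event kind (minimum for LOH/loss, maximum for amplification)
with a warning. Arm-level calls use the length-weighted arm mean: gain
at ≥ expected + 0.6 copies, loss at ≤ expected − 0.6, LOH when ≥ 90% of
the covered arm has minor allele 0; arms under 50% segment coverage are
no-calls. Arm spans and the default gene set (PTEN, RB1, TP53, AR) ship
as editable hg38 TSVs in `clonevo/data/`.

Events are then compared across samples and partitioned into
shared-by-all (truncal candidates), shared-by-subset and private sets.

## Clone tree

The MRCA is the cluster whose CCF center is at least 0.9 in every
sample. Several qualifying clusters are merged into one root clone
(size-weighted mean center, with a warning — they are statistically
indistinguishable from one truncal population); if none qualifies the
maximin cluster is used with a prominent warning.

Remaining clusters attach greedily in descending total-CCF order, each
to the *deepest* existing node satisfying (a) the presence-subset rule —
every sample where the child is present (center > 0.10), the parent is
present too, with slack for barely-present samples — and (b) the
pigeonhole sum rule `center_parent ≥ Σ center_children − ε` in every
sample, with ε = 0.15 absorbing CCF estimation noise at ~100–150×
depth. When several nodes at maximal depth qualify, preference goes to
the attachment consistent with the copy-number sharing partition (a
cluster whose sample footprint falls inside a CNA sharing-set attaches
inside that branch) — this, plus branch decoration, is how "CNAs take
precedence over SNVs" is operationalized as an algorithm; remaining
ties break on cluster id, making construction deterministic. A cluster
satisfying the constraints nowhere attaches to the root flagged
`unplaced-constraint-violation`. The constructed tree is re-validated
against both rules before being returned.

Decoration: truncal events sit on the root; any other event decorates
every highest node whose sample footprint is contained in the event's
presence set (an event shared by two sibling branches therefore appears
on both, reflecting that the sampled tree has no node for that exact
footprint). Newick branch lengths are child-cluster SNV counts.

## Event timing

Samples sharing a collection date are pooled into one time point (an
event is present at a date if any sample collected then carries it).
Assuming persistence — once acquired, never lost — an event first
observed at date `t_k` with all earlier dates lacking it originated in
`(t_{k−1}, t_k]`; an event present at every date gets `(origin, t_1]`,
with "origin" denoting tumor initiation (no mutation-rate chronological
dating is attempted). A pattern that turns absent after being present is
flagged `non-persistent` and left un-timed; this is expected for events
private to one branch when lineages are sampled at different dates, a
known limitation of date-level timing rather than an error.

## Synthetic data

The generator emits exactly the formats the pipeline consumes plus a
`truth.json`. Clone CCFs in a `SimConfig` must satisfy the subset and
sum rules exactly (validated before any output); read counts follow the
same binomial model the clustering stage assumes, with Poisson depth
(default mean 100×, matching a typical ~90× exome), and segments show
each CNA's integer state in every sample where a carrying clone is
present — clonal copy number only, as in the consumed format; subclonal
CNA dosage effects on VAF are out of scope. SNVs acquired before a WGD
(clones on the root-to-WGD path) get multiplicity `n_major`, reproducing
the CCF ≈ 1 truncal signature after doubling; random SNV positions avoid
CNA intervals so those semantics stay exact.

Presets: `case1_like` (four dated samples 2012–2017 including one
ductal-morphology region, truncal WGD, truncal 53-SNV clone carrying a
PTEN SNV, focal chrX AR amplification absent only from the earliest
sample, ductal-private 1p LOH / 6q gain, and a 34-SNV clone private to
the last sample), `case2_like` (two synchronous regions with a 13q-LOH +
RB1-loss trunk and a 3p-gain / 4p-LOH / 17p-LOH branch private to the
neuroendocrine region; the panel's dates are ordinal region labels),
and `null_single_clone`. Purities (0.7 / 0.65) are plausible for
macro-dissected archival prostate tissue. The generator reproduces the
statistical structure the pipeline assumes — it does not model
sequencing error, FFPE artifacts, mapping bias, subclonal copy number or
violations of the infinite-sites/persistence assumptions, so passing
tests demonstrate correctness of the inference machinery under the
stated model, not robustness to every failure mode of real exomes.

## Scale of the bundled benchmarks

The test-suite and acceptance-script scenarios use 150–300 SNVs per
patient across 2–4 samples at 100–150× — desk-scale sizes chosen so a
full validation sweep (tens of simulations and pipeline runs) completes
in well under a minute while leaving the per-scenario statistical power
(binomial noise vs. cluster separation) representative of exome
practice.

## Known limitations

- Single-sample-per-lineage timing: branch-private events between
  non-nested dates are flagged rather than timed (see above).
- No uncertainty on the tree: one deterministic topology is returned,
  not a posterior over trees.
- Multiplicity is a point estimate; no mutation-copy-number posterior.
- LOH calling requires minor allele exactly 0, so subclonal LOH encoded
  as fractional states upstream would be missed (integer input assumed).
- The DP sampler's equivalence to any particular off-the-shelf
  implementation is not claimed; it is a documented reference semantics.
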