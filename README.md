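# clonevo

Multi-sample tumor clonal-evolution analysis: copy-number- and
purity-corrected cancer-cell-fraction (CCF) estimation, Dirichlet-process
clustering of SNVs into clones, whole-genome-doubling and gene/arm-level
copy-number event calling, clone-tree reconstruction with copy-number
precedence, and interval timing of events across dated samples.

The package is aimed at the longitudinal / multi-region exome setting:
a handful of tumor samples from one patient (different time points or
different regions of one resection), somatic SNVs called jointly against
a matched normal, and allele-specific copy-number segments with per-sample
purity from an ASCAT-style caller. From those it reconstructs which
mutation clusters define the most recent common ancestor (MRCA), how
subclones branch between samples, and when copy-number events such as a
focal androgen-receptor (AR) amplification arose relative to the sampling
dates. A first-class synthetic-data generator produces fully specified
patients (VCF + segments + panel + truth) for validation.

## The model

For a variant present in a fraction `CCF` of tumor cells on `m` of the
locus's `cn` tumor copies, in a sample of purity `ρ` whose contaminating
normal cells carry `n_normal` copies (2 for autosomes; 1 for chrX in
males), the expected variant allele frequency is

```
E[VAF] = CCF · ρ · m / (ρ · cn + (1 − ρ) · n_normal)
```

Multiplicity `m ∈ {1..n_major}` is chosen per variant and per sample as
the value whose clonal expectation is closest to the observed VAF; the
formula is then inverted to give the CCF.

Clustering treats each variant's alt count as
`Binomial(depth, φ_ks · c_is)`, where `φ_ks` is the CCF of cluster `k` in
sample `s` (on a 0.01 grid over [0, 1]) and `c_is` the variant-specific
VAF conversion factor above. Cluster membership follows a Chinese-
restaurant-process prior whose concentration `α` is resampled each sweep
under a Gamma(1, 1) hyperprior; inference is collapsed Gibbs sampling
(2000 sweeps, 500 burn-in by default) with hard assignments read off the
posterior co-clustering matrix (average-linkage cut). The clone tree is
built greedily under the classical pigeonhole sum rule
(`CCF_parent ≥ Σ CCF_children − ε` in every sample) and the
presence-subset rule, with copy-number sharing patterns given precedence
as a tie-breaker and as branch decorations. Ploidy is the segment-length-
weighted mean total copy number; whole-genome doubling (WGD) means
ploidy > 3.

## Worked example

Simulate the bundled four-sample longitudinal scenario (truncal WGD,
late focal chrX amplification, branching ductal/neuroendocrine lineages)
and analyse it:

```
$ clonevo simulate --preset case1_like --seed 1 --out demo/sim
$ clonevo run --vcf demo/sim/sim.vcf --segments demo/sim/segments.tsv \
              --panel demo/sim/panel.tsv --seed 1 --out demo/out
variants clustered: 182
clusters: 5
sample NE_2012: ploidy 3.90, WGD yes
sample NE_2015: ploidy 3.90, WGD yes
sample DUCTAL_2015: ploidy 3.85, WGD yes
sample NE_2017: ploidy 3.90, WGD yes
MRCA cluster: A
tree: ((E:34)B:40,C:30,D:25)A:53;
event AR (focal_amplification): (2012, 2015]
event 1p (LOH): non-persistent
event 1p (loss): non-persistent
event 6q (gain): non-persistent
```

Reading the output: all four samples are whole-genome doubled
(ploidy ≈ 3.9 > 3). Cluster A — 53 SNVs at CCF ≈ 1 in every sample — is
the MRCA; branch lengths in the Newick string are SNV counts, so the
34-SNV cluster E private to the last sample hangs below the
neuroendocrine branch B. The focal AR amplification is absent only from
the earliest sample and is therefore timed to the interval
(2012, 2015]. The 1p-LOH and 6q-gain events are private to the ductal
region sampled in 2015 and absent from the later sample, so date-level
persistence timing does not apply to them and they are flagged instead.
All tables (`ccf.tsv`, `clusters.tsv`, `assignments.tsv`, `events.tsv`,
`timed_events.tsv`), `tree.json` and `tree.nwk` are written to
`demo/out/`.

Every stage is also exposed separately (`clonevo ccf`, `clonevo cluster`,
`clonevo cnv`, `clonevo tree`) and reads/writes the same documented
files, so stages can be run and inspected independently.

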