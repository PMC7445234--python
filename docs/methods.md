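# Methods

## Model and assumptions

The package treats "cell identity" as a property maintained by a small
core of transcription factors: TFs whose expression is highly specific
to the query phenotype (identity TFs), plus co-factors that are more
specific than chance and are wired into the identity core in both
directions. Regulatory interactions are only accepted where three
independent layers of evidence align: the target's regulatory region is
active (H3K4me3 for promoters, H3K27ac for enhancers), the region is
accessible (DNase), and the source TF physically binds there (ChIP-seq).
Underlying assumptions:

- the background compendium spans enough cell types that specificity to
  the query is meaningful; polyA and total RNA libraries are never mixed
  (their coverage profiles differ systematically);
- enhancer–gene assignment is taken from the association table
  (GeneHancer-style) as given; chromatin conformation data are used only
  for validation, never for assignment;
- the TF ChIP-seq atlas need not be phenotype-specific — accessibility
  and histone gating supply the phenotype specificity;
- all genomic inputs share one genome build; chromosome names are
  matched as exact strings (a preflight check warns when peak files and
  annotation share no chromosome names, since silent aliasing yields
  empty networks).

## Specificity scoring

For one gene with expression x over query + N background samples
(TPM), Q = x/Σx and P is the indicator of the query sample.
JSD(P, Q) = H(M) − [H(P)+H(Q)]/2 with M = (P+Q)/2, base-2 logs and
0·log 0 := 0, hence JSD ∈ [0, 1] bits. Conventions:

- an all-zero profile returns 1.0 — an unexpressed TF is maximally
  non-specific, not undefined;
- the divergence itself is used, not its square root (the bounded [0,1]
  scale makes the "lowest 10" selection well defined);
- identity selection breaks JSD ties by lexicographic TF symbol so runs
  are reproducible.

The co-factor null treats each background sample in turn as a
pseudo-query against the remaining N−1 samples, mirroring the query
computation. The query's rank is 1 + (# null JSDs strictly below it),
clamped to [1, N] so the z-score stays on the null rank scale; z uses
the population moments of the uniform distribution on 1..N. The
z-of-rank reading was chosen over z-scoring the raw JSD value against
the null JSDs because the rank scale is distribution-free; the
alternative would be sensitive to the heavy right tail of null JSDs.
Identity and co-factor sets are disjoint by construction: the two roles
are distinct, and a top-10 TF always has an extreme rank anyway.

## Background assembly

Filtering precedes normalisation: depth filtering (strictly below
15,000 counts removed; exactly 15,000 retained) and greedy decorrelation
run on raw counts over all genes, and only the retained samples are
TPM-transformed. Pearson r with a zero-variance sample is defined as 0
so a degenerate sample can never block the greedy pass. The greedy
visit order comes from a seeded generator recorded in the output
sidecar, making the selection reproducible. Single-cell removal is
purely metadata-driven; no heuristic detection from expression is
attempted.

## Regions and network

- Promoter windows: 1500 bp up / 500 bp down of the TSS, strand-aware,
  clipped at position 0. A gene with several annotated TSSs is active if
  any window is active, and every active window is carried as a separate
  region.
- "Overlap" means ≥ 1 shared base, strand-blind, everywhere: activation
  calls, accessibility, and ChIP support. Requiring full containment of
  a ChIP peak in an accessible site was rejected because it discards
  peaks straddling site borders.
- Enhancer truncation uses the intersection of the annotated interval
  with each overlapping H3K27ac peak, so truncated pieces never extend
  beyond the annotation.
- DNase gating is mandatory by default; `--no-dnase` (logged) treats
  active regions as fully accessible for datasets without accessibility
  data.
- The co-factor connectivity filter is iterated to a fixpoint. Under the
  identity-anchored qualification rule a single pass already suffices
  (a co-factor's qualifying edges touch only identity TFs, which are
  never removed), but the fixpoint loop makes the invariant hold by
  construction and is what the tests verify against an independent
  delete-until-stable oracle.
- Cooperative/competitive classification is strictly per region: a TF
  pair may form a complex at one promoter and compete at an enhancer.
  Competitive requires only peak overlap without complex membership — no
  PPI evidence is demanded for the competitive call.
- Threshold calibration: pooled per-pair maximum reciprocal overlaps
  (one value per labelled pair per cell type); the threshold is the
  smallest *observed positive* overlap t such that for every observed
  value t' ≥ t the fraction of positives ≥ t' strictly exceeds the
  fraction of negatives ≥ t' — i.e. the point above which an observed
  co-localization is more likely to come from an interacting pair.
  Inseparable label sets raise an error rather than returning an
  arbitrary cutoff.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `n_top` | 10 | identity TFs = lowest-JSD TFs |
| `z_cut` | −1.5 | co-factor rank z-score cutoff (strict <) |
| `min_counts` | 15,000 | background sample depth floor (strict <) |
| `r_max` | 0.7 | decorrelation Pearson cutoff (strict <) |
| `up` / `down` | 1500 / 500 bp | promoter window extents |
| `ppi_min` | 800 | PPI confidence cutoff (strict >, 0–1000 scale) |
| `ro_min` | 0.62 | reciprocal peak overlap for cooperativity (≥) |
| `seed` | 1 | RNG seed for background selection |

`ro_min` defaults to 0.62; a data-derived cutoff (e.g. 0.6243 from a
large labelled calibration) can be substituted when labelled PPI data
are available via `calibrate_from_atlas`.

## Synthetic data generator

`moni.fixtures.generate_bundle` emulates every input around a planted
truth: 200 TFs + 100 non-TF genes on one chromosome (one gene per
100 kb slot so regions of different genes never collide), 50 background
samples + 1 query, 10 identity TFs (query-only expression), 5 co-factors
(strong in the query, weak in ~10% of background samples — which puts
their query JSD at rank 1 of the null, z ≈ −1.70 < −1.5 at N = 50),
and all remaining genes i.i.d. across samples so that background samples
are mutually uncorrelated and survive decorrelation. Planted edges get
consistent H3K4me3/H3K27ac/DNase/ChIP evidence; three cooperative
complexes (identical member peaks, PPI 900) and two competitive pairs
(50% reciprocal overlap, PPI 300) are laid out at designated identity
promoters; other co-bound TFs get disjoint peaks. Hi-C interactions link
each active enhancer to its owner's promoter window. Noise dials
(H3K27ac dropout, decoy ChIP evidence, expression noise, Hi-C thinning)
all default to 0 so recovery tests are exact; stochastic tests set them
explicitly.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: read-level noise and mapping
artifacts; overlapping genes and shared regulatory regions; enhancers
serving several genes; batch structure and compositional correlation in
expression compendia (real samples correlate far more than i.i.d.
counts, so real decorrelation removes most of a compendium); incomplete
or cell-type-biased ChIP atlases; indirect (non-physical) gold-standard
edges. Exact recovery on the fixture demonstrates internal consistency
of the pipeline's logic, not expected performance on ENCODE-scale data.

## Problem sizes and runtime

Tests and the acceptance script use the generator's default scale
(200 TFs, 50 background samples, ~40 planted edges), the package's
standard desk-scale configuration; a full pipeline run completes in
well under a second, and the whole test suite in a few seconds.
Degradation checks use binomial 3σ bands around the configured dropout
rates at this scale (~24 planted enhancers), which is why their bands
are wide.

## Numerical choices

- entropies via x·log₂x with the 0-term convention; no epsilon padding;
- TPM columns sum to 1e6 within 1e-9 relative; an all-zero sample stays
  all-zero (documented exception);
- all output tables have fixed sort orders and fixed float formatting,
  so identical runs are byte-identical;
- rank ties (equal null JSDs) resolve downward via strictly-below
  counting, the conservative direction for co-factor calling.

## Known limitations

- Edges are unsigned (no activation/repression distinction) and carry no
  strength; a TF without ChIP data in the atlas can never gain outgoing
  edges (logged as a warning).
- Multi-promoter genes contribute one region per TSS but a single
  active/inactive call per TF for enhancer linkage.
- The calibration estimator assumes the labelled overlap distributions
  are separable in their upper tail; heavily overlapping label sets
  raise an error by design.
- Hi-C validation matches raw annotated enhancer intervals (anchors are
  fragment-scale); truncated intervals are used everywhere else.
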