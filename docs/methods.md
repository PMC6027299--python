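# Methods

## Model and procedure

`cernet` infers candidate ceRNA (miRNA-sponge) triples from bulk
expression of three RNA classes in a tumor/normal design.  The working
assumption is that sponge activity is visible in co-expression: if a
lncRNA sequesters a miRNA that represses an mRNA, then across tumor
samples the lncRNA and mRNA rise and fall together while each moves
against the miRNA.  The pipeline therefore combines three orthogonal
filters — differential expression (the triple's members must be
dysregulated in tumor, in the directions consistent with an oncogenic
sponge: lncRNA and mRNA up, miRNA down), co-expression significance,
and catalogued miRNA–target interactions — and only combinations
passing all three become triples.

### Matrix preparation

Genes are kept when expressed (value > 0, missing counting as
unexpressed) in *strictly more than* a fraction `min_fraction` (default
0.9) of samples.  Remaining zero or missing values are replaced per
gene by half that gene's minimum non-zero value, and values are then
log2-transformed.  The order filter → impute → transform is enforced:
imputation needs the filter to have removed all-zero genes, the
transform needs strictly positive input.  Imputation is idempotent;
the transform is guarded by a flag so it cannot run twice.  "Expressed"
is read as value > 0 — the weakest reading consistent with FPKM-like
units — and the 90% boundary is strict (a gene expressed in exactly 90%
of samples is dropped); both conventions are tested explicitly.

Gene classes come either from per-class input matrices or from a
biotype table: biotypes `lincRNA`, `antisense`, `processed_transcript`,
`non_coding` with length > 200 nt are lncRNA, `protein_coding` is mRNA,
everything else is excluded.  When a transcript's length is unknown the
biotype alone decides.

### Differential expression

Per gene, a two-tailed Mann–Whitney U test compares tumor with normal.
With pooled sample size ≤ 12 and no ties the exact U null distribution
is used; otherwise the normal approximation with tie and continuity
correction.  The switch point is a package choice: 12 keeps exact
enumeration trivially cheap while covering the sizes where the normal
approximation is at its worst.  P-values are BH-adjusted within each
RNA class by default (the three dysregulated sets are defined per
class); a pooled mode is available.

"Fold change" is the difference of log2-scale group means (tumor −
normal).  This interpretation is the only one under which the default
gates are coherent — an upregulation cut of 1 next to a downregulation
cut of −0.6 only makes sense on the log2 scale — but the underlying
convention (means rather than medians, base 2) is an interpretation,
and the gates are fully configurable.  Fold-change bounds are
inclusive (≥ 1, ≤ −0.6), FDR bounds strict (< 0.001).

### Co-expression and threshold calibration

Pearson correlation is computed with the sample (n−1) convention over
**tumor samples only** by default: the sponge competition is a property
of the tumor compartment, and the imbalanced design means normal
samples would mostly add noise.  An all-sample mode exists behind a
flag.  Significance cutoffs are calibrated, not fixed: for each
cross-class pair type the PCC of *every* cross pair (all genes
surviving preparation, not only the dysregulated ones) forms an
empirical background distribution, and the positive / negative cutoffs
are its `quantile_level` / `1 − quantile_level` quantiles (default
0.95), computed with type-7 linear interpolation so results are
reproducible across environments.  The negative cutoff is deliberately
the lower-tail quantile of the same distribution rather than the
negated positive cutoff — correlation backgrounds of real expression
data are asymmetric, and the two tails differ.  On top of the quantile
cut, pairs must pass a two-sided p-value gate (default 1e-4) from the
Student-t transform t = r·√((n−2)/(1−r²)) on n−2 df.  Whether such a
p-value should come from a t reference or a permutation null is
under-determined; the t approximation is standard at these sample sizes
and is the package's choice.  Both inequalities are strict.  At the
scales this package targets the full cross-correlation matrices fit in
memory, so the complete PCC distribution is retained exactly rather
than approximated by a streaming sketch.

### Interactions and triple assembly

Interaction tables are merged with deduplication on (miRNA, target);
when a pair carries both evidence levels, `validated` wins.  Evidence
is routed per arm: the miRNA–mRNA arm requires `validated` evidence,
the miRNA–lncRNA arm accepts `predicted` (configurable) — matching how
public catalogs are built, validated databases for mRNA targets and
sequence-based prediction for lncRNA targets.  After restricting to
the dysregulated sets, one triple is emitted per (lncRNA, miRNA, mRNA)
combination such that the lncRNA–mRNA pair is significantly positive
and both partners are significantly negative with, and catalogued
against, the shared miRNA.  Output is sorted (lnc, mirna, mrna) for
stable diffs, and each row embeds its three supporting correlation
records so the table is self-contained.

### Network, hubs, coverage

The network's nodes are the genes of the emitted triples; edges are the
unique lncRNA–miRNA and miRNA–mRNA pairs (no direct lncRNA–mRNA edges —
that relation is mediated).  Betweenness centrality is unnormalized,
endpoint-excluding, with each unordered pair counted once (undirected
convention); normalized BC is available behind a flag.  Hubs are the
top-k (default 3) lncRNAs by BC, ties broken lexicographically.

A hub's subnetwork is **triple-scoped** by default: its members are the
miRNAs and mRNAs of the triples containing the hub.  The alternative
reading — the full two-hop graph neighborhood, in which a neighboring
miRNA drags in mRNAs it shares with other lncRNAs — is implemented
behind `scope="graph"`.  Triple scoping is the default because it makes
per-hub triple and mRNA counts well-defined and additive in the way
coverage tables are conventionally reported.  Coverage percentages
(members / full-network counts × 100) are rounded to two decimals;
union coverage unites member sets before counting.  Whether the network
is a single connected component is reported but never required.

### Enrichment

Over-representation of a query gene set in user-supplied GMT terms uses
the upper hypergeometric tail P(X ≥ k) with BH correction across terms
and a conventional report filter of p < 0.05.  The universe defaults to
all mRNAs surviving preparation; no annotation content is bundled, so
term databases (and their release-dependent term counts) are entirely
the user's input.

## Synthetic data

The generator emulates the regime the pipeline targets: log2-scale
gene baselines drawn from Uniform(3, 8); independent Normal(0,
noise_sd) noise; severe group imbalance; class-specific DE direction;
zeros injected on the linear scale (so the half-minimum imputation path
is really exercised); and planted correlation structure.  For each of
`n_triples` planted triples and each tumor sample j a latent activity
z_j ~ N(0, 1) is added to the triple's lncRNA and mRNA (loadings
`coupling_lnc`, `coupling_mrna`) and subtracted from its miRNA
(`coupling_mirna`), on top of the tumor-mean shifts `de_lfc_*`.  The
latent factor acts in tumor samples only, matching the tumor-only
correlation convention; normal samples draw from baseline.  A fraction
`frac_de_background` of non-planted genes receive the DE shift without
any correlation structure, so specificity (not just sensitivity) of
triple calling is testable.  One gene belongs to at most one planted
triple.  Interaction tables contain all planted (miRNA, lncRNA) and
(miRNA, mRNA) pairs plus `n_decoy_interactions` uniformly sampled false
pairs carrying the evidence class their target would need — decoys that
survive evidence routing and fail only on co-expression.

The documented strong-signal condition (the `SimConfig` defaults) is
100 tumor / 20 normal samples, 60/120/30 genes per class, 20 planted
triples, couplings 1.0 against noise 0.5, tumor shifts +2/+2/−1.5,
zero rate 0.02, 200 decoys, 20% background DE.  Under it a planted
lncRNA–mRNA pair has population correlation ≈ 1/(1+noise_sd²) = 0.8 in
tumor samples, far above the calibrated ~0.17 background cut, and the
full pipeline recovers the planted triples with precision and recall
≥ 0.9.  These problem sizes were chosen so a full pipeline run takes a
fraction of a second, making replicate studies cheap.

What the generator does **not** emulate: count noise (no
negative-binomial read model — values are Gaussian on the log scale),
isoform structure, sequence-level seed matching, overlapping triples
(a gene in several sponge relations), batch effects, or realistic
correlation backgrounds between non-planted genes (they are
independent).  Passing the recovery tests therefore shows the pipeline
correctly extracts the signature it defines; it does not certify
performance on real tumor data, where the background co-expression
structure is far richer.  No generative model is claimed for real
data; the latent-factor construction is a stand-in with controllable,
recoverable structure.

## Numerical choices and degenerate inputs

- Quantiles: numpy's default type-7 linear interpolation, stated and
  frozen for reproducibility.
- MWU with all observations identical returns p = 1 (the tie-corrected
  normal approximation is 0/0 there; no evidence either way).
- Zero-variance genes are skipped in correlation with a warning
  (undefined PCC), |r| = 1 maps to p = 0 with a warning.
- Empty matrices, empty interaction tables and zero-triple networks
  propagate cleanly (warnings, empty outputs, exit 0), never crash.
- All randomness flows from explicit integer seeds
  (`numpy.random.default_rng`); identical configuration gives
  byte-identical fixtures.

## Known limitations

- Correlation is marginal Pearson; no partial correlation or
  miRNA-conditioned sensitivity correlation, so triples reflect
  co-expression compatible with sponging, not causal evidence.
- The DE test assumes exchangeable samples within groups; no covariate
  adjustment or batch correction.
- Threshold calibration needs enough pairs for stable tail quantiles
  (a warning fires below 100 pairs per class pair).
- The ORA statistic ignores gene-set overlap structure and annotation
  bias; term content is entirely user-supplied.
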