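# cernet

Inference of dysregulated lncRNA-associated competing-endogenous-RNA
(ceRNA) networks from matched lncRNA / mRNA / miRNA expression profiles
of tumor and normal samples.

Under the ceRNA hypothesis, a long non-coding RNA can act as a miRNA
sponge: it shares miRNA binding sites with an mRNA, competes for the
shared miRNA, and thereby de-represses the mRNA.  At the expression
level this leaves a characteristic signature — the lncRNA and mRNA are
positively co-expressed while each is negatively co-expressed with the
shared miRNA.  `cernet` turns that signature into a pipeline:

1. **Matrix preparation** — keep genes expressed (value > 0) in more
   than 90% of samples, replace remaining zero/missing values per gene
   by (minimum non-zero value)/2, then log2-transform.
2. **Differential expression** — per-gene two-tailed Mann–Whitney U
   test of tumor vs normal with Benjamini–Hochberg FDR within each RNA
   class.  Defaults keep upregulated lncRNAs/mRNAs (log2FC ≥ 1,
   FDR < 0.001) and downregulated miRNAs (log2FC ≤ −0.6, FDR < 0.001):
   the candidate oncogenic sponges and the miRNAs they would deplete.
3. **Co-expression** — Pearson correlation
   `r(X,Y) = 1/(n−1) Σᵢ z_X(i)·z_Y(i)` over the *n* tumor samples, for
   every cross-class pair.  Significance cutoffs are not fixed numbers
   but the empirical 95% / 5% quantiles of each pair type's all-pairs
   PCC distribution, combined with a t-test p-value gate (p < 1e-4).
4. **Triple assembly** — merge validated miRNA–mRNA and predicted
   miRNA–lncRNA interaction tables, restrict them to the dysregulated
   sets, and emit a ceRNA triple (lncRNA, miRNA, mRNA) whenever a
   significantly positive lncRNA–mRNA pair shares a miRNA that is
   negatively co-expressed with, and catalogued against, both partners.
5. **Network analysis** — build the tripartite network (edges only
   lncRNA–miRNA and miRNA–mRNA), rank nodes by unnormalized betweenness
   centrality `BC(i) = Σ_{s≠i≠t} p_st(i)/p_st`, select the top-k hub
   lncRNAs, and report each hub subnetwork's coverage of the network's
   miRNAs, mRNAs and triples.
6. **Enrichment** — hypergeometric over-representation of subnetwork
   mRNAs against user-supplied GMT gene sets.

A synthetic-data generator plants sponge triples through a shared
latent factor per triple (lncRNA and mRNA load positively, the miRNA
negatively, in tumor samples only), so every stage can be scored
against ground truth.

## Worked example

```bash
cernet simulate --seed 11 --out fixture/
cernet run-all --fixture fixture/ --out run/
cernet report --coverage run/coverage.tsv
```

The simulated dataset has 100 tumor and 20 normal samples, 60 lncRNAs,
120 mRNAs, 30 miRNAs and 20 planted sponge triples.  `run-all` prints a
summary (abridged):

```
 "n_del": 28, "n_dem": 40, "n_demi": 22,
 "pairs_kept": {"pos_lnc_mrna": 20, "neg_lnc_mirna": 19, "neg_mrna_mirna": 20},
 "n_triples": 19, "n_nodes": 57, "n_edges": 38,
 "hubs": ["LNC0002", "LNC0003", "LNC0004"]
```

28 lncRNAs, 40 mRNAs and 22 miRNAs pass the DE gates (the planted DE
genes plus the simulated background DE genes); the co-expression and
interaction filters then cut the candidates down to 19 triples, all of
them planted (precision 1.0, recall 0.95 at this seed).  The same
stages are available individually (`preprocess`, `de`, `correlate`,
`triples`, `network`, `enrich`), reading and writing plain TSV/JSON.

The coverage report has one row per hub plus their union and the full
network, formatted as `count (percentage)` — e.g. the packaged
worked-example count table for a published gastric-cancer ceRNA network
(16 miRNAs, 130 mRNAs, 442 triples) renders as:

```
Associated network  No. of DEMis  No. of DEMs  No. of triples
3 hub lncRNAs       14 (87.5%)    114 (87.69%) 238 (53.85%)
RP5-1120P11         9 (56.25%)    64 (49.23%)  92 (20.81%)
DLEU2               7 (43.75%)    77 (59.23%)  96 (21.72%)
DDX11-AS1           6 (37.5%)     45 (34.62%)  51 (11.54%)
full network        16 (100%)     130 (100%)   442 (100%)
```

i.e. three hub lncRNAs alone account for 87.5% of the network's miRNAs
and over half of its sponge triples.

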