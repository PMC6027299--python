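{
 "connected": false,
 "genes_after_filter": {
  "lncRNA": 60,
  "mRNA": 120,
  "miRNA": 30
 },
 "hubs": [
  "LNC0002",
  "LNC0003",
  "LNC0004"
 ],
 "n_del": 28,
 "n_del_demi_interactions": 35,
 "n_dem": 40,
 "n_dem_demi_interactions": 51,
 "n_demi": 22,
 "n_edges": 38,
 "n_interactions": 240,
 "n_nodes": 57,
 "n_triples": 19,
 "nodes_by_class": {
  "lncRNA": 19,
  "mRNA": 19,
  "miRNA": 19
 },
 "pairs_kept": {
  "neg_lnc_mirna": 19,
  "neg_mrna_mirna": 20,
  "pos_lnc_mrna": 20
 }
}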