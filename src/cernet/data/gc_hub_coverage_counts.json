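{
  "description": "Worked-example member counts for the published gastric-cancer ceRNA network: 16 miRNAs, 130 mRNAs and 442 sponge triples in total, with the member counts of the three hub-lncRNA subnetworks and of their union. Percentages are recomputed by cernet.network.coverage_table_from_counts.",
  "totals": {"mirnas": 16, "mrnas": 130, "triples": 442},
  "union": {"mirnas": 14, "mrnas": 114, "triples": 238},
  "hubs": {
    "RP5-1120P11": {"mirnas": 9, "mrnas": 64, "triples": 92},
    "DLEU2": {"mirnas": 7, "mrnas": 77, "triples": 96},
    "DDX11-AS1": {"mirnas": 6, "mrnas": 45, "triples": 51}
  }
}
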