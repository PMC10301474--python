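{
  "comment": "Panel-restricted CYP2D6 star-allele definitions. defining_variants lists the panel assays at which the allele carries the variant (alt) base within its CYP2D6-derived segment. Activity values follow the CPIC/DPWG consensus; hybrid and deletion alleles are nonfunctional. probe_vector gives the allele's contribution to the (promoter, intron 6, exon 9) copy-number probes.",
  "alleles": [
    {"name": "*1",  "defining_variants": [], "activity_value": 1.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*2",  "defining_variants": ["c.886C>T", "c.1457G>C"], "activity_value": 1.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*2A", "defining_variants": ["c.-1584C>G", "c.886C>T", "c.1457G>C"], "activity_value": 1.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*3",  "defining_variants": ["c.775delA"], "activity_value": 0.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*4",  "defining_variants": ["c.100C>T", "c.506-1G>A", "c.1457G>C"], "activity_value": 0.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*5",  "defining_variants": [], "activity_value": 0.0, "structure_class": "deletion", "probe_vector": [0, 0, 0]},
    {"name": "*6",  "defining_variants": ["c.454delT"], "activity_value": 0.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*9",  "defining_variants": ["c.841_843delAAG"], "activity_value": 0.5, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*10", "defining_variants": ["c.100C>T", "c.1457G>C"], "activity_value": 0.25, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*13", "defining_variants": [], "activity_value": 0.0, "structure_class": "hybrid_2D7_2D6", "probe_vector": [0, 1, 1]},
    {"name": "*17", "defining_variants": ["c.320C>T", "c.886C>T", "c.1457G>C"], "activity_value": 0.5, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*27", "defining_variants": ["c.886C>T", "c.1320G>A", "c.1457G>C"], "activity_value": 1.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*29", "defining_variants": ["c.886C>T", "c.1012G>A", "c.1457G>C"], "activity_value": 0.5, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*35", "defining_variants": ["c.31G>A", "c.886C>T", "c.1457G>C"], "activity_value": 1.0, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*36", "defining_variants": ["c.100C>T"], "activity_value": 0.0, "structure_class": "hybrid_2D6_2D7_late", "probe_vector": [1, 1, 0]},
    {"name": "*41", "defining_variants": ["c.886C>T", "c.985+39G>A", "c.1457G>C"], "activity_value": 0.5, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*59", "defining_variants": ["c.886C>T", "c.980G>A", "c.1457G>C"], "activity_value": 0.5, "structure_class": "full", "probe_vector": [1, 1, 1]},
    {"name": "*68", "defining_variants": ["c.100C>T"], "activity_value": 0.0, "structure_class": "hybrid_2D6_2D7_early", "probe_vector": [1, 0, 0]}
  ]
}
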