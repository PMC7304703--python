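{
  "ontology_path": "ontology.owl",
  "tool_annotations_path": "tools.json",
  "dimension_roots": [
    "http://example.org/proteomics/operation#Operation",
    "http://example.org/proteomics/data#Type",
    "http://example.org/proteomics/format#Format"
  ],
  "inputs": [
    {"Type": "Mass_spectrum", "Format": "mzML"}
  ],
  "outputs": [
    {"Type": "Amino_acid_index_hydropathy"}
  ],
  "constraints": [
    {"template": "use_operation", "args": ["Peptide_identification"]},
    {"template": "use_operation", "args": ["Retention_time_prediction"]}
  ],
  "min_length": 1,
  "max_length": 3,
  "max_solutions": 100,
  "output_dir": "out",
  "exports": {"text": true, "dot": true, "shell": true, "cwl": true}
}
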