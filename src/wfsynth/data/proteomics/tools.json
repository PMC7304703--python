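{
  "functions": [
    {
      "id": "comet",
      "label": "Comet",
      "operation": ["Peptide_database_search"],
      "inputs": [
        {"Type": ["Mass_spectrum"], "Format": ["mzML", "mzXML"]}
      ],
      "outputs": [
        {"Type": ["Peptide_identification"], "Format": ["pepXML"]}
      ],
      "implementation": {"shell_command": "cat {in1} > {out1}"}
    },
    {
      "id": "msconvert",
      "label": "msconvert",
      "operation": ["Formatting", "Filtering"],
      "inputs": [
        {"Type": ["Mass_spectrum"], "Format": ["MGF", "mzXML", "mzML"]}
      ],
      "outputs": [
        {"Type": ["Mass_spectrum"], "Format": ["MGF", "mzXML", "mzML"]}
      ],
      "implementation": {"shell_command": "cat {in1} > {out1}"}
    },
    {
      "id": "peptide_prophet",
      "label": "Peptide Prophet",
      "operation": ["Peptide_identification", "Statistical_modelling"],
      "inputs": [
        {"Type": ["Peptide_identification"], "Format": ["pepXML", "mzIdentML"]}
      ],
      "outputs": [
        {"Type": ["Peptide_identification"], "Format": ["pepXML"]}
      ],
      "implementation": {"shell_command": "cat {in1} > {out1}"}
    },
    {
      "id": "rt4",
      "label": "rt4",
      "operation": ["Retention_time_prediction"],
      "inputs": [
        {"Type": ["Peptide_property"], "Format": ["TSV", "pepXML"]}
      ],
      "outputs": [
        {"Type": ["Amino_acid_index_hydropathy"], "Format": ["TSV", "XML"]}
      ],
      "implementation": {"shell_command": "cat {in1} > {out1}"}
    },
    {
      "id": "ssrcalc",
      "label": "SSRCalc",
      "operation": ["Retention_time_prediction"],
      "inputs": [
        {"Type": ["Peptide_property"], "Format": ["Textual_format", "TSV"]}
      ],
      "outputs": [
        {"Type": ["Amino_acid_index_hydropathy"], "Format": ["Textual_format"]}
      ],
      "implementation": {"shell_command": "cat {in1} > {out1}"}
    },
    {
      "id": "xml2tsv",
      "label": "xml2tsv",
      "operation": ["Conversion"],
      "inputs": [
        {"Type": ["Peptide_identification"], "Format": ["mzIdentML"]}
      ],
      "outputs": [
        {"Type": ["Peptide_identification"], "Format": ["TSV"]}
      ],
      "implementation": {"shell_command": "cat {in1} > {out1}"}
    }
  ]
}
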