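{
  "hydropathy_any_format": [
    "comet@0 comet@0 rt4@0",
    "comet@0 comet@0 rt4@1",
    "comet@0 msconvert@0 rt4@0",
    "comet@0 msconvert@0 rt4@1",
    "comet@0 msconvert@1 rt4@0",
    "comet@0 msconvert@1 rt4@1",
    "comet@0 msconvert@2 rt4@0",
    "comet@0 msconvert@2 rt4@1",
    "comet@0 peptide_prophet@0 rt4@0",
    "comet@0 peptide_prophet@0 rt4@1",
    "comet@0 rt4@0",
    "comet@0 rt4@0 comet@0",
    "comet@0 rt4@0 msconvert@0",
    "comet@0 rt4@0 msconvert@1",
    "comet@0 rt4@0 msconvert@2",
    "comet@0 rt4@0 peptide_prophet@0",
    "comet@0 rt4@0 rt4@0",
    "comet@0 rt4@0 rt4@1",
    "comet@0 rt4@0 ssrcalc@0",
    "comet@0 rt4@1",
    "comet@0 rt4@1 comet@0",
    "comet@0 rt4@1 msconvert@0",
    "comet@0 rt4@1 msconvert@1",
    "comet@0 rt4@1 msconvert@2",
    "comet@0 rt4@1 peptide_prophet@0",
    "comet@0 rt4@1 rt4@0",
    "comet@0 rt4@1 rt4@1",
    "msconvert@0 comet@0 rt4@0",
    "msconvert@0 comet@0 rt4@1",
    "msconvert@1 comet@0 rt4@0",
    "msconvert@1 comet@0 rt4@1",
    "msconvert@2 comet@0 rt4@0",
    "msconvert@2 comet@0 rt4@1"
  ],
  "hydropathy_constrained": [
    "comet@0 comet@0 rt4@0",
    "comet@0 comet@0 rt4@1",
    "comet@0 msconvert@0 rt4@0",
    "comet@0 msconvert@0 rt4@1",
    "comet@0 msconvert@1 rt4@0",
    "comet@0 msconvert@1 rt4@1",
    "comet@0 msconvert@2 rt4@0",
    "comet@0 msconvert@2 rt4@1",
    "comet@0 peptide_prophet@0 rt4@0",
    "comet@0 peptide_prophet@0 rt4@1",
    "comet@0 rt4@0",
    "comet@0 rt4@0 comet@0",
    "comet@0 rt4@0 msconvert@0",
    "comet@0 rt4@0 msconvert@1",
    "comet@0 rt4@0 msconvert@2",
    "comet@0 rt4@0 peptide_prophet@0",
    "comet@0 rt4@0 rt4@0",
    "comet@0 rt4@0 rt4@1",
    "comet@0 rt4@0 ssrcalc@0",
    "comet@0 rt4@1",
    "comet@0 rt4@1 comet@0",
    "comet@0 rt4@1 msconvert@0",
    "comet@0 rt4@1 msconvert@1",
    "comet@0 rt4@1 msconvert@2",
    "comet@0 rt4@1 peptide_prophet@0",
    "comet@0 rt4@1 rt4@0",
    "comet@0 rt4@1 rt4@1",
    "msconvert@0 comet@0 rt4@0",
    "msconvert@0 comet@0 rt4@1",
    "msconvert@1 comet@0 rt4@0",
    "msconvert@1 comet@0 rt4@1",
    "msconvert@2 comet@0 rt4@0",
    "msconvert@2 comet@0 rt4@1"
  ],
  "peptide_identification_tsv": []
}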