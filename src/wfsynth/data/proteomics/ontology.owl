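<?xml version="1.0"?>
<rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#" xmlns:rdfs="http://www.w3.org/2000/01/rdf-schema#" xmlns:owl="http://www.w3.org/2002/07/owl#">
  <owl:Class rdf:about="http://example.org/proteomics/operation#Operation">
    <rdfs:label>Operation</rdfs:label>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Peptide_identification">
    <rdfs:label>Peptide identification</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Peptide_database_search">
    <rdfs:label>Peptide database search</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Peptide_identification"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Validation_of_peptide_spectrum_matches">
    <rdfs:label>Validation of peptide spectrum matches</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Formatting">
    <rdfs:label>Formatting</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Filtering">
    <rdfs:label>Filtering</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Conversion">
    <rdfs:label>Conversion</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Statistical_modelling">
    <rdfs:label>Statistical modelling</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/operation#Retention_time_prediction">
    <rdfs:label>Retention time prediction</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/operation#Operation"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/data#Type">
    <rdfs:label>Type</rdfs:label>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/data#Mass_spectrum">
    <rdfs:label>Mass spectrum</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/data#Type"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/data#Peptide_property">
    <rdfs:label>Peptide property</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/data#Type"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/data#Peptide_identification">
    <rdfs:label>Peptide identification</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/data#Peptide_property"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/data#Amino_acid_index">
    <rdfs:label>Amino acid index</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/data#Peptide_property"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/data#Amino_acid_index_hydropathy">
    <rdfs:label>Amino acid index (hydropathy)</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/data#Amino_acid_index"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#Format">
    <rdfs:label>Format</rdfs:label>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#Thermo_RAW_format">
    <rdfs:label>Thermo RAW format</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#Format"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#Textual_format">
    <rdfs:label>Textual format</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#Format"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#TSV">
    <rdfs:label>TSV</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#Textual_format"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#MGF">
    <rdfs:label>MGF</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#Textual_format"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#XML">
    <rdfs:label>XML</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#Format"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#mzML">
    <rdfs:label>mzML</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#XML"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#mzXML">
    <rdfs:label>mzXML</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#XML"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#pepXML">
    <rdfs:label>pepXML</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#XML"/>
  </owl:Class>
  <owl:Class rdf:about="http://example.org/proteomics/format#mzIdentML">
    <rdfs:label>mzIdentML</rdfs:label>
    <rdfs:subClassOf rdf:resource="http://example.org/proteomics/format#XML"/>
  </owl:Class>
</rdf:RDF>
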