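# The same prostate-carcinoma weight question (Q1) as an OWL/Turtle model:
# concept classes described by someValuesFrom restrictions, the query as a
# boolean class expression over the concept classes.
@prefix sox: <http://example.org/sox#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

# --- XML structure tree ---------------------------------------------------

sox:pehr a sox:XML_Structure ;
    sox:local_name "pehr" ;
    sox:namespace "urn:soxpath:synth:base" ;
    sox:children ( sox:content ) .

sox:content a sox:XML_Structure ;
    sox:local_name "content" ;
    sox:namespace "urn:soxpath:synth:base" ;
    sox:children ( sox:Macroscopy sox:Overall_interpretation sox:Localisation sox:Typification ) .

sox:Macroscopy a sox:XML_Structure ;
    sox:local_name "Macroscopy" ;
    sox:namespace "urn:soxpath:synth:findings" .

sox:Overall_interpretation a sox:XML_Structure ;
    sox:local_name "Overall_interpretation" ;
    sox:namespace "urn:soxpath:synth:interp" .

sox:Localisation a sox:XML_Structure ;
    sox:local_name "Localisation" ;
    sox:namespace "urn:soxpath:synth:interp" .

sox:Typification a sox:XML_Structure ;
    sox:local_name "Typification" ;
    sox:namespace "urn:soxpath:synth:interp" .

# --- search terms ---------------------------------------------------------

sox:g_unit a sox:Simple_Term ; rdfs:label "g" .
sox:blister a sox:Simple_Term ; rdfs:label "Blister(\\w)*" .
sox:adenocarcinoma a sox:Simple_Term ; rdfs:label "Adenokarzinom(\\w)*" .
sox:icd_o_c61 a sox:Simple_Term ; rdfs:label "C61" .
sox:icd_o_m8140_3 a sox:Simple_Term ; rdfs:label "M-8140/3" .

# --- search concepts: term bound to a structure node ----------------------

sox:g_unit_in_macro a sox:Search_Concept ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:described_by ; owl:someValuesFrom sox:g_unit ] ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:in ; owl:someValuesFrom sox:Macroscopy ] .

sox:blister_in_interp a sox:Search_Concept ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:described_by ; owl:someValuesFrom sox:blister ] ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:in ; owl:someValuesFrom sox:Overall_interpretation ] .

sox:adeno_in_interp a sox:Search_Concept ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:described_by ; owl:someValuesFrom sox:adenocarcinoma ] ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:in ; owl:someValuesFrom sox:Overall_interpretation ] .

sox:c61_in_loc a sox:Search_Concept ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:described_by ; owl:someValuesFrom sox:icd_o_c61 ] ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:in ; owl:someValuesFrom sox:Localisation ] .

sox:m8140_in_typ a sox:Search_Concept ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:described_by ; owl:someValuesFrom sox:icd_o_m8140_3 ] ;
    rdfs:subClassOf [ a owl:Restriction ;
        owl:onProperty sox:in ; owl:someValuesFrom sox:Typification ] .

# --- the query: boolean class expression ----------------------------------

sox:Q1 a sox:Search_Query ;
    rdfs:subClassOf [
        owl:intersectionOf (
            sox:g_unit_in_macro
            [ owl:complementOf sox:blister_in_interp ]
            [ owl:unionOf (
                sox:adeno_in_interp
                [ owl:intersectionOf ( sox:c61_in_loc sox:m8140_in_typ ) ]
            ) ]
        )
    ] .
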