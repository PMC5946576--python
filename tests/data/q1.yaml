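# Prostate-carcinoma weight question (Q1) in the native model format:
# gram unit in Macroscopy, no Blister in the interpretation, and either the
# adenocarcinoma term in the interpretation or the ICD-O topography +
# morphology code pair.
structure:
  name: pehr
  namespace: urn:soxpath:synth:base
  children:
    - name: content
      namespace: urn:soxpath:synth:base
      children:
        - {name: Macroscopy, namespace: 'urn:soxpath:synth:findings'}
        - {name: Overall_interpretation, namespace: 'urn:soxpath:synth:interp'}
        - {name: Localisation, namespace: 'urn:soxpath:synth:interp'}
        - {name: Typification, namespace: 'urn:soxpath:synth:interp'}

simple_terms:
  g_unit:
    - 'g'
  blister:
    - 'Blister(\w)*'
  adenocarcinoma:
    - 'Adenokarzinom(\w)*'
  icd_o_c61:
    - 'C61'
  icd_o_m8140_3:
    - 'M-8140/3'

concepts:
  g_unit_in_macro: {term: g_unit, node: Macroscopy}
  blister_in_interp: {term: blister, node: Overall_interpretation}
  adeno_in_interp: {term: adenocarcinoma, node: Overall_interpretation}
  c61_in_loc: {term: icd_o_c61, node: Localisation}
  m8140_in_typ: {term: icd_o_m8140_3, node: Typification}

queries:
  Q1:
    - and
    - g_unit_in_macro
    - [not, blister_in_interp]
    - [or, adeno_in_interp, [and, c61_in_loc, m8140_in_typ]]
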