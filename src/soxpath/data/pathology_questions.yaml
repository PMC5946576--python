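# Five pathology research questions over section-structured PEHR documents,
# in the native model format (seven query variants: Q2 and Q5 split in two).
structure:
  name: pehr
  namespace: urn:soxpath:synth:base
  children:
    - name: content
      namespace: urn:soxpath:synth:base
      children:
        - {name: Material, namespace: 'urn:soxpath:synth:findings'}
        - {name: Macroscopy, namespace: 'urn:soxpath:synth:findings'}
        - {name: Microscopy, namespace: 'urn:soxpath:synth:findings'}
        - {name: Overall_interpretation, namespace: 'urn:soxpath:synth:interp'}
        - {name: Overall_staging, namespace: 'urn:soxpath:synth:interp'}
        - name: Localisation
          namespace: 'urn:soxpath:synth:interp'
          children:
            - {name: value, namespace: 'urn:soxpath:synth:icd', id: icd_value}
        - {name: Typification, namespace: 'urn:soxpath:synth:interp'}
        - name: staging
          namespace: 'urn:soxpath:synth:interp'
          children:
            - {name: value, namespace: 'urn:soxpath:synth:tnm', id: tnm_value}

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
  k_no_rest:
    - 'ohne Rest(\w)*'
  k_rest:
    - 'mit Rest(\w)*'
  prostate_flake:
    - 'Prostataspan(\w)*'
    - 'Prostataspäne'
  cm_unit:
    - 'cm'
  leiomyoma:
    - 'Leiomyom(\w)*'
  uterus:
    - 'Uterus(\w)*'
  icd_o_c18:
    - 'C18'
  colon:
    - 'Colon(\w)*'
  t2:
    - 'pT2(a|b|c)?'
  tnm_sub_pn:
    - 'pN[0-3](\w)*'
  barretts_mucosa:
    - 'Barrett-Schleimhaut'
  cave_no_barrett:
    - 'ohne Nachweis einer Barrett-Schleimhaut'
  esophagus_biopsy:
    - 'Ösophagusbiopsie(\w)*'
    - 'Ösophagus-PE'

concepts:
  g_unit_in_macro: {term: g_unit, node: Macroscopy}
  blister_in_interp: {term: blister, node: Overall_interpretation}
  adeno_in_interp: {term: adenocarcinoma, node: Overall_interpretation}
  c61_in_loc: {term: icd_o_c61, node: Localisation}
  m8140_in_typ: {term: icd_o_m8140_3, node: Typification}
  k_no_rest_in_macro: {term: k_no_rest, node: Macroscopy}
  k_rest_in_macro: {term: k_rest, node: Macroscopy}
  flake_in_macro: {term: prostate_flake, node: Macroscopy}
  flake_in_interp: {term: prostate_flake, node: Overall_interpretation}
  cm_unit_in_interp: {term: cm_unit, node: Overall_interpretation}
  leiomyoma_in_interp: {term: leiomyoma, node: Overall_interpretation}
  uterus_in_material: {term: uterus, node: Material}
  c18_in_loc: {term: icd_o_c18, node: Localisation}
  colon_in_material: {term: colon, node: Material}
  t2_in_staging: {term: t2, node: Overall_staging}
  pn_in_staging: {term: tnm_sub_pn, node: staging}
  barrett_in_interp: {term: barretts_mucosa, node: Overall_interpretation}
  cave_in_interp: {term: cave_no_barrett, node: Overall_interpretation}
  esophagus_in_material: {term: esophagus_biopsy, node: Material}

queries:
  Q1:
    - and
    - g_unit_in_macro
    - [not, blister_in_interp]
    - [or, adeno_in_interp, [and, c61_in_loc, m8140_in_typ]]
  Q2_without_residual:
    - and
    - k_no_rest_in_macro
    - [not, blister_in_interp]
    - [or, adeno_in_interp, [and, c61_in_loc, m8140_in_typ]]
    - [or, flake_in_macro, flake_in_interp]
  Q2_with_residual:
    - and
    - k_rest_in_macro
    - [not, blister_in_interp]
    - [or, adeno_in_interp, [and, c61_in_loc, m8140_in_typ]]
    - [or, flake_in_macro, flake_in_interp]
  Q3:
    - and
    - cm_unit_in_interp
    - leiomyoma_in_interp
    - uterus_in_material
  Q4:
    - and
    - [or, c18_in_loc, colon_in_material]
    - t2_in_staging
    - pn_in_staging
  Q5_numerator:
    - and
    - barrett_in_interp
    - [not, cave_in_interp]
  Q5_denominator: esophagus_in_material
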