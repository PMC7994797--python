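regions:
- id: body
  name: body
  patterns:
  - body
  - whole body
- id: chest
  name: chest
  patterns:
  - chest
  - thorax
- id: lungs
  name: lungs
  patterns:
  - lungs
- id: left_lung
  name: left lung
  patterns:
  - left lung
- id: right_lung
  name: right lung
  patterns:
  - right lung
- id: abdomen
  name: abdomen
  patterns:
  - abdomen
- id: liver
  name: liver
  patterns:
  - liver
  - hepatic
- id: spleen
  name: spleen
  patterns:
  - spleen
  - splenic
- id: kidneys
  name: kidneys
  patterns:
  - kidneys
  - renal
- id: left_kidney
  name: left kidney
  patterns:
  - left kidney
- id: right_kidney
  name: right kidney
  patterns:
  - right kidney
- id: lymph_nodes
  name: lymph nodes
  patterns:
  - lymph nodes
  - lymph node
- id: axillary_lymph_nodes
  name: axillary lymph nodes
  patterns:
  - axillary lymph nodes
  - axillary lymph node
- id: inguinal_lymph_nodes
  name: inguinal lymph nodes
  patterns:
  - inguinal lymph nodes
  - inguinal lymph node
edges:
- - abdomen
  - kidneys
- - abdomen
  - liver
- - abdomen
  - spleen
- - body
  - abdomen
- - body
  - chest
- - body
  - lymph_nodes
- - chest
  - lungs
- - kidneys
  - left_kidney
- - kidneys
  - right_kidney
- - lungs
  - left_lung
- - lungs
  - right_lung
- - lymph_nodes
  - axillary_lymph_nodes
- - lymph_nodes
  - inguinal_lymph_nodes
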