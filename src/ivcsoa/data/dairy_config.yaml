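# Worked-example model configuration: dairy-products establishment,
# food product line.  Weights are the published percentages expressed as
# fractions (the transversal group sums to 0.9999 and is renormalized at
# validation); reference tables carry the published condition labels.
betas:
  vt: 0.45
  vp: 0.25
  soa: 0.30
soa_aggregation: max
variables:
  - id: VT1
    name: "Tipo de actividad de la cadena productiva"
    scope: transversal
    product_line: all
    weight: 0.1124
    reference_table:
      entries:
        - {condition: "Fabrica, almacena y distribuye", score: 4}
  - id: VT2
    name: "Cumplimiento de estándares sanitarios"
    scope: transversal
    product_line: all
    weight: 0.1852
    reference_table:
      entries:
        - {condition: "Favorable con observaciones", score: 3}
  - id: VT3
    name: "Tiempo transcurrido desde la última visita"
    scope: transversal
    product_line: all
    weight: 0.0508
    reference_table:
      entries:
        - {condition: "Dos años y dos meses", score: 3}
        - {condition: "Más de cuatro años", score: 5}
  - id: VT4
    name: "Medidas sanitarias aplicadas al establecimiento"
    scope: transversal
    product_line: all
    weight: 0.2250
    reference_table:
      entries:
        - {condition: "Una medida en los últimos 3 años", score: 2}
  - id: VT5
    name: "Histórico de denuncias asociadas al establecimiento"
    scope: transversal
    product_line: all
    weight: 0.1343
    reference_table:
      entries:
        - {condition: "Una denuncia por publicidad", score: 3}
  - id: VT6
    name: "Número de registros por establecimiento"
    scope: transversal
    product_line: all
    weight: 0.1432
    reference_table:
      entries:
        - {condition: "1 para quesos frescos, 1 para quesos madurados", score: 2}
  - id: VT7
    name: "Responsable técnico ante la autoridad sanitaria"
    scope: transversal
    product_line: all
    weight: 0.1490
    reference_table:
      entries:
        - {condition: "No tiene responsable técnico, el cargo está vacante", score: 5}
  - id: VP1
    name: "Tipo de establecimiento"
    scope: propia
    product_line: alimentos
    weight: 0.37
    reference_table:
      entries:
        - {condition: "Derivados lácteos (lácteos de alto riesgo)", score: 5}
  - id: VP2
    name: "Reporte ETA"
    scope: propia
    product_line: alimentos
    weight: 0.53
    reference_table:
      entries:
        - {condition: "1 ETA en 1 año", score: 4}
  - id: VP3
    name: "Certificación HACCP"
    scope: propia
    product_line: alimentos
    weight: 0.10
    reference_table:
      entries:
        - {condition: "No certificada HACCP", score: 3}
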