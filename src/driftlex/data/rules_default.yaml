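# Default keyword rule sets: pandemic context, five topics, four countries.
# Keywords are data, not code; phrases are normalized at load time.
context:
  - covid
  - covid19
  - coronavirus
topics:
  government:
    - corrupcion
    - gestion
    - politico
    - democracia
    - gobierno
    - autoridad
  health:
    - depresion
    - estres
    - psicologo
    - angustia
    - confinamiento
    - aislamiento
  economy:
    - negocio
    - empresa
    - deuda
    - quiebra
    - pib
    - economia
  employment:
    - zoom
    - skype
    - videoconferencia
    - desempleo
    - despido
    - teletrabajo
  vaccines:
    - astrazeneca
    - pfizer
    - pcr
    - antigenos
    - eficacia
    - vacuna
countries:
  - CL
  - MX
  - PE
  - ES
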