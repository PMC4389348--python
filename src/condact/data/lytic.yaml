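# Lytic-pathway condition preset (VALUE-EMPTY placeholder).
# See lysogenic.yaml; transcribe the lytic fixed-point concentrations.
pathway: lytic
temperature_K: 310
concentrations_M:
  CI2: null    # TODO: transcribe (lytic fixed point)
  Cro2: null   # TODO: transcribe (lytic fixed point)
  RNAP: null   # TODO: transcribe (free RNAP concentration)
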