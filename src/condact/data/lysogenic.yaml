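# Lysogenic-pathway condition preset (VALUE-EMPTY placeholder).
# Concentrations are the fixed-point values of the protein production /
# degradation model they were derived from in the literature (dimer and
# RNAP concentrations, molar); transcribe them before use.
pathway: lysogenic
temperature_K: 310
concentrations_M:
  CI2: null    # TODO: transcribe (lysogenic fixed point)
  Cro2: null   # TODO: transcribe (lysogenic fixed point)
  RNAP: null   # TODO: transcribe (free RNAP concentration)
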