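# Phage-lambda switch free-energy parameters (schema-complete, VALUE-EMPTY).
#
# Every delta_g below is null on purpose: the numerical binding and
# cooperativity energies must be transcribed from the experimental
# literature (see the provenance slots) before pathway reports are
# meaningful.  The loader flags a file with null values as a placeholder and
# pathway_report refuses it unless explicitly overridden.
#
# Suggested sources to transcribe from:
#   - Santillan & Mackey (2004), Biophys J 86:75-84 (collected parameter set)
#   - Darling, Holt & Ackers (2000), J Mol Biol 302:625-638 (CI energetics)
#   - Reinitz & Vaisnys (1990), J Theor Biol 145:295-318 (Cro / RNAP)
units: kcal/mol
intrinsic_energies:
  - {site: O_R1, species: CI2,  delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_R2, species: CI2,  delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_R3, species: CI2,  delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_L1, species: CI2,  delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_L2, species: CI2,  delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_L3, species: CI2,  delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_R1, species: Cro2, delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_R2, species: Cro2, delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_R3, species: Cro2, delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_L1, species: Cro2, delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_L2, species: Cro2, delta_g: null, provenance: "TODO: transcribe"}
  - {site: O_L3, species: Cro2, delta_g: null, provenance: "TODO: transcribe"}
  - {site: P_R,  species: RNAP, delta_g: null, provenance: "TODO: transcribe"}
  - {site: P_RM, species: RNAP, delta_g: null, provenance: "TODO: transcribe"}
  - {site: P_L,  species: RNAP, delta_g: null, provenance: "TODO: transcribe"}
pair_cooperativities:
  - {site_a: O_R1, species_a: CI2, site_b: O_R2, species_b: CI2, delta_g: null,
     provenance: "TODO: transcribe"}
  - {site_a: O_R2, species_a: CI2, site_b: O_R3, species_b: CI2, delta_g: null,
     provenance: "TODO: transcribe"}
  - {site_a: O_L1, species_a: CI2, site_b: O_L2, species_b: CI2, delta_g: null,
     provenance: "TODO: transcribe"}
  - {site_a: O_L2, species_a: CI2, site_b: O_L3, species_b: CI2, delta_g: null,
     provenance: "TODO: transcribe"}
  # CI-RNAP stabilization at O_R2 / P_RM may be added here as a binding
  # energy; transcription-rate enhancement is outside this model's scope.
  - {site_a: O_R2, species_a: CI2, site_b: P_RM, species_b: RNAP, delta_g: null,
     provenance: "TODO: transcribe"}
looping_terms:
  # Long-range CI octamer bridging the two operators (looped DNA), plus any
  # octamer+tetramer decomposition published for the looped configurations.
  - label: CI octamer loop
    condition:
      - {site: O_R1, species: CI2}
      - {site: O_R2, species: CI2}
      - {site: O_L1, species: CI2}
      - {site: O_L2, species: CI2}
    delta_g: null
    provenance: "TODO: transcribe"
  - label: CI octamer+tetramer loop
    condition:
      - {site: O_R1, species: CI2}
      - {site: O_R2, species: CI2}
      - {site: O_R3, species: CI2}
      - {site: O_L1, species: CI2}
      - {site: O_L2, species: CI2}
      - {site: O_L3, species: CI2}
    delta_g: null
    provenance: "TODO: transcribe"
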