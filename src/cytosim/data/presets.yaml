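# Editable material and population preset table.
#
# These dielectric constants are plausible literature-style stand-ins chosen
# so that the qualitative orderings hold (tumor lines larger than WBCs;
# tumor Opacity_2/0.5 below WBC Opacity_2/0.5; bead opacity flat across
# sizes).  They are NOT measured values; edit freely and pass the file to
# cytosim.dielectrics.load_presets(path).
#
# Keys:
#   media.<name>:  conductivity_S_per_m, relative_permittivity
#   cells.<name>:  diameter_um (default), membrane_thickness_nm,
#                  membrane_conductivity_S_per_m,
#                  membrane_relative_permittivity,
#                  cytoplasm_conductivity_S_per_m,
#                  cytoplasm_relative_permittivity, label (WBC|TUMOR|OTHER)
#   beads.<name>:  diameter_um (default), relative_permittivity,
#                  conductivity_S_per_m
#   populations.<name>: mean_um, sd_um, lo_um, hi_um  (truncated normal)

schema_version: 1

media:
  PBS:
    conductivity_S_per_m: 1.6
    relative_permittivity: 78.0

cells:
  WBC:
    diameter_um: 9.0
    membrane_thickness_nm: 7.0
    membrane_conductivity_S_per_m: 1.0e-7
    membrane_relative_permittivity: 5.0
    cytoplasm_conductivity_S_per_m: 0.70
    cytoplasm_relative_permittivity: 65.0
    label: WBC
  MCF-7:
    diameter_um: 17.5
    membrane_thickness_nm: 4.0
    membrane_conductivity_S_per_m: 1.0e-7
    membrane_relative_permittivity: 11.0
    cytoplasm_conductivity_S_per_m: 0.45
    cytoplasm_relative_permittivity: 60.0
    label: TUMOR
  A549:
    diameter_um: 18.5
    membrane_thickness_nm: 4.0
    membrane_conductivity_S_per_m: 1.0e-7
    membrane_relative_permittivity: 10.0
    cytoplasm_conductivity_S_per_m: 0.50
    cytoplasm_relative_permittivity: 60.0
    label: TUMOR
  SW480:
    diameter_um: 17.0
    membrane_thickness_nm: 4.0
    membrane_conductivity_S_per_m: 1.0e-7
    membrane_relative_permittivity: 9.5
    cytoplasm_conductivity_S_per_m: 0.50
    cytoplasm_relative_permittivity: 60.0
    label: TUMOR

beads:
  polystyrene:
    diameter_um: 10.0
    relative_permittivity: 2.5
    conductivity_S_per_m: 0.0

populations:
  WBC:     {mean_um: 9.0,  sd_um: 1.5, lo_um: 5.0,  hi_um: 14.0}
  MCF-7:   {mean_um: 17.5, sd_um: 2.5, lo_um: 11.0, hi_um: 28.0}
  A549:    {mean_um: 18.5, sd_um: 2.5, lo_um: 11.0, hi_um: 28.0}
  SW480:   {mean_um: 17.0, sd_um: 2.5, lo_um: 11.0, hi_um: 28.0}
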