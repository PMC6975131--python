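# Bundled optical-constant snapshots at a reference wavelength of
# 0.165312 nm (7.5 keV photon energy).  delta/beta are snapshots in the
# style of the standard optical-constant tabulations (CXRO-like); they are
# plain inputs and can be edited or overridden from a user config.
#
# paraffin is referenced at 0.164 nm, the rounded mean wavelength commonly
# quoted for a 7.5 keV mean energy.
materials:
  water:
    formula: H2O
    mass_density: 1.0        # g/cm^3
    delta: 4.097e-6
    beta: 1.65e-8
    wavelength_ref: 0.165312 # nm
  hemoglobin:
    formula: C2932H4724N828O840S8Fe4
    mass_density: 1.335
    delta: 5.275e-6
    beta: 1.62e-8
    wavelength_ref: 0.165312
  paraffin:
    formula: C30H62
    mass_density: 0.9
    delta: 3.810e-6
    beta: 5.467e-9
    wavelength_ref: 0.164

mixtures:
  blood:
    components: [water, hemoglobin]
    fractions: [0.675, 0.325]
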