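# Bill of materials for the biodegradable vessel-closure case study:
# PLGA suture, GA-CL-TMC anchor/cap copolymer, PEG sealant.
# Scaling factor 2 covers bilateral (two-device) clinical use.
device_name: Biodegradable vessel closure system
scaling_factor: 2
entries:
  - polymer: "PLGA 75:25"
    mass_mg: 100
  - polymer: "GA-CL-TMC 50:25:25"
    mass_mg: 30
  - polymer: PEG
    mass_mg: 5.0
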