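# Radiation quality presets: six qualities spanning the study's LET range.
# LET values are dose-averaged, in keV/um; energies in MeV (MeV/u for ions).
xray:
  particle: photon
  energy_mev: 0.225   # 225 kVp tube spectrum; secondary-electron dose-mean LET
  let: 0.45
proton_1:
  particle: proton
  energy_mev: 58.0    # pristine high-energy beam
  let: 1.0
proton_12:
  particle: proton
  energy_mev: 11.0    # distal edge of a spread-out Bragg peak
  let: 12.0
carbon_34:
  particle: carbon
  energy_mev: 71.0
  let: 34.0
carbon_73:
  particle: carbon
  energy_mev: 26.0
  let: 73.0
alpha:
  particle: alpha
  energy_mev: 2.88    # 241-Am source, Mylar-dish geometry
  let: 129.3
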