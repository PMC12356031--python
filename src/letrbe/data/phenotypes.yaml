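# Simplified radiation phenotypes of the eight RPE-1-derived lines.
# Pathway statuses: functional | defective | complex_only_defective.
# Rate scales < 1 slow that pathway's breaks and proportionally raise their
# misrepair weight (longer time at risk). alt_ej_failure_prob is the
# probability that a break handed to the alt-EJ backup is never rejoined.
# All numeric values are model calibration choices, not measured constants.

wild_type: {}

p53:
  # checkpoint-null only; repair pathways intact
  g1_checkpoint_activity: 0.0

fancd2:
  # mild phenotype: HR machinery intact but slowed, with a fraction of
  # HR-routed breaks failing over to the backup
  hr_failure_prob: 0.6
  hr_rate_scale: 0.5

brca1:
  # HR-null: complex S/G2 breaks lose their preferred pathway
  hr: defective

artemis:
  # end-processing nuclease: canonical NHEJ fails only on complex breaks
  nhej: complex_only_defective

dnapk:
  # DNA-PKcs: complex-break NHEJ failure, partial failure on simple breaks
  # (break sensing/synapsis), and slowed canonical NHEJ
  nhej: complex_only_defective
  nhej_failure_prob: 0.08
  nhej_rate_scale: 0.5

lig4:
  # ligation-null: canonical NHEJ fully defective, all breaks to backup
  nhej: defective

atm:
  # sensor/signalling null: canonical NHEJ ineffective, backup repair
  # compromised (resection/signalling), and G1 checkpoint lost
  nhej: defective
  alt_ej_failure_prob: 0.15
  g1_checkpoint_activity: 0.0
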