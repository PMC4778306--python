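outdir: demo_out
seed: 11
genome_preset: custom
chromosomes:
  - {name: "1", bp_length: 80000000, cm_length: 110.0, n_snps: 2400}
  - {name: "2", bp_length: 80000000, cm_length: 110.0, n_snps: 2400}
  - {name: "3", bp_length: 80000000, cm_length: 110.0, n_snps: 2400}
n_rils: 100
observe_rate: 0.5
n_perm: 200
scan_step_cm: 2.0
traits:
  - {name: PH, grand_mean: 200.0, env_offsets: [-8.0, 8.0, 0.0], gxe_sd: 2.0, resid_sd: 5.0, n_reps: 2}
  - {name: EH, grand_mean: 80.0, env_offsets: [1.5, -1.0, -0.5], gxe_sd: 1.5, resid_sd: 4.0, n_reps: 2}
qtl:
  - {trait: PH, chrom: "1", pos: 40000000, effect: 6.0}
  - {trait: PH, chrom: "3", pos: 20000000, effect: 5.0}
  - {trait: EH, chrom: "1", pos: 42000000, effect: 4.0}
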