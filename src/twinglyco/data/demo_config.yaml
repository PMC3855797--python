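# Demo pipeline configuration: a small twin cohort with three planted
# methylation effects on low-heritability traits, end-to-end in ~1 minute.
outdir: demo_run
seed: 42
stages: [simulate, traits, heritability, ewas, enrich, report]
lrt_alpha: 0.05
array_alpha: 0.05
heritability_threshold: 0.35
ewas_subset: low
simulation:
  n_mz: 50
  n_dz: 50
  seed: 42
  trait_specs:
    - {name: trait_ae_high, a2: 0.80, c2: 0.00, e2: 0.20}
    - {name: trait_ae_mid, a2: 0.70, c2: 0.00, e2: 0.30}
    - {name: trait_ace_a, a2: 0.45, c2: 0.29, e2: 0.26}
    - {name: trait_ce_high, a2: 0.00, c2: 0.66, e2: 0.34}
    - {name: trait_ce_low, a2: 0.00, c2: 0.28, e2: 0.72}
    - {name: trait_e_only, a2: 0.00, c2: 0.00, e2: 1.00}
  methyl_model:
    n_probes: 200
    family_var: 0.2
    planted:
      - {probe: cg00000005, trait: trait_ce_low, beta: 0.40}
      - {probe: cg00000017, trait: trait_e_only, beta: -0.36}
      - {probe: cg00000042, trait: trait_ce_high, beta: 0.35}
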