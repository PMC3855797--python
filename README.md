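# twinglyco

Genetic and epigenetic decomposition of immunoglobulin G (IgG) N-glycan
variation, built around the classical twin design.

IgG carries N-glycans at Asn-297 whose composition — measured by UPLC as 24
chromatographic peaks (GP1–GP24, % of total integrated area) plus derived
ratio traits averaging structural features (galactosylation, fucosylation,
bisecting GlcNAc, sialylation) — varies widely between people and is
remarkably stable within a person. `twinglyco` answers two questions about
that variation for cohorts of monozygotic (MZ) and dizygotic (DZ) twin
pairs:

1. **How heritable is each glycan trait?**  The phenotypic variance is
   decomposed into additive genetic (A), shared environmental (C) and unique
   environmental (E) components by maximum likelihood: each twin pair is
   bivariate normal with cross-twin covariance `a² + c²` (MZ) or
   `a²/2 + c²` (DZ).  Submodels (AE, CE, E) are compared by sequential
   likelihood-ratio drops plus AIC; components get profile-likelihood 95%
   CIs, traits get intra-class correlations (double-entry) and a
   low/high-heritability classification (`h² ≤ 0.35` → low).
2. **Are weakly heritable traits epigenetically mediated?**  Standardized
   DNA-methylation probes are tested against traits with a linear
   family-random-intercept model `y = βm + γ'x + u_fam + ε` (REML),
   Bonferroni-controlled array-wide, and the rate of array-wide hits is
   compared between heritability classes with a one-sided Fisher exact
   test.

Because real twin-glycomics cohorts are rarely shareable, the package ships
a first-class synthetic-cohort generator with planted ground truth (trait
variance structures, covariate effects, Dirichlet peak compositions,
methylation effects of known size), so every stage of the chain is testable
end to end.

## Worked example

```python
import numpy as np
from twinglyco import TwinACEModel, simulate_twin_trait

rng = np.random.default_rng(7)
mz, dz = simulate_twin_trait(220, 310, a2=0.7, c2=0.1, rng=rng)
model = TwinACEModel(mz, dz, trait="GP8n-like")
sel = model.select(alpha=0.05)
print(sel.summary())
print(sel.best.summary())
```

```
Model selection (sequential drops from ACE):
  ACE -> AE: LRT stat 0.6204 (df 1), p 0.4309 drop accepted
  ACE -> CE: LRT stat 66.4073 (df 1), p 3.667e-16 drop rejected
  ACE -> E: LRT stat 280.5823 (df 2), p 1.181e-61 drop rejected
  AIC among surviving: ACE 2665.66, AE 2664.28
  chosen: AE
Twin ACE decomposition — model AE, trait GP8n-like
  pairs: 220 MZ, 310 DZ
  loglik -1330.138   AIC 2664.276
  a2 = 0.804 [0.759, 0.840]
  c2 = 0 (fixed)
  e2 = 0.196 [0.160, 0.241]
```

The selection trace shows the shared-environment drop accepted (its true
contribution, 0.1, is hard to resolve at this sample size, so A absorbs it)
and the additive drop decisively rejected; the chosen AE model attributes
~0.80 of the variance to additive genetics with a tight profile CI — the
behaviour of the most heritable traits on the real panel.

The full pipeline — simulate → glycan traits → heritability → EWAS →
enrichment → report — runs from a YAML config:

```bash
twinglyco run --config src/twinglyco/data/demo_config.yaml --out demo_run
cat demo_run/report.txt
```

The demo cohort (50 MZ + 50 DZ pairs, 200 probes, 3 planted methylation
effects on weakly heritable traits) finishes in about two minutes and the
report flags exactly the planted probe–trait pairs, e.g.

```
     probe  chr  position   gene        glycan  beta   se           P
cg00000005    3 180291378  GENE5  trait_ce_low  0.63 0.07 1.08x10^-18
```

Every stage is also exposed individually (`twinglyco simulate|traits|
heritability|power|ewas|enrich|report`) and as library functions
(`compute_all_traits`, `heritability_table`, `run_ewas`,
`compare_proportions`, ...).

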