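# iezmeta

Trait-based meta-analysis of linear-infrastructure impacts on terrestrial
vertebrate abundance.

Roads, railways, power lines and other linear infrastructure suppress (or
sometimes boost) wildlife populations well beyond their physical footprint.
Field studies report species abundance at several distances from a piece of
infrastructure together with a far/undisturbed control site. `iezmeta`
turns such paired records into effect sizes, fits multilevel
meta-regressions that let the distance response depend on species traits
and local context, and derives **infrastructure-effect zones (IEZs)** — the
distance at which the modelled abundance response returns to the control
level. It is written for quantitative ecologists and impact-assessment
modellers who want species- and context-specific effect zones rather than
a single buffer width.

## The model

For study *i*, species *s* and distance *d*, the effect size is the log
response ratio with a small-sample (delta-method) correction, computed on
truncated means so undetected species (zero sample means) remain usable:

    LRRΔ_isd = log(Ã_isd / Ã_isc)
             + ½ [ SD²_isd/(n_isd Ã²_isd) − SD²_isc/(n_isc Ã²_isc) ]

    Ã = Ā                 if Ā > 0
        1/(2 n D)         if Ā = 0      (D = reporting-scale constant)

with sampling variance

    var(LRRΔ) = SD²_d/(n_d Ã²_d) + SD²_c/(n_c Ã²_c)
              + ½ [ SD⁴_d/(n²_d Ã⁴_d) + SD⁴_c/(n²_c Ã⁴_c) ].

Missing or zero SDs are imputed (Poisson `SD = √Ã` by default; Bracken-
ratio and hot-deck nearest-neighbour alternatives for sensitivity).
Effect sizes sharing a control site are sampling-correlated; the full
variance–covariance matrix carries the shared-control covariance
`SD²_c/(n_c Ã²_c)`.

The meta-regression is a multilevel random-effects model

    y ~ N(Xβ, V + Σ_k σ²_k Z_k Z_kᵀ)

with five variance components — observation (σ₁²), clade (σ₂²), species in
clade (σ₃²), source (σ₄²), study in source (σ₅²) — estimated by REML.
Moderators are log₁₀ distance (and its square), log₁₀ body mass, diet (%
vertebrates/fish/scavenging), habitat (open vs closed) and infrastructure
type, with trait × distance interactions. Candidate moderator sets are
ranked by AICc from the full likelihood; fit quality is summarized by
Cochran's Q_E, omnibus Q_M tests, and marginal/conditional R². The IEZ for
a given trait/context combination is the smallest distance where the
fitted quadratic-in-log-distance prediction crosses zero.

A fully-tested synthetic-data generator reproduces the hierarchical
structure, zero-mean rates and missing-SD rates of the published field
database, so every stage is testable without downloading the archived
deposit.

## Worked example

Predict near-infrastructure abundance change and effect zones from the
bundled published coefficient tables:

```python
from iezmeta import percentage_change, predict_lrr, find_iez
from iezmeta.reference_estimates import reference_model

mam = reference_model("mammal")
est = find_iez(mam, diet_pct=80, body_mass_g=100, habitat="closed")
print(round(est.iez_m), est.sign_near)

amph = reference_model("amphibian")
print(round(percentage_change(predict_lrr(amph, 1.0).lrr)))
```

prints

```
107 +
-52
```

i.e. small carnivorous mammals (100 g, 80% carnivorous diet) in closed
habitats are *more* abundant near infrastructure, with the effect fading
107 m out, while amphibian abundance 1 m from infrastructure is about
half its control level.

An end-to-end run on synthetic data:

```bash
iezmeta simulate --taxon reptile --seed 1 --out sim.csv --truth truth.json
iezmeta fit sim.csv --taxon reptile --terms distance,distance2,habitat
iezmeta iez --reference reptile
```

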