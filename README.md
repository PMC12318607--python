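# ambycolor

Quantifying and modelling larval salamander pigmentation responses to
ultraviolet radiation (UVR).

Larvae of *Ambystoma barbouri* and *A. texanum* (and their reciprocal
hybrids) darken their skin under UVR by expanding melanophore (dark) and
xanthophore (yellow) pigment-cell cover. `ambycolor` is a reusable
pipeline for the two measurements this kind of experiment produces from
a standardized 250 × 420-pixel skin patch, and for the Bayesian models
that analyse them across a fully crossed exposure-time × mother-genotype
× father-genotype design with clutch as a grouping factor:

1. **Skin darkness** `y ∈ (0, 1)` — mean grayscale darkness of the
   patch — modelled with a beta distributional regression,

   ```
   y ~ Beta(μφ, (1−μ)φ)
   logit(μ) = β_Time + β_Mother + β_Father + β_Mother×Father + Z_Clutch
   log(φ)   = γ_Time + γ_Mother + γ_Father + γ_Mother×Father + Z_Clutch
   ```

2. **Chromatophore composition** — counts of black (melanophore),
   yellow (xanthophore) and clear pixels, treated as a 3-part
   composition and modelled on two isometric log-ratio balances,

   ```
   z1 = √(2/3) · ln( g(p_yellow, p_black) / p_clear )   (chromatophore vs clear)
   z2 = √(1/2) · ln( p_black / p_yellow )               (melanophore vs xanthophore)

   (z1, z2) ~ MVNormal(μ, Σ)
   μ = B_Time + B_Mother + B_Father + B_Mother×Father
       + B_Mother×Time + B_Father×Time + U_Clutch
   ```

Posterior summaries use highest-density continuous intervals (HDCI);
model variants are ranked by WAIC and PSIS-LOO. A synthetic-data module
generates the full factorial design (4 pairings × 3 clutches × 4
exposure levels × 6 larvae = 288 rows), model-based observations with
known ground truth, and rendered skin-patch images with exact per-pixel
label masks, so the entire pipeline is testable without any data
download. An automated HSV-rule pixel classifier replaces the manual
magic-wand workflow such experiments traditionally use.

## Worked example

```python
import pandas as pd
from ambycolor import design, synthetic
from ambycolor.darkness import fit_darkness, predict_darkness, relative_effect
from ambycolor.compmodel import fit_composition, predict_composition
from ambycolor.sampler import SamplerConfig

d = design.generate_design()                      # 288-larva factorial design
obs = synthetic.simulate_dataset(d, seed=21)      # darkness + pixel counts

fit = fit_darkness(obs, sampler=SamplerConfig(warmup=1200, steps=320, thin=4, seed=21))
cells = pd.DataFrame([
    {"mother": "barbouri", "father": "barbouri", "exposure_h": 4},
    {"mother": "texanum",  "father": "texanum",  "exposure_h": 4},
])
print(predict_darkness(fit, cells))
print(relative_effect(fit,
    {"mother": "barbouri", "father": "texanum", "exposure_h": 4},
    {"mother": "texanum",  "father": "texanum", "exposure_h": 4}))

fc = fit_composition(obs, sampler=SamplerConfig(warmup=1800, steps=400, thin=4, seed=21))
print(predict_composition(fc, cells)[["mother", "p_black", "p_black_low", "p_black_high"]])
```

prints (exactly reproducible with these seeds):

```
     mother    father  exposure_h      mean  hdci_low  hdci_high
0  barbouri  barbouri           4  0.621606  0.566229   0.680579
1   texanum   texanum           4  0.417117  0.360653   0.483514
{'mean': 23.482411823208974, 'hdci_low': 1.4338504058361181, 'hdci_high': 47.02531035223607}
     mother   p_black  p_black_low  p_black_high
0  barbouri  0.725495     0.668342      0.779672
1   texanum  0.348211     0.280300      0.419282
```

Read: in this simulated study, pure *A. barbouri* larvae reach a
posterior mean darkness of 0.62 (95 % HDCI 0.57–0.68) after 4 h of UVR
versus 0.42 for *A. texanum*; switching a hybrid's mother from
*texanum* to *barbouri* raises expected darkness by ~23 % (HDCI
1.4–47 %); and melanophores cover ~73 % of *barbouri* skin after 4 h
versus ~35 % for *texanum*. The interval widths reflect both clutch
heterogeneity and residual variation.

The same workflow is available from the shell:

```sh
ambycolor simulate --seed 1 --out study/          # design, observations, images
ambycolor quantify --manifest study/manifest.csv --out study/quantified.csv
ambycolor fit-darkness --data study/observations.csv --seed 1 --out study/fit/
ambycolor report --data study/observations.csv --seed 1 --out study/report/
```

`report` writes coefficient tables, per-cell predictions, ternary plots
(observed and posterior-predictive), a darkness-by-exposure panel, a
WAIC/LOO model-comparison table, and a `results.json` that is
byte-reproducible for a fixed config and seed.

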