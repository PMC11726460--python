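# palaeofeed

Multi-proxy stable-isotope inference of prehistoric cattle diet.

Early Neolithic farmers of Central Europe raised cattle in landscapes that
were largely forest. How much of the herds' feed actually came from forests
— grazed under the canopy, or cut as winter "leafy hay" — is recorded in the
carbon, oxygen and nitrogen isotopes of the animals' surviving tissues and
of the milk fats absorbed by pottery. `palaeofeed` turns those scattered
proxies into one coherent, testable analysis for zooarchaeologists and
isotope ecologists.

## The model

Three δ¹³C proxies are placed on a common **diet scale** with fixed trophic
enrichment offsets, applied additively (δ¹³C_diet = δ¹³C_tissue + Δ):

| tissue | offset Δ (‰) |
|---|---|
| bone collagen (Δ_collagen-diet) | −5.1 |
| dairy C₁₆:₀ lipid (Δ_lipids-diet) | +1.5 |
| enamel bioapatite (Δ_bioap-diet) | −14.5 |

Pottery lipid extracts are attributed to ruminant dairy fat when
Δ¹³C = δ¹³C₁₈:₀ − δ¹³C₁₆:₀ ≤ −3.1 ‰. Diet values are judged against a
forest-herbivore baseline built from deer bone collagen (diet ≈ −27.7 ± 1 ‰;
low values reflect the **canopy effect**, the ¹³C depletion of plants under
dense forest).

Sequential enamel δ¹⁸O along each molar crown is fitted with an annual
cosine, δ¹⁸O(x) = A·cos(2π(x − x₀)/X) + M, giving each tooth a season
scale; positions where the curve drops below M − A/2 approximate the cold
season. A crown-height clock converts positions to ages in months
(crown forms over 12 months; dentine mineralizes ~6 months before the
enamel at the same height), so dentine amino-acid records can be aligned
with enamel records in time.

Dentine **β values** — the glutamate-minus-phenylalanine δ¹⁵N spacing minus
a −4.0 ‰ trophic offset — classify the plant base of the diet as woody
(reference −9.3 ± 1.6 ‰) or herbaceous (−5.4 ± 2.1 ‰); woody feed in cold
months is the isotopic signature of winter leafy-hay foddering.

Finally, site-level summaries are cross-correlated with reconstructed
environmental covariates (mean forest cover averaged over three pollen
time slices, palaeoclimate, hydrology) with Bonferroni/Benjamini–Hochberg
control, and diet isoscapes are interpolated by inverse-distance weighting
with the power exponent chosen by leave-one-out cross-validation.

A first-class synthetic-data generator produces complete worlds with known
ground truth (canopy effect, seasonal cosines, winter foddering), so every
stage is testable without any data download.

## Worked example

```sh
palaeofeed simulate --seed 3 --out fixtures/
palaeofeed spatial --in fixtures/ --out run/ --seed 3
```

or in Python:

```python
from palaeofeed.synthetic_data import WorldConfig, generate_world, write_world
from palaeofeed.pipeline import RunConfig, run_pipeline

write_world(generate_world(WorldConfig(seed=3)), "fixtures")
report = run_pipeline(RunConfig(indir="fixtures", outdir="run", seed=3))
print(report["stages"]["diet"]["baseline"])
for c in report["stages"]["spatial"]["correlations"][:2]:
    print(c["pair"], round(c["statistic"], 3), c["p_bonferroni"], c["n"])
```

prints (seed 3):

```
{'mean': -27.497389996436656, 'sd': 0.998615385263077, 'n': 35}
mfc~d13c_coll -0.278 1.3270975684542829e-07 400
mfc~d13c_dairy -0.241 8.750937233105211e-06 400
```

The deer-collagen baseline recovers the forest diet the generator drew
(−27.7 ± 1 ‰), and forest cover correlates negatively with collagen δ¹³C
across the 40 sites × 10 samples — the canopy effect the world was built
with, surviving conversion, noise and multiple-testing correction.

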