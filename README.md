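# tauquant

Rater-independent quantification of tau-marker immunoreactive area and
ThioflavinS plaque load in multi-channel fluorescence sections of human
cortex, together with the aggregation and statistics of a Braak-staged
cohort design — and a synthetic section generator with exact ground truth so
every stage of the pipeline can be validated without human tissue.

**Who it is for.** Neuropathology image-analysis work where tau pathology
(neurofibrillary tangles, neuropil threads) and amyloid plaque cores are
quantified as *percent immunoreactive area* per section, across brain
regions and disease stages, with every section processed by the same fixed
parameters.

## The method

For each section, channels are max-projected over z, background-corrected by
subtracting a Gaussian lowpass estimate, and cleaned of autofluorescence:
the unlabeled autofluorescence channel (lipofuscin appears in every emission
channel) is thresholded, dilated by one pixel, and the mask is subtracted
from the marker channel. After high-boost edge enhancement, objects are
detected by thresholding with size and shape (roundness = 4πA/P²)
restrictions, and

&nbsp;&nbsp;&nbsp;&nbsp;IR% = 100 · Σ object areas / imaged area.

Plaque cores in the ThioflavinS channel are detected by thresholding plus a
minimum-size filter (default 200 µm²) alone: cores are large and intensely
labeled while tangles are small and only weakly ThioS-positive, so the two
are separated without any manual intervention.

Study statistics mirror the factorial design (4 Braak-stage groups × 5
regions × N cases): mosaic averaging, per-case isocortex means over the four
isocortical regions, documented exclusions, two-way ANOVA with Bonferroni
post-hoc families (stages within region / regions within stage), one-way
ANOVA with Tukey HSD or Newman-Keuls, fold change relative to the control
group, and Kolmogorov-Smirnov (Lilliefors) normality checks. See
`docs/methods.md` for the full model description and parameter rationale.

## Worked example

```python
import tauquant as tq

params = tq.SectionSimParams()
burden = tq.StageBurdenProfile("V_VI", {"tangle": 0.02, "thread": 0.01,
                                        "lipofuscin": 0.003})
section = tq.generate_section(params, burden, seed=42)

record = tq.quantify_marker(section.channels, tq.tau_marker_params(params),
                            case_id="case16", region="TEntR")
truth = 100 * (section.ground_truth.true_area_fraction["tangle"]
               + section.ground_truth.true_area_fraction["thread"])
print(f"measured IR area: {record.ir_area_percent:.3f}%  "
      f"(ground truth {truth:.3f}%, {record.n_objects} objects)")
```

prints

```
measured IR area: 3.083%  (ground truth 3.088%, 24 objects)
```

— a late-stage section carrying 3% combined tangle+thread burden is
measured to within 0.2% relative, with the 1% lipofuscin-class burden fully
removed by the autofluorescence mask. A whole simulated study then exercises
the statistics layer:

```python
measurements, cases = tq.run_simulated_study(n_cases_per_group=5, seed=0)
result = tq.two_way_anova(measurements)
print(result.table.round(4))
```

```
                      sum_sq    df          F    p
braak_group         173.5230   3.0  9707.3918  0.0
region                9.9404   4.0   417.0711  0.0
braak_group:region    9.6942  12.0   135.5806  0.0
residual              0.4767  80.0        NaN  NaN
```

The Braak-group main effect dominates (stage burdens are simulated as
monotone increasing), the region effect reflects the regional modulation
(transentorhinal strongest), and fold changes versus controls rise with
stage, e.g. in the transentorhinal region:

```
braak_group  fold_change
    control         1.00
       I_II         3.84
     III_IV        10.02
       V_VI        26.36
```

## Command line

```bash
tauquant simulate --out sim/ --seed 7            # sections + ground truth
tauquant quantify --config cfg.yaml --images sim/ --out quant/
tauquant stats    --measurements quant/measurements.csv --cases sim/cases.csv --out stats/
tauquant run      --out study/ --seed 7          # all three, end to end
```

Outputs are plain CSV/SVG plus a `run_config.yaml` snapshot; repeated runs
with the same seed are byte-identical.

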