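# camola

Stable-isotope labeling analysis for thermally generated aroma compounds:
isotopologue envelope correction, carbon-module fragment inference, formation
kinetics, and external-standard calibration, with forward simulators that make
every analysis step testable end to end.

## The scientific problem

When green tea leaf (or a model system of sugars and amino acids) is roasted,
Maillard chemistry converts precursors such as glucose and free amino acids
into odor-active volatiles — pyrazines, furans, Strecker aldehydes. Two
questions drive the experimental design this package supports:

1. **Where do the product's carbon atoms come from?** Roast the system once
   with fully ¹³C-labeled glucose ("all" system) and once with a 1:1 molar mix
   of labeled and unlabeled glucose ("half" system). If a product molecule is
   assembled from *k* independent precursor fragments, each fragment is labeled
   with probability 0.5 in the mixed pool, so the product's mass-isotopologue
   pattern is the convolution of *k* Bernoulli label states. An intact C₅
   skeleton gives a 50:50 [M]:[M+5] doublet; a 2+3 assembly gives a
   25:25:25:25 quartet at M, M+2, M+3, M+5. Reading the pattern backwards
   identifies the number and sizes of the fragments.
2. **How fast is the compound formed?** Concentration–time courses at several
   roasting temperatures are fitted with zero-order lines, first-order
   log-linear models, or a three-parameter exponential-offset model, and the
   best form is selected by R².

Before either question can be answered, raw GC-MS isotopologue envelopes must
be cleaned of two instrumental distortions: hydrogen loss under electron
ionization (an M−1 satellite with ratio *r* = (M−1)/M measured on an unlabeled
control) and natural ¹³C/³³S/³⁴S abundance leaking intensity into M+1/M+2.

## What is implemented

| Module | Contents |
| --- | --- |
| `camola.records` | Validated data types: compounds, envelopes, percentage distributions, time courses, run configuration |
| `camola.isotopologue_correction` | Hydrogen-loss inversion, sequential and matrix natural-abundance correction, normalization |
| `camola.camola_inference` | Fragment-hypothesis enumeration, expected-pattern convolution, scoring, origin classification |
| `camola.kinetics` | Zero-order, first-order, and exponential-offset fits; model selection; detection-limit masking |
| `camola.calibration` | External-standard lines, inverse prediction, internal-standard quantification |
| `camola.synthetic_data` | Forward simulators (envelopes, time courses, standards) and reference fixture tables |
| `camola.tables_io` | CSV/TSV readers and writers, JSON reports |
| `camola.cli` | `camola simulate / correct / infer / kinetics / calibrate` |

## Worked example

```python
from camola import (CorrectionParams, LabelingDesign, correct_envelope,
                    gen_envelope, infer_fragments, gen_timecourse, select_model)
from camola.kinetics import KineticModelForm, fit_all_forms
from camola.records import CorrectedDistribution

# 1. simulate a raw GC-MS envelope for 2-methylpyrazine in the equimolar pool
true_half = CorrectedDistribution({0: 25, 2: 25, 3: 25, 5: 25})
params = CorrectionParams(r=0.10)          # (M-1)/M hydrogen-loss ratio
raw = gen_envelope(true_half, "C5H6N2", params, noise_cv=0.05, seed=42)
print("raw areas:", {k: round(v) for k, v in raw.areas.items()})

# 2. correct it back to a percentage isotopologue distribution
half = correct_envelope(raw, params, formula="C5H6N2")
print("corrected:", half.rounded(0))

# 3. infer the precursor fragments behind the pattern
all_dist = CorrectedDistribution({5: 100})   # fully labeled pool: M+5 only
call = infer_fragments(all_dist, half, LabelingDesign(p=0.5))
best = call.best_hypotheses[0]
print("origin call:", call.call)
print("best fragments:", best.hypothesis.label(), "distance", round(best.distance, 2))

# 4. fit formation kinetics for the same compound at 110 C
tc = gen_timecourse(KineticModelForm.ZERO_ORDER, {"K": 0.08362, "A0": -4.14681},
                    times=[2, 4, 6, 8, 10, 12], compound="2-Methylpyrazine",
                    temperature=110)
fit = select_model(fit_all_forms(tc))
print("kinetic model:", fit.form.value, fit.equation_string(), f"R2={fit.r2:.4f}")
```

Output:

```text
raw areas: {-1: 23047, 0: 216680, 1: 36528, 2: 263012, 3: 218361, 4: 32967, 5: 229700, 6: 12289}
corrected: {0: 24, 1: 0, 2: 27, 3: 23, 4: 0, 5: 26, 6: 0}
origin call: precursor_exclusive
best fragments: 2+3 distance 9.81
kinetic model: zero_order y = 0.08362x - 4.14681 R2=1.0000
```

The 5 % instrument noise leaves a few points of scatter in the corrected
distribution, yet the fragment inference still recovers the generating 2+3
assembly as the best hypothesis and classifies the compound as
precursor-exclusive.

The same pipeline runs from the command line:

```bash
camola simulate --preset all --seed 1 --out data/
camola correct  --input data/envelopes_c13.csv --out out/corrected
camola infer    --input data/distributions_c13.csv --out out/calls
camola kinetics --input data/timecourses.csv --out out/fits
camola calibrate --input data/standards.csv --out out/curves
```

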