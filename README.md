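# ifhdr

High-dynamic-range (HDR) processing and PD-L1 quantification for
immunofluorescence (IF) microscopy.

Membranous PD-L1 expression guides immunotherapy in non-small-cell lung
cancer, but a 12-bit fluorescence camera cannot capture it in one shot:
signal spans several decades, so weak membranes vanish at short exposure
while strong ones clip at long exposure. `ifhdr` merges exposures taken at
6.5, 25 and 55 ms into a single radiance map and quantifies PD-L1 expression
area the way digital-pathology pipelines do, for people building or
validating IF-based PD-L1 scoring against chromogenic IHC.

The core is the log-exposure response model g(Z_ij) = ln E_i + ln Δt_j,
recovered by regularized least squares with hat weights w(z) and the
weighted-average merge

    ln E(p) = Σ_j w(Z_j) [g(Z_j) − ln Δt_j] / Σ_j w(Z_j),

specialized for IF: fitting samples are drawn near segmented nuclei where
membranous signal lives; each frame also contributes an eroded-and-blurred
"virtual exposure"; the merged map is linearly rescaled to the input range
and enhanced by mean-anchored gamma, CLAHE, and white/black top-hat
contrast. Around it sit Macenko stain deconvolution for IHC (OD transform,
principal-plane stain vectors, pseudo-inverse concentrations),
area-proportion measurement inside tumor annotations, TPS categorization
(<1%, 1–49%, ≥50%), and agreement statistics (accuracy, linear weighted
kappa κ = (P_o − P_e)/(1 − P_e) with Landis–Koch bands, one-sided paired
t-tests). A seeded phantom generator provides ground truth for every stage;
see `docs/methods.md` for the model details and design choices.

## Worked example

```python
from ifhdr import experiments

case = experiments.run_case(seed=1)
print(f"true membrane fraction: {case.true_percent:.2f}%")
for arm in ("LOW", "MED", "HIGH", "HDR"):
    print(f"{arm:>4}: measured {case.proportions[arm]:.2f}%"
          f"  error {case.signed_errors[arm]:+.2f}%")
```

```
true membrane fraction: 3.21%
 LOW: measured 2.30%  error -0.90%
 MED: measured 2.90%  error -0.31%
HIGH: measured 4.28%  error +1.07%
 HDR: measured 3.44%  error +0.23%
```

One synthetic field is imaged at the three exposure times and its PD-L1
area proportion measured per arm. The 6.5 ms frame under-measures (dim
membranes fall below the detection threshold), the 55 ms frame
over-measures (elevated background noise crosses it), 25 ms is the best
single exposure, and the HDR merge beats all three — the failure modes and
their resolution that motivate the method.

The agreement side works directly on score tables:

```python
from ifhdr import agreement, benchmarks

cm, _, _ = benchmarks.ALL_CASES[("pathologist1", "HDR")]
s = agreement.agreement_summary(cm)
print(f"accuracy {100*s.accuracy:.1f}%  kappa {s.kappa:.2f} ({s.band})")
# accuracy 82.1%  kappa 0.78 (substantial)
```

A CLI mirrors the library: `ifhdr simulate | fit-response | merge |
enhance | quantify-if | quantify-ihc | agreement`, each with explicit
`--in/--out` paths and `--seed` where stochastic (`ifhdr --help`).

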