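# anurascore

Two-stage classification of anuran (frog and toad) calls for acoustic
monitoring, built for the situation faced by wireless acoustic sensor
networks: short mono recordings taken in the field, heavy ambient noise, a
strongly imbalanced set of call classes, and expert annotations that mark
only the regions of interest (ROIs) where a call is actually present.

## The method

A recording is split into 25 ms Hamming-windowed frames (10 ms hop) and each
frame is represented by 13 HTK-dialect Mel-frequency cepstral coefficients
(pre-emphasis α = 0.97, 20 triangular Mel filters between 300 and 3700 Hz,
orthonormal DCT-II keeping c₁..c₁₃, sine lifter L = 22).  Features are
z-scored with training-set statistics, x′ᵢⱼ = (xᵢⱼ − μⱼ)/σⱼ, and every frame
is classified into one of C call classes or silence/noise by one of eight
pluggable families (minimum distance, Gaussian-mixture maximum likelihood,
decision tree, kNN, logistic regression, a 10-neuron feed-forward net,
linear discriminant, naive Bayes).

The **counting baseline** labels the recording with the class owning the
most frames.  This fails in a characteristic way: a rare call lasting a few
hundred milliseconds contributes only a handful of frames, so noise frames
leaking into the majority class outvote it.

The package's core replaces counting with **score-series classification**.
The frame classifier's per-class scores sᵢₖ are kept as C time series over
the recording; each series is summarized by 13 *linear-frequency* cepstral
coefficients (whole-series energy spectral density, 20 triangular filters
linearly spaced from 0 Hz to the series Nyquist 1/(2·hop), log energies,
DCT-II, keep c₁..c₁₃ — no pre-emphasis, band limiting, Mel warping or
liftering, since score series are not sounds).  The concatenated 13·C vector
(52 features for C = 4) is classified by a second-stage classifier from the
same eight families.

The evaluation apparatus is included: the C×C confusion matrix and ten
macro/global metrics (SNS, SPC, PRC, NPV, ACC, F1, GM and normalized MCC,
BM, MK, with the multiclass MCC computed as the Gorodkin R_K statistic and
the [−1,1] metrics mapped to [0,1] by (μ+1)/2); 7-fold cross-validation with
cyclic train/validation/test role rotation; a joint 9 × 8 (score method ×
frame classifier) grid; and paired percentile-bootstrap comparison of
methods (Nb = 10 000, γ = 0.95) including the probability of outperformance
Pr[δₖ > 0].

Because the original museum recordings are not publicly deposited, the
package ships a synthetic call generator (amplitude-modulated sinusoidal
pulse trains with class-specific carriers and pulse rates, additive noise at
a configurable SNR, ROI bookkeeping, WAV/TSV/CSV interchange) that emulates
the statistical structure of such datasets, including the hard
short-minority-call regime.

## Worked example

The built-in benchmark generates 400 two-second recordings (class mix
43/7/48/2 %, in-call SNR 3 dB, 250 ms minority calls spectrally adjacent to
the majority class), runs 7-fold cross-validation with a decision-tree frame
classifier, and labels recordings both by counting and by a
minimum-distance second stage on the LFCC score-series features:

```python
import numpy as np
from anurascore.benchmark import minority_call_benchmark

results = minority_call_benchmark(seed=1)
for name, res in results.items():
    mv = res.pooled
    print(f"{name:13s} ACC={mv.acc:.3f}  macro-F1={mv.f1:.3f}  SNS={mv.sns:.3f}")

minority = results["counting"].pooled_true == 2
err_c = np.mean(results["counting"].pooled_pred[minority] != 2)
err_s = np.mean(results["score_series"].pooled_pred[minority] != 2)
print(f"minority-class error rate: counting {err_c:.2f}, score series {err_s:.2f}")
```

prints

```
counting      ACC=0.945  macro-F1=0.847  SNS=0.823
score_series  ACC=0.955  macro-F1=0.938  SNS=0.941
minority-class error rate: counting 0.71, score series 0.16
```

Counting labels 71 % of the rare-call recordings wrongly (almost always as
the majority mating call, exactly the failure mode described above), while
the second stage recovers most of them and lifts macro-F1 by about nine
points; overall accuracy barely moves because the minority class is only 7 %
of the data — which is why the macro metrics, not accuracy, are the ones to
watch.

A command-line interface wraps the library for shell use
(`anurascore synth | features | train | classify | evaluate | grid |
bootstrap`); every stage reads/writes plain WAV, TSV and CSV files and all
randomness is controlled by explicit seeds.

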