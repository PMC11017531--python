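# prevcal

Prevalence-calibrated validation metrics for binary classifiers.

## Why

When a QSAR (or any binary) classifier is validated against a test set,
the confusion matrix it produces depends on two different things: the
model (captured by sensitivity *Sen* = TP/(TP+FN) and specificity
*Spe* = TN/(FP+TN)) and the test set's composition (captured by the
positive prevalence *Pre* = (TP+FN)/N and the size N).  Most popular
summary metrics — accuracy, Matthews' correlation coefficient (MCC),
positive/negative predictivity, Cohen's kappa, F1, markedness — mix the
two.  Compare them across test sets of different prevalence (internal vs
external validation, applicability-domain filtering, cluster splits,
drifting data streams) and they can move in the *opposite* direction from
the model's actual performance change.

prevcal is for modellers and validators who need metric comparisons that
survive a prevalence shift.  Its core device is the **derived confusion
matrix**: since (Sen, Spe, Pre, N) fully characterises a confusion matrix
via

    TP = Sen·Pre·N          FN = (1 − Sen)·Pre·N
    TN = Spe·(1 − Pre)·N    FP = (1 − Spe)·(1 − Pre)·N

any matrix can be reconstructed at an arbitrary target prevalence with
the model's Sen/Spe held fixed, and any metric evaluated on the
reconstruction.  Calibrating to Pre = 0.5 yields the **balanced** metrics,
which depend only on (Sen, Spe):

    Bal.Acc = (Sen + Spe)/2        Bal.MCC = (Sen + Spe − 1)/√(1 − (Sen − Spe)²)

The library provides the matrix/profile data model, the full metric
catalogue, closed forms for accuracy and MCC as functions of
(Sen, Spe, Pre), prevalence-sweep curves and plots, packaged synthetic
scenarios, and a comparison report that flags prevalence shifts and
raw-metric contradictions.  A `prevcal` CLI wraps all of it.

## Worked example: a tale of two MCCs

An applicability-domain (AD) filter is applied to a test set of 2000
instances (prevalence 0.600).  1000 instances are out of domain, so
coverage drops to 50 %, and the in-domain half has prevalence 0.900.
Sensitivity improves 0.680 → 0.710 and specificity 0.850 → 0.890 — the
model genuinely predicts better inside its domain:

```python
from prevcal import (PerformanceProfile, ValidationRun, balanced_mcc,
                     compare, from_labels, mcc, realise_labels)

full_p = PerformanceProfile(0.680, 0.850, 0.600, 2000)
in_p = PerformanceProfile(0.710, 0.890, 0.900, 1000)
full = from_labels(*realise_labels(full_p, seed=1), positive_label=1)
ind = from_labels(*realise_labels(in_p, seed=2), positive_label=1)
print("full counts:", full.counts())
print("in-domain counts:", ind.counts())
print(f"raw MCC:      {float(mcc(full)):.3f} -> {float(mcc(ind)):.3f}")
print(f"balanced MCC: {balanced_mcc(0.680, 0.850):.3f} -> {balanced_mcc(0.710, 0.890):.3f}")
report = compare(ValidationRun("full", full), ValidationRun("in_domain", ind))
print(report.verdict, report.flags)
```

prints

```
full counts: (816.0, 384.0, 120.0, 680.0)
in-domain counts: (639.0, 261.0, 11.0, 89.0)
raw MCC:      0.520 -> 0.377
balanced MCC: 0.538 -> 0.610
better ('prevalence_shift', 'raw_metric_contradiction')
```

The raw MCC *drops* from 0.520 to 0.377 — judged on it alone, the AD
filter looks harmful.  The drop is an artefact of the prevalence shift
0.600 → 0.900 (MCC is anchored at 0 at extreme prevalence), not of the
model: the balanced MCC rises 0.538 → 0.610, in agreement with the
sensitivity and specificity gains.  The report's verdict is `better`
(both Sen and Spe increased) and it flags both the prevalence shift and
the contradicting raw metric.

The same analysis from the shell, including every catalogue metric raw
and balanced:

```sh
prevcal compare --scenario ad_split      # exits 2: contradiction flagged
prevcal sweep --metric mcc --sen 0.71 --spe 0.89 --out mcc_curve.csv
prevcal plot  --metric mcc --sen 0.71 --spe 0.89 --out mcc_curve.png
```

The sweep/plot show the umbrella-shaped MCC-vs-prevalence curve at fixed
(Sen, Spe) with the balanced value marked at 0.5; `prevcal compute` prints
the metric table for a single matrix or label file, and
`prevcal fixtures` regenerates the packaged scenario files.

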