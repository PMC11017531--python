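# Methods

## The problem

A binary QSAR classifier validated against a test set yields a confusion
matrix — the counts TP, FN, FP, TN of the four prediction types.  Most
summary metrics computed from it (accuracy, MCC, PPV, NPV, Cohen's kappa,
F1, markedness) depend not only on the model but also on the *positive
prevalence* of the test set, Pre = (TP + FN)/N.  When two validation runs
use test sets of different prevalence — internal vs external validation,
applicability-domain (AD) filtering, cluster splits, drifting data
streams — those raw metrics are not comparable, and their variation can
point in the opposite direction from the model's actual performance
change.

## Model

The package is built on a single algebraic observation.  Sensitivity
Sen = TP/(TP + FN) and specificity Spe = TN/(FP + TN) are
prevalence-independent properties of the model, and the quadruple
(Sen, Spe, Pre, N) carries exactly the same information as the four
counts, through the *derived confusion matrix*:

    TP = Sen·Pre·N          FN = (1 − Sen)·Pre·N
    TN = Spe·(1 − Pre)·N    FP = (1 − Spe)·(1 − Pre)·N

Substituting an arbitrary target prevalence into these products
reconstructs the matrix the same model would produce on a test set of
that composition (`calibrate_matrix`).  Evaluating any count-based metric
on the reconstruction defines its *calibrated* version
(`calibrated_metric`); N cancels out of every catalogue metric, so the
result depends only on (Sen, Spe, target prevalence).  Calibrating to the
reference prevalence 0.5 gives the *balanced* metrics.  Two have
closed forms used as the public fast path:

    Acc(Pre)  = Sen·Pre + Spe·(1 − Pre)                      — affine, slope Sen − Spe
    MCC(Pre)  = (Sen + Spe − 1) /
                √[(Sen + (1−Spe)(1−Pre)/Pre)(Spe + (1−Sen)Pre/(1−Pre))]
    Bal.Acc   = Acc(0.5)  = (Sen + Spe)/2
    Bal.MCC   = MCC(0.5)  = (Sen + Spe − 1)/√(1 − (Sen − Spe)²)

Useful identities, all enforced by tests: informedness (Youden's index)
Sen + Spe − 1 equals balanced accuracy rescaled to [−1, 1] and is the
numerator of MCC in the form above; balanced kappa equals informedness;
balanced PPV = Sen/(Sen + 1 − Spe) and balanced NPV = Spe/(Spe + 1 − Sen).
The generic derived-matrix route is retained as the independent oracle for
every closed form (agreement to 1e-12 is asserted over 10^4 random
profiles).

## Comparison reports

For two runs, the variation of Sen and Spe defines the verdict: `better`
if both increase, `worse` if both decrease, `trade_off` otherwise
(including the all-constant case of identical runs — deltas within the
variation tolerance count as no change).  The report tabulates every
catalogue metric twice — raw, and calibrated to the reference
prevalence — with variation directions, and raises two flags:

* `prevalence_shift` when |ΔPre| exceeds a threshold (default 0.02; any
  shift matters in principle, the threshold only suppresses noise between
  near-identical sets);
* `raw_metric_contradiction` when a raw metric's direction opposes a
  `better`/`worse` verdict — the signature of a prevalence artefact.

More than two runs are compared pairwise against the first.  The CLI
`compare` command exits with status 2 when a contradiction is flagged, so
it can gate a validation pipeline.

## Numerical choices

* **Fractional counts.**  Calibrated matrices keep real-valued cells; the
  algebra is continuous and rounding would break the metric identities.
  Integer realisation is confined to the scenario fixtures.
* **Per-cell products.**  `from_profile` computes each cell by its own
  product rather than by complement subtraction: FN = Pre·N − TP loses all
  relative precision when Sen → 1.  Class totals TP + FN = Pre·N then hold
  to one unit in the last place rather than bitwise, which is what the
  round-trip tests assert (1e-9 relative per cell; Sen/Spe preserved to
  1e-12 under calibration).
* **Undefined statistics.**  Sen is 0/0 on an all-negative set, Spe on an
  all-positive one; these carry an explicit `UNDEFINED` marker and any
  operation consuming one raises `UndefinedMetricError` — never a silent
  0 or 1.
* **MCC conventions.**  A zero marginal makes count-based MCC 0/0; the
  package defines it as 0, consistent with the anchor behaviour of the
  prevalence curve (MCC → 0 as Pre → 0 or 1 for interior Sen/Spe).  At the
  prevalence endpoints the closed form returns the anchor value 0 with a
  `DegenerateLimitWarning`; when Sen or Spe is exactly 0 or 1 there the
  limit does not exist and `UndefinedLimitError` is raised.  Balanced MCC
  at |Sen − Spe| = 1 is likewise 0/0 and returns 0 with a warning.
* **Sweeps.**  Prevalence grids are open-interval, [ε, 1 − ε] with
  defaults ε = 0.005 and 199 points (odd, so 0.5 is on the grid); the
  endpoints are limit points, not evaluation points.
* **Display.**  Values are carried at full double precision; tables round
  to 3 decimal places at the reporting layer only.
* **Tolerances.**  Closed-form identities are asserted at 1e-12 absolute,
  round trips at 1e-9 relative; the report treats |Δ| < 1e-9 as constant.

## Synthetic scenarios

All worked examples are synthetic — the argument operates purely at the
confusion-matrix level, so no chemical data or model training is involved
and nothing about descriptors, chemistry or AD algorithms is emulated.
The four packaged scenarios use two performance pairs, (Sen, Spe) =
(0.710, 0.890) and (0.680, 0.850), chosen to be integer-consistent with
every (Pre, N) combination used:

| scenario            | runs                                                          | flags raised |
|---------------------|---------------------------------------------------------------|--------------|
| `same_prevalence`   | (0.710, 0.890, Pre 0.900, N 2000) vs (0.680, 0.850, 0.900, 1000) | none |
| `shifted_prevalence`| (0.710, 0.890, 0.900, 2000) vs (0.680, 0.850, 0.600, 1000)     | shift + contradiction |
| `ad_split`          | (0.680, 0.850, 0.600, 2000) vs (0.710, 0.890, 0.900, 1000)     | shift + contradiction |
| `stream_drift`      | 10 windows, N 500, Pre linear 0.3 → 0.9, Sen 0.75, Spe 0.85     | shift |

The `stream_drift` parameterisation is illustrative (round numbers at a
window size typical of temporal validation batches); its windows are not
integer-consistent and are realised by largest-remainder rounding, which
preserves N exactly and prevalence to the nearest achievable count.  The
cluster-splits use case is the same mathematics as `shifted_prevalence`
(shared Sen/Spe, heterogeneous prevalence) and is not packaged separately;
no clustering is performed.

`realise_labels` expands a profile into shuffled (actual, predicted)
label arrays that tabulate back to the rounded matrix exactly; the shuffle
order is the only randomness in the package and is fully determined by the
seed.  Because scenarios are exact by construction, passing tests
demonstrate the algebra and the reporting logic — they say nothing about
sampling variability in real validation data (confidence intervals on
metrics are out of scope).

## Known limitations

* Binary, hard-label classification only: no multi-class matrices, no
  probabilistic scores or thresholding, no ROC/AUC (rank-based metrics are
  not defined from a single confusion matrix and cannot be calibrated this
  way).
* Sen/Spe are treated as fixed model properties under prevalence shift;
  in real AD filtering they may themselves change (as the `ad_split`
  scenario illustrates), and the framework compares whatever values each
  run exhibits rather than modelling why they moved.
* The prevalence-shift threshold (0.02) and the reference prevalence
  (0.5) are conventions, both configurable; domain-specific reference
  prevalences can be supplied via `target_prevalence` /
  `reference_prevalence` arguments.
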