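# shmclass

Somatic-hypermutation (SHM) targeting models and machine-learning
classification for B-cell receptor (BCR) heavy-chain repertoires.

## The problem

Bulk AIRR-seq of the immunoglobulin heavy chain yields, per subject, tens of
thousands of rearranged sequences with inferred germlines.  In chronic
immune-mediated disease, no *single* repertoire summary (CDR3 length,
mutation frequency, clonal diversity, V gene usage) may separate patients
from controls, while multivariate patterns — in particular the
context-dependent *specificity* of somatic hypermutation — still can.
`shmclass` provides the full pipeline for that analysis: per-repertoire
5-mer SHM models, hotspot-motif dissection, repertoire featurisation, and a
leakage-free leave-one-out elastic-net classification protocol with
shuffled-label calibration, plus a synthetic cohort generator that makes
every stage verifiable end to end without access-controlled patient data.

## The model

For a repertoire R, each observed mutation is attributed to its germline
5-mer context w.  With m(w) mutations in context w and b(w) informative
germline occurrences of w, the model is

    mutability   μ(w) ∝ m(w) / b(w),      Σ_w μ(w) = 1
    substitution σ(w, x) = P(replacement base = x | mutation in w)
    targeting    τ(w, x) = μ(w) · σ(w, x)

(the S5F decomposition).  5-mers are partitioned into the Polη hotspot
class WA/TW (centre A preceded by W = {A,T}, or centre T followed by W;
128 + 128 of the 1024), the AID class WRC/GYW (64 + 64; R = {A,G},
Y = {C,T}), and 640 neutral contexts.  Flattened model entries — per
subject, optionally restricted to one hotspot class — feed a classifier:
per-fold Student's-t screening (top 30), standardisation, and elastic-net
logistic regression (λ·[α‖β‖₁ + (1−α)/2‖β‖₂²], (α, λ) by inner stratified
CV), evaluated by leave-one-out cross-validation and reported as
F1/accuracy/sensitivity/specificity with 95% Clopper–Pearson intervals
against a shuffled-label null.

See `docs/methods.md` for the complete method description and the
generator's assumptions.

## Worked example

The `analysis/` scripts run the whole study on synthetic cohorts (8 + 8
subjects × 500 sequences; cases carry a Polη specificity shift — WA
contexts ×1.5, TW rescaled so overall mutation load is unchanged):

```sh
python analysis/01_simulate_cohorts.py          # writes results/cohorts/
python analysis/02_single_features.py
python analysis/03_targeting_models.py
python analysis/04_feature_set_classification.py
python analysis/05_motif_ratios.py
python analysis/06_cross_cohort_transfer.py
```

Script 02 finds no usable single feature (`18 single features tested; 1
nominally significant at p<0.05 (~0.9 expected by chance)`) — the injected
effect moves neither mutation load nor diversity nor gene usage.  Script 03
shows where the signal lives; the case/control concordance of mean 5-mer
mutabilities is lowest exactly in the Polη class:

```
per-motif-class Spearman (mean control vs mean case):
   WA/TW: rho = 0.531
 WRC/GYW: rho = 0.933
 neutral: rho = 0.796
```

and script 05 resolves it into the generalised 3-mer motifs, with AAN/TAN
elevated and NTT/NTA depressed in cases, consistently across two
independently simulated cohorts:

```
discovery: case/control mutability ratios per generalised motif
  AAN: median 1.456   TAN: median 1.477
  NTT: median 0.553   NTA: median 0.529
```

Script 04 compares feature sets by leave-one-out F1 against per-run
shuffled-label nulls: the SHM-derived feature sets classify perfectly at
this effect size (`shm_5mer_all`, `shm_wa_tw`, `shm_3mer`: F1 = 1.000,
null medians 0.48/0.54/0.38) while CDR3 3-mers, V usage and V-J-length
cluster frequencies stay at their null bands (F1 0.17/0.50/0.43), and
restricting to WRC/GYW — the motif class the effect does not touch —
abolishes the signal (F1 = 0.353).  Script 06 transfers the
discovery-trained model to the replication cohort
(`discovery -> replication: accuracy=1.000 ... f1=1.000`) and to a null
cohort (`accuracy=0.500`), showing the classifier learned the group effect,
not cohort idiosyncrasies.

The same operations are scriptable from the CLI (`shmclass simulate`,
`validate`, `shm-model`, `features`, `classify`, `null`, `run`,
`transfer`); see `shmclass --help`.

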