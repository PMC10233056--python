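# lirads-auto

Fully automatic LI-RADS scoring of liver lesions on multi-phase
contrast-enhanced volumes, for imaging researchers who want the whole chain —
lesion segmentation, major-feature characterization, and rule-based category
inference — as one tested, configurable pipeline.

LI-RADS grades the likelihood that a liver observation in a high-risk patient
is hepatocellular carcinoma. Instead of mapping images straight to a grade,
this package mirrors how radiologists actually reason: it first segments each
lesion, then characterizes the three major features across contrast phases —
non-rim arterial phase hyperenhancement (APHE, B1), non-peripheral washout
(B2), and enhancing capsule (B3) — and finally applies the deterministic rule
table that maps (B1, B2+B3, size) to LR-3 / LR-4 / LR-5. The intermediate
feature calls make every category auditable.

The core pieces:

- **Segmentation** — a nested encoder–decoder (UNet++-style) with a residual,
  CBAM-attention encoder, fed 2.5D windows (three neighbouring slices as
  channels), trained with a hybrid loss
  `L = (1 − dice_soft) + focal`, where the focal term is
  `−(1/N) Σ α_c (1−p)^γ y log p`, plus a Lovász–Softmax (IoU-surrogate) term
  latched in once training progresses.
- **Characterization** — one shared convolutional backbone with three sigmoid
  heads, trained with the phase-adaptive multi-task loss
  `L = (1 − x)·L_B1 + x·(L_B2 + L_B3)` (x = 0 for arterial crops, 1 for
  portal-venous/delayed), so each phase supervises exactly the features it
  can show while every crop trains the shared weights.
- **Scoring** — maximum in-plane Feret diameter for size, then an exact
  lookup over half-open size bins ([0,10), [10,20), [20,∞) mm) with an
  explicit policy for the table's one ambiguous LR-4/5 cell.
- **Evaluation** — per-patient ("local") vs pooled ("global") DICE, threshold
  sweeps, pixel/lesion/patient-level precision–recall, and the 3×3 category
  confusion matrix.
- **Phantoms** — a synthetic multi-phase generator whose lesions carry known
  APHE/washout/capsule dynamics and rule-consistent labels, so the entire
  pipeline is exercised end-to-end without clinical data.

The networks run on a compact numpy layer library with hand-written,
finite-difference-verified backward passes; no GPU or deep-learning framework
is required.

## Worked example

Score a table of characterized lesions with the rule engine:

```bash
$ cat features.csv
lesion_id,B1,B2,B3,size_mm
lesion-01,1,1,0,24.6
lesion-02,1,1,0,14.1
lesion-03,0,0,1,9.2

$ lirads-auto score --features features.csv --out scored.csv
scored 3 lesions -> scored.csv

$ cat scored.csv
lesion_id,B1,B2,B3,size_mm,category,resolved
lesion-01,1,1,0,24.6,LR-5,LR-5
lesion-02,1,1,0,14.1,LR-4/5,LR-5
lesion-03,0,0,1,9.2,LR-3,LR-3
```

lesion-01 (APHE + washout, ≥20 mm) is definite LR-5. lesion-02 falls in the
table's ambiguous cell — APHE with exactly one minor feature at 10–19 mm —
reported as `LR-4/5` and resolved to LR-5 by the default
`prefer_washout_rule` policy because the minor feature is washout; capsule
alone would have resolved to LR-4. lesion-03 has no APHE and one minor
feature under 20 mm: LR-3.

Run the whole chain on synthetic phantoms (generates data, trains both
networks on one CPU, scores held-out patients, writes
`scores.csv` / `eval_report.json` / `run_manifest.json`):

```bash
$ lirads-auto run-all --out-dir runs/demo --seed 1
11 lesions scored; median test DICE 0.856; LI-RADS accuracy 0.9090909090909091
artifacts in runs/demo

$ lirads-auto ablation --out-dir runs/demo-ablation --seed 1
```

In a library workflow the same run is:

```python
from lirads_auto.pipeline import RunConfig, run_pipeline
result = run_pipeline(RunConfig(out_dir="runs/demo", seed=1))
print(result["scores"][["lesion_id", "size_mm", "resolved"]].head())
```

Numbers above are from the default desk-scale configuration: 40 easy
phantoms (high feature contrast, low noise), a reduced 2-stage network, a
quarter of patients held out. Expect training to take a few minutes.

## Layout

```
src/lirads_auto/
  phantom.py            synthetic multi-phase studies + datasets (NIfTI/CSV)
  preprocessing.py      normalization, standardization, 2.5D windows, folds
  losses.py             hybrid dice+focal, Lovász–Softmax, adaptive multi-task
  segmentation.py       nested encoder–decoder, training, prediction
  characterization.py   crops, shared-backbone three-head model, fusion
  scoring.py            Feret size, LI-RADS rule engine, ambiguity policies
  evaluation.py         DICE variants, sweeps, detection metrics, confusion
  pipeline.py           end-to-end orchestration + ablation harness
  nn/                   numpy layers with hand-written backprop
  cli.py                `lirads-auto` subcommands
docs/methods.md         model, conventions, parameters, limitations
```

Not modelled: LR-1/2/M/TIV categories, threshold growth (needs longitudinal
studies), inter-phase registration, and anatomically realistic liver texture
— see `docs/methods.md` for the full list of conventions and limitations.
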