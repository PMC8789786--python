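# hyokin

Hyoid kinematic analysis of videofluoroscopic swallow studies (VFSS).

During the pharyngeal phase of swallowing, the hyoid bone is pulled
anteriorly and superiorly; this excursion shields the airway and opens the
upper esophageal sphincter.  Reduced or slowed hyoid movement is associated
with aspiration and with post-swallow residue in the pyriform sinuses.
`hyokin` is a toolkit for clinicians and researchers who annotate
lateral-view VFSS frames with bony landmarks and want a reproducible path
from those annotations to kinematic parameters, group statistics and ROC
screening cutoffs.

The pipeline:

1. **Landmark I/O** — read/write per-frame annotations of six points of
   interest (anterior–inferior corners of C2–C5, hyoid, mandible) in a
   documented CSV/JSON schema, with an exclusion rule for recordings whose
   landmarks could not be recognized.
2. **Anatomical frame** — per-frame, vertebra-anchored coordinates: origin
   at the C4 corner, superior axis along C5→C3, anterior axis fixed by the
   mandible side.  Rigid head motion cancels exactly; pixels become
   millimetres via the calibration scale.
3. **Kinematics** — detect the motion window (onset of recognizable hyoid
   motion to its termination after the swallow) and compute, per swallow,

   | symbol | meaning | units |
   |---|---|---|
   | Dx, Dy | maximal anterior / superior hyoid displacement | mm |
   | Dxy | maximal hyoid displacement (Pythagorean) | mm |
   | Vx, Vy, Vxy | average velocities, D / duration | mm/s |

4. **Grouping** — normal (PAS 1, MBSImP residue 0–1), aspiration (PAS 6–8),
   stasis (residue 2–4); combined cases excluded, PAS 2–5 unclassified.
5. **Statistics** — per-group n / mean / quartiles / 95% CI, Shapiro–Wilk
   gate, Kruskal–Wallis with pairwise Mann–Whitney post hoc tests.
6. **ROC screening** — lower-positive ROC per parameter, trapezoidal AUC
   (= Mann–Whitney concordance), Youden-index cutoff, AUC > 0.7
   acceptability flag.
7. **Synthetic cohorts** — a calibrated generator that emits landmark-level
   recordings whose parameter distributions match published
   (mean, q1, q3) triples, with head motion, annotation jitter and full
   ground truth; it backs every end-to-end test.

See `docs/methods.md` for the model details and assumptions.

## Worked example

Simulate the default cohort (230 normal / 87 aspiration / 132 stasis
swallows), extract kinematics, compare groups, and screen for aspiration:

```python
import hyokin as hk
from hyokin.pipeline import extract_table
from hyokin.roc import run_roc_battery, battery_table
from hyokin.stats import compare_groups

cohort = hk.simulate_cohort(seed=1)
table = extract_table(cohort.recordings).table

report = compare_groups(table)
print(report.to_frame().query("parameter == 'Dx'").round(3))

battery = run_roc_battery(table, target="aspiration")
print(battery_table(battery).round(3))
```

Output (anterior displacement rows, then the ROC battery):

```text
parameter      group   n   mean     q1     q3  ci_low  ci_high  kruskal_wallis_H  kruskal_wallis_p
       Dx     normal 230 17.564 12.075 22.225  16.664   18.465            62.046               0.0
       Dx aspiration  87 11.377  7.760 14.496  10.217   12.536            62.046               0.0
       Dx     stasis 132 13.978 10.158 17.847  13.010   14.947            62.046               0.0

Measure  cutoff   AUC  sensitivity  specificity  acceptable
     Dx  14.530 0.716        0.759        0.597        True
     Dy  20.641 0.561        0.655        0.503       False
    Dxy  23.476 0.612        0.621        0.605       False
     Vx  10.566 0.840        0.747        0.804        True
     Vy  16.544 0.739        0.690        0.702        True
    Vxy  19.526 0.776        0.713        0.738        True
```

Reading this: the aspiration group's mean anterior excursion (11.4 mm) sits
well below the normal group's (17.6 mm) and the omnibus test is highly
significant, while superior displacement (Dy) barely discriminates —
its AUC stays near 0.56, whereas anterior displacement and the velocity
parameters reach acceptable discrimination (AUC > 0.7).  The `cutoff`
column is the Youden-optimal threshold: e.g. predicting aspiration when
Dx ≤ 14.5 mm catches 76% of aspirating swallows at 60% specificity on this
cohort.

The same workflow is available from the shell:

```bash
hyokin simulate --seed 1 --out runs/sim
hyokin extract  --input runs/sim/recordings --out runs/kinematics.csv
hyokin compare  --kinematics runs/kinematics.csv --out runs/stats
hyokin roc      --kinematics runs/kinematics.csv --target aspiration --out runs/roc
```

Every output directory contains a `run_manifest.json` with the seed and a
configuration hash; reruns with the same seed reproduce artifacts byte for
byte.

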