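# atlastcp

Voxel-wise tumor control probability (TCP) modelling for prostate
radiotherapy, with histopathology-driven parameter adjustment, constrained
radiosensitivity calibration, and recurrence-oriented statistical
evaluation.

## The problem

Local recurrence after definitive prostate radiotherapy often originates at
the primary tumor site, so a model that localizes sub-volumes at risk of
low tumor control could guide focal dose escalation without whole-gland
dose (and toxicity) increases.  `atlastcp` implements an atlas-based
workflow for this: population cell-density and tumor-probability atlases
supply per-voxel clonogen estimates, the patient's biopsy report supplies
segment-wise tumor grade and involvement, and a Poisson linear-quadratic
model turns dose, fractionation and radiosensitivity into overall TCP
values and voxel-level TCP maps.  It is aimed at medical-physics and
radiobiology researchers studying biologically targeted planning.

## The model

Each voxel *i* holds an independent Poisson population of `N_i` clonogenic
cells.  After `n` fractions of `d_i` Gy over `T_exp` days, with LQ
radiosensitivity `α` (Gy⁻¹), ratio `α/β` (Gy) and potential doubling time
`T_pot` (days), the per-clonogen surviving fraction is

    SF_i = exp( −α·n·d_i − (α / (α/β))·n·d_i² + ln2 · T_exp / T_pot )

and

    TCP_i = exp(−N_i · SF_i),     TCP = Π_i TCP_i .

Inter-patient radiosensitivity variation is modelled by a log-normal `α`
(mean 0.15 Gy⁻¹, SD 0.04 Gy⁻¹, truncated to [0.05, 0.40] Gy⁻¹); the overall
TCP is the mean whole-prostate TCP across sampled "virtual patients".

Four histopathology adjustment methods are provided:

1. **baseline** — atlas cell density, sampled `α`, single `α/β`;
2. **cell density** — `N_i` scaled by each segment's % adenocarcinoma
   (benign segments floored at 1%);
3. **density + Gleason-Pattern α** — fixed pattern-specific `α` applied
   75:25 (primary:secondary) within each voxel;
4. **density + Gleason-Score α/β** — score-specific `α/β` per segment.

A calibration module fits the radiosensitivity parameters (single `α/β`,
four pattern-dependent `α`, nine score-dependent `α/β` with the ranking
constraints `α_GP2 > … > α_GP5` and `α/β_2+2 < … < α/β_5+5` inside
[1, 8.3] Gy) by differential evolution against per-schedule population
control rates, and the evaluation module provides the exact Wilcoxon
signed-rank test, volume-weighted GTV/nonGTV comparison, low-TCP/GTV
alignment, histograms and sensitivity curves.  A synthetic-data module
generates phantoms, atlases, biopsy reports, dose grids and calibration
cohorts with known ground truth, so the entire pipeline runs without any
clinical data.

## Worked example

```python
import atlastcp as atp

# synthetic patient: ellipsoidal prostate phantom, posterior peripheral-zone
# lesion (Gleason 4+3) that later relapsed
spec = atp.PhantomSpec(
    lesions=(atp.Lesion((48.0, 48.0, 30.0), 10.0, "4+3", 3.0, relapse=True),),
    seed=3,
)
phantom = atp.make_phantom(spec)
labelmap = atp.segment_prostate(phantom.mask, n_segments=6)
report = atp.make_report(labelmap, spec)

params = atp.RadiosensitivityParams.reference()   # alpha/beta 1.77 Gy etc.
schedule = atp.TreatmentSchedule.weekday(20, 60.0)  # 60 Gy in 20 fractions

for method in (1, 2, 3, 4):
    model = atp.build_patient_model(
        phantom.cd_atlas, phantom.tp_atlas, None, schedule,
        labelmap, report, params, method, grid=phantom.grid,
    )
    result = atp.overall_tcp(model, schedule, params,
                             n_realizations=1000, seed=5)
    print(f"method {method}: overall TCP = {100 * result.overall_tcp:.1f}%")

# exact signed-rank comparison of the published nine-patient table
table = atp.load_reference_cohort()
for m in (2, 4):
    res = atp.wilcoxon_signed_rank(table["method1"], table[f"method{m}"])
    print(f"method {m} vs baseline: W+ = {res.statistic:.0f}, "
          f"p = {res.pvalue:.3f} (exact, n = {res.n})")
```

Output:

```
method 1: overall TCP = 95.4%
method 2: overall TCP = 98.4%
method 3: overall TCP = 100.0%
method 4: overall TCP = 96.2%
method 2 vs baseline: W+ = 17, p = 0.570 (exact, n = 9)
method 4 vs baseline: W+ = 0, p = 0.004 (exact, n = 9)
```

The per-method overall TCPs are for the synthetic phantom: the density
adjustment (method 2) raises TCP because biopsy involvement caps the atlas
clonogen count, and the pattern-specific fixed-α method (3) saturates near
100% — the known insensitivity of that adjustment.  The signed-rank lines
reproduce the reference nine-patient comparison: the score-dependent-α/β
method lowers overall TCP for all nine recurrent patients (p = 0.004),
while the density-only adjustment does not reach significance (p = 0.570).

The same pipeline is scriptable from the shell:

```sh
atlastcp simulate --out run/sim --seed 7
atlastcp tcp --in run/sim --seed 7 --out run/maps
atlastcp evaluate --maps-dir run/maps --in run/sim --out run/eval
atlastcp report --maps-dir run/maps --in run/sim --out run/figs
atlastcp calibrate single-ab --cohort run/sim/cohort.csv \
    --targets run/sim/targets.csv --seed 7 --out run/fit.yaml
```

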