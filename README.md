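# pbsautoplan

Automated four-field multi-field-optimized (MFO) pencil-beam-scanning (PBS)
proton treatment planning for bilateral head-and-neck targets — a desk-scale,
open reimplementation of a clinical in-house planning automation, exercised on
a seeded synthetic phantom.

## Who this is for

Medical-physics researchers and students who want a transparent, testable
model of what a clinical H&N PBS automation script does: how avoidance
structures control spot placement, how geometry-based OAR dose prediction
produces patient-specific objectives, how minimax robust optimization handles
setup and range uncertainty, and how a plan is graded under a 24-perturbation
robust evaluation. It is **not** a clinical treatment planning system: dose is
computed with an analytic pencil-beam kernel, not Monte Carlo.

## The technique

Bilateral H&N targets (CTV50, 50 CGE in 25 fractions) are planned with beams
at gantry 30°, 330°, 135°, and 225°, each carrying a 7.5 cm water-equivalent
range shifter (minimum deliverable energy 97.5 MeV ↔ 7.5 cm range in water,
via a Bragg–Kleeman law R = αE^1.77). Automation builds:

* `ant_avoid` — oral cavity minus target, plus dental hardware, plus an 8 mm
  margin (half the 16 mm spot FWHM): anterior beams never place a spot
  through or within it;
* `post_avoid` — everything inferior to the shoulder-apex plane: posterior
  beams stay out of the variable shoulder region, and an SFO region with a
  per-anterior-beam maximum dose splits the supraclavicular target equally
  between the two anterior fields;
* `PostNeck` (cord grown laterally/posteriorly) and a 5 mm skin rind, each
  with maximum-dose objectives.

Spots are placed on a lattice overlapping at the 80% dose fall-off
(spacing ≈ 9.08 mm), with energy layers every 5 mm WET, a minimum spot depth
of 0.5 cm, and a deliverable-MU window capping the max/min nonzero spot
weight at 150. Weights are optimized by minimax robust optimization over the
clinical 15-scenario family (2 mm right/left/superior/inferior shifts ×
{−1%, 0, +1%} range scaling):

    minimize_w≥0  Σ non-robust penalties(A₀ w) + max_s Σ robust penalties(A_s w)

Plans are evaluated under 24 perturbations (3 mm shifts, ±3.5% range, ±3°
roll/yaw, 3 mm independent anterior- and posterior-beam shifts) against
CTV50 V95% > 99% and the rule that D95% changes at most 3% on any
perturbation. Predicted OAR mean doses come from simulated isodose rings at
every 10% of prescription around the target (a monotone distance-to-dose
fall-off), applied to parotids, oral cavity, larynx, and trachea.

See `docs/methods.md` for the dose kernel, objective set, phantom anatomy,
and limitations.

## Worked example

```bash
pbsautoplan phantom --seed 0 --out case/
pbsautoplan autoplan --case case/ --dose 50 --fractions 25 --out plan/
```

The second command runs the whole pipeline (structures → prediction → spots →
15-scenario optimization → 24-perturbation evaluation) and ends with a line
like

```
V95% = 100.00%, worst D95 deviation = 2.93%, robustness PASS
```

meaning: all of the CTV50 receives at least 95% of the 50 CGE
prescription on the nominal plan (goal > 99%), and across all 24
perturbations the CTV50 D95% never changed by more than 2.93% of its nominal
value (in-house rule: ≤ 3%). `plan/` then contains the optimized plan JSON
(spot list with MU weights), the nominal dose as NRRD, per-OAR predicted and
achieved doses (CSV), the clinical-goal table, the per-scenario robustness
table, DVH-band data, the convergence log, and the fully resolved
configuration with its hash.

The same stages are available as library calls:

```python
import pbsautoplan as p
grid, structures, apex_z = p.generate_phantom(p.PhantomSpec(seed=0))
result = p.autoplan(grid, structures, apex_z, p.Prescription(50.0, 25), p.RunConfig())
print(result.goals)                       # V95%, OAR mean/max doses
print(result.robust_report.worst_d95_deviation_pct)
```

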