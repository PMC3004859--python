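# bcrnet

Cross-linking the B-cell antigen receptor (BCR) on immature B cells does not
activate them — it arrests them in G1 and ultimately kills them, the process
that purges self-reactive B cells during development. `bcrnet` is a Python
toolkit for the computational chain that maps this decision in a model
immature-B system: it quantifies signaling and transcription-factor (TF)
array measurements, reconstructs the receptor-to-gene network from
evidence-filtered protein–protein interaction (PPI) data, extracts the
effector-gene signature of the arrest, models the receptor-proximal
kinase–phosphatase balance, and scores two-channel co-localization. It is
aimed at systems biologists who want each of these stages as a reusable,
tested library component (or CLI) rather than a one-off analysis.

The stages, each its own module:

- **densitometry** — background-subtracted, loading-normalized fold-change
  profiles from Western blot band intensities; intermediates are *activated*
  at peak fold ≥ 2.
- **tf_array** — spot intensities normalized to border-control means;
  each of 345 TFs called activated (fold > 2 in both duplicates),
  suppressed (fold < 1/2 in both), or unaffected.
- **interactome** — multi-database interaction records merged into one
  undirected network; edges need ≥ 2 distinct supporting publications;
  CD79A/CD79B collapse into a single BCR complex node.
- **pathway** — *all* shortest paths BCR → activated intermediates → short-
  listed TFs, merged into subnetworks and assembled into a hybrid PPI +
  TF→gene network.
- **regulon** — candidate TF→gene links intersected with array-modulated
  TFs to form a dense overlapping regulon (DOR); effector signature by set
  subtraction against the mature-B-cell response.
- **lyn_syk** — ODE model of Lyn/Syk initiation under a transient
  phosphatase dip,

      dLp/dt = k1 + k2·Lp − d1·g(t)·Lp,  g(t) = 1 − α·sin(2πt/ω)
      dSm/dt = A − k3·Sm·Lp
      dSp/dt = k3·Sm·Lp − d2·Sp,         Lp* = k1/(d1 − k2)

  with steady-state analysis, d1 sweeps and least-squares parameter
  recovery.
- **colocalization** — pixel-wise Pearson coefficient with optional
  Gaussian/unsharp pre-filters.
- **synthetic** — generators for every input class with planted ground
  truth (paths, TF sets, peak folds, parameters, correlations), so the
  full chain runs and is tested without external data.

## Worked example

Recover a planted signaling response and ask whether basal Lyn activity
shapes it:

```python
import numpy as np
from bcrnet.synthetic import gen_timecourse
from bcrnet.densitometry import build_profile
from bcrnet.lyn_syk import OdeParameters, steady_state, peak_response_sweep

# a phospho-Lyn time course with a planted 3.2-fold peak at 10 min
table = gen_timecourse(["Lyn"], {"Lyn": (3.2, 10.0)}, noise_cv=0.0, seed=4)
profile = build_profile(table, "Lyn")
print(profile.peak_fold, profile.activated)

# basal active Lyn under strong vs weak negative regulation
for d1 in (0.25, 1.1):
    print(d1, steady_state(OdeParameters(d1=d1))[0])

# sweep the negative-regulation strength: fold response vs basal state
sweep = peak_response_sweep(OdeParameters(), np.linspace(0.23, 1.2, 6))
print(sweep.round(3).to_string(index=False))
```

prints

```
3.1999999999999997 True
0.25 0.5
1.1 0.09523809523809523
   d1  Lp_star  peak  peak_fold
0.230    0.556 0.708      1.275
0.424    0.267 0.392      1.468
0.618    0.176 0.288      1.637
0.812    0.131 0.235      1.789
1.006    0.105 0.202      1.927
1.200    0.087 0.179      2.054
```

The densitometry round trip returns the planted 3.2-fold peak (to
floating-point precision) and calls Lyn activated. The steady states show that weak negative regulation
(d1 = 0.25) means high basal active Lyn (Lp\* = 0.5) and strong regulation
(d1 = 1.1) means low basal Lyn (Lp\* ≈ 0.095). The sweep exposes the
model's central prediction: reading down the table, the higher the basal
level `Lp_star`, the *smaller* the fold response `peak_fold` to receptor
engagement — cells with constitutively active Lyn (the immature-B
situation) respond below the 2-fold activation call, while low-basal cells
exceed it.

The same stages are scriptable from the shell, e.g.

```sh
bcrnet synth tfarray --seed 4 --out plates.csv
bcrnet tfarray call --plates plates.csv --out calls.csv
# -> activated 36 / suppressed 30 / unaffected 279 of 345
```

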