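# crhmem

Analysis pipeline for contextual memory in hypothalamic CRH neurons.

CRH-synthesizing neurons of the paraventricular nucleus (CRH^PVN) sit at the
top of the endocrine stress axis. Calcium imaging shows that they carry
*physiological* memories of context: after footshocks in a novel
environment, re-exposure recruits previously weak cells into a strong
anticipatory response; after an appetitive experience (hazelnut spread) the
population response to the context scales down instead. `crhmem` implements
the computational side of that finding as a tested, reusable package:

* **`crhmem.network`** — a population of 100 adaptive leaky
  integrate-and-fire neurons driven by Poisson context input, shock and
  hazelnut currents, with two plasticity rules acting on each neuron's
  context weight total s through a delayed auxiliary variable a
  (tau_omega ds/dt = a - s, tau_omega = 400 s):

      aversive (two-factor):   da/dt = eps (Omega - s) r_slow H(r_slow - r_thresh)
      appetitive (one-factor): da/dt = eps (Omega - s) H(Nut(t) - nut_thresh)

  The ceiling term (Omega - s) recruits *weak* cells hardest; the Heaviside
  gate opens only for shock-evoked bursts of the slow calcium-like trace
  r_slow (aversive) or during the appetitive stimulus.
* **`crhmem.photometry`** — dual-channel fiber-photometry preprocessing:
  5-min head/tail exclusion, second-order bleach detrending, isosbestic
  (405 nm) fitting and subtraction, dF/F = (F465 - F_fit405)/F_fit405, and
  z = (F - F0)/sigma_F with day-1 SD referencing for multi-day series.
* **`crhmem.miniscope`** — integrated dF/F (idF/F: mean of dF/F at 0.1 s
  over 3 min, x100) and cross-day field-of-view registration by stochastic
  descent on the weighted Frobenius metric 0.3 GA_mask + 0.7 GA_raw, plus
  nearest-centroid cell matching.
* **`crhmem.subpop`** — Weak/Intermediate/Strong clustering: affinity
  propagation (preference = minimum similarity) followed by exemplar-based
  agglomerative merging to k = 3; and a ±1 SD tail classifier.
* **`crhmem.statespace`** — cross-day population matrices, PCA via SVD,
  paired Pre/Post tests, Pre–Post correlations, recruitment regressions,
  and freezing-time summaries.
* **`crhmem.synthetic`** — seeded generators (photometry sessions, cell
  tables, FOV image pairs, behavior barcodes) with ground truth for every
  downstream check; no raw recordings are publicly deposited, so these
  define the validation conditions.

See `docs/methods.md` for the model equations, parameter defaults and the
reasoning behind every free constant.

## Worked example

Simulate the aversive experiment on the 4x-compressed timeline, cluster the
simulated cells by their pre-shock activity, and test for recruitment:

```python
import numpy as np
from crhmem import network as nw, subpop as sp, statespace as ss

params = nw.preset_params("fs_table1", seed=1)       # standard parameter set
proto  = nw.build_protocol("aversive")               # 10 shocks, 900..1170 s
params, proto = nw.shorten(params, proto, 4)         # compressed timeline
res = nw.simulate(params, proto)

em = res.epoch_means()                               # per-neuron pre/fs/post
labels = sp.fit_subpopulations(em["pre"].to_numpy()).labels
for g in ("Weak", "Intermediate", "Strong"):
    m = labels == g
    d, t, p = ss.paired_comparison(em["pre"][m], em["post"][m])
    print(f"{g:12s} n={m.sum():3d}  post-pre={d:+.3f}  t={t:+.2f}  p={p:.2g}")
```

Output from this exact snippet:

```
Weak         n= 32  post-pre=+0.795  t=+8.08  p=3.9e-09
Intermediate n= 27  post-pre=+0.915  t=+11.20  p=1.9e-11
Strong       n= 41  post-pre=+0.522  t=+9.01  p=3.5e-11
```

Cells that were weak or intermediate before the shocks gain ~0.8–0.9 units
of the calcium-like indicator on re-exposure; the strong pool — closest to
the weight ceiling — gains the least: the two-factor rule reproduces the
recruitment asymmetry seen in vivo (sharper when cells are split by their
true initial weights rather than by noisy activity estimates). A no-shock
control run (`build_protocol("control")`) shows no change in any group, and
the appetitive preset (`preset_params("nutella_table1")`,
`build_protocol("appetitive")`) scales all groups down with the per-cell
rank order preserved.

Every module also has a CLI, e.g.:

```bash
crhmem sim run --preset fs_table1 --seed 7 --shorten 4 --out run.h5
crhmem synth cells --seed 3 --out cells.csv
crhmem clusters fit --in cells.csv --epoch pre --out labels.csv
crhmem analyze recall --cells cells.csv --labels labels.csv --out stats/
crhmem align run --days d1.tif --days d2.tif --seed 3 --out align/
```

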