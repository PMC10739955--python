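# Methods

This note records the models implemented in `crhmem`, the assumptions and
free parameters behind them, and the numerical choices that matter for
reproducing the package's outputs. The system under study is the population
of corticotropin-releasing-hormone neurons of the hypothalamic
paraventricular nucleus (CRH^PVN), which control the endocrine stress axis
and carry contextual memories of aversive and appetitive experience: a
footshock-paired context recruits previously *weak* cells into a strong
anticipatory response, while a hazelnut-paired context scales the whole
population's response down.

## 1. Spiking-network model (`crhmem.network`)

### Dynamics

N = 100 leaky integrate-and-fire neurons with spike-frequency adaptation:

    tau_m dV_i/dt = -V_i + I_bias + I_i_syn(t) - w_i(t) + gamma_i(t)
    dw_i/dt     = -w_i / tau_w + d * sum_k delta(t - t_ik)

with tau_m = 10 ms, V_reset = -65 mV, V_th = -40 mV, I_bias = -41 pA,
d = 20 pA, tau_w = 100 ms. A spike resets V to V_reset and increments the
adaptation current by d. The synaptic current decomposes into a context
term, a footshock term and a hazelnut term:

    I_syn = g_ctx * w_i^T r_ctx(t) + g_FS * w_FS_i * FS(t) + g_Nut * w_Nut_i * Nut(t)

* **Context**: N_ctx = 1000 Poisson trains at 8 Hz (novel context) or 1 Hz
  (home cage), filtered by the double exponential
  exp(-t/20 ms) - exp(-t/2 ms) and weighted by the plastic vector w_i.
* **Footshock**: FS(t) = sum_k exp(-(t - t_k)^2), t in seconds, ten shocks
  30 s apart on [900, 1200] s; w_FS_i ~ N(2, 1) per neuron, fixed.
* **Hazelnut**: Nut(t) = exp(-(t - 930 s)^2 / 1e4); w_Nut_i ~ U[-0.09, 0.01]
  (appetitive stimuli inhibit these cells).

All spikes additionally drive a slow indicator trace r_slow (rise 100 ms,
decay 1 s) — the model's calcium-like readout and the signal the learning
rules see. The default timeline is 2190 s: novel-context exposures on
[500, 1290] s and [1790, 2190] s, home cage otherwise.

### Learning rules

Both rules act on each neuron's **total** context weight s_i = sum_j w_ij
through a delayed auxiliary variable a_i (standing in for slow molecular
plasticity):

    aversive (two-factor):  da_i/dt = eps (Omega - s_i) r_slow_i H(r_slow_i - r_thresh)
    appetitive (one-factor): da_i/dt = eps (Omega - s_i) H(Nut(t) - nut_thresh)
    both:                   tau_omega ds_i/dt = a_i - s_i     (tau_omega = 400 s)

The first factor is a weight ceiling (Omega = 0.0031 aversive, -1
appetitive): cells far below the ceiling are recruited hardest, so the
previously weak cells gain the most — the opposite of Hebbian winner-take-
all recruitment. The second factor is a gate: only shock-evoked bursts
(aversive) or the appetitive stimulus itself open plasticity. H is strict
(H(0) = 0). a_i(0) = s_i(0), so weights are stationary until the gate first
opens; any other initialization would erase all weights within a few
tau_omega even without stimulation.

**Why per-neuron totals.** Applying the da/dt increment to each of the 1000
channel weights separately multiplies the loop gain on the total by N_ctx.
For the aversive constants this turns the ceiling dynamics into a
near-undamped oscillator (natural frequency sqrt(N_ctx * eps * r / tau_omega)
~ 0.4 rad/s against a 1/tau_omega ~ 0.0025 1/s damping rate; overshoot
~75x Omega) — unusable. We therefore keep one a_i per neuron and update
channel weights in lockstep; the dense reference stepper distributes each
increment equally over channels so the total follows the rule above.
Conversely the appetitive rate constant is only effective per channel
(2e-6/s on the total changes s by ~1e-3 of what the observed scaling
requires), so the appetitive preset uses 2e-3/s = 2e-6 x N_ctx on the
total. These two conventions are the only readings under which each rule
produces its documented phenomenology.

### Free parameters (and why these defaults)

The constants above fix the dynamics but not the current scale of the
three inputs, the noise amplitude, the plasticity thresholds, or the weight
initialization. Choices, made once while establishing the operating regime:

| parameter | default | rationale |
|---|---|---|
| `context_gain` | 4000 (aversive/control), 10 (appetitive) | a ceiling-level weight total must deliver O(1 pA) against the 1 pA bias-to-threshold gap; unit-amplitude context bumps weighted by w <= 0.0031 give ~4e-4 pA, so a conversion scale is unavoidable. 4000 puts the strongest cells ~1.8 pA above baseline in the novel context. The appetitive preset's weight totals are O(1), hence the smaller gain. |
| `fs_input_gain` | 5 pA | w_FS ~ N(2,1) alone gives ~2 pA shocks — drowned by the 20 pA adaptation jump. At 5 pA/unit, shocks drive 5–15 Hz bursts whose r_slow clearly exceeds context-evoked levels, which the gate requires. |
| `nut_input_gain` | 20 pA | makes the direct inhibitory transient during consumption visible (up to ~-1.8 pA); the appetitive *learning* does not depend on it. |
| `noise_sd` | 0.7 pA | discretized as noise_sd * sqrt(dt/tau_m) per Euler step (stationary voltage SD = noise_sd/sqrt 2, dt-independent). Gives sparse home-cage firing (~1–2 Hz); larger values bury the context/shock responses in baseline firing. |
| `r_thresh` | 4.0 (fixed) | above the context-evoked r_slow range (<= ~3.5) but below shock-burst peaks (>= ~5). An adaptive per-neuron percentile of home-cage r_slow is selectable (`"adaptive:90"`), but any threshold inside the context-evoked range opens the gate during plain exposure and lets no-shock control runs drift toward the ceiling, erasing the aversive-vs-control correlation contrast. |
| `nut_thresh` | 0.5 | opens the gate for ~166 s around the hazelnut presentation. |
| initial weight totals | U[0, Omega] (aversive), U[0, 1.5] (appetitive) | spans weak-to-ceiling cells, creating the Pre heterogeneity both rules act on. |

### Integration and implementation

Forward Euler at dt = 1 ms for V, w, a and s; the two double-exponential
filters use their exact per-step decay factors (they are defined as sums of
exponentials). Halving dt changes population epoch means by < 1.5%.
Because the rules never individuate context channels and the channel
weights are uniform within a neuron, the context input enters only through
the pooled spike train; `simulate()` exploits this exactly (one pooled
Poisson process, scalar weight totals) in a numba kernel, ~2 s per run on
the compressed timeline. The dense per-channel stepper is kept as the
reference implementation and agrees with the fast path to the last bit on
shared inputs (asserted in tests). The forward-Euler integrator's ISI bias
is ~ISI * dt/(2 tau_m); closed-form comparisons are run at dt = 0.1 ms
where the bias is below one step for suprathreshold drives.

**Compressed timeline.** Validation runs compress the protocol 4x (all
times /4, eps x4, tau_omega /4, hazelnut width /16), preserving every
plasticity integral while keeping 10-seed batches to ~2 minutes. Epoch
windows: `pre` = first novel interval up to stimulus onset (truncated to the
Post duration), `fs` = the shock block, `post` = the second exposure.

### What the model reproduces

Over 10 seeds (compressed timeline): population mean Post > Pre in every
aversive seed; bottom-tercile (weak) median recruitment exceeds the top
tercile; per-cell Pre–Post correlation drops to ~0.3–0.7 versus ~1.0 in
matched no-shock controls; zeroing the shock weights abolishes the increase
(pooled paired-difference CI covers 0); the appetitive preset scales
activity down (Post < Pre every seed) with Pre–Post correlation ~0.98.
These are the directions and orderings of the in vivo findings; absolute
magnitudes are not calibrated to data.

## 2. Photometry preprocessing (`crhmem.photometry`)

Chain: exclude the first/last 5 min (kept for bleach fitting only) →
per-channel second-order polynomial detrend, fitted on those head/tail
home-cage windows so evoked activity does not bias the curve → affine
least-squares fit of the 405 nm reference onto the signal channel →
dF = signal - fitted reference. The normalized alternative
dF/F = (F465 - F_fit405)/F_fit405 (degree-2 polynomial map of the
reference) and z-scoring z = (F - F0)/sigma_F are also provided; for
multi-day series sigma_F may be taken from day 1 so amplitudes share one
scale (F0 stays each session's own baseline mean by default). Sample SD
uses the n-1 denominator. Sessions shorter than 10 min fall back to a
full-trace fit window with a logged warning.

Recovery on synthetic sessions (quadratic multiplicative bleaching, shared
motion artifacts, exponential transients; 100 randomized sessions): bleach
coefficients within 1%, event amplitudes within 5%, common-mode motion
attenuated >= 20 dB in dF.

## 3. Miniscope measures and registration (`crhmem.miniscope`)

idF/F = mean of a cell's dF/F resampled at 0.1 s over a 3-min window,
x100.

Cross-day registration aligns per-day (max-projection, cell-mask) image
pairs by stochastic descent on GA, the sum of Frobenius distances over day
pairs, computed per channel and combined as 0.3*GA_mask + 0.7*GA_raw.
Proposals perturb one day's rotation/translation/scale (initial scales 5
deg / 10 px / 0.1, Gaussian); only strict improvements are accepted, so the
accepted-metric trajectory is non-increasing. The perturbation size halves
every 500 iterations and the perturbed day cycles every 400; 10,000
iterations and 5 restarts from perturbed initial conditions are the
defaults. Two numerical safeguards: channels are intensity-normalized and
Gaussian-smoothed (sigma 3 px) before the metric, widening the similarity
basin beyond a cell body; and proposals retaining < 50% of the raw
channel's intensity mass are rejected, closing the degenerate minimum in
which the field of view slides out of frame. With both, known transforms
(rotation <= 10 deg, translation <= 10 px, scale 0.95–1.05) are recovered
to ~0.1 deg / 0.1 px / 0.005 on noiseless fixtures.

Cell correspondence is greedy nearest-centroid matching in the reference
frame under a 6 px cap, one-to-one, unmatched cells flagged. A
`pair_mode="vs_reference"` switch restricts GA to comparisons against day 1.

## 4. Subpopulation clustering (`crhmem.subpop`)

Affinity propagation on similarities = negative squared Euclidean
distances, shared preference = minimum off-diagonal similarity (the
conservative, few-exemplar choice), damping 0.9, <= 1000 iterations
(non-convergence raises). The exemplar-based agglomerative step then merges
cluster pairs — always the pair whose merged members have the best joint
exemplar (highest mean within-cluster similarity) — down to k = 3, labeled
Weak / Intermediate / Strong by ascending mean feature. The merge objective
is our interpretation of exemplar-based agglomeration; it is oracle-tested
on separable mixtures (>= 95% accuracy at >= 4 SD separation). The
alternative ±1 SD tail classifier is provided for cross-checks; the two
agree on >= 90% of tail cells on separable fixtures.

## 5. Recall statistics and state space (`crhmem.statespace`)

The population matrix is cells x time (0.1 s grid), rows keyed by cross-day
identity (cells unmatched on any included day are dropped with a logged
count), day blocks concatenated. PCA runs directly via the SVD; columns
(time samples) are mean-centered across cells by default (switchable:
`rows`, `none`), and explained-variance fractions are s_k^2 / sum s^2 —
verified against covariance eigenvalue ratios to 1e-8. Paired Pre/Post
comparisons use the paired two-tailed t-test (a constant shift is reported
as infinite t with a warning); Pre–Post association uses Pearson r with the
regression slope test; recruitment is the within-group regression of
(Post - Pre) on the shock-epoch response (groups under 3 cells skipped).
Freezing summaries count only bouts >= 3 s. A repeated-measures ANOVA
wrapper (statsmodels) is included as a convenience.

## 6. Synthetic data (`crhmem.synthetic`)

The generators define the validation conditions:

* **Photometry**: 15-min sessions at 100 Hz; multiplicative quadratic
  bleaching (strictly positive, ~10–30% decay); transients with instant
  rise and 2 s exponential decay in the signal channel only; a sustained
  context step; brief Gaussian motion bumps added to both channels with
  shared gain 1.0 (so subtraction is exact in the noiseless case); white
  noise. No quantitative noise model is available for such recordings;
  amplitudes here are free parameters chosen to resemble typical sessions
  (noise SD ~0.15% of baseline, events 5–15%, motion 30–50%).
* **Cell tables**: Weak/Intermediate/Strong mixture (fractions
  0.35/0.45/0.20; Pre means 2/7/15 idF/F) with shock responses stronger in
  Weak cells (means 13/8/5). Aversive ground truth: Post = Pre + k_g * FS
  with k = 1/0.5/0 (Weak lands at the Strong level — the ceiling); we
  allocate the intermediate pool half the Weak gain, a choice the rules
  leave open. Appetitive: Post = (1 - s_g) Pre with s = 0.05/0.30/0.60
  (Strong drops most, ranks preserved). Day-to-day measurement noise
  SD 0.5 idF/F.
* **FOV pairs**: Gaussian blobs (radius 2.5 px) with labeled disk masks on
  64x64 frames; day 2 is day 1 under a known similarity transform
  (bilinear for raw, nearest-neighbor for masks); placement is
  rejection-sampled so all cells stay in frame under the transform.
* **Behavior barcodes**: 10 Hz binary annotations from bout intervals,
  rejecting bouts under 3 s.

Every generator takes an explicit seed and touches no global state; ground
truth objects carry everything downstream checks score against.

**What passing these tests does not show.** The synthetic data contain no
hemodynamic or autofluorescence contamination, no non-rigid tissue
deformation, no source-extraction crosstalk, and Gaussian noise only;
recovery tolerances achieved here are upper bounds on real-data
performance. The network results establish that the two rules *suffice* to
produce the recruitment/scaling phenomenology at a self-consistent
operating point — not that the canonical constants do so under a literal per-channel
reading, nor that the model is quantitatively fitted to recordings.

## Known limitations

* The current scales (`context_gain`, `fs_input_gain`, `nut_input_gain`)
  and the plasticity thresholds are free parameters; conclusions are
  qualitative (directions, orderings, correlation contrasts).
* In aversive runs the auxiliary variable can overshoot the ceiling while
  the weights lag (the ceiling reads s, not a); totals transiently exceed
  Omega by up to ~20% before relaxing.
* Registration assumes a similarity transform (no shear, no non-rigid
  component) and benefits from the smoothing prior; heavily occluded or
  low-cell-count fields will have flatter metrics.
* The agglomerative merge objective and the cell-matching rule are
  documented interpretations where the procedure is otherwise unspecified.
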