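# hybridseek

Epileptic-seizure *prediction* from scalp EEG: classify short analysis
windows as **preictal** (inside the horizon before a seizure onset) or
**interictal** (seizure-free baseline), so that an alarm can be raised
before the seizure starts rather than after. The package is a library for
researchers working with multi-channel EEG recordings (EDF files such as
the CHB-MIT or Siena scalp databases, or synthetic records generated
in-package), plus a thin `hybridseek` command-line wrapper.

## Method

1. **Preprocessing** — optional anti-aliased downsampling, then a
   zero-phase 4th-order Butterworth band-pass restricted to 0–75 Hz.
   Non-overlapping windows (default 4 s) are labeled preictal iff they lie
   fully inside `[onset − horizon, onset)`; ictal windows and a post-seizure
   guard period are discarded.
2. **Band decomposition** — each window is filtered into the five clinical
   bands: delta 0–4, theta 4–8, alpha 8–13, beta 13–22, gamma 22–30 Hz.
3. **Features** — per band and channel, the vector
   `F = {F_MN, F_VR, F_SDN, F_SKW, F_KRT, F_WEY, F_WEN, F_HEN}`:
   mean, variance, standard deviation, skewness `Σ(A_r−F_MN)³/(q d³)`,
   kurtosis `Σ(A_r−F_MN)⁴/(q d⁴)`, relative wavelet detail energy
   `F_WEY = 1 − B(approx)/ΣB(w)` from a db4 level-5 DWT, wavelet entropy
   `F_WEN = −Σ_w p_w log₂ p_w` over the relative sub-band energies, and the
   amplitude-histogram entropy `F_HEN = −Σ_x L_x log₂ L_x`.
4. **Hybrid seek optimization** — a swarm of agents whose proposals are the
   midpoint of a *corvid* (crow-search) move
   `J_e + λ₁ a (Z_f − J_e)` toward a random flock-mate's memory (with
   awareness probability `P_aw` triggering a uniform random relocation) and
   a *gregarious* (sparrow-search) move
   `J_best + θ |J_e − J_best(1 + ν₁ϖ) + V|` toward the global best (the
   current best agent instead explores via
   `J_e + χ |J_e − J_worst| / ((j_e − j_ws) + ς)`). Out-of-bounds proposals
   are rejected (old position kept) and per-agent memories make the
   best-so-far fitness monotone. The optimizer drives both **wrapper
   feature selection** (positions in `[0,1]^D`, thresholded at 0.5) and
   **fusion-weight tuning** (positions in `[0,1]³`, projected onto the
   simplex).
5. **Ensemble** — AdaBoost over decision stumps
   (`φ_c = Σ_s p_s 1[u_c(v_s) ≠ t_s]`, `τ_c = ½ ln((1−φ_c)/φ_c)`,
   `C_AB = sign(Σ τ_c u_c)`), a random forest (bootstrap `Q = n`,
   `h = ⌊√D⌋ < D` features per node, unpruned), and a Gini decision tree
   (`C_DT = 1 − Σ V_χ²`). Their class-1 scores are fused as
   `E_c = τ E_AB + ρ E_RF + ε E_DT` with `τ + ρ + ε = 1`.
6. **Evaluation** — accuracy `(T_pos+T_neg)/(R_pos+R_neg)`, sensitivity
   `T_pos/R_pos`, specificity `T_neg/R_neg`, under stratified
   training-percentage splits (40/50/60/80/90 %) or stratified k-fold
   (k ∈ {2,4,6,8,10,12}).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
python examples/05_full_pipeline.py
```

prints (exactly, for the fixed seed):

```
540 segments x 160 features
train/test split: 432/108 (80% training)
selected 74 features; fusion weights [0.648, 0.27, 0.083]
held-out metrics: {"accuracy": 1.0, "sensitivity": 1.0, "specificity": 1.0}
```

Two synthetic 20-minute, 4-channel records (one seizure each, slow-rhythm
amplitude tripled during the 300 s preictal horizon) yield 540 labeled 4 s
windows with 160 features (5 bands x 4 channels x 8). The optimizer keeps
74 features and weights AdaBoost/forest/tree as (0.648, 0.270, 0.083);
the held-out 108 windows are classified perfectly because the class signal
is planted by construction — real EEG is far harder (see the methods
note). The other examples demonstrate EDF round trips, band features, the
optimizer benchmark, and selection/fusion in isolation; the same steps are
available from the shell via
`hybridseek simulate|extract|select|train|evaluate|run`.

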