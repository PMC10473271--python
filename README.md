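# arrowtime

Arrow-of-time (nonreversibility) estimation for multivariate brain-signal
time series.

## What problem this solves

A system in thermodynamic equilibrium looks statistically the same whether
its recordings are played forward or backward; a system driven away from
equilibrium — a brain engaged by a task, for example — does not. The degree
to which a parcellated BOLD recording can be distinguished from its
time-reversed copy ("breaking of detailed balance") is a scalar signature of
how strongly the underlying dynamics are driven and hierarchically
organised. `arrowtime` measures this signature at three granularities
(whole brain, network/system, single region) for researchers working with
parcel-level fMRI time series, and validates every stage on synthetic
stochastic processes whose irreversibility is known in closed form.

## The method

1. **Windowing.** Each recording (regions × time, z-scored per region,
   optionally band-pass filtered at 0.008–0.08 Hz) is cut into sliding
   windows of *w* samples shifted by *s*. Every window yields two flattened
   patterns: the window itself (label *forward*) and its time reversal
   (label *backward*).
2. **Direction classifier.** A fully connected network — input *N·w*, ten
   hidden layers of 2048, 1024, 512, 256, 128, 64, 32, 16, 8, 4 units with
   batch normalization + ReLU, and a softmax pair — is trained with Adam
   (10 epochs, minibatch 128, lr 10⁻³, L2 10⁻⁴) to tell forward from
   backward. Training and evaluation participants are disjoint.
3. **Reversibility index.** For each held-out window with outputs
   *o_f* (forward pattern) and *o_b* (its reversal),

   R(t) = [(o_f(2) − o_f(1)) + (o_b(1) − o_b(2))] / 2,

   clipped to 0 if either margin is negative. R = 0: window
   indistinguishable from its reversal; R = 1: perfectly distinguishable
   (maximal nonreversibility). Per participant, mean R over windows is the
   nonreversibility summary and std R a second-order nonstationarity
   measure.
4. **Detailed balance.** The lagged functional connectivity
   FC_ij(τ) = corr(x_i(t), x_j(t+τ)) is symmetric for reversible dynamics;
   its asymmetric part (mean off-diagonal |FC_ij − FC_ji|, and per-node
   in/out flow differences |F_out(i) − F_in(i)|) quantifies broken detailed
   balance, and can be contrasted between low- and high-R windows.
5. **Statistics & classification.** Group contrasts use Wilcoxon rank-sum
   with Benjamini–Hochberg FDR and rank-biserial effect sizes; conditions
   can be classified from per-network mean-R features with a one-vs-one
   RBF-kernel SVM whose chance level is estimated by label permutation.

The synthetic testbed is a multivariate Ornstein–Uhlenbeck process
dx = −Ax dt + √2 dW with A = S + κK (S symmetric positive definite, K
antisymmetric): reversible exactly when κ = 0, with closed-form stationary
covariance (Lyapunov equation), lagged covariance C(τ) = e^{−Aτ}Σ, exact
per-window forward/backward KL divergence, and a discrete-state entropy
production H_P = Σ P_ij log(P_ij/P_ji).

## Worked example

```python
import numpy as np
from arrowtime import synthetic as syn, signal_io as sio, pipeline as pl

# two cohorts: reversible (kappa = 0) vs strongly driven (kappa = 2)
groups = [syn.GroupSpec("equilibrium", 20, 0.0, 10, 176),
          syn.GroupSpec("driven", 20, 2.0, 10, 176)]
cohort = [sio.normalize_series(s)
          for s in syn.make_cohort(syn.CohortSpec(groups, seed=42))]

for label in ("equilibrium", "driven"):
    sub = [s for s in cohort if s.condition == label]
    r = pl.condition_mean_R(sub, w=20, shift=3, n_shuffles=3, seed=0)
    print(f"{label:12s} mean R = {r:.3f}")
```

Output:

```
equilibrium  mean R = 0.096
driven       mean R = 0.299
```

The driven cohort's windows are far easier to tell apart from their
reversals, so its mean reversibility index is much higher; the reversible
cohort sits at the small positive floor produced by finite training data
(compare it against a label-randomized null before interpreting it).

The same pipeline is available from the shell:

```
arrowtime simulate --out data --group ctrl:0 --group task:2 --n-participants 20
arrowtime train    --manifest data/manifest.tsv --registry models --w 20 --shift 3
arrowtime score    --manifest data/manifest.tsv --registry models --out scores
arrowtime compare  --summaries scores/summaries.tsv --out comparison.tsv
```

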