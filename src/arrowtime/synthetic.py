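"""Synthetic nonequilibrium processes with analytic irreversibility oracles.

The testbed is a multivariate Ornstein–Uhlenbeck (OU) process

    dx = -A x dt + sqrt(2 D) dW,

with drift ``A = S + kappa * K`` (S symmetric positive definite, K
antisymmetric with unit spectral norm) and isotropic diffusion ``D = I``.
For such a system detailed balance holds iff ``A @ Sigma`` is symmetric,
which with isotropic noise reduces to A itself being symmetric; the
antisymmetry knob ``kappa`` therefore tunes ground-truth irreversibility
continuously from a reversible equilibrium process (kappa = 0) upward.

Everything needed to check downstream estimators in closed form is here:
the stationary covariance (Lyapunov equation), the lagged covariance
``C(tau) = expm(-A tau) @ Sigma`` whose asymmetric part is the oracle for
lagged functional-connectivity asymmetry, and a discrete-state entropy
production H_P = sum_ij P_ij log(P_ij / P_ji) for model-free checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

from arrowtime.signal_io import ParcelTimeSeries, save_timeseries


# --------------------------------------------------------------------------
# Ornstein–Uhlenbeck testbed
# --------------------------------------------------------------------------

@dataclass
class OUSystem:
    """A stable linear stochastic system with known irreversibility.

    Attributes
    ----------
    drift : ndarray (n, n)
        A in dx = -A x dt + sqrt(2D) dW; all eigenvalues have positive
        real part.
    diffusion : ndarray (n, n)
        Symmetric positive-definite D.
    asymmetry_strength : float
        kappa >= 0; 0 iff the system satisfies detailed balance (under the
        package constructor with D = I).
    stationary_cov : ndarray (n, n)
        Sigma solving A Sigma + Sigma A^T = 2 D.
    dt : float
        Recording interval of simulated samples (plays the role of one TR).
    seed : int
    """

    drift: np.ndarray
    diffusion: np.ndarray
    asymmetry_strength: float
    stationary_cov: np.ndarray
    dt: float
    seed: int

    @property
    def n_regions(self) -> int:
        return self.drift.shape[0]


def stationary_covariance(A: np.ndarray, D: np.ndarray) -> np.ndarray:
    """Solve the continuous Lyapunov equation A Sigma + Sigma A^T = 2 D.

    Raises if A is unstable or D is not symmetric positive definite.
    """
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    eig = np.linalg.eigvals(A)
    if np.min(eig.real) <= 0:
        raise ValueError("drift matrix is unstable (eigenvalue with Re <= 0)")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("diffusion matrix must be symmetric")
    if np.min(np.linalg.eigvalsh((D + D.T) / 2)) <= 0:
        raise ValueError("diffusion matrix must be positive definite")
    sigma = sla.solve_continuous_lyapunov(A, 2.0 * D)
    sigma = (sigma + sigma.T) / 2  # symmetrize solver round-off
    resid = np.linalg.norm(A @ sigma + sigma @ A.T - 2.0 * D)
    if resid > 1e-8 * max(1.0, np.linalg.norm(D)):
        raise RuntimeError(f"Lyapunov solve residual too large: {resid:g}")
    return sigma


def _random_spd_and_antisym(n: int, rng: np.random.Generator):
    """S = Q^T Q / n + I (SPD), K antisymmetric with unit spectral norm."""
    Q = rng.standard_normal((n, n))
    S = Q.T @ Q / n + np.eye(n)
    M = rng.standard_normal((n, n))
    K = (M - M.T) / 2
    K /= np.linalg.norm(K, 2)
    return S, K


def make_ou_system(n_regions: int, asymmetry_strength: float,
                   seed: int, dt: float = 0.2) -> OUSystem:
    """Construct a stable OU system whose irreversibility is set by kappa.

    A = S + kappa K with S SPD and K antisymmetric of unit spectral norm,
    D = I.  Since the symmetric part of A is S (positive definite), every
    eigenvalue of A has real part >= lambda_min(S) > 0: the system is
    stable by construction for any kappa.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    if asymmetry_strength < 0:
        raise ValueError("asymmetry_strength must be >= 0")
    rng = np.random.default_rng(seed)
    S, K = _random_spd_and_antisym(n_regions, rng)
    A = S + asymmetry_strength * K
    D = np.eye(n_regions)
    sigma = stationary_covariance(A, D)
    return OUSystem(A, D, float(asymmetry_strength), sigma, float(dt), int(seed))


def make_ou_family(n_regions: int, asymmetry_strengths, seed: int,
                   dt: float = 0.2) -> list:
    """OU systems sharing the same S and K, differing only in kappa.

    Use this for graded-irreversibility comparisons: with fixed S, K the
    oracle asymmetry of C(tau) is monotone in kappa, so ground-truth
    ordering across the returned systems is known.
    """
    if n_regions < 2:
        raise ValueError("n_regions must be >= 2")
    rng = np.random.default_rng(seed)
    S, K = _random_spd_and_antisym(n_regions, rng)
    D = np.eye(n_regions)
    systems = []
    for kappa in asymmetry_strengths:
        if kappa < 0:
            raise ValueError("asymmetry_strength must be >= 0")
        A = S + kappa * K
        systems.append(OUSystem(A, D, float(kappa),
                                stationary_covariance(A, D), float(dt),
                                int(seed)))
    return systems


def lagged_cov_oracle(system: OUSystem, tau: float,
                      normalize: bool = False) -> np.ndarray:
    """Closed-form lagged covariance C(tau) = expm(-A tau) Sigma.

    C_ij(tau) = E[x_i(t) x_j(t + tau)] under stationarity; note the lagged
    index is j, matching the empirical lagged-FC convention.  With
    ``normalize=True`` entries are scaled to correlations by
    sqrt(Sigma_ii Sigma_jj), the population counterpart of Pearson lagged FC.
    The asymmetric part of C(tau) vanishes iff detailed balance holds.
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    # E[x(t) x(t+tau)^T] = Sigma expm(-A^T tau); entry (i, j) lags region j.
    C = system.stationary_cov @ sla.expm(-system.drift.T * tau)
    if normalize:
        s = np.sqrt(np.diag(system.stationary_cov))
        C = C / np.outer(s, s)
    return C


def simulate_ou(system: OUSystem, n_timepoints: int, seed: int,
                participant_id: str = "", condition: str = "",
                noise_scale: float = 0.0) -> ParcelTimeSeries:
    """Sample a stationary OU trajectory at the recording interval ``dt``.

    Sampling uses the exact Gaussian transition of the OU process,
    x_{t+1} = F x_t + eta with F = expm(-A dt) and
    Cov(eta) = Sigma - F Sigma F^T, started from the stationary
    distribution, so the recorded series has the exact stationary and
    lagged covariances at every recording interval (no discretization
    bias).  ``noise_scale`` adds iid Gaussian measurement noise on top.
    """
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    n = system.n_regions
    F = sla.expm(-system.drift * system.dt)
    Q = system.stationary_cov - F @ system.stationary_cov @ F.T
    Q = (Q + Q.T) / 2
    L_noise = np.linalg.cholesky(Q + 1e-12 * np.eye(n))
    L_stat = np.linalg.cholesky(system.stationary_cov)
    rng = np.random.default_rng(seed)
    x = np.empty((n_timepoints, n))
    x[0] = L_stat @ rng.standard_normal(n)
    eps = rng.standard_normal((n_timepoints - 1, n)) @ L_noise.T
    for t in range(1, n_timepoints):
        x[t] = F @ x[t - 1] + eps[t - 1]
    values = x.T
    if noise_scale > 0:
        values = values + noise_scale * rng.standard_normal(values.shape)
    return ParcelTimeSeries(values, tr_seconds=system.dt,
                            participant_id=participant_id,
                            condition=condition)


def window_direction_kl(system: OUSystem, w: int) -> float:
    """Exact KL divergence between forward and time-reversed windows.

    For a stationary Gaussian process the distribution of a w-sample,
    n-region window is zero-mean Gaussian with a block-Toeplitz covariance
    built from the lagged covariances C(k dt); the reversed window permutes
    the time blocks.  The divergence KL(forward || reversed), in nats per
    window, is the information available to *any* direction classifier at
    this window size: zero iff the system is reversible, and an upper
    bound (via Pinsker's inequality) on achievable classification margin.
    """
    if w < 2:
        raise ValueError("w must be >= 2")
    n = system.n_regions
    F = sla.expm(-system.drift * system.dt)
    blocks = [system.stationary_cov]
    for _ in range(1, w):
        blocks.append(blocks[-1] @ F.T)
    G = np.empty((n * w, n * w))
    for a in range(w):
        for b in range(w):
            blk = blocks[abs(b - a)]
            G[a * n:(a + 1) * n, b * n:(b + 1) * n] = blk if b >= a else blk.T
    idx = np.concatenate([np.arange(n) + p * n for p in range(w - 1, -1, -1)])
    Gr = G[np.ix_(idx, idx)]
    _, ld_g = np.linalg.slogdet(G)
    _, ld_gr = np.linalg.slogdet(Gr)
    return float(0.5 * (np.trace(np.linalg.solve(Gr, G)) - n * w
                        + ld_gr - ld_g))


# --------------------------------------------------------------------------
# Degenerate fixtures: maximally irreversible ramps, exchangeable noise
# --------------------------------------------------------------------------

def make_ramp_series(n_regions: int, n_timepoints: int, noise_scale: float,
                     seed: int, tr_seconds: float = 1.0,
                     participant_id: str = "",
                     condition: str = "ramp") -> ParcelTimeSeries:
    """Strictly monotone drift per region plus optional white noise.

    Each region rises with a random slope drawn from U(0.5, 1.5) per step;
    ``noise_scale`` is in units of the mean per-step drift (1.0).  At
    noise_scale = 0 every window is strictly increasing and its reversal
    strictly decreasing, so forward/backward windows are linearly separable
    — the maximally irreversible limit where R(t) should reach 1.
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    rng = np.random.default_rng(seed)
    slopes = rng.uniform(0.5, 1.5, size=(n_regions, 1))
    t = np.arange(n_timepoints)[None, :]
    values = slopes * t
    if noise_scale > 0:
        values = values + noise_scale * rng.standard_normal(values.shape)
    return ParcelTimeSeries(values, tr_seconds,
                            participant_id=participant_id,
                            condition=condition)


def make_noise_series(n_regions: int, n_timepoints: int, seed: int,
                      tr_seconds: float = 1.0, participant_id: str = "",
                      condition: str = "noise") -> ParcelTimeSeries:
    """Iid standard-normal series: forward and reversed windows are
    identically distributed, the exactly reversible null."""
    rng = np.random.default_rng(seed)
    return ParcelTimeSeries(rng.standard_normal((n_regions, n_timepoints)),
                            tr_seconds, participant_id=participant_id,
                            condition=condition)


# --------------------------------------------------------------------------
# Cohorts
# --------------------------------------------------------------------------

@dataclass
class GroupSpec:
    label: str
    n_participants: int
    asymmetry_strength: float
    n_regions: int
    series_length: int
    noise_scale: float = 0.0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")


@dataclass
class CohortSpec:
    """Specification of a labelled synthetic cohort.

    Groups sharing ``n_regions`` draw their OU systems from one family
    (shared S and K), so the group ordering of ground-truth irreversibility
    is exactly the ordering of ``asymmetry_strength``.
    """

    groups: list = field(default_factory=list)
    seed: int = 0
    min_series_length: int = 2

    def __post_init__(self):
        for g in self.groups:
            if g.series_length < self.min_series_length:
                raise ValueError(
                    f"group {g.label!r}: series_length {g.series_length} "
                    f"below required minimum {self.min_series_length}"
                )


def make_cohort(spec: CohortSpec) -> list:
    """Simulate one ParcelTimeSeries per participant per group.

    Deterministic in ``spec.seed``: participant seeds are spawned from a
    SeedSequence so the cohort is a pure function of the spec.
    """
    if not spec.groups:
        raise ValueError("cohort spec has no groups")
    # one OU family per distinct n_regions so kappa ordering is exact
    families = {}
    for g in spec.groups:
        families.setdefault(g.n_regions, [])
    for n_reg in families:
        kappas = [g.asymmetry_strength for g in spec.groups
                  if g.n_regions == n_reg]
        labels = [g.label for g in spec.groups if g.n_regions == n_reg]
        systems = make_ou_family(n_reg, kappas, seed=spec.seed)
        families[n_reg] = dict(zip(labels, systems))
    cohort = []
    children = np.random.SeedSequence(spec.seed).spawn(len(spec.groups))
    for g, child in zip(spec.groups, children):
        system = families[g.n_regions][g.label]
        seeds = child.generate_state(g.n_participants) % (2 ** 31)
        for pi in range(g.n_participants):
            pid = f"{g.label}_p{pi:03d}"
            cohort.append(simulate_ou(system, g.series_length,
                                      seed=int(seeds[pi]),
                                      participant_id=pid, condition=g.label,
                                      noise_scale=g.noise_scale))
    return cohort


def write_cohort(cohort: list, out_dir, metadata: dict | None = None) -> str:
    """Write a cohort as TSV matrices plus a manifest and JSON sidecar.

    Returns the manifest path.  One TSV per participant (regions as rows),
    a manifest TSV (participant_id, condition, path, tr_seconds) and a
    ``cohort.json`` sidecar with caller-supplied metadata.
    """
    import json
    import os

    os.makedirs(out_dir, exist_ok=True)
    rows = []
    for s in cohort:
        fname = f"{s.participant_id}_{s.condition}.tsv"
        save_timeseries(s, os.path.join(out_dir, fname))
        rows.append({"participant_id": s.participant_id,
                     "condition": s.condition, "path": fname,
                     "tr_seconds": s.tr_seconds})
    import pandas as pd

    manifest = os.path.join(out_dir, "manifest.tsv")
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False)
    with open(os.path.join(out_dir, "cohort.json"), "w") as fh:
        json.dump(metadata or {}, fh, indent=2, default=str)
    return manifest


# --------------------------------------------------------------------------
# Discrete-state entropy production
# --------------------------------------------------------------------------

@dataclass
class TransitionMatrix:
    """Empirical one-step transition structure of a discrete state sequence."""

    counts: np.ndarray
    pseudocount: float

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]

    @property
    def probs(self) -> np.ndarray:
        """Row-stochastic conditional transition probabilities."""
        c = self.counts + self.pseudocount
        return c / c.sum(axis=1, keepdims=True)

    @property
    def joint(self) -> np.ndarray:
        """Pair-frequency distribution over (state_t, state_{t+1})."""
        c = self.counts + self.pseudocount
        return c / c.sum()


def transition_counts(state_sequence, n_states: int) -> np.ndarray:
    seq = np.asarray(state_sequence, dtype=int)
    if seq.size < 2:
        raise ValueError("state_sequence must have length >= 2")
    if seq.min() < 0 or seq.max() >= n_states:
        raise ValueError("states must lie in [0, n_states)")
    counts = np.zeros((n_states, n_states))
    np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    return counts


def entropy_production_discrete(state_sequence, n_states: int,
                                pseudocount: float = 1e-6) -> float:
    """Entropy production H_P = sum_ij P_ij log(P_ij / P_ji) >= 0.

    P here is the pair-frequency distribution over ordered transitions
    (i at t, j at t+1), regularized with ``pseudocount`` added to every
    transition count so the ratio is always finite.  Normalizing over all
    pairs (rather than per row) makes H_P the Kullback–Leibler divergence
    between the forward and time-reversed transition distributions, hence
    nonnegative, and zero exactly for detailed-balanced chains.
    """
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0 (keeps H_P finite)")
    tm = TransitionMatrix(transition_counts(state_sequence, n_states),
                          pseudocount)
    P = tm.joint
    return float(np.sum(P * np.log(P / P.T)))


def quantile_discretize(values, n_states: int) -> np.ndarray:
    """Equal-occupancy (quantile) binning of a 1-D signal into n_states."""
    x = np.asarray(values, dtype=float).ravel()
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    edges = np.quantile(x, np.linspace(0, 1, n_states + 1)[1:-1])
    return np.searchsorted(edges, x, side="right")
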