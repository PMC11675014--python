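"""Synthetic generators for exercising the pipeline end to end.

Everything the test surface needs is generated here, seeded and pure:

* a trefoil-knot point cloud (ground truth: a closed loop);
* the two-state global-coupling schedule and its four state labels
  (stable-low, transition-up, stable-high, transition-down, twice each);
* a two-population (excitatory/inhibitory) network rate model with a
  hemodynamic stage — a parameterized BOLD-like simulator;
* a phenomenological circular-trajectory generator with the same label
  structure (two attractor patterns joined by two distinct arcs);
* SNR-targeted noise injection, boxcar-smoothed downsampling, and the
  block-shuffle null that destroys global temporal structure while
  preserving within-block autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import DataMatrix

__all__ = [
    "StateLabels", "SimulatorConfig",
    "g_schedule", "task_paradigm", "simulate_wc_bold", "synth_circular_bold",
    "trefoil_knot", "add_noise", "smooth_downsample", "shuffle_blocks",
    "modular_connectome",
]


@dataclass
class StateLabels:
    """Per-time-point categorical state plus the segment boundaries."""

    labels: np.ndarray            # length N
    boundaries: np.ndarray        # segment start times (seconds), incl. 0
    tr: float

    @property
    def n(self) -> int:
        return len(self.labels)

    def interior_boundaries(self) -> np.ndarray:
        """Transition times between segments (excludes t=0), in seconds."""
        return self.boundaries[1:]


def g_schedule(g_low: float = 1.1, g_high: float = 5.0, stable_s: float = 100.0,
               trans_s: float = 200.0, cycles: int = 2, tr: float = 0.72,
               ) -> tuple[np.ndarray, StateLabels]:
    """Global-coupling schedule: [low, ramp up, high, ramp down] x cycles.

    Defaults give a 1,200-s (20-min) course sampled at TR 0.72 s into
    1,667 points over 8 labeled segments (2 of each of the 4 state types).
    Returns the per-sample G values and the labels.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if stable_s <= 0 or trans_s <= 0:
        raise ValueError("durations must be positive")
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    segs = []  # (duration, state)
    for _ in range(cycles):
        segs += [(stable_s, "stable-low"), (trans_s, "transition-up"),
                 (stable_s, "stable-high"), (trans_s, "transition-down")]
    total = sum(d for d, _ in segs)
    t = np.arange(0.0, total, tr)
    t = t[t < total]
    G = np.empty_like(t)
    labels = np.empty(t.size, dtype=object)
    starts = np.concatenate([[0.0], np.cumsum([d for d, _ in segs])])[:-1]
    for (dur, state), t0 in zip(segs, starts):
        m = (t >= t0) & (t < t0 + dur)
        if state == "stable-low":
            G[m] = g_low
        elif state == "stable-high":
            G[m] = g_high
        elif state == "transition-up":
            G[m] = g_low + (g_high - g_low) * (t[m] - t0) / dur
        else:
            G[m] = g_high - (g_high - g_low) * (t[m] - t0) / dur
        labels[m] = state
    return G, StateLabels(labels=labels.astype(str), boundaries=starts, tr=tr)


def task_paradigm(tasks: list[str] | None = None, block_s: float = 180.0,
                  instruction_s: float = 12.0, tr: float = 1.5,
                  ) -> StateLabels:
    """Task-block paradigm labels: blocks separated by instruction periods.

    The default eight 180-s blocks with 12-s instructions between
    consecutive blocks total 1,524 s (25 min 24 s).  Labels carry the task
    name during blocks and ``"instruction"`` between them; the expected
    transition times are the instruction onsets.
    """
    if tasks is None:
        tasks = ["rest", "memory", "video", "math"] * 2
    segs: list[tuple[float, str]] = []
    for i, task in enumerate(tasks):
        if i > 0:
            segs.append((instruction_s, "instruction"))
        segs.append((block_s, task))
    total = sum(d for d, _ in segs)
    t = np.arange(0.0, total, tr)
    t = t[t < total]
    labels = np.empty(t.size, dtype=object)
    starts = np.concatenate([[0.0], np.cumsum([d for d, _ in segs])])[:-1]
    for (dur, state), t0 in zip(segs, starts):
        labels[(t >= t0) & (t < t0 + dur)] = state
    return StateLabels(labels=labels.astype(str), boundaries=starts, tr=tr)


def modular_connectome(n_nodes: int = 66, n_modules: int = 4,
                       p_within: float = 0.3, p_between: float = 0.05,
                       seed: int = 0) -> np.ndarray:
    """Seeded random modular coupling matrix C (symmetric, zero diagonal,
    rows normalized to unit sum) standing in for a structural connectome."""
    rng = np.random.default_rng(seed)
    module = np.arange(n_nodes) % n_modules
    same = module[:, None] == module[None, :]
    p = np.where(same, p_within, p_between)
    mask = rng.random((n_nodes, n_nodes)) < p
    w = rng.random((n_nodes, n_nodes)) * mask
    C = np.triu(w, 1)
    C = C + C.T
    rowsum = C.sum(axis=1, keepdims=True)
    rowsum[rowsum == 0] = 1.0
    return C / rowsum


@dataclass
class SimulatorConfig:
    """Parameters of the two-population network rate model.

    The model is a generic Wilson-Cowan-style excitatory/inhibitory pair
    per node with long-range coupling between excitatory populations
    scaled by the schedule G(t); defaults are this package's own
    phenomenological choices, tuned for bistable-looking global dynamics
    rather than matching any published parameter set.
    """

    n_nodes: int = 66
    coupling: np.ndarray | None = None   # C_ij; default: modular_connectome
    w_ee: float = 2.0
    w_ei: float = 1.5
    w_ie: float = 2.5
    w_ii: float = 1.0
    tau_e: float = 1.0       # s
    tau_i: float = 0.8       # s
    gain_slope: float = 4.0  # sigmoid transfer slope
    gain_thresh: float = 1.0
    i_ext: float = 0.4       # constant external drive to E
    dt: float = 0.05         # integration step, s
    noise_sd: float = 0.01
    seed: int = 0
    hrf: str = "double-gamma"  # or "none"

    def __post_init__(self) -> None:
        if min(self.tau_e, self.tau_i, self.dt) <= 0:
            raise ValueError("time constants and dt must be positive")
        if self.coupling is None:
            self.coupling = modular_connectome(self.n_nodes, seed=self.seed)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("coupling matrix shape mismatch")
        if np.any(self.coupling < 0) or np.any(np.diag(self.coupling) != 0):
            raise ValueError("coupling must be nonnegative with zero diagonal")


def _sigmoid(x: np.ndarray, slope: float, thresh: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-slope * (x - thresh)))


def double_gamma_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr``."""
    from scipy.stats import gamma as gamma_dist
    t = np.arange(0.0, duration, tr)
    peak = gamma_dist.pdf(t, 6)
    under = gamma_dist.pdf(t, 16)
    h = peak - under / 6.0
    return h / h.sum()


def simulate_wc_bold(cfg: SimulatorConfig, schedule: np.ndarray,
                     labels: StateLabels) -> DataMatrix:
    """Integrate the network rate model under the coupling schedule.

    Per node i, with S_E/S_I the open-channel fractions of the two
    populations and f the sigmoid transfer:

        dS_E/dt = (-S_E + f(w_ee S_E - w_ie S_I + G(t) sum_j C_ij S_E,j
                   + i_ext)) / tau_e + noise
        dS_I/dt = (-S_I + f(w_ei S_E - w_ii S_I)) / tau_i + noise

    Euler-Maruyama integration at ``cfg.dt``; the excitatory activity is
    convolved with a double-gamma hemodynamic response (optional) and
    sampled at the schedule's TR.
    """
    G_sched = np.asarray(schedule, dtype=float)
    n_samples = G_sched.size
    if n_samples != labels.n:
        raise ValueError("schedule and labels disagree in length")
    tr = labels.tr
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_nodes
    steps_per_tr = max(1, int(round(tr / cfg.dt)))
    S_E = np.full(n, 0.1)
    S_I = np.full(n, 0.1)
    out = np.empty((n_samples, n))
    sqdt = np.sqrt(cfg.dt)
    for s in range(n_samples):
        g = G_sched[s]
        for _ in range(steps_per_tr):
            inp_e = (cfg.w_ee * S_E - cfg.w_ie * S_I +
                     g * (cfg.coupling @ S_E) + cfg.i_ext)
            inp_i = cfg.w_ei * S_E - cfg.w_ii * S_I
            dE = (-S_E + _sigmoid(inp_e, cfg.gain_slope, cfg.gain_thresh)) / cfg.tau_e
            dI = (-S_I + _sigmoid(inp_i, cfg.gain_slope, cfg.gain_thresh)) / cfg.tau_i
            S_E = S_E + cfg.dt * dE + cfg.noise_sd * sqdt * rng.standard_normal(n)
            S_I = S_I + cfg.dt * dI + cfg.noise_sd * sqdt * rng.standard_normal(n)
            if not (np.all(np.isfinite(S_E)) and np.all(np.isfinite(S_I))):
                raise FloatingPointError(
                    f"non-finite state at sample {s} (t={s * tr:.2f} s)")
        out[s] = S_E
    if cfg.hrf == "double-gamma":
        h = double_gamma_hrf(tr)
        out = np.apply_along_axis(
            lambda col: np.convolve(col, h)[:n_samples], 0, out)
    return DataMatrix(out, tr=tr, labels=labels.labels.copy())


def synth_circular_bold(n_features: int = 66, schedule: StateLabels | None = None,
                        arc_separation: float = 1.0, noise_sd: float = 0.1,
                        seed: int = 0) -> DataMatrix:
    """Phenomenological circular trajectory with the four-state labeling.

    Two attractor patterns (stable-low, stable-high) live in feature
    space; the transition-up and transition-down segments interpolate
    between them along two DISTINCT arcs, bowed apart by
    ``arc_separation`` in a third orthogonal direction, so the noiseless
    trajectory is a closed loop with a preferred direction.
    """
    if n_features < 3:
        raise ValueError("need at least 3 features for two distinct arcs")
    if arc_separation <= 0:
        raise ValueError("arc_separation must be positive")
    if schedule is None:
        _, schedule = g_schedule()
    rng = np.random.default_rng(seed)
    basis = np.linalg.qr(rng.standard_normal((n_features, 3)))[0]
    a_low = basis[:, 0]
    a_high = basis[:, 1]
    bow = basis[:, 2]
    labels = schedule.labels
    t = np.arange(schedule.n) * schedule.tr
    starts = schedule.boundaries
    # per-sample progress through its own segment
    ends = np.concatenate([starts[1:], [schedule.n * schedule.tr]])
    seg_idx = np.searchsorted(starts, t, side="right") - 1
    prog = (t - starts[seg_idx]) / (ends[seg_idx] - starts[seg_idx])
    X = np.empty((schedule.n, n_features))
    for i, (state, p) in enumerate(zip(labels, prog)):
        if state == "stable-low":
            X[i] = a_low
        elif state == "stable-high":
            X[i] = a_high
        elif state == "transition-up":
            X[i] = ((1 - p) * a_low + p * a_high +
                    np.sin(np.pi * p) * (arc_separation / 2) * bow)
        else:
            X[i] = ((1 - p) * a_high + p * a_low -
                    np.sin(np.pi * p) * (arc_separation / 2) * bow)
    X += noise_sd * rng.standard_normal(X.shape)
    return DataMatrix(X, tr=schedule.tr, labels=labels.copy())


def trefoil_knot(n: int = 500, noise_sd: float = 0.0, seed: int = 0,
                 ) -> tuple[DataMatrix, np.ndarray]:
    """Trefoil-knot point cloud: the standard (2,3)-torus-knot curve.

    Points ``(sin t + 2 sin 2t, cos t - 2 cos 2t, -sin 3t)`` at ``n``
    evenly spaced parameters in [0, 2 pi), plus seeded Gaussian noise.
    Returns the matrix and the parameter angle per row.
    """
    if n < 10:
        raise ValueError("need at least 10 points")
    t = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    X = np.column_stack([np.sin(t) + 2 * np.sin(2 * t),
                         np.cos(t) - 2 * np.cos(2 * t),
                         -np.sin(3 * t)])
    if noise_sd > 0:
        X = X + np.random.default_rng(seed).normal(0, noise_sd, X.shape)
    return DataMatrix(X, tr=1.0), t


def add_noise(data: DataMatrix, target_snr: float, seed: int = 0,
              components: tuple[str, ...] = ("drift", "ar", "white"),
              ) -> DataMatrix:
    """Add structured noise scaled to a target signal-to-noise ratio.

    Per feature, a noise vector (equal-variance mix of linear+quadratic
    drift, AR(1), and white components) is scaled so its standard
    deviation equals (signal sd) / target_snr — "amplitude" is read as the
    per-feature standard deviation.  ``target_snr=inf`` returns the data
    unchanged; zero-variance features are skipped with a warning.
    """
    if target_snr <= 0:
        raise ValueError("target_snr must be positive")
    if np.isinf(target_snr):
        return DataMatrix(data.values.copy(), tr=data.tr,
                          feature_names=list(data.feature_names),
                          labels=None if data.labels is None else data.labels.copy())
    rng = np.random.default_rng(seed)
    n, m = data.values.shape
    t = np.linspace(-1, 1, n)
    X = data.values.copy()
    for j in range(m):
        sd = X[:, j].std()
        if sd == 0:
            warnings.warn(f"feature {j} has zero variance; noise skipped")
            continue
        parts = []
        if "drift" in components:
            drift = rng.normal() * t + rng.normal() * (t ** 2)
            parts.append(drift)
        if "ar" in components:
            e = rng.standard_normal(n)
            ar = np.empty(n)
            phi = 0.8
            ar[0] = e[0]
            for i in range(1, n):
                ar[i] = phi * ar[i - 1] + e[i]
            parts.append(ar)
        if "white" in components:
            parts.append(rng.standard_normal(n))
        noise = np.zeros(n)
        for p in parts:
            psd = p.std()
            if psd > 0:
                noise += p / psd   # equal-variance mixing
        nsd = noise.std()
        if nsd == 0:
            continue
        X[:, j] += noise * (sd / target_snr / nsd)
    return DataMatrix(X, tr=data.tr, feature_names=list(data.feature_names),
                      labels=None if data.labels is None else data.labels.copy())


def smooth_downsample(data: DataMatrix, factor: int, width: int = 4,
                      ) -> DataMatrix:
    """Boxcar-smooth (moving average of ``width`` samples, edge-truncated)
    then keep rows 0, factor, 2*factor, ...; TR is multiplied by factor."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if width < 1:
        raise ValueError("width must be >= 1")
    n = data.n_timepoints
    if factor >= n:
        raise ValueError(f"factor {factor} >= number of rows {n}")
    kernel = np.ones(width)
    # same-length smoothing with edge truncation: divide by the actual
    # window coverage at the boundaries
    cover = np.convolve(np.ones(n), kernel, mode="same")
    sm = np.empty_like(data.values)
    for j in range(data.n_features):
        sm[:, j] = np.convolve(data.values[:, j], kernel, mode="same") / cover
    keep = np.arange(0, n, factor)
    labels = None if data.labels is None else data.labels[keep].copy()
    return DataMatrix(sm[keep], tr=data.tr * factor,
                      feature_names=list(data.feature_names), labels=labels)


def shuffle_blocks(data: DataMatrix, block: int = 7, seed: int = 0,
                   ) -> DataMatrix:
    """Permute consecutive blocks of ``block`` rows (within-block order
    preserved) with a seeded uniform permutation.

    The same seed produces the same block permutation for any matrix with
    the same row count, so a cohort can be shuffled coherently.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    n = data.n_timepoints
    starts = np.arange(0, n, block)
    perm = np.random.default_rng(seed).permutation(len(starts))
    idx = np.concatenate([np.arange(starts[p], min(starts[p] + block, n))
                          for p in perm])
    labels = None if data.labels is None else data.labels[idx].copy()
    return DataMatrix(data.values[idx], tr=data.tr,
                      feature_names=list(data.feature_names), labels=labels)
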