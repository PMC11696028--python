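"""Task-optimized recurrent model classes for mental pong.

Four model classes share one gated recurrent architecture (a GRU with
linear output heads) and differ only in their loss masks:

* ``Intercept`` — one paddle output, trained on exactly two samples per
  trial (the initial central paddle position and the paddle position at
  interception time).
* ``Vis`` — adds two ball-tracking outputs (x, y) supervised during the
  visible epoch only.
* ``Vis&Occ`` — the two tracking outputs are supervised across the whole
  trial (one common subspace for both epochs).
* ``Vis+Occ`` — four tracking outputs: one (x, y) pair supervised during
  the visible epoch and a separate pair during occlusion.

Inputs are a coordinate vector per simulator timestep (41.66 ms): the
ball position while visible (zeroed under occlusion), epoch flags, and
normalized elapsed time. Training is full-batch Adam on the class's
masked mean-squared error, implemented in numpy with exact
backpropagation through time (gradients are verified against numerical
differentiation in the test suite).

The simulation index (SI) measures how explicitly a network represents
the occluded ball: the mean absolute error of a condition-wise
cross-validated linear regression from hidden states to the true ball
position over occluded timesteps, sign-flipped so that higher SI means
more simulation capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .task import (DEFAULT_DT_MS, FrameGeometry, TaskCondition,
                   Trajectory, endpoint_error_and_chance,
                   simulate_trajectory)
from .synth import BinGrid

CLASSES = ("Intercept", "Vis", "Vis&Occ", "Vis+Occ")
N_OUTPUTS = {"Intercept": 1, "Vis": 3, "Vis&Occ": 3, "Vis+Occ": 5}
N_INPUTS = 5
POS_SCALE = 10.0  # positions are fed and supervised in units of half-width


@dataclass
class RnnSpec:
    cls: str = "Vis&Occ"
    hidden: int = 48
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown class {self.cls!r}; valid: {CLASSES}")

    @property
    def n_outputs(self) -> int:
        return N_OUTPUTS[self.cls]


@dataclass
class TrainingTargets:
    """Per-condition padded targets and loss masks.

    ``target``/``mask`` are (T, n_outputs); channel 0 is the paddle head
    (mask non-zero at exactly two samples), the rest are tracking heads.
    """

    target: np.ndarray
    mask: np.ndarray
    n_steps: int
    n_vis_steps: int


@dataclass
class GRUModel:
    spec: RnnSpec
    params: dict               # Wz,Uz,bz,Wr,Ur,br,Wh,Uh,bh,Wo,bo

    def copy(self) -> "GRUModel":
        return GRUModel(self.spec, {k: v.copy() for k, v in self.params.items()})


def build_rnn(spec: RnnSpec) -> GRUModel:
    """Gated recurrent network with per-class linear output heads.

    Output heads are separate rows of one readout matrix, so heads with no
    loss term receive zero gradient and stay at their initialization.
    """
    rng = np.random.default_rng(spec.seed)
    H, I, O = spec.hidden, N_INPUTS, spec.n_outputs
    def w(shape, scale):
        return rng.standard_normal(shape) * scale
    p = {}
    for gate in ("z", "r", "h"):
        p[f"W{gate}"] = w((H, I), 1.0 / np.sqrt(I))
        p[f"U{gate}"] = w((H, H), 1.0 / np.sqrt(H))
        p[f"b{gate}"] = np.zeros(H)
    p["bz"] -= 1.0  # open update gate at init (slow dynamics)
    p["Wo"] = w((O, H), 1.0 / np.sqrt(H))
    p["bo"] = np.zeros(O)
    return GRUModel(spec=spec, params=p)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def rnn_inputs(cond: TaskCondition, traj: Trajectory,
               dt_ms: float = DEFAULT_DT_MS) -> np.ndarray:
    """(T, 5) input sequence: masked ball x, y, epoch flags, time."""
    n_vis = int(round(cond.t_vis_ms / dt_ms))
    n_occ = int(round(cond.t_occ_ms / dt_ms))
    T = n_vis + n_occ
    t = (np.arange(T) + 0.5) * dt_ms
    bx = np.interp(t, traj.times, traj.ball_x) / POS_SCALE
    by = np.interp(t, traj.times, traj.ball_y) / POS_SCALE
    vis = (np.arange(T) < n_vis).astype(float)
    u = np.column_stack([bx * vis, by * vis, vis, 1.0 - vis,
                         np.arange(T) / 90.0])
    return u


def make_training_targets(cond: TaskCondition, traj: Trajectory, cls: str,
                          dt_ms: float = DEFAULT_DT_MS) -> TrainingTargets:
    """Targets and loss masks implementing the four class definitions."""
    if cls not in CLASSES:
        raise ValueError(f"unknown class {cls!r}; valid: {CLASSES}")
    n_vis = int(round(cond.t_vis_ms / dt_ms))
    n_occ = int(round(cond.t_occ_ms / dt_ms))
    T = n_vis + n_occ
    t = (np.arange(T) + 0.5) * dt_ms
    bx = np.interp(t, traj.times, traj.ball_x) / POS_SCALE
    by = np.interp(t, traj.times, traj.ball_y) / POS_SCALE
    O = N_OUTPUTS[cls]
    target = np.zeros((T, O))
    mask = np.zeros((T, O))
    # paddle head: exactly two supervised samples
    target[0, 0] = 0.0
    target[T - 1, 0] = cond.yf / POS_SCALE
    mask[0, 0] = 1.0
    mask[T - 1, 0] = 1.0
    vis = np.arange(T) < n_vis
    if cls == "Vis":
        target[:, 1], target[:, 2] = bx, by
        mask[vis, 1] = mask[vis, 2] = 1.0
    elif cls == "Vis&Occ":
        target[:, 1], target[:, 2] = bx, by
        mask[:, 1] = mask[:, 2] = 1.0
    elif cls == "Vis+Occ":
        target[:, 1], target[:, 2] = bx, by
        target[:, 3], target[:, 4] = bx, by
        mask[vis, 1] = mask[vis, 2] = 1.0
        mask[~vis, 3] = mask[~vis, 4] = 1.0
    return TrainingTargets(target=target, mask=mask, n_steps=T,
                           n_vis_steps=n_vis)


def _pad_batch(conds, trajs, cls, dt_ms):
    tt = [make_training_targets(c, tr, cls, dt_ms)
          for c, tr in zip(conds, trajs)]
    inputs = [rnn_inputs(c, tr, dt_ms) for c, tr in zip(conds, trajs)]
    T = max(t.n_steps for t in tt)
    N = len(conds)
    O = N_OUTPUTS[cls]
    X = np.zeros((T, N, N_INPUTS))
    Y = np.zeros((T, N, O))
    M = np.zeros((T, N, O))
    step_mask = np.zeros((T, N), dtype=bool)
    for i, (u, t) in enumerate(zip(inputs, tt)):
        X[:t.n_steps, i] = u
        Y[:t.n_steps, i] = t.target
        M[:t.n_steps, i] = t.mask
        step_mask[:t.n_steps, i] = True
    return X, Y, M, step_mask, tt


def forward(model: GRUModel, X: np.ndarray, step_mask: np.ndarray | None = None,
            cache: bool = False):
    """Run the GRU over a padded batch; returns hidden states and outputs.

    ``X`` is (T, N, I). Hidden states are frozen on padded steps so padded
    tails do not corrupt anything downstream.
    """
    p = model.params
    T, N, _ = X.shape
    H = model.spec.hidden
    h = np.zeros((N, H))
    hs = np.zeros((T, N, H))
    saved = [] if cache else None
    for t in range(T):
        x = X[t]
        z = _sigmoid(x @ p["Wz"].T + h @ p["Uz"].T + p["bz"])
        r = _sigmoid(x @ p["Wr"].T + h @ p["Ur"].T + p["br"])
        rh = r * h
        hb = np.tanh(x @ p["Wh"].T + rh @ p["Uh"].T + p["bh"])
        h_new = (1.0 - z) * h + z * hb
        if step_mask is not None:
            live = step_mask[t][:, None]
            h_new = np.where(live, h_new, h)
        if cache:
            saved.append((h.copy(), z, r, rh, hb))
        h = h_new
        hs[t] = h
    out = hs @ p["Wo"].T + p["bo"]
    return (hs, out, saved) if cache else (hs, out)


def loss_weights(M: np.ndarray) -> np.ndarray:
    """Per-channel normalized loss weights.

    Each output channel's masked MSE is averaged over its own supervised
    samples and the channels are weighted equally, so the two-sample paddle
    term is not diluted by the dense tracking terms.
    """
    n_per_chan = M.sum(axis=(0, 1))           # (O,)
    active = n_per_chan > 0
    W = M / np.where(active, n_per_chan, 1.0)[None, None, :]
    return W / max(active.sum(), 1)


def _backward(model: GRUModel, X, Y, W, step_mask, hs, out, saved):
    """Exact BPTT gradients of the weighted MSE loss."""
    p = model.params
    T, N, H = hs.shape
    dout = 2.0 * W * (out - Y)                # (T, N, O)
    g = {k: np.zeros_like(v) for k, v in p.items()}
    g["Wo"] = np.einsum("tno,tnh->oh", dout, hs)
    g["bo"] = dout.sum(axis=(0, 1))
    dh_next = np.zeros((N, H))
    for t in range(T - 1, -1, -1):
        h_prev, z, r, rh, hb = saved[t]
        dh = dh_next + dout[t] @ p["Wo"]
        if step_mask is not None:
            live = step_mask[t][:, None]
            dh_frozen = np.where(live, 0.0, dh)
            dh = np.where(live, dh, 0.0)
        else:
            dh_frozen = 0.0
        dz = dh * (hb - h_prev) * z * (1.0 - z)
        dhb = dh * z * (1.0 - hb ** 2)
        drh = dhb @ p["Uh"]
        dr = drh * h_prev * r * (1.0 - r)
        dh_prev = (dh * (1.0 - z) + drh * r
                   + dz @ p["Uz"] + dr @ p["Ur"])
        x = X[t]
        g["Wz"] += dz.T @ x; g["Uz"] += dz.T @ h_prev; g["bz"] += dz.sum(0)
        g["Wr"] += dr.T @ x; g["Ur"] += dr.T @ h_prev; g["br"] += dr.sum(0)
        g["Wh"] += dhb.T @ x; g["Uh"] += dhb.T @ rh; g["bh"] += dhb.sum(0)
        dh_next = dh_prev + dh_frozen
    return g


def masked_loss(out, Y, M) -> float:
    """Channel-balanced masked MSE (weights from :func:`loss_weights`)."""
    return float(np.sum(loss_weights(M) * (out - Y) ** 2))


def train_rnn(model: GRUModel, conds: list[TaskCondition],
              geom: FrameGeometry | None = None, n_iters: int = 500,
              lr: float = 5e-3, dt_ms: float = DEFAULT_DT_MS,
              seed: int = 0, clip: float = 5.0) -> dict:
    """Full-batch Adam on the class's masked MSE; returns the loss curve.

    Aborts with a RuntimeError if the loss goes non-finite (logging the
    offending step).
    """
    geom = geom or FrameGeometry()
    trajs = [simulate_trajectory(c, geom, dt_ms) for c in conds]
    X, Y, M, step_mask, _ = _pad_batch(conds, trajs, model.spec.cls, dt_ms)
    W = loss_weights(M)
    p = model.params
    m1 = {k: np.zeros_like(v) for k, v in p.items()}
    m2 = {k: np.zeros_like(v) for k, v in p.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    losses = np.empty(n_iters)
    for it in range(n_iters):
        hs, out, saved = forward(model, X, step_mask, cache=True)
        loss = masked_loss(out, Y, M)
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged at iteration {it}")
        losses[it] = loss
        g = _backward(model, X, Y, W, step_mask, hs, out, saved)
        norm = np.sqrt(sum(float(np.sum(v ** 2)) for v in g.values()))
        if norm > clip:
            g = {k: v * (clip / norm) for k, v in g.items()}
        for k in p:
            m1[k] = b1 * m1[k] + (1 - b1) * g[k]
            m2[k] = b2 * m2[k] + (1 - b2) * g[k] ** 2
            mhat = m1[k] / (1 - b1 ** (it + 1))
            vhat = m2[k] / (1 - b2 ** (it + 1))
            p[k] -= lr * mhat / (np.sqrt(vhat) + eps)
    return {"loss": losses}


def hidden_states(model: GRUModel, conds: list[TaskCondition],
                  geom: FrameGeometry | None = None,
                  dt_ms: float = DEFAULT_DT_MS):
    """Hidden-state trajectories plus per-condition step bookkeeping."""
    geom = geom or FrameGeometry()
    trajs = [simulate_trajectory(c, geom, dt_ms) for c in conds]
    X, Y, M, step_mask, tt = _pad_batch(conds, trajs, model.spec.cls, dt_ms)
    hs, out = forward(model, X, step_mask)
    n_steps = np.array([t.n_steps for t in tt])
    n_vis = np.array([t.n_vis_steps for t in tt])
    return hs, out, n_steps, n_vis, trajs


@dataclass
class SimulationIndexResult:
    mae_deg: float
    si: float                  # = -mae_deg
    per_fold_mae: np.ndarray
    null_mae: np.ndarray       # shuffled-target MAEs (empty if not requested)


def simulation_index(model: GRUModel, conds: list[TaskCondition],
                     n_folds: int = 5, seed: int = 0,
                     geom: FrameGeometry | None = None,
                     n_shuffles: int = 0,
                     states: np.ndarray | None = None) -> SimulationIndexResult:
    """Cross-validated linear readout error of the occluded ball position.

    Hidden states are regressed onto the true ball (x, y) with
    condition-grouped k-fold cross-validation; the MAE over occluded
    timesteps of held-out conditions is the (negated) simulation index.
    ``states`` overrides the model's own hidden states (same layout) —
    used to test invariance to invertible linear mixing.
    """
    if len(conds) < n_folds:
        raise ValueError(f"need >= {n_folds} conditions to split")
    hs, _, n_steps, n_vis, trajs = hidden_states(model, conds, geom)
    if states is not None:
        hs = states
    rows, targ, group = [], [], []
    for i, (tr, T, nv) in enumerate(zip(trajs, n_steps, n_vis)):
        t = (np.arange(T) + 0.5) * DEFAULT_DT_MS
        bx = np.interp(t, tr.times, tr.ball_x)
        by = np.interp(t, tr.times, tr.ball_y)
        occ = np.arange(T) >= nv
        rows.append(hs[np.where(occ)[0], i])
        targ.append(np.column_stack([bx[occ], by[occ]]))
        group.append(np.full(occ.sum(), i))
    H = np.vstack(rows)
    Yb = np.vstack(targ)
    G = np.concatenate(group)

    def cv_mae(Y):
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(conds))
        folds = np.array_split(order, n_folds)
        maes = []
        for fold in folds:
            te = np.isin(G, fold)
            A = np.column_stack([np.ones((~te).sum()), H[~te]])
            beta, *_ = np.linalg.lstsq(A, Y[~te], rcond=None)
            pred = np.column_stack([np.ones(te.sum()), H[te]]) @ beta
            maes.append(np.mean(np.abs(Y[te] - pred)))
        return np.array(maes)

    per_fold = cv_mae(Yb)
    null = np.empty(n_shuffles)
    rng = np.random.default_rng(seed + 1)
    for s in range(n_shuffles):
        # scramble the condition-to-trajectory assignment of the targets
        perm = rng.permutation(len(conds))
        Yp = np.empty_like(Yb)
        for i in range(len(conds)):
            src = Yb[G == perm[i]]
            dst = np.where(G == i)[0]
            k = min(len(src), len(dst))
            Yp[dst[:k]] = src[:k]
            if len(dst) > k:      # pad with the source endpoint
                Yp[dst[k:]] = src[-1]
        null[s] = cv_mae(Yp).mean()
    mae = float(per_fold.mean())
    return SimulationIndexResult(mae_deg=mae, si=-mae, per_fold_mae=per_fold,
                                 null_mae=null)


def rnn_task_performance(model: GRUModel, conds: list[TaskCondition],
                         geom: FrameGeometry | None = None,
                         n_shuffles: int = 1000, seed: int = 0) -> dict:
    """Mean absolute endpoint error of the paddle head, plus chance.

    The paddle output at the interception timestep (rescaled to degrees)
    is taken as the final paddle position.
    """
    hs, out, n_steps, _, _ = hidden_states(model, conds, geom)
    paddle_final = np.array([out[T - 1, i, 0] for i, T in enumerate(n_steps)])
    paddle_final *= POS_SCALE
    yf = np.array([c.yf for c in conds])
    err, chance = endpoint_error_and_chance(paddle_final, yf,
                                            n_shuffles=n_shuffles, seed=seed)
    return {"mae_deg": err, "chance_deg": chance, "paddle_final": paddle_final}


def hidden_to_bin_grid(model: GRUModel, conds: list[TaskCondition],
                       grid: BinGrid, geom: FrameGeometry | None = None
                       ) -> np.ndarray:
    """Hidden states resampled to the neural 50-ms analysis grid.

    Returns (H, C, max_bins) with NaN padding — the same container layout
    the consistency module uses for neural tensors.
    """
    hs, _, n_steps, _, _ = hidden_states(model, conds, geom)
    H = model.spec.hidden
    out = np.full((H, grid.n_conditions, grid.max_bins), np.nan)
    for c in range(grid.n_conditions):
        T = n_steps[c]
        t_rnn = (np.arange(T) + 0.5) * DEFAULT_DT_MS
        centers = grid.bin_centers(c)
        for hdim in range(H):
            out[hdim, c, :grid.n_bins[c]] = np.interp(
                centers, t_rnn, hs[:T, c, hdim])
    return out
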