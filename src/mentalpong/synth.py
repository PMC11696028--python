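"""Synthetic behavior and neural data with known ground truth.

This is the data stage of the pipeline: it emulates the structure of the
recorded dataset (eye traces, paddle/joystick traces, and a Poisson
pseudo-population of spiking units over 79 task conditions) from a known
generative model, so that every downstream analysis can be validated
against planted structure.

Generative model for the neural data: each condition has a set of latent
time courses on the 50-ms analysis bin grid (ball position, eye position,
hand variables, a time ramp, event transients, and the trial's endpoint);
each unit mixes all latents through a dense random loading vector (mixed
selectivity) passed through a softplus link, and emits independent Poisson
spike counts per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task import (FrameGeometry, PaddleTrace, TaskCondition, Trajectory,
                   PADDLE_SPEED_DEG_PER_MS, REFRESH_MS, joystick_state,
                   paddle_update, sample_conditions, simulate_trajectory)

LATENT_NAMES = ("ball_x", "ball_y", "eye_x", "eye_y", "paddle_y", "joystick",
                "time_ramp", "start_transient", "occ_transient", "endpoint_yf")

LATENT_GROUPS = {
    "ball": (0, 1),
    "eye": (2, 3),
    "hand": (4, 5),
    "time": (6,),
    "event": (7, 8),
    "endpoint": (9,),
}


@dataclass(frozen=True)
class BinGrid:
    """Per-condition analysis bin grid (variable trial lengths, NaN-padded).

    ``n_bins[c]`` bins of ``bin_ms`` cover condition c from trial start; a
    bin belongs to the visible epoch iff its center falls before occlusion.
    """

    bin_ms: float
    n_bins: np.ndarray      # (C,) int
    n_vis: np.ndarray       # (C,) int — visible-epoch bins per condition

    @property
    def n_conditions(self) -> int:
        return len(self.n_bins)

    @property
    def max_bins(self) -> int:
        return int(self.n_bins.max())

    def bin_centers(self, c: int) -> np.ndarray:
        return (np.arange(self.n_bins[c]) + 0.5) * self.bin_ms

    def valid_mask(self) -> np.ndarray:
        """(C, max_bins) bool: bin exists for this condition."""
        b = np.arange(self.max_bins)[None, :]
        return b < self.n_bins[:, None]

    def visible_mask(self) -> np.ndarray:
        b = np.arange(self.max_bins)[None, :]
        return (b < self.n_vis[:, None]) & self.valid_mask()

    def occluded_mask(self) -> np.ndarray:
        return self.valid_mask() & ~self.visible_mask()


def make_grid(conds: list[TaskCondition], bin_ms: float = 50.0) -> BinGrid:
    n_bins = np.array([int(np.floor(c.duration_ms / bin_ms + 1e-9))
                       for c in conds])
    n_vis = np.array([
        int(np.sum((np.arange(nb) + 0.5) * bin_ms < c.t_vis_ms))
        for nb, c in zip(n_bins, conds)
    ])
    return BinGrid(bin_ms=bin_ms, n_bins=n_bins, n_vis=n_vis)


@dataclass
class BehaviorTraces:
    """One condition's (trial-averaged) eye and hand traces.

    Eye is sampled every 1 ms; paddle and joystick on the 16.6-ms refresh.
    """

    eye_times: np.ndarray
    eye_x: np.ndarray
    eye_y: np.ndarray
    paddle: PaddleTrace | None = None


@dataclass
class GroundTruthLatents:
    """Latent time courses and the unit mixing that generated the rates."""

    latents: np.ndarray        # (n_latents, C, max_bins), z-scored, NaN-padded
    loading: np.ndarray        # (n_units, n_latents)
    baseline_hz: np.ndarray    # (n_units,)
    gain: float
    grid: BinGrid
    latent_names: tuple = LATENT_NAMES
    channels: dict | None = None  # raw per-bin behavioral channels (C, B)

    def rates_hz(self) -> np.ndarray:
        """Noiseless firing rates, (n_units, C, max_bins), NaN-padded.

        The latent drive is scaled by each unit's baseline so that ``gain``
        is a fractional modulation depth (gain = 0.5 means the latent drive
        swings the softplus input by ~50% of baseline per latent-SD).
        """
        drive = np.einsum("ul,lcb->ucb", self.loading, self.latents)
        base = np.log(np.expm1(self.baseline_hz))[:, None, None]
        x = self.gain * self.baseline_hz[:, None, None] * drive + base
        with np.errstate(invalid="ignore", over="ignore"):
            rates = np.logaddexp(0.0, x)  # softplus, overflow-safe
        if np.nanmax(rates) > 1e4:
            u = int(np.unravel_index(np.nanargmax(rates), rates.shape)[0])
            raise FloatingPointError(
                f"rate overflow for unit {u}: softplus link exceeded 10 kHz")
        return rates


@dataclass
class SpikeDataset:
    """Per-trial spike counts on the analysis grid.

    ``counts[u, r, c, b]`` is the spike count of unit u on trial r of
    condition c in bin b (NaN outside the condition's grid or in missing
    unit x condition cells).
    """

    counts: np.ndarray         # (n_units, n_trials, C, max_bins)
    grid: BinGrid
    missing: np.ndarray        # (n_units, C) bool
    trial_table: pd.DataFrame  # columns: trial, condition_id, success
    ground_truth: GroundTruthLatents | None = None

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_trials(self) -> int:
        return self.counts.shape[1]


def gen_eye_trace(traj: Trajectory, lag_ms: float = 150.0,
                  noise_sd: float = 0.5, saccade_rate_hz: float = 1.0,
                  seed: int = 0, paddle_y: float = 0.0) -> BehaviorTraces:
    """Eye trace: lagged ball pursuit with noise and sporadic saccades.

    The eye follows the ball delayed by ``lag_ms`` (holding the initial ball
    position for the first ``lag_ms``), with additive smooth Gaussian
    jitter. Saccadic excursions occur at Poisson times and displace gaze
    toward the paddle or the ball-paddle midpoint for ~100 ms.
    """
    if lag_ms < 0:
        raise ValueError("lag must be non-negative")
    T = traj.duration_ms
    if lag_ms > T:
        raise ValueError(f"lag {lag_ms} ms exceeds trial duration {T} ms")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, np.floor(T) + 1.0)
    bx = np.interp(np.maximum(t - lag_ms, 0.0), traj.times, traj.ball_x)
    by = np.interp(np.maximum(t - lag_ms, 0.0), traj.times, traj.ball_y)
    if noise_sd > 0:
        # slow jitter: smooth white noise with ~100-ms correlation length
        def smooth_noise():
            w = rng.standard_normal(len(t))
            k = np.exp(-0.5 * (np.arange(-300, 301) / 100.0) ** 2)
            k /= k.sum()
            s = np.convolve(w, k, mode="same")
            return s / max(s.std(), 1e-12) * noise_sd
        bx = bx + smooth_noise()
        by = by + smooth_noise()
    if saccade_rate_hz > 0:
        n_sac = rng.poisson(saccade_rate_hz * T / 1000.0)
        sac_times = np.sort(rng.uniform(0, T, n_sac))
        for i, ts in enumerate(sac_times):
            sel = (t >= ts) & (t < ts + 100.0)
            if not sel.any():
                continue
            # alternate targets: paddle, then ball-paddle midpoint
            tx = traj.ball_x[-1] if i % 2 == 0 else 0.5 * (np.interp(ts, t, bx)
                                                           + traj.ball_x[-1])
            ty = paddle_y if i % 2 == 0 else 0.5 * (np.interp(ts, t, by)
                                                    + paddle_y)
            bx[sel] += (tx - bx[sel]) * 0.8
            by[sel] += (ty - by[sel]) * 0.8
    return BehaviorTraces(eye_times=t, eye_x=bx, eye_y=by)


def gen_paddle_trace(cond: TaskCondition, movement_delay_ms: float = 0.0,
                     seed: int = 0, geom: FrameGeometry | None = None,
                     jitter_sd_v: float = 0.0) -> PaddleTrace:
    """Bang-bang joystick controller driving the paddle toward yf.

    After ``movement_delay_ms`` the controller emits up/down voltages
    (down: 1 V, neutral: 2.5 V, up: 4 V) that move the paddle toward the
    condition's endpoint at the 0.01 deg/ms speed limit; once within one
    refresh-step of the target it goes neutral.
    """
    if movement_delay_ms < 0:
        raise ValueError("movement delay must be non-negative")
    geom = geom or FrameGeometry()
    if np.isnan(cond.yf):
        raise ValueError("condition has no endpoint; run analyze_condition")
    rng = np.random.default_rng(seed)
    T = cond.duration_ms
    times = np.arange(0.0, T, REFRESH_MS)
    step = PADDLE_SPEED_DEG_PER_MS * REFRESH_MS
    paddle = np.empty_like(times)
    volts = np.empty_like(times)
    y = 0.0
    for i, t in enumerate(times):
        if t < movement_delay_ms or abs(cond.yf - y) <= step:
            v = 2.5
        elif cond.yf > y:
            v = 4.0
        else:
            v = 1.0
        if jitter_sd_v > 0:
            v = float(np.clip(v + rng.normal(0, jitter_sd_v), 0.0, 5.0))
        paddle[i] = y
        volts[i] = v
        y = paddle_update(v, y, REFRESH_MS, geom)
    triggered = np.zeros(len(times), dtype=bool)
    nonneutral = np.array([joystick_state(v) != "neutral" for v in volts])
    if nonneutral.any():
        triggered[np.argmax(nonneutral):] = True
    return PaddleTrace(times=times, paddle_y=paddle, joystick_voltage=volts,
                       triggered=triggered)


def _bin_series(t_src: np.ndarray, y_src: np.ndarray, centers: np.ndarray):
    return np.interp(centers, t_src, y_src)


def build_latents(conds: list[TaskCondition], grid: BinGrid,
                  geom: FrameGeometry | None = None, seed: int = 0,
                  eye_lag_ms: float = 150.0, eye_noise_sd: float = 0.5,
                  saccade_rate_hz: float = 1.0,
                  paddle_delay_frac: float = 0.8,
                  ) -> tuple[np.ndarray, dict]:
    """Latent time courses per condition on the bin grid, z-scored.

    Returns the (n_latents, C, max_bins) array and a dict of the per-bin
    behavioral channels (raw units) used to build it, keyed by name —
    downstream encoding designs are built from the same channels.
    """
    geom = geom or FrameGeometry()
    C, B = grid.n_conditions, grid.max_bins
    raw = {k: np.full((C, B), np.nan) for k in
           ("ball_x", "ball_y", "ball_dx", "ball_dy", "eye_x", "eye_y",
            "paddle_y", "joystick", "time_ramp", "start_transient",
            "occ_transient", "endpoint_yf")}
    rng = np.random.default_rng(seed)
    for c, cond in enumerate(conds):
        traj = simulate_trajectory(cond, geom)
        centers = grid.bin_centers(c)
        nb = grid.n_bins[c]
        delay = paddle_delay_frac * cond.t_vis_ms
        eye = gen_eye_trace(traj, eye_lag_ms, eye_noise_sd, saccade_rate_hz,
                            seed=int(rng.integers(2**31)))
        pad = gen_paddle_trace(cond, movement_delay_ms=delay,
                               seed=int(rng.integers(2**31)), geom=geom)
        raw["ball_x"][c, :nb] = _bin_series(traj.times, traj.ball_x, centers)
        raw["ball_y"][c, :nb] = _bin_series(traj.times, traj.ball_y, centers)
        raw["ball_dx"][c, :nb] = cond.dx0
        # vertical velocity flips sign at each bounce
        sgn = np.ones(nb)
        for tb in traj.bounce_times:
            sgn[centers > tb] *= -1.0
        raw["ball_dy"][c, :nb] = cond.dy0 * sgn
        raw["eye_x"][c, :nb] = _bin_series(eye.eye_times, eye.eye_x, centers)
        raw["eye_y"][c, :nb] = _bin_series(eye.eye_times, eye.eye_y, centers)
        raw["paddle_y"][c, :nb] = _bin_series(pad.times, pad.paddle_y, centers)
        raw["joystick"][c, :nb] = _bin_series(pad.times, pad.joystick_voltage,
                                              centers)
        raw["time_ramp"][c, :nb] = centers / cond.duration_ms
        raw["start_transient"][c, :nb] = np.exp(-centers / 200.0)
        raw["occ_transient"][c, :nb] = np.where(
            centers >= cond.t_vis_ms,
            np.exp(-(centers - cond.t_vis_ms) / 200.0), 0.0)
        raw["endpoint_yf"][c, :nb] = cond.yf
    lat = np.stack([raw[name] for name in LATENT_NAMES])
    # z-score each latent over valid cells so loading scales are comparable
    for i in range(lat.shape[0]):
        v = lat[i][np.isfinite(lat[i])]
        sd = v.std()
        lat[i] = (lat[i] - v.mean()) / (sd if sd > 1e-12 else 1.0)
    return lat, raw


DEFAULT_LOADING_SCALES = {"ball": 1.0, "eye": 1.0, "hand": 1.0,
                          "time": 1.0, "event": 1.0, "endpoint": 0.5}


def make_ground_truth(conds: list[TaskCondition], grid: BinGrid,
                      n_units: int = 200, gain: float = 0.5,
                      loading_scales: dict | None = None,
                      baseline_range_hz: tuple = (3.0, 20.0),
                      geom: FrameGeometry | None = None, seed: int = 0,
                      **latent_kwargs) -> GroundTruthLatents:
    """Dense random loadings over all latent groups (mixed selectivity)."""
    scales = {**DEFAULT_LOADING_SCALES, **(loading_scales or {})}
    lat, raw = build_latents(conds, grid, geom=geom, seed=seed, **latent_kwargs)
    rng = np.random.default_rng(seed + 1)
    L = rng.standard_normal((n_units, len(LATENT_NAMES)))
    L /= np.sqrt(len(LATENT_NAMES))
    for group, idx in LATENT_GROUPS.items():
        L[:, list(idx)] *= scales[group]
    baseline = rng.uniform(*baseline_range_hz, size=n_units)
    return GroundTruthLatents(latents=lat, loading=L, baseline_hz=baseline,
                              gain=gain, grid=grid, channels=raw)


def gen_population_spikes(latents: GroundTruthLatents,
                          n_trials_per_cond: int = 10,
                          missing_frac: float = 0.0,
                          seed: int = 0) -> SpikeDataset:
    """Poisson spike counts per trial per analysis bin.

    Counts in a bin are Poisson with mean rate x bin width; independent
    across trials, units, and bins. A random ``missing_frac`` of
    unit x condition cells is marked missing (emulating units not recorded
    for every condition).
    """
    if n_trials_per_cond < 2:
        raise ValueError("need >= 2 trials per condition for split-half work")
    rng = np.random.default_rng(seed)
    rates = latents.rates_hz()
    U, C, B = rates.shape
    mean_counts = rates * latents.grid.bin_ms / 1000.0
    counts = np.full((U, n_trials_per_cond, C, B), np.nan)
    valid = latents.grid.valid_mask()
    lam = np.where(np.isfinite(mean_counts), mean_counts, 0.0)
    draws = rng.poisson(lam[:, None, :, :].repeat(n_trials_per_cond, axis=1))
    counts[:, :, valid] = draws[:, :, valid].astype(float)
    missing = rng.random((U, C)) < missing_frac
    counts[np.where(missing)[0], :, np.where(missing)[1], :] = np.nan
    trials = pd.DataFrame({
        "trial": np.tile(np.arange(n_trials_per_cond), C),
        "condition_id": np.repeat(np.arange(C), n_trials_per_cond),
        "success": True,
    })
    return SpikeDataset(counts=counts, grid=latents.grid, missing=missing,
                        trial_table=trials, ground_truth=latents)


def tracking_error_curves(traces: list[BehaviorTraces],
                          trajs: list[Trajectory],
                          grid: BinGrid) -> dict:
    """Eye-ball and hand-target tracking error vs. time.

    Eye error is the Euclidean distance between gaze and the instantaneous
    ball position; hand error is |paddle - yf|. Errors are computed per
    condition on the bin grid, then summarized as mean +/- SEM across
    conditions per bin.
    """
    C, B = grid.n_conditions, grid.max_bins
    eye_err = np.full((C, B), np.nan)
    hand_err = np.full((C, B), np.nan)
    for c, (tr, traj) in enumerate(zip(traces, trajs)):
        centers = grid.bin_centers(c)
        if centers[-1] > tr.eye_times[-1] + grid.bin_ms:
            raise ValueError(
                f"condition {c}: behavior trace grid ends at "
                f"{tr.eye_times[-1]} ms but bins extend to {centers[-1]} ms")
        nb = grid.n_bins[c]
        ex = _bin_series(tr.eye_times, tr.eye_x, centers)
        ey = _bin_series(tr.eye_times, tr.eye_y, centers)
        bx = _bin_series(traj.times, traj.ball_x, centers)
        by = _bin_series(traj.times, traj.ball_y, centers)
        eye_err[c, :nb] = np.hypot(ex - bx, ey - by)
        if tr.paddle is not None:
            py = _bin_series(tr.paddle.times, tr.paddle.paddle_y, centers)
            hand_err[c, :nb] = np.abs(py - traj.yf)
    import warnings as _warnings

    out = {}
    for name, err in (("eye", eye_err), ("hand", hand_err)):
        n = np.sum(np.isfinite(err), axis=0)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(err, axis=0)
            sem = np.nanstd(err, axis=0) / np.sqrt(np.maximum(n, 1))
        out[name] = {"mean": mean, "sem": sem, "n": n}
    return out


def generate_dataset(n_conditions: int = 79, n_units: int = 200,
                     n_trials: int = 10, missing_frac: float = 0.01,
                     bin_ms: float = 50.0, seed: int = 0,
                     geom: FrameGeometry | None = None,
                     loading_scales: dict | None = None,
                     gain: float = 0.5):
    """End-to-end synthetic session: conditions, grid, ground truth, spikes.

    Defaults mirror the study's scale where printed (79 conditions, 50-ms
    bins) and a desk-scale population (200 units, 10 trials/condition)
    elsewhere.
    """
    geom = geom or FrameGeometry()
    conds = sample_conditions(n_conditions, geom, seed=seed)
    grid = make_grid(conds, bin_ms)
    gt = make_ground_truth(conds, grid, n_units=n_units, gain=gain,
                           loading_scales=loading_scales, geom=geom,
                           seed=seed + 7)
    spikes = gen_population_spikes(gt, n_trials_per_cond=n_trials,
                                   missing_frac=missing_frac, seed=seed + 13)
    return conds, grid, gt, spikes
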