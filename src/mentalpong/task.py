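"""Mental-pong world: geometry, ball kinematics with reflecting walls,
condition sampling, paddle/joystick dynamics, and endpoint-error metrics.

The task frame is a square arena spanning 20 degrees of visual angle,
centered at the origin. A ball starts on the left at (x0, y0) with a
rightward velocity (dx0, dy0) in deg/s and moves at constant speed,
reflecting off the horizontal walls at y = +/-half_height. An occluder
covers the right portion of the frame, so the ball is visible only while
ball_x < occluder_left_x. The trial ends when the ball reaches the
interception line at x = +half_width; the ball's vertical position there
(yf) is the behavioral target for the paddle.

All positions are in degrees of visual angle, velocities in deg/s, and
times in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Simulator step implied by 15 timesteps = 624.9 ms.
DEFAULT_DT_MS = 624.9 / 15.0  # 41.66 ms

#: Allowed duration window for each of the visible and occluded epochs (ms),
#: i.e. [15, 45] simulator timesteps.
EPOCH_MS_MIN = 15 * DEFAULT_DT_MS
EPOCH_MS_MAX = 45 * DEFAULT_DT_MS

#: Parameter box for condition sampling: x0, y0 (deg) and dx0, dy0 (deg/s).
DEFAULT_RANGES = {
    "x0": (-8.0, 0.0),
    "y0": (-10.0, 10.0),
    "dx0": (6.25, 18.75),
    "dy0": (-18.75, 18.75),
}

#: Paddle speed limit: 0.17 deg per 16.6-ms screen refresh = 0.01 deg/ms.
PADDLE_SPEED_DEG_PER_MS = 0.01
REFRESH_MS = 16.6

#: Joystick voltage bands (volts): down [0, 2), neutral [2, 3], up (3, 5].
VOLT_DOWN_MAX = 2.0
VOLT_UP_MIN = 3.0


@dataclass(frozen=True)
class FrameGeometry:
    """Arena geometry. ``interception_x`` is fixed to the right edge."""

    half_width: float = 10.0
    half_height: float = 10.0
    occluder_left_x: float = 0.0

    @property
    def interception_x(self) -> float:
        return self.half_width

    def __post_init__(self) -> None:
        if not self.occluder_left_x < self.interception_x:
            raise ValueError(
                "occluder_left_x must lie left of the interception line "
                f"(got {self.occluder_left_x} >= {self.interception_x})"
            )


@dataclass
class TaskCondition:
    """One sampled mental-pong condition.

    ``t_vis_ms``, ``t_occ_ms``, ``n_bounce`` and ``yf`` are derived from the
    kinematics; the sampler fills them in via :func:`analyze_condition`.
    """

    x0: float
    y0: float
    dx0: float
    dy0: float
    t_vis_ms: float = float("nan")
    t_occ_ms: float = float("nan")
    n_bounce: int = -1
    yf: float = float("nan")
    condition_id: int = -1

    @property
    def duration_ms(self) -> float:
        return self.t_vis_ms + self.t_occ_ms


@dataclass
class Trajectory:
    """Time-resolved ball path on the simulator grid."""

    times: np.ndarray           # ms, includes t=0 and the interception time
    ball_x: np.ndarray          # deg, strictly increasing
    ball_y: np.ndarray          # deg, |y| <= half_height
    visible: np.ndarray         # bool, True while ball_x < occluder_left_x
    bounce_times: np.ndarray    # ms
    t_vis_ms: float = 0.0
    t_occ_ms: float = 0.0
    yf: float = 0.0

    @property
    def duration_ms(self) -> float:
        return float(self.times[-1])

    @property
    def n_bounce(self) -> int:
        return int(len(self.bounce_times))


@dataclass
class PaddleTrace:
    """Paddle position and joystick voltage on the 16.6-ms refresh grid."""

    times: np.ndarray
    paddle_y: np.ndarray
    joystick_voltage: np.ndarray
    triggered: np.ndarray  # bool, True from the first non-neutral voltage on


def _fold(z: np.ndarray | float, half_height: float):
    """Reflect an unfolded vertical coordinate into [-H, H].

    Free motion plus specular wall reflection is the triangle-wave folding
    of the straight-line coordinate, with period 4H.
    """
    h = half_height
    u = np.mod(np.asarray(z, dtype=float) + h, 4.0 * h)
    return np.where(u <= 2.0 * h, u - h, 3.0 * h - u)


def _bounce_times_ms(y0: float, dy0: float, duration_ms: float,
                     half_height: float) -> np.ndarray:
    """Exact wall-contact times for constant-velocity motion from y0."""
    if abs(dy0) < 1e-9:  # effectively horizontal: no wall contact
        return np.array([])
    v = dy0 / 1000.0  # deg/ms
    h = half_height
    times = []
    # unfolded coordinate crosses levels +/-h + 2hk in sequence
    k = 0
    while True:
        level = (h if v > 0 else -h) + 2.0 * h * k * np.sign(v)
        t = (level - y0) / v
        if t > duration_ms + 1e-9:
            break
        if t > 1e-9:
            times.append(t)
        k += 1
    return np.asarray(times)


def analyze_condition(cond: TaskCondition, geom: FrameGeometry) -> TaskCondition:
    """Fill the derived fields (epoch durations, bounce count, endpoint)."""
    if cond.dx0 <= 0:
        raise ValueError("ball must move rightward (dx0 > 0)")
    if abs(cond.y0) > geom.half_height:
        raise ValueError("y0 outside the frame")
    vx = cond.dx0 / 1000.0
    duration = (geom.interception_x - cond.x0) / vx
    t_vis = (geom.occluder_left_x - cond.x0) / vx
    t_vis = float(np.clip(t_vis, 0.0, duration))
    yf = float(_fold(cond.y0 + cond.dy0 / 1000.0 * duration, geom.half_height))
    n_b = len(_bounce_times_ms(cond.y0, cond.dy0, duration, geom.half_height))
    return replace(cond, t_vis_ms=t_vis, t_occ_ms=duration - t_vis,
                   n_bounce=n_b, yf=yf)


def simulate_trajectory(cond: TaskCondition, geom: FrameGeometry | None = None,
                        dt_ms: float = DEFAULT_DT_MS,
                        max_bounces: int | None = 1) -> Trajectory:
    """Simulate the ball path on a regular time grid.

    Wall reflections are resolved exactly (continuous-time folding of the
    straight-line path), not grid-snapped. The grid always includes t=0 and
    the exact interception time as the last sample.

    Raises ``ValueError`` if the path bounces more than ``max_bounces``
    times (pass ``max_bounces=None`` to disable the check).
    """
    geom = geom or FrameGeometry()
    if dt_ms <= 0:
        raise ValueError("dt_ms must be positive")
    if cond.dx0 <= 0:
        raise ValueError("ball must move rightward (dx0 > 0)")
    vx = cond.dx0 / 1000.0
    duration = (geom.interception_x - cond.x0) / vx
    bounces = _bounce_times_ms(cond.y0, cond.dy0, duration, geom.half_height)
    if max_bounces is not None and len(bounces) > max_bounces:
        raise ValueError(
            f"condition bounces {len(bounces)} times (> {max_bounces}); "
            "not a valid task condition"
        )
    n = int(np.floor(duration / dt_ms + 1e-9))
    times = np.arange(n + 1) * dt_ms
    if times[-1] < duration - 1e-9:
        times = np.append(times, duration)
    else:
        times[-1] = duration
    ball_x = cond.x0 + vx * times
    ball_y = np.asarray(_fold(cond.y0 + cond.dy0 / 1000.0 * times,
                              geom.half_height))
    visible = ball_x < geom.occluder_left_x
    t_vis = float(np.clip((geom.occluder_left_x - cond.x0) / vx, 0.0, duration))
    return Trajectory(times=times, ball_x=ball_x, ball_y=ball_y,
                      visible=visible, bounce_times=bounces,
                      t_vis_ms=t_vis, t_occ_ms=duration - t_vis,
                      yf=float(ball_y[-1]))


def simulate_trajectory_euler(cond: TaskCondition, geom: FrameGeometry | None = None,
                              dt_ms: float = 0.01) -> float:
    """Fine-step Euler integration with reflection; returns the endpoint yf.

    Independent oracle for the analytic folding used by
    :func:`simulate_trajectory` — deliberately simple and slow.
    """
    geom = geom or FrameGeometry()
    x, y = cond.x0, cond.y0
    vy = cond.dy0 / 1000.0
    vx = cond.dx0 / 1000.0
    h = geom.half_height
    while x < geom.interception_x:
        step = min(dt_ms, (geom.interception_x - x) / vx)
        x += vx * step
        y += vy * step
        if y > h:
            y = 2.0 * h - y
            vy = -vy
        elif y < -h:
            y = -2.0 * h - y
            vy = -vy
    return y


def euler_endpoints_batch(conds: list[TaskCondition],
                          geom: FrameGeometry | None = None,
                          dt_ms: float = 0.01) -> np.ndarray:
    """Fine-step Euler endpoints for many conditions, stepped in lockstep.

    Same reflect-on-overshoot scheme as :func:`simulate_trajectory_euler`
    but vectorized across conditions (each condition stops advancing once
    its ball reaches the interception line).
    """
    geom = geom or FrameGeometry()
    h = geom.half_height
    x = np.array([c.x0 for c in conds], dtype=float)
    y = np.array([c.y0 for c in conds], dtype=float)
    vx = np.array([c.dx0 for c in conds], dtype=float) / 1000.0
    vy = np.array([c.dy0 for c in conds], dtype=float) / 1000.0
    active = np.ones(len(conds), dtype=bool)
    while active.any():
        step = np.minimum(dt_ms, (geom.interception_x - x) / vx)
        step = np.where(active, step, 0.0)
        x += vx * step
        y += vy * step
        over = y > h
        y[over] = 2.0 * h - y[over]
        vy[over] = -vy[over]
        under = y < -h
        y[under] = -2.0 * h - y[under]
        vy[under] = -vy[under]
        active = x < geom.interception_x - 1e-12
    return y


def sample_conditions(n: int, geom: FrameGeometry | None = None,
                      ranges: dict | None = None, seed: int = 0,
                      max_attempts: int = 1_000_000) -> list[TaskCondition]:
    """Rejection-sample task conditions from the parameter box.

    A draw is accepted iff (1) the ball moves rightward, (2) the visible
    epoch and (3) the occluded epoch each last between 15 and 45 simulator
    timesteps (624.9-1874.7 ms), and (4) the path bounces at most once.
    """
    geom = geom or FrameGeometry()
    ranges = {**DEFAULT_RANGES, **(ranges or {})}
    rng = np.random.default_rng(seed)
    out: list[TaskCondition] = []
    stats = {"rightward": 0, "t_vis": 0, "t_occ": 0, "n_bounce": 0}
    attempts = 0
    while len(out) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"sampler failed: {len(out)}/{n} accepted in {attempts} draws; "
                f"rejections by constraint: {stats}"
            )
        attempts += 1
        draw = TaskCondition(
            x0=rng.uniform(*ranges["x0"]), y0=rng.uniform(*ranges["y0"]),
            dx0=rng.uniform(*ranges["dx0"]), dy0=rng.uniform(*ranges["dy0"]),
        )
        if draw.dx0 <= 0:
            stats["rightward"] += 1
            continue
        cond = analyze_condition(draw, geom)
        if not (EPOCH_MS_MIN - 1e-9 <= cond.t_vis_ms <= EPOCH_MS_MAX + 1e-9):
            stats["t_vis"] += 1
            continue
        if not (EPOCH_MS_MIN - 1e-9 <= cond.t_occ_ms <= EPOCH_MS_MAX + 1e-9):
            stats["t_occ"] += 1
            continue
        if cond.n_bounce > 1:
            stats["n_bounce"] += 1
            continue
        cond.condition_id = len(out)
        out.append(cond)
    return out


def joystick_state(voltage: float) -> str:
    """Classify a joystick voltage into up / down / neutral."""
    if not 0.0 <= voltage <= 5.0:
        raise ValueError(f"joystick voltage {voltage} outside [0, 5] V")
    if voltage > VOLT_UP_MIN:
        return "up"
    if voltage < VOLT_DOWN_MAX:
        return "down"
    return "neutral"


def paddle_update(voltage: float, paddle_y: float,
                  refresh_dt_ms: float = REFRESH_MS,
                  geom: FrameGeometry | None = None) -> float:
    """Advance the paddle one refresh given the joystick voltage.

    Up/down moves the paddle at the 0.01 deg/ms speed limit; neutral leaves
    it unchanged. The paddle is clipped to the frame.
    """
    geom = geom or FrameGeometry()
    state = joystick_state(voltage)
    step = PADDLE_SPEED_DEG_PER_MS * refresh_dt_ms
    if state == "up":
        paddle_y = paddle_y + step
    elif state == "down":
        paddle_y = paddle_y - step
    return float(np.clip(paddle_y, -geom.half_height, geom.half_height))


def endpoint_error_and_chance(paddle_final, yf, n_shuffles: int = 1000,
                              seed: int = 0) -> tuple[float, float]:
    """Mean absolute endpoint error and its shuffle chance level.

    Chance is the same statistic with the correct endpoints permuted across
    conditions, averaged over ``n_shuffles`` permutations.
    """
    paddle_final = np.asarray(paddle_final, dtype=float)
    yf = np.asarray(yf, dtype=float)
    if paddle_final.shape != yf.shape:
        raise ValueError("paddle_final and yf must be paired, equal-length")
    if paddle_final.size < 2:
        raise ValueError("chance level undefined with fewer than 2 conditions")
    err = float(np.mean(np.abs(paddle_final - yf)))
    rng = np.random.default_rng(seed)
    chance = float(np.mean([
        np.mean(np.abs(paddle_final - rng.permutation(yf)))
        for _ in range(n_shuffles)
    ]))
    return err, chance


def interception_success(paddle_final: float, yf: float,
                         paddle_half_height: float = 1.25) -> bool:
    """Reward bookkeeping: hit iff the endpoint lies within the half-paddle."""
    return abs(paddle_final - yf) <= paddle_half_height


# ---------------------------------------------------------------------------
# serialization

CONDITION_COLUMNS = ["condition_id", "x0", "y0", "dx0", "dy0",
                     "t_vis_ms", "t_occ_ms", "n_bounce", "yf"]


def conditions_to_frame(conds: list[TaskCondition]) -> pd.DataFrame:
    rows = [{c: getattr(cond, c) for c in CONDITION_COLUMNS} for cond in conds]
    return pd.DataFrame(rows, columns=CONDITION_COLUMNS)


def conditions_from_frame(df: pd.DataFrame) -> list[TaskCondition]:
    return [TaskCondition(**{c: (int(r[c]) if c in ("condition_id", "n_bounce")
                                 else float(r[c]))
                             for c in CONDITION_COLUMNS})
            for _, r in df.iterrows()]


def save_trajectories(path, conds: list[TaskCondition],
                      geom: FrameGeometry | None = None,
                      dt_ms: float = DEFAULT_DT_MS) -> None:
    """Write one HDF5 group per condition (times, ball_x, ball_y, visible)."""
    import h5py

    geom = geom or FrameGeometry()
    with h5py.File(path, "w") as f:
        f.attrs["dt_ms"] = dt_ms
        f.attrs["occluder_left_x"] = geom.occluder_left_x
        for cond in conds:
            traj = simulate_trajectory(cond, geom, dt_ms)
            g = f.create_group(f"condition_{cond.condition_id:03d}")
            g.create_dataset("times", data=traj.times)
            g.create_dataset("ball_x", data=traj.ball_x)
            g.create_dataset("ball_y", data=traj.ball_y)
            g.create_dataset("visible", data=traj.visible)
            g.attrs["yf"] = traj.yf
            g.attrs["n_bounce"] = traj.n_bounce
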