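"""Per-neuron encoding models and variance partitioning.

Each unit's binned response is regressed on 15 task regressors — six ball
variables (x, y, dx, dy, speed magnitude, direction angle), six eye
variables (same scheme), two hand variables (paddle position, joystick
voltage), and one bounce nuisance indicator — with an identity-link
Gaussian least-squares fit per epoch, a temporal-jitter search over
+/-300 ms, and 10-fold cross-validation grouped by condition.

Commonality analysis then splits the full model's explained variance into
the unique contributions of the ball, eye and hand categories and the
variance they share, via the seven nested model fits. The seven components
sum exactly to the full-model in-sample R^2; cross-validated components can
individually be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .synth import BinGrid

BALL_COLS = ["ball_x", "ball_y", "ball_dx", "ball_dy", "ball_speed",
             "ball_dir"]
EYE_COLS = ["eye_x", "eye_y", "eye_dx", "eye_dy", "eye_speed", "eye_dir"]
HAND_COLS = ["paddle_y", "joystick"]
NUISANCE_COLS = ["bounce"]
DESIGN_COLS = BALL_COLS + EYE_COLS + HAND_COLS + NUISANCE_COLS

CATEGORY = {"ball": BALL_COLS, "eye": EYE_COLS, "hand": HAND_COLS}

#: jitter search grid: -300..+300 ms inclusive in 50-ms steps (13 offsets,
#: 12 of them non-zero)
DEFAULT_JITTER_MS = tuple(np.arange(-300, 301, 50))


@dataclass
class EncodingDesign:
    """Row-per-(condition, bin) regressor matrix with epoch labels."""

    X: np.ndarray              # (n_rows, 15)
    condition: np.ndarray      # (n_rows,) condition index per row
    bin_index: np.ndarray      # (n_rows,) bin index within condition
    visible: np.ndarray        # (n_rows,) bool epoch label
    columns: tuple = tuple(DESIGN_COLS)


@dataclass
class GlmFit:
    coef: np.ndarray
    best_jitter_ms: float
    cv_r2: float               # out-of-fold, may be negative
    per_jitter_r2: dict


@dataclass
class VarianceComponents:
    """The 7 unique/common R^2 components and the 7 nested R^2 values."""

    nested_r2: dict            # keys: 'ball', 'eye', 'hand', 'ball+eye', ...
    components: dict           # keys: 'U_ball', ..., 'C_ball_eye_hand'

    @property
    def total(self) -> float:
        return self.nested_r2["ball+eye+hand"]


def _velocity(pos: np.ndarray, bin_ms: float, valid_len: int) -> np.ndarray:
    """Central-difference velocity (deg/s) on the bin grid, one-sided ends."""
    v = np.gradient(pos[:valid_len], bin_ms / 1000.0)
    out = np.full_like(pos, np.nan)
    out[:valid_len] = v
    return out


def build_design(raw: dict, grid: BinGrid, bounce_flags: np.ndarray,
                 egocentric: bool = False) -> EncodingDesign:
    """Assemble the 15-column design from per-bin behavioral channels.

    ``raw`` is the channel dict produced by :func:`mentalpong.synth.build_latents`
    (ball_x/y/dx/dy, eye_x/y, paddle_y, joystick as (C, B) arrays).
    ``egocentric=True`` replaces ball position with ball - eye.
    """
    needed = ("ball_x", "ball_y", "ball_dx", "ball_dy", "eye_x", "eye_y",
              "paddle_y", "joystick")
    for k in needed:
        if k not in raw:
            raise KeyError(f"behavior channel '{k}' missing from raw dict")
    C, B = raw["ball_x"].shape
    cols = {}
    bx = raw["ball_x"].copy()
    by = raw["ball_y"].copy()
    if egocentric:
        bx = bx - raw["eye_x"]
        by = by - raw["eye_y"]
    cols["ball_x"], cols["ball_y"] = bx, by
    cols["ball_dx"], cols["ball_dy"] = raw["ball_dx"], raw["ball_dy"]
    cols["ball_speed"] = np.hypot(raw["ball_dx"], raw["ball_dy"])
    cols["ball_dir"] = np.arctan2(raw["ball_dy"], raw["ball_dx"])
    edx = np.full((C, B), np.nan)
    edy = np.full((C, B), np.nan)
    for c in range(C):
        nb = grid.n_bins[c]
        edx[c] = _velocity(raw["eye_x"][c], grid.bin_ms, nb)
        edy[c] = _velocity(raw["eye_y"][c], grid.bin_ms, nb)
    cols["eye_x"], cols["eye_y"] = raw["eye_x"], raw["eye_y"]
    cols["eye_dx"], cols["eye_dy"] = edx, edy
    cols["eye_speed"] = np.hypot(edx, edy)
    cols["eye_dir"] = np.arctan2(edy, edx)
    cols["paddle_y"] = raw["paddle_y"]
    cols["joystick"] = raw["joystick"]
    cols["bounce"] = np.broadcast_to(
        np.asarray(bounce_flags, dtype=float)[:, None], (C, B))
    valid = grid.valid_mask()
    cond_idx, bin_idx = np.where(valid)
    X = np.column_stack([cols[name][valid] for name in DESIGN_COLS])
    vis = grid.visible_mask()[valid]
    return EncodingDesign(X=X, condition=cond_idx, bin_index=bin_idx,
                          visible=vis)


def _ols_r2(X: np.ndarray, y: np.ndarray, train: np.ndarray,
            test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fit OLS (with intercept) on train rows; return (coef, test preds)."""
    Xt = np.column_stack([np.ones(train.sum()), X[train]])
    beta, *_ = np.linalg.lstsq(Xt, y[train], rcond=None)
    pred = np.column_stack([np.ones(test.sum()), X[test]]) @ beta
    return beta, pred


def _shift_rows(y: np.ndarray, condition: np.ndarray, bin_index: np.ndarray,
                shift_bins: int) -> np.ndarray:
    """Response shifted in time by shift_bins within each condition.

    Positive shift means the response at bin b is replaced by the response
    at bin b - shift (i.e., the neural signal lags the regressors). Rows
    without a source bin become NaN and are dropped by the caller.
    """
    out = np.full_like(y, np.nan, dtype=float)
    for c in np.unique(condition):
        rows = np.where(condition == c)[0]
        order = rows[np.argsort(bin_index[rows])]
        vals = y[order]
        n = len(vals)
        shifted = np.full(n, np.nan)
        if shift_bins >= 0:
            shifted[shift_bins:] = vals[:n - shift_bins] if shift_bins else vals
        else:
            shifted[:n + shift_bins] = vals[-shift_bins:]
        out[order] = shifted
    return out


def _cv_r2(X: np.ndarray, y: np.ndarray, groups: np.ndarray, k_folds: int,
           seed: int) -> float:
    """Out-of-fold R^2 with folds grouped by condition."""
    rng = np.random.default_rng(seed)
    uniq = rng.permutation(np.unique(groups))
    folds = np.array_split(uniq, min(k_folds, len(uniq)))
    pred = np.full_like(y, np.nan, dtype=float)
    for fold in folds:
        test = np.isin(groups, fold)
        train = ~test
        if y[train].std() == 0:
            continue
        _, p = _ols_r2(X, y, train, test)
        pred[test] = p
    ok = np.isfinite(pred)
    ss_res = np.sum((y[ok] - pred[ok]) ** 2)
    ss_tot = np.sum((y[ok] - y[ok].mean()) ** 2)
    return 1.0 - ss_res / ss_tot


def fit_glm_cv(design: EncodingDesign, rates: np.ndarray, k_folds: int = 10,
               jitter_ms: tuple = DEFAULT_JITTER_MS, bin_ms: float = 50.0,
               seed: int = 0, epoch: str | None = None) -> GlmFit:
    """Identity-link least-squares encoding fit with jitter search.

    ``rates`` is the unit's response per design row. For each temporal
    jitter the response is shifted within condition, rows without overlap
    are dropped, and out-of-fold R^2 is computed with condition-grouped
    k-fold CV; the best jitter's fit is returned. ``epoch`` restricts rows
    to 'visible' or 'occluded' (fits per epoch are independent).
    """
    rows = np.ones(len(rates), dtype=bool)
    if epoch == "visible":
        rows = design.visible
    elif epoch == "occluded":
        rows = ~design.visible
    per_jitter = {}
    best = (None, -np.inf, None)
    for j in jitter_ms:
        # positive jitter = response lags the regressors; advance it to align
        shift = -int(round(j / bin_ms))
        y = _shift_rows(rates, design.condition, design.bin_index, shift)
        ok = rows & np.isfinite(y) & np.isfinite(design.X).all(axis=1)
        r2 = _cv_r2(design.X[ok], y[ok], design.condition[ok], k_folds, seed)
        per_jitter[float(j)] = r2
        if r2 > best[1]:
            Xt = np.column_stack([np.ones(ok.sum()), design.X[ok]])
            beta, *_ = np.linalg.lstsq(Xt, y[ok], rcond=None)
            best = (float(j), r2, beta)
    return GlmFit(coef=best[2], best_jitter_ms=best[0], cv_r2=best[1],
                  per_jitter_r2=per_jitter)


def _category_columns(cats: tuple[str, ...]) -> list[int]:
    names = sum((CATEGORY[c] for c in cats), []) + NUISANCE_COLS
    return [DESIGN_COLS.index(n) for n in names]


def variance_partition(design: EncodingDesign, rates: np.ndarray,
                       k_folds: int = 10, seed: int = 0,
                       epoch: str | None = None, jitter_bins: int = 0,
                       cross_validated: bool = False) -> VarianceComponents:
    """Commonality analysis over the ball / eye / hand categories.

    Fits the seven nested models (each category alone, each pair, all
    three; the bounce nuisance column rides along in every model) on the
    same rows and folds, then forms the unique and common components:

        U_ball        = R2_full - R2_eye+hand          (and cyclically)
        C_ball,eye    = R2_ball+hand + R2_eye+hand - R2_hand - R2_full
        C_ball,eye,hand = R2_full + R2_ball + R2_eye + R2_hand
                          - R2_ball+eye - R2_eye+hand - R2_ball+hand

    With in-sample R^2 (default) the seven components sum to the
    full-model R^2 exactly; with ``cross_validated=True`` they are
    out-of-fold and individually may be negative.
    """
    rows = np.ones(len(rates), dtype=bool)
    if epoch == "visible":
        rows = design.visible
    elif epoch == "occluded":
        rows = ~design.visible
    y = _shift_rows(rates, design.condition, design.bin_index, jitter_bins)
    ok = rows & np.isfinite(y) & np.isfinite(design.X).all(axis=1)
    X, y, groups = design.X[ok], y[ok], design.condition[ok]

    def r2_for(cats):
        cols = _category_columns(cats)
        if cross_validated:
            return _cv_r2(X[:, cols], y, groups, k_folds, seed)
        all_rows = np.ones(len(y), dtype=bool)
        _, pred = _ols_r2(X[:, cols], y, all_rows, all_rows)
        return 1.0 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)

    singles = {c: r2_for((c,)) for c in ("ball", "eye", "hand")}
    pairs = {frozenset(p): r2_for(p)
             for p in combinations(("ball", "eye", "hand"), 2)}
    full = r2_for(("ball", "eye", "hand"))

    def pair(a, b):
        return pairs[frozenset((a, b))]

    comp = {}
    for cat in ("ball", "eye", "hand"):
        others = [c for c in ("ball", "eye", "hand") if c != cat]
        comp[f"U_{cat}"] = full - pair(*others)
    for a, b in combinations(("ball", "eye", "hand"), 2):
        c = ({"ball", "eye", "hand"} - {a, b}).pop()
        comp[f"C_{a}_{b}"] = pair(a, c) + pair(b, c) - singles[c] - full
    comp["C_ball_eye_hand"] = (full + sum(singles.values())
                               - sum(pairs.values()))
    nested = {**singles,
              **{"+".join(sorted(k)): v for k, v in
                 ((tuple(sorted(fs)), v) for fs, v in pairs.items())},
              "ball+eye+hand": full}
    return VarianceComponents(nested_r2=nested, components=comp)
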