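"""Static linear population readouts and their controls.

All decoders here are static read-outs: a single linear regression maps
every time point of population activity to a time-varying target, trained
and tested on disjoint sets of task conditions (GroupShuffleSplit over
condition ids; 50% train, 100 splits by default). Accuracy is summarized
by Pearson r and RMSE on held-out conditions, pooled or masked per epoch
and per bin. Partial correlations residualize both the prediction and the
target on nuisance covariates before correlating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import GroupShuffleSplit

from .preprocess import FactorTensor


@dataclass
class ReadoutResult:
    """Per-split held-out metrics and pooled held-out predictions."""

    r: np.ndarray               # (n_splits, n_targets)
    rmse: np.ndarray            # (n_splits, n_targets)
    weights: np.ndarray         # (n_splits, n_features + 1, n_targets)
    pred_mean: np.ndarray       # (n_rows, n_targets) mean held-out prediction
    pred_count: np.ndarray      # (n_rows,) times each row was held out
    rows_condition: np.ndarray  # (n_rows,)
    rows_bin: np.ndarray        # (n_rows,)
    rows_visible: np.ndarray    # (n_rows,) bool
    target: np.ndarray          # (n_rows, n_targets)
    train_frac: float = 0.5

    @property
    def n_splits(self) -> int:
        return len(self.r)


def _pool_rows(factors: FactorTensor):
    valid = factors.grid.valid_mask()
    cond, bins = np.where(valid)
    X = factors.scores[:, valid].T          # (n_rows, F)
    vis = factors.grid.visible_mask()[valid]
    return X, cond, bins, vis


def _metrics(y: np.ndarray, p: np.ndarray):
    r = np.empty(y.shape[1])
    rmse = np.empty(y.shape[1])
    for j in range(y.shape[1]):
        r[j] = stats.pearsonr(y[:, j], p[:, j])[0] if y[:, j].std() > 0 else np.nan
        rmse[j] = np.sqrt(np.mean((y[:, j] - p[:, j]) ** 2))
    return r, rmse


def fit_static_readout(factors: FactorTensor, target: np.ndarray,
                       train_frac: float = 0.5, n_splits: int = 100,
                       seed: int = 0) -> ReadoutResult:
    """One fixed linear map from factor scores to a time-varying target.

    ``target`` is (C, B[, n_targets]) on the same grid as the factors (a
    per-condition constant such as the endpoint may be broadcast by the
    caller). Splits never share a condition between train and test.
    """
    X, cond, bins, vis = _pool_rows(factors)
    valid = factors.grid.valid_mask()
    t = np.asarray(target, dtype=float)
    if t.ndim == 2:
        t = t[..., None]
    Y = t[valid]                            # (n_rows, n_targets)
    ok = np.isfinite(Y).all(axis=1)
    if not ok.all():
        raise ValueError("target contains NaNs inside the valid grid")
    n_rows, n_t = Y.shape
    gss = GroupShuffleSplit(n_splits=n_splits, train_size=train_frac,
                            random_state=seed)
    r = np.empty((n_splits, n_t))
    rmse = np.empty((n_splits, n_t))
    W = np.empty((n_splits, X.shape[1] + 1, n_t))
    pred_sum = np.zeros((n_rows, n_t))
    pred_cnt = np.zeros(n_rows)
    for s, (tr, te) in enumerate(gss.split(X, Y, groups=cond)):
        reg = LinearRegression().fit(X[tr], Y[tr])
        p = reg.predict(X[te])
        r[s], rmse[s] = _metrics(Y[te], p)
        W[s, 0] = reg.intercept_
        W[s, 1:] = reg.coef_.T
        pred_sum[te] += p
        pred_cnt[te] += 1
    with np.errstate(invalid="ignore"):
        pred_mean = pred_sum / pred_cnt[:, None]
    return ReadoutResult(r=r, rmse=rmse, weights=W, pred_mean=pred_mean,
                         pred_count=pred_cnt, rows_condition=cond,
                         rows_bin=bins, rows_visible=vis, target=Y,
                         train_frac=train_frac)


def evaluate_by_time_epoch(result: ReadoutResult,
                           by: str = "epoch") -> dict:
    """Per-epoch or per-bin metrics from the same held-out predictions.

    No re-fitting: the stored mean held-out predictions are masked by epoch
    (``by='epoch'``) or by bin index (``by='bin'``) and the metrics are
    recomputed on each subset.
    """
    ok = result.pred_count > 0
    out = {}
    if by == "epoch":
        masks = {"visible": result.rows_visible & ok,
                 "occluded": ~result.rows_visible & ok,
                 "pooled": ok}
    elif by == "bin":
        masks = {int(b): (result.rows_bin == b) & ok
                 for b in np.unique(result.rows_bin)}
    else:
        raise ValueError("by must be 'epoch' or 'bin'")
    for key, m in masks.items():
        if m.sum() < 3:
            out[key] = {"r": np.nan, "rmse": np.nan, "n": int(m.sum())}
            continue
        r, rmse = _metrics(result.target[m], result.pred_mean[m])
        out[key] = {"r": r, "rmse": rmse, "n": int(m.sum())}
    return out


def partial_corr(pred: np.ndarray, truth: np.ndarray,
                 covariates: np.ndarray) -> float:
    """Partial Pearson correlation of pred and truth given covariates.

    Both series are residualized on the covariates (with intercept) by
    linear least squares; the Pearson correlation of the residuals is
    returned. A covariate collinear with the truth to machine precision is
    flagged with a warning (the partial correlation is then ill-defined).
    """
    pred = np.asarray(pred, float).ravel()
    truth = np.asarray(truth, float).ravel()
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] == pred.size and Z.ndim == 2 and Z.shape[1] != pred.size:
        pass
    elif Z.shape[-1] == pred.size:
        Z = Z.T
    Z = np.column_stack([np.ones(pred.size), Z])

    def residual(v):
        beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
        return v - Z @ beta

    rt = residual(truth)
    if rt.std() < 1e-12 * max(truth.std(), 1.0):
        warnings.warn("covariates are collinear with the truth series; "
                      "partial correlation is ill-defined")
    rp = residual(pred)
    # residuals at numerical-noise level carry no correlation information
    if (rp.std() <= 1e-10 * max(pred.std(), 1e-300)
            or rt.std() <= 1e-10 * max(truth.std(), 1e-300)):
        return 0.0
    return float(stats.pearsonr(rp, rt)[0])


@dataclass
class EndpointDecode:
    """Per-bin endpoint-decoding accuracy and its shuffle control."""

    bins: np.ndarray
    r: np.ndarray               # (n_bins,) across held-out conditions
    rmse: np.ndarray
    shuffle_r: np.ndarray       # (n_shuffles, n_bins)
    result: ReadoutResult | None = None


def _per_bin_r(result: ReadoutResult) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ok = result.pred_count > 0
    bins = np.unique(result.rows_bin)
    r = np.full(len(bins), np.nan)
    rmse = np.full(len(bins), np.nan)
    for i, b in enumerate(bins):
        m = (result.rows_bin == b) & ok
        if m.sum() >= 3 and result.target[m, 0].std() > 0:
            r[i] = stats.pearsonr(result.target[m, 0],
                                  result.pred_mean[m, 0])[0]
            rmse[i] = np.sqrt(np.mean((result.target[m, 0]
                                       - result.pred_mean[m, 0]) ** 2))
    return bins, r, rmse


def decode_endpoint_timecourse(factors: FactorTensor, yf: np.ndarray,
                               train_frac: float = 0.5, n_splits: int = 100,
                               n_shuffles: int = 20,
                               seed: int = 0) -> EndpointDecode:
    """Static read-out of the endpoint yf, evaluated per time bin.

    One readout is trained on all bins jointly (yf constant within a
    condition); accuracy is the across-condition correlation of held-out
    predictions with true yf at each bin. The shuffle control permutes yf
    across conditions before fitting.
    """
    grid = factors.grid
    yf = np.asarray(yf, float)
    target = np.broadcast_to(yf[:, None], (grid.n_conditions, grid.max_bins))
    res = fit_static_readout(factors, target, train_frac, n_splits, seed)
    bins, r, rmse = _per_bin_r(res)
    rng = np.random.default_rng(seed + 1)
    sh = np.full((n_shuffles, len(bins)), np.nan)
    for i in range(n_shuffles):
        perm = rng.permutation(yf)
        t2 = np.broadcast_to(perm[:, None], target.shape)
        res_s = fit_static_readout(factors, t2, train_frac,
                                   max(10, n_splits // 10), seed + 2 + i)
        _, sh[i], _ = _per_bin_r(res_s)
    return EndpointDecode(bins=bins, r=r, rmse=rmse, shuffle_r=sh, result=res)


def behavioral_consistency_endpoint(neural_yf_est: np.ndarray,
                                    paddle_final: np.ndarray,
                                    yf: np.ndarray) -> np.ndarray:
    """Neural-behavioral residual correlation per bin.

    ``neural_yf_est`` is the (C, n_bins) split-averaged neural estimate of
    the endpoint. Both the neural estimate and the behavioral endpoint are
    residualized on the true yf across conditions; the per-bin Pearson
    correlation of the residuals is returned.
    """
    est = np.asarray(neural_yf_est, float)
    paddle_final = np.asarray(paddle_final, float)
    yf = np.asarray(yf, float)
    if est.shape[0] < 3:
        raise ValueError("behavioral consistency needs >= 3 conditions")
    out = np.full(est.shape[1], np.nan)
    for b in range(est.shape[1]):
        col = est[:, b]
        ok = np.isfinite(col)
        if ok.sum() < 3:
            continue
        out[b] = partial_corr(col[ok], paddle_final[ok], yf[ok])
    return out


def endpoint_estimate_matrix(result: ReadoutResult,
                             n_conditions: int, n_bins: int) -> np.ndarray:
    """Arrange split-averaged held-out endpoint predictions as (C, B)."""
    est = np.full((n_conditions, n_bins), np.nan)
    ok = result.pred_count > 0
    est[result.rows_condition[ok], result.rows_bin[ok]] = \
        result.pred_mean[ok, 0]
    return est


def two_stage_endpoint(factors: FactorTensor, intermediates: np.ndarray,
                       yf: np.ndarray, train_frac: float = 0.5,
                       n_splits: int = 100, seed: int = 0) -> dict:
    """Mediation control: decode intermediates, then regress yf on them.

    Stage 1 decodes the intermediary variables (position, or position and
    velocity; (C, B, k) array) from the factors with held-out predictions.
    Stage 2 regresses yf on the split-averaged decoded intermediates only,
    per time bin, with condition-grouped splits. Returns per-bin r for the
    two-stage decoder alongside the direct endpoint decoder from the same
    protocol.
    """
    grid = factors.grid
    stage1 = fit_static_readout(factors, intermediates, train_frac,
                                n_splits, seed)
    C, B = grid.n_conditions, grid.max_bins
    k = stage1.target.shape[1]
    dec = np.full((C, B, k), np.nan)
    ok = stage1.pred_count > 0
    dec[stage1.rows_condition[ok], stage1.rows_bin[ok]] = stage1.pred_mean[ok]
    yf = np.asarray(yf, float)
    rng = np.random.default_rng(seed + 5)
    bins = np.arange(B)
    r_two = np.full(B, np.nan)
    for b in bins:
        Xb = dec[:, b, :]
        rows = np.isfinite(Xb).all(axis=1)
        if rows.sum() < 6:
            continue
        idx = np.where(rows)[0]
        preds = np.full(len(idx), np.nan)
        rs = []
        for s in range(max(20, n_splits // 5)):
            perm = rng.permutation(len(idx))
            half = len(idx) // 2
            tr, te = idx[perm[:half]], idx[perm[half:]]
            reg = LinearRegression().fit(Xb[tr], yf[tr])
            p = reg.predict(Xb[te])
            if yf[te].std() > 0:
                rs.append(stats.pearsonr(yf[te], p)[0])
        r_two[b] = np.mean(rs) if rs else np.nan
    direct = decode_endpoint_timecourse(factors, yf, train_frac,
                                        n_splits, n_shuffles=0, seed=seed)
    return {"bins": bins, "two_stage_r": r_two, "direct_r": direct.r,
            "stage1": stage1}
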