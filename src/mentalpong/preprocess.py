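"""From per-trial spikes to the analysis tensor.

Pipeline: trial averaging and 50-ms binning (no temporal smoothing),
exclusion of units with too many missing conditions, global-mean imputation
of remaining missing cells, split-half reliability filtering against an
analytic Pearson significance threshold, and factor-analysis reduction of
the population with scree diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .synth import BinGrid, SpikeDataset


@dataclass
class PopulationTensor:
    """Trial-averaged rate tensor, units x conditions x bins (spikes/bin)."""

    rates: np.ndarray            # (U, C, B); NaN outside grid / missing
    grid: BinGrid
    missing: np.ndarray          # (U, C) bool — cells not observed
    imputed: np.ndarray | None = None   # (U, C) bool — cells filled in
    reliability: np.ndarray | None = None  # (U,)
    unit_ids: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.rates.shape[0]


@dataclass
class FactorTensor:
    """Latent-factor scores, factors x conditions x bins, plus loadings."""

    scores: np.ndarray           # (F, C, B), NaN-padded
    loading: np.ndarray          # (U, F)
    grid: BinGrid
    n_factors: int
    rotated: bool = False


def bin_average(spikes: SpikeDataset, bin_ms: float = 50.0) -> PopulationTensor:
    """Average counts across trials of each condition, then bin to bin_ms.

    Success and failure trials are pooled. No smoothing is applied. A
    unit x condition cell with no observed trials is marked missing, not
    zeroed.
    """
    src_ms = spikes.grid.bin_ms
    ratio = bin_ms / src_ms
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(f"bin_ms={bin_ms} must be a multiple of the "
                         f"recording resolution {src_ms} ms")
    ratio = int(round(ratio))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(spikes.counts, axis=1)     # (U, C, B_src)
    U, C, B = mean.shape
    if ratio > 1:
        nb = B // ratio
        mean = mean[:, :, :nb * ratio].reshape(U, C, nb, ratio).sum(axis=3)
        grid = BinGrid(bin_ms=bin_ms,
                       n_bins=spikes.grid.n_bins // ratio,
                       n_vis=spikes.grid.n_vis // ratio)
    else:
        grid = spikes.grid
    missing = spikes.missing.copy()
    # a condition with zero observed trials for a unit is missing too
    no_trials = np.all(np.isnan(spikes.counts), axis=(1, 3))
    missing |= no_trials
    return PopulationTensor(rates=mean, grid=grid, missing=missing)


def exclude_impute(tensor: PopulationTensor,
                   max_missing_conditions: int = 5) -> PopulationTensor:
    """Drop units missing too many conditions; impute the rest.

    Units with more than ``max_missing_conditions`` missing conditions are
    excluded. Remaining missing cells are replaced by the unit's global
    mean rate over its observed (condition, time) cells, and flagged.
    """
    n_missing = tensor.missing.sum(axis=1)
    all_missing = n_missing == tensor.missing.shape[1]
    keep = (n_missing <= max_missing_conditions) & ~all_missing
    rates = tensor.rates[keep].copy()
    missing = tensor.missing[keep]
    valid = tensor.grid.valid_mask()
    imputed = missing.copy()
    for u in range(rates.shape[0]):
        if not missing[u].any():
            continue
        observed_cells = rates[u][~missing[u]][valid[~missing[u]]]
        fill = float(np.nanmean(observed_cells))
        for c in np.where(missing[u])[0]:
            rates[u, c, valid[c]] = fill
    ids = (tensor.unit_ids if tensor.unit_ids is not None
           else np.arange(tensor.missing.shape[0]))
    return PopulationTensor(rates=rates, grid=tensor.grid,
                            missing=np.zeros_like(missing), imputed=imputed,
                            reliability=None, unit_ids=ids[keep])


def _flatten_valid(rates_uc: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Flatten a (C, B) matrix over the valid cells of the grid."""
    return rates_uc[valid]


def split_half_reliability(spikes: SpikeDataset, n_repeats: int = 10,
                           seed: int = 0, bin_ms: float = 50.0) -> np.ndarray:
    """Per-unit split-half internal reliability.

    Trials of each condition are randomly halved; each half is averaged and
    binned exactly as the full pipeline does; the Pearson correlation
    between the two flattened (condition x bin) response estimates is
    averaged over repeats. Conditions with a single trial are excluded from
    the split (with a warning).
    """
    rng = np.random.default_rng(seed)
    U, R, C, B = spikes.counts.shape
    obs = ~np.all(np.isnan(spikes.counts), axis=(0, 3))  # (R, C) trial exists
    n_trials = obs.sum(axis=0)
    if (n_trials == 1).any():
        warnings.warn(f"{int((n_trials == 1).sum())} condition(s) have a "
                      "single trial and are excluded from the split")
    out = np.zeros((U, n_repeats))
    valid = spikes.grid.valid_mask()
    for rep in range(n_repeats):
        half = np.zeros((R, C), dtype=bool)
        for c in range(C):
            idx = np.where(obs[:, c])[0]
            if len(idx) < 2:
                continue
            pick = rng.permutation(idx)[:len(idx) // 2]
            half[pick, c] = True
        h1 = np.where(half[None, :, :, None], spikes.counts, np.nan)
        h2 = np.where((~half & obs)[None, :, :, None], spikes.counts, np.nan)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            m1 = np.nanmean(h1, axis=1)
            m2 = np.nanmean(h2, axis=1)
        for u in range(U):
            a = m1[u][valid]
            b = m2[u][valid]
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 4 or a[ok].std() == 0 or b[ok].std() == 0:
                out[u, rep] = np.nan
                continue
            out[u, rep] = np.corrcoef(a[ok], b[ok])[0, 1]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(out, axis=1)


def critical_r(n_points: int, alpha: float = 0.01) -> float:
    """Two-sided critical Pearson correlation at significance ``alpha``.

    Uses the exact t-distribution relation with n-2 degrees of freedom:
    r* = t* / sqrt(t*^2 + n - 2).
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_points - 2
    t_star = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(t_star / np.sqrt(t_star ** 2 + df))


def filter_reliable(tensor: PopulationTensor, spikes: SpikeDataset,
                    alpha: float = 0.01, n_repeats: int = 10,
                    seed: int = 0) -> PopulationTensor:
    """Keep units whose split-half reliability clears the analytic threshold.

    The number of points entering each correlation is the package's own
    (condition x bin) grid size; the threshold is critical_r(n, alpha).
    This selects for reliability only, not for task modulation.
    """
    rel = split_half_reliability(spikes, n_repeats=n_repeats, seed=seed,
                                 bin_ms=tensor.grid.bin_ms)
    ids = (tensor.unit_ids if tensor.unit_ids is not None
           else np.arange(len(rel)))
    rel = rel[ids]
    n_points = int(tensor.grid.valid_mask().sum())
    thr = critical_r(n_points, alpha)
    keep = np.isfinite(rel) & (rel > thr)
    return replace(tensor, rates=tensor.rates[keep], missing=tensor.missing[keep],
                   imputed=None if tensor.imputed is None else tensor.imputed[keep],
                   reliability=rel[keep], unit_ids=ids[keep])


def _stack_matrix(tensor: PopulationTensor) -> tuple[np.ndarray, np.ndarray]:
    """(samples x units) matrix over valid grid cells, plus the valid mask."""
    valid = tensor.grid.valid_mask()
    X = tensor.rates[:, valid].T  # (n_samples, U)
    if not np.isfinite(X).all():
        raise ValueError("tensor contains NaNs inside the valid grid; run "
                         "exclude_impute first")
    return X, valid


def reduce_factors(tensor: PopulationTensor, n_factors: int = 50,
                   rotate: bool = False, seed: int = 0) -> FactorTensor:
    """Factor analysis of the population, scores per (condition, bin).

    Captures shared variability across units; optional varimax rotation
    (decoding results are insensitive to it).
    """
    from sklearn.decomposition import FactorAnalysis

    X, valid = _stack_matrix(tensor)
    if tensor.n_units < n_factors:
        raise ValueError(f"{tensor.n_units} units < {n_factors} factors")
    rank = np.linalg.matrix_rank(np.cov(X.T))
    if rank < n_factors:
        raise ValueError(f"covariance rank {rank} below n_factors={n_factors}")
    fa = FactorAnalysis(n_components=n_factors,
                        rotation="varimax" if rotate else None,
                        random_state=seed)
    Z = fa.fit_transform(X)
    F, C, B = n_factors, tensor.grid.n_conditions, tensor.grid.max_bins
    scores = np.full((F, C, B), np.nan)
    scores[:, valid] = Z.T
    return FactorTensor(scores=scores, loading=fa.components_.T,
                        grid=tensor.grid, n_factors=n_factors, rotated=rotate)


def eigen_spectrum(tensor: PopulationTensor, n_shuffles: int = 10,
                   seed: int = 0) -> dict:
    """PCA variance fractions and a shuffled-data null envelope.

    The null independently permutes each unit's entries across
    (condition, bin), destroying shared structure while preserving each
    unit's marginal distribution.
    """
    X, _ = _stack_matrix(tensor)
    def frac(M):
        M = M - M.mean(axis=0)
        s = np.linalg.svd(M, compute_uv=False) ** 2
        return s / s.sum()
    rng = np.random.default_rng(seed)
    null = np.empty((n_shuffles, min(X.shape)))
    for i in range(n_shuffles):
        Xs = np.column_stack([rng.permutation(X[:, u])
                              for u in range(X.shape[1])])
        null[i] = frac(Xs)
    return {"fractions": frac(X), "null_mean": null.mean(axis=0),
            "null_max": null.max(axis=0)}


def preprocess_pipeline(spikes: SpikeDataset, bin_ms: float = 50.0,
                        max_missing_conditions: int = 5, alpha: float = 0.01,
                        n_factors: int = 50, rotate: bool = False,
                        seed: int = 0) -> tuple[PopulationTensor, FactorTensor]:
    """Full preprocessing chain: bin, exclude/impute, filter, reduce."""
    tensor = bin_average(spikes, bin_ms)
    tensor = exclude_impute(tensor, max_missing_conditions)
    tensor = filter_reliable(tensor, spikes, alpha=alpha, seed=seed)
    factors = reduce_factors(tensor, n_factors=min(n_factors, tensor.n_units),
                             rotate=rotate, seed=seed)
    return tensor, factors
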