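"""Model-to-brain comparison via noise-adjusted distance correlations.

A system (neural population or network) visiting states over conditions
and time bins is summarized by the matrix of pairwise distances between
all of its states (occluded-epoch states by default). Two systems are
compared by the Pearson correlation between their distance matrices'
vectorized upper triangles, divided by the geometric mean of each
system's split-half internal reliability — the noise-adjusted consistency

    rho_hat(m, b) = corr(m, b) / sqrt(corr(m, m) * corr(b, b)).

All four correlations are computed from half-trial estimates so every
term uses the same amount of data; no Spearman-Brown extrapolation is
applied. A model that is an exact replica of a noisy brain (independent
noise draws) has expected consistency 1.0. Because the adjustment divides
by a noisy reliability estimate, individual repeats can overshoot 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from scipy import stats

from .synth import BinGrid, SpikeDataset


@dataclass
class StateDistanceMatrix:
    """Condensed pairwise distances between population states."""

    condensed: np.ndarray      # upper triangle, scipy pdist order
    n_states: int
    system: str = ""
    split_id: int = -1

    def square(self) -> np.ndarray:
        from scipy.spatial.distance import squareform
        return squareform(self.condensed)


@dataclass
class ConsistencyScore:
    raw: float                 # mean cross-system half-data correlation
    reliability_model: float
    reliability_brain: float
    adjusted: float            # Eq. rho_hat; NaN if a reliability <= 0
    per_repeat: np.ndarray     # (n_repeats,) adjusted scores (NaN where undefined)

    @property
    def n_repeats(self) -> int:
        return len(self.per_repeat)


def _select_states(states: np.ndarray, grid: BinGrid, epoch: str) -> np.ndarray:
    """(n_states, n_dims) matrix of state vectors for the chosen epoch."""
    if states.shape[1:] != (grid.n_conditions, grid.max_bins):
        raise ValueError(
            f"states grid {states.shape[1:]} does not match the bin grid "
            f"({grid.n_conditions}, {grid.max_bins})")
    if epoch == "occluded":
        mask = grid.occluded_mask()
    elif epoch == "visible":
        mask = grid.visible_mask()
    elif epoch == "full":
        mask = grid.valid_mask()
    else:
        raise ValueError("epoch must be 'occluded', 'visible' or 'full'")
    return states[:, mask].T


def state_distance_matrix(states: np.ndarray, grid: BinGrid,
                          epoch: str = "occluded",
                          metric: str = "euclidean",
                          system: str = "") -> StateDistanceMatrix:
    """Pairwise distances between all selected state vectors.

    ``states`` is (dims, conditions, bins) — factors or raw units for a
    brain, hidden units for a model (resampled to the neural grid).
    ``metric`` is 'euclidean' or 'correlation'.
    """
    V = _select_states(states, grid, epoch)
    if not np.isfinite(V).all():
        raise ValueError("state vectors contain NaNs inside the epoch mask")
    d = pdist(V, metric=metric)
    return StateDistanceMatrix(condensed=d, n_states=V.shape[0], system=system)


def _halves_from_spikes(spikes: SpikeDataset, rng: np.random.Generator):
    """Two independent trial-averaged rate tensors from disjoint halves."""
    U, R, C, B = spikes.counts.shape
    half = np.zeros((R, C), dtype=bool)
    obs = ~np.all(np.isnan(spikes.counts), axis=(0, 3))
    for c in range(C):
        idx = np.where(obs[:, c])[0]
        pick = rng.permutation(idx)[:len(idx) // 2]
        half[pick, c] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(np.where(half[None, :, :, None], spikes.counts,
                                 np.nan), axis=1)
        m2 = np.nanmean(np.where((~half & obs)[None, :, :, None],
                                 spikes.counts, np.nan), axis=1)
    # missing unit x condition cells: global-mean imputation, as in the
    # preprocessing stage, so state vectors are complete
    valid = spikes.grid.valid_mask()
    for m in (m1, m2):
        bad = np.isnan(m) & valid[None, :, :]
        if bad.any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fill = np.nanmean(np.where(valid[None], m, np.nan),
                                  axis=(1, 2))
            m[bad] = np.broadcast_to(fill[:, None, None], m.shape)[bad]
    return m1, m2


def split_half_distance_reliability(spikes: SpikeDataset, n_repeats: int = 10,
                                    seed: int = 0, epoch: str = "occluded",
                                    metric: str = "euclidean") -> float:
    """Split-half reliability of a stochastic system's distance matrix.

    Trials are split into two equal halves; each half yields a distance
    matrix; the Pearson correlation between the two condensed matrices is
    averaged over repeats. A deterministic system (no trial noise) has
    reliability 1 by definition — don't call this for it.
    """
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_repeats):
        m1, m2 = _halves_from_spikes(spikes, rng)
        d1 = state_distance_matrix(m1, spikes.grid, epoch, metric)
        d2 = state_distance_matrix(m2, spikes.grid, epoch, metric)
        vals.append(stats.pearsonr(d1.condensed, d2.condensed)[0])
    return float(np.mean(vals))


def consistency_score(model_spikes: SpikeDataset | np.ndarray,
                      brain_spikes: SpikeDataset,
                      n_repeats: int = 10, seed: int = 0,
                      epoch: str = "occluded",
                      metric: str = "euclidean") -> ConsistencyScore:
    """Noise-adjusted consistency between two systems.

    Per repeat, each stochastic system's trials are split into halves and
    a distance matrix is estimated from each half. The raw cross-system
    correlation is the mean over the four half-pair correlations; each
    system's reliability is the correlation between its own two halves;
    the adjusted score divides the raw correlation by the geometric mean
    of the reliabilities. Repeats with non-positive reliability are
    reported as NaN rather than divided through silently.

    ``model_spikes`` may instead be a deterministic state tensor
    (dims, C, B) — e.g. RNN hidden states on the neural grid — whose
    reliability is 1 by definition.
    """
    rng = np.random.default_rng(seed)
    deterministic = isinstance(model_spikes, np.ndarray)
    per_repeat = np.full(n_repeats, np.nan)
    raws, rel_ms, rel_bs = [], [], []
    for rep in range(n_repeats):
        b1, b2 = _halves_from_spikes(brain_spikes, rng)
        db1 = state_distance_matrix(b1, brain_spikes.grid, epoch, metric)
        db2 = state_distance_matrix(b2, brain_spikes.grid, epoch, metric)
        rel_b = stats.pearsonr(db1.condensed, db2.condensed)[0]
        if deterministic:
            dm = state_distance_matrix(model_spikes, brain_spikes.grid,
                                       epoch, metric)
            dm1 = dm2 = dm
            rel_m = 1.0
        else:
            m1, m2 = _halves_from_spikes(model_spikes, rng)
            dm1 = state_distance_matrix(m1, model_spikes.grid, epoch, metric)
            dm2 = state_distance_matrix(m2, model_spikes.grid, epoch, metric)
            rel_m = stats.pearsonr(dm1.condensed, dm2.condensed)[0]
        raw = np.mean([stats.pearsonr(a.condensed, b.condensed)[0]
                       for a in (dm1, dm2) for b in (db1, db2)])
        raws.append(raw)
        rel_ms.append(rel_m)
        rel_bs.append(rel_b)
        if rel_m <= 0 or rel_b <= 0:
            warnings.warn(f"repeat {rep}: non-positive reliability "
                          f"(model {rel_m:.3f}, brain {rel_b:.3f}); "
                          "score undefined for this repeat")
            continue
        per_repeat[rep] = raw / np.sqrt(rel_m * rel_b)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        adjusted = float(np.nanmean(per_repeat))
    return ConsistencyScore(raw=float(np.mean(raws)),
                            reliability_model=float(np.mean(rel_ms)),
                            reliability_brain=float(np.mean(rel_bs)),
                            adjusted=adjusted, per_repeat=per_repeat)
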