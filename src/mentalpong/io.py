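"""HDF5 / CSV persistence for the pipeline's containers."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import FactorTensor, PopulationTensor
from .synth import BinGrid, GroundTruthLatents, SpikeDataset


def _write_grid(g, grid: BinGrid) -> None:
    g.attrs["bin_ms"] = grid.bin_ms
    g.create_dataset("n_bins", data=grid.n_bins)
    g.create_dataset("n_vis", data=grid.n_vis)


def _read_grid(g) -> BinGrid:
    return BinGrid(bin_ms=float(g.attrs["bin_ms"]),
                   n_bins=g["n_bins"][:], n_vis=g["n_vis"][:])


def save_spikes(path, spikes: SpikeDataset) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=spikes.counts, compression="gzip")
        f.create_dataset("missing", data=spikes.missing)
        _write_grid(f.create_group("grid"), spikes.grid)
        tt = f.create_group("trial_table")
        for col in spikes.trial_table.columns:
            tt.create_dataset(col, data=spikes.trial_table[col].to_numpy())
        if spikes.ground_truth is not None:
            gt = spikes.ground_truth
            g = f.create_group("ground_truth")
            g.create_dataset("latents", data=gt.latents, compression="gzip")
            g.create_dataset("loading", data=gt.loading)
            g.create_dataset("baseline_hz", data=gt.baseline_hz)
            g.attrs["gain"] = gt.gain
            g.attrs["latent_names"] = list(gt.latent_names)


def load_spikes(path) -> SpikeDataset:
    import h5py

    with h5py.File(path, "r") as f:
        grid = _read_grid(f["grid"])
        trial_table = pd.DataFrame({c: f["trial_table"][c][:]
                                    for c in f["trial_table"]})
        gt = None
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruthLatents(
                latents=g["latents"][:], loading=g["loading"][:],
                baseline_hz=g["baseline_hz"][:], gain=float(g.attrs["gain"]),
                grid=grid,
                latent_names=tuple(str(s) for s in g.attrs["latent_names"]))
        return SpikeDataset(counts=f["counts"][:], grid=grid,
                            missing=f["missing"][:].astype(bool),
                            trial_table=trial_table, ground_truth=gt)


def save_tensor(path, tensor: PopulationTensor) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("rates", data=tensor.rates, compression="gzip")
        f.create_dataset("missing", data=tensor.missing)
        _write_grid(f.create_group("grid"), tensor.grid)
        if tensor.reliability is not None:
            f.create_dataset("reliability", data=tensor.reliability)
        if tensor.unit_ids is not None:
            f.create_dataset("unit_ids", data=tensor.unit_ids)


def load_tensor(path) -> PopulationTensor:
    import h5py

    with h5py.File(path, "r") as f:
        return PopulationTensor(
            rates=f["rates"][:], grid=_read_grid(f["grid"]),
            missing=f["missing"][:].astype(bool),
            reliability=f["reliability"][:] if "reliability" in f else None,
            unit_ids=f["unit_ids"][:] if "unit_ids" in f else None)


def save_factors(path, factors: FactorTensor) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("scores", data=factors.scores, compression="gzip")
        f.create_dataset("loading", data=factors.loading)
        _write_grid(f.create_group("grid"), factors.grid)
        f.attrs["n_factors"] = factors.n_factors
        f.attrs["rotated"] = factors.rotated


def load_factors(path) -> FactorTensor:
    import h5py

    with h5py.File(path, "r") as f:
        return FactorTensor(scores=f["scores"][:], loading=f["loading"][:],
                            grid=_read_grid(f["grid"]),
                            n_factors=int(f.attrs["n_factors"]),
                            rotated=bool(f.attrs["rotated"]))
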