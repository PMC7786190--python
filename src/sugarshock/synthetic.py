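"""Pseudo-experimental smFISH snapshot datasets.

The generator emulates the statistical surface of single-cell
smFISH-STORM counting experiments: per-timepoint lists of per-cell integer
SgrS and *ptsG* mRNA counts with 85-200 cells per timepoint, basal SgrS of
1-3 and ptsG of 30-40 copies at t = 0, and broad unimodal distributions
thereafter.  Each synthetic cell is one SSA replicate of the ground-truth
model observed through the labeled-RNA totals at the aliquot schedule, so
with noise disabled a synthetic dataset is distributionally identical to a
model ensemble -- the clean generative path is the faithful stand-in for
background-subtracted experimental counts.  An optional additive Poisson
background per cell and species is available to stress-test fitting.

A rifampicin-chase generator produces pure-death count tables for
decay-rate estimation (transcription silenced at t = 0).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ensemble import (
    BasalSpec,
    CountDistribution,
    DEFAULT_SCHEDULE_MIN,
    run_ensemble,
)
from .errors import ConfigurationError, DataError
from .network import Reaction, ReactionNetwork, SpeciesState, Variant
from .parameters import KineticParameters
from .ssa import simulate
from .stats import SnapshotDataset

__all__ = ["SyntheticSpec", "generate_dataset", "generate_chase_dataset"]

#: Cells-per-timepoint range reported for the imaging experiments.
CELLS_PER_TIMEPOINT_RANGE = (85, 200)

_MAX_SEED = 2**31


@dataclass(frozen=True)
class SyntheticSpec:
    """Ground truth and sampling layout for a synthetic dataset.

    ``cells_per_timepoint`` may be an integer (same for every timepoint), a
    sequence (one per timepoint) or ``None`` to draw each uniformly from
    85-200 as in the imaging experiments.  ``noise_background_mean`` adds a
    per-cell, per-species Poisson background count (default off).
    """

    params: KineticParameters = field(default_factory=KineticParameters)
    variant: Variant = Variant.FULL
    cells_per_timepoint: int | Sequence[int] | None = None
    schedule_min: tuple[float, ...] = DEFAULT_SCHEDULE_MIN
    basal_spec: BasalSpec = field(default_factory=BasalSpec)
    noise_background_mean: float = 0.0
    master_seed: int = 0

    def resolve_cells(self, rng: np.random.Generator) -> np.ndarray:
        n_t = len(self.schedule_min)
        cpt = self.cells_per_timepoint
        if cpt is None:
            lo, hi = CELLS_PER_TIMEPOINT_RANGE
            cells = rng.integers(lo, hi + 1, size=n_t)
        elif np.isscalar(cpt):
            cells = np.full(n_t, int(cpt))
        else:
            cells = np.asarray(list(cpt), dtype=np.int64)
            if cells.size != n_t:
                raise ConfigurationError(
                    "cells_per_timepoint length must match the schedule"
                )
        if np.any(cells < 1):
            raise ConfigurationError("need at least one cell per timepoint")
        return cells

    def to_json(self, path: str | Path | None = None, indent: int = 2) -> str:
        payload = {
            "params": self.params.to_dict(),
            "variant": self.variant.value,
            "cells_per_timepoint": (
                None
                if self.cells_per_timepoint is None
                else np.asarray(self.cells_per_timepoint).tolist()
            ),
            "schedule_min": list(self.schedule_min),
            "noise_background_mean": self.noise_background_mean,
            "master_seed": self.master_seed,
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            Path(path).write_text(text)
        return text


def generate_dataset(spec: SyntheticSpec) -> SnapshotDataset:
    """Generate one synthetic snapshot dataset from a ground-truth model.

    Deterministic given ``spec.master_seed``.  The per-timepoint cell lists
    are the first ``n_t`` replicates of a single ensemble, mirroring
    independent aliquots of a shared culture.
    """
    rng = np.random.default_rng(spec.master_seed)
    cells = spec.resolve_cells(rng)
    ens_seed = int(rng.integers(0, _MAX_SEED))
    ensemble = run_ensemble(
        spec.params,
        variant=spec.variant,
        n_replicates=int(cells.max()),
        schedule_min=spec.schedule_min,
        base_seed=ens_seed,
        basal_spec=spec.basal_spec,
    )
    total_s, total_p = ensemble.totals()
    frames = []
    for j, t in enumerate(ensemble.schedule_min):
        n = int(cells[j])
        for name, totals in (("sgrs", total_s), ("ptsg", total_p)):
            counts = totals[:n, j].copy()
            if spec.noise_background_mean > 0:
                counts = counts + rng.poisson(spec.noise_background_mean, size=n)
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(n),
                        "time_min": float(t),
                        "species": name,
                        "count": counts,
                    }
                )
            )
    return SnapshotDataset(pd.concat(frames, ignore_index=True), "synthetic")


def generate_chase_dataset(
    truth_rate: float,
    n_cells: int = 500,
    schedule_min: Sequence[float] = DEFAULT_SCHEDULE_MIN,
    seed: int = 0,
    initial: CountDistribution | None = None,
) -> SnapshotDataset:
    """Synthetic rifampicin-chase count table for one RNA species.

    Transcription stops at t = 0; each cell runs a pure-death SSA
    (``rna -> 0`` at ``truth_rate``) from a basal initial count (default
    uniform on {30..40}).  Feeding the per-timepoint means to the
    log-linear fit recovers ``truth_rate``.
    """
    if not truth_rate > 0:
        raise DataError("truth_rate must be positive")
    if n_cells < 1:
        raise DataError("need at least one cell")
    initial = initial or CountDistribution.uniform_range(30, 40)
    network = ReactionNetwork(
        species=("S",),
        reactions=(
            Reaction("rna_degradation", "decay_rate", float(truth_rate),
                     ("S",), {"S": -1}),
        ),
        variant=Variant.NO_HFQ_NO_GENEDUP,
        params=KineticParameters(),
    )
    schedule = np.asarray(schedule_min, dtype=float)
    record_times = schedule * 60.0
    horizon = max(float(record_times[-1]), 1.0)
    frames = []
    counts = np.zeros((n_cells, schedule.size), dtype=np.int64)
    for i in range(n_cells):
        cell_seed = (int(seed) + i) % _MAX_SEED
        rng = np.random.default_rng(cell_seed)
        n0 = int(initial.sample(rng))
        traj = simulate(
            network, SpeciesState(S=n0), horizon, record_times, cell_seed
        )
        counts[i] = traj.counts[:, 0]
    for j, t in enumerate(schedule):
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.arange(n_cells),
                    "time_min": float(t),
                    "species": "rna",
                    "count": counts[:, j],
                }
            )
        )
    return SnapshotDataset(pd.concat(frames, ignore_index=True), "synthetic")
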