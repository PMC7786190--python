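"""Heterogeneous cell-population ensembles.

Each simulation replicate stands for one imaged cell.  Fast-growing
*E. coli* carry overlapping replication forks, so an unsynchronized
population mixes cells with different gene dosage: *sgrS* (near the
replication origin) is present in 2 or 4 copies and *ptsG* (mid-replichore)
in 1 or 2.  A replicate first draws its gene configuration (independent
coin flips with the configured high-state fractions), then draws basal RNA
counts, then runs the SSA to the horizon with snapshots on the
experimental schedule (minutes {0, 2, 4, 6, 8, 10, 15, 20} by default; the
0-min snapshot is the sampled pre-induction state).  All *sgrS* gene
copies start OFF; free Hfq starts at the full pool.

Replicate ``i`` uses seed ``base_seed + i`` so ensembles are reproducible
and embarrassingly parallel; dosage/basal draws and the SSA event stream
use independent generators derived from that seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .network import (
    SPECIES,
    ReactionNetwork,
    SpeciesState,
    Variant,
    build_network,
)
from .parameters import KineticParameters
from .ssa import simulate

__all__ = [
    "DEFAULT_SCHEDULE_MIN",
    "DEFAULT_HORIZON_S",
    "CountDistribution",
    "BasalSpec",
    "GeneConfiguration",
    "EnsembleResult",
    "sample_gene_configuration",
    "sample_initial_state",
    "run_ensemble",
    "observables",
]

#: Experimental aliquot schedule, minutes post-induction.
DEFAULT_SCHEDULE_MIN = (0.0, 2.0, 4.0, 6.0, 8.0, 10.0, 15.0, 20.0)

#: Simulation horizon, seconds (25 min, bracketing the 20-min schedule).
DEFAULT_HORIZON_S = 25.0 * 60.0

_MAX_SEED = 2**31


@dataclass(frozen=True)
class CountDistribution:
    """A finite integer-support distribution for basal RNA counts."""

    values: tuple[int, ...]
    probs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0 or len(self.values) != len(self.probs):
            raise DataError("values and probs must be equal-length and non-empty")
        if any(v < 0 or not float(v).is_integer() for v in self.values):
            raise DataError("support must be non-negative integers")
        total = float(sum(self.probs))
        if any(p < 0 for p in self.probs) or not np.isclose(total, 1.0):
            raise DataError("probs must be non-negative and sum to 1")

    @classmethod
    def uniform_range(cls, lo: int, hi: int) -> "CountDistribution":
        """Discrete uniform on the inclusive integer range ``{lo..hi}``."""
        if lo > hi:
            raise DataError(f"empty range {lo}..{hi}")
        values = tuple(range(int(lo), int(hi) + 1))
        return cls(values=values, probs=(1.0 / len(values),) * len(values))

    @classmethod
    def from_counts(cls, counts: Sequence[int]) -> "CountDistribution":
        """Empirical distribution of a measured count sample."""
        vals, freq = np.unique(np.asarray(counts, dtype=np.int64), return_counts=True)
        probs = freq / freq.sum()
        return cls(values=tuple(int(v) for v in vals), probs=tuple(probs))

    def sample(self, rng: np.random.Generator, size: int | None = None):
        return rng.choice(np.array(self.values), size=size, p=np.array(self.probs))

    @property
    def mean(self) -> float:
        return float(np.dot(self.values, self.probs))


@dataclass(frozen=True)
class BasalSpec:
    """Pre-induction RNA count distributions.

    Defaults reflect the measured basal ranges: SgrS uniform on {1..3} and
    ptsG mRNA uniform on {30..40}.  Measured histograms can be plugged in
    via :meth:`CountDistribution.from_counts`.
    """

    sgrs: CountDistribution = field(
        default_factory=lambda: CountDistribution.uniform_range(1, 3)
    )
    ptsg: CountDistribution = field(
        default_factory=lambda: CountDistribution.uniform_range(30, 40)
    )


@dataclass(frozen=True)
class GeneConfiguration:
    """Per-cell gene dosage: *sgrS* in 2/4 copies, *ptsG* in 1/2.

    Variants without gene duplication use a single copy of each.
    """

    n_sgrS_genes: int
    n_ptsG_genes: int

    def __post_init__(self) -> None:
        if self.n_sgrS_genes not in (1, 2, 4):
            raise ConfigurationError(
                f"n_sgrS_genes must be 1, 2 or 4, got {self.n_sgrS_genes}"
            )
        if self.n_ptsG_genes not in (1, 2):
            raise ConfigurationError(
                f"n_ptsG_genes must be 1 or 2, got {self.n_ptsG_genes}"
            )


def sample_gene_configuration(
    params: KineticParameters, rng: np.random.Generator
) -> GeneConfiguration:
    """Independent coin flips for the high/low dosage state of each gene."""
    n_sgrs = 4 if rng.random() < params.f_high_sgrS else 2
    n_ptsg = 2 if rng.random() < params.f_high_ptsG else 1
    return GeneConfiguration(n_sgrs, n_ptsg)


def sample_initial_state(
    params: KineticParameters,
    gene_config: GeneConfiguration,
    basal_spec: BasalSpec,
    rng: np.random.Generator,
    variant: Variant | str = Variant.FULL,
) -> SpeciesState:
    """Pre-induction state: basal RNA, full free-Hfq pool, all genes OFF."""
    variant = Variant.coerce(variant)
    return SpeciesState(
        Ds_off=gene_config.n_sgrS_genes,
        Ds_on=0,
        Dp=gene_config.n_ptsG_genes,
        S=int(basal_spec.sgrs.sample(rng)),
        H=params.hfq_pool if variant.has_hfq else 0,
        HS=0,
        P=int(basal_spec.ptsg.sample(rng)),
        HSP=0,
    )


@dataclass(frozen=True)
class EnsembleResult:
    """Snapshots of every replicate at the scheduled timepoints."""

    params: KineticParameters
    variant: Variant
    schedule_min: np.ndarray  # (n_times,)
    species: tuple[str, ...]  # canonical 8-species order
    counts: np.ndarray  # (n_replicates, n_times, 8) int64
    gene_configs: np.ndarray  # (n_replicates, 2): sgrS copies, ptsG copies
    seeds: np.ndarray  # (n_replicates,)
    base_seed: int

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    def species_counts(self, name: str) -> np.ndarray:
        return self.counts[:, :, self.species.index(name)]

    def totals(self) -> tuple[np.ndarray, np.ndarray]:
        """(total SgrS, total ptsG) per replicate per timepoint."""
        s = self.species_counts("S") + self.species_counts("HS") + self.species_counts("HSP")
        p = self.species_counts("P") + self.species_counts("HSP")
        return s, p

    def to_tidy(self) -> pd.DataFrame:
        """Long format: one row per replicate per timepoint."""
        total_s, total_p = self.totals()
        n_rep, n_t = total_s.shape
        rep = np.repeat(np.arange(n_rep), n_t)
        return pd.DataFrame(
            {
                "replicate": rep,
                "time_min": np.tile(self.schedule_min, n_rep),
                "n_sgrS_genes": np.repeat(self.gene_configs[:, 0], n_t),
                "n_ptsG_genes": np.repeat(self.gene_configs[:, 1], n_t),
                "total_sgrs": total_s.ravel(),
                "total_ptsg": total_p.ravel(),
            }
        )

    def to_dataset(self, provenance: str = "simulated"):
        """View as a per-cell snapshot dataset (see :mod:`sugarshock.stats`)."""
        from .stats import SnapshotDataset

        total_s, total_p = self.totals()
        frames = []
        for j, t in enumerate(self.schedule_min):
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(self.n_replicates),
                        "time_min": float(t),
                        "species": "sgrs",
                        "count": total_s[:, j],
                    }
                )
            )
            frames.append(
                pd.DataFrame(
                    {
                        "cell_id": np.arange(self.n_replicates),
                        "time_min": float(t),
                        "species": "ptsg",
                        "count": total_p[:, j],
                    }
                )
            )
        return SnapshotDataset(pd.concat(frames, ignore_index=True), provenance)


def observables(state: SpeciesState) -> tuple[int, int]:
    """smFISH-comparable totals ``(total_sgrs, total_ptsg)``.

    Tiled fluorescent probes label a transcript whether or not it is bound
    by Hfq or engaged in the ternary complex, so labeled SgrS is
    ``S + HS + HSP`` and labeled ptsG mRNA is ``P + HSP``.
    """
    return state.total_sgrs, state.total_ptsg


def run_ensemble(
    params: KineticParameters,
    variant: Variant | str = Variant.FULL,
    n_replicates: int = 2000,
    schedule_min: Sequence[float] = DEFAULT_SCHEDULE_MIN,
    base_seed: int = 0,
    basal_spec: BasalSpec | None = None,
    horizon_s: float | None = None,
) -> EnsembleResult:
    """Run ``n_replicates`` independent cells and collect scheduled snapshots.

    Each replicate samples its gene configuration and basal RNA counts, then
    simulates the variant network with the Gillespie direct method.  Results
    are deterministic given ``base_seed``.
    """
    variant = Variant.coerce(variant)
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    basal_spec = basal_spec or BasalSpec()
    schedule = np.asarray(schedule_min, dtype=np.float64)
    if horizon_s is None:
        horizon_s = max(DEFAULT_HORIZON_S, float(schedule[-1]) * 60.0)
    record_times = schedule * 60.0
    if record_times[-1] > horizon_s:
        raise ConfigurationError("schedule extends beyond the simulation horizon")

    network = build_network(params, variant)
    sp_index = [network.species.index(s) if s in network.species else -1
                for s in SPECIES]

    n_t = schedule.size
    counts = np.zeros((n_replicates, n_t, len(SPECIES)), dtype=np.int64)
    gene_configs = np.zeros((n_replicates, 2), dtype=np.int64)
    seeds = np.zeros(n_replicates, dtype=np.int64)

    for i in range(n_replicates):
        seed_i = (int(base_seed) + i) % _MAX_SEED
        seeds[i] = seed_i
        setup_rng = np.random.default_rng(seed_i)
        try:
            if variant.has_gene_duplication:
                config = sample_gene_configuration(params, setup_rng)
            else:
                config = GeneConfiguration(1, 1)
            init = sample_initial_state(
                params, config, basal_spec, setup_rng, variant
            )
            traj = simulate(network, init, horizon_s, record_times, seed_i)
        except Exception as exc:
            raise type(exc)(f"replicate {i}: {exc}") from exc
        gene_configs[i] = (config.n_sgrS_genes, config.n_ptsG_genes)
        for full_idx, net_idx in enumerate(sp_index):
            if net_idx >= 0:
                counts[i, :, full_idx] = traj.counts[:, net_idx]

    return EnsembleResult(
        params=params,
        variant=variant,
        schedule_min=schedule,
        species=SPECIES,
        counts=counts,
        gene_configs=gene_configs,
        seeds=seeds,
        base_seed=int(base_seed),
    )
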