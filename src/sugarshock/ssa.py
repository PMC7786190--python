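"""Exact stochastic simulation via the Gillespie direct method.

The direct method samples the chemical master equation exactly: waiting
times are exponential in the total propensity ``a0`` and the firing channel
is chosen with probability ``a_j / a0``.  Copy numbers in this network are
small (tens of molecules), so the exact method is cheap and no approximate
acceleration is used.

States are recorded on a fixed time grid with last-event-before-time
semantics: the recorded state at time ``t`` is the state immediately before
the first event whose time exceeds ``t`` (the right-continuous step
function evaluated at ``t``).

The inner loop is JIT-compiled with numba when available; a pure-Python
fallback with the same draw order (one exponential, then one uniform per
event, legacy MT19937 stream) is used otherwise.  Either way a trajectory
is bit-reproducible from ``(network, initial state, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, StructuralError
from .network import SPECIES, ReactionNetwork, SpeciesState, propensities

__all__ = ["Trajectory", "step", "simulate"]

_MAX_SEED = 2**31


def _python_kernel(stoich, r1, r2, rates, state, record_times, seed):
    rng = np.random.RandomState(seed)
    n_rec = record_times.shape[0]
    n_ch = rates.shape[0]
    out = np.empty((n_rec, state.shape[0]), dtype=np.int64)
    a = np.empty(n_ch)
    t = 0.0
    k = 0
    while k < n_rec:
        a0 = 0.0
        for j in range(n_ch):
            p = rates[j]
            i1 = r1[j]
            if i1 >= 0:
                p *= state[i1]
            i2 = r2[j]
            if i2 >= 0:
                p *= state[i2]
            a[j] = p
            a0 += p
        if a0 <= 0.0:
            while k < n_rec:
                out[k] = state
                k += 1
            break
        t_next = t + rng.exponential(1.0 / a0)
        while k < n_rec and record_times[k] < t_next:
            out[k] = state
            k += 1
        if k >= n_rec:
            break
        r = rng.random_sample() * a0
        c = 0.0
        j_sel = n_ch - 1
        for j in range(n_ch):
            c += a[j]
            if r < c:
                j_sel = j
                break
        state += stoich[j_sel]
        t = t_next
    return out


def _make_numba_kernel():
    import numba

    @numba.njit(cache=False)
    def kernel(stoich, r1, r2, rates, state, record_times, seed):
        np.random.seed(seed)
        n_rec = record_times.shape[0]
        n_ch = rates.shape[0]
        out = np.empty((n_rec, state.shape[0]), dtype=np.int64)
        a = np.empty(n_ch)
        t = 0.0
        k = 0
        while k < n_rec:
            a0 = 0.0
            for j in range(n_ch):
                p = rates[j]
                i1 = r1[j]
                if i1 >= 0:
                    p *= state[i1]
                i2 = r2[j]
                if i2 >= 0:
                    p *= state[i2]
                a[j] = p
                a0 += p
            if a0 <= 0.0:
                while k < n_rec:
                    out[k] = state
                    k += 1
                break
            t_next = t + np.random.exponential(1.0 / a0)
            while k < n_rec and record_times[k] < t_next:
                out[k] = state
                k += 1
            if k >= n_rec:
                break
            r = np.random.random() * a0
            c = 0.0
            j_sel = n_ch - 1
            for j in range(n_ch):
                c += a[j]
                if r < c:
                    j_sel = j
                    break
            state += stoich[j_sel]
            t = t_next
        return out

    return kernel


try:  # numba accelerates the event loop by ~two orders of magnitude
    _numba_kernel = _make_numba_kernel()
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is declared as a dependency
    _numba_kernel = _python_kernel
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class Trajectory:
    """States of one replicate on a fixed recording grid."""

    species: tuple[str, ...]
    record_times: np.ndarray  # seconds, strictly increasing
    counts: np.ndarray  # (n_times, n_species) int64
    seed: int

    @property
    def states(self) -> list[SpeciesState]:
        return [
            SpeciesState.from_vector(row, self.species) for row in self.counts
        ]

    def count(self, species_name: str) -> np.ndarray:
        try:
            idx = self.species.index(species_name)
        except ValueError as exc:
            raise StructuralError(f"no species {species_name!r}") from exc
        return self.counts[:, idx]

    def to_tidy(self, replicate: int = 0) -> pd.DataFrame:
        """Long-format table (time_s, species, count, replicate)."""
        n_t, n_sp = self.counts.shape
        return pd.DataFrame(
            {
                "time_s": np.repeat(self.record_times, n_sp),
                "species": np.tile(np.asarray(self.species, dtype=object), n_t),
                "count": self.counts.ravel(),
                "replicate": replicate,
            }
        )


def step(
    network: ReactionNetwork,
    state: SpeciesState,
    rng: np.random.Generator,
) -> tuple[float, Optional[int]]:
    """One direct-method draw: ``(waiting time, channel index)``.

    Returns ``(inf, None)`` at an absorbing state (total propensity zero).
    """
    a = propensities(network, state)
    if np.any(a < 0):  # pragma: no cover - unreachable for valid params
        raise StructuralError("negative propensity encountered")
    a0 = float(a.sum())
    if a0 <= 0.0:
        return float("inf"), None
    tau = rng.exponential(1.0 / a0)
    channel = int(np.searchsorted(np.cumsum(a), rng.random() * a0, side="right"))
    return tau, min(channel, len(a) - 1)


def simulate(
    network: ReactionNetwork,
    init_state: SpeciesState,
    horizon: float,
    record_times: Sequence[float],
    seed: int,
) -> Trajectory:
    """Simulate one replicate and record states on ``record_times``.

    ``record_times`` (seconds) must be strictly increasing and lie within
    ``[0, horizon]``.  The result is bit-reproducible from the seed.
    """
    if not horizon > 0:
        raise DataError(f"horizon must be positive, got {horizon!r}")
    times = np.asarray(record_times, dtype=np.float64)
    if times.ndim != 1 or times.size == 0:
        raise DataError("record_times must be a non-empty 1-D sequence")
    if np.any(np.diff(times) <= 0):
        raise DataError("record_times must be strictly increasing")
    if times[0] < 0 or times[-1] > horizon:
        raise DataError("record_times must lie within [0, horizon]")
    seed = int(seed) % _MAX_SEED
    stoich, r1, r2, rates = network.compiled()
    state0 = init_state.as_vector(network.species)
    counts = _numba_kernel(stoich, r1, r2, rates, state0.copy(), times, seed)
    return Trajectory(
        species=network.species,
        record_times=times,
        counts=np.asarray(counts),
        seed=seed,
    )
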