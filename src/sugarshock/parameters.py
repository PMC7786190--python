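"""Kinetic parameters of the SgrS--ptsG silencing network.

The model describes the glucose-phosphate ("sugar shock") stress response of
*E. coli*: upon induction the transcription factor SgrR activates the small
RNA SgrS, which is stabilized by the RNA chaperone Hfq and, as an Hfq--SgrS
complex, anneals to *ptsG* mRNA; the ternary complex is co-degraded by
RNase E.  All first-order rate constants are in s^-1; the annealing rate
``k_on`` is per molecule per second; gene-state fractions are probabilities;
the Hfq pool is a molecule count.

Parameter roles
---------------
k_t_p      constitutive *ptsG* transcription per gene copy (Mlc repression is
           relieved under stress and is not modeled).
beta_p     degradation of free *ptsG* mRNA.
k_on_Ds,   switching of each *sgrS* gene copy between the transcriptionally
k_off_Ds   OFF and ON states (SgrR activation/deactivation).
k_t_s      SgrS transcription per ON *sgrS* gene copy.
k_ds       degradation of free (Hfq-unbound) SgrS -- the decay rate measured
           in an hfq deletion strain.
k_bind     pseudo-first-order SgrS+Hfq association at the nominal free pool.
k_unbind   rate-limiting loss of SgrS from the Hfq--SgrS complex, equal to
           the SgrS decay rate measured with Hfq present.
k_on       Hfq--SgrS annealing to *ptsG* mRNA (bimolecular, per molecule).
k_off      dissociation of the Hfq--SgrS--ptsG ternary complex.
k_cat      RNase-E co-degradation of the ternary complex (Hfq recycled).
f_high_*   probability that a cell carries the high gene-dosage state
           (4 *sgrS* copies / 2 *ptsG* copies) due to overlapping
           replication forks in fast-growing cells.
hfq_pool   Hfq hexamers effectively available to the SgrS regulon.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any, Mapping

from .errors import ConfigurationError

__all__ = [
    "KineticParameters",
    "WT",
    "U224G_OVERRIDES",
    "PARAMETER_UNCERTAINTY",
    "RATE_FIELDS",
    "FRACTION_FIELDS",
    "preset",
]

#: Names of non-negative first-order / bimolecular rate constants.
RATE_FIELDS = (
    "k_t_p",
    "beta_p",
    "k_on_Ds",
    "k_off_Ds",
    "k_t_s",
    "k_ds",
    "k_bind",
    "k_unbind",
    "k_on",
    "k_off",
    "k_cat",
)

#: Names of [0, 1] gene-dosage fractions.
FRACTION_FIELDS = ("f_high_sgrS", "f_high_ptsG")


@dataclass(frozen=True)
class KineticParameters:
    """Complete parameterization of the wild-type silencing network.

    Defaults are the wild-type values; the U224G polyU-tail point mutant is
    obtained with :func:`preset` and differs only in the four Hfq-related
    rates (``k_bind``, ``k_unbind``, ``k_on``, ``k_off``).
    """

    k_t_p: float = 0.12
    beta_p: float = 3.7e-3
    k_on_Ds: float = 3.0e-2
    k_off_Ds: float = 9.5e-3
    k_t_s: float = 0.33
    k_ds: float = 0.022
    k_bind: float = 0.063
    k_unbind: float = 0.0018
    k_on: float = 3.1e-4
    k_off: float = 0.22
    k_cat: float = 0.3
    f_high_sgrS: float = 0.25
    f_high_ptsG: float = 0.46
    hfq_pool: int = 250

    def __post_init__(self) -> None:
        for name in RATE_FIELDS:
            value = getattr(self, name)
            if not (value >= 0.0):  # also rejects NaN
                raise ConfigurationError(f"rate {name!r} must be >= 0, got {value!r}")
        for name in FRACTION_FIELDS:
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigurationError(
                    f"fraction {name!r} must lie in [0, 1], got {value!r}"
                )
        pool = self.hfq_pool
        if not (isinstance(pool, (int,)) or float(pool).is_integer()) or pool < 0:
            raise ConfigurationError(
                f"hfq_pool must be a non-negative integer, got {pool!r}"
            )
        object.__setattr__(self, "hfq_pool", int(pool))

    def replace(self, **changes: Any) -> "KineticParameters":
        """Return a copy with the named fields replaced (and re-validated)."""
        unknown = set(changes) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, values: Mapping[str, Any]) -> "KineticParameters":
        unknown = set(values) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**dict(values))


#: Wild-type defaults.
WT = KineticParameters()

#: The four Hfq-association rates refitted for the U224G polyU-tail mutant.
U224G_OVERRIDES: dict[str, float] = {
    "k_bind": 0.033,
    "k_unbind": 0.003,
    "k_on": 2.1e-4,
    "k_off": 0.27,
}

#: Reported one-sigma uncertainties on the wild-type parameters, used by the
#: fitting recovery experiments as target bands.
PARAMETER_UNCERTAINTY: dict[str, float] = {
    "k_t_p": 0.01,
    "beta_p": 0.5e-3,
    "k_on_Ds": 0.1e-2,
    "k_off_Ds": 0.1e-3,
    "k_t_s": 0.01,
    "k_ds": 0.002,
    "k_bind": 0.014,
    "k_unbind": 0.0004,
    "k_on": 0.2e-4,
    "k_off": 0.02,
    "k_cat": 0.1,
    "f_high_sgrS": 0.12,
    "f_high_ptsG": 0.20,
    "hfq_pool": 167,
}


def preset(name: str) -> KineticParameters:
    """Return a named parameter preset: ``"WT"`` or ``"U224G"``."""
    key = name.upper()
    if key == "WT":
        return WT
    if key == "U224G":
        return WT.replace(**U224G_OVERRIDES)
    raise ConfigurationError(f"unknown parameter preset {name!r}; use 'WT' or 'U224G'")
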