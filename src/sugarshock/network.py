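"""Reaction network of the SgrS regulatory circuit and its reduced variants.

Species
-------
Ds_off / Ds_on   inactive / SgrR-activated *sgrS* gene copies
Dp               *ptsG* gene copies (constitutively transcribed)
S                free SgrS sRNA
H                free Hfq (pool available to the SgrS regulon)
HS               Hfq--SgrS complex
P                free *ptsG* mRNA
HSP              Hfq--SgrS--ptsG ternary complex (or the direct SgrS--ptsG
                 duplex in the Hfq-free baseline variant)

The full model has 11 mass-action channels.  Hfq binding is a true
bimolecular channel with microscopic constant ``k_bind / hfq_pool`` so that
the pseudo-first-order rate is recovered exactly when the pool is free while
depletion of free Hfq slows binding.  Loss of SgrS from the Hfq--SgrS
complex consumes the sRNA (``HS -> H``): the unbinding rate is calibrated to
the measured SgrS decay rate with Hfq present, under the assumption that
unbinding is the rate-limiting step of that decay; releasing intact SgrS
would let instant rebinding inflate the effective lifetime far beyond the
measurement.  Co-degradation of the ternary complex recycles Hfq, so
``H + HS + HSP`` is conserved.

Variants (used for the model-complexity ladder):

``FULL``                regulation + gene duplication + explicit Hfq.
``NO_REG``              gene switching removed; every *sgrS* copy
                        transcribes regardless of state.
``NO_GENEDUP``          single copy of each gene (dosage sampling disabled).
``NO_HFQ_NO_GENEDUP``   additionally removes Hfq: SgrS binds *ptsG* mRNA
                        directly and free SgrS decays at the with-Hfq
                        effective rate -- the constitutive single-copy
                        baseline model.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, StructuralError
from .parameters import KineticParameters

__all__ = [
    "SPECIES",
    "Variant",
    "SpeciesState",
    "Reaction",
    "ReactionNetwork",
    "build_network",
    "propensities",
]

#: Canonical species order for the full model.
SPECIES = ("Ds_off", "Ds_on", "Dp", "S", "H", "HS", "P", "HSP")


class Variant(str, enum.Enum):
    """Model-complexity variant tags."""

    FULL = "FULL"
    NO_REG = "NO_REG"
    NO_GENEDUP = "NO_GENEDUP"
    NO_HFQ_NO_GENEDUP = "NO_HFQ_NO_GENEDUP"

    @property
    def has_regulation(self) -> bool:
        return self in (Variant.FULL, Variant.NO_GENEDUP)

    @property
    def has_gene_duplication(self) -> bool:
        return self in (Variant.FULL, Variant.NO_REG)

    @property
    def has_hfq(self) -> bool:
        return self is not Variant.NO_HFQ_NO_GENEDUP

    @classmethod
    def coerce(cls, value: "Variant | str") -> "Variant":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).upper())
        except ValueError as exc:
            raise ConfigurationError(
                f"unknown model variant {value!r}; expected one of "
                f"{[v.value for v in cls]}"
            ) from exc


#: Ladder order for variant comparison, from the reduced baseline upward.
LADDER = (
    Variant.NO_HFQ_NO_GENEDUP,
    Variant.NO_GENEDUP,
    Variant.NO_REG,
    Variant.FULL,
)


@dataclass(frozen=True)
class SpeciesState:
    """Integer molecule counts for the eight model species.

    In Hfq-free variants ``H`` and ``HS`` must be zero and ``HSP`` holds the
    direct SgrS--ptsG duplex.
    """

    Ds_off: int = 0
    Ds_on: int = 0
    Dp: int = 0
    S: int = 0
    H: int = 0
    HS: int = 0
    P: int = 0
    HSP: int = 0

    def __post_init__(self) -> None:
        for name in SPECIES:
            value = getattr(self, name)
            if not float(value).is_integer() or value < 0:
                raise StructuralError(
                    f"species count {name} must be a non-negative integer, "
                    f"got {value!r}"
                )
            object.__setattr__(self, name, int(value))

    def as_vector(self, species: Sequence[str] = SPECIES) -> np.ndarray:
        """Counts in the order of ``species``; any omitted species must be 0."""
        omitted = set(SPECIES) - set(species)
        for name in omitted:
            if getattr(self, name) != 0:
                raise StructuralError(
                    f"state has {name}={getattr(self, name)} but the network "
                    f"does not contain species {name!r}"
                )
        return np.array([getattr(self, name) for name in species], dtype=np.int64)

    @classmethod
    def from_vector(
        cls, counts: Iterable[int], species: Sequence[str] = SPECIES
    ) -> "SpeciesState":
        return cls(**{name: int(c) for name, c in zip(species, counts, strict=True)})

    @property
    def total_sgrs(self) -> int:
        """smFISH-labeled SgrS: free + Hfq-bound + in the ternary complex."""
        return self.S + self.HS + self.HSP

    @property
    def total_ptsg(self) -> int:
        """smFISH-labeled ptsG mRNA: free + in the ternary complex."""
        return self.P + self.HSP


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel.

    ``reactants`` lists the species whose counts multiply the rate constant
    (at most two, always distinct species in this model); ``stoich`` maps
    species name -> net change when the channel fires.
    """

    name: str
    rate_name: str
    rate_value: float
    reactants: tuple[str, ...]
    stoich: dict[str, int]


@dataclass(frozen=True)
class ReactionNetwork:
    """A variant-tagged list of channels over an ordered species tuple."""

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    variant: Variant
    params: KineticParameters

    @property
    def n_channels(self) -> int:
        return len(self.reactions)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError as exc:
            raise StructuralError(f"species {name!r} not in network") from exc

    def compiled(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Arrays for the SSA kernel.

        Returns ``(stoich, r1, r2, rates)`` where ``stoich`` is the
        (channels x species) net-change matrix, ``r1``/``r2`` are reactant
        species indices (-1 where absent) and ``rates`` the rate constants.
        """
        n_ch, n_sp = self.n_channels, self.n_species
        stoich = np.zeros((n_ch, n_sp), dtype=np.int64)
        r1 = np.full(n_ch, -1, dtype=np.int64)
        r2 = np.full(n_ch, -1, dtype=np.int64)
        rates = np.zeros(n_ch, dtype=np.float64)
        for j, rxn in enumerate(self.reactions):
            rates[j] = rxn.rate_value
            for name, change in rxn.stoich.items():
                stoich[j, self.species_index(name)] = change
            if len(rxn.reactants) > 0:
                r1[j] = self.species_index(rxn.reactants[0])
            if len(rxn.reactants) > 1:
                r2[j] = self.species_index(rxn.reactants[1])
            if len(rxn.reactants) > 2:  # pragma: no cover - not constructible
                raise StructuralError("at most bimolecular channels supported")
        return stoich, r1, r2, rates

    def apply(self, state: SpeciesState, channel: int) -> SpeciesState:
        """State after firing ``channel`` once (validates the result)."""
        rxn = self.reactions[channel]
        counts = {name: getattr(state, name) for name in SPECIES}
        for name, change in rxn.stoich.items():
            counts[name] += change
        return SpeciesState(**counts)

    # -- serialization ----------------------------------------------------

    def to_records(self) -> list[dict]:
        """Plain channel table (JSON-friendly) for inspection/golden files."""
        return [
            {
                "channel": j + 1,
                "name": rxn.name,
                "rate_name": rxn.rate_name,
                "rate_value": rxn.rate_value,
                "reactants": list(rxn.reactants),
                "stoichiometry": dict(rxn.stoich),
            }
            for j, rxn in enumerate(self.reactions)
        ]

    def to_json(self, indent: int = 2) -> str:
        payload = {
            "variant": self.variant.value,
            "species": list(self.species),
            "channels": self.to_records(),
        }
        return json.dumps(payload, indent=indent)


def _full_channels(p: KineticParameters, regulated: bool) -> list[Reaction]:
    channels: list[Reaction] = []
    if regulated:
        channels += [
            Reaction("sgrS_gene_activation", "k_on_Ds", p.k_on_Ds,
                     ("Ds_off",), {"Ds_off": -1, "Ds_on": +1}),
            Reaction("sgrS_gene_deactivation", "k_off_Ds", p.k_off_Ds,
                     ("Ds_on",), {"Ds_on": -1, "Ds_off": +1}),
            Reaction("sgrS_transcription", "k_t_s", p.k_t_s,
                     ("Ds_on",), {"S": +1}),
        ]
    else:
        # Unregulated variants transcribe from every sgrS copy regardless of
        # its switching state, so both gene species carry a transcription
        # channel and the OFF/ON split becomes inert.
        channels += [
            Reaction("sgrS_transcription_off_state", "k_t_s", p.k_t_s,
                     ("Ds_off",), {"S": +1}),
            Reaction("sgrS_transcription_on_state", "k_t_s", p.k_t_s,
                     ("Ds_on",), {"S": +1}),
        ]
    channels += [
        Reaction("ptsG_transcription", "k_t_p", p.k_t_p, ("Dp",), {"P": +1}),
        Reaction("ptsG_degradation", "beta_p", p.beta_p, ("P",), {"P": -1}),
    ]
    return channels


def build_network(
    params: KineticParameters, variant: Variant | str = Variant.FULL
) -> ReactionNetwork:
    """Construct the reaction network for a model variant.

    The FULL network has exactly 11 channels over 8 species; NO_REG has 10
    (gene switching removed, one transcription channel per gene-state
    species); NO_GENEDUP shares the FULL channel list but is simulated with
    single gene copies; NO_HFQ_NO_GENEDUP has 8 channels over 6 species
    (no H/HS), with direct SgrS--ptsG binding and free-SgrS decay at the
    with-Hfq effective rate ``k_unbind``.
    """
    variant = Variant.coerce(variant)
    p = params
    if variant.has_hfq:
        if p.hfq_pool <= 0:
            raise ConfigurationError(
                "hfq_pool must be positive for variants with explicit Hfq "
                "(the bimolecular binding constant is k_bind / hfq_pool)"
            )
        channels = _full_channels(p, regulated=variant.has_regulation)
        channels += [
            Reaction("sgrS_degradation_free", "k_ds", p.k_ds, ("S",), {"S": -1}),
            Reaction("hfq_sgrs_binding", "k_bind/hfq_pool",
                     p.k_bind / p.hfq_pool, ("S", "H"),
                     {"S": -1, "H": -1, "HS": +1}),
            Reaction("hfq_sgrs_unbinding_degradation", "k_unbind", p.k_unbind,
                     ("HS",), {"HS": -1, "H": +1}),
            Reaction("ternary_annealing", "k_on", p.k_on, ("HS", "P"),
                     {"HS": -1, "P": -1, "HSP": +1}),
            Reaction("ternary_dissociation", "k_off", p.k_off, ("HSP",),
                     {"HSP": -1, "HS": +1, "P": +1}),
            Reaction("ternary_codegradation", "k_cat", p.k_cat, ("HSP",),
                     {"HSP": -1, "H": +1}),
        ]
        species = SPECIES
    else:
        channels = _full_channels(p, regulated=False)
        channels += [
            Reaction("sgrS_degradation_effective", "k_unbind", p.k_unbind,
                     ("S",), {"S": -1}),
            Reaction("duplex_annealing", "k_on", p.k_on, ("S", "P"),
                     {"S": -1, "P": -1, "HSP": +1}),
            Reaction("duplex_dissociation", "k_off", p.k_off, ("HSP",),
                     {"HSP": -1, "S": +1, "P": +1}),
            Reaction("duplex_codegradation", "k_cat", p.k_cat, ("HSP",),
                     {"HSP": -1}),
        ]
        species = ("Ds_off", "Ds_on", "Dp", "S", "P", "HSP")
    return ReactionNetwork(
        species=tuple(species),
        reactions=tuple(channels),
        variant=variant,
        params=params,
    )


def propensities(network: ReactionNetwork, state: SpeciesState) -> np.ndarray:
    """Mass-action propensity of every channel at ``state``.

    Element ``j`` equals the channel's rate constant times the product of
    its reactant counts.
    """
    vec = state.as_vector(network.species)
    _, r1, r2, rates = network.compiled()
    a = rates.copy()
    mask1 = r1 >= 0
    a[mask1] *= vec[r1[mask1]]
    mask2 = r2 >= 0
    a[mask2] *= vec[r2[mask2]]
    return a


def check_hfq_conservation(network: ReactionNetwork, state: SpeciesState) -> bool:
    """Whether ``H + HS + HSP`` equals the configured Hfq pool (Hfq variants)."""
    if not network.variant.has_hfq:
        return True
    return state.H + state.HS + state.HSP == network.params.hfq_pool
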