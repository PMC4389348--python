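"""Declarative binding-site models and microstate enumeration.

A model is a set of named binding sites, each of which is always in exactly
one *configuration* (the first configuration is always ``"empty"``).  Ligand
species map (site, configuration) assignments to bound-molecule counts,
pairwise exclusion rules encode steric overlap, and additive free-energy
terms (kcal/mol) assign each joint assignment its standard free energy.

A *microstate* is one joint assignment of configurations to all sites that
violates no exclusion rule.  Enumeration is deterministic: lexicographic over
sites in declaration order and configurations in declared order, with 0-based
indices.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

EMPTY = "empty"

Assignment = tuple[str, str]  # (site, configuration)

__all__ = [
    "EMPTY",
    "SiteSpec",
    "LigandSpec",
    "ExclusionRule",
    "EnergyTerm",
    "Microstate",
    "ModelSpec",
    "ModelError",
    "validate_model",
    "enumerate_microstates",
    "microstate_energy",
    "config_matrix",
]


class ModelError(ValueError):
    """Raised for invalid model specifications or enumeration failures."""


@dataclass(frozen=True)
class SiteSpec:
    """One binding site: name, ordered configurations, and a kind tag.

    ``configurations[0]`` must be ``"empty"``; operators typically carry
    ``("empty", "CI2", "Cro2")`` and promoters ``("empty", "RNAP")``.
    """

    name: str
    configurations: tuple[str, ...]
    kind: str = "other"  # one of {"operator", "promoter", "other"}

    def __post_init__(self) -> None:
        object.__setattr__(self, "configurations", tuple(self.configurations))


@dataclass(frozen=True)
class LigandSpec:
    """A ligand species and the (site, configuration) pairs it occupies.

    Each listed pair counts as one bound molecule of the species in any
    microstate satisfying it.
    """

    species: str
    occupancy_map: frozenset[Assignment]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "occupancy_map", frozenset(tuple(p) for p in self.occupancy_map)
        )


@dataclass(frozen=True)
class ExclusionRule:
    """Forbids two (site, configuration) assignments from co-occurring."""

    assignment_a: Assignment
    assignment_b: Assignment

    def __post_init__(self) -> None:
        object.__setattr__(self, "assignment_a", tuple(self.assignment_a))
        object.__setattr__(self, "assignment_b", tuple(self.assignment_b))

    @property
    def pair(self) -> frozenset[Assignment]:
        return frozenset((self.assignment_a, self.assignment_b))


@dataclass(frozen=True)
class EnergyTerm:
    """An additive free-energy contribution, in kcal/mol.

    The term contributes ``delta_g`` iff *all* assignments in ``condition``
    hold in a microstate.  Singleton conditions encode intrinsic binding
    energies; two-assignment conditions pairwise cooperativity; larger
    conditions multi-site effects such as DNA looping.
    """

    condition: frozenset[Assignment]
    delta_g: float
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "condition", frozenset(tuple(p) for p in self.condition)
        )


@dataclass(frozen=True)
class Microstate:
    """One joint assignment of configurations to all sites."""

    index: int
    assignment: Mapping[str, str]
    stoichiometry: Mapping[str, int]
    delta_g: float

    def chi(self, site: str, configuration: str) -> int:
        """Indicator: 1 iff this microstate has ``site`` in ``configuration``."""
        return int(self.assignment[site] == configuration)


@dataclass
class ModelSpec:
    """A complete binding-site model."""

    sites: list[SiteSpec] = field(default_factory=list)
    ligands: list[LigandSpec] = field(default_factory=list)
    exclusions: list[ExclusionRule] = field(default_factory=list)
    energy_terms: list[EnergyTerm] = field(default_factory=list)

    @property
    def site_names(self) -> list[str]:
        return [s.name for s in self.sites]

    @property
    def species_names(self) -> list[str]:
        return [l.species for l in self.ligands]

    def site(self, name: str) -> SiteSpec:
        for s in self.sites:
            if s.name == name:
                return s
        raise ModelError(f"unknown site {name!r}")

    def site_index(self, name: str) -> int:
        for i, s in enumerate(self.sites):
            if s.name == name:
                return i
        raise ModelError(f"unknown site {name!r}")

    def assignments(self) -> set[Assignment]:
        """All valid (site, configuration) pairs."""
        return {(s.name, c) for s in self.sites for c in s.configurations}


def validate_model(spec: ModelSpec) -> list[str]:
    """Check every structural invariant; return diagnostics (empty iff valid)."""
    diags: list[str] = []
    seen: set[str] = set()
    for s in spec.sites:
        if s.name in seen:
            diags.append(f"duplicate site name {s.name!r}")
        seen.add(s.name)
        if len(s.configurations) < 2:
            diags.append(f"site {s.name!r} has fewer than 2 configurations")
        if s.configurations.count(EMPTY) != 1 or (
            s.configurations and s.configurations[0] != EMPTY
        ):
            diags.append(
                f"site {s.name!r} must list {EMPTY!r} exactly once and first"
            )
        if len(set(s.configurations)) != len(s.configurations):
            diags.append(f"site {s.name!r} has duplicate configurations")
        if s.kind not in ("operator", "promoter", "other"):
            diags.append(f"site {s.name!r} has unknown kind {s.kind!r}")

    valid = spec.assignments()
    claimed: dict[Assignment, str] = {}
    for lig in spec.ligands:
        for pair in lig.occupancy_map:
            if pair not in valid:
                diags.append(
                    f"ligand {lig.species!r} references unknown assignment {pair}"
                )
            elif pair[1] == EMPTY:
                diags.append(
                    f"ligand {lig.species!r} claims the empty configuration at "
                    f"site {pair[0]!r}"
                )
            if pair in claimed and claimed[pair] != lig.species:
                diags.append(
                    f"assignment {pair} claimed by both {claimed[pair]!r} "
                    f"and {lig.species!r}"
                )
            claimed[pair] = lig.species

    for rule in spec.exclusions:
        for pair in (rule.assignment_a, rule.assignment_b):
            if pair not in valid:
                diags.append(f"exclusion references unknown assignment {pair}")
        if rule.assignment_a[0] == rule.assignment_b[0]:
            diags.append(
                f"exclusion {rule.assignment_a} / {rule.assignment_b} "
                "involves a single site"
            )

    for term in spec.energy_terms:
        if not term.condition:
            diags.append(f"energy term {term.label!r} has an empty condition")
        for pair in term.condition:
            if pair not in valid:
                diags.append(
                    f"energy term {term.label or term.condition!r} references "
                    f"unknown assignment {pair}"
                )
    return diags


def microstate_energy(
    assignment: Mapping[str, str], energy_terms: Iterable[EnergyTerm]
) -> float:
    """Free energy of a joint assignment: sum of all satisfied terms (kcal/mol)."""
    total = 0.0
    for term in energy_terms:
        if all(assignment.get(site) == cfg for site, cfg in term.condition):
            total += term.delta_g
    return total


def enumerate_microstates(
    spec: ModelSpec, max_states: int = 200_000
) -> list[Microstate]:
    """Enumerate all exclusion-respecting microstates, deterministically ordered.

    Order is lexicographic over sites in declaration order, configurations in
    their declared order; indices are 0-based over the surviving states.

    Raises
    ------
    ModelError
        If the model fails validation, or the unconstrained product of
        configuration counts exceeds ``max_states``.
    """
    diags = validate_model(spec)
    if diags:
        raise ModelError("invalid model: " + "; ".join(diags))
    n_raw = 1
    for s in spec.sites:
        n_raw *= len(s.configurations)
    if n_raw > max_states:
        raise ModelError(
            f"unconstrained state count {n_raw} exceeds cap {max_states}; "
            "raise max_states only if you know the model is tractable"
        )

    names = spec.site_names
    forbidden = [r.pair for r in spec.exclusions]
    states: list[Microstate] = []
    idx = 0
    for combo in itertools.product(*(s.configurations for s in spec.sites)):
        assignment = dict(zip(names, combo))
        pairs = set(assignment.items())
        if any(f <= pairs for f in forbidden):
            continue
        stoich = {
            lig.species: sum(1 for p in lig.occupancy_map if p in pairs)
            for lig in spec.ligands
        }
        states.append(
            Microstate(
                index=idx,
                assignment=assignment,
                stoichiometry=stoich,
                delta_g=microstate_energy(assignment, spec.energy_terms),
            )
        )
        idx += 1
    return states


def config_matrix(spec: ModelSpec, microstates: Sequence[Microstate]) -> np.ndarray:
    """(n_states, n_sites) integer matrix of per-site configuration indices."""
    cfg_index = [
        {c: k for k, c in enumerate(s.configurations)} for s in spec.sites
    ]
    out = np.empty((len(microstates), len(spec.sites)), dtype=np.int64)
    for i, ms in enumerate(microstates):
        for j, s in enumerate(spec.sites):
            out[i, j] = cfg_index[j][ms.assignment[s.name]]
    return out
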