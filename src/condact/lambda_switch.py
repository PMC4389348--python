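"""The phage-lambda lysogeny/lysis switch model instance.

Nine binding sites on the prophage DNA: the right operator O_R1..O_R3
flanked by the promoters P_R (cro transcription) and P_RM (cI
transcription), and the left operator O_L1..O_L3 with the promoter P_L.
Operator sites bind a CI dimer or a Cro dimer; promoters bind RNA
polymerase.  Steric overlap: RNAP at P_R blocks O_R1 and O_R2, RNAP at P_RM
blocks O_R3, and RNAP at P_L blocks O_L1 and O_L2.  With those exclusions
the nine sites admit 1200 microstates (40 right-operator joint
configurations x 30 left-operator ones).

Free energies enter as an additive parameter set: intrinsic binding energies
per (site, species), pairwise cooperativities, and multi-site DNA-looping
terms (e.g. the CI octamer bridging O_R1,O_R2,O_L1,O_L2).  Numerical values
must be transcribed from the experimental literature into the shipped
parameter file; the loader refuses to produce a pathway report from a
placeholder (value-free) file unless explicitly overridden, so that no
unvetted numbers silently masquerade as measured ones.

Lysogeny and lysis are two fixed concentration conditions for CI2, Cro2,
and RNAP.  The tendency to switch toward lysis is reported through the
stationary binding statistics of RNAP at P_R (more RNAP at P_R means faster
Cro production).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import ca_analytic, kinetics, thermo
from .model_core import (
    EnergyTerm,
    ExclusionRule,
    LigandSpec,
    Microstate,
    ModelSpec,
    SiteSpec,
    enumerate_microstates,
)
from .thermo import Condition, EquilibriumDistribution

__all__ = [
    "OPERATOR_SITES",
    "PROMOTER_SITES",
    "SITE_ORDER",
    "OVERLAPS",
    "LambdaParameterSet",
    "LambdaCondition",
    "PlaceholderParameterError",
    "build_lambda_model",
    "right_operator_submodel",
    "project_to_right_operator",
    "pathway_report",
    "load_lambda_parameters",
    "load_lambda_condition",
    "synthetic_parameters",
    "zero_parameters",
]

OPERATOR_SITES = ("O_R1", "O_R2", "O_R3", "O_L1", "O_L2", "O_L3")
PROMOTER_SITES = ("P_R", "P_RM", "P_L")
# Declaration order groups the right-operator complex first so that the
# right x left factorization (40 x 30 = 1200) is visible in the indexing.
SITE_ORDER = ("O_R1", "O_R2", "O_R3", "P_R", "P_RM", "O_L1", "O_L2", "O_L3", "P_L")
RIGHT_SITES = ("O_R1", "O_R2", "O_R3", "P_R", "P_RM")
LEFT_SITES = ("O_L1", "O_L2", "O_L3", "P_L")

# Steric overlap: RNAP at each promoter blocks the listed operator sites.
OVERLAPS: dict[str, tuple[str, ...]] = {
    "P_R": ("O_R1", "O_R2"),
    "P_RM": ("O_R3",),
    "P_L": ("O_L1", "O_L2"),
}

OPERATOR_SPECIES = ("CI2", "Cro2")
SPECIES = ("CI2", "Cro2", "RNAP")


class PlaceholderParameterError(ValueError):
    """A parameter or condition file still contains placeholder (null) values."""


@dataclass
class LambdaParameterSet:
    """Free-energy inputs of the lambda switch, in kcal/mol.

    ``intrinsic_energies`` must cover every allowed (site, species) pair:
    each operator site for CI2 and Cro2, each promoter for RNAP.  Pairwise
    cooperativities and looping terms are optional.  ``provenance`` carries a
    citation string per named value; ``placeholder`` marks a schema-complete
    set whose numbers have not been transcribed from the literature.
    """

    intrinsic_energies: dict[tuple[str, str], float] = field(default_factory=dict)
    pair_cooperativities: dict[
        tuple[tuple[str, str], tuple[str, str]], float
    ] = field(default_factory=dict)
    looping_terms: list[EnergyTerm] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)
    placeholder: bool = False

    def missing_intrinsic(self) -> list[tuple[str, str]]:
        required = [(s, sp) for s in OPERATOR_SITES for sp in OPERATOR_SPECIES]
        required += [(p, "RNAP") for p in PROMOTER_SITES]
        return [k for k in required if k not in self.intrinsic_energies]


@dataclass
class LambdaCondition:
    """One pathway preset: a tag plus the thermodynamic condition."""

    pathway: str  # "lysogenic" or "lytic"
    condition: Condition

    def __post_init__(self) -> None:
        missing = [s for s in SPECIES if s not in self.condition.concentrations]
        if missing:
            raise ValueError(f"lambda condition lacks concentrations for {missing}")


def _site_specs(names: Sequence[str]) -> list[SiteSpec]:
    out = []
    for name in names:
        if name in PROMOTER_SITES:
            out.append(SiteSpec(name, ("empty", "RNAP"), kind="promoter"))
        else:
            out.append(SiteSpec(name, ("empty", "CI2", "Cro2"), kind="operator"))
    return out


def _ligands(site_names: Sequence[str]) -> list[LigandSpec]:
    ops = [s for s in site_names if s in OPERATOR_SITES]
    proms = [s for s in site_names if s in PROMOTER_SITES]
    return [
        LigandSpec("CI2", frozenset((s, "CI2") for s in ops)),
        LigandSpec("Cro2", frozenset((s, "Cro2") for s in ops)),
        LigandSpec("RNAP", frozenset((p, "RNAP") for p in proms)),
    ]


def _exclusions(site_names: Sequence[str]) -> list[ExclusionRule]:
    rules = []
    for prom, blocked in OVERLAPS.items():
        if prom not in site_names:
            continue
        for op in blocked:
            if op not in site_names:
                continue
            for sp in OPERATOR_SPECIES:
                rules.append(ExclusionRule((prom, "RNAP"), (op, sp)))
    return rules


def _energy_terms(
    params: LambdaParameterSet, site_names: Sequence[str]
) -> list[EnergyTerm]:
    terms = []
    for (site, sp), dg in params.intrinsic_energies.items():
        if site in site_names:
            terms.append(
                EnergyTerm(frozenset({(site, sp)}), dg, label=f"{site}:{sp}")
            )
    for (a, b), dg in params.pair_cooperativities.items():
        if a[0] in site_names and b[0] in site_names:
            terms.append(
                EnergyTerm(
                    frozenset({a, b}), dg, label=f"{a[0]}:{a[1]}--{b[0]}:{b[1]}"
                )
            )
    for term in params.looping_terms:
        if all(site in site_names for site, _ in term.condition):
            terms.append(term)
    return terms


def build_lambda_model(params: LambdaParameterSet) -> ModelSpec:
    """Assemble the full nine-site lambda ModelSpec from a parameter set.

    Raises
    ------
    ValueError
        Listing the missing intrinsic-energy entries if the set is
        incomplete.
    """
    missing = params.missing_intrinsic()
    if missing:
        raise ValueError(
            "incomplete lambda parameter set; missing intrinsic energies for "
            + ", ".join(f"{s}:{sp}" for s, sp in missing)
        )
    return ModelSpec(
        sites=_site_specs(SITE_ORDER),
        ligands=_ligands(SITE_ORDER),
        exclusions=_exclusions(SITE_ORDER),
        energy_terms=_energy_terms(params, SITE_ORDER),
    )


def right_operator_submodel(params: LambdaParameterSet | None = None) -> ModelSpec:
    """The right-operator complex alone (O_R1-3, P_R, P_RM): 40 microstates."""
    params = params if params is not None else zero_parameters()
    return ModelSpec(
        sites=_site_specs(RIGHT_SITES),
        ligands=_ligands(RIGHT_SITES),
        exclusions=_exclusions(RIGHT_SITES),
        energy_terms=_energy_terms(params, RIGHT_SITES),
    )


def project_to_right_operator(
    dist: EquilibriumDistribution,
    spec: ModelSpec,
    microstates: Sequence[Microstate],
) -> dict[tuple[str, ...], float]:
    """Marginal over the 40 right-operator joint configurations.

    Each projected entry is the sum of the occupancies of the 30 full
    microstates that share the right-operator assignment but differ on the
    left-operator complex.
    """
    if tuple(spec.site_names) != SITE_ORDER:
        raise ValueError("not the full lambda model (site set mismatch)")
    out: dict[tuple[str, ...], float] = {}
    for ms, k in zip(microstates, dist.probabilities):
        key = tuple(ms.assignment[s] for s in RIGHT_SITES)
        out[key] = out.get(key, 0.0) + k
    return out


@dataclass
class PathwayReport:
    """Stationary analysis bundle for one pathway condition."""

    pathway: str
    spec: ModelSpec
    microstates: list[Microstate]
    dist: EquilibriumDistribution
    marginals: dict[str, dict[str, float]]
    entropies: dict[str, float]
    mi: "np.ndarray"  # site x site, bits; diagonal = entropies
    ca: dict[str, dict[str, float]]
    ca_failures: dict[str, str]
    top_states: list[tuple[int, dict[str, str], float]]
    p_rnap_pr: float
    p_rnap_prm: float


def pathway_report(
    params: LambdaParameterSet,
    lambda_cond: LambdaCondition,
    base_rate: float = 1.0,
    allow_placeholder: bool = False,
    n_top: int = 5,
) -> PathwayReport:
    """Full stationary analysis of the lambda switch at one condition.

    Computes the equilibrium distribution, per-site marginals and entropies,
    the MI matrix, the analytic CA matrix, the highest-occupancy
    microstates, and the RNAP occupancies of P_R and P_RM (the lysis
    tendency proxy).  Deterministic given (params, condition).
    """
    if params.placeholder and not allow_placeholder:
        raise PlaceholderParameterError(
            "the lambda parameter set is a placeholder (values not yet "
            "transcribed from the literature); pass allow_placeholder=True "
            "to analyze it anyway"
        )
    spec = build_lambda_model(params)
    microstates = enumerate_microstates(spec)
    dist = thermo.equilibrium(spec, microstates, lambda_cond.condition)
    rm = kinetics.build_rate_matrix(spec, microstates, dist, base_rate)
    marginals = {
        s: thermo.site_marginal(dist, spec, microstates, s)
        for s in spec.site_names
    }
    entropies = {s: thermo.site_entropy(m) for s, m in marginals.items()}
    mi = thermo.mutual_information_matrix(dist, spec, microstates)
    ca, failures = ca_analytic.analytic_ca_matrix(rm, dist)
    order = np.argsort(dist.probabilities)[::-1][:n_top]
    top = [
        (int(i), dict(microstates[i].assignment), float(dist.probabilities[i]))
        for i in order
    ]
    return PathwayReport(
        pathway=lambda_cond.pathway,
        spec=spec,
        microstates=microstates,
        dist=dist,
        marginals=marginals,
        entropies=entropies,
        mi=mi,
        ca=ca,
        ca_failures=failures,
        top_states=top,
        p_rnap_pr=marginals["P_R"]["RNAP"],
        p_rnap_prm=marginals["P_RM"]["RNAP"],
    )


# ---------------------------------------------------------------------------
# Parameter/condition file handling


def _parse_params(doc: Mapping) -> LambdaParameterSet:
    if doc.get("units", "kcal/mol") != "kcal/mol":
        raise ValueError("lambda parameter file must declare units: kcal/mol")
    placeholder = False
    intrinsic: dict[tuple[str, str], float] = {}
    provenance: dict[str, str] = {}
    for entry in doc.get("intrinsic_energies", []):
        key = (entry["site"], entry["species"])
        if entry.get("delta_g") is None:
            placeholder = True
            intrinsic[key] = 0.0
        else:
            intrinsic[key] = float(entry["delta_g"])
        if entry.get("provenance"):
            provenance[f"{key[0]}:{key[1]}"] = entry["provenance"]
    pairs: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    for entry in doc.get("pair_cooperativities", []):
        a = (entry["site_a"], entry["species_a"])
        b = (entry["site_b"], entry["species_b"])
        if entry.get("delta_g") is None:
            placeholder = True
            pairs[(a, b)] = 0.0
        else:
            pairs[(a, b)] = float(entry["delta_g"])
        if entry.get("provenance"):
            provenance[f"{a[0]}:{a[1]}--{b[0]}:{b[1]}"] = entry["provenance"]
    loops: list[EnergyTerm] = []
    for entry in doc.get("looping_terms", []):
        cond = frozenset((p["site"], p["species"]) for p in entry["condition"])
        dg = entry.get("delta_g")
        if dg is None:
            placeholder = True
            dg = 0.0
        loops.append(EnergyTerm(cond, float(dg), label=entry.get("label", "loop")))
        if entry.get("provenance"):
            provenance[entry.get("label", "loop")] = entry["provenance"]
    return LambdaParameterSet(
        intrinsic_energies=intrinsic,
        pair_cooperativities=pairs,
        looping_terms=loops,
        provenance=provenance,
        placeholder=placeholder,
    )


def load_lambda_parameters(path: str | None = None) -> LambdaParameterSet:
    """Load a lambda parameter file (YAML); defaults to the shipped file.

    The shipped file is schema-complete but value-empty (all ``delta_g``
    null): the loaded set is flagged ``placeholder`` and pathway_report will
    refuse it unless overridden.
    """
    if path is None:
        ref = resources.files("condact").joinpath("data/lambda_parameters.yaml")
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    return _parse_params(doc)


def load_lambda_condition(path_or_name: str) -> LambdaCondition:
    """Load a condition preset: a file path or one of 'lysogenic' / 'lytic'."""
    if path_or_name in ("lysogenic", "lytic"):
        ref = resources.files("condact").joinpath(f"data/{path_or_name}.yaml")
        doc = yaml.safe_load(ref.read_text())
    else:
        with open(path_or_name) as fh:
            doc = yaml.safe_load(fh)
    conc = doc.get("concentrations_M") or {}
    if any(v is None for v in conc.values()):
        raise PlaceholderParameterError(
            f"condition {path_or_name!r} has placeholder concentrations; "
            "transcribe the pathway concentrations before use"
        )
    return LambdaCondition(
        pathway=doc.get("pathway", "custom"),
        condition=Condition(
            temperature=float(doc.get("temperature_K", thermo.DEFAULT_TEMPERATURE)),
            concentrations={k: float(v) for k, v in conc.items()},
        ),
    )


def zero_parameters() -> LambdaParameterSet:
    """All-zero intrinsic energies, no cooperativity: the non-interacting limit."""
    intrinsic = {(s, sp): 0.0 for s in OPERATOR_SITES for sp in OPERATOR_SPECIES}
    intrinsic.update({(p, "RNAP"): 0.0 for p in PROMOTER_SITES})
    return LambdaParameterSet(intrinsic_energies=intrinsic)


def synthetic_parameters() -> LambdaParameterSet:
    """A SYNTHETIC lambda parameter set for structural testing.

    Magnitudes are plausible for protein-DNA binding (intrinsic energies
    around -10 kcal/mol, cooperativities of a few kcal/mol, a strong CI
    octamer looping term) but are NOT transcribed from the experimental
    literature; use only for exercising the machinery, never for
    biological conclusions.
    """
    intrinsic = {
        ("O_R1", "CI2"): -12.0, ("O_R2", "CI2"): -10.5, ("O_R3", "CI2"): -9.5,
        ("O_R1", "Cro2"): -10.5, ("O_R2", "Cro2"): -10.5, ("O_R3", "Cro2"): -12.0,
        ("O_L1", "CI2"): -12.0, ("O_L2", "CI2"): -10.5, ("O_L3", "CI2"): -9.5,
        ("O_L1", "Cro2"): -10.5, ("O_L2", "Cro2"): -10.5, ("O_L3", "Cro2"): -12.0,
        ("P_R", "RNAP"): -12.5, ("P_RM", "RNAP"): -11.5, ("P_L", "RNAP"): -12.5,
    }
    pairs = {
        (("O_R1", "CI2"), ("O_R2", "CI2")): -2.5,
        (("O_R2", "CI2"), ("O_R3", "CI2")): -2.5,
        (("O_L1", "CI2"), ("O_L2", "CI2")): -2.5,
        (("O_L2", "CI2"), ("O_L3", "CI2")): -2.5,
    }
    loops = [
        EnergyTerm(
            frozenset(
                {("O_R1", "CI2"), ("O_R2", "CI2"), ("O_L1", "CI2"), ("O_L2", "CI2")}
            ),
            -3.0,
            label="CI octamer loop (synthetic)",
        )
    ]
    return LambdaParameterSet(
        intrinsic_energies=intrinsic,
        pair_cooperativities=pairs,
        looping_terms=loops,
        provenance={"*": "synthetic illustrative values, not literature"},
    )
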