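"""Self-contained toy models with closed-form or oracle-checkable answers.

Every fixture is a tiny, valid (ModelSpec, Condition) pair built so that the
quantities downstream modules compute — occupancies, mutual information,
persistence/exchange times, conditional activity — have hand-derivable
expectations:

single_site       one site, two configurations; an alternating-renewal
                  process with binding rate k_bind and unbinding rate
                  k_unbind (tau_p, tau_x, CA all closed form)
independent_pair  two uncoupled sites: MI = 0 and CA[a<-b] = 0 exactly
cooperative_pair  two sites plus a pairwise interaction energy; the 4-state
                  Boltzmann weights are hand-computable
blocker_pair      two sites whose bound configurations sterically exclude
                  each other (the promoter/operator overlap motif)
chain_n           n sites with nearest-neighbor cooperativity; optionally a
                  steric exclusion between the two end sites

Under the detailed-balance kinetics every binding transition runs at the
common rate D, so a site's unbinding rate is D divided by its statistical
weight w = [ligand] * exp(-dG/RT); choosing dG = 0 makes the concentration
the direct bind/unbind rate ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model_core import EnergyTerm, ExclusionRule, LigandSpec, ModelSpec, SiteSpec
from .thermo import Condition, DEFAULT_TEMPERATURE

__all__ = ["FixtureSpec", "make_fixture", "FIXTURE_KINDS"]

FIXTURE_KINDS = (
    "single_site",
    "independent_pair",
    "cooperative_pair",
    "blocker_pair",
    "chain_n",
)


@dataclass
class FixtureSpec:
    """Recipe for one toy model: a kind tag plus its named parameters."""

    kind: str
    parameters: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _two_state_site(name: str, species: str) -> tuple[SiteSpec, LigandSpec]:
    site = SiteSpec(name=name, configurations=("empty", species), kind="other")
    lig = LigandSpec(species=species, occupancy_map=frozenset({(name, species)}))
    return site, lig


def _single_site(p: dict) -> tuple[ModelSpec, Condition]:
    k_bind = p.get("k_bind", 3.0)
    k_unbind = p.get("k_unbind", 1.0)
    site, lig = _two_state_site("A", "L")
    spec = ModelSpec(sites=[site], ligands=[lig])
    cond = Condition(
        temperature=DEFAULT_TEMPERATURE,
        concentrations={"L": k_bind / k_unbind},
    )
    return spec, cond


def _independent_pair(p: dict) -> tuple[ModelSpec, Condition]:
    c_a = p.get("c_a", 3.0)
    c_b = p.get("c_b", 0.4)
    sa, la = _two_state_site("A", "LA")
    sb, lb = _two_state_site("B", "LB")
    spec = ModelSpec(sites=[sa, sb], ligands=[la, lb])
    cond = Condition(concentrations={"LA": c_a, "LB": c_b})
    return spec, cond


def _cooperative_pair(p: dict) -> tuple[ModelSpec, Condition]:
    c_a = p.get("c_a", 1.0)
    c_b = p.get("c_b", 1.0)
    dg_a = p.get("dg_a", 0.0)
    dg_b = p.get("dg_b", 0.0)
    dg_coop = p.get("dg_coop", -1.5)
    sa, la = _two_state_site("A", "LA")
    sb, lb = _two_state_site("B", "LB")
    terms = [
        EnergyTerm(condition=frozenset({("A", "LA")}), delta_g=dg_a, label="A"),
        EnergyTerm(condition=frozenset({("B", "LB")}), delta_g=dg_b, label="B"),
        EnergyTerm(
            condition=frozenset({("A", "LA"), ("B", "LB")}),
            delta_g=dg_coop,
            label="A:B cooperativity",
        ),
    ]
    spec = ModelSpec(sites=[sa, sb], ligands=[la, lb], energy_terms=terms)
    cond = Condition(concentrations={"LA": c_a, "LB": c_b})
    return spec, cond


def _blocker_pair(p: dict) -> tuple[ModelSpec, Condition]:
    c_a = p.get("c_a", 1.0)
    c_b = p.get("c_b", 1.0)
    dg_a = p.get("dg_a", 0.0)
    dg_b = p.get("dg_b", 0.0)
    sa, la = _two_state_site("A", "LA")
    sb, lb = _two_state_site("B", "LB")
    terms = [
        EnergyTerm(condition=frozenset({("A", "LA")}), delta_g=dg_a, label="A"),
        EnergyTerm(condition=frozenset({("B", "LB")}), delta_g=dg_b, label="B"),
    ]
    spec = ModelSpec(
        sites=[sa, sb],
        ligands=[la, lb],
        exclusions=[ExclusionRule(("A", "LA"), ("B", "LB"))],
        energy_terms=terms,
    )
    cond = Condition(concentrations={"LA": c_a, "LB": c_b})
    return spec, cond


def _chain_n(p: dict) -> tuple[ModelSpec, Condition]:
    n = int(p.get("n", 3))
    if n < 2:
        raise ValueError("chain_n needs n >= 2 sites")
    c = p.get("c", 1.0)
    dg_coop = p.get("dg_coop", -1.5)
    exclude_ends = bool(p.get("exclude_ends", False))
    sites, ligs, terms = [], [], []
    for i in range(1, n + 1):
        s, l = _two_state_site(f"S{i}", f"L{i}")
        sites.append(s)
        ligs.append(l)
    for i in range(1, n):
        terms.append(
            EnergyTerm(
                condition=frozenset({(f"S{i}", f"L{i}"), (f"S{i+1}", f"L{i+1}")}),
                delta_g=dg_coop,
                label=f"S{i}:S{i+1} cooperativity",
            )
        )
    exclusions = []
    if exclude_ends:
        exclusions.append(ExclusionRule(("S1", "L1"), (f"S{n}", f"L{n}")))
    spec = ModelSpec(
        sites=sites, ligands=ligs, exclusions=exclusions, energy_terms=terms
    )
    cond = Condition(concentrations={f"L{i}": c for i in range(1, n + 1)})
    return spec, cond


_BUILDERS = {
    "single_site": _single_site,
    "independent_pair": _independent_pair,
    "cooperative_pair": _cooperative_pair,
    "blocker_pair": _blocker_pair,
    "chain_n": _chain_n,
}


def make_fixture(fs: FixtureSpec) -> tuple[ModelSpec, Condition]:
    """Build the (ModelSpec, Condition) pair for a fixture recipe."""
    try:
        builder = _BUILDERS[fs.kind]
    except KeyError:
        raise ValueError(
            f"unknown fixture kind {fs.kind!r}; choose from {FIXTURE_KINDS}"
        ) from None
    return builder(fs.parameters)
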