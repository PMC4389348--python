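"""Equilibrium occupancies, site marginals, entropies, and mutual information.

The probability of microstate *i* at temperature *T* and ligand
concentrations [s] is the grand-canonical Boltzmann weight

    K_i = (1/Z) exp(-dG_i / RT) * prod_s [s]^(n_i,s)

with n_i,s the number of bound molecules of species *s* in state *i* and Z the
partition function.  Weights are accumulated in log space with
max-subtraction for numerical stability.

Mutual information between two sites is computed in bits from the joint
configuration table P(a=x, b=y) = sum_i K_i chi_i(a,x) chi_i(b,y).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .model_core import Microstate, ModelSpec, config_matrix

# Gas constant in kcal / (mol K).
R_KCAL = 1.9872e-3

# Default temperature (kelvin) for phage-lambda conditions.
DEFAULT_TEMPERATURE = 310.0

NORMALIZATION_TOL = 1e-12

__all__ = [
    "R_KCAL",
    "DEFAULT_TEMPERATURE",
    "Condition",
    "EquilibriumDistribution",
    "equilibrium",
    "site_marginal",
    "joint_marginal",
    "site_entropy",
    "mutual_information",
]


@dataclass(frozen=True)
class Condition:
    """Thermodynamic condition: temperature (K) and concentrations (molar)."""

    temperature: float = DEFAULT_TEMPERATURE
    concentrations: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        for s, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"concentration of {s!r} is negative")


@dataclass(frozen=True)
class EquilibriumDistribution:
    """Normalized microstate probabilities K_i with partition function Z.

    ``partition_function`` is Z in the weight convention above (concentrations
    in molar, energies in kcal/mol).
    """

    probabilities: np.ndarray
    partition_function: float

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        object.__setattr__(self, "probabilities", p)
        if np.any(p < 0):
            raise ValueError("negative probability")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities do not sum to 1")

    def __len__(self) -> int:
        return len(self.probabilities)


def equilibrium(
    spec: ModelSpec,
    microstates: Sequence[Microstate],
    cond: Condition,
) -> EquilibriumDistribution:
    """Boltzmann equilibrium over microstates at the given condition.

    Raises
    ------
    ValueError
        If a model species has no concentration entry, or every microstate
        has zero weight (e.g. a required concentration is zero).
    """
    missing = [s for s in spec.species_names if s not in cond.concentrations]
    if missing:
        raise ValueError(f"condition lacks concentrations for {missing}")
    rt = R_KCAL * cond.temperature
    logw = np.empty(len(microstates))
    for i, ms in enumerate(microstates):
        lw = -ms.delta_g / rt
        for s, n in ms.stoichiometry.items():
            if n == 0:
                continue
            c = cond.concentrations[s]
            lw += -np.inf if c == 0.0 else n * np.log(c)
        logw[i] = lw
    m = np.max(logw)
    if not np.isfinite(m):
        raise ValueError(
            "all microstate weights are zero; check for zero concentrations "
            "with no ligand-free state"
        )
    w = np.exp(logw - m)
    z_scaled = w.sum()
    return EquilibriumDistribution(
        probabilities=w / z_scaled,
        partition_function=float(z_scaled * np.exp(m)),
    )


def site_marginal(
    dist: EquilibriumDistribution,
    spec: ModelSpec,
    microstates: Sequence[Microstate],
    site: str,
) -> dict[str, float]:
    """Marginal configuration distribution of one site, P(a = x)."""
    s = spec.site(site)
    out = {c: 0.0 for c in s.configurations}
    for ms, k in zip(microstates, dist.probabilities):
        out[ms.assignment[site]] += k
    return out


def joint_marginal(
    dist: EquilibriumDistribution,
    spec: ModelSpec,
    microstates: Sequence[Microstate],
    a: str,
    b: str,
) -> np.ndarray:
    """Joint table P(a = x, b = y), shape (|configs a|, |configs b|)."""
    ia, ib = spec.site_index(a), spec.site_index(b)
    cfg = config_matrix(spec, microstates)
    na = len(spec.sites[ia].configurations)
    nb = len(spec.sites[ib].configurations)
    joint = np.zeros((na, nb))
    np.add.at(joint, (cfg[:, ia], cfg[:, ib]), dist.probabilities)
    return joint


def site_entropy(marginal: Mapping[str, float] | np.ndarray) -> float:
    """Shannon entropy in bits, with 0 log 0 = 0."""
    p = np.asarray(
        list(marginal.values()) if isinstance(marginal, Mapping) else marginal,
        dtype=float,
    ).ravel()
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("marginal is not normalized")
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def mutual_information(
    dist: EquilibriumDistribution,
    spec: ModelSpec,
    microstates: Sequence[Microstate],
    a: str,
    b: str,
) -> float:
    """MI(a, b) = H(a) + H(b) - H(a, b), in bits; tiny negatives clamp to 0."""
    if a == b:
        raise ValueError("mutual information needs two distinct sites; "
                         "use site_entropy for a single site")
    joint = joint_marginal(dist, spec, microstates, a, b)
    h_a = site_entropy(joint.sum(axis=1))
    h_b = site_entropy(joint.sum(axis=0))
    h_ab = site_entropy(joint)
    return max(0.0, h_a + h_b - h_ab)


def mutual_information_matrix(
    dist: EquilibriumDistribution,
    spec: ModelSpec,
    microstates: Sequence[Microstate],
) -> "np.ndarray":
    """Symmetric site-by-site MI matrix (bits); diagonal holds site entropies."""
    names = spec.site_names
    n = len(names)
    out = np.zeros((n, n))
    for i, a in enumerate(names):
        out[i, i] = site_entropy(site_marginal(dist, spec, microstates, a))
        for j in range(i + 1, n):
            mi = mutual_information(dist, spec, microstates, a, names[j])
            out[i, j] = out[j, i] = mi
    return out
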