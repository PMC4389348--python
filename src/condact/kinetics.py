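"""Detailed-balance CTMC generator over microstates.

Two microstates are *adjacent* when they differ at exactly one site and one
of the two differing configurations is empty — each transition is a single
binding or unbinding event (ligand substitution is two transitions).  All
binding transitions share one diffusion-limited rate D; unbinding rates are
fixed by detailed balance against the equilibrium distribution:

    q_ij = D                 (i -> j binds one molecule)
    q_ij = D * K_j / K_i     (i -> j unbinds one molecule)

so K_i q_ij = K_j q_ji for every adjacent pair and the stationary law of the
chain is exactly the thermodynamic one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .model_core import EMPTY, Microstate, ModelSpec, config_matrix
from .thermo import EquilibriumDistribution

DENSE_STATE_CAP = 5000

__all__ = ["RateMatrix", "build_rate_matrix", "stationarity_check", "flux"]


@dataclass
class RateMatrix:
    """CTMC generator q_ij with per-edge annotations.

    Attributes
    ----------
    rates : (n, n) dense generator; rows sum to zero.
    base_rate : the common binding rate D (inverse time units).
    edge_i, edge_j : directed adjacency (both orientations listed).
    edge_site : index of the single site changed by each edge.
    edge_kind : "binding" or "unbinding" per edge.
    site_configs : (n, n_sites) configuration-index matrix.
    site_names : site labels in declaration order.
    """

    rates: np.ndarray
    base_rate: float
    edge_i: np.ndarray
    edge_j: np.ndarray
    edge_site: np.ndarray
    edge_kind: list[str]
    site_configs: np.ndarray
    site_names: list[str]
    config_labels: list[tuple[str, ...]]

    @property
    def n_states(self) -> int:
        return self.rates.shape[0]

    def adjacency_tag(self, i: int, j: int) -> str:
        """Tag for an ordered state pair: 'binding', 'unbinding', or 'none'."""
        mask = (self.edge_i == i) & (self.edge_j == j)
        hits = np.flatnonzero(mask)
        return self.edge_kind[hits[0]] if hits.size else "none"

    def is_irreducible(self) -> bool:
        """True iff the adjacency graph has a single communicating class."""
        n = self.n_states
        adj = sp.coo_matrix(
            (np.ones(len(self.edge_i)), (self.edge_i, self.edge_j)), shape=(n, n)
        )
        ncomp, _ = connected_components(adj, directed=False)
        return ncomp == 1


def build_rate_matrix(
    spec: ModelSpec,
    microstates: Sequence[Microstate],
    dist: EquilibriumDistribution,
    base_rate: float = 1.0,
) -> RateMatrix:
    """Construct the detailed-balance generator for one condition.

    Raises
    ------
    ValueError
        If ``base_rate <= 0`` or any microstate has zero equilibrium
        probability (advise flooring concentrations or reducing the model).
    """
    if base_rate <= 0:
        raise ValueError("base_rate D must be positive")
    k = dist.probabilities
    if np.any(k == 0):
        raise ValueError(
            "equilibrium distribution has zero-probability microstates; "
            "detailed-balance rates are undefined — floor the offending "
            "concentrations or remove the unreachable states"
        )
    n = len(microstates)
    if n > DENSE_STATE_CAP:
        raise ValueError(
            f"{n} states exceeds the dense-generator cap {DENSE_STATE_CAP}"
        )
    names = spec.site_names
    cfg = config_matrix(spec, microstates)
    index_of = {tuple(row): i for i, row in enumerate(cfg)}

    q = np.zeros((n, n))
    ei: list[int] = []
    ej: list[int] = []
    esite: list[int] = []
    ekind: list[str] = []
    # For each state and each bound site, the unbinding partner has that site
    # empty (configuration index 0); binding is the reverse orientation.
    for i in range(n):
        for s in range(len(names)):
            if cfg[i, s] == 0:
                continue
            partner = list(cfg[i])
            partner[s] = 0
            j = index_of.get(tuple(partner))
            if j is None:  # partner excluded: cannot happen (removing a
                continue  # molecule never violates a pairwise exclusion)
            q_unbind = base_rate * k[j] / k[i]
            q[i, j] += q_unbind
            q[j, i] += base_rate
            ei += [i, j]
            ej += [j, i]
            esite += [s, s]
            ekind += ["unbinding", "binding"]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return RateMatrix(
        rates=q,
        base_rate=base_rate,
        edge_i=np.asarray(ei, dtype=np.int64),
        edge_j=np.asarray(ej, dtype=np.int64),
        edge_site=np.asarray(esite, dtype=np.int64),
        edge_kind=ekind,
        site_configs=cfg,
        site_names=list(names),
        config_labels=[tuple(s.configurations) for s in spec.sites],
    )


def stationarity_check(rm: RateMatrix, dist: EquilibriumDistribution) -> float:
    """Max-norm residual of K Q = 0, scaled by the base rate D."""
    resid = dist.probabilities @ rm.rates
    return float(np.max(np.abs(resid)) / rm.base_rate)


def flux(
    rm: RateMatrix, dist: EquilibriumDistribution, i: int, j: int
) -> tuple[float, str]:
    """Probability flux K_i q_ij over one ordered pair, with its edge tag.

    Non-adjacent pairs return (0.0, "none") rather than raising.
    """
    tag = rm.adjacency_tag(i, j)
    if tag == "none":
        return 0.0, "none"
    return float(dist.probabilities[i] * rm.rates[i, j]), tag
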