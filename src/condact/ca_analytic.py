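"""Conditional activity directly from the transition-rate matrix.

For a site *a*, split the generator Q into Q^a (transitions that keep a's
configuration, with the *full* exit rates on the diagonal) and R^a (the
a-changing transitions).  Q^a is block diagonal over the connected components
of the a-preserving transition graph; each block is a sub-generator whose
absorption time is the time to a's next transition.  With the fundamental
matrix N^a = -(Q^a)^-1:

    (N^a)_ij            expected time in j before a next changes, from i
    B^a = N^a R^a       distribution over the first state with a changed
    K^a_i ~ sum_j K_j (R^a)_ji   state just after an a-transition (flux-weighted)
    tau^a = K^a N^a 1            mean interval between a-transitions

    tau_p[a]    = (1/tau^a) K^a N^a N^a 1          (E[T^2]/2 over E[T])
    tau_x[a<-b] = (1/tau^b) K^b N^b B^b (N^a 1)

The exchange contraction uses the occupation-time identity
E_i[time in j, absorbed at k] = (N^b)_ij (B^b)_jk: it is the expected product
of b's waiting time with a's residual time from the state where b next
changes.  CA[a<-b] = -log10(tau_x/tau_p) then needs no simulation.

Everything is computed with per-block LU solves against the needed
right-hand sides; no global dense inverse is ever formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .kinetics import RateMatrix
from .thermo import EquilibriumDistribution

__all__ = [
    "MaskedChain",
    "build_masked_chain",
    "post_transition_distribution",
    "analytic_persistence",
    "analytic_exchange",
    "analytic_ca_matrix",
    "CA_ZERO_TOL",
]

CONDITION_CAP = 1e12
CA_ZERO_TOL = 1e-9


@dataclass
class MaskedChain:
    """Per-site absorbing-chain machinery for one site of one rate matrix.

    Holds the block partition of the a-preserving transition graph, LU
    factors of each block of Q^a, the a-changing rate matrix R^a (sparse),
    the post-transition distribution K^a, the mean interval tau^a, and the
    expected-absorption-time vector n = N^a 1.
    """

    site: str
    labels: np.ndarray                    # block id per microstate
    blocks: list[np.ndarray] = field(repr=False)
    lu_factors: list = field(repr=False)
    R: sp.csr_matrix = field(repr=False)  # R^a
    K_post: np.ndarray = field(repr=False)  # K^a
    n_vec: np.ndarray = field(repr=False)   # N^a 1
    tau: float = 0.0                        # tau^a
    condition_estimates: list[float] = field(default_factory=list)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    def solve_N(self, v: np.ndarray) -> np.ndarray:
        """x = N^a v, i.e. solve Q^a x = -v block by block."""
        x = np.empty_like(v, dtype=float)
        for blk, lu in zip(self.blocks, self.lu_factors):
            x[blk] = sla.lu_solve(lu, -v[blk])
        return x

    def solve_NT(self, v: np.ndarray) -> np.ndarray:
        """x = (N^a)^T v, i.e. solve (Q^a)^T x = -v block by block."""
        x = np.empty_like(v, dtype=float)
        for blk, lu in zip(self.blocks, self.lu_factors):
            x[blk] = sla.lu_solve(lu, -v[blk], trans=1)
        return x


def _site_edges(rm: RateMatrix, site_idx: int) -> np.ndarray:
    return rm.edge_site == site_idx


def post_transition_distribution(
    dist: EquilibriumDistribution, R: sp.spmatrix
) -> np.ndarray:
    """K^a: flux-weighted distribution over states just after an a-transition.

    K^a_i is proportional to the total stationary probability flux entering
    state i through a-changing transitions.
    """
    influx = np.asarray(R.T @ dist.probabilities).ravel()
    total = influx.sum()
    if total <= 0:
        raise ValueError(
            "zero total flux through this site's transitions; the site never "
            "changes configuration at this condition"
        )
    return influx / total


def build_masked_chain(
    rm: RateMatrix, dist: EquilibriumDistribution, site: str
) -> MaskedChain:
    """Assemble the absorbing-chain machinery for one site.

    Raises
    ------
    ValueError
        If some a-preserving block has no a-changing exit (the sub-generator
        is then singular: the site is frozen in that subspace), if a block is
        numerically near-singular, or if the site carries zero flux.
    """
    try:
        s_idx = rm.site_names.index(site)
    except ValueError:
        raise ValueError(f"unknown site {site!r}") from None
    n = rm.n_states
    on_site = _site_edges(rm, s_idx)

    # a-preserving adjacency -> block partition of Q^a
    keep_i = rm.edge_i[~on_site]
    keep_j = rm.edge_j[~on_site]
    adj = sp.coo_matrix((np.ones(len(keep_i)), (keep_i, keep_j)), shape=(n, n))
    n_blocks, labels = connected_components(adj, directed=False)
    blocks = [np.flatnonzero(labels == b) for b in range(n_blocks)]

    # R^a: the a-changing rates
    ri = rm.edge_i[on_site]
    rj = rm.edge_j[on_site]
    R = sp.csr_matrix(
        (rm.rates[ri, rj], (ri, rj)), shape=(n, n)
    )
    r_rowsum = np.asarray(R.sum(axis=1)).ravel()

    lu_factors = []
    conds = []
    for blk in blocks:
        if r_rowsum[blk].max() <= 0:
            raise ValueError(
                f"site {site!r} is frozen in the subspace containing "
                f"microstate {blk[0]}: its sub-generator is singular"
            )
        sub = rm.rates[np.ix_(blk, blk)].copy()
        # Diagonal already carries the full exit rate (incl. a-changing
        # transitions), which is what makes the block strictly substochastic.
        c = float(np.linalg.cond(sub))
        conds.append(c)
        if c > CONDITION_CAP:
            warnings.warn(
                f"block of {len(blk)} states for site {site!r} has condition "
                f"estimate {c:.2e} (rate spread too large); refusing to solve",
                stacklevel=2,
            )
            raise ValueError(
                f"ill-conditioned block for site {site!r} "
                f"(condition estimate {c:.2e} > {CONDITION_CAP:.0e})"
            )
        lu_factors.append(sla.lu_factor(sub))

    chain = MaskedChain(
        site=site,
        labels=labels,
        blocks=blocks,
        lu_factors=lu_factors,
        R=R,
        K_post=np.empty(n),
        n_vec=np.empty(n),
        condition_estimates=conds,
    )
    chain.K_post = post_transition_distribution(dist, R)
    chain.n_vec = chain.solve_N(np.ones(n))
    if np.any(chain.n_vec < 0):
        raise ValueError(f"negative expected absorption time for {site!r}")
    chain.tau = float(chain.K_post @ chain.n_vec)
    return chain


def absorption_matrix_rowsums(chain: MaskedChain) -> np.ndarray:
    """Row sums of B^a = N^a R^a (must all be 1: absorption is certain)."""
    r1 = np.asarray(chain.R.sum(axis=1)).ravel()
    return chain.solve_N(r1)


def analytic_persistence(chain: MaskedChain) -> float:
    """tau_p[a] = (1/tau^a) K^a N^a N^a 1 = E[T^2]/2 / E[T] from K^a."""
    n2 = chain.solve_N(chain.n_vec)
    return float(chain.K_post @ n2 / chain.tau)


def analytic_exchange(
    chain_a: MaskedChain,
    chain_b: MaskedChain,
    printed_variant: bool = False,
) -> float:
    """tau_x[a<-b] = (1/tau^b) K^b N^b B^b (N^a 1).

    With ``printed_variant=True`` an extra post-transition weight K^a is
    interposed before N^a (a variant of the contraction kept available for
    comparison; it does not reproduce the simulation estimator and breaks
    the independent-sites identity tau_x = tau_p).
    """
    v = chain_a.n_vec.copy()
    if printed_variant:
        v = chain_a.K_post * v
    w = np.asarray(chain_b.R @ v).ravel()      # R^b (N^a 1)
    y1 = chain_b.solve_NT(chain_b.K_post)      # (N^b)^T K^b
    y2 = chain_b.solve_NT(y1)                  # (N^b)^T (N^b)^T K^b
    return float(y2 @ w / chain_b.tau)


def analytic_ca_matrix(
    rm: RateMatrix,
    dist: EquilibriumDistribution,
    sites: list[str] | None = None,
    zero_tol: float = CA_ZERO_TOL,
) -> tuple[dict[str, dict[str, float]], dict[str, str]]:
    """Full asymmetric CA table from the rate matrix alone.

    Returns ``(table, failures)`` where ``table[a][b]`` is CA[a<-b] (NaN for
    cells whose site machinery failed) and ``failures`` maps site name to the
    reason it could not be processed (zero flux, frozen subspace, ...).
    Masked chains are built once per site and reused across the row/column.
    """
    names = sites if sites is not None else list(rm.site_names)
    chains: dict[str, MaskedChain] = {}
    failures: dict[str, str] = {}
    for s in names:
        try:
            chains[s] = build_masked_chain(rm, dist, s)
        except ValueError as exc:
            failures[s] = str(exc)
    tau_p = {s: analytic_persistence(c) for s, c in chains.items()}
    table: dict[str, dict[str, float]] = {}
    for a in names:
        table[a] = {}
        for b in names:
            if a not in chains or b not in chains:
                table[a][b] = float("nan")
                continue
            tx = analytic_exchange(chains[a], chains[b])
            ca = -float(np.log10(tx / tau_p[a]))
            table[a][b] = 0.0 if abs(ca) < zero_tol else ca
    return table, failures
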