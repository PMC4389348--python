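"""Readers and writers for the package's text formats.

All on-disk formats are plain text: YAML for model and condition
descriptions, TSV for microstate tables, event series, rate-matrix edge
lists, and MI/CA matrices, and DOT/GraphML for the microstate graph.  Every
writer/reader pair round-trips: writing an in-memory object and reading it
back yields an equal object.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .ca_empirical import CAEstimate
from .gillespie_sim import SiteEventSeries
from .kinetics import RateMatrix
from .model_core import (
    EnergyTerm,
    ExclusionRule,
    LigandSpec,
    Microstate,
    ModelSpec,
    SiteSpec,
)
from .thermo import Condition, EquilibriumDistribution

__all__ = [
    "write_model",
    "read_model",
    "write_condition",
    "read_condition",
    "write_microstates",
    "write_event_series",
    "read_event_series",
    "write_ca_table",
    "write_ca_long",
    "write_matrix",
    "write_edge_list",
    "microstate_graph",
    "write_dot",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# Model description file (YAML)


def write_model(spec: ModelSpec, path: str) -> None:
    doc = {
        "units": "kcal/mol",
        "sites": [
            {"name": s.name, "kind": s.kind, "configurations": list(s.configurations)}
            for s in spec.sites
        ],
        "ligands": [
            {
                "species": l.species,
                "occupancy": sorted([list(p) for p in l.occupancy_map]),
            }
            for l in spec.ligands
        ],
        "exclusions": [
            [list(r.assignment_a), list(r.assignment_b)] for r in spec.exclusions
        ],
        "energy_terms": [
            {
                "label": t.label,
                "condition": sorted([list(p) for p in t.condition]),
                "delta_g": t.delta_g,
            }
            for t in spec.energy_terms
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path: str) -> ModelSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("units", "kcal/mol") != "kcal/mol":
        raise ValueError(
            f"model file {path!r} declares units {doc.get('units')!r}; "
            "energies must be kcal/mol"
        )
    return ModelSpec(
        sites=[
            SiteSpec(d["name"], tuple(d["configurations"]), d.get("kind", "other"))
            for d in doc.get("sites", [])
        ],
        ligands=[
            LigandSpec(d["species"], frozenset(tuple(p) for p in d["occupancy"]))
            for d in doc.get("ligands", [])
        ],
        exclusions=[
            ExclusionRule(tuple(a), tuple(b)) for a, b in doc.get("exclusions", [])
        ],
        energy_terms=[
            EnergyTerm(
                frozenset(tuple(p) for p in d["condition"]),
                float(d["delta_g"]),
                d.get("label", ""),
            )
            for d in doc.get("energy_terms", [])
        ],
    )


def write_condition(cond: Condition, path: str) -> None:
    doc = {
        "temperature_K": cond.temperature,
        "concentrations_M": dict(cond.concentrations),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_condition(path: str) -> Condition:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return Condition(
        temperature=float(doc["temperature_K"]),
        concentrations={k: float(v) for k, v in doc["concentrations_M"].items()},
    )


# ---------------------------------------------------------------------------
# Microstate table (TSV)


def write_microstates(
    spec: ModelSpec,
    microstates: Sequence[Microstate],
    path: str,
    dist: EquilibriumDistribution | None = None,
) -> None:
    rows = []
    for ms in microstates:
        row: dict[str, object] = {"index": ms.index}
        row.update({s: ms.assignment[s] for s in spec.site_names})
        row.update({f"n_{sp}": ms.stoichiometry.get(sp, 0) for sp in spec.species_names})
        row["delta_g"] = ms.delta_g
        if dist is not None:
            row["probability"] = dist.probabilities[ms.index]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Event-series TSV dialect: '#'-prefixed header with window and seed, then
# columns (time, site, new_configuration), times with 15 significant digits.


def write_event_series(
    series: Sequence[SiteEventSeries], path: str, seed: int | None = None
) -> None:
    if not series:
        raise ValueError("no series to write")
    w = series[0].window
    for s in series:
        if not np.allclose(s.window, w):
            raise ValueError("series share no common window")
    merged = []
    for s in series:
        for t, c in zip(s.event_times, s.new_configurations):
            merged.append((float(t), s.site, str(c)))
    merged.sort(key=lambda r: r[0])
    site_list = "\t".join(s.site for s in series)
    with open(path, "w") as fh:
        fh.write(f"# window\t{w[0]:.15g}\t{w[1]:.15g}\n")
        fh.write(f"# seed\t{'' if seed is None else seed}\n")
        fh.write(f"# sites\t{site_list}\n")
        fh.write("time\tsite\tnew_configuration\n")
        for t, site, cfg in merged:
            fh.write(f"{t:.15g}\t{site}\t{cfg}\n")


def read_event_series(path: str) -> dict[str, SiteEventSeries]:
    """Read the event TSV dialect back into per-site series.

    Rejects non-monotone times and duplicate timestamps: coincident events
    have measure zero under the continuous-time model, so duplicates signal
    a truncated or corrupted export — jitter or re-export the data.
    """
    window: tuple[float, float] | None = None
    sites_declared: list[str] = []
    rows: list[tuple[float, str, str]] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if parts[0] == "window":
                    window = (float(parts[1]), float(parts[2]))
                elif parts[0] == "sites":
                    sites_declared = parts[1:]
                continue
            if line.startswith("time\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 3 columns, got {len(parts)}")
            rows.append((float(parts[0]), parts[1], parts[2]))
    if window is None:
        if not rows:
            raise ValueError(f"{path}: empty event file without a window header")
        window = (0.0, rows[-1][0])
    times = [r[0] for r in rows]
    for k in range(1, len(times)):
        if times[k] < times[k - 1]:
            raise ValueError(f"{path}: non-monotone times at row {k + 1}")
        if times[k] == times[k - 1]:
            raise ValueError(
                f"{path}: duplicate timestamp {times[k]!r}; coincident events "
                "are measure-zero in continuous time — jitter or re-export"
            )
    sites = sites_declared or sorted({r[1] for r in rows})
    out: dict[str, SiteEventSeries] = {}
    for site in sites:
        mine = [(t, c) for t, s, c in rows if s == site]
        out[site] = SiteEventSeries(
            site=site,
            event_times=np.array([t for t, _ in mine]),
            new_configurations=np.array([c for _, c in mine], dtype=object),
            window=window,
        )
    return out


# ---------------------------------------------------------------------------
# Matrices and tables


def write_matrix(matrix: np.ndarray, names: Sequence[str], path: str) -> None:
    """Site-by-site numeric matrix with a name header row/column."""
    pd.DataFrame(matrix, index=list(names), columns=list(names)).to_csv(
        path, sep="\t", float_format="%.10g", index_label="site"
    )


def _fmt_ca(v: float) -> str:
    return "NA" if (v is None or (isinstance(v, float) and math.isnan(v))) else f"{v:.4f}"


def write_ca_table(table: Mapping[str, Mapping[str, object]], path: str) -> None:
    """Square CA table; rows are the following site a, columns the leader b.

    Accepts either floats or CAEstimate cells; undefined cells become NA.
    """
    names = list(table.keys())
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(names) + "\n")
        for a in names:
            cells = []
            for b in names:
                v = table[a][b]
                if isinstance(v, CAEstimate):
                    v = v.value if v.defined else float("nan")
                cells.append(_fmt_ca(v))
            fh.write(a + "\t" + "\t".join(cells) + "\n")


def write_ca_long(
    table: Mapping[str, Mapping[str, CAEstimate]], path: str
) -> None:
    rows = []
    for a, row in table.items():
        for b, est in row.items():
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "CA": _fmt_ca(est.value if est.defined else float("nan")),
                    "tau_x": est.tau_x,
                    "tau_p": est.tau_p,
                    "n_terms": est.n_b,
                    "n_dropped": est.n_dropped,
                    "se": "NA" if est.se is None else f"{est.se:.4g}",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_edge_list(
    rm: RateMatrix, dist: EquilibriumDistribution, path: str
) -> None:
    """Rate-matrix TSV edge list: i, j, q_ij, flux K_i q_ij, site, kind."""
    with open(path, "w") as fh:
        fh.write("i\tj\tq_ij\tflux\tsite\tkind\n")
        for i, j, s, kind in zip(
            rm.edge_i, rm.edge_j, rm.edge_site, rm.edge_kind
        ):
            q = rm.rates[i, j]
            fh.write(
                f"{i}\t{j}\t{q:.10g}\t{dist.probabilities[i] * q:.10g}"
                f"\t{rm.site_names[s]}\t{kind}\n"
            )


# ---------------------------------------------------------------------------
# Microstate graph exports (DOT and GraphML); node size follows
# log10-occupancy, edge weight log10-flux.


def microstate_graph(
    rm: RateMatrix, dist: EquilibriumDistribution
) -> nx.DiGraph:
    g = nx.DiGraph()
    k = dist.probabilities
    for i in range(rm.n_states):
        g.add_node(int(i), log10_occupancy=float(np.log10(k[i])))
    for i, j, s, kind in zip(rm.edge_i, rm.edge_j, rm.edge_site, rm.edge_kind):
        fl = k[i] * rm.rates[i, j]
        g.add_edge(
            int(i),
            int(j),
            log10_flux=float(np.log10(fl)) if fl > 0 else float("-inf"),
            site=rm.site_names[s],
            kind=kind,
        )
    return g


def write_dot(g: nx.DiGraph, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("digraph microstates {\n")
        for n, data in g.nodes(data=True):
            fh.write(
                f'  {n} [log10_occupancy="{data["log10_occupancy"]:.6g}"];\n'
            )
        for u, v, data in g.edges(data=True):
            fh.write(
                f'  {u} -> {v} [log10_flux="{data["log10_flux"]:.6g}", '
                f'site="{data["site"]}", kind="{data["kind"]}"];\n'
            )
        fh.write("}\n")


def write_graphml(g: nx.DiGraph, path: str) -> None:
    nx.write_graphml(g, path)
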