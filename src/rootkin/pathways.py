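"""Topology-aware pathway over-representation analysis.

Given a hit list of differentially accumulated compounds, a compound
universe and a library of pathways (member sets plus an undirected graph
per pathway), each pathway is scored by

* a hypergeometric upper-tail p-value for the overlap between hits and
  members,
* Benjamini-Hochberg FDR across pathways, and
* a topological impact score: the sum of relative betweenness-centrality
  weights of the hit members, normalized so a pathway's weights sum to 1.

A pathway is flagged dominant when -log10(p) > 2, impact > 0.1 and
FDR < 0.1 (defaults; all gates configurable).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy import stats

from .config import AnalysisThresholds
from .omics import bh_fdr

__all__ = [
    "PathwayDefinition",
    "PathwayError",
    "hypergeom_p",
    "node_importance",
    "pathway_impact",
    "enrich",
    "dominance_filter",
    "read_gmt",
    "read_edge_list",
    "load_pathways",
]


class PathwayError(ValueError):
    pass


@dataclass
class PathwayDefinition:
    """A pathway: member compound set plus undirected edges over members."""

    id: str
    name: str
    members: frozenset
    edges: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.members = frozenset(self.members)
        if not self.members:
            raise PathwayError(f"pathway {self.id} has no members")
        for a, b in self.edges:
            if a not in self.members or b not in self.members:
                raise PathwayError(f"pathway {self.id}: edge ({a}, {b}) references a non-member")

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.members)
        g.add_edges_from(self.edges)
        return g


def hypergeom_p(N: int, m: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``N`` universe size, ``m`` pathway size, ``n`` hit-list size, ``k``
    observed overlap.
    """
    if not (0 <= k <= min(m, n)) or m > N or n > N or min(N, m, n) < 0:
        raise PathwayError(f"inconsistent counts N={N}, m={m}, n={n}, k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, m, n))


def node_importance(pw: PathwayDefinition,
                    isolated_floor: bool = True) -> dict:
    """Relative betweenness-centrality weight per member, summing to 1.

    Betweenness is computed on the (possibly multi-component) pathway
    graph; isolated members, which carry no shortest paths, receive a
    uniform floor of 1/|members| before normalization so that compounds
    absent from the edge list still contribute (disable with
    ``isolated_floor=False``).  A single-member pathway gets weight 1.
    """
    g = pw.graph()
    if len(pw.members) == 1:
        return {next(iter(pw.members)): 1.0}
    bc = nx.betweenness_centrality(g, normalized=False)
    if isolated_floor:
        floor = 1.0 / len(pw.members)
        for node in g.nodes:
            if g.degree(node) == 0:
                bc[node] = floor
    total = sum(bc.values())
    if total == 0:
        # no interior nodes at all (e.g. a single edge): uniform weights
        return {node: 1.0 / len(pw.members) for node in pw.members}
    return {node: w / total for node, w in bc.items()}


def pathway_impact(pw: PathwayDefinition, hits) -> float:
    """Topological impact: summed weight of the hit members, in [0, 1]."""
    weights = node_importance(pw)
    return float(sum(w for node, w in weights.items() if node in set(hits)))


def enrich(pathways, hits, universe,
           thresholds: AnalysisThresholds = AnalysisThresholds()) -> pd.DataFrame:
    """Hypergeometric enrichment with impact and BH FDR across pathways.

    Returns a DataFrame sorted by p-value with columns ``pathway, name,
    N, m, n, k, p, fdr, impact, dominant``.  Raises when hits are not a
    subset of the universe.
    """
    hits = set(hits)
    universe = set(universe)
    strays = hits - universe
    if strays:
        raise PathwayError("hits absent from the universe: " + ", ".join(sorted(map(str, strays))[:10]))
    N, n = len(universe), len(hits)
    rows = []
    for pw in pathways:
        members = pw.members & universe
        m = len(members)
        k = len(members & hits)
        p = hypergeom_p(N, m, n, k) if m else 1.0
        rows.append({"pathway": pw.id, "name": pw.name, "N": N, "m": m, "n": n,
                     "k": k, "p": p, "impact": pathway_impact(pw, hits)})
    out = pd.DataFrame(rows)
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    return dominance_filter(out, thresholds)


def dominance_filter(results: pd.DataFrame,
                     thresholds: AnalysisThresholds = AnalysisThresholds()) -> pd.DataFrame:
    """Flag dominant pathways: -log10 p > 2, impact > 0.1, FDR < 0.1."""
    import numpy as np

    for col in ("p", "impact", "fdr"):
        if col not in results.columns:
            raise PathwayError(f"results lack the {col!r} column")
    p = results["p"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        neglog = np.where(p > 0, -np.log10(p), np.inf)
    out = results.copy()
    out["dominant"] = (
        (neglog > thresholds.pathway_neglog10p)
        & (out["impact"].to_numpy() > thresholds.pathway_impact)
        & (out["fdr"].to_numpy() < thresholds.pathway_fdr)
    )
    return out


# ---------------------------------------------------------------------------
# loaders


def read_gmt(path) -> dict[str, tuple[str, frozenset]]:
    """Read GMT pathway membership: id <TAB> description <TAB> members..."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise PathwayError(f"malformed GMT line: {line[:60]!r}")
            out[parts[0]] = (parts[1], frozenset(parts[2:]))
    return out


def read_edge_list(path) -> dict[str, list[tuple[str, str]]]:
    """Read a pathway edge list TSV: pathway <TAB> node_a <TAB> node_b."""
    df = pd.read_csv(path, sep="\t")
    for col in ("pathway", "node_a", "node_b"):
        if col not in df.columns:
            raise PathwayError(f"edge list lacks the {col!r} column")
    out: dict[str, list[tuple[str, str]]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["pathway"], []).append((row["node_a"], row["node_b"]))
    return out


def load_pathways(gmt_path, edges_path=None) -> list[PathwayDefinition]:
    """Assemble pathway definitions from a GMT file and optional edges."""
    membership = read_gmt(gmt_path)
    edges = read_edge_list(edges_path) if edges_path is not None else {}
    return [
        PathwayDefinition(id=pid, name=name, members=members,
                          edges=tuple(edges.get(pid, ())))
        for pid, (name, members) in membership.items()
    ]
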