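"""Heterogeneous strain-enzyme-metabolite graph and coverage/role statistics.

The metabolic graph has three node types (strain, enzyme, metabolite) and
three typed edge classes: binary strain-enzyme association (present iff the
strain's copy number is > 0), enzyme-substrate edges weighted by catalytic
efficiency (k_cat, defaulting to 1.0 where no value is supplied), and
strain-strain metabolic-complementarity edges weighted by a composite of
pathway-coverage Jaccard similarity and a metabolite exchange score, with
only the top fraction of pairs retained. Node count is always the sum of the
three type cardinalities; edge counts are emergent from the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MetabolicGraph",
    "StrainRole",
    "build_graph",
    "complementarity",
    "strain_coverage",
    "classify_roles",
]


@dataclass
class MetabolicGraph:
    """Typed heterogeneous graph plus the pollutant-pathway index."""

    graph: nx.Graph
    strains: list[str]
    enzymes: list[str]
    metabolites: list[str]
    pollutant_pathways: dict[str, list[str]]
    pathway_map: dict = field(default_factory=dict)
    profiles: pd.DataFrame | None = None

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def edges_of_type(self, etype: str) -> list[tuple]:
        return [
            (u, v, d) for u, v, d in self.graph.edges(data=True) if d.get("etype") == etype
        ]

    def to_edge_list(self) -> pd.DataFrame:
        rows = [
            {"src": u, "dst": v, "edge_type": d.get("etype"), "weight": d.get("weight", 1.0)}
            for u, v, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["src", "dst", "edge_type", "weight"])


@dataclass(frozen=True)
class StrainRole:
    """Ecological role of a strain inferred from its pathway repertoire.

    generalist: >= 1 pathway enzyme for every pollutant class;
    specialist: some but not all classes covered; inactive: none.
    Versatility rescales mean pathway completeness to a 0-4 score.
    """

    strain: str
    role: str  # {"generalist", "specialist", "inactive"}
    versatility: float  # in [0, 4]


def _pathway_enzymes_present(profiles: pd.DataFrame, strain: str, pathway: list[str]) -> set:
    row = profiles.loc[strain]
    return {e for e in pathway if e in profiles.columns and row[e] > 0}


def _strain_pathway_sets(profiles: pd.DataFrame, pathway_map: dict, strain: str) -> set:
    """All pathway enzymes (any pollutant) carried by the strain."""
    out = set()
    for pol in pathway_map["pollutants"]:
        out |= _pathway_enzymes_present(profiles, strain, pathway_map["pathways"][pol])
    return out


def _exchange_score(profiles: pd.DataFrame, pathway_map: dict, a: str, b: str) -> float:
    """Fraction of chain metabolites producible by one strain and consumable
    by the other, symmetrized by averaging the two directions."""
    producers: dict[str, set] = {}
    consumers: dict[str, set] = {}
    for pol, steps in pathway_map.get("chains", {}).items():
        for step in steps:
            for e in step["enzymes"]:
                producers.setdefault(step["product"], set()).add(e)
                consumers.setdefault(step["substrate"], set()).add(e)
    mets = sorted(set(producers) | set(consumers))
    if not mets:
        return 0.0

    def has_any(strain: str, enzymes: set) -> bool:
        row = profiles.loc[strain]
        return any(e in profiles.columns and row[e] > 0 for e in enzymes)

    def directional(src: str, dst: str) -> float:
        n = 0
        for m in mets:
            if has_any(src, producers.get(m, set())) and has_any(dst, consumers.get(m, set())):
                n += 1
        return n / len(mets)

    return 0.5 * (directional(a, b) + directional(b, a))


def complementarity(
    strain_a: str,
    strain_b: str,
    profiles: pd.DataFrame,
    pathway_map: dict,
    alpha: float = 0.5,
) -> float:
    """Composite metabolic complementarity of two strains, in [0, 1].

    ``alpha * Jaccard(pathway-enzyme sets) + (1 - alpha) * exchange score``.
    Symmetric; equals 1 for identical enzyme sets at alpha = 1.
    """
    for s in (strain_a, strain_b):
        if s not in profiles.index:
            raise KeyError(f"unknown strain: {s}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    sa = _strain_pathway_sets(profiles, pathway_map, strain_a)
    sb = _strain_pathway_sets(profiles, pathway_map, strain_b)
    union = sa | sb
    jac = 1.0 if not union else len(sa & sb) / len(union)
    if alpha == 1.0:
        return float(jac)
    ex = _exchange_score(profiles, pathway_map, strain_a, strain_b)
    return float(alpha * jac + (1.0 - alpha) * ex)


def build_graph(
    profiles: pd.DataFrame,
    pathway_map: dict,
    kcat_table: dict | None = None,
    complementarity_top_fraction: float = 0.10,
    alpha: float = 0.5,
    strict: bool = True,
) -> MetabolicGraph:
    """Assemble the heterogeneous metabolic graph from profiles and pathways.

    Parameters
    ----------
    profiles : DataFrame
        Strain x enzyme counts.
    pathway_map : dict
        As produced by :func:`syncomdesign.synthetic.generate_profiles` (or
        loaded from JSON): pollutant pathways, metabolite chains, and
        enzyme-substrate pairs.
    kcat_table : dict, optional
        EC number -> catalytic-efficiency weight for enzyme-substrate edges;
        absent entries default to 1.0. Overrides weights in the pathway map.
    complementarity_top_fraction : float
        Fraction of strain pairs (by composite weight) kept as strain-strain
        edges (top 10% by default).
    strict : bool
        If True, an enzyme present in the profiles but absent from the
        pathway map's namespace raises; otherwise a warning is emitted.
    """
    strains = list(profiles.index)
    enzymes = list(profiles.columns)
    metabolites = list(pathway_map["metabolites"])
    pathways = {pol: list(pathway_map["pathways"][pol]) for pol in pathway_map["pollutants"]}

    known = set(enzymes)
    mapped = set()
    for members in pathways.values():
        mapped |= set(members)
    for e, _m, _k in pathway_map.get("enzyme_substrate", []):
        mapped.add(e)
    orphan_mapped = mapped - known
    if orphan_mapped:
        msg = f"pathway map references enzymes absent from profiles: {sorted(orphan_mapped)[:5]}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)

    g = nx.Graph()
    g.add_nodes_from(strains, ntype="strain")
    g.add_nodes_from(enzymes, ntype="enzyme")
    g.add_nodes_from(metabolites, ntype="metabolite")

    # strain-enzyme: binary presence
    arr = profiles.to_numpy()
    for i, s in enumerate(strains):
        for j, e in enumerate(enzymes):
            if arr[i, j] > 0:
                g.add_edge(s, e, etype="strain-enzyme", weight=1.0)

    # enzyme-substrate: weighted by catalytic efficiency
    kcat_table = kcat_table or {}
    for e, m, kcat in pathway_map.get("enzyme_substrate", []):
        if e not in known or m not in set(metabolites):
            continue
        w = float(kcat_table.get(e, kcat if kcat is not None else 1.0))
        g.add_edge(e, m, etype="enzyme-substrate", weight=w)

    # strain-strain: composite complementarity, top fraction kept
    pairs = []
    if complementarity_top_fraction > 0:
        for i in range(len(strains)):
            for j in range(i + 1, len(strains)):
                w = complementarity(strains[i], strains[j], profiles, pathway_map, alpha=alpha)
                pairs.append((w, strains[i], strains[j]))
    if pairs and complementarity_top_fraction > 0:
        pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
        keep = max(1, int(round(complementarity_top_fraction * len(pairs))))
        for w, a, b in pairs[:keep]:
            g.add_edge(a, b, etype="strain-strain", weight=w)

    return MetabolicGraph(
        graph=g,
        strains=strains,
        enzymes=enzymes,
        metabolites=metabolites,
        pollutant_pathways=pathways,
        pathway_map=pathway_map,
        profiles=profiles,
    )


def strain_coverage(mg: MetabolicGraph, pollutant: str) -> dict:
    """Fraction of strains carrying >= 1 pathway enzyme for the pollutant."""
    if pollutant not in mg.pollutant_pathways:
        raise KeyError(f"unknown pollutant: {pollutant}")
    if mg.profiles is None:
        raise ValueError("graph carries no profile table")
    pathway = mg.pollutant_pathways[pollutant]
    n = sum(
        1
        for s in mg.strains
        if _pathway_enzymes_present(mg.profiles, s, pathway)
    )
    frac = n / len(mg.strains) if mg.strains else 0.0
    return {"fraction": frac, "percent": round(100.0 * frac, 1), "n_covered": n}


def classify_roles(mg: MetabolicGraph, completeness_scale: int = 3) -> list[StrainRole]:
    """Assign generalist/specialist/inactive roles and 0-4 versatility scores.

    Versatility = 4 x mean over pollutants of min(1, n_pathway_enzymes /
    ``completeness_scale``) — a saturating proxy for pathway completeness and
    enzyme redundancy, clipped to [0, 4]. Each strain's score depends only on
    its own repertoire (locality).
    """
    if mg.profiles is None:
        raise ValueError("graph carries no profile table")
    pollutants = list(mg.pollutant_pathways)
    roles = []
    for s in mg.strains:
        per_class = [
            len(_pathway_enzymes_present(mg.profiles, s, mg.pollutant_pathways[pol]))
            for pol in pollutants
        ]
        covered = sum(1 for c in per_class if c > 0)
        if covered == len(pollutants):
            role = "generalist"
        elif covered == 0:
            role = "inactive"
        else:
            role = "specialist"
        vers = 4.0 * float(
            np.mean([min(1.0, c / completeness_scale) for c in per_class])
        )
        roles.append(StrainRole(strain=s, role=role, versatility=float(np.clip(vers, 0.0, 4.0))))
    return roles
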