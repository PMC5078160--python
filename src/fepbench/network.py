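"""Perturbation networks of relative binding free energies.

Alchemical transformations connect ligands (and auxiliary reference
ligands inserted to keep each perturbation small) in a graph whose edge
values are relative binding free energies,
``value = dG_bind(to) - dG_bind(from)`` in kJ/mol.  Relative affinities
between any two ligands follow from the thermodynamic cycle by summing
signed edge values along a path; edge standard errors combine in
quadrature (correlations between shared path segments are ignored).

Edges perturbing a ring-flippable ligand carry two conformer candidates;
the selected one is the candidate giving the most favourable binding
energy of the non-reference ligand relative to the reference, matching how
the study resolved its duplicate perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

from .estimators import FreeEnergyEstimate
from .exceptions import ConfigurationError, InputError, PathError

__all__ = [
    "Ligand",
    "EdgeCandidate",
    "PerturbationEdge",
    "PerturbationNetwork",
    "select_conformer",
    "relative_affinity",
    "all_pairs_table",
]


@dataclass(frozen=True)
class Ligand:
    """One ligand node; reference ligands have no experimental affinity."""

    id: str
    set_id: int
    experimental_dg: float | None = None
    is_reference: bool = False
    non_binder: bool = False

    def __post_init__(self):
        if self.is_reference and self.experimental_dg is not None:
            raise InputError(
                f"reference ligand {self.id!r} cannot carry experimental data"
            )


@dataclass(frozen=True)
class EdgeCandidate:
    """One conformer's estimate for an edge: ddG value, SE, conformer label."""

    value: float
    se: float
    conformer: str = "conf1"

    def __post_init__(self):
        if self.se < 0:
            raise InputError(f"candidate SE must be >= 0, got {self.se}")


@dataclass
class PerturbationEdge:
    """A directed alchemical transformation with >= 1 conformer candidate.

    ``selected`` may pre-record the chosen candidate (e.g. for edges between
    two non-reference ligands where the automatic rule is undefined).
    """

    from_ligand: str
    to_ligand: str
    candidates: tuple[EdgeCandidate, ...]
    selected: EdgeCandidate | None = None

    def __post_init__(self):
        self.candidates = tuple(self.candidates)
        if not self.candidates:
            raise InputError(
                f"edge {self.from_ligand}->{self.to_ligand}: no candidates"
            )
        if self.selected is not None and self.selected not in self.candidates:
            raise InputError(
                f"edge {self.from_ligand}->{self.to_ligand}: selected "
                "candidate not among candidates"
            )


def select_conformer(
    edge: PerturbationEdge, references: Iterable[str] = ()
) -> EdgeCandidate:
    """Pick the conformer giving the most favourable non-reference binding.

    With ``value = dG_bind(to) - dG_bind(from)``: for an edge X -> ref the
    most favourable dG_bind(X) corresponds to the maximal value; for
    ref -> X to the minimal value.  Ties keep the first-listed candidate.
    For an edge between two non-reference ligands the rule is undefined and
    a pre-recorded selection is required.
    """
    if len(edge.candidates) == 1:
        return edge.candidates[0]
    refs = set(references)
    to_ref = edge.to_ligand in refs
    from_ref = edge.from_ligand in refs
    if to_ref and not from_ref:
        best = max(edge.candidates, key=lambda c: c.value)
    elif from_ref and not to_ref:
        best = min(edge.candidates, key=lambda c: c.value)
    else:
        if edge.selected is not None:
            return edge.selected
        raise ConfigurationError(
            f"edge {edge.from_ligand}->{edge.to_ligand}: conformer selection "
            "between two non-reference ligands is undefined; record an "
            "explicit selection"
        )
    # max/min return the first of tied candidates only for max; enforce
    # first-listed tie-breaking explicitly for both directions.
    target = best.value
    for cand in edge.candidates:
        if cand.value == target:
            return cand
    return best


@dataclass
class PerturbationNetwork:
    """Ligand nodes plus directed perturbation edges for one ligand set."""

    ligands: dict[str, Ligand]
    edges: list[PerturbationEdge]
    set_id: int | None = None
    _graph: nx.Graph = field(init=False, repr=False)

    def __post_init__(self):
        seen = set()
        for edge in self.edges:
            key = (edge.from_ligand, edge.to_ligand)
            if key in seen:
                raise InputError(f"duplicate directed edge {key[0]}->{key[1]}")
            seen.add(key)
            for lid in key:
                if lid not in self.ligands:
                    raise InputError(f"edge references unknown ligand {lid!r}")
        self._rebuild_graph()

    def _rebuild_graph(self):
        g = nx.Graph()
        g.add_nodes_from(self.ligands)
        refs = self.reference_ids()
        for edge in self.edges:
            cand = edge.selected or select_conformer(edge, refs)
            edge.selected = cand
            g.add_edge(
                edge.from_ligand, edge.to_ligand,
                value=cand.value, se=cand.se,
                source=edge.from_ligand,
            )
        self._graph = g

    def reference_ids(self) -> set[str]:
        return {l.id for l in self.ligands.values() if l.is_reference}

    def real_ligands(self, include_nonbinders: bool = False) -> list[Ligand]:
        """Non-reference ligands with experimental data, ordered by id."""
        out = [
            l for l in self.ligands.values()
            if not l.is_reference and l.experimental_dg is not None
            and (include_nonbinders or not l.non_binder)
        ]
        return sorted(out, key=lambda l: l.id)


def relative_affinity(
    net: PerturbationNetwork,
    ligand_a: str,
    ligand_b: str,
    max_edges: int | None = None,
) -> FreeEnergyEstimate:
    """Relative binding free energy dG_bind(b) - dG_bind(a) along the
    shortest path (fewest edges), with SE the quadrature sum of edge SEs.

    ``relative_affinity(net, a, a)`` is exactly 0 +/- 0.  Raises
    :class:`PathError` when no path exists within ``max_edges`` edges.
    """
    for lid in (ligand_a, ligand_b):
        if lid not in net.ligands:
            raise InputError(f"unknown ligand {lid!r}")
    if ligand_a == ligand_b:
        return FreeEnergyEstimate(0.0, 0.0, "network", (ligand_a, ligand_b))
    try:
        path = nx.shortest_path(net._graph, ligand_a, ligand_b)
    except nx.NetworkXNoPath:
        raise PathError(
            f"no path between {ligand_a!r} and {ligand_b!r}"
        ) from None
    n_edges = len(path) - 1
    if max_edges is not None and n_edges > max_edges:
        raise PathError(
            f"path {ligand_a!r}->{ligand_b!r} needs {n_edges} edges, more "
            f"than the allowed {max_edges}"
        )
    total = 0.0
    var = 0.0
    for x, y in zip(path[:-1], path[1:]):
        data = net._graph.edges[x, y]
        sign = 1.0 if data["source"] == x else -1.0
        total += sign * data["value"]
        var += data["se"] ** 2
    return FreeEnergyEstimate(
        value=float(total), se=float(np.sqrt(var)), method="network",
        direction=(ligand_a, ligand_b), meta={"n_edges": n_edges},
    )


def all_pairs_table(
    net: PerturbationNetwork,
    scheme: str,
    reference: str | None = None,
    include_nonbinders: bool = False,
) -> pd.DataFrame:
    """Tabulate calculated vs experimental relative affinities.

    Schemes mirror the three comparison modes of the study:

    * ``"fixed_reference"`` — every ligand against one chosen ligand (which
      must carry experimental data);
    * ``"max_two_edges"`` — all ligand pairs reachable within two
      perturbations;
    * ``"all_pairs"`` — every pair of experimentally characterised ligands.

    Returns a DataFrame with columns ``ligand_a, ligand_b, calc, se, exp``
    where ``calc`` and ``exp`` are dG(b) - dG(a).  Non-binders are excluded
    unless ``include_nonbinders`` (they then enter at their assigned bound).
    """
    real = net.real_ligands(include_nonbinders=include_nonbinders)
    ids = [l.id for l in real]
    exp = {l.id: l.experimental_dg for l in real}

    if scheme == "fixed_reference":
        if reference is None:
            raise ConfigurationError("fixed_reference scheme needs a reference")
        if reference not in exp:
            raise ConfigurationError(
                f"reference {reference!r} has no experimental value or is "
                "excluded"
            )
        pairs = [(lid, reference) for lid in ids if lid != reference]
        max_edges = None
    elif scheme == "max_two_edges":
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        max_edges = 2
    elif scheme == "all_pairs":
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        max_edges = None
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")

    rows = []
    for a, b in pairs:
        try:
            est = relative_affinity(net, a, b, max_edges=max_edges)
        except PathError:
            if scheme == "max_two_edges":
                continue
            raise
        rows.append({
            "ligand_a": a, "ligand_b": b,
            "calc": est.value, "se": est.se,
            "exp": exp[b] - exp[a],
        })
    return pd.DataFrame(rows, columns=["ligand_a", "ligand_b", "calc", "se", "exp"])
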