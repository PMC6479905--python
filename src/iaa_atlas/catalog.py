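"""Declarative model of the tryptophan-dependent IAA biosynthesis pathways.

Bacteria synthesize the auxin indole-3-acetic acid (IAA) from tryptophan
through four canonical routes named after their first committed
intermediate: indole-3-pyruvate (IPA), tryptamine (TPM), indole-3-acetamide
(IAM) and indole-3-acetonitrile (IAN).  This module represents that
biochemistry as a small directed multigraph whose nodes are metabolites and
whose edges are enzyme roles, each role carrying the set of KEGG orthology
(KO) identifiers that evidence it.  All downstream classification logic
operates on this graph, so the KO roster is configuration, never code.

Two structural facts of the network matter for classification and are
encoded in the default catalog:

* IPA -> IAA has two route variants (one-step YUCCA-like monooxygenase, or
  indolepyruvate decarboxylase ipdC followed by an aldehyde dehydrogenase),
  and likewise IAN -> IAA (one-step nitrilase, or nitrile hydratase into the
  IAM hydrolase).  The nitrile hydratase therefore links the IAN and IAM
  pathways, and shared roles may legitimately serve several pathways.
* The Trp -> IAOX oxidoreductase opening the IAN pathway has no known
  bacterial orthologue, so with the default catalog the IAN pathway can be
  completed only from the IAN intermediate, never de novo from Trp.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import yaml

__all__ = [
    "Metabolite",
    "EnzymeRole",
    "Route",
    "PathwayCatalog",
    "CatalogError",
    "load_catalog",
    "save_catalog",
    "default_catalog",
    "enumerate_routes",
]

PATHWAY_IDS = ("IPA", "TPM", "IAM", "IAN")


class CatalogError(ValueError):
    """Raised when a pathway-catalog definition fails validation."""


@dataclass(frozen=True)
class Metabolite:
    """A node of the pathway graph.

    ``pathway`` optionally pins the metabolite to one of the four named
    pathways; intermediates default to the pathway carrying their own name
    (IPA, TPM, IAM, IAN).
    """

    id: str
    is_intermediate: bool = False
    pathway: str | None = None


@dataclass(frozen=True)
class EnzymeRole:
    """A catalytic step: one enzyme class converting substrate to product.

    ``ko_ids`` is the non-empty set of KEGG orthology identifiers whose
    presence in a genome evidences the role.
    """

    role_id: str
    ko_ids: frozenset[str]
    substrate: str
    product: str

    def __post_init__(self) -> None:
        if not self.ko_ids:
            raise CatalogError(f"role {self.role_id!r} has an empty KO set")
        if self.substrate == self.product:
            raise CatalogError(
                f"role {self.role_id!r}: substrate equals product ({self.substrate!r})"
            )


@dataclass(frozen=True)
class Route:
    """An ordered chain of enzyme roles from a start metabolite to IAA."""

    route_id: str
    pathway_id: str
    start: str
    steps: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.steps)


def _route_id(start: str, steps: Iterable[str]) -> str:
    return f"{start}:" + "+".join(steps)


class PathwayCatalog:
    """Validated collection of metabolites, enzyme roles and routes.

    Routes are derived by exhaustive simple-path enumeration over the role
    multigraph; the constructor validates referential integrity, uniqueness,
    the single terminal metabolite, and that the source metabolite (Trp) has
    no producing role.
    """

    def __init__(
        self,
        metabolites: Iterable[Metabolite],
        roles: Iterable[EnzymeRole],
        version: str = "",
        source: str = "Trp",
        terminal: str = "IAA",
    ) -> None:
        self.version = version
        self.source = source
        self.terminal = terminal
        self.metabolites: dict[str, Metabolite] = {}
        for m in metabolites:
            if m.id in self.metabolites:
                raise CatalogError(f"duplicate metabolite id {m.id!r}")
            self.metabolites[m.id] = m
        for required in (source, terminal):
            if required not in self.metabolites:
                raise CatalogError(f"catalog lacks required metabolite {required!r}")
        self.roles: dict[str, EnzymeRole] = {}
        for r in roles:
            if r.role_id in self.roles:
                raise CatalogError(f"duplicate role id {r.role_id!r}")
            for met in (r.substrate, r.product):
                if met not in self.metabolites:
                    raise CatalogError(
                        f"role {r.role_id!r} references unknown metabolite {met!r}"
                    )
            if r.product == source:
                raise CatalogError(
                    f"role {r.role_id!r} produces the source metabolite {source!r}"
                )
            self.roles[r.role_id] = r

        self._graph = nx.MultiDiGraph()
        self._graph.add_nodes_from(self.metabolites)
        for r in self.roles.values():
            self._graph.add_edge(r.substrate, r.product, key=r.role_id)

        self._pathway_of = self._resolve_pathways()
        self.routes: dict[str, Route] = {}
        for start in [source, *self.intermediate_ids]:
            for route in self._enumerate_from(start):
                self.routes[route.route_id] = route
        for m in self.metabolites.values():
            if m.is_intermediate and not any(
                r.start == m.id for r in self.routes.values()
            ):
                raise CatalogError(
                    f"intermediate {m.id!r}: no route to {terminal!r} (chain break)"
                )

    # -- structure ---------------------------------------------------------

    @property
    def graph(self) -> nx.MultiDiGraph:
        return self._graph

    @property
    def intermediate_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites.values() if m.is_intermediate)

    @property
    def pathway_ids(self) -> tuple[str, ...]:
        return tuple(sorted({r.pathway_id for r in self.routes.values()}))

    @property
    def trp_roles(self) -> tuple[EnzymeRole, ...]:
        """Roles whose substrate is the source metabolite (the Trp-catalyzing step)."""
        return tuple(
            r for r in self.roles.values() if r.substrate == self.source
        )

    @property
    def all_ko_ids(self) -> frozenset[str]:
        return frozenset(ko for r in self.roles.values() for ko in r.ko_ids)

    def _resolve_pathways(self) -> dict[str, str]:
        mapping: dict[str, str] = {}
        for m in self.metabolites.values():
            if m.pathway is not None:
                mapping[m.id] = m.pathway
            elif m.is_intermediate:
                mapping[m.id] = m.id
        return mapping

    def pathway_of(self, metabolite_id: str) -> str:
        """Named pathway a metabolite belongs to (intermediates own their name)."""
        if metabolite_id not in self.metabolites:
            raise CatalogError(f"unknown metabolite {metabolite_id!r}")
        try:
            return self._pathway_of[metabolite_id]
        except KeyError:
            raise CatalogError(
                f"metabolite {metabolite_id!r} is not assigned to a pathway"
            ) from None

    def pathways_of_role(self, role_id: str) -> frozenset[str]:
        """Pathways whose routes use the role (shared roles serve several)."""
        if role_id not in self.roles:
            raise CatalogError(f"unknown role {role_id!r}")
        return frozenset(
            r.pathway_id for r in self.routes.values() if role_id in r.steps
        )

    # -- route enumeration -------------------------------------------------

    def _enumerate_from(self, start: str) -> list[Route]:
        if start == self.terminal:
            return []
        routes = []
        for edge_path in nx.all_simple_edge_paths(self._graph, start, self.terminal):
            steps = tuple(key for (_, _, key) in edge_path)
            # a route belongs to the pathway of its first intermediate (de novo)
            # or of its start; metabolites without a pathway keep their own name
            anchor = edge_path[0][1] if start == self.source else start
            pathway = self._pathway_of.get(anchor, anchor)
            routes.append(
                Route(
                    route_id=_route_id(start, steps),
                    pathway_id=pathway,
                    start=start,
                    steps=steps,
                )
            )
        return sorted(routes, key=lambda r: r.route_id)

    def routes_from(self, start: str) -> tuple[Route, ...]:
        """All routes from ``start`` to the terminal metabolite."""
        if start not in self.metabolites:
            raise CatalogError(f"unknown metabolite {start!r}")
        cached = tuple(
            r for r in sorted(self.routes.values(), key=lambda r: r.route_id)
            if r.start == start
        )
        if cached or start == self.source or start in self.intermediate_ids:
            return cached
        return tuple(self._enumerate_from(start))

    def denovo_routes(self) -> tuple[Route, ...]:
        return self.routes_from(self.source)

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "source": self.source,
            "terminal": self.terminal,
            "metabolites": [
                {
                    "id": m.id,
                    **({"intermediate": True} if m.is_intermediate else {}),
                    **({"pathway": m.pathway} if m.pathway else {}),
                }
                for m in self.metabolites.values()
            ],
            "roles": {
                r.role_id: {
                    "ko_ids": sorted(r.ko_ids),
                    "substrate": r.substrate,
                    "product": r.product,
                }
                for r in self.roles.values()
            },
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PathwayCatalog):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"<PathwayCatalog v{self.version or '?'}: "
            f"{len(self.metabolites)} metabolites, {len(self.roles)} roles, "
            f"{len(self.routes)} routes>"
        )


def catalog_from_dict(data: Mapping) -> PathwayCatalog:
    """Build and validate a catalog from a parsed config mapping."""
    try:
        raw_mets = data["metabolites"]
        raw_roles = data["roles"]
    except (KeyError, TypeError) as exc:
        raise CatalogError(f"catalog config missing section: {exc}") from exc
    metabolites = [
        Metabolite(
            id=m["id"],
            is_intermediate=bool(m.get("intermediate", False)),
            pathway=m.get("pathway"),
        )
        for m in raw_mets
    ]
    roles = []
    for role_id, spec in raw_roles.items():
        try:
            roles.append(
                EnzymeRole(
                    role_id=role_id,
                    ko_ids=frozenset(spec["ko_ids"]),
                    substrate=spec["substrate"],
                    product=spec["product"],
                )
            )
        except KeyError as exc:
            raise CatalogError(f"role {role_id!r} missing field {exc}") from exc
    return PathwayCatalog(
        metabolites,
        roles,
        version=str(data.get("version", "")),
        source=data.get("source", "Trp"),
        terminal=data.get("terminal", "IAA"),
    )


def load_catalog(path: str | Path) -> PathwayCatalog:
    """Load and validate a pathway catalog from a YAML (or JSON) config file."""
    path = Path(path)
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise CatalogError(f"cannot parse catalog config {path}: {exc}") from exc
    if not isinstance(data, Mapping):
        raise CatalogError(f"catalog config {path} is not a mapping")
    return catalog_from_dict(data)


def save_catalog(catalog: PathwayCatalog, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(catalog.to_dict(), fh, sort_keys=False)


def default_catalog() -> PathwayCatalog:
    """The catalog shipped with the package (the four-pathway default graph)."""
    ref = importlib.resources.files("iaa_atlas").joinpath("data/default_catalog.yaml")
    data = yaml.safe_load(ref.read_text())
    return catalog_from_dict(data)


def enumerate_routes(catalog: PathwayCatalog, start: str) -> frozenset[Route]:
    """All simple role-paths from ``start`` to IAA, deduplicated."""
    return frozenset(catalog.routes_from(start))
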