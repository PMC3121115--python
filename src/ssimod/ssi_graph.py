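"""Typed reaction-graph representation and validation of SSI metabolic modules.

An SSI module is a triple (state nodes, reactions, inhibitions) in which every
reaction converts a single substrate into a single product and at least one
reaction is inhibited by a metabolite.  Node roles (input / output / state)
are always *derived* from the directions of the reaction edges; inhibition
edges never influence a role.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import networkx as nx

from .errors import StructuralError

__all__ = [
    "KineticParams",
    "Reaction",
    "MetaboliteNode",
    "SSIModule",
    "ReactionClassMap",
    "NodeClassification",
    "Violation",
    "ValidationReport",
    "validate_module",
    "classify_nodes",
    "classify_reactions",
    "export_reaction_graph",
    "state_order",
]

ROLES = ("input", "output", "state")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of one reaction.

    ``k_m`` is canonical; the saturation constant ``k`` is always the derived
    quantity ``k_m ** n`` and is never stored independently.  Inhibition
    constants are keyed by inhibitor node id.
    """

    v_max: float
    k_m: float
    n: float = 1.0
    k_c: Mapping[str, float] = field(default_factory=dict)
    k_u: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.v_max > 0 and math.isfinite(self.v_max)):
            raise ValueError(f"v_max must be positive and finite, got {self.v_max}")
        if not (self.k_m > 0 and math.isfinite(self.k_m)):
            raise ValueError(f"k_m must be positive and finite, got {self.k_m}")
        if not (self.n >= 1 and math.isfinite(self.n)):
            raise ValueError(f"Hill coefficient n must be >= 1, got {self.n}")
        for name, table in (("k_c", self.k_c), ("k_u", self.k_u)):
            for node, value in table.items():
                if not (value > 0 and math.isfinite(value)):
                    raise ValueError(f"{name}[{node!r}] must be positive, got {value}")
        object.__setattr__(self, "k_c", dict(self.k_c))
        object.__setattr__(self, "k_u", dict(self.k_u))

    @property
    def k(self) -> float:
        """Saturation constant ``k_m ** n`` (derived, never stored)."""
        return self.k_m ** self.n

    @classmethod
    def from_k(cls, v_max: float, k: float, n: float = 1.0, **kw) -> "KineticParams":
        """Build params from the saturation constant ``k`` instead of ``k_m``."""
        if not (k > 0 and math.isfinite(k)):
            raise ValueError(f"k must be positive and finite, got {k}")
        return cls(v_max=v_max, k_m=k ** (1.0 / n), n=n, **kw)


@dataclass(frozen=True)
class Reaction:
    """A single-substrate single-product reaction.

    A reversible reaction must be declared as two separate records (forward
    and reverse).  ``inhibitors`` lists the metabolites inhibiting this
    reaction; the data model allows several, downstream analysis may not.
    """

    id: str
    substrate: str
    product: str
    inhibitors: tuple[str, ...] = ()
    params: Optional[KineticParams] = None

    def __post_init__(self):
        object.__setattr__(self, "inhibitors", tuple(self.inhibitors))


@dataclass(frozen=True)
class MetaboliteNode:
    id: str
    role: str  # derived: "input" | "output" | "state"

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")


class SSIModule:
    """The triple (state nodes, reactions, inhibitions) plus bookkeeping.

    ``nodes`` is the ordered tuple of all metabolite ids (declaration order
    fixes the state ordering used by every downstream matrix).  Declared
    roles, if any, are cross-checked against derived roles at validation.
    ``allow_ssn`` flags a module deliberately built without inhibition
    (an SSN-like module); the nonempty-inhibition clause is then recorded as
    a note instead of a violation.
    """

    def __init__(
        self,
        nodes: Iterable[str],
        reactions: Iterable[Reaction],
        declared_roles: Optional[Mapping[str, str]] = None,
        allow_ssn: bool = False,
        name: str = "",
    ):
        self.nodes: tuple[str, ...] = tuple(nodes)
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.declared_roles: dict[str, str] = dict(declared_roles or {})
        self.allow_ssn = bool(allow_ssn)
        self.name = name
        self._check_structure()

    # -- structural well-formedness (references resolve, ids unique) --------
    def _check_structure(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            raise StructuralError("duplicate node ids")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            raise StructuralError("duplicate reaction ids")
        node_set = set(self.nodes)
        for r in self.reactions:
            for ref in (r.substrate, r.product, *r.inhibitors):
                if ref not in node_set:
                    raise StructuralError(
                        f"reaction {r.id!r} references unknown node {ref!r}"
                    )
        for node, role in self.declared_roles.items():
            if node not in node_set:
                raise StructuralError(f"declared role for unknown node {node!r}")
            if role not in ROLES:
                raise StructuralError(f"unknown declared role {role!r} for {node!r}")

    @property
    def inhibitions(self) -> frozenset[tuple[str, str]]:
        """The inhibition relation as (inhibitor node id, reaction id) pairs."""
        return frozenset(
            (i, r.id) for r in self.reactions for i in r.inhibitors
        )

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SSIModule):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.reactions == other.reactions
            and self.declared_roles == other.declared_roles
            and self.allow_ssn == other.allow_ssn
            and self.name == other.name
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SSIModule(name={self.name!r}, nodes={len(self.nodes)}, "
            f"reactions={len(self.reactions)}, inhibitions={len(self.inhibitions)})"
        )


# ---------------------------------------------------------------------------
# node classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NodeClassification:
    roles: Mapping[str, str]
    heads: frozenset[str]  # state nodes adjacent (by reaction edge) to an input
    ends: frozenset[str]   # state nodes adjacent (by reaction edge) to an output

    def of_role(self, role: str) -> frozenset[str]:
        return frozenset(n for n, r in self.roles.items() if r == role)


def classify_nodes(module: SSIModule) -> NodeClassification:
    """Derive input/output/state roles from reaction-edge directions only.

    A node whose reaction edges all point away is an input node; all pointing
    toward it, an output node; anything else is a state node.  A node with no
    incident reaction edge cannot be classified (it is relevant to nothing).
    """
    outgoing: dict[str, int] = {n: 0 for n in module.nodes}
    incoming: dict[str, int] = {n: 0 for n in module.nodes}
    for r in module.reactions:
        outgoing[r.substrate] += 1
        incoming[r.product] += 1
    roles: dict[str, str] = {}
    for n in module.nodes:
        if outgoing[n] == 0 and incoming[n] == 0:
            raise StructuralError(
                f"node {n!r} has no incident reaction edge and cannot be classified"
            )
        if incoming[n] == 0:
            roles[n] = "input"
        elif outgoing[n] == 0:
            roles[n] = "output"
        else:
            roles[n] = "state"
    heads, ends = set(), set()
    for r in module.reactions:
        if roles[r.substrate] == "input" and roles[r.product] == "state":
            heads.add(r.product)
        if roles[r.product] == "output" and roles[r.substrate] == "state":
            ends.add(r.substrate)
    return NodeClassification(roles=roles, heads=frozenset(heads), ends=frozenset(ends))


def state_order(module: SSIModule) -> tuple[str, ...]:
    """State nodes in module declaration order — the coordinate order of
    every state vector and Jacobian built from this module."""
    roles = classify_nodes(module).roles
    return tuple(n for n in module.nodes if roles[n] == "state")


# ---------------------------------------------------------------------------
# reaction classification (N1..N4)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionClassMap:
    """Partition of reaction ids by (inhibited?, substrate role).

    n1: uninhibited, input substrate;   n2: inhibited, input substrate;
    n3: uninhibited, state substrate;   n4: inhibited, state substrate.
    """

    n1: frozenset[str]
    n2: frozenset[str]
    n3: frozenset[str]
    n4: frozenset[str]

    def __post_init__(self):
        sets = [self.n1, self.n2, self.n3, self.n4]
        total = sum(len(s) for s in sets)
        if len(self.n1 | self.n2 | self.n3 | self.n4) != total:
            raise ValueError("classes must be disjoint")


def classify_reactions(module: SSIModule) -> ReactionClassMap:
    roles = classify_nodes(module).roles
    n1, n2, n3, n4 = set(), set(), set(), set()
    for r in module.reactions:
        inhibited = bool(r.inhibitors)
        sub_role = roles[r.substrate]
        if sub_role == "input":
            (n2 if inhibited else n1).add(r.id)
        else:
            (n4 if inhibited else n3).add(r.id)
    return ReactionClassMap(
        n1=frozenset(n1), n2=frozenset(n2), n3=frozenset(n3), n4=frozenset(n4)
    )


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    clause: str     # "i".."vi" or a named structural rule
    message: str
    offenders: tuple[str, ...] = ()


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.violations

    def clauses(self) -> set[str]:
        return {v.clause for v in self.violations}

    def __str__(self) -> str:
        if self.is_valid:
            return "valid module" + (f" ({len(self.notes)} notes)" if self.notes else "")
        lines = [f"[{v.clause}] {v.message}" for v in self.violations]
        return "invalid module:\n" + "\n".join(lines)


def _relevant_nodes(r: Reaction) -> set[str]:
    return {r.substrate, r.product, *r.inhibitors}


def validate_module(module: SSIModule) -> ValidationReport:
    """Check the module-definition clauses (i)-(vi) plus the structural rules.

    Returns a report listing every violated clause with offenders; the report
    is empty exactly when the triple is a well-formed module.  Unresolvable
    references raise :class:`StructuralError` (already enforced at
    construction) rather than appearing as clause violations.
    """
    report = ValidationReport()
    cls = classify_nodes(module)  # raises StructuralError for isolated nodes
    roles = cls.roles
    states = [n for n in module.nodes if roles[n] == "state"]
    state_set = set(states)

    # (i) nonempty state-node set
    if not states:
        report.violations.append(
            Violation("i", "module has no state nodes")
        )

    # (ii) declared reactions == reactions relevant to the state nodes
    for r in module.reactions:
        if not (_relevant_nodes(r) & state_set):
            report.violations.append(
                Violation(
                    "ii",
                    f"reaction {r.id!r} is relevant to no state node (extra reaction)",
                    (r.id,),
                )
            )

    # (iii) all reactions single-substrate single-product. The data model
    # only represents SS reactions; substrate == product is the remaining
    # degenerate case.
    for r in module.reactions:
        if r.substrate == r.product:
            report.violations.append(
                Violation("iii", f"reaction {r.id!r} has substrate == product", (r.id,))
            )

    # (iv) inhibition relation nonempty (references resolve by construction)
    if not module.inhibitions:
        if module.allow_ssn:
            report.notes.append(
                "no inhibition edges: SSN-like module (explicitly allowed)"
            )
        else:
            report.violations.append(
                Violation("iv", "inhibition set is empty")
            )

    # (v) with both input and output nodes present, every state node must lie
    # on a directed input -> output path of reaction edges
    inputs = [n for n in module.nodes if roles[n] == "input"]
    outputs = [n for n in module.nodes if roles[n] == "output"]
    if inputs and outputs:
        dg = nx.DiGraph()
        dg.add_nodes_from(module.nodes)
        dg.add_edges_from((r.substrate, r.product) for r in module.reactions)
        reach_from_input = set()
        for i in inputs:
            reach_from_input |= nx.descendants(dg, i)
        reach_to_output = set()
        rg = dg.reverse(copy=False)
        for o in outputs:
            reach_to_output |= nx.descendants(rg, o)
        stranded = sorted(state_set - (reach_from_input & reach_to_output))
        if stranded:
            report.violations.append(
                Violation(
                    "v",
                    "state node(s) on no directed input->output path: "
                    + ", ".join(stranded),
                    tuple(stranded),
                )
            )
    else:
        report.notes.append(
            "input->output path clause not applicable "
            "(module lacks input nodes, output nodes, or both)"
        )

    # (vi) connectivity of the undirected state-to-state reaction graph
    if states:
        ug = nx.Graph()
        ug.add_nodes_from(states)
        for r in module.reactions:
            if r.substrate in state_set and r.product in state_set:
                ug.add_edge(r.substrate, r.product)
        if not nx.is_connected(ug):
            comps = [sorted(c) for c in nx.connected_components(ug)]
            report.violations.append(
                Violation(
                    "vi",
                    f"state graph is disconnected: components {comps}",
                    tuple(states),
                )
            )

    # structural rule: an inhibitor may not be the substrate or product of
    # the reaction it inhibits (outside the scope of the rate laws)
    for r in module.reactions:
        for i in r.inhibitors:
            if i in (r.substrate, r.product):
                report.violations.append(
                    Violation(
                        "inhibitor_overlap",
                        f"node {i!r} inhibits reaction {r.id!r} while being its "
                        "substrate or product",
                        (i, r.id),
                    )
                )

    # structural rule: declared roles must match derived roles
    for node, declared in module.declared_roles.items():
        if roles[node] != declared:
            report.violations.append(
                Violation(
                    "role_mismatch",
                    f"node {node!r} declared {declared!r} but derived {roles[node]!r}",
                    (node,),
                )
            )

    # flagged (valid but restricts downstream analysis)
    multi = [r.id for r in module.reactions if len(r.inhibitors) > 1]
    if multi:
        report.notes.append(
            "reaction(s) with more than one inhibitor "
            f"({', '.join(multi)}): valid, but the uniqueness certificate "
            "and the rate-model builder do not support them"
        )

    return report


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

def export_reaction_graph(module: SSIModule) -> str:
    """Render the reaction graph as Graphviz DOT text.

    Reaction edges are plain arrows labeled by reaction id; inhibition edges
    are dashed tee-arrows drawn from the inhibitor toward the product of the
    inhibited reaction.
    """
    roles = classify_nodes(module).roles
    shape = {"input": "invtriangle", "output": "triangle", "state": "ellipse"}
    lines = [f'digraph "{module.name or "module"}" {{']
    for n in module.nodes:
        lines.append(f'  "{n}" [shape={shape[roles[n]]}];')
    for r in module.reactions:
        lines.append(f'  "{r.substrate}" -> "{r.product}" [label="{r.id}"];')
    for r in module.reactions:
        for i in r.inhibitors:
            lines.append(
                f'  "{i}" -> "{r.product}" '
                f'[style=dashed, arrowhead=tee, label="inhibits {r.id}"];'
            )
    lines.append("}")
    return "\n".join(lines) + "\n"
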