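"""Module-definition file handling, built-in fixtures and random generation.

The canonical serialization is JSON (YAML is accepted for convenience); the
schema is strict (unknown keys rejected) and published as
``module.schema.json`` next to this file.  A reaction's kinetics block gives
``k_m`` by default; the saturation constant may be supplied instead under the
explicit key ``k`` (exactly one of the two).
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import jsonschema
import numpy as np
import yaml

from ..errors import ConfigurationError, ModuleValidationError, SsimodError
from ..model_build import ParameterSet
from ..ssi_graph import (
    KineticParams,
    Reaction,
    SSIModule,
    classify_nodes,
    validate_module,
)

__all__ = [
    "SCHEMA",
    "SchemaError",
    "load_module",
    "loads_module",
    "save_module",
    "fixture",
    "fixture_names",
    "random_module",
    "random_parameters",
]

logger = logging.getLogger(__name__)

with resources.files(__package__).joinpath("module.schema.json").open() as _fh:
    SCHEMA = json.load(_fh)

_VALIDATOR = jsonschema.Draft202012Validator(SCHEMA)


class SchemaError(ConfigurationError):
    """The document violates the module-definition schema."""


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------

def _parse_text(text: str, fmt: str) -> dict:
    if fmt == "json":
        return json.loads(text)
    if fmt == "yaml":
        return yaml.safe_load(text)
    raise ValueError(f"unknown format {fmt!r}")


def _format_for(path: Path) -> str:
    return "yaml" if path.suffix.lower() in (".yaml", ".yml") else "json"


def _document_to_objects(doc: dict) -> tuple[SSIModule, ParameterSet]:
    errors = sorted(_VALIDATOR.iter_errors(doc), key=lambda e: list(e.absolute_path))
    if errors:
        first = errors[0]
        where = "/".join(str(p) for p in first.absolute_path) or "<root>"
        raise SchemaError(f"schema violation at {where}: {first.message}")

    reactions = []
    kinetics = {}
    for rdoc in doc["reactions"]:
        rid = rdoc["id"]
        has_km, has_k = "k_m" in rdoc, "k" in rdoc
        if has_km == has_k:
            raise SchemaError(
                f"reaction {rid!r} must give exactly one of 'k_m' or 'k'"
            )
        n = float(rdoc.get("n", 1.0))
        k_c, k_u, inhibitors = {}, {}, []
        for idoc in rdoc.get("inhibitors", []):
            inhibitors.append(idoc["id"])
            k_c[idoc["id"]] = float(idoc["k_c"])
            k_u[idoc["id"]] = float(idoc["k_u"])
        try:
            if has_km:
                params = KineticParams(
                    v_max=float(rdoc["v_max"]), k_m=float(rdoc["k_m"]), n=n,
                    k_c=k_c, k_u=k_u,
                )
            else:
                params = KineticParams.from_k(
                    v_max=float(rdoc["v_max"]), k=float(rdoc["k"]), n=n,
                    k_c=k_c, k_u=k_u,
                )
        except ValueError as exc:
            raise SchemaError(f"reaction {rid!r}: {exc}") from None
        reactions.append(
            Reaction(
                id=rid, substrate=rdoc["substrate"], product=rdoc["product"],
                inhibitors=tuple(inhibitors), params=params,
            )
        )
        kinetics[rid] = params

    declared_roles = {
        nd["id"]: nd["role"] for nd in doc["nodes"] if "role" in nd
    }
    module = SSIModule(
        nodes=[nd["id"] for nd in doc["nodes"]],
        reactions=reactions,
        declared_roles=declared_roles,
        allow_ssn=bool(doc.get("allow_ssn", False)),
        name=doc.get("name", ""),
    )

    inputs = {k: float(v) for k, v in doc.get("inputs", {}).items()}
    roles = classify_nodes(module).roles
    for node in inputs:
        if node not in roles:
            raise SchemaError(f"'inputs' references unknown node {node!r}")
        if roles[node] != "input":
            raise SchemaError(
                f"'inputs' declares a concentration for {node!r}, which is "
                f"a derived {roles[node]} node, not an input node"
            )
    return module, ParameterSet(kinetics=kinetics, inputs=inputs)


def loads_module(
    text: str, fmt: str = "json", validate: bool = True
) -> tuple[SSIModule, ParameterSet]:
    """Parse a module document from a string."""
    module, params = _document_to_objects(_parse_text(text, fmt))
    if validate:
        report = validate_module(module)
        if not report.is_valid:
            raise ModuleValidationError(report)
    return module, params


def load_module(
    path: Union[str, Path], validate: bool = True
) -> tuple[SSIModule, ParameterSet]:
    """Load and schema-check a JSON or YAML module file.

    With ``validate`` (default), the module-definition clauses are also
    checked and a violation raises :class:`ModuleValidationError`.
    """
    path = Path(path)
    return loads_module(path.read_text(), _format_for(path), validate=validate)


def load_analysis(path: Union[str, Path]) -> dict:
    """The optional per-file analysis defaults block (may be empty)."""
    path = Path(path)
    doc = _parse_text(path.read_text(), _format_for(path))
    return dict(doc.get("analysis", {})) if isinstance(doc, dict) else {}


def module_to_document(
    module: SSIModule, params: ParameterSet, analysis: Optional[dict] = None
) -> dict:
    roles = classify_nodes(module).roles
    doc: dict = {"schema_version": 1}
    if module.name:
        doc["name"] = module.name
    if module.allow_ssn:
        doc["allow_ssn"] = True
    doc["nodes"] = [
        {"id": n, "role": module.declared_roles[n]}
        if n in module.declared_roles
        else {"id": n}
        for n in module.nodes
    ]
    doc["reactions"] = []
    for r in module.reactions:
        p = params.kinetics.get(r.id) or r.params
        if p is None:
            raise ConfigurationError(f"no kinetic parameters for reaction {r.id!r}")
        rdoc = {
            "id": r.id,
            "substrate": r.substrate,
            "product": r.product,
            "v_max": p.v_max,
            "k_m": p.k_m,
            "n": p.n,
        }
        if r.inhibitors:
            rdoc["inhibitors"] = [
                {"id": i, "k_c": p.k_c[i], "k_u": p.k_u[i]} for i in r.inhibitors
            ]
        doc["reactions"].append(rdoc)
    if params.inputs:
        doc["inputs"] = dict(params.inputs)
    if analysis:
        doc["analysis"] = dict(analysis)
    _ = roles  # roles derived above to fail early on unclassifiable nodes
    return doc


def save_module(
    module: SSIModule,
    params: ParameterSet,
    path: Optional[Union[str, Path]] = None,
    analysis: Optional[dict] = None,
    fmt: Optional[str] = None,
) -> str:
    """Serialize a module (+ parameters) to JSON or YAML; returns the text
    and, if ``path`` is given, writes it."""
    doc = module_to_document(module, params, analysis)
    if fmt is None:
        fmt = _format_for(Path(path)) if path is not None else "json"
    if fmt == "json":
        text = json.dumps(doc, indent=2) + "\n"
    elif fmt == "yaml":
        text = yaml.safe_dump(doc, sort_keys=False)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if path is not None:
        Path(path).write_text(text)
    return text


# ---------------------------------------------------------------------------
# built-in fixtures
# ---------------------------------------------------------------------------

def _kp(v_max, k_m=None, k=None, n=1.0, **kw) -> KineticParams:
    if k is not None:
        return KineticParams.from_k(v_max=v_max, k=k, n=n, **kw)
    return KineticParams(v_max=v_max, k_m=k_m, n=n, **kw)


def _fig1() -> tuple[SSIModule, ParameterSet]:
    # raw reaction graph: two reactions A->B, C->D with D inhibiting A->B;
    # every node is input or output, so this is NOT a valid module
    unit = dict(k_c={"D": 1.0}, k_u={"D": 1.0})
    reactions = [
        Reaction("r1", "A", "B", ("D",), _kp(1.0, k_m=1.0, **unit)),
        Reaction("r2", "C", "D", (), _kp(1.0, k_m=1.0)),
    ]
    module = SSIModule(["A", "B", "C", "D"], reactions, name="fig1")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions},
        inputs={"A": 1.0, "C": 1.0},
    )


def _fig2a() -> tuple[SSIModule, ParameterSet]:
    # linear pathway whose single inhibition acts on the head reaction;
    # decomposes into an uninhibited part (fig2b) and a smaller inhibited
    # part (fig2c)
    reactions = [
        Reaction("v1", "X", "S1", ("S2",),
                 _kp(2.0, k_m=0.5, k_c={"S2": 2.0}, k_u={"S2": 3.0})),
        Reaction("v2", "S1", "S2", (), _kp(1.5, k_m=0.8)),
        Reaction("v3", "S2", "Y", (), _kp(1.8, k_m=0.6)),
    ]
    module = SSIModule(["X", "S1", "S2", "Y"], reactions, name="fig2a")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs={"X": 1.0}
    )


def _fig2b() -> tuple[SSIModule, ParameterSet]:
    reactions = [
        Reaction("v1", "X", "T1", (), _kp(1.0, k_m=0.5)),
        Reaction("v2", "T1", "Y", (), _kp(1.5, k_m=0.8)),
    ]
    module = SSIModule(["X", "T1", "Y"], reactions, allow_ssn=True, name="fig2b")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs={"X": 0.6}
    )


def _fig2c() -> tuple[SSIModule, ParameterSet]:
    reactions = [
        Reaction("v1", "X", "U1", ("U2",),
                 _kp(2.0, k_m=0.5, k_c={"U2": 2.0}, k_u={"U2": 3.0})),
        Reaction("v2", "U1", "U2", (), _kp(1.5, k_m=0.8)),
        Reaction("v3", "U2", "Y", (), _kp(1.8, k_m=0.6)),
    ]
    module = SSIModule(["X", "U1", "U2", "Y"], reactions, name="fig2c")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs={"X": 1.0}
    )


def _fig3() -> tuple[SSIModule, ParameterSet]:
    # reversible interconversion S1 <-> S2 with crossed inhibitions: cannot
    # be split into an uninhibited part and a smaller inhibited one
    reactions = [
        Reaction("v1", "X", "S1", ("S2",),
                 _kp(2.0, k_m=0.4, k_c={"S2": 1.5}, k_u={"S2": 2.5})),
        Reaction("v2", "S1", "S2", (), _kp(1.2, k_m=0.7)),
        Reaction("v3", "S2", "S1", (), _kp(0.9, k_m=0.5)),
        Reaction("v4", "S2", "Y", ("S1",),
                 _kp(1.6, k_m=0.6, k_c={"S1": 2.0}, k_u={"S1": 4.0})),
    ]
    module = SSIModule(["X", "S1", "S2", "Y"], reactions, name="fig3")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs={"X": 1.0}
    )


def _fig4(v_max4: float = 1.3, v_max5: float = 1.5) -> tuple[SSIModule, ParameterSet]:
    # the bistable worked example: A -> B branches to C and D, each branch
    # inhibited by the other branch's product
    reactions = [
        Reaction("v1", "A", "B", (), _kp(2.6, k=0.14, n=1)),
        Reaction("v2", "B", "C", ("D",),
                 _kp(3.7, k=0.23, n=2, k_c={"D": 5.4}, k_u={"D": 9.8})),
        Reaction("v3", "B", "D", ("C",),
                 _kp(4.3, k=0.23, n=2, k_c={"C": 6.2}, k_u={"C": 8.7})),
        Reaction("v4", "C", "E", (), _kp(v_max4, k=0.29, n=1)),
        Reaction("v5", "D", "F", (), _kp(v_max5, k=0.27, n=1)),
    ]
    module = SSIModule(["A", "B", "C", "D", "E", "F"], reactions, name="fig4")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs={"A": 1.0}
    )


def _fig4_noeq() -> tuple[SSIModule, ParameterSet]:
    module, params = _fig4(v_max4=0.5, v_max5=0.5)
    module.name = "fig4_noeq"
    return module, params


def _chain_ssn() -> tuple[SSIModule, ParameterSet]:
    reactions = [
        Reaction("v1", "X", "S1", (), _kp(1.0, k_m=0.5)),
        Reaction("v2", "S1", "S2", (), _kp(2.0, k_m=0.7)),
        Reaction("v3", "S2", "Y", (), _kp(1.8, k_m=0.9)),
    ]
    module = SSIModule(["X", "S1", "S2", "Y"], reactions, allow_ssn=True,
                       name="chain_ssn")
    return module, ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs={"X": 0.6}
    )


_FIXTURES = {
    "fig1": _fig1,
    "fig2a": _fig2a,
    "fig2b": _fig2b,
    "fig2c": _fig2c,
    "fig3": _fig3,
    "fig4": _fig4,
    "fig4_noeq": _fig4_noeq,
    "chain_ssn": _chain_ssn,
}


def fixture_names() -> tuple[str, ...]:
    return tuple(_FIXTURES)


def fixture(name: str) -> tuple[SSIModule, ParameterSet]:
    """A named built-in module (fresh objects on every call).

    Every fixture passes validation except ``fig1``, which is a raw reaction
    graph whose nodes are all inputs/outputs.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(_FIXTURES)}"
        ) from None
    return builder()


# ---------------------------------------------------------------------------
# random generation
# ---------------------------------------------------------------------------

PARAM_RANGE = (0.05, 10.0)
HILL_CHOICES = (1.0, 2.0)


def _log_uniform(rng: np.random.Generator, size=None):
    lo, hi = PARAM_RANGE
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


def _draw_params(rng: np.random.Generator, inhibitors: tuple[str, ...]) -> KineticParams:
    return KineticParams(
        v_max=float(_log_uniform(rng)),
        k_m=float(_log_uniform(rng)),
        n=float(rng.choice(HILL_CHOICES)),
        k_c={i: float(_log_uniform(rng)) for i in inhibitors},
        k_u={i: float(_log_uniform(rng)) for i in inhibitors},
    )


def random_module(
    n_states: int,
    n_reactions: int,
    p_inhibit: float = 0.4,
    seed: int = 0,
    allow_ssn: bool = False,
) -> tuple[SSIModule, ParameterSet]:
    """Generate a random valid module with ``<= 1`` inhibitor per reaction.

    Topology: with ``n_reactions == n_states`` a directed cycle through all
    state nodes; otherwise an input -> S1 -> ... -> Sk -> output chain plus
    random extra reactions.  Inhibitors are state nodes distinct from the
    inhibited reaction's substrate and product.  Kinetic constants are
    log-uniform in [0.05, 10] with Hill coefficients in {1, 2}.  The same
    seed always produces the identical module.
    """
    if n_states < 1:
        raise ValueError("n_states must be >= 1")
    if n_reactions < n_states:
        raise ValueError("n_reactions must be >= n_states")
    states = [f"S{i + 1}" for i in range(n_states)]
    if n_reactions == n_states:
        if n_states < 2:
            raise ValueError(
                "a 1-state module needs at least 2 reactions (inflow and "
                "outflow); increase n_reactions"
            )
        edges = [(states[i], states[(i + 1) % n_states]) for i in range(n_states)]
        nodes = list(states)
    else:
        edges = (
            [("X_in", states[0])]
            + [(states[i], states[i + 1]) for i in range(n_states - 1)]
            + [(states[-1], "X_out")]
        )
        nodes = ["X_in", *states, "X_out"]

    rng = np.random.default_rng(seed)
    candidates = [
        (a, b)
        for a in states
        for b in [*states, *(["X_out"] if "X_out" in nodes else [])]
        if a != b and (a, b) not in set(edges)
    ]
    n_extra = n_reactions - len(edges)
    if n_extra > len(candidates):
        raise ValueError(
            f"cannot place {n_reactions} distinct reactions on {n_states} "
            "state nodes; lower n_reactions or raise n_states"
        )
    if n_extra > 0:
        picks = rng.choice(len(candidates), size=n_extra, replace=False)
        edges += [candidates[i] for i in sorted(picks)]

    inhibitor_of: dict[int, str] = {}
    for j, (a, b) in enumerate(edges):
        pool = [s for s in states if s not in (a, b)]
        if pool and rng.random() < p_inhibit:
            inhibitor_of[j] = str(rng.choice(pool))
    if not inhibitor_of:
        eligible = [
            j for j, (a, b) in enumerate(edges)
            if [s for s in states if s not in (a, b)]
        ]
        if eligible and not allow_ssn:
            j = int(rng.choice(eligible))
            a, b = edges[j]
            pool = [s for s in states if s not in (a, b)]
            inhibitor_of[j] = str(rng.choice(pool))
        elif not eligible and not allow_ssn:
            raise ValueError(
                "no reaction can carry an inhibitor at this size; "
                "pass allow_ssn=True or increase n_states"
            )

    reactions = []
    for j, (a, b) in enumerate(edges):
        inhibitors = (inhibitor_of[j],) if j in inhibitor_of else ()
        reactions.append(
            Reaction(
                id=f"v{j + 1}", substrate=a, product=b, inhibitors=inhibitors,
                params=_draw_params(rng, inhibitors),
            )
        )
    module = SSIModule(
        nodes, reactions, allow_ssn=allow_ssn and not inhibitor_of,
        name=f"random_{seed}",
    )
    roles = classify_nodes(module).roles
    inputs = {
        n: float(_log_uniform(rng)) for n in module.nodes if roles[n] == "input"
    }
    params = ParameterSet(
        kinetics={r.id: r.params for r in reactions}, inputs=inputs
    )
    report = validate_module(module)
    if not report.is_valid:  # pragma: no cover - generator correctness
        raise ModuleValidationError(report)
    return module, params


def random_parameters(module: SSIModule, seed: int = 0) -> ParameterSet:
    """Redraw every kinetic constant and input concentration of a module
    (log-uniform in [0.05, 10], Hill n in {1, 2}), keeping the topology."""
    rng = np.random.default_rng(seed)
    kinetics = {
        r.id: _draw_params(rng, r.inhibitors) for r in module.reactions
    }
    roles = classify_nodes(module).roles
    inputs = {
        n: float(_log_uniform(rng)) for n in module.nodes if roles[n] == "input"
    }
    return ParameterSet(kinetics=kinetics, inputs=inputs)
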