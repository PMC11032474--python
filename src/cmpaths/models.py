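"""Canonical path-model definitions and the text model syntax.

Models are recursive (acyclic) observed-variable path models with strictly
diagonal residual covariance.  The text syntax accepts one directed edge
per line, ``child <- parent [: label]``; blank lines and ``#`` comments
are ignored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple


class Edge(NamedTuple):
    child: str
    parent: str
    label: str


@dataclass(frozen=True)
class PathModel:
    """A recursive directed model over named observed variables."""

    variables: tuple
    edges: tuple
    label: str = ""
    exogenous_covariances: bool = True

    def __post_init__(self):
        seen = set()
        for e in self.edges:
            if e.child not in self.variables or e.parent not in self.variables:
                raise ValueError(f"edge {e} references unknown variable")
            if (e.child, e.parent) in seen:
                raise ValueError(f"duplicate edge {e.child} <- {e.parent}")
            seen.add((e.child, e.parent))
        labels = [e.label for e in self.edges if e.label]
        if len(labels) != len(set(labels)):
            raise ValueError("edge labels must be unique")
        self.topological_order()  # raises on cycles

    @property
    def endogenous(self) -> tuple:
        children = {e.child for e in self.edges}
        return tuple(v for v in self.variables if v in children)

    @property
    def exogenous(self) -> tuple:
        children = {e.child for e in self.edges}
        return tuple(v for v in self.variables if v not in children)

    def parents(self, var: str) -> tuple:
        return tuple(e.parent for e in self.edges if e.child == var)

    def topological_order(self) -> tuple:
        """Variables ordered so every parent precedes its children."""
        remaining = dict.fromkeys(self.variables)
        deps = {v: set(self.parents(v)) for v in self.variables}
        order = []
        while remaining:
            ready = [v for v in remaining if not (deps[v] & set(remaining))]
            if not ready:
                raise ValueError("path model contains a cycle (must be recursive)")
            for v in ready:
                order.append(v)
                del remaining[v]
        return tuple(order)

    def edge_by_label(self, label: str) -> Edge:
        for e in self.edges:
            if e.label == label:
                return e
        raise KeyError(f"no edge labelled {label!r}")


def parse_model(text: str, label: str = "") -> PathModel:
    """Parse the one-edge-per-line model syntax."""
    edges = []
    variables: list = []
    for lineno, raw in enumerate(text.splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "<-" not in line:
            raise ValueError(f"line {lineno}: expected 'child <- parent [: label]'")
        lhs, rhs = (s.strip() for s in line.split("<-", 1))
        lab = ""
        if ":" in rhs:
            rhs, lab = (s.strip() for s in rhs.split(":", 1))
        for v in (lhs, rhs):
            if v not in variables:
                variables.append(v)
        edges.append(Edge(lhs, rhs, lab))
    return PathModel(tuple(variables), tuple(edges), label=label)


def model_to_text(model: PathModel) -> str:
    lines = []
    for e in model.edges:
        suffix = f" : {e.label}" if e.label else ""
        lines.append(f"{e.child} <- {e.parent}{suffix}")
    return "\n".join(lines) + "\n"


def h1_model() -> PathModel:
    """Four-variable model: CM -> {BMI, AT, CRP}; {BMI, AT} -> CRP."""
    return parse_model(
        """
        bmi <- cm  : a1
        at  <- cm  : a3
        crp <- cm  : a2
        crp <- bmi : b1
        crp <- at  : b2
        """,
        label="h1",
    )


def full_model(region: str = "mri") -> PathModel:
    """Brain-inclusive model with direct BMI, CRP and AT effects on a region."""
    return parse_model(
        f"""
        bmi <- cm  : a1
        at  <- cm  : a3
        crp <- cm  : a2
        crp <- bmi : b1
        crp <- at  : b2
        {region} <- bmi : c1
        {region} <- crp : c2
        {region} <- at  : c3
        """,
        label="full",
    )


def sparse_model(region: str = "mri") -> PathModel:
    """Brain-inclusive model where only CRP affects the region directly."""
    return parse_model(
        f"""
        bmi <- cm  : a1
        at  <- cm  : a3
        crp <- cm  : a2
        crp <- bmi : b1
        crp <- at  : b2
        {region} <- crp : c2
        """,
        label="sparse",
    )


def independence_model(variables) -> PathModel:
    """Baseline model: no edges and no covariances (all variables independent)."""
    return PathModel(tuple(variables), (), label="independence", exogenous_covariances=False)
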