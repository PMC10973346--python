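"""Causal DAGs over traits and their d-separation basis sets.

A causal model is a directed acyclic graph whose testable content is its
*basis set*: one conditional-independence claim per non-adjacent vertex
pair, conditioning on the union of both vertices' parents (the directed
d-separation basis used in path analysis). The module also ships the
twelve-model comparison set over {case, verb_final, flexible} used in the
study of argument-marking strategies, plus the edgeless null model.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx

from .treedata import ANALYSIS_TRAITS


class DAGError(ValueError):
    """Raised for invalid causal graph specifications."""


@dataclass(frozen=True)
class IndependenceClaim:
    """x independent of y given conditioning_set, with y the regression response."""

    x: str
    y: str
    conditioning_set: frozenset

    def __str__(self) -> str:
        cond = ", ".join(sorted(self.conditioning_set)) or "{}"
        return f"{self.x} _||_ {self.y} | {cond}"


@dataclass(frozen=True)
class CausalDAG:
    """A validated directed acyclic graph over named trait vertices."""

    vertices: tuple
    edges: tuple            # of (cause, effect) pairs
    model_id: str

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def parents(self, v: str) -> frozenset:
        return frozenset(c for c, e in self.edges if e == v)

    def q(self) -> int:
        """Parameter count used by the information criterion: |V| + |E|."""
        return len(self.vertices) + len(self.edges)

    def __str__(self) -> str:
        lines = [f"# model {self.model_id}"]
        lines += [f"{c} -> {e}" for c, e in self.edges]
        return "\n".join(lines)


def make_dag(edges, model_id: str = "model", vertices=None) -> CausalDAG:
    """Build and validate a :class:`CausalDAG`.

    ``edges`` is an iterable of (cause, effect) pairs; ``vertices`` defaults
    to the sorted union of edge endpoints (supply it explicitly for graphs
    with isolated vertices, e.g. the null model).
    """
    edges = [tuple(e) for e in edges]
    seen = set()
    for e in edges:
        if len(e) != 2:
            raise DAGError(f"edge must be a (cause, effect) pair: {e!r}")
        if e[0] == e[1]:
            raise DAGError(f"self-loop not allowed: {e[0]!r}")
        if e in seen:
            raise DAGError(f"duplicate edge: {e[0]} -> {e[1]}")
        seen.add(e)
    if vertices is None:
        vertices = sorted({v for e in edges for v in e})
    else:
        vertices = list(vertices)
        unknown = {v for e in edges for v in e} - set(vertices)
        if unknown:
            raise DAGError(f"edges mention unknown vertices: {sorted(unknown)}")
    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        pretty = " -> ".join([cycle[0][0]] + [e[1] for e in cycle])
        raise DAGError(f"graph contains a directed cycle: {pretty}")
    return CausalDAG(vertices=tuple(vertices), edges=tuple(edges), model_id=model_id)


def basis_set(dag: CausalDAG) -> list:
    """Directed d-separation basis set of ``dag``.

    One claim per non-adjacent vertex pair; the response ``y`` is the member
    of the pair that is not a causal ancestor of the other (lexicographic
    tie-break when neither is), and the conditioning set is
    parents(x) | parents(y). The claim count equals C(|V|, 2) - |E|.
    """
    g = dag.graph()
    ancestors = {v: nx.ancestors(g, v) for v in dag.vertices}
    claims = []
    for u, v in itertools.combinations(sorted(dag.vertices), 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        if u in ancestors[v]:       # u is an ancestor of v: regress v on u
            x, y = u, v
        elif v in ancestors[u]:
            x, y = v, u
        else:                       # neither is an ancestor: lexicographic
            x, y = u, v
        cond = dag.parents(x) | dag.parents(y)
        claims.append(IndependenceClaim(x=x, y=y, conditioning_set=cond))
    return claims


def markov_equivalent(a: CausalDAG, b: CausalDAG) -> bool:
    """True if the two DAGs share a skeleton and v-structures (colliders)."""
    if set(a.vertices) != set(b.vertices):
        return False

    def skeleton(d):
        return {frozenset(e) for e in d.edges}

    def vstructs(d):
        g = d.graph()
        out = set()
        for v in d.vertices:
            ps = sorted(g.predecessors(v))
            for p1, p2 in itertools.combinations(ps, 2):
                if not (g.has_edge(p1, p2) or g.has_edge(p2, p1)):
                    out.add((p1, v, p2))
        return out

    return skeleton(a) == skeleton(b) and vstructs(a) == vstructs(b)


def equivalence_classes(models: dict) -> dict:
    """Group model ids into Markov equivalence classes.

    Returns a map model_id -> class label ("eq1", "eq2", ...), in the order
    classes are first encountered.
    """
    labels: dict = {}
    reps: list = []
    for mid, dag in models.items():
        for i, rep in enumerate(reps):
            if markov_equivalent(dag, rep):
                labels[mid] = f"eq{i + 1}"
                break
        else:
            reps.append(dag)
            labels[mid] = f"eq{len(reps)}"
    return labels


# ------------------------------------------------------------ model library

_C, _VF, _F = ANALYSIS_TRAITS  # case, verb_final, flexible


def null_model(vertices=ANALYSIS_TRAITS) -> CausalDAG:
    """The edgeless DAG: all traits mutually independent given the phylogeny."""
    return make_dag([], model_id="null", vertices=vertices)


def paper_model_set() -> dict:
    """The twelve-model comparison set over {case, verb_final, flexible}.

    Four single-edge models (i: verb_final -> case from the processing /
    noisy-channel hypotheses; j: case -> flexible from licensing theory;
    k and l their reversals) and eight two-edge models. Of the two-edge
    models, b (fork at case), c (verb_final -> case -> flexible) and
    d (flexible -> case -> verb_final) are fixed by the study's results;
    the remaining five are the other chains through each mediator plus the
    collider into case, assigned to the free letters in a fixed order.
    Interpret results by topology rather than by letter.
    """
    spec = {
        # two-edge models
        "a": [(_VF, _F), (_F, _C)],    # verb_final -> flexible -> case
        "b": [(_C, _F), (_C, _VF)],    # fork at case
        "c": [(_VF, _C), (_C, _F)],    # verb_final -> case -> flexible
        "d": [(_F, _C), (_C, _VF)],    # flexible -> case -> verb_final
        "e": [(_F, _VF), (_VF, _C)],   # flexible -> verb_final -> case
        "f": [(_C, _VF), (_VF, _F)],   # case -> verb_final -> flexible
        "g": [(_C, _F), (_F, _VF)],    # case -> flexible -> verb_final
        "h": [(_VF, _C), (_F, _C)],    # collider into case
        # single-edge models
        "i": [(_VF, _C)],
        "j": [(_C, _F)],
        "k": [(_C, _VF)],
        "l": [(_F, _C)],
    }
    return {
        mid: make_dag(edges, model_id=mid, vertices=ANALYSIS_TRAITS)
        for mid, edges in spec.items()
    }


# ------------------------------------------------------------- serialization


def parse_dag_text(text: str, model_id: str = "model", vertices=None) -> CausalDAG:
    """Parse an edge-list format: one ``cause -> effect`` per line, # comments."""
    edges = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "->" not in line:
            raise DAGError(f"line {lineno}: expected 'cause -> effect', got {raw!r}")
        cause, _, effect = line.partition("->")
        cause, effect = cause.strip(), effect.strip()
        if not cause or not effect:
            raise DAGError(f"line {lineno}: empty vertex name in {raw!r}")
        edges.append((cause, effect))
    return make_dag(edges, model_id=model_id, vertices=vertices)


def load_model_file(path) -> dict:
    """Load one or more DAGs from a text file.

    Models are separated by lines of the form ``[model_id]``; a file without
    section headers defines a single model named after the file.
    """
    import os
    with open(path, "r", encoding="utf-8-sig") as fh:
        content = fh.read()
    sections: list = []
    current_id, current_lines = None, []
    for raw in content.splitlines():
        stripped = raw.strip()
        if stripped.startswith("[") and stripped.endswith("]"):
            if current_id is not None or current_lines:
                sections.append((current_id, current_lines))
            current_id, current_lines = stripped[1:-1].strip(), []
        else:
            current_lines.append(raw)
    sections.append((current_id, current_lines))
    models = {}
    for mid, lines in sections:
        body = "\n".join(lines)
        if mid is None:
            if not body.strip():
                continue
            mid = os.path.splitext(os.path.basename(str(path)))[0]
        models[mid] = parse_dag_text(body, model_id=mid, vertices=ANALYSIS_TRAITS)
    if not models:
        raise DAGError(f"no models found in {path}")
    return models
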