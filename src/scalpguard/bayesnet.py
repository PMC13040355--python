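"""Discrete Bayesian-network scoring over discretized behavioral features.

The default structure is naive — the latent class is the sole parent of
each discretized feature — because the deployed system's dependency graph
is not published; arbitrary user DAGs are accepted via :class:`BayesNetSpec`.
Features are discretized into quartile bins computed on training data and
each conditional probability table (CPT) row is Laplace-smoothed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ScalpGuardError
from .features import DesignMatrix

CLASS_NODE = "class"
_ROW_TOL = 1e-9


@dataclass
class Cpt:
    """CPT of one node: P(node = v | parents = assignment).

    ``table`` maps a tuple of parent values (``()`` for roots) to a
    probability vector over ``domain``; every row must sum to one.
    """

    parents: tuple[str, ...]
    domain: tuple
    table: dict[tuple, np.ndarray]

    def prob(self, value, parent_values: tuple) -> float:
        row = self.table.get(tuple(parent_values))
        if row is None:
            raise ScalpGuardError(f"no CPT row for parent assignment {parent_values!r}")
        try:
            idx = self.domain.index(value)
        except ValueError:
            raise ScalpGuardError(f"value {value!r} outside domain {self.domain!r}") from None
        return float(row[idx])


@dataclass
class BayesNetSpec:
    """Directed acyclic network over (a subset of) the features + class node."""

    nodes: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    cpts: dict[str, Cpt]
    bins: dict[str, np.ndarray] = field(default_factory=dict)  # discretization edges

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ScalpGuardError("network graph contains a cycle")
        for node in self.nodes:
            if node not in self.cpts:
                raise ScalpGuardError(f"missing CPT for node {node!r}")
            cpt = self.cpts[node]
            expected = tuple(sorted(g.predecessors(node)))
            if tuple(sorted(cpt.parents)) != expected:
                raise ScalpGuardError(
                    f"CPT parents {cpt.parents!r} of {node!r} disagree with edges {expected!r}")
            for pa, row in cpt.table.items():
                if abs(float(np.sum(row)) - 1.0) > _ROW_TOL:
                    raise ScalpGuardError(
                        f"CPT row of {node!r} at {pa!r} sums to {float(np.sum(row))}, not 1")

    def domains(self) -> dict[str, tuple]:
        return {n: self.cpts[n].domain for n in self.nodes}


def bn_joint(spec: BayesNetSpec, assignment: dict) -> float:
    """Joint probability of a full assignment: product of CPT entries."""
    missing = [n for n in spec.nodes if n not in assignment]
    if missing:
        raise ScalpGuardError(f"assignment missing nodes: {missing}")
    p = 1.0
    for node in spec.nodes:
        cpt = spec.cpts[node]
        pv = tuple(assignment[q] for q in cpt.parents)
        try:
            p *= cpt.prob(assignment[node], pv)
        except ScalpGuardError as e:
            raise ScalpGuardError(f"node {node!r}: {e}") from e
    return p


def bn_class_posterior(spec: BayesNetSpec, evidence: dict,
                       class_node: str = CLASS_NODE) -> float:
    """P(class = 1 | evidence on all other nodes) by direct enumeration."""
    num, den = 0.0, 0.0
    for c in spec.cpts[class_node].domain:
        a = dict(evidence, **{class_node: c})
        j = bn_joint(spec, a)
        den += j
        if c == 1:
            num += j
    if den == 0.0:
        raise ScalpGuardError("evidence has zero probability under the network")
    return num / den


def quartile_bins(values: np.ndarray) -> np.ndarray:
    """Inner quartile cut points (training-data discretization)."""
    return np.unique(np.quantile(np.asarray(values, dtype=float), [0.25, 0.5, 0.75]))


def discretize(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    return np.searchsorted(edges, np.asarray(values, dtype=float), side="right")


def fit_naive_bn(dm: DesignMatrix, columns=None, laplace: float = 1.0,
                 prior: float = 0.05) -> BayesNetSpec:
    """Naive-structure network (class -> each feature) from training data.

    The class node's marginal is the fixed audited prior, mirroring the
    Gaussian path; feature CPTs are empirical quartile-bin frequencies with
    Laplace smoothing ``laplace``.
    """
    X = dm.X if columns is None else dm.X[list(columns)]
    y = np.asarray(dm.y, dtype=int)
    nodes = [CLASS_NODE] + list(X.columns)
    edges = tuple((CLASS_NODE, c) for c in X.columns)
    cpts: dict[str, Cpt] = {}
    cpts[CLASS_NODE] = Cpt(parents=(), domain=(0, 1),
                           table={(): np.array([1.0 - prior, prior])})
    bins: dict[str, np.ndarray] = {}
    for c in X.columns:
        edges_c = quartile_bins(X[c].to_numpy())
        bins[c] = edges_c
        v = discretize(X[c].to_numpy(), edges_c)
        k = len(edges_c) + 1
        table = {}
        for cls in (0, 1):
            counts = np.bincount(v[y == cls], minlength=k).astype(float) + laplace
            table[(cls,)] = counts / counts.sum()
        cpts[c] = Cpt(parents=(CLASS_NODE,), domain=tuple(range(k)), table=table)
    return BayesNetSpec(nodes=tuple(nodes), edges=edges, cpts=cpts, bins=bins)


def bn_score_frame(spec: BayesNetSpec, X: pd.DataFrame) -> np.ndarray:
    """Class posterior per row of a natural-unit feature frame."""
    feats = [n for n in spec.nodes if n != CLASS_NODE]
    disc = {c: discretize(X[c].to_numpy(), spec.bins[c]) for c in feats}
    out = np.empty(len(X))
    for i in range(len(X)):
        evidence = {c: int(disc[c][i]) for c in feats}
        out[i] = bn_class_posterior(spec, evidence)
    return out
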