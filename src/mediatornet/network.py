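"""Correlation networks, hub extraction and preserved/lost/acquired algebra.

Edges connect analyte pairs whose correlation is *strong* and *significant*:
|coefficient| >= 0.67 (inclusive) and p < 0.05. Both Pearson and Spearman
coefficients are recorded for every pair; the edge rule selects which one(s)
gate an edge (``spearman`` by default, since serum mediator panels are
non-normal; ``pearson``, ``either`` and ``both`` are available).

p-values are two-sided. For pairs with more than 9 complete observations
the usual t approximation is used (for Spearman this is the standard
large-sample test); for n <= 9 the full permutation distribution is
enumerated, which matters for small subgroups (e.g. a trimester cell with
n=7) where asymptotic p-values are unreliable.

Connectivity is reported in the degree-sum convention: the count for a
category is the summed degree of its member nodes, so the four category
counts add up to the network total, which equals twice the edge count.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, SubgroupKey
from .panel import CATEGORIES, DEFAULT_PANEL, MediatorPanel

EXACT_P_MAX_N = 9
RULES = ("spearman", "pearson", "either", "both")


@dataclass
class CorrelationRecord:
    """Dual correlation record for one unordered analyte pair."""

    a: str
    b: str
    r_pearson: float
    p_pearson: float
    rho_spearman: float
    p_spearman: float
    n: int
    ok: bool  # enough complete cases for edge calling

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.a, self.b))


@lru_cache(maxsize=4)
def _permutation_indices(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_perm_p(x: np.ndarray, y: np.ndarray, observed: float) -> float:
    """Two-sided exact permutation p for a correlation coefficient.

    Enumerates all n! orderings of ``y`` and counts |coef| >= |observed|.
    Valid for Pearson on raw values and Spearman on (average) ranks alike.
    """
    n = len(x)
    perms = _permutation_indices(n)
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    coefs = (yc[perms] @ xc) / denom
    return float(np.mean(np.abs(coefs) >= abs(observed) - 1e-12))


def _t_approx_p(coef: float, n: int) -> float:
    if np.isnan(coef) or n < 3:
        return float("nan")
    if abs(coef) >= 1.0:
        return 0.0
    t = coef * np.sqrt((n - 2) / (1.0 - coef * coef))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _corr_p(coef: float, x: np.ndarray, y: np.ndarray) -> float:
    n = len(x)
    if np.isnan(coef):
        return float("nan")
    if n <= EXACT_P_MAX_N:
        return _exact_perm_p(x, y, coef)
    return _t_approx_p(coef, n)


def _pair_record(a: str, b: str, xa: np.ndarray, xb: np.ndarray,
                 min_n: int) -> CorrelationRecord:
    mask = ~(np.isnan(xa) | np.isnan(xb))
    x, y = xa[mask], xb[mask]
    n = int(mask.sum())
    if n < 3:
        return CorrelationRecord(a, b, np.nan, np.nan, np.nan, np.nan, n, False)
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return CorrelationRecord(a, b, np.nan, np.nan, np.nan, np.nan, n,
                                 n >= min_n)
    r = float(np.corrcoef(x, y)[0, 1])
    rx = stats.rankdata(x)  # average ranks for ties
    ry = stats.rankdata(y)
    if rx.std() == 0 or ry.std() == 0:
        rho = float("nan")
        p_s = float("nan")
    else:
        rho = float(np.corrcoef(rx, ry)[0, 1])
        p_s = _corr_p(rho, rx, ry)
    p_r = _corr_p(r, x, y)
    return CorrelationRecord(a, b, r, p_r, rho, p_s, n, n >= min_n)


def correlation_matrix(cohort: Cohort, subgroup: SubgroupKey,
                       min_n: int = 5) -> list[CorrelationRecord]:
    """Dual correlation records for all analyte pairs of one subgroup.

    Pairs are computed on pairwise-complete cases; pairs with fewer than
    ``min_n`` complete cases are flagged (``ok=False``) and excluded from
    edge calling downstream.
    """
    samples = cohort.subgroup(subgroup)
    if len(samples) < min_n:
        raise ValueError(f"subgroup {subgroup.label()} has {len(samples)} "
                         f"samples; need at least min_n={min_n}")
    analytes = list(cohort.panel.mediators)
    data = np.array([[s.concentrations.get(a, np.nan) for a in analytes]
                     for s in samples], dtype=float)
    complete = not np.isnan(data).any()
    records: list[CorrelationRecord] = []
    if complete and len(samples) > EXACT_P_MAX_N:
        # fast path: full-matrix coefficients + vectorised t-approximation
        n = data.shape[0]
        r_mat = np.corrcoef(data, rowvar=False)
        ranks = np.apply_along_axis(stats.rankdata, 0, data)
        with np.errstate(invalid="ignore"):
            rho_mat = np.corrcoef(ranks, rowvar=False)
        for i, a in enumerate(analytes):
            for j in range(i + 1, len(analytes)):
                records.append(CorrelationRecord(
                    a, analytes[j],
                    float(r_mat[i, j]), _t_approx_p(float(r_mat[i, j]), n),
                    float(rho_mat[i, j]), _t_approx_p(float(rho_mat[i, j]), n),
                    n, n >= min_n))
    else:
        for i, a in enumerate(analytes):
            for j in range(i + 1, len(analytes)):
                records.append(_pair_record(a, analytes[j], data[:, i],
                                            data[:, j], min_n))
    return records


def records_frame(records: list[CorrelationRecord]) -> pd.DataFrame:
    """Edge-list style DataFrame of all correlation records."""
    return pd.DataFrame([{
        "analyte_a": r.a, "analyte_b": r.b, "r_pearson": r.r_pearson,
        "p_pearson": r.p_pearson, "rho_spearman": r.rho_spearman,
        "p_spearman": r.p_spearman, "n": r.n, "ok": r.ok} for r in records])


@dataclass
class MediatorNetwork:
    """Edges passing the strong-correlation rule for one subgroup."""

    subgroup: SubgroupKey | None
    graph: nx.Graph
    records: list[CorrelationRecord]
    rule: str
    r_min: float
    alpha: float

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    @classmethod
    def from_edges(cls, edges, nodes=None, subgroup=None) -> "MediatorNetwork":
        """Build a bare network from an explicit edge list (testing/IO)."""
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        return cls(subgroup=subgroup, graph=g, records=[], rule="spearman",
                   r_min=0.67, alpha=0.05)


def _passes(coef: float, p: float, r_min: float, alpha: float) -> bool:
    return (not np.isnan(coef) and not np.isnan(p)
            and abs(coef) >= r_min and p < alpha)


def build_edges(records: list[CorrelationRecord],
                rule: str = "spearman", r_min: float = 0.67,
                alpha: float = 0.05, subgroup: SubgroupKey | None = None,
                nodes: tuple[str, ...] | None = None,
                adjust: str | None = None) -> MediatorNetwork:
    """Call edges from correlation records.

    A pair becomes an edge iff the selected coefficient(s) reach
    ``|coef| >= r_min`` (inclusive) with ``p < alpha``. ``rule`` is one of
    ``spearman``, ``pearson``, ``either`` (at least one method passes) or
    ``both``. ``adjust="bh"`` applies Benjamini-Hochberg across the
    evaluable pairs per method before the significance gate (off by
    default).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if adjust not in (None, "bh"):
        raise ValueError(f"adjust must be None or 'bh', got {adjust!r}")
    usable = [r for r in records if r.ok]
    p_pearson = {id(r): r.p_pearson for r in usable}
    p_spearman = {id(r): r.p_spearman for r in usable}
    if adjust == "bh":
        for pmap in (p_pearson, p_spearman):
            keys = [k for k, v in pmap.items() if not np.isnan(v)]
            if keys:
                adj = stats.false_discovery_control(
                    [pmap[k] for k in keys], method="bh")
                pmap.update(dict(zip(keys, adj)))
    g = nx.Graph()
    if nodes is None and records:
        nodes = tuple(sorted({r.a for r in records} | {r.b for r in records}))
    g.add_nodes_from(nodes or ())
    for r in usable:
        sp = _passes(r.rho_spearman, p_spearman[id(r)], r_min, alpha)
        pe = _passes(r.r_pearson, p_pearson[id(r)], r_min, alpha)
        hit = {"spearman": sp, "pearson": pe,
               "either": sp or pe, "both": sp and pe}[rule]
        if hit:
            g.add_edge(r.a, r.b, r_pearson=r.r_pearson, p_pearson=r.p_pearson,
                       rho_spearman=r.rho_spearman, p_spearman=r.p_spearman,
                       n=r.n)
    return MediatorNetwork(subgroup=subgroup, graph=g, records=records,
                           rule=rule, r_min=r_min, alpha=alpha)


@dataclass
class ConnectivityReport:
    """Degree-sum connectivity accounting for one network."""

    total_connections: int
    by_category: dict[str, int]
    degrees: pd.Series


def connectivity(network: MediatorNetwork,
                 panel: MediatorPanel = DEFAULT_PANEL) -> ConnectivityReport:
    """Count strong correlations per category (degree-sum convention).

    Each edge contributes to the degree of both endpoints, so the sum of
    the four category counts equals the total, which is 2x the edge count.
    """
    degrees = pd.Series({a: network.graph.degree(a) if a in network.graph else 0
                         for a in panel.mediators}, name="degree")
    by_category = {c: int(degrees[list(panel.members(c))].sum())
                   for c in CATEGORIES}
    return ConnectivityReport(total_connections=int(degrees.sum()),
                              by_category=by_category, degrees=degrees)


def hub_set(network: MediatorNetwork, k: int = 5) -> frozenset[str]:
    """Analytes with at least ``k`` strong correlations (degree >= k)."""
    return frozenset(a for a in network.graph.nodes
                     if network.graph.degree(a) >= k)


@dataclass
class VennResult:
    """Hub-set algebra between trimester-matched HC and COVID networks."""

    trimester: int | str
    preserved: frozenset[str]
    lost: frozenset[str]
    acquired: frozenset[str]


def venn_classify(hubs_hc: frozenset[str] | set[str],
                  hubs_covid: frozenset[str] | set[str],
                  trimester: int | str,
                  panel: MediatorPanel = DEFAULT_PANEL) -> VennResult:
    """preserved = HC∩COVID, lost = HC∖COVID, acquired = COVID∖HC."""
    hc = frozenset(hubs_hc)
    covid = frozenset(hubs_covid)
    stray = (hc | covid) - set(panel.mediators)
    if stray:
        raise ValueError(f"hub analytes not in panel: {sorted(stray)}")
    return VennResult(trimester=trimester, preserved=hc & covid,
                      lost=hc - covid, acquired=covid - hc)


def export_network(network: MediatorNetwork, path: str | Path,
                   fmt: str = "csv", panel: MediatorPanel = DEFAULT_PANEL) -> Path:
    """Write a network as SIF, GraphML or edge-list CSV.

    GraphML nodes carry name, display_index, category and degree
    attributes; edges carry both correlation coefficients, p-values and n.
    SIF uses the interaction type ``corr`` (edge lines only).
    """
    path = Path(path)
    if fmt == "sif":
        lines = [f"{a}\tcorr\t{b}" for a, b in sorted(map(sorted, network.graph.edges))]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        g = nx.Graph()
        for node in network.graph.nodes:
            g.add_node(node, name=node,
                       display_index=int(panel.display_index.get(node, 0)),
                       category=panel.category.get(node, ""),
                       degree=int(network.graph.degree(node)))
        for a, b, attrs in network.graph.edges(data=True):
            g.add_edge(a, b, **{k: float(v) if isinstance(v, float) else v
                                for k, v in attrs.items()})
        nx.write_graphml(g, path)
    elif fmt == "csv":
        frame = records_frame(network.records) if network.records else pd.DataFrame(
            [{"analyte_a": a, "analyte_b": b} for a, b in network.graph.edges])
        frame.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected sif, graphml or csv")
    return path
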