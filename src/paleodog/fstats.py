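"""f-statistics, D, f4-ratio, weighted block jackknife and admixture graphs.

Patterson-style estimators on per-site derived-allele frequencies:

    f2(A,B)     = E[(a-b)^2]                (optionally bias-corrected)
    f3(C;A,B)   = E[(c-a)(c-b)]             (outgroup-f3: shared drift of A,B)
    f4(A,B;C,D) = E[(a-b)(c-d)]
    D(A,B;C,D)  = sum (a-b)(c-d) / sum (a+b-2ab)(c+d-2cd)

Standard errors come from a weighted delete-one-block jackknife (weights
proportional to per-block site counts).  Expected f-statistics on a
user-specified admixture graph are computed by admixture-weighted edge
overlap, and graphs are fitted to observed statistics by bounded weighted
least squares with residual-Z outlier reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .simdata import GenotypePanel, MISSING

__all__ = [
    "FreqPanel",
    "FStatResult",
    "AdmixtureGraph",
    "GraphEdge",
    "f2",
    "f3",
    "f4",
    "d_stat",
    "f4_ratio",
    "expected_f",
    "fit_graph",
    "weighted_block_jackknife",
    "blocks_from_genetic_map",
]


# ---------------------------------------------------------------------------
# frequency panel
# ---------------------------------------------------------------------------

@dataclass
class FreqPanel:
    """Per-site derived-allele frequency and haploid sample size per population."""

    pops: list[str]
    freq: dict[str, np.ndarray]   # NaN where population has no data
    count: dict[str, np.ndarray]  # haploid counts
    block_id: np.ndarray

    @classmethod
    def from_genotype_panel(cls, panel: GenotypePanel) -> "FreqPanel":
        pops = sorted(set(panel.sample_pops))
        freq, count = {}, {}
        G = panel.genotypes
        for pop in pops:
            idx = panel.pop_indices(pop)
            sub = G[:, idx]
            valid = sub != MISSING
            n_hap = 2 * valid.sum(axis=1)
            dos = np.where(valid, sub, 0).sum(axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                f = np.where(n_hap > 0, dos / np.maximum(n_hap, 1), np.nan)
            freq[pop] = f
            count[pop] = n_hap
        return cls(pops=pops, freq=freq, count=count, block_id=panel.block_id.copy())

    def n_sites(self) -> int:
        return len(self.block_id)


@dataclass
class FStatResult:
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_sites: int
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# weighted block jackknife
# ---------------------------------------------------------------------------

def weighted_block_jackknife(
    num: np.ndarray,
    den: np.ndarray,
    block_id: np.ndarray,
    counts: np.ndarray | None = None,
) -> tuple[float, float, int]:
    """Delete-one-block jackknife of a ratio-of-sums estimator.

    ``num`` and ``den`` are per-site (or per-block) contributions; the
    estimate is sum(num)/sum(den).  Block weights are proportional to
    per-block totals of ``counts`` — site counts by default — following the
    weighted delete-one jackknife of Busing et al.
    Returns (estimate, SE, n_blocks); SE is NaN with < 2 usable blocks.
    """
    if counts is None:
        counts = np.ones_like(np.asarray(num, dtype=float))
    blocks, inv = np.unique(block_id, return_inverse=True)
    g_all = len(blocks)
    bnum = np.bincount(inv, weights=num, minlength=g_all)
    bden = np.bincount(inv, weights=den, minlength=g_all)
    bcnt = np.bincount(inv, weights=counts, minlength=g_all)
    tot_num, tot_den, n = bnum.sum(), bden.sum(), bcnt.sum()
    if tot_den == 0:
        raise ZeroDivisionError("denominator of the statistic is zero")
    est = tot_num / tot_den
    use = (bcnt > 0) & (bcnt < n) & (bden != tot_den)
    g = int(use.sum())
    if g < 2:
        return est, np.nan, g
    bnum, bden, m = bnum[use], bden[use], bcnt[use]
    n = m.sum()
    loo = (tot_num - bnum) / (tot_den - bden)
    h = n / m
    theta_j = g * est - ((1.0 - m / n) * loo).sum()
    tau = h * est - (h - 1.0) * loo
    var = np.sum((tau - theta_j) ** 2 / (h - 1.0)) / g
    return est, float(np.sqrt(max(var, 0.0))), g


def _result(num, den, block_id, flags=None) -> FStatResult:
    mask = np.isfinite(num) & np.isfinite(den)
    est, se, g = weighted_block_jackknife(num[mask], den[mask], block_id[mask])
    flags = list(flags or [])
    if g < 2:
        flags.append("no-se")
        z = np.nan
    else:
        z = est / se if se > 0 else np.nan
    return FStatResult(float(est), float(se), float(z), g, int(mask.sum()), flags)


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _freqs(panel: FreqPanel, *pops: str) -> list[np.ndarray]:
    for p in pops:
        if p not in panel.freq:
            raise KeyError(f"population {p!r} not in panel")
    return [panel.freq[p] for p in pops]


def _het_correction(panel: FreqPanel, pop: str) -> np.ndarray:
    """hat(h)/n = p(1-p)/(n-1): the sampling-variance term of a frequency."""
    p = panel.freq[pop]
    n = panel.count[pop].astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n > 1, p * (1 - p) / np.maximum(n - 1, 1), np.nan)


def f2(panel: FreqPanel, a: str, b: str, *, bias_correction: bool = True) -> FStatResult:
    pa, pb = _freqs(panel, a, b)
    if a == b:
        # f2 of a population with itself is identically zero; the finite-sample
        # correction applies only to independently sampled frequency estimates
        z = np.zeros_like(pa)
        return _result(z, np.ones_like(z), panel.block_id)
    num = (pa - pb) ** 2
    if bias_correction:
        num = num - _het_correction(panel, a) - _het_correction(panel, b)
    return _result(num, np.ones_like(num), panel.block_id)


def f3(panel: FreqPanel, c: str, a: str, b: str, *, bias_correction: bool = True) -> FStatResult:
    """f3(C; A, B): with C an outgroup this is the shared drift of A and B."""
    pc, pa, pb = _freqs(panel, c, a, b)
    num = (pc - pa) * (pc - pb)
    if bias_correction:
        num = num - _het_correction(panel, c)
    return _result(num, np.ones_like(num), panel.block_id)


def f4(panel: FreqPanel, a: str, b: str, c: str, d: str) -> FStatResult:
    pa, pb, pc, pd = _freqs(panel, a, b, c, d)
    num = (pa - pb) * (pc - pd)
    return _result(num, np.ones_like(num), panel.block_id)


def d_stat(panel: FreqPanel, a: str, b: str, c: str, d: str) -> FStatResult:
    pa, pb, pc, pd = _freqs(panel, a, b, c, d)
    num = (pa - pb) * (pc - pd)
    den = (pa + pb - 2 * pa * pb) * (pc + pd - 2 * pc * pd)
    return _result(num, den, panel.block_id)


def f4_ratio(
    panel: FreqPanel,
    numerator: Sequence[str],
    denominator: Sequence[str],
) -> FStatResult:
    """Ratio of two f4 statistics; jackknife taken on the ratio itself.

    With numerator f4(A,O;X,C) and denominator f4(A,O;B,C) the ratio estimates
    the admixture proportion of B-ancestry in target X.
    """
    an, bn, cn, dn = _freqs(panel, *numerator)
    ad, bd, cd, dd = _freqs(panel, *denominator)
    num = (an - bn) * (cn - dn)
    den = (ad - bd) * (cd - dd)
    res = _result(num, den, panel.block_id)
    den_res = f4(panel, *denominator)
    if np.isfinite(den_res.se) and abs(den_res.estimate) < 2 * den_res.se:
        res.flags.append("unstable-denominator")
    return res


def blocks_from_genetic_map(
    pos: np.ndarray, map_pos: np.ndarray, map_cm: np.ndarray, window_cm: float = 5.0
) -> np.ndarray:
    """Assign block ids by ``window_cm`` windows of a (pos, cM) genetic map."""
    cm = np.interp(pos, map_pos, map_cm)
    return (cm // window_cm).astype(np.int64)


# ---------------------------------------------------------------------------
# admixture graphs
# ---------------------------------------------------------------------------

@dataclass
class GraphEdge:
    parent: str
    child: str
    length: float
    proportion: float | None = None  # ancestry share for admixture edges


class AdmixtureGraph:
    """DAG of drift edges (lengths in f2 units) with two-parent admixture nodes."""

    def __init__(self, edges: Sequence[GraphEdge], leaves: dict[str, str]):
        self.edges = list(edges)
        self.leaves = dict(leaves)  # population label -> node name
        self._validate()

    def _validate(self) -> None:
        children: dict[str, list[GraphEdge]] = {}
        nodes = set()
        for e in self.edges:
            children.setdefault(e.child, []).append(e)
            nodes.add(e.parent)
            nodes.add(e.child)
        self.nodes = nodes
        for child, es in children.items():
            if len(es) == 1:
                if es[0].proportion is not None:
                    raise ValueError(f"single-parent node {child} must not set a proportion")
            elif len(es) == 2:
                props = [e.proportion for e in es]
                if any(p is None for p in props):
                    raise ValueError(f"admixture node {child} needs proportions on both edges")
                if not np.isclose(sum(props), 1.0):
                    raise ValueError(f"admixture proportions into {child} must sum to 1")
                if not all(0.0 <= p <= 1.0 for p in props):
                    raise ValueError("admixture proportions must be in [0,1]")
            else:
                raise ValueError(f"node {child} has {len(es)} parents")
        roots = nodes - set(children)
        if len(roots) != 1:
            raise ValueError(f"graph must have exactly one root, found {sorted(roots)}")
        self.root = roots.pop()
        self._children_edges = children
        # cycle check via DFS child->parent
        state: dict[str, int] = {}

        def visit(v: str) -> None:
            state[v] = 1
            for e in children.get(v, []):
                s = state.get(e.parent, 0)
                if s == 1:
                    raise ValueError("graph contains a cycle")
                if s == 0:
                    visit(e.parent)
            state[v] = 2

        for v in nodes:
            if state.get(v, 0) == 0:
                visit(v)
        for pop, node in self.leaves.items():
            if node not in nodes:
                raise ValueError(f"leaf node {node} for population {pop} not in graph")

    # -- edge ancestry weights ---------------------------------------------
    def edge_weights(self, pop: str) -> np.ndarray:
        """Probability that a lineage sampled from ``pop`` drifts through each edge."""
        if pop not in self.leaves:
            raise KeyError(f"population {pop!r} not mapped to a leaf")
        node_w: dict[str, float] = {self.leaves[pop]: 1.0}
        w = np.zeros(len(self.edges))
        edge_index = {id(e): i for i, e in enumerate(self.edges)}
        # child-before-parent order so a node's weight is final when flushed
        for v in self._topo_child_first():
            wv = node_w.get(v, 0.0)
            if wv == 0.0:
                continue
            for e in self._children_edges.get(v, []):
                share = wv * (e.proportion if e.proportion is not None else 1.0)
                w[edge_index[id(e)]] += share
                node_w[e.parent] = node_w.get(e.parent, 0.0) + share
        return w

    def _topo_child_first(self) -> list[str]:
        out: list[str] = []
        # Kahn ordering on the child->parent DAG
        indeg = {v: 0 for v in self.nodes}
        for e in self.edges:
            indeg[e.parent] += 1
        ready = [v for v, d in indeg.items() if d == 0]
        while ready:
            v = ready.pop()
            out.append(v)
            for e in self._children_edges.get(v, []):
                indeg[e.parent] -= 1
                if indeg[e.parent] == 0:
                    ready.append(e.parent)
        return out

    def lengths(self) -> np.ndarray:
        return np.array([e.length for e in self.edges])

    # -- JSON ---------------------------------------------------------------
    def to_json(self, path) -> None:
        obj = {
            "edges": [
                {"parent": e.parent, "child": e.child, "length": e.length,
                 **({"proportion": e.proportion} if e.proportion is not None else {})}
                for e in self.edges
            ],
            "leaves": self.leaves,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "AdmixtureGraph":
        with open(path) as fh:
            obj = json.load(fh)
        edges = [
            GraphEdge(d["parent"], d["child"], float(d["length"]),
                      d.get("proportion"))
            for d in obj["edges"]
        ]
        return cls(edges, obj["leaves"])


def expected_f(graph: AdmixtureGraph, statistic: str, pops: Sequence[str]) -> float:
    """Expected f2/f3/f4 on a graph by admixture-weighted edge overlap.

    f4(A,B;C,D) = sum_e (wA - wB)(wC - wD) * length(e) where w_X(e) is the
    expected ancestry share of X drifting through edge e; f2 and f3 are the
    corresponding quadratic forms.
    """
    if statistic == "f2":
        a, b = pops
        quad = (a, b, a, b)
    elif statistic == "f3":
        c, a, b = pops
        quad = (c, a, c, b)
    elif statistic == "f4":
        quad = tuple(pops)
    else:
        raise ValueError(f"unknown statistic {statistic!r}")
    wa, wb, wc, wd = (graph.edge_weights(p) for p in quad)
    return float(np.sum((wa - wb) * (wc - wd) * graph.lengths()))


@dataclass
class GraphFit:
    graph: AdmixtureGraph
    residual_z: np.ndarray
    outliers: list[tuple[str, tuple, float]]
    identifiable: bool
    null_space: np.ndarray | None
    cost: float


def fit_graph(
    graph: AdmixtureGraph,
    observations: Sequence[tuple[str, Sequence[str], float, float]],
    *,
    outlier_z: float = 3.0,
) -> GraphFit:
    """Fit edge lengths and admixture proportions to observed f-statistics.

    ``observations`` are ``(statistic, populations, estimate, se)`` tuples.
    Minimizes sum(((obs - expected)/se)^2) with lengths >= 0 and proportions
    in [0,1]; statistics with |Z-residual| >= ``outlier_z`` at the optimum are
    reported as outliers.  A rank-deficient Jacobian flags the fit as
    non-identifiable, with the parameter null space attached.
    """
    if not observations:
        raise ValueError("no observed statistics supplied")
    edges = graph.edges
    adm_children = sorted({e.child for e in edges if e.proportion is not None})
    first_adm_edge = {
        c: next(i for i, e in enumerate(edges) if e.child == c and e.proportion is not None)
        for c in adm_children
    }

    def build(params: np.ndarray) -> AdmixtureGraph:
        lengths = params[: len(edges)]
        props = dict(zip(adm_children, params[len(edges):]))
        new_edges = []
        for i, e in enumerate(edges):
            prop = e.proportion
            if prop is not None:
                p_first = props[e.child]
                prop = p_first if i == first_adm_edge[e.child] else 1.0 - p_first
            new_edges.append(GraphEdge(e.parent, e.child, float(lengths[i]), prop))
        return AdmixtureGraph(new_edges, graph.leaves)

    obs = np.array([o[2] for o in observations])
    ses = np.array([o[3] for o in observations])

    def residuals(params: np.ndarray) -> np.ndarray:
        g = build(params)
        exp = np.array([expected_f(g, o[0], o[1]) for o in observations])
        return (obs - exp) / ses

    x0 = np.concatenate([
        np.maximum(graph.lengths(), 1e-6),
        [next(e.proportion for e in edges
              if e.child == c and e.proportion is not None) for c in adm_children],
    ])
    lb = np.concatenate([np.zeros(len(edges)), np.zeros(len(adm_children))])
    ub = np.concatenate([np.full(len(edges), np.inf), np.ones(len(adm_children))])
    sol = least_squares(residuals, x0=x0, bounds=(lb, ub), method="trf",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    fitted = build(sol.x)
    z = residuals(sol.x)
    outliers = [
        (observations[i][0], tuple(observations[i][1]), float(z[i]))
        for i in np.flatnonzero(np.abs(z) >= outlier_z)
    ]
    # identifiability: numerical rank of the Jacobian at the solution
    J = sol.jac
    svals = np.linalg.svd(J, compute_uv=False)
    tol = max(J.shape) * np.finfo(float).eps * (svals[0] if len(svals) else 1.0)
    rank = int((svals > max(tol, 1e-10)).sum())
    identifiable = rank >= len(sol.x)
    null_space = None
    if not identifiable:
        _, _, vt = np.linalg.svd(J)
        null_space = vt[rank:]
    return GraphFit(fitted, -z, outliers, identifiable, null_space, float(2 * sol.cost))
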