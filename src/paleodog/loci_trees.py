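"""Sequence-divergence matrices, neighbour-joining trees and locus haplotypes.

Pairwise divergence between diploid samples is the probability that two
randomly drawn alleles differ,

    d(x, y) = mean over sites of p_x(1-p_y) + p_y(1-p_x),  p = dosage/2,

which feeds Saitou-Nei neighbour joining (deterministic tie-breaking) with
node support from a genomic-window bootstrap (default 5 cM windows sampled
with replacement).  Candidate-locus haplotypes of a query sample are
classified dog-like / wolf-like / heterozygous-like by distance to the dog
and wolf panel centroids after a minor-allele-frequency filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .simdata import GenotypePanel, MISSING

__all__ = [
    "DistanceMatrix",
    "LocusCall",
    "pairwise_divergence",
    "nj_tree",
    "window_bootstrap_support",
    "classify_locus",
    "GeneticMap",
]


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    missing_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        finite = np.isfinite(v)
        if not np.allclose(v[finite], v.T[finite], atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.labels) + "\n")
            for i, lab in enumerate(self.labels):
                fh.write(lab + "\t" + "\t".join(f"{x:.10g}" for x in self.values[i]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "DistanceMatrix":
        with open(path) as fh:
            labels = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [
                [float(x) for x in line.rstrip("\n").split("\t")[1:]] for line in fh
            ]
        return cls(labels, np.array(rows))


def pairwise_divergence(panel: GenotypePanel) -> DistanceMatrix:
    """Sequence-divergence distance matrix over the panel's samples.

    Sites missing in either member of a pair are dropped pairwise; a pair
    with no shared sites gets a NaN entry and is flagged.
    """
    G = panel.genotypes.astype(float)
    n = G.shape[1]
    if n < 2:
        raise ValueError("need >= 2 samples")
    valid = panel.genotypes != MISSING
    P = np.where(valid, G / 2.0, 0.0)
    D = np.zeros((n, n))
    missing_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[:, i] & valid[:, j]
            m = int(both.sum())
            if m == 0:
                D[i, j] = D[j, i] = np.nan
                missing_pairs.append((panel.samples[i], panel.samples[j]))
                continue
            pi, pj = P[both, i], P[both, j]
            d = np.mean(pi * (1 - pj) + pj * (1 - pi))
            D[i, j] = D[j, i] = d
    return DistanceMatrix(list(panel.samples), D, missing_pairs)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbour joining; ties broken by lowest label index.

    Returns an unrooted dendropy tree; negative branch lengths arising from
    noisy matrices are clamped at zero.
    """
    if np.isnan(d.values).any():
        raise ValueError("distance matrix has missing entries")
    n = len(d.labels)
    if n < 3:
        raise ValueError("need >= 3 taxa")
    D = d.values
    active = list(range(n))
    # grow newick fragments per active node
    sub = {i: d.labels[i] for i in range(n)}
    Dw = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n
    while len(active) > 2:
        r = len(active)
        sums = {i: sum(Dw[(i, j)] for j in active if j != i) for i in active}
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * Dw[(i, j)] - sums[i] - sums[j]
                key = (q, i, j)  # deterministic: lowest index pair on ties
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = Dw[(i, j)]
        li = 0.5 * dij + (sums[i] - sums[j]) / (2 * (r - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            Dw[(u, k)] = Dw[(k, u)] = 0.5 * (Dw[(i, k)] + Dw[(j, k)] - dij)
        sub[u] = f"({sub[i]}:{li:.10g},{sub[j]}:{lj:.10g})"
        active = [k for k in active if k not in (i, j)] + [u]
    i, j = active
    dij = max(Dw[(i, j)], 0.0)
    newick_str = f"({sub[i]}:{dij/2:.10g},{sub[j]}:{dij/2:.10g});"
    tree = dendropy.Tree.get(data=newick_str, schema="newick", preserve_underscores=True)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# window bootstrap
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Two-column (pos, cM) map with linear interpolation."""

    pos: np.ndarray
    cm: np.ndarray

    def interpolate(self, pos: np.ndarray) -> np.ndarray:
        return np.interp(pos, self.pos, self.cm)

    @classmethod
    def from_tsv(cls, path) -> "GeneticMap":
        pos, cm = [], []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                a, b = line.split()[:2]
                pos.append(int(a))
                cm.append(float(b))
        return cls(np.array(pos), np.array(cm))

    @classmethod
    def uniform(cls, max_pos: int, cm_per_site: float) -> "GeneticMap":
        return cls(np.array([0, max_pos]), np.array([0.0, max_pos * cm_per_site]))


def _bipartitions(tree: dendropy.Tree, labels: list[str]) -> set[frozenset]:
    """Non-trivial splits as frozensets of the smaller label side."""
    label_set = set(labels)
    out = set()
    tree2 = tree.clone(depth=1)
    tree2.encode_bipartitions()
    for edge in tree2.preorder_edge_iter():
        if edge.head_node is None or edge.head_node.parent_node is None:
            continue
        side = {
            leaf.taxon.label
            for leaf in edge.head_node.leaf_iter()
        }
        if 1 < len(side) < len(label_set) - 1:
            other = label_set - side
            out.add(frozenset(min(side, other, key=lambda s: (len(s), sorted(s)))))
    return out


def window_bootstrap_support(
    panel: GenotypePanel,
    genetic_map: GeneticMap,
    *,
    window_cm: float = 5.0,
    n_replicates: int = 100,
    seed: int = 0,
) -> tuple[dendropy.Tree, dict[frozenset, float]]:
    """NJ tree with split support from resampled genomic windows.

    The genome is cut into ``window_cm`` windows on the genetic map; each
    bootstrap replicate samples windows with replacement, rebuilds the NJ
    tree, and support is the fraction of replicates containing each split of
    the original tree.
    """
    cm = genetic_map.interpolate(panel.pos)
    window_id = (cm // window_cm).astype(np.int64)
    windows = np.unique(window_id)
    if len(windows) < 10:
        import warnings

        warnings.warn("fewer than 10 windows: bootstrap support unreliable")
    tree = nj_tree(pairwise_divergence(panel))
    splits = _bipartitions(tree, list(panel.samples))
    support = {s: 0.0 for s in splits}
    if n_replicates == 0:
        return tree, {}
    rng = np.random.default_rng(seed)
    site_lists = {w: np.flatnonzero(window_id == w) for w in windows}
    for _ in range(n_replicates):
        chosen = rng.choice(windows, size=len(windows), replace=True)
        idx = np.concatenate([site_lists[w] for w in chosen])
        rep_panel = panel.take_sites(idx)
        rep_tree = nj_tree(pairwise_divergence(rep_panel))
        rep_splits = _bipartitions(rep_tree, list(panel.samples))
        for s in splits:
            if s in rep_splits:
                support[s] += 1.0
    return tree, {s: v / n_replicates for s, v in support.items()}


# ---------------------------------------------------------------------------
# locus classification
# ---------------------------------------------------------------------------

@dataclass
class LocusCall:
    window: int
    label: str  # dog-like | wolf-like | heterozygous-like | unclassified
    score: float
    n_sites: int


def classify_locus(
    panel: GenotypePanel,
    windows: list[np.ndarray],
    dog_samples: list[str],
    wolf_samples: list[str],
    query: str,
    *,
    maf_range: tuple[float, float] = (0.05, 0.49),
    min_sites: int = 20,
    margin: float = 0.25,
    apply_maf_filter: bool = True,
) -> list[LocusCall]:
    """Classify the query's haplotype per window against dog/wolf centroids.

    Sites are filtered to minor-allele frequency within ``maf_range`` across
    the combined dog+wolf panels (unless disabled); per window the mean
    absolute dosage distance of the query to each panel centroid is compared,
    and the call is dog-like or wolf-like when the difference exceeds
    ``margin`` dosage units, heterozygous-like otherwise.  Windows with fewer
    than ``min_sites`` usable sites are unclassified.  The score is
    (distance to wolf centroid) - (distance to dog centroid): positive means
    dog-like.
    """
    sidx = {s: i for i, s in enumerate(panel.samples)}
    dog_i = [sidx[s] for s in dog_samples]
    wolf_i = [sidx[s] for s in wolf_samples]
    qi = sidx[query]
    G = panel.genotypes.astype(float)
    valid = panel.genotypes != MISSING

    panel_i = dog_i + wolf_i
    pv = valid[:, panel_i]
    dos = np.where(pv, G[:, panel_i], 0.0)
    n_al = 2.0 * pv.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_al > 0, dos.sum(axis=1) / np.maximum(n_al, 1), np.nan)
    maf = np.minimum(freq, 1.0 - freq)
    if apply_maf_filter:
        site_ok = (maf >= maf_range[0]) & (maf <= maf_range[1])
    else:
        site_ok = np.isfinite(freq)

    calls = []
    for w, site_idx in enumerate(windows):
        use = site_idx[site_ok[site_idx] & valid[site_idx, qi]]
        use = use[valid[use][:, dog_i].any(axis=1) & valid[use][:, wolf_i].any(axis=1)]
        if len(use) < min_sites:
            calls.append(LocusCall(w, "unclassified", np.nan, len(use)))
            continue
        dog_cent = np.nanmean(
            np.where(valid[use][:, dog_i], G[use][:, dog_i], np.nan), axis=1
        )
        wolf_cent = np.nanmean(
            np.where(valid[use][:, wolf_i], G[use][:, wolf_i], np.nan), axis=1
        )
        q = G[use, qi]
        d_dog = float(np.mean(np.abs(q - dog_cent)))
        d_wolf = float(np.mean(np.abs(q - wolf_cent)))
        score = d_wolf - d_dog
        if score >= margin:
            label = "dog-like"
        elif score <= -margin:
            label = "wolf-like"
        else:
            label = "heterozygous-like"
        calls.append(LocusCall(w, label, score, len(use)))
    return calls
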