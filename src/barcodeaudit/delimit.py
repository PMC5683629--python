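"""Candidate OTU partitions from a distance matrix.

Three delimitation routes are provided, mirroring common practice in DNA
barcoding studies of poorly sampled faunas:

* a fixed-threshold proxy for Barcode Index Numbers — single-linkage
  clustering at 2.2% uncorrected COI distance (:func:`threshold_partition`);
* Automatic Barcode Gap Discovery (:func:`abgd_partition`) — recursive
  partitioning at the discontinuity ("barcode gap") between intra- and
  inter-specific pairwise distances, scanned over a geometric grid of prior
  maximum intraspecific divergences, with the reported partition chosen by
  stability across consecutive priors;
* neighbor-joining trees (:func:`neighbor_joining`) with a conspecificity
  predicate for the 16S locus (:func:`conspecificity_clusters`), either as a
  single-linkage threshold or as maximal label-consistent clades of the
  midpoint-rooted tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .distances import DistanceMatrix

__all__ = [
    "Partition",
    "ABGDConfig",
    "ABGDResult",
    "threshold_partition",
    "abgd_partition",
    "neighbor_joining",
    "conspecificity_clusters",
]


@dataclass
class Partition:
    """A method-tagged mapping of specimens to group labels.

    Labels are canonical: consecutive integers starting at 1, assigned by
    order of first member appearance in the input id order.
    """

    method: str
    groups: dict[str, int]

    def __post_init__(self):
        labels = list(dict.fromkeys(self.groups.values()))
        if labels != list(range(1, len(labels) + 1)):
            raise ValueError("labels must be consecutive 1..k in first-appearance order")

    @property
    def n_groups(self) -> int:
        return len(set(self.groups.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, g in self.groups.items():
            out.setdefault(g, []).append(sid)
        return out

    @classmethod
    def from_labels(cls, method: str, ids, raw_labels) -> "Partition":
        """Canonicalise arbitrary labels into 1..k by first appearance."""
        remap: dict = {}
        groups = {}
        for sid, lab in zip(ids, raw_labels):
            if lab not in remap:
                remap[lab] = len(remap) + 1
            groups[sid] = remap[lab]
        return cls(method=method, groups=groups)


def _single_linkage_labels(d: np.ndarray, t: float) -> np.ndarray:
    adj = csr_matrix(d <= t)
    _, labels = connected_components(adj, directed=False)
    return labels


def threshold_partition(D: DistanceMatrix, t: float = 0.022,
                        method: str | None = None) -> Partition:
    """Single-linkage clusters at distance threshold ``t``.

    Specimens are in one group whenever they are connected by a chain of
    pairs each within ``t``. The default 0.022 is the fixed-difference proxy
    for BOLD's Barcode Index Numbers.
    """
    labels = _single_linkage_labels(D.d, t)
    return Partition.from_labels(method or f"threshold@{t}", D.ids, labels)


# -- ABGD ---------------------------------------------------------------------

@dataclass
class ABGDConfig:
    """Parameters of barcode-gap discovery.

    Pmin/Pmax bound the geometric grid of prior maximum intraspecific
    divergences; ``steps`` grid points are scanned. ``X`` is the minimum
    relative width of an acceptable gap (a gap must exceed X times the local
    mean consecutive-gap width) and ``Nb`` controls the sliding-window size
    used for that local mean.
    """

    Pmin: float = 0.001
    Pmax: float = 0.1
    steps: int = 10
    X: float = 1.5
    Nb: int = 20

    def __post_init__(self):
        if not (0 < self.Pmin < self.Pmax < 1):
            raise ValueError("need 0 < Pmin < Pmax < 1")
        if self.steps < 2 or self.Nb < 2 or self.X <= 0:
            raise ValueError("steps >= 2, Nb >= 2, X > 0 required")

    def prior_grid(self) -> np.ndarray:
        k = np.arange(self.steps)
        return self.Pmin * (self.Pmax / self.Pmin) ** (k / (self.steps - 1))


@dataclass
class ABGDResult:
    priors: list[float]
    initial: list[Partition]
    recursive: list[Partition]
    selected: Partition
    selected_prior: float

    def summary_rows(self):
        for p, ini, rec in zip(self.priors, self.initial, self.recursive):
            yield (p, ini.n_groups, rec.n_groups, p == self.selected_prior)


def _gap_threshold(dist_sorted: np.ndarray, P: float, X: float, Nb: int) -> float | None:
    """First barcode gap beyond prior P; returns the split threshold or None.

    Scans the ascending pairwise distances for the first index i where the
    next distance exceeds P and the jump d[i+1]-d[i] is wider than X times
    the mean consecutive-gap width over a window of w = max(3, ceil(N/Nb))
    distances ending at i. The split threshold is the midpoint of the gap.
    """
    N = len(dist_sorted)
    if N < 2:
        return None
    w = max(3, math.ceil(N / Nb))
    gaps = np.diff(dist_sorted)
    for i in range(N - 1):
        if dist_sorted[i + 1] <= P:
            continue
        lo = max(0, i - w + 1)
        window_gaps = gaps[lo:i]  # gaps within the w distances ending at i
        theta = window_gaps.mean() if len(window_gaps) else 0.0
        if gaps[i] > X * theta and gaps[i] > 0:
            return (dist_sorted[i] + dist_sorted[i + 1]) / 2
    return None


def _abgd_once(D: DistanceMatrix, P: float, cfg: ABGDConfig):
    """One initial split; returns list of id-groups (None means no split)."""
    iu = np.triu_indices(len(D.ids), k=1)
    dist_sorted = np.sort(D.d[iu])
    thr = _gap_threshold(dist_sorted, P, cfg.X, cfg.Nb)
    if thr is None:
        return None
    labels = _single_linkage_labels(D.d, thr)
    if len(set(labels)) == 1:
        return None
    groups: dict[int, list[str]] = {}
    for sid, lab in zip(D.ids, labels):
        groups.setdefault(lab, []).append(sid)
    return list(groups.values())


def _abgd_recursive(D: DistanceMatrix, P: float, cfg: ABGDConfig) -> list[list[str]]:
    split = _abgd_once(D, P, cfg)
    if split is None:
        return [list(D.ids)]
    out: list[list[str]] = []
    for grp in split:
        if len(grp) < 2:
            out.append(grp)
        else:
            out.extend(_abgd_recursive(D.submatrix(grp), P, cfg))
    return out


def abgd_partition(D: DistanceMatrix, cfg: ABGDConfig | None = None) -> ABGDResult:
    """Automatic Barcode Gap Discovery over a grid of priors.

    For each prior the matrix is split at the first acceptable gap and the
    procedure recurses within each resulting group until no further gap is
    found. The selected partition is the recursive partition whose group
    count is stable over the longest run of consecutive priors (ties broken
    toward smaller priors).
    """
    if len(D.ids) < 2:
        raise ValueError("need at least 2 specimens")
    cfg = cfg or ABGDConfig()
    priors = list(cfg.prior_grid())
    initial, recursive = [], []
    for P in priors:
        ini = _abgd_once(D, P, cfg)
        ini_groups = ini if ini is not None else [list(D.ids)]
        initial.append(_partition_from_groups(f"abgd-initial@P={P:.6g}", D.ids, ini_groups))
        rec_groups = _abgd_recursive(D, P, cfg)
        recursive.append(_partition_from_groups(f"abgd@P={P:.6g}", D.ids, rec_groups))

    counts = [p.n_groups for p in recursive]
    best_start, best_len = 0, 1
    i = 0
    while i < len(counts):
        j = i
        while j + 1 < len(counts) and counts[j + 1] == counts[i]:
            j += 1
        if j - i + 1 > best_len:
            best_start, best_len = i, j - i + 1
        i = j + 1
    selected = recursive[best_start]
    return ABGDResult(priors=priors, initial=initial, recursive=recursive,
                      selected=selected, selected_prior=priors[best_start])


def _partition_from_groups(method: str, id_order, groups: list[list[str]]) -> Partition:
    lab_of = {sid: gi for gi, grp in enumerate(groups) for sid in grp}
    ids = [sid for sid in id_order]
    return Partition.from_labels(method, ids, [lab_of[s] for s in ids])


# -- neighbor joining ---------------------------------------------------------

def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Classic agglomerative neighbor joining (Saitou & Nei) on ``D``.

    Ties in the Q criterion are broken toward the lexicographically smallest
    pair of node names (a node is named by the smallest tip id beneath it),
    so results are deterministic. Negative branch-length estimates are
    clamped to zero. Returns an unrooted dendropy tree; for n=2 the single
    edge is split evenly between the two tips.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("need at least 2 tips")
    # each active node: (sort_key, newick_fragment); distances in a dict matrix
    names = list(D.ids)
    frags = {i: _quote(names[i]) for i in range(n)}
    keys = {i: names[i] for i in range(n)}
    dist = {(i, j): D.d[i, j] for i in range(n) for j in range(n) if i != j}
    active = list(range(n))
    next_id = n

    if n == 2:
        h = D.d[0, 1] / 2
        newick = f"({frags[0]}:{h:.10g},{frags[1]}:{h:.10g});"
        return _parse(newick)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dist[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist[i, j] - r[i] - r[j]
                tie = tuple(sorted((keys[i], keys[j])))
                cand = (q, tie, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        li = 0.5 * dist[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = dist[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        u = next_id
        next_id += 1
        frags[u] = f"({frags[i]}:{li:.10g},{frags[j]}:{lj:.10g})"
        keys[u] = min(keys[i], keys[j])
        for k in active:
            if k in (i, j):
                continue
            duk = max(0.5 * (dist[i, k] + dist[j, k] - dist[i, j]), 0.0)
            dist[u, k] = dist[k, u] = duk
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = sorted(active, key=lambda k: keys[k])
    la = max(0.5 * (dist[a, b] + dist[a, c] - dist[b, c]), 0.0)
    lb = max(0.5 * (dist[a, b] + dist[b, c] - dist[a, c]), 0.0)
    lc = max(0.5 * (dist[a, c] + dist[b, c] - dist[a, b]), 0.0)
    newick = (f"({frags[a]}:{la:.10g},{frags[b]}:{lb:.10g},"
              f"{frags[c]}:{lc:.10g});")
    return _parse(newick)


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]':;,"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


# -- 16S conspecificity -------------------------------------------------------

def conspecificity_clusters(D16: DistanceMatrix, mode: str = "threshold",
                            t16: float = 0.03,
                            tree: dendropy.Tree | None = None,
                            labels: dict[str, str] | None = None) -> Partition:
    """Cluster 16S sequences into putative conspecific groups.

    ``threshold`` mode is single-linkage at ``t16`` (default 3%), the
    deterministic stand-in for visually delimited clades. ``monophyly`` mode
    midpoint-roots ``tree`` and returns the maximal clades whose tips carry
    at most one distinct reference name (``labels``: tip id -> binomial for
    labeled reference tips).
    """
    if mode == "threshold":
        return threshold_partition(D16, t16, method=f"16s-cluster@{t16}")
    if mode != "monophyly":
        raise ValueError(f"unknown mode {mode!r}")
    if tree is None or not labels:
        raise ValueError("monophyly mode requires a tree and labeled reference tips")
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=True)
    groups: list[list[str]] = []

    def names_under(node):
        tips = [lf.taxon.label for lf in node.leaf_iter()]
        return tips, {labels[x] for x in tips if x in labels}

    def walk(node):
        tips, nameset = names_under(node)
        if len(nameset) <= 1:
            groups.append(tips)
            return
        for child in node.child_nodes():
            walk(child)

    walk(t.seed_node)
    order = [lf.taxon.label for lf in t.leaf_node_iter()]
    lab_of = {sid: gi for gi, grp in enumerate(groups) for sid in grp}
    # keep the input id order of the distance matrix for canonical labels
    ids = [s for s in D16.ids if s in lab_of] or order
    return Partition.from_labels(f"16s-monophyly", ids, [lab_of[s] for s in ids])
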