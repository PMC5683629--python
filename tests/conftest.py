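"""Shared fixtures and oracle helpers for the test suite."""

import itertools

import numpy as np
import pytest

from barcodeaudit.distances import DistanceMatrix
from barcodeaudit.io import SpecimenRecord


def make_matrix(ids, entries, fill=0.5, n_sites=600):
    """Build a DistanceMatrix from a dict {(a, b): d}; unspecified pairs = fill."""
    n = len(ids)
    idx = {s: i for i, s in enumerate(ids)}
    d = np.full((n, n), fill)
    np.fill_diagonal(d, 0.0)
    for (a, b), v in entries.items():
        d[idx[a], idx[b]] = d[idx[b], idx[a]] = v
    return DistanceMatrix(list(ids), d, np.full((n, n), n_sites))


def clustered_matrix(rng, sizes, intra=(0.0, 0.012), inter=(0.08, 0.2)):
    """Random matrix with a clean barcode gap; returns (matrix, true labels)."""
    ids, labels = [], []
    for k, s in enumerate(sizes):
        for i in range(s):
            ids.append(f"c{k}_{i}")
            labels.append(k)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lo, hi = intra if labels[i] == labels[j] else inter
            d[i, j] = d[j, i] = rng.uniform(lo, hi)
    return DistanceMatrix(ids, d, np.full((n, n), 600)), labels


def same_partition(groups_a, groups_b):
    """True when two id->label mappings induce the same set partition."""
    def blocks(groups):
        out = {}
        for sid, g in groups.items():
            out.setdefault(g, set()).add(sid)
        return set(map(frozenset, out.values()))
    return blocks(groups_a) == blocks(groups_b)


def additive_matrix_from_random_tree(rng, n_tips):
    """Random additive distance matrix: agglomerate random joins, summing
    branch lengths into pairwise tip distances."""
    tips = [f"t{i}" for i in range(n_tips)]
    clusters = [[t] for t in tips]
    depth = {t: 0.0 for t in tips}  # distance from tip up to its cluster root
    idx = {t: i for i, t in enumerate(tips)}
    d = np.zeros((n_tips, n_tips))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        a, b = clusters[i], clusters[j]
        la, lb = rng.uniform(0.005, 0.05, size=2)  # keeps tip paths within [0,1]
        for ta in a:
            for tb in b:
                d[idx[ta], idx[tb]] = d[idx[tb], idx[ta]] = (
                    depth[ta] + la + depth[tb] + lb)
        for ta in a:
            depth[ta] += la
        for tb in b:
            depth[tb] += lb
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [a + b]
    return DistanceMatrix(tips, d, np.full((n_tips, n_tips), 600))


def patristic_matrix(tree, ids):
    """Tip-to-tip path lengths of a dendropy tree, ordered like ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        out[i, j] = out[j, i] = pdm.distance(taxa[ids[i]], taxa[ids[j]])
    return out


def survey(sid, locality="L1", event="E1", season="S1", genus="Xeno",
           morpho=None, site="study", flags=None):
    return SpecimenRecord(
        specimen_id=sid, role="survey", site=site, locality=locality,
        sampling_event=event, season=season, field_genus=genus,
        field_morphospecies=morpho or f"{genus} sp1",
        morphology_flags=flags or {})


def reference(sid, name, locality="R1", site="external"):
    return SpecimenRecord(
        specimen_id=sid, role="reference", site=site, locality=locality,
        sampling_event="ref", reference_name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
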