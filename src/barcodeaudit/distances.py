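"""Uncorrected pairwise distances (p-distances) with pairwise deletion.

All delimitation methods in this package operate on the same currency:
the fraction of mismatching sites among alignment columns where *both*
sequences carry an unambiguous base (A, C, G or T). Columns containing a
gap or an N in either member of a pair are excluded for that pair only
(pairwise deletion), so the number of compared sites varies per pair.
No substitution-model correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DistanceMatrix", "p_distance", "distance_matrix"]

_VALID_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default minimum number of comparable sites for a pair to be trusted
DEFAULT_MIN_OVERLAP = 100


class InsufficientOverlapError(ValueError):
    """A pair (or pairs) of sequences share fewer comparable sites than allowed."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        msg = ", ".join(f"({a}, {b}): {n} sites" for a, b, n in self.pairs)
        super().__init__(f"pairs below minimum overlap: {msg}")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of uncorrected p-distances plus per-pair site counts.

    Attributes
    ----------
    ids:
        Specimen identifiers, in input order; row/column order of ``d``.
    d:
        Fractional distances in [0, 1]; zero diagonal.
    n_sites:
        Number of pairwise-comparable sites behind each entry of ``d``.
    """

    ids: list[str]
    d: np.ndarray
    n_sites: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self):
        self.ids = list(self.ids)
        self.d = np.asarray(self.d, dtype=float)
        self.n_sites = np.asarray(self.n_sites)
        n = len(self.ids)
        if self.d.shape != (n, n) or self.n_sites.shape != (n, n):
            raise ValueError("matrix shape does not match number of ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix must be symmetric")
        if (self.d < 0).any() or (self.d > 1).any():
            raise ValueError("distances must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = np.array([self._index[s] for s in ids])
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)],
                              self.n_sites[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances as a flat vector (scipy condensed order)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.d[iu]

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("\t".join(["id"] + self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                row = "\t".join(f"{x:.8f}" for x in self.d[i])
                fh.write(f"{sid}\t{row}\n")


def p_distance(a: str, b: str, min_overlap: int = 1) -> tuple[float, int]:
    """Uncorrected distance between two aligned sequences under pairwise deletion.

    Only columns where both characters are in {A, C, G, T} are compared;
    the distance is the fraction of those columns that mismatch.

    Returns
    -------
    (distance, compared_sites)

    Raises
    ------
    ValueError
        If the sequences differ in length.
    InsufficientOverlapError
        If fewer than ``min_overlap`` columns are comparable.
    """
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    xa, xb = _encode(a), _encode(b)
    ok = np.isin(xa, _VALID_BYTES) & np.isin(xb, _VALID_BYTES)
    n = int(ok.sum())
    if n < min_overlap:
        raise InsufficientOverlapError([("a", "b", n)])
    mism = int(((xa != xb) & ok).sum())
    return mism / n, n


def distance_matrix(alignment, min_overlap: int = DEFAULT_MIN_OVERLAP) -> DistanceMatrix:
    """All-pairs p-distance matrix for a locus alignment.

    Parameters
    ----------
    alignment:
        A :class:`~barcodeaudit.io.LocusAlignment` (anything with an ordered
        ``sequences`` mapping of id -> aligned string works).
    min_overlap:
        Pairs sharing fewer comparable sites raise
        :class:`InsufficientOverlapError` listing every offending pair, so
        the caller can drop fragmentary specimens and retry.
    """
    ids = list(alignment.sequences)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    mat = np.vstack([_encode(alignment.sequences[s]) for s in ids])
    valid = np.isin(mat, _VALID_BYTES)
    n = len(ids)
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    bad = []
    for i in range(n):
        ok = valid[i] & valid[i + 1:]
        counts = ok.sum(axis=1)
        mism = ((mat[i] != mat[i + 1:]) & ok).sum(axis=1)
        for k, j in enumerate(range(i + 1, n)):
            sites[i, j] = sites[j, i] = counts[k]
            if counts[k] < min_overlap:
                bad.append((ids[i], ids[j], int(counts[k])))
            elif counts[k]:
                d[i, j] = d[j, i] = mism[k] / counts[k]
    # diagonal: every valid site of the sequence compares with itself
    np.fill_diagonal(sites, valid.sum(axis=1))
    if bad:
        raise InsufficientOverlapError(bad)
    return DistanceMatrix(ids, d, sites)
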