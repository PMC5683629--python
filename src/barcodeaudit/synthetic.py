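"""Synthetic two-locus communities with known species truth.

The generator emulates the structure of a barcode-audited amphibian
inventory: K true species, each with a COI and a 16S centroid sequence,
specimens scattered over localities and sampling events, a fraction of
identified reference material, and a field-labeling error process that
produces the three error modes seen in real inventories — splitting one
polymorphic species into several morphospecies, lumping two species under
one label, and assigning the wrong genus.

Sequences evolve from their species centroid by uniform per-site
substitution to a random different base (Jukes-Cantor-like), at rate
``mu_intra / 2`` per specimen copy, so two conspecific specimens differ at
an expected fraction ~``mu_intra`` of sites. Centroids are drawn by
rejection sampling until every inter-centroid p-distance reaches
``d_min_inter``, guaranteeing a clean barcode gap when
``mu_intra << d_min_inter``. Both loci share the species structure — no
gene-tree discordance is simulated.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .distances import p_distance
from .io import LocusAlignment, SpecimenRecord

__all__ = ["SyntheticConfig", "SyntheticTruth", "generate_community",
           "apply_field_errors"]

_BASES = np.array(list("ACGT"))

# invented genus/epithet stems for plausible-looking binomials
_GENERA = ["Xeniractis", "Calopyge", "Thaumatops", "Rheobates2", "Nyctimystax",
           "Pareiolalax", "Omphalura", "Brachyselis"]
_EPITHETS = ["viridans", "maculosa", "riparia", "collaris", "punctulata",
             "silvestris", "gracilenta", "obscura", "fluviatica", "montium",
             "aurita", "pallidula", "nebulosa", "torrentis", "umbrosa"]


@dataclass
class SyntheticConfig:
    """Generating parameters of a synthetic community.

    ``mu_intra`` is the expected conspecific p-distance and ``d_min_inter``
    the minimum distance between species centroids; a clean barcode gap needs
    ``mu_intra`` well below ``d_min_inter``. Error rates parameterise the
    field-labeling process (probabilities per species / species pair).
    """

    K: int = 8
    specimens_per_species: tuple[int, int] = (3, 8)  # inclusive range
    coi_length: int = 654
    s16_length: int = 550
    mu_intra: float = 0.01
    d_min_inter: float = 0.08
    n_localities: int = 4
    n_events: int = 8
    n_seasons: int = 2
    reference_fraction: float = 0.15
    p_split: float = 0.2
    p_lump: float = 0.05
    p_wrong_genus: float = 0.1
    seed: int = 0
    max_rejection_iter: int = 10_000

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("K >= 1 required")
        if not self.mu_intra < self.d_min_inter:
            raise ValueError("mu_intra must be below d_min_inter")
        for rate in (self.p_split, self.p_lump, self.p_wrong_genus,
                     self.reference_fraction):
            if not 0 <= rate <= 1:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated community."""

    species_of: dict[str, str]              # specimen_id -> true binomial
    species_names: list[str]                # in species index order
    centroids: dict[str, tuple[str, str]]   # binomial -> (COI, 16S)
    min_inter_coi: float
    mean_intra_coi: float
    label_map: dict[str, str] = field(default_factory=dict)  # truth -> field label(s) note

    @property
    def k(self) -> int:
        return len(self.species_names)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hits = rng.random(len(arr)) < rate
    if hits.any():
        # substitute to a uniformly chosen *different* base
        for i in np.flatnonzero(hits):
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _centroids(rng: np.random.Generator, cfg: SyntheticConfig) -> list[tuple[str, str]]:
    """Rejection-sample K centroid pairs with all pairwise distances >= d_min_inter."""
    out: list[tuple[str, str]] = []
    tries = 0
    while len(out) < cfg.K:
        tries += 1
        if tries > cfg.max_rejection_iter:
            raise RuntimeError(
                "centroid rejection sampling exceeded iteration cap; "
                "reduce K or d_min_inter")
        coi = _random_seq(rng, cfg.coi_length)
        s16 = _random_seq(rng, cfg.s16_length)
        ok = all(p_distance(coi, prev_coi)[0] >= cfg.d_min_inter and
                 p_distance(s16, prev_s16)[0] >= cfg.d_min_inter
                 for prev_coi, prev_s16 in out)
        if ok:
            out.append((coi, s16))
    return out


def _species_names(rng: np.random.Generator, k: int) -> list[str]:
    n_gen = max(1, -(-k // 4))  # ~4 species per genus
    genera = [_GENERA[i % len(_GENERA)] + ("" if i < len(_GENERA) else str(i))
              for i in range(n_gen)]
    names = []
    for i in range(k):
        genus = genera[i % n_gen]
        epithet = _EPITHETS[i % len(_EPITHETS)]
        if i >= len(_EPITHETS):
            epithet += str(i // len(_EPITHETS))
        names.append(f"{genus} {epithet}")
    return names


def generate_community(cfg: SyntheticConfig):
    """Generate (records, {"COI": aln, "16S": aln}, truth), reproducibly from seed.

    Reference specimens carry their true binomial and sit at a designated
    external locality; survey specimens get field labels only after
    :func:`apply_field_errors`.
    """
    rng = np.random.default_rng(cfg.seed)
    centroid_pairs = _centroids(rng, cfg)
    names = _species_names(rng, cfg.K)
    centroids = {nm: pair for nm, pair in zip(names, centroid_pairs)}

    records: list[SpecimenRecord] = []
    coi_seqs: dict[str, str] = {}
    s16_seqs: dict[str, str] = {}
    species_of: dict[str, str] = {}
    counter = itertools.count(1)
    intra_pairs: list[float] = []

    for sp_idx, nm in enumerate(names):
        lo, hi = cfg.specimens_per_species
        n_spec = int(rng.integers(lo, hi + 1))
        coi_c, s16_c = centroids[nm]
        sp_ids = []
        for _ in range(n_spec):
            sid = f"SYN{next(counter):04d}"
            sp_ids.append(sid)
            coi_seqs[sid] = _mutate(rng, coi_c, cfg.mu_intra / 2)
            s16_seqs[sid] = _mutate(rng, s16_c, cfg.mu_intra / 2)
            species_of[sid] = nm
            is_ref = rng.random() < cfg.reference_fraction
            loc = f"LOC{rng.integers(0, cfg.n_localities) + 1}"
            event = int(rng.integers(0, cfg.n_events))
            season = f"S{event * cfg.n_seasons // cfg.n_events + 1}"
            if is_ref:
                records.append(SpecimenRecord(
                    specimen_id=sid, role="reference", site="external",
                    locality=f"REF{rng.integers(0, cfg.n_localities) + 1}",
                    sampling_event="ref", season=None,
                    reference_name=nm))
            else:
                records.append(SpecimenRecord(
                    specimen_id=sid, role="survey", site="study",
                    locality=loc, sampling_event=f"EV{event + 1:02d}",
                    season=season, field_genus=nm.split()[0],
                    field_morphospecies=nm))
        for a, b in itertools.combinations(sp_ids[:4], 2):  # summary sample
            intra_pairs.append(p_distance(coi_seqs[a], coi_seqs[b])[0])

    min_inter = min(
        p_distance(centroids[a][0], centroids[b][0])[0]
        for a, b in itertools.combinations(names, 2)) if cfg.K > 1 else 1.0

    truth = SyntheticTruth(
        species_of=species_of, species_names=names, centroids=centroids,
        min_inter_coi=min_inter,
        mean_intra_coi=float(np.mean(intra_pairs)) if intra_pairs else 0.0)
    alignments = {
        "COI": LocusAlignment("COI", coi_seqs),
        "16S": LocusAlignment("16S", s16_seqs),
    }
    return records, alignments, truth


def apply_field_errors(truth: SyntheticTruth, records: list[SpecimenRecord],
                       cfg: SyntheticConfig) -> list[SpecimenRecord]:
    """Overwrite survey field labels with an error-injected version.

    Per species: with probability ``p_split`` its survey members are
    randomly divided among 2-4 distinct morphospecies labels; with
    probability ``p_lump`` a species *pair* shares one label; with
    probability ``p_wrong_genus`` a label's genus token is replaced by a
    different genus. Deterministic given ``cfg.seed``. Returns the same
    record list, mutated in place.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # separate stream from sequences
    label_of_species = {nm: nm for nm in truth.species_names}

    # lumping: walk disjoint consecutive pairs
    order = list(truth.species_names)
    i = 0
    while i + 1 < len(order):
        if rng.random() < cfg.p_lump:
            a, b = order[i], order[i + 1]
            label_of_species[b] = label_of_species[a]
            truth.label_map[b] = f"lumped-with:{a}"
            i += 2
        else:
            i += 1

    split_labels: dict[str, list[str]] = {}
    for nm in truth.species_names:
        if rng.random() < cfg.p_split:
            n_labels = int(rng.integers(2, 5))
            base = label_of_species[nm]
            split_labels[nm] = [base] + [f"{base.split()[0]} msp{j}"
                                         for j in range(1, n_labels)]
            truth.label_map[nm] = f"split:{n_labels}"

    genera = sorted({nm.split()[0] for nm in truth.species_names})

    def maybe_wrong_genus(label: str) -> str:
        if len(genera) > 1 and rng.random() < cfg.p_wrong_genus:
            g = label.split()[0]
            others = [x for x in genera if x != g]
            return others[rng.integers(0, len(others))] + " " + " ".join(label.split()[1:])
        return label

    final_label: dict[str, str] = {}
    for nm in truth.species_names:
        if nm not in split_labels:
            final_label[nm] = maybe_wrong_genus(label_of_species[nm])

    wrong_split: dict[str, list[str]] = {
        nm: [maybe_wrong_genus(lab) for lab in labs]
        for nm, labs in split_labels.items()}

    for rec in records:
        if rec.role != "survey":
            continue
        nm = truth.species_of[rec.specimen_id]
        if nm in wrong_split:
            labs = wrong_split[nm]
            lab = labs[rng.integers(0, len(labs))]
        else:
            lab = final_label[nm]
        rec.field_genus = lab.split()[0]
        rec.field_morphospecies = lab
    return records
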