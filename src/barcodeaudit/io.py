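"""Readers/writers for the pipeline's external formats.

The pipeline consumes pre-aligned per-locus FASTA files plus a tab-separated
specimen metadata table, and emits TSV/JSON report files and newick trees.
Sequences are normalised on read: upper-cased, RNA U mapped to T, and every
IUPAC ambiguity code other than N collapsed to N (the pairwise-deletion
distance rule treats all ambiguity identically, so finer codes carry no
information here). Gaps are kept as '-'.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

__all__ = [
    "SpecimenRecord",
    "LocusAlignment",
    "read_alignment",
    "read_specimen_table",
    "write_specimen_table",
    "validate_dataset",
    "write_newick",
    "read_newick",
    "write_reports",
]

REQUIRED_COLUMNS = ["specimen_id", "role", "site", "locality", "sampling_event"]
OPTIONAL_COLUMNS = [
    "catalog", "region", "season", "field_genus", "field_morphospecies",
    "reference_name", "morphology_flags",
]

_KEEP = set("ACGTN-")


@dataclass
class SpecimenRecord:
    """One voucher/tissue with its locality, sampling event and field labels.

    ``role`` is ``"survey"`` for inventory specimens (which must carry a field
    morphospecies label) or ``"reference"`` for identified comparative
    material (which must carry a ``reference_name`` binomial).
    ``morphology_flags`` maps candidate binomials to whether the specimen is
    consistent with that species' morphological description; it is an input
    judgement, never computed here.
    """

    specimen_id: str
    role: str
    site: str
    locality: str
    sampling_event: str
    catalog: str | None = None
    region: str | None = None
    season: str | None = None
    field_genus: str | None = None
    field_morphospecies: str | None = None
    reference_name: str | None = None
    morphology_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if self.role not in ("survey", "reference"):
            raise ValueError(f"{self.specimen_id}: role must be survey|reference, got {self.role!r}")
        if self.role == "reference" and not self.reference_name:
            raise ValueError(f"{self.specimen_id}: reference specimen lacks reference_name")
        if self.role == "survey" and not self.field_morphospecies:
            raise ValueError(f"{self.specimen_id}: survey specimen lacks field_morphospecies")

    @property
    def field_label(self) -> str | None:
        """The full field identification, 'Genus morphospecies' when both are set."""
        if not self.field_morphospecies:
            return None
        if self.field_genus and not self.field_morphospecies.startswith(self.field_genus + " "):
            return f"{self.field_genus} {self.field_morphospecies}"
        return self.field_morphospecies


@dataclass
class LocusAlignment:
    """An aligned locus: equal-length sequences over {A,C,G,T,N,-} keyed by specimen id."""

    locus: str
    sequences: dict[str, str]

    def __post_init__(self):
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.locus}: ragged alignment, lengths {sorted(lengths)}")
        bad = [i for i, s in self.sequences.items() if set(s) - _KEEP]
        if bad:
            raise ValueError(f"{self.locus}: non-normalised characters in {bad[0]}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)


def normalize_sequence(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    return re.sub(r"[^ACGT\-]", "N", s)


def read_alignment(path, locus: str) -> LocusAlignment:
    """Read one per-locus aligned FASTA.

    The specimen id is the first whitespace-delimited token of the header.
    Duplicate ids, ragged lengths and empty files are rejected with the
    offending record named.
    """
    path = Path(path)
    sequences: dict[str, str] = {}
    length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        sid = rec.id
        if sid in sequences:
            raise ValueError(f"{path}: duplicate sequence id {sid!r}")
        seq = normalize_sequence(str(rec.seq))
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise ValueError(
                f"{path}: record {sid!r} has length {len(seq)}, expected {length}")
        sequences[sid] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records found")
    return LocusAlignment(locus=locus, sequences=sequences)


def write_alignment(alignment: LocusAlignment, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for sid, seq in alignment.sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def _parse_flags(text: str) -> dict[str, bool]:
    if not text:
        return {}
    return {k: bool(v) for k, v in json.loads(text).items()}


def read_specimen_table(path) -> list[SpecimenRecord]:
    """Read the specimen metadata TSV (header row required, row order kept).

    Unknown columns are ignored with a logged warning; missing optional
    columns leave the corresponding fields unset.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    extras = [c for c in df.columns if c not in REQUIRED_COLUMNS + OPTIONAL_COLUMNS]
    if extras:
        log.warning("%s: ignoring unknown column(s) %s", path, extras)
    dup = df["specimen_id"][df["specimen_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate specimen_id {dup.iloc[0]!r}")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in REQUIRED_COLUMNS}
        for c in OPTIONAL_COLUMNS:
            if c in df.columns and row[c] != "":
                if c == "morphology_flags":
                    kwargs[c] = _parse_flags(row[c])
                else:
                    kwargs[c] = row[c]
        records.append(SpecimenRecord(**kwargs))
    return records


def write_specimen_table(records, path) -> None:
    rows = []
    for r in records:
        row = {c: getattr(r, c) or "" for c in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
        row["morphology_flags"] = (
            json.dumps(r.morphology_flags, sort_keys=True) if r.morphology_flags else "")
        rows.append(row)
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS + OPTIONAL_COLUMNS).to_csv(
        path, sep="\t", index=False, lineterminator="\n")


def validate_dataset(records, *alignments) -> None:
    """Cross-check: every sequence id must resolve to a known specimen."""
    known = {r.specimen_id for r in records}
    orphans = []
    for aln in alignments:
        orphans += [f"{aln.locus}:{sid}" for sid in aln.sequences if sid not in known]
    if orphans:
        raise ValueError(f"alignment ids missing from specimen table: {orphans}")


# -- trees -------------------------------------------------------------------

def write_newick(tree, path) -> None:
    """Write a dendropy tree as newick with branch lengths.

    Every leaf must be labelled; labels with spaces are quoted by dendropy
    so the file round-trips.
    """
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree has an unlabeled tip")
    # labels with spaces are quoted so a read with preserve_underscores
    # round-trips exactly
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               preserve_spaces=True)


def read_newick(path):
    import dendropy
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


# -- reports -----------------------------------------------------------------

def write_reports(partitions, assignment, audit, richness, out_dir) -> None:
    """Write the pipeline's result tables to ``out_dir``.

    Outputs (all deterministic given identical inputs):
      partitions.tsv   specimen_id, method, group — one row per specimen/method
      species.tsv      specimen_id, otu_id, name, status, rules_applied
      conflicts.tsv    cell_a, cell_b, rule, note
      provenance.json  list of rule firings behind every merge decision
      audit.json       per-specimen verdicts + percent_correct
      genus_table.tsv  field vs barcode species counts per genus and season
      richness.tsv     method, season, h, tau, var, lo84, hi84
      estimates.tsv    method, season, chao2, var, lo84, hi84
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with open(out / "partitions.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("specimen_id\tmethod\tgroup\n")
        for part in partitions:
            for sid in sorted(part.groups):
                fh.write(f"{sid}\t{part.method}\t{part.groups[sid]}\n")

    with open(out / "species.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("specimen_id\totu_id\tname\tstatus\trules_applied\n")
        if assignment is not None:
            rules_by_otu = {}
            for prov in assignment.provenance:
                for otu in prov.get("otus", []):
                    rules_by_otu.setdefault(otu, set()).add(prov["rule"])
            for sid in sorted(assignment.otu_of):
                otu = assignment.otu_of[sid]
                entry = assignment.names.get(otu, {"name": "", "status": ""})
                rules = ",".join(sorted(rules_by_otu.get(otu, ())))
                fh.write(f"{sid}\t{otu}\t{entry['name']}\t{entry['status']}\t{rules}\n")

    with open(out / "conflicts.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("cell_a\tcell_b\trule\tnote\n")
        if assignment is not None:
            for c in assignment.conflicts:
                fh.write(f"{c['cells'][0]}\t{c['cells'][1]}\t{c['rule']}\t{c['note']}\n")

    with open(out / "provenance.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(assignment.provenance if assignment is not None else [],
                  fh, indent=2, sort_keys=True)
        fh.write("\n")

    with open(out / "audit.json", "w", encoding="utf-8", newline="\n") as fh:
        if audit is None:
            json.dump({}, fh)
        else:
            json.dump({"percent_correct": audit.percent_correct,
                       "verdicts": dict(sorted(audit.verdicts.items()))},
                      fh, indent=2, sort_keys=True)
        fh.write("\n")
        if audit is not None and audit.genus_table is not None:
            audit.genus_table.to_csv(out / "genus_table.tsv", sep="\t",
                                     lineterminator="\n")

    curves, estimates = [], []
    for key, res in (richness or {}).items():
        method, season = key
        for pt in res["curve"].points:
            curves.append((method, season, pt.h, pt.tau, pt.var, pt.lo84, pt.hi84))
        est = res["chao2"]
        estimates.append((method, season, est.point, est.var, est.lo84, est.hi84))
    with open(out / "richness.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("method\tseason\th\ttau\tvar\tlo84\thi84\n")
        for row in sorted(curves):
            fh.write("\t".join(str(x) for x in row) + "\n")
    with open(out / "estimates.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("method\tseason\tchao2\tvar\tlo84\thi84\n")
        for row in sorted(estimates):
            fh.write("\t".join(str(x) for x in row) + "\n")
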