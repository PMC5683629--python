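"""Field-vs-barcode identification concordance.

A survey specimen counts as *correctly identified* when (a) its field name
equals the name assigned to its OTU, or (b) its field morphospecies label and
its OTU correspond one-to-one within the audited scope — i.e. the label was
applied only to members of that OTU and the OTU carries no other label. When
one OTU's members were field-labeled as several different species, every
member of that OTU is misidentified: the field partition failed on that
cluster, whichever label any individual happened to get.

The per-genus summary table mirrors the standard inventory layout: for each
genus, the number of distinct field morphospecies versus the number of
barcode OTUs (tallied under their *corrected* genus), per season and
combined, with a totals row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .io import SpecimenRecord
from .reconcile import SpeciesAssignment

log = logging.getLogger(__name__)

__all__ = ["ConcordanceReport", "audit", "genus_summary"]


@dataclass
class ConcordanceReport:
    verdicts: dict[str, str] = field(default_factory=dict)
    percent_correct: float = 0.0
    n_scored: int = 0
    genus_table: pd.DataFrame | None = None

    def counts(self) -> dict[str, int]:
        out = {"correct": 0, "misidentified": 0, "unscored": 0}
        for v in self.verdicts.values():
            out[v] += 1
        return out


def _in_scope(rec: SpecimenRecord, scope) -> bool:
    if rec.role != "survey":
        return False
    if scope is None:
        return True
    if callable(scope):
        return scope(rec)
    return rec.site == scope


def audit(records: list[SpecimenRecord], assignment: SpeciesAssignment,
          scope=None) -> ConcordanceReport:
    """Score every in-scope survey specimen as correct/misidentified/unscored.

    ``scope`` is a site name (e.g. the study area) or a predicate over
    records; ``None`` audits all survey specimens. Specimens lacking a field
    label or an OTU are unscored and logged.
    """
    in_scope = [r for r in records if _in_scope(r, scope)]
    label_of = {}
    for r in in_scope:
        label_of[r.specimen_id] = r.field_label

    # labels seen within each OTU, and OTUs using each label (scope only)
    labels_in_otu: dict[int, set[str]] = {}
    otus_of_label: dict[str, set[int]] = {}
    for r in in_scope:
        otu = assignment.otu_of.get(r.specimen_id)
        lab = label_of[r.specimen_id]
        if otu is None or lab is None:
            continue
        labels_in_otu.setdefault(otu, set()).add(lab)
        otus_of_label.setdefault(lab, set()).add(otu)

    verdicts: dict[str, str] = {}
    for r in in_scope:
        sid = r.specimen_id
        otu = assignment.otu_of.get(sid)
        lab = label_of[sid]
        if otu is None or lab is None:
            verdicts[sid] = "unscored"
            log.warning("specimen %s unscored (missing %s)", sid,
                        "field label" if lab is None else "OTU")
            continue
        if len(labels_in_otu[otu]) > 1:
            verdicts[sid] = "misidentified"
            continue
        otu_name = assignment.names.get(otu, {}).get("name")
        name_match = otu_name is not None and lab == otu_name
        bijective = len(otus_of_label[lab]) == 1  # with len(labels_in_otu)==1
        verdicts[sid] = "correct" if (name_match or bijective) else "misidentified"

    scored = [v for v in verdicts.values() if v != "unscored"]
    pct = (100.0 * sum(v == "correct" for v in scored) / len(scored)
           if scored else 0.0)
    return ConcordanceReport(verdicts=verdicts, percent_correct=pct,
                             n_scored=len(scored))


def genus_summary(records: list[SpecimenRecord], assignment: SpeciesAssignment,
                  seasons: list[str] | None = None,
                  scope=None) -> pd.DataFrame:
    """Per-genus field vs barcode species counts by season and combined.

    Field counts tally distinct field morphospecies labels under the genus
    the field team assigned; barcode counts tally distinct OTUs under the
    genus of their final name (which may correct the field genus). A Totals
    row sums each column.
    """
    in_scope = [r for r in records if _in_scope(r, scope)]
    if seasons is None:
        seasons = sorted({r.season for r in in_scope if r.season})
    season_keys = list(seasons) + ["combined"]

    field_sets: dict[tuple[str, str], set[str]] = {}
    otu_sets: dict[tuple[str, str], set[int]] = {}
    genera: set[str] = set()

    for r in in_scope:
        for sk in ([r.season] if r.season in seasons else []) + ["combined"]:
            if r.field_genus and r.field_label:
                field_sets.setdefault((r.field_genus, sk), set()).add(r.field_label)
                genera.add(r.field_genus)
            otu = assignment.otu_of.get(r.specimen_id)
            if otu is not None:
                name = assignment.names.get(otu, {}).get("name")
                if name:
                    g = name.split()[0]
                    otu_sets.setdefault((g, sk), set()).add(otu)
                    genera.add(g)

    cols = pd.MultiIndex.from_product([season_keys, ["field", "barcode"]],
                                      names=["season", "method"])
    table = pd.DataFrame(0, index=sorted(genera), columns=cols, dtype=int)
    for (g, sk), labs in field_sets.items():
        table.loc[g, (sk, "field")] = len(labs)
    for (g, sk), otus in otu_sets.items():
        table.loc[g, (sk, "barcode")] = len(otus)
    table.loc["Totals"] = table.sum(axis=0)
    table.index.name = "genus"
    return table


def overestimation_percent(genus_table: pd.DataFrame,
                           season: str = "combined") -> float:
    """How much the field inventory overstates richness, in percent:
    (field_total - barcode_total) / barcode_total * 100."""
    f = int(genus_table.loc["Totals", (season, "field")])
    b = int(genus_table.loc["Totals", (season, "barcode")])
    if b == 0:
        raise ValueError("no barcode species in scope")
    return round((f - b) / b * 100.0, 1)
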