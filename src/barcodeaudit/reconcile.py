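"""Reconciling COI partitions with 16S clusters and localities into species.

The two COI partitions (threshold/BIN-proxy and barcode-gap discovery) are
first intersected into *cells* — the finest units either method supports.
Pairs of cells are then evaluated with decision rules that mirror how
integrative barcoding studies resolve disagreements between loci:

R2  same 16S cluster, no shared locality  -> same species
    (genetic variation attributed to geography)
R3  same 16S cluster, shared locality     -> same species
    (population-level variation within a site)
R4  different 16S clusters, shared locality -> separate species (merge
    forbidden; sympatric lineages with divergent 16S are kept apart)
R5  different 16S clusters, disjoint localities -> same species only when a
    shared morphological candidate name is flagged true for both cells,
    otherwise kept separate

Final OTUs are the connected components of the merge graph over cells. A
component that also contains an R4-forbidden pair is split back apart by
removing merge edges incident to the forbidden pair (R3 edges dropped before
R2) and the pair is logged as a conflict rather than silently resolved.

Naming follows the field convention: OTUs anchored by reference material take
the reference binomial; OTUs whose members share a 16S cluster with a named
reference adopt that name; OTUs close to (within ``d_cf`` 16S distance) but
not inside a named cluster get "Genus cf. epithet"; everything else becomes
"Genus sp. A", "Genus sp. B", ... under its modal field genus.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .delimit import Partition
from .distances import DistanceMatrix
from .io import SpecimenRecord

__all__ = ["RuleConfig", "SpeciesAssignment", "refine_cells", "reconcile",
           "assign_names"]


@dataclass
class RuleConfig:
    """Toggles for the merge rules; everything on by default."""

    use_r2: bool = True
    use_r3: bool = True
    use_r4: bool = True
    use_r5: bool = True
    # R5 merges require a shared morphology flag set true for both cells
    require_morphology_for_r5: bool = True


@dataclass
class SpeciesAssignment:
    """Final OTU membership with names, rule provenance and flagged conflicts."""

    otu_of: dict[str, int] = field(default_factory=dict)
    names: dict[int, dict] = field(default_factory=dict)
    provenance: list[dict] = field(default_factory=list)
    conflicts: list[dict] = field(default_factory=list)
    unassigned: list[str] = field(default_factory=list)
    cell_of: dict[str, int] = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(set(self.otu_of.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid, o in self.otu_of.items():
            out.setdefault(o, []).append(sid)
        return out

    def name_of(self, specimen_id: str) -> str | None:
        otu = self.otu_of.get(specimen_id)
        if otu is None:
            return None
        return self.names.get(otu, {}).get("name")


def refine_cells(bin_part: Partition, abgd_part: Partition,
                 s16_part: Partition) -> tuple[Partition, list[str]]:
    """Intersect the two COI partitions into cells; attach COI-less specimens.

    A specimen present in both COI partitions lands in the cell identified by
    its (BIN-proxy group, gap-discovery group) pair. A specimen with 16S only
    joins the unique cell whose members share its 16S cluster; if its 16S
    cluster spans several cells (or none), it is returned as unassigned.

    Returns (cells, unassigned_ids).
    """
    coi_ids = [s for s in bin_part.groups if s in abgd_part.groups]
    raw = {s: (bin_part.groups[s], abgd_part.groups[s]) for s in coi_ids}
    cells = Partition.from_labels("cells", coi_ids, [raw[s] for s in coi_ids])

    no_coi = [s for s in s16_part.groups if s not in cells.groups]
    unassigned = []
    groups = dict(cells.groups)
    for sid in no_coi:
        cluster = s16_part.groups[sid]
        mates = {groups[x] for x in cells.groups
                 if x in s16_part.groups and s16_part.groups[x] == cluster}
        if len(mates) == 1:
            groups[sid] = mates.pop()
        else:
            unassigned.append(sid)
    ids = list(groups)
    cells = Partition.from_labels("cells", ids, [groups[s] for s in ids])
    return cells, unassigned


def _cell_info(cells: Partition, s16_part: Partition, records_by_id):
    info = {}
    for cell, members in cells.members().items():
        s16 = {s16_part.groups[s] for s in members if s in s16_part.groups}
        locs = {records_by_id[s].locality for s in members if s in records_by_id}
        morph = {}
        for s in members:
            rec = records_by_id.get(s)
            if rec:
                for name, ok in rec.morphology_flags.items():
                    morph[name] = morph.get(name, False) or ok
        info[cell] = {"s16": s16, "locs": locs,
                      "morph": {k for k, v in morph.items() if v}}
    return info


def reconcile(cells: Partition, s16_part: Partition,
              records: list[SpecimenRecord],
              cfg: RuleConfig | None = None) -> SpeciesAssignment:
    """Apply the merge/split rules over refined cells and build OTUs."""
    cfg = cfg or RuleConfig()
    by_id = {r.specimen_id: r for r in records}
    info = _cell_info(cells, s16_part, by_id)
    cell_ids = sorted(info)

    merge_edges: dict[tuple[int, int], str] = {}
    forbidden: list[tuple[int, int]] = []
    provenance: list[dict] = []

    for a, b in itertools.combinations(cell_ids, 2):
        same16 = bool(info[a]["s16"] & info[b]["s16"])
        shared_loc = bool(info[a]["locs"] & info[b]["locs"])
        rule = action = None
        if same16 and not shared_loc and cfg.use_r2:
            rule, action = "R2", "merge"
        elif same16 and shared_loc and cfg.use_r3:
            rule, action = "R3", "merge"
        elif not same16 and shared_loc and cfg.use_r4:
            rule, action = "R4", "forbid"
        elif not same16 and not shared_loc and cfg.use_r5:
            shared_morph = info[a]["morph"] & info[b]["morph"]
            if shared_morph and cfg.require_morphology_for_r5:
                rule, action = "R5", "merge"
            elif not cfg.require_morphology_for_r5:
                rule, action = "R5", "merge"
            else:
                rule, action = "R5", "separate"
        if rule is None:
            continue
        provenance.append({"cells": [a, b], "rule": rule, "action": action})
        if action == "merge":
            merge_edges[(a, b)] = rule
        elif action == "forbid":
            forbidden.append((a, b))

    conflicts: list[dict] = []
    components = _components(cell_ids, merge_edges)
    for a, b in forbidden:
        if components[a] != components[b]:
            continue
        # forbidden pair connected through merges: drop edges incident to the
        # pair, R3 before R2, until separated
        conflicts.append({"cells": [a, b], "rule": "R4",
                          "note": "merge chain connected a forbidden pair; "
                                  "incident merge edges removed"})
        for pref in ("R3", "R2", "R5"):
            changed = True
            while changed and components[a] == components[b]:
                changed = False
                for edge in list(merge_edges):
                    if merge_edges[edge] != pref:
                        continue
                    if a in edge or b in edge:
                        del merge_edges[edge]
                        changed = True
                components = _components(cell_ids, merge_edges)
            if components[a] != components[b]:
                break

    components = _components(cell_ids, merge_edges)
    # canonical OTU ids: order of first appearance over cells' member order
    otu_of: dict[str, int] = {}
    remap: dict[int, int] = {}
    for sid, cell in cells.groups.items():
        comp = components[cell]
        if comp not in remap:
            remap[comp] = len(remap) + 1
        otu_of[sid] = remap[comp]

    # annotate provenance with final OTU ids for merges that survived
    for prov in provenance:
        a, b = prov["cells"]
        if prov["action"] == "merge" and (a, b) not in merge_edges:
            prov["action"] = "merge-dropped"
        prov["otus"] = sorted({remap[components[a]], remap[components[b]]})

    return SpeciesAssignment(otu_of=otu_of, provenance=provenance,
                             conflicts=conflicts,
                             cell_of=dict(cells.groups))


def _components(nodes, edges) -> dict[int, int]:
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b) in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    return {n: find(n) for n in nodes}


def _modal(values: list[str]) -> tuple[str, bool]:
    """Most common value; ties broken alphabetically. Returns (value, tied)."""
    counts: dict[str, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values())
    winners = sorted(k for k, v in counts.items() if v == best)
    return winners[0], len(winners) > 1


def _genus(name: str) -> str:
    return name.split()[0]


def assign_names(assignment: SpeciesAssignment, records: list[SpecimenRecord],
                 s16_part: Partition, D16: DistanceMatrix,
                 d_cf: float = 0.05) -> SpeciesAssignment:
    """Name every OTU: reference binomial, adopted name, cf., or sp. letter.

    Order of precedence per OTU:
      (a) contains reference specimens -> majority reference name (ties ->
          alphabetical with status ``cf``);
      (b) a member shares a 16S cluster with a named reference -> that name,
          status ``named``;
      (c) nearest named reference OTU within ``d_cf`` minimum 16S distance ->
          "Genus cf. epithet", status ``cf``;
      (d) otherwise "Genus sp. <letter>" under the modal field genus, letters
          assigned per genus by order of first member appearance.
    """
    by_id = {r.specimen_id: r for r in records}
    members = assignment.members()
    order = sorted(members, key=lambda o: min(
        list(assignment.otu_of).index(s) for s in members[o]))

    ref_name_of_16s: dict[int, set[str]] = {}
    for r in records:
        if r.role == "reference" and r.specimen_id in s16_part.groups:
            ref_name_of_16s.setdefault(
                s16_part.groups[r.specimen_id], set()).add(r.reference_name)

    names: dict[int, dict] = {}
    named_otus: dict[int, str] = {}

    for otu in order:
        mem = members[otu]
        refs = [by_id[s].reference_name for s in mem
                if s in by_id and by_id[s].role == "reference"]
        if refs:
            name, tied = _modal(refs)
            names[otu] = {"name": name, "status": "cf" if tied else "named",
                          "rule": "reference-member"}
            named_otus[otu] = name
            continue
        adopted = set()
        for s in mem:
            cluster = s16_part.groups.get(s)
            if cluster is not None:
                adopted |= ref_name_of_16s.get(cluster, set())
        if adopted:
            name, _ = _modal(sorted(adopted))
            names[otu] = {"name": name, "status": "named",
                          "rule": "shared-16s-cluster"}
            named_otus[otu] = name

    # (c) nearest named reference OTU by minimum 16S distance
    provisional = [o for o in order if o not in names]
    for otu in provisional:
        mem16 = [s for s in members[otu] if s in D16._index]
        best = None
        for other, oname in named_otus.items():
            other16 = [s for s in members[other] if s in D16._index]
            for a in mem16:
                for b in other16:
                    dd = D16.get(a, b)
                    if best is None or dd < best[0]:
                        best = (dd, oname)
        if best is not None and best[0] <= d_cf:
            genus, epithet = _genus(best[1]), best[1].split()[-1]
            names[otu] = {"name": f"{genus} cf. {epithet}", "status": "cf",
                          "rule": "near-named-16s"}

    # (d) provisional letters per genus
    letters: dict[str, int] = {}
    for otu in order:
        if otu in names:
            continue
        genera = [by_id[s].field_genus for s in members[otu]
                  if s in by_id and by_id[s].field_genus]
        genus, tied = _modal(genera) if genera else ("Incertae", False)
        if tied:
            assignment.conflicts.append(
                {"cells": [otu, otu], "rule": "naming",
                 "note": f"OTU {otu} spans multiple modal genera; "
                         f"named under {genus}"})
        k = letters.get(genus, 0)
        letters[genus] = k + 1
        letter = chr(ord("A") + k) if k < 26 else f"A{k}"
        names[otu] = {"name": f"{genus} sp. {letter}", "status": "provisional",
                      "rule": "provisional-letter"}

    assignment.names = names
    return assignment
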