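"""End-to-end inventory audit: sequences + metadata in, audited species out."""

from __future__ import annotations

from dataclasses import dataclass, field

from . import concordance, delimit, reconcile, richness
from .distances import DistanceMatrix, distance_matrix
from .io import LocusAlignment, SpecimenRecord, validate_dataset


@dataclass
class PipelineConfig:
    bin_threshold: float = 0.022
    abgd: delimit.ABGDConfig = field(default_factory=delimit.ABGDConfig)
    t16: float = 0.03
    d_cf: float = 0.05
    min_overlap: int = 100
    scope: str | None = None     # site filter for the audit/richness stages
    z: float = richness.Z_84


@dataclass
class InventoryResult:
    d_coi: DistanceMatrix
    d_16s: DistanceMatrix
    bin_part: delimit.Partition
    abgd_result: delimit.ABGDResult
    s16_part: delimit.Partition
    cells: delimit.Partition
    unassigned: list[str]
    assignment: reconcile.SpeciesAssignment
    report: concordance.ConcordanceReport
    genus_table: object
    richness: dict  # (method, season) -> {"incidence", "curve", "chao2"}

    @property
    def partitions(self) -> list[delimit.Partition]:
        return [self.bin_part, self.abgd_result.selected, self.s16_part,
                self.cells]


def run_inventory(records: list[SpecimenRecord],
                  coi: LocusAlignment, s16: LocusAlignment,
                  cfg: PipelineConfig | None = None) -> InventoryResult:
    """Run delimitation, reconciliation, naming, audit and richness.

    ``cfg.scope`` restricts the concordance audit and richness estimation to
    one site (the study area); delimitation and naming always use every
    specimen, reference material included.
    """
    cfg = cfg or PipelineConfig()
    validate_dataset(records, coi, s16)

    d_coi = distance_matrix(coi, min_overlap=cfg.min_overlap)
    d_16s = distance_matrix(s16, min_overlap=cfg.min_overlap)

    bin_part = delimit.threshold_partition(d_coi, cfg.bin_threshold)
    abgd_result = delimit.abgd_partition(d_coi, cfg.abgd)
    s16_part = delimit.conspecificity_clusters(d_16s, mode="threshold",
                                               t16=cfg.t16)

    cells, unassigned = reconcile.refine_cells(bin_part, abgd_result.selected,
                                               s16_part)
    assignment = reconcile.reconcile(cells, s16_part, records)
    assignment.unassigned = unassigned
    assignment = reconcile.assign_names(assignment, records, s16_part,
                                        d_16s, d_cf=cfg.d_cf)

    report = concordance.audit(records, assignment, scope=cfg.scope)
    genus_table = concordance.genus_summary(records, assignment,
                                            scope=cfg.scope)
    report.genus_table = genus_table

    seasons = sorted({r.season for r in records
                      if r.role == "survey" and r.season})
    rich: dict = {}
    for method, species_of in (
            ("barcode", lambda r: assignment.name_of(r.specimen_id)),
            ("field", lambda r: r.field_label)):
        for season in seasons + ["combined"]:
            def in_season(r, s=season):
                ok = cfg.scope is None or r.site == cfg.scope
                return ok and (s == "combined" or r.season == s)
            try:
                inc = richness.build_incidence(records, species_of,
                                               scope=in_season)
            except ValueError:
                continue
            entry = {"incidence": inc}
            if inc.m >= 2:
                entry["curve"] = richness.rarefaction(inc, z=cfg.z)
                entry["chao2"] = richness.chao2(inc, z=cfg.z)
            rich[(method, season)] = entry

    return InventoryResult(
        d_coi=d_coi, d_16s=d_16s, bin_part=bin_part,
        abgd_result=abgd_result, s16_part=s16_part, cells=cells,
        unassigned=unassigned, assignment=assignment, report=report,
        genus_table=genus_table, richness=rich)
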