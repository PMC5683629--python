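"""Reconciliation rules, cell refinement and OTU naming."""

import numpy as np
import pytest

from barcodeaudit.delimit import Partition
from barcodeaudit.reconcile import (RuleConfig, assign_names, reconcile,
                                    refine_cells)
from conftest import make_matrix, reference, survey


def part(method, mapping):
    ids = list(mapping)
    return Partition.from_labels(method, ids, [mapping[s] for s in ids])


class TestRefineCells:
    def test_identical_partitions_unchanged(self):
        p = {"a": 1, "b": 1, "c": 2}
        cells, un = refine_cells(part("bin", p), part("abgd", p), part("16s", p))
        assert cells.n_groups == 2 and not un

    def test_intersection_oracle(self):
        bins = {"a": 1, "b": 1, "c": 2}    # {a,b | c}
        abgd = {"a": 1, "b": 2, "c": 2}    # {a | b,c}
        cells, _ = refine_cells(part("bin", bins), part("abgd", abgd),
                                part("16s", {"a": 1, "b": 1, "c": 1}))
        assert cells.n_groups == 3          # {a | b | c}

    def test_no_coi_specimen_joins_unique_cell(self):
        bins = {"a": 1, "b": 2}
        abgd = {"a": 1, "b": 2}
        s16 = {"a": 1, "b": 2, "x": 2}     # x shares 16S cluster with b only
        cells, un = refine_cells(part("bin", bins), part("abgd", abgd),
                                 part("16s", s16))
        assert not un
        assert cells.groups["x"] == cells.groups["b"]

    def test_no_coi_ambiguous_cluster_unassigned(self):
        bins = {"a": 1, "b": 2}
        abgd = {"a": 1, "b": 2}
        s16 = {"a": 1, "b": 1, "x": 1}     # x's cluster spans both cells
        cells, un = refine_cells(part("bin", bins), part("abgd", abgd),
                                 part("16s", s16))
        assert un == ["x"]
        assert "x" not in cells.groups


class TestReconcileRules:
    def test_same_locality_same_16s_merges(self):
        """Two COI cells, one 16S cluster, one shared locality -> one species
        (the sympatric population-variation case)."""
        records = [survey(s, locality="LMR") for s in ("n1", "n2", "n3")]
        cells = part("cells", {"n1": 1, "n2": 1, "n3": 2})
        s16 = part("16s", {"n1": 1, "n2": 1, "n3": 1})
        asg = reconcile(cells, s16, records)
        assert asg.n_otus == 1
        assert any(p["rule"] == "R3" and p["action"] == "merge"
                   for p in asg.provenance)

    def test_allopatric_same_16s_merges_r2(self):
        records = [survey("g1", locality="GA"), survey("g2", locality="RC")]
        cells = part("cells", {"g1": 1, "g2": 2})
        s16 = part("16s", {"g1": 1, "g2": 1})
        asg = reconcile(cells, s16, records)
        assert asg.n_otus == 1
        assert asg.provenance[0]["rule"] == "R2"

    def test_different_16s_shared_locality_kept_apart(self):
        records = [survey("h1", locality="LMR"), survey("h2", locality="LMR")]
        cells = part("cells", {"h1": 1, "h2": 2})
        s16 = part("16s", {"h1": 1, "h2": 2})
        asg = reconcile(cells, s16, records)
        assert asg.n_otus == 2

    def test_allopatric_different_16s_needs_morphology(self):
        base = dict(locality="GA")
        r1 = survey("x1", **base, flags={"Xeno viridans": True})
        r2 = survey("x2", locality="RC", flags={"Xeno viridans": True})
        r3 = survey("x3", locality="RC")
        cells = part("cells", {"x1": 1, "x2": 2, "x3": 3})
        s16 = part("16s", {"x1": 1, "x2": 2, "x3": 3})
        asg = reconcile(cells, s16, [r1, r2, r3])
        # x1-x2 share a morphology candidate -> merged; x3 stays apart
        assert asg.otu_of["x1"] == asg.otu_of["x2"]
        assert asg.otu_of["x3"] != asg.otu_of["x1"]
        assert asg.n_otus == 2

    def test_forbidden_pair_splits_merge_chain(self):
        """X~Y (R3) and Y~Z (R2) but X,Z sympatric with different 16S: the
        chain must be cut and the conflict logged, never silently merged."""
        rx = survey("x", locality="LMR")
        ry1 = survey("y1", locality="LMR")
        ry2 = survey("y2", locality="FAR")
        rz = survey("z", locality="LMR")
        cells = part("cells", {"x": 1, "y1": 2, "y2": 2, "z": 3})
        s16 = part("16s", {"x": 1, "y1": 1, "y2": 2, "z": 2})
        asg = reconcile(cells, s16, [rx, ry1, ry2, rz])
        assert asg.otu_of["x"] != asg.otu_of["z"]
        assert asg.conflicts and asg.conflicts[0]["rule"] == "R4"

    def test_single_cell_no_rules(self):
        records = [survey("a"), survey("b")]
        cells = part("cells", {"a": 1, "b": 1})
        s16 = part("16s", {"a": 1, "b": 1})
        asg = reconcile(cells, s16, records)
        assert asg.n_otus == 1 and not asg.provenance

    def test_disabled_rules_yield_cells(self):
        records = [survey(s, locality=f"L{i}") for i, s in enumerate("abcd")]
        cells = part("cells", {"a": 1, "b": 2, "c": 3, "d": 4})
        s16 = part("16s", {s: 1 for s in "abcd"})
        off = RuleConfig(use_r2=False, use_r3=False, use_r5=False)
        asg = reconcile(cells, s16, records, off)
        assert asg.n_otus == cells.n_groups

    def test_merging_is_monotone(self):
        records = [survey(s, locality="L") for s in "abcde"]
        cells = part("cells", {"a": 1, "b": 2, "c": 3, "d": 4, "e": 5})
        s16 = part("16s", {s: 1 for s in "abcde"})
        asg = reconcile(cells, s16, records)
        assert asg.n_otus <= cells.n_groups

    def test_provenance_replay_reproduces_partition(self):
        records = [survey("a", locality="L1"), survey("b", locality="L2"),
                   survey("c", locality="L1"), survey("d", locality="L3")]
        cells = part("cells", {"a": 1, "b": 2, "c": 3, "d": 4})
        s16 = part("16s", {"a": 1, "b": 1, "c": 2, "d": 2})
        asg = reconcile(cells, s16, records)
        # replay surviving merges over cells
        parent = {c: c for c in set(cells.groups.values())}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for p in asg.provenance:
            if p["action"] == "merge":
                a, b = p["cells"]
                parent[find(a)] = find(b)
        replayed = {sid: find(cells.groups[sid]) for sid in cells.groups}
        from conftest import same_partition
        assert same_partition(replayed, asg.otu_of)


class TestAssignNames:
    def _setup(self):
        # OTU1: two references named Arthroleptis sylvaticus + a survey
        # OTU2: survey-only, same 16S cluster as a named reference
        # OTU3: survey-only, isolated
        records = [
            reference("r1", "Arthroleptis sylvaticus"),
            reference("r2", "Arthroleptis sylvaticus"),
            survey("s1", genus="Arthroleptis"),
            survey("s2", genus="Arthroleptis"),
            survey("s3", genus="Arthroleptis"),
        ]
        asg_otu = {"r1": 1, "r2": 1, "s1": 1, "s2": 2, "s3": 3}
        from barcodeaudit.reconcile import SpeciesAssignment
        asg = SpeciesAssignment(otu_of=asg_otu)
        s16 = part("16s", {"r1": 1, "r2": 1, "s1": 1, "s2": 1, "s3": 2})
        ids = ["r1", "r2", "s1", "s2", "s3"]
        D16 = make_matrix(ids, {("s3", "r1"): 0.2, ("s3", "r2"): 0.2,
                                ("s3", "s1"): 0.2, ("s3", "s2"): 0.2},
                          fill=0.01)
        return records, asg, s16, D16

    def test_reference_majority_and_adoption_and_letters(self):
        records, asg, s16, D16 = self._setup()
        asg = assign_names(asg, records, s16, D16)
        assert asg.names[1] == {"name": "Arthroleptis sylvaticus",
                                "status": "named", "rule": "reference-member"}
        # OTU2 shares 16S cluster 1 with the named references
        assert asg.names[2]["name"] == "Arthroleptis sylvaticus"
        assert asg.names[2]["status"] == "named"
        # OTU3 is 20% away from anything named -> provisional letter
        assert asg.names[3]["name"] == "Arthroleptis sp. A"
        assert asg.names[3]["status"] == "provisional"

    def test_cf_naming_within_dcf(self):
        records, asg, s16, D16 = self._setup()
        # move s3 to within 5% of the named material but different 16S cluster
        ids = D16.ids
        d = D16.d.copy()
        for other in ("r1", "r2", "s1", "s2"):
            i, j = ids.index("s3"), ids.index(other)
            d[i, j] = d[j, i] = 0.04
        from barcodeaudit.distances import DistanceMatrix
        D16b = DistanceMatrix(ids, d, D16.n_sites)
        asg = assign_names(asg, records, s16, D16b)
        assert asg.names[3]["name"] == "Arthroleptis cf. sylvaticus"
        assert asg.names[3]["status"] == "cf"

    def test_provisional_letters_unique_per_genus(self):
        records = [survey(f"s{i}", genus="Hyperolius") for i in range(4)]
        from barcodeaudit.reconcile import SpeciesAssignment
        asg = SpeciesAssignment(otu_of={"s0": 1, "s1": 2, "s2": 3, "s3": 4})
        s16 = part("16s", {f"s{i}": i + 1 for i in range(4)})
        D16 = make_matrix([f"s{i}" for i in range(4)], {}, fill=0.2)
        asg = assign_names(asg, records, s16, D16)
        names = [asg.names[o]["name"] for o in sorted(asg.names)]
        assert names == [f"Hyperolius sp. {ch}" for ch in "ABCD"]

    def test_reference_tie_flags_cf(self):
        records = [reference("r1", "Xeno alpha"), reference("r2", "Xeno beta")]
        from barcodeaudit.reconcile import SpeciesAssignment
        asg = SpeciesAssignment(otu_of={"r1": 1, "r2": 1})
        s16 = part("16s", {"r1": 1, "r2": 1})
        D16 = make_matrix(["r1", "r2"], {}, fill=0.01)
        asg = assign_names(asg, records, s16, D16)
        assert asg.names[1]["name"] == "Xeno alpha"  # alphabetical on tie
        assert asg.names[1]["status"] == "cf"
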