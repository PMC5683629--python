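# barcodeaudit

**DNA-barcode auditing of biodiversity inventories.**

Rapid field inventories identify specimens by morphology, often under time
pressure and without taxonomic specialists. When the same specimens are later
DNA-barcoded, the field species list rarely survives contact with the
molecular data: polymorphic species get split into several morphospecies,
cryptic species get lumped under one name, and some specimens land in the
wrong genus entirely. `barcodeaudit` implements the full audit workflow that
quantifies this disagreement for two-locus (COI + 16S) amphibian-style
surveys:

1. **OTU delimitation** from uncorrected COI p-distances, by two methods:
   single-linkage clustering at a fixed 2.2% threshold (a proxy for Barcode
   Index Numbers) and Automatic Barcode Gap Discovery (ABGD) — recursive
   partitioning at the gap between intra- and inter-specific distances,
   scanned over a geometric grid of priors P_k = Pmin·(Pmax/Pmin)^(k/(s−1))
   with the reported partition chosen by stability across consecutive priors.
2. **Reconciliation** of the two COI partitions (intersected into cells) with
   16S clusters and collecting localities, via explicit merge/split rules
   (same 16S + allopatry → geographic variation; same 16S + sympatry →
   population variation; different 16S + sympatry → separate species;
   different 16S + allopatry → merge only on shared morphology), then naming
   every OTU from reference material (`named`, `cf.`, or provisional
   `sp. A/B/…`), with full rule provenance.
3. **Concordance scoring** of field identifications against barcode OTUs: a
   specimen is *correct* iff its field name equals the OTU's assigned name or
   its morphospecies label maps one-to-one onto its OTU; an OTU whose members
   carry several field labels makes *all* of them misidentified. A per-genus
   field-vs-barcode table (by season and combined) summarises the inventory.
4. **Richness comparison**: sample-based rarefaction
   τ(h) = Σ_j [1 − C(m−Y_j, h)/C(m, h)] with unconditional variance, and the
   Chao2 estimator S_obs + ((m−1)/m)·Q1²/(2Q2) with log-normal confidence
   intervals, both at the 84% level so that non-overlap of two intervals
   approximates a P = 0.05 test.
5. A **synthetic-community generator** with known species truth (two
   correlated loci, localities, sampling events, reference specimens, and a
   configurable split/lump/wrong-genus field-error process), so every stage
   is testable end to end.

The package also ships, as TSV fixtures, the printed result tables of a
published barcode audit of an amphibian inventory (Gabon / Republic of
Congo): per-site sequencing effort, the species × BIN/ABGD partition table,
and the per-genus field-vs-barcode counts.

## Worked example

```python
import barcodeaudit as ba
from barcodeaudit.synthetic import SyntheticConfig, generate_community, apply_field_errors

cfg = SyntheticConfig(K=8, specimens_per_species=(4, 8), seed=7,
                      p_split=0.4, p_lump=0.1, p_wrong_genus=0.1)
records, alignments, truth = generate_community(cfg)
apply_field_errors(truth, records, cfg)

result = ba.run_inventory(records, alignments["COI"], alignments["16S"],
                          ba.PipelineConfig(scope="study"))
print(truth.k, result.assignment.n_otus, round(result.report.percent_correct, 1))
```

prints

```
8 8 36.2
```

— the pipeline recovers all 8 true species as OTUs, while only 36.2% of
survey specimens had been labeled correctly in the field under these error
rates. `result.genus_table` holds the per-genus field/barcode species counts
(here 10 field morphospecies vs 8 barcode species, a 25% overestimate) and
`result.richness` the rarefaction curves and Chao2 estimates per
identification method and season. The scripts in `examples/` walk through
each capability (delimitation, reconciliation and naming, the concordance
audit, richness comparison, and the packaged published tables); each prints
the numbers it computes and what they mean.

## Layout

```
src/barcodeaudit/
  io.py           FASTA / specimen-TSV / newick / report IO
  distances.py    p-distances with pairwise deletion
  delimit.py      threshold clustering, ABGD, neighbor joining, 16S clusters
  reconcile.py    COI x 16S x locality rules, OTU naming
  concordance.py  field-vs-barcode audit and genus table
  richness.py     rarefaction, Chao2, 84% CI overlap
  synthetic.py    community generator with known truth
  pipeline.py     end-to-end driver
  fixtures.py     packaged published tables
docs/methods.md   models, assumptions, numerical choices, limitations
```
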