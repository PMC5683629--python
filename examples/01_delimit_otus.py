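"""Delimit OTUs in a small synthetic community with two COI methods.

Generates 5 species with a clean barcode gap (0.4% within species, >=8%
between), then clusters the COI distance matrix with the fixed 2.2%
threshold (the BIN proxy) and with automatic barcode-gap discovery, and
prints the gap-discovery scan over its prior grid. At the smallest priors
gap discovery shatters species into haplotype groups, as it does on real
data; the stability selection picks the partition whose group count holds
over the longest run of priors.
"""

from barcodeaudit import distance_matrix, threshold_partition, abgd_partition
from barcodeaudit.synthetic import SyntheticConfig, generate_community

cfg = SyntheticConfig(K=5, specimens_per_species=(4, 6), mu_intra=0.004,
                      d_min_inter=0.08, seed=42)
records, alignments, truth = generate_community(cfg)
print(f"community: {truth.k} true species, {len(records)} specimens")
print(f"realized distances: mean within-species {truth.mean_intra_coi:.4f}, "
      f"min between-centroids {truth.min_inter_coi:.4f}")

D = distance_matrix(alignments["COI"], min_overlap=100)

bins = threshold_partition(D, t=0.022)
print(f"\nBIN proxy (single linkage at 2.2%): {bins.n_groups} groups")

res = abgd_partition(D)
print("\nbarcode-gap discovery over the prior grid:")
print("prior     initial  recursive  selected")
for prior, n_ini, n_rec, sel in res.summary_rows():
    print(f"{prior:8.5f}  {n_ini:7d}  {n_rec:9d}  {'<--' if sel else ''}")
print(f"\nselected partition: {res.selected.n_groups} groups "
      f"(stable run of priors around P={res.selected_prior:.4f})")
print("both methods recover the", truth.k, "generating species when the gap "
      "is clean; the counts above should equal the true K.")
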