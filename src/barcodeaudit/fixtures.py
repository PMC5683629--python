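"""Packaged fixture tables from a published amphibian inventory audit.

Three small TSVs ship with the package (``barcodeaudit/data/``), transcribed
from the printed result tables of a DNA-barcoding audit of an amphibian
inventory in Gabon and the Republic of Congo:

* ``sites.tsv`` — specimens and successful COI/16S sequences per collection
  locality;
* ``species_partitions.tsv`` — every species-level unit with its specimen
  counts per region, its Barcode Index Number and its barcode-gap group,
  one row per (species, BIN) combination;
* ``genus_counts.tsv`` — field vs barcode species counts per genus, per
  season and combined.

They serve as worked examples: summary statistics recomputed from these
tables (total sequence counts, numbers of distinct BIN and gap-discovery
groups, field vs barcode totals, the overestimation percentage) reproduce
the published headline numbers.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_sites", "load_species_partitions", "load_genus_counts",
           "partition_counts", "genus_totals"]


def _read(name: str) -> pd.DataFrame:
    with resources.files("barcodeaudit.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_sites() -> pd.DataFrame:
    """Per-locality specimen and sequence tallies (no totals row)."""
    return _read("sites.tsv")


def load_species_partitions() -> pd.DataFrame:
    """Species-unit table: counts per region, BIN id, gap-group id, no-COI counts."""
    return _read("species_partitions.tsv")


def load_genus_counts() -> pd.DataFrame:
    """Field vs barcode species counts per genus, by season and combined."""
    return _read("genus_counts.tsv")


def partition_counts(df: pd.DataFrame | None = None) -> dict[str, int]:
    """Distinct BINs and gap-discovery groups in the species table."""
    df = load_species_partitions() if df is None else df
    return {"bins": df["bin"].nunique(), "abgd_groups": df["abgd_group"].nunique()}


def genus_totals(df: pd.DataFrame | None = None) -> dict[str, float]:
    """Field/barcode totals per season plus the field overestimation percent."""
    df = load_genus_counts() if df is None else df
    out: dict[str, float] = {}
    for season in ("dry", "wet", "combined"):
        out[f"{season}_field"] = int(df[f"{season}_field"].sum())
        out[f"{season}_barcode"] = int(df[f"{season}_barcode"].sum())
    f, b = out["combined_field"], out["combined_barcode"]
    out["overestimation_pct"] = round((f - b) / b * 100.0, 1)
    return out
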