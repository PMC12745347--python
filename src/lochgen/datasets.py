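"""Packaged reference tables for UK and Irish Arctic charr populations.

Two small tab-delimited tables ship with the package:

* ``uk_charr_population_summary.tsv`` -- 64 populations with coordinates,
  sample sizes and published genomic summary statistics (private alleles,
  observed/expected heterozygosity, nucleotide diversity, population-specific
  F_ST).
* ``uk_charr_unit_metadata.tsv`` -- the 58 Scottish populations with the
  metadata flags the conservation-unit rules consume (ecotype status,
  sole-population-in-Hydrometric-Area status, documented translocation and
  shared-history links) together with the expected published delineation.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .units import ConservationUnitSet, delineate_units


def _load(name: str) -> pd.DataFrame:
    with resources.files("lochgen.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_population_summary() -> pd.DataFrame:
    """64 charr populations with genomic diversity summaries."""
    return _load("uk_charr_population_summary.tsv")


def load_unit_metadata() -> pd.DataFrame:
    """Delineation metadata (and expected unit labels) for the 58 Scottish
    populations."""
    df = _load("uk_charr_unit_metadata.tsv")
    df["ecotype_flag"] = df["ecotype_flag"].astype(bool)
    df["sole_ha"] = df["sole_ha"].astype(bool)
    return df


def delineate_reference_units() -> tuple[ConservationUnitSet, pd.DataFrame]:
    """Run the delineation engine on the packaged Scottish metadata.

    Merging relies on the documented translocation and shared-history links
    only (no F_ST matrix is packaged, so the proximity-plus-gene-flow rule is
    inactive).  Returns the computed units together with the metadata table
    (whose ``expected_type``/``expected_unit`` columns carry the published
    classification for cross-checking).
    """
    meta = load_unit_metadata()
    units = delineate_units(meta, fst=None)
    return units, meta
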