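"""Published reference tables for the type 1 diabetes (T1D) candidate-gene
Alu survey, shipped as worked-example inputs.

The survey covered 941 T1D candidate genes and, per region category, the
number of sequences (all isoforms counted), total length, GC level, repeat
and Alu element counts, orientation tallies in the UTRs, and the per-
transcript Alu inventories of the 3'UTRs that harbor inverted Alu pairs.
These tables are *inputs* for the package's arithmetic (densities, display
percentages, IRAlu gene counts, enrichment bounds); the raw genome-scale
annotation behind them is not reproduced here.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .iralu import IRAluRow, read_iralu_table

__all__ = [
    "region_summary",
    "orientation_counts",
    "iralu_table",
    "N_GENES",
    "N_GENES_WITH_ALUS",
    "ALU_COVERAGE_T1D_PCT",
    "ALU_COVERAGE_GENOME_PCT",
    "GENOME_LENGTH_RANGE",
]

#: candidate genes surveyed / genes found to harbor Alu elements
N_GENES = 941
N_GENES_WITH_ALUS = 554

#: percent of candidate-gene sequence covered by Alus vs the genome average
ALU_COVERAGE_T1D_PCT = 15.03
ALU_COVERAGE_GENOME_PCT = 11.0

#: plausible span of human genome sizes (nt) for background base counts
GENOME_LENGTH_RANGE = (2_800_000_000, 3_200_000_000)


def _data(name: str):
    return resources.files("alulandscape.data").joinpath(name)


def region_summary() -> pd.DataFrame:
    """Per-category survey characteristics, indexed by region category."""
    with resources.as_file(_data("t1d_region_summary.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="category")


def orientation_counts() -> pd.DataFrame:
    """Sense/antisense Alu counts in T1D and background (human) UTRs."""
    with resources.as_file(_data("t1d_orientation_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t", index_col="region")


def iralu_table() -> list[IRAluRow]:
    """Per-transcript Alu inventories of T1D 3'UTRs harboring inverted Alus."""
    with resources.as_file(_data("t1d_iralu_3utr.tsv")) as path:
        return read_iralu_table(path)
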