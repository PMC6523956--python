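"""Bundled reference tables.

Small published inputs shipped with the package: the qPCR primer panel
used for the family's expression validation, and the per-species Sox
duplication-class counts for seven galliform genomes (inputs to the
percentage summaries).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .seqio import PrimerRecord, read_primer_table

__all__ = ["load_primer_table", "load_galliform_sox_counts"]


def _data_path(name: str):
    return resources.files("soxkit").joinpath("data", name)


def load_primer_table() -> list[PrimerRecord]:
    """The 12-primer qPCR panel (six genes, forward/reverse, all 20 bp)."""
    with resources.as_file(_data_path("galliform_sox_primers.tsv")) as path:
        return read_primer_table(path)


def load_galliform_sox_counts() -> dict[str, dict[str, int]]:
    """Sox duplication-class counts per galliform species."""
    with resources.as_file(_data_path("galliform_sox_dup_counts.tsv")) as path:
        df = pd.read_csv(path, sep="\t", index_col="species")
    return {sp: {c: int(v) for c, v in row.items()} for sp, row in df.iterrows()}
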