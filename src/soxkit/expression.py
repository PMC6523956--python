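"""qPCR relative quantification by the Livak 2^-ddCT method, and
z-scored matrices for heatmap-style reporting of externally quantified
expression.

The ddCT computation averages technical replicates to one CT per
gene x sample, forms dCT = CT_gene - CT_reference per sample, averages
biological replicates on the dCT scale (the standard Livak formulation),
and reports ddCT against the calibrator condition with
fold = 2^-ddCT.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FoldChange",
    "CT_COLUMNS",
    "delta_delta_ct",
    "zscore_matrix",
]

CT_COLUMNS = ["gene", "condition", "biological_replicate",
              "technical_replicate", "ct"]


@dataclass(frozen=True)
class FoldChange:
    gene: str
    condition: str
    delta_delta_ct: float
    fold: float  # 2^-ddCT exactly


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CT table missing column(s): {missing}")
    if (table["ct"] <= 0).any():
        raise ValueError("CT values must be positive")
    return table


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str,
    calibrator_condition: str,
) -> list[FoldChange]:
    """Relative expression of every non-reference gene per condition.

    Requires the reference gene in every gene x condition x biological
    replicate sample; a missing reference measurement is an error naming
    the sample.
    """
    table = _check_table(table)
    if calibrator_condition not in set(table["condition"]):
        raise ValueError(f"calibrator condition {calibrator_condition!r} absent")
    # technical replicates -> one CT per gene x condition x bio replicate
    ct = (
        table.groupby(["gene", "condition", "biological_replicate"])["ct"]
        .mean()
        .reset_index()
    )
    ref = ct[ct["gene"] == reference_gene].set_index(
        ["condition", "biological_replicate"]
    )["ct"]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not measured")
    dct_rows = []
    for _, row in ct[ct["gene"] != reference_gene].iterrows():
        key = (row["condition"], row["biological_replicate"])
        if key not in ref.index:
            raise ValueError(
                f"reference gene {reference_gene!r} missing in sample "
                f"condition={key[0]!r} biological_replicate={key[1]!r}"
            )
        dct_rows.append(
            {"gene": row["gene"], "condition": row["condition"],
             "dct": row["ct"] - ref[key]}
        )
    dct = pd.DataFrame(dct_rows)
    # biological replicates averaged on the dCT (cycle) scale
    mean_dct = dct.groupby(["gene", "condition"])["dct"].mean()
    out: list[FoldChange] = []
    for gene in sorted(dct["gene"].unique()):
        if (gene, calibrator_condition) not in mean_dct.index:
            raise ValueError(
                f"gene {gene!r} not measured in calibrator condition"
            )
        base = mean_dct[(gene, calibrator_condition)]
        for condition in sorted(dct.loc[dct["gene"] == gene, "condition"].unique()):
            ddct = mean_dct[(gene, condition)] - base
            out.append(FoldChange(gene, condition, float(ddct),
                                  float(2.0 ** -ddct)))
    return out


def zscore_matrix(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Row-standardize an expression matrix (genes x samples).

    Each row is centred and scaled to unit variance using the population
    (n) standard deviation.  Constant rows are mapped to all zeros and
    their gene ids returned as flags.  Fewer than 2 samples is an error.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 samples per gene to standardize")
    values = matrix.to_numpy(dtype=float)
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=0, keepdims=True)
    flagged = [str(matrix.index[i]) for i in np.flatnonzero(sds.ravel() == 0)]
    sds[sds == 0] = 1.0
    z = (values - means) / sds
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns), flagged
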