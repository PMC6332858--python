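"""Relative qPCR quantification by the comparative-Ct (ddCt) method.

Expression of a target gene is normalised to a reference gene within
each sample (dCt = Ct_target - Ct_reference) and then to a designated
calibrator sample (ddCt = dCt_sample - dCt_calibrator).  Assuming an
amplification efficiency of 2 (perfect doubling per cycle), relative
expression is 2**(-ddCt); the calibrator reads exactly 1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

_CT_RANGE = (0.0, 50.0)


def _check_ct(values: pd.Series, label: str) -> None:
    v = values.to_numpy(dtype=float)
    if not np.all((v > _CT_RANGE[0]) & (v < _CT_RANGE[1])):
        raise ValueError(f"{label} Ct values must lie in (0, 50) cycles")


def ddct_relative_expression(records: pd.DataFrame) -> pd.Series:
    """Relative expression per sample for one gene.

    ``records`` needs columns sample_id, ct_target, ct_reference and a
    boolean is_calibrator marking exactly one row.  Technical replicates
    (duplicate sample_ids) are averaged on the Ct scale before dCt.
    """
    required = {"sample_id", "ct_target", "ct_reference", "is_calibrator"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    _check_ct(records["ct_target"], "target")
    _check_ct(records["ct_reference"], "reference")

    cal_samples = records.loc[records["is_calibrator"].astype(bool), "sample_id"].unique()
    if len(cal_samples) == 0:
        raise ValueError("no calibrator sample designated")
    if len(cal_samples) > 1:
        raise ValueError(f"multiple calibrator samples: {list(cal_samples)}")
    cal = cal_samples[0]

    ct = records.groupby("sample_id", sort=False)[["ct_target", "ct_reference"]].mean()
    dct = ct["ct_target"] - ct["ct_reference"]
    ddct = dct - dct[cal]
    re = np.power(2.0, -ddct)
    re[cal] = 1.0  # exact by definition
    re.name = "relative_expression"
    return re


def ddct_table(records: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample relative-expression table.

    ``records`` carries a ``gene_id`` column in addition to the per-gene
    schema of :func:`ddct_relative_expression`; each gene group must
    designate its own calibrator.
    """
    if "gene_id" not in records.columns:
        raise ValueError("missing gene_id column")
    rows = {
        gene: ddct_relative_expression(grp)
        for gene, grp in records.groupby("gene_id", sort=False)
    }
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out
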