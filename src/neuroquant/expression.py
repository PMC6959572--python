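"""Relative qPCR quantification against multiple reference genes.

Delta-delta-Ct with three biologically diverse internal references
(GAPDH, beta-Actin, HPRT roles): per sample, the target Ct (triplicates
averaged) is normalized to a combination of the reference Cts, then
expressed as fold change 2^-(dCt_sample - mean dCt_calibrator) relative
to the calibrator group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["relative_expression", "combine_reference_cts"]

CT_RANGE = (5.0, 40.0)


def combine_reference_cts(ref_cts: np.ndarray, method: str = "arithmetic") -> np.ndarray:
    """Combine reference-gene Ct values per sample.

    'arithmetic' mean of Cts equals the geometric mean on the expression
    scale; 'geometric' takes the geometric mean of the Ct values
    themselves.  Both are exposed because the field uses either.
    """
    ref_cts = np.asarray(ref_cts, dtype=float)
    if method == "arithmetic":
        return ref_cts.mean(axis=-1)
    if method == "geometric":
        return np.exp(np.log(ref_cts).mean(axis=-1))
    raise ValueError("method must be 'arithmetic' or 'geometric'")


def relative_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    reference_genes: list[str],
    calibrator_group: str,
    combine: str = "arithmetic",
) -> pd.DataFrame:
    """Fold change per sample relative to the calibrator-group mean.

    ``ct_table`` is tidy with columns sample, group, gene, ct (one row
    per replicate; replicates are averaged).  Samples missing any
    reference gene are excluded with a log entry.  Returns one row per
    sample with dct and fold columns; group summaries are a groupby away.
    """
    need = {"sample", "group", "gene", "ct"}
    if not need.issubset(ct_table.columns):
        raise ValueError(f"ct_table needs columns {sorted(need)}")
    bad = ~ct_table["ct"].between(*CT_RANGE)
    if bad.any():
        raise ValueError(f"{bad.sum()} Ct values outside plausible range {CT_RANGE}")

    mean_ct = (
        ct_table.groupby(["sample", "group", "gene"])["ct"].mean().reset_index()
    )
    wide = mean_ct.pivot_table(index=["sample", "group"], columns="gene", values="ct")
    missing_cols = [g for g in [target_gene, *reference_genes] if g not in wide.columns]
    if missing_cols:
        raise ValueError(f"genes absent from table: {missing_cols}")

    complete = wide[[target_gene, *reference_genes]].notna().all(axis=1)
    dropped = wide.index[~complete].get_level_values("sample").tolist()
    if dropped:
        logger.warning("excluding samples with incomplete references: %s", dropped)
    wide = wide[complete]
    if wide.empty:
        raise ValueError("no samples with complete target and reference Cts")

    ref = combine_reference_cts(wide[reference_genes].to_numpy(), method=combine)
    dct = wide[target_gene].to_numpy() - ref
    out = wide.reset_index()[["sample", "group"]]
    out["dct"] = dct
    cal = out.loc[out["group"] == calibrator_group, "dct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    out["fold"] = 2.0 ** -(out["dct"] - cal.mean())
    return out
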