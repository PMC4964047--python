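"""Allelic imbalance in chromatin accessibility at heterozygous sites.

The imbalance of a heterozygous site is the log2 ratio of reads carrying
each allele; its magnitude |log2(ref/alt)| is the working statistic
(allele orientation at arbitrary het sites is unpolarized).  Sites need
a depth of at least 10, and a zero count on either allele excludes the
site with a reason (it is itself extreme imbalance, reported
separately rather than pseudocounted).  Imbalance magnitudes are
median-normalized against the control SNP set per cell type, so the
control median maps to zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["allelic_imbalance"]


def allelic_imbalance(
    counts: pd.DataFrame, control_ids, min_depth: int = 10
) -> pd.DataFrame:
    """Normalized allelic-imbalance table.

    Parameters
    ----------
    counts
        Columns ``snp_id``, ``ref_reads``, ``alt_reads`` and optionally
        ``cell_type`` (normalization is per cell type when present).
    control_ids
        SNP ids of the control set; their median imbalance defines the
        zero point.

    Returns a copy with ``depth``, ``imbalance_log2`` (signed),
    ``imbalance_abs``, ``imbalance_norm`` and an ``excluded`` reason
    column (empty string = included).
    """
    out = counts.copy()
    out["depth"] = out["ref_reads"] + out["alt_reads"]
    excluded = np.where(
        out["depth"] < min_depth,
        "low_depth",
        np.where((out["ref_reads"] == 0) | (out["alt_reads"] == 0), "zero_count", ""),
    )
    out["excluded"] = excluded
    ok = out["excluded"] == ""
    with np.errstate(divide="ignore", invalid="ignore"):
        log2r = np.log2(out["ref_reads"] / out["alt_reads"])
    out["imbalance_log2"] = np.where(ok, log2r, np.nan)
    out["imbalance_abs"] = np.abs(out["imbalance_log2"])

    control_ids = set(control_ids)
    is_control = out["snp_id"].isin(control_ids)
    group_cols = ["cell_type"] if "cell_type" in out.columns else []
    out["imbalance_norm"] = np.nan
    if group_cols:
        for _, idx in out.groupby(group_cols[0]).groups.items():
            sub = out.loc[idx]
            med = sub.loc[is_control.loc[idx] & (sub["excluded"] == ""), "imbalance_abs"].median()
            out.loc[idx, "imbalance_norm"] = sub["imbalance_abs"] - med
    else:
        med = out.loc[is_control & ok, "imbalance_abs"].median()
        out["imbalance_norm"] = out["imbalance_abs"] - med
    return out
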