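"""Relative qPCR quantification by the 2^-ddCt method.

dCt(sample, gene) = Ct_gene - Ct_reference for that sample;
ddCt(gene) = mean dCt(tumor) - mean dCt(control);
fold change = 2^-ddCt.

The group test is an unpaired two-tailed Student's t-test on the dCt
values (the log2 scale), not on fold changes. An alternative per-sample
convention (mean over tumor samples of 2^-(dCt - mean control dCt)) is
available via ``method="per_sample"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .groupstats import compare_groups, significance_stars

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def _delta_ct(table: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"Ct table is missing column {col!r}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct values in table")
    ref = table[table["gene"] == reference_gene]
    if ref.empty:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    ref_ct = ref.set_index("sample")["ct"]
    if ref_ct.index.duplicated().any():
        raise ValueError("duplicate reference-gene rows for a sample")
    missing = set(table["sample"]) - set(ref_ct.index)
    if missing:
        raise ValueError(
            f"samples without a reference-gene row: {', '.join(sorted(missing))}"
        )
    out = table.copy()
    out["dct"] = out["ct"].to_numpy() - ref_ct.loc[out["sample"]].to_numpy()
    return out


def delta_delta_ct(
    table: pd.DataFrame,
    reference_gene: str = "Gapdh",
    control_group: str = "naive",
    method: str = "group_mean",
) -> pd.DataFrame:
    """Per-gene fold change (2^-ddCt) with group statistics.

    Returns a DataFrame indexed by gene with columns ``fold_change``,
    ``ddct``, ``n_control``, ``n_treated``, ``t``, ``p_value``, ``stars``.
    The reference gene is included (fold change identically 1). The
    t-test requires n >= 2 per group; with fewer samples the p-value is
    NaN.
    """
    if method not in ("group_mean", "per_sample"):
        raise ValueError("method must be 'group_mean' or 'per_sample'")
    dct = _delta_ct(table, reference_gene)
    groups = [g for g in dct["group"].unique()]
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} not in table")
    treated = [g for g in groups if g != control_group]
    if len(treated) != 1:
        raise ValueError(
            f"expected exactly one non-control group, found {treated}"
        )
    treated = treated[0]

    rows = []
    for gene, sub in dct.groupby("gene", sort=False):
        ctrl = sub.loc[sub["group"] == control_group, "dct"].to_numpy()
        trt = sub.loc[sub["group"] == treated, "dct"].to_numpy()
        if ctrl.size == 0 or trt.size == 0:
            raise ValueError(f"gene {gene!r} missing in one group")
        ddct = float(trt.mean() - ctrl.mean())
        if method == "group_mean":
            fold = float(2.0 ** (-ddct))
        else:
            fold = float(np.mean(2.0 ** (-(trt - ctrl.mean()))))
        if ctrl.size >= 2 and trt.size >= 2:
            cmp_ = compare_groups(ctrl, trt, metric=gene, labels=(control_group, treated))
            t, p = cmp_.t, cmp_.p
        else:
            t, p = float("nan"), float("nan")
        rows.append(
            {
                "gene": gene,
                "fold_change": fold,
                "ddct": ddct,
                "n_control": int(ctrl.size),
                "n_treated": int(trt.size),
                "t": t,
                "p_value": p,
                "stars": significance_stars(p) if np.isfinite(p) else "",
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def panel_report(
    results: pd.DataFrame, reference_gene: str = "Gapdh"
) -> pd.DataFrame:
    """Panel table for reporting: reference gene excluded, stars attached.

    ``results`` is the output of :func:`delta_delta_ct`. Raises on an
    empty panel.
    """
    if results is None or results.empty:
        raise ValueError("empty qPCR panel")
    out = results.drop(index=reference_gene, errors="ignore")
    if out.empty:
        raise ValueError("panel contains only the reference gene")
    return out
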