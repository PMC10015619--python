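"""Differential allele-specific expression between developmental timepoints.

For each tissue sampled at both timepoints, genes with ASE at either
timepoint are tested with a two-sided Fisher's exact test on the 2x2
table of (marine, freshwater) counts at (early, late), counts summed
across replicates; p-values are BH-adjusted within each tissue.
Significant genes are classified by bias (which timepoint has the larger
|lfc|) and by mode (timepoint-specific ASE versus magnitude change).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from asekit.calling import bh_adjust, log2_fold_change

logger = logging.getLogger(__name__)

EARLY, LATE = 1, 2


def diff_ase_test(early_counts: tuple[int, int], late_counts: tuple[int, int]) -> float:
    """Two-sided Fisher's exact p for one gene's (marine, freshwater) counts
    at the early versus late timepoint. Returns NaN if a timepoint has zero
    total reads (untestable)."""
    m1, f1 = early_counts
    m2, f2 = late_counts
    if m1 + f1 == 0 or m2 + f2 == 0:
        return float("nan")
    return float(stats.fisher_exact([[m1, f1], [m2, f2]], alternative="two-sided")[1])


def classify_temporal(row: pd.Series, fdr_threshold: float) -> tuple[str, str]:
    """Bias / mode labels for one tested gene row.

    Significant genes are ``early_bias`` when |lfc_early| > |lfc_late|,
    otherwise ``late_bias`` (exact ties go to late_bias and are logged);
    mode is ``timepoint_specific`` when ASE is called at exactly one
    timepoint and ``magnitude_change`` when called at both.
    """
    if not (row["fdr"] < fdr_threshold) or not row["testable"]:
        return "no_change", "none"
    abs_early, abs_late = abs(row["lfc_early"]), abs(row["lfc_late"])
    if abs_early == abs_late:
        logger.info("gene %s: |lfc| tie between timepoints, assigned late_bias", row["gene_id"])
    bias = "early_bias" if abs_early > abs_late else "late_bias"
    n_ase = int(row["is_ase_early"]) + int(row["is_ase_late"])
    mode = "timepoint_specific" if n_ase == 1 else "magnitude_change"
    return bias, mode


def run_developmental_ase(
    counts: pd.DataFrame,
    ase_results: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Differential-ASE analysis for every tissue present at both timepoints.

    ``ase_results`` is the per-tissue-timepoint output of
    :func:`asekit.calling.ase_test`; only genes with ASE at >= 1 of the
    two timepoints are tested. Returns one row per tested gene with
    fisher_p, fdr, bias and mode labels, and per-timepoint lfc values.
    """
    pooled = (
        counts.groupby(["gene_id", "tissue", "timepoint"], sort=True)[
            ["marine_count", "freshwater_count"]
        ]
        .sum()
        .reset_index()
    )
    tp_per_tissue = pooled.groupby("tissue")["timepoint"].unique()
    both = [t for t, tps in tp_per_tissue.items() if {EARLY, LATE} <= set(tps)]
    if not both:
        raise ValueError("no tissue was sampled at both timepoints")

    calls = ase_results.set_index(["gene_id", "tissue", "timepoint"])["is_ase"]
    out_rows = []
    for tissue in both:
        sub = pooled[pooled["tissue"] == tissue]
        wide = sub.pivot_table(
            index="gene_id",
            columns="timepoint",
            values=["marine_count", "freshwater_count"],
            fill_value=0,
            aggfunc="sum",
        )
        gene_ids = wide.index.to_numpy()
        m1 = wide.get(("marine_count", EARLY), pd.Series(0, index=wide.index)).to_numpy(np.int64)
        f1 = wide.get(("freshwater_count", EARLY), pd.Series(0, index=wide.index)).to_numpy(np.int64)
        m2 = wide.get(("marine_count", LATE), pd.Series(0, index=wide.index)).to_numpy(np.int64)
        f2 = wide.get(("freshwater_count", LATE), pd.Series(0, index=wide.index)).to_numpy(np.int64)

        def call(gene: str, tp: int) -> bool:
            try:
                return bool(calls.loc[(gene, tissue, tp)])
            except KeyError:
                return False

        is_ase_early = np.array([call(g, EARLY) for g in gene_ids])
        is_ase_late = np.array([call(g, LATE) for g in gene_ids])
        eligible = is_ase_early | is_ase_late
        testable = (m1 + f1 > 0) & (m2 + f2 > 0)

        tested = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "tissue": tissue,
                "m_early": m1,
                "f_early": f1,
                "m_late": m2,
                "f_late": f2,
                "lfc_early": log2_fold_change(m1, f1),
                "lfc_late": log2_fold_change(m2, f2),
                "is_ase_early": is_ase_early,
                "is_ase_late": is_ase_late,
                "testable": testable,
            }
        )
        tested = tested[eligible].reset_index(drop=True)
        pvals = np.full(len(tested), np.nan)
        for i, row in tested.iterrows():
            if row["testable"]:
                pvals[i] = diff_ase_test(
                    (row["m_early"], row["f_early"]), (row["m_late"], row["f_late"])
                )
        tested["fisher_p"] = pvals
        tested["fdr"] = np.nan
        ok = tested["testable"].to_numpy()
        if ok.any():
            tested.loc[ok, "fdr"] = bh_adjust(tested.loc[ok, "fisher_p"].to_numpy())
        labels = [classify_temporal(row, fdr_threshold) for _, row in tested.iterrows()]
        tested["bias"] = [b for b, _ in labels]
        tested["mode"] = [m for _, m in labels]
        out_rows.append(tested)
    return pd.concat(out_rows, ignore_index=True)
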