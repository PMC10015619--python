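"""Site filtering and per-tissue gene-level ASE testing.

The gene-level test pools counts across replicates and applies a
two-sided exact binomial test of the marine read fraction against 0.5
(minimum-likelihood two-sided rule). An optional beta-binomial variant
estimates per-tissue overdispersion across replicates by method of
moments and guards against replicate variability. P-values are adjusted
by Benjamini-Hochberg within each tissue-timepoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

LFC_PSEUDOCOUNT = 0.5
RATIO_FILTER_LOG2 = 10.0


def filter_sites(sites: pd.DataFrame, max_abs_log2_ratio: float = RATIO_FILTER_LOG2):
    """Remove heterozygous sites with mapping-bias signatures.

    Drops sites where either pooled allele count is zero, then sites with
    ``|log2(marine/freshwater)| > max_abs_log2_ratio``. Counts are pooled
    across all libraries upstream (the filter sees one row per site).

    Returns ``(kept_sites, removal_log)``; the log has one row per removed
    site with a ``reason`` of ``zero-allele`` or ``ratio``. Idempotent.
    """
    m = sites["marine_count"].to_numpy(dtype=float)
    f = sites["freshwater_count"].to_numpy(dtype=float)
    zero = (m == 0) | (f == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs(np.log2(m / f))
    extreme = ~zero & (ratio > max_abs_log2_ratio)
    reason = np.where(zero, "zero-allele", np.where(extreme, "ratio", ""))
    removed = sites.loc[zero | extreme].copy()
    removed["reason"] = reason[zero | extreme]
    kept = sites.loc[~(zero | extreme)].reset_index(drop=True)
    logger.info(
        "site filter: kept %d of %d sites (%d zero-allele, %d ratio)",
        len(kept), len(sites), int(zero.sum()), int(extreme.sum()),
    )
    return kept, removed.reset_index(drop=True)


def _minlike_two_sided_pvalues(x: np.ndarray, n: np.ndarray, pmf) -> np.ndarray:
    """Vectorized minimum-likelihood two-sided exact p-values.

    For each observation, sums the pmf over all outcomes whose probability
    is <= the observed outcome's probability (ties included). ``pmf(k, n)``
    must return the null pmf for a scalar n over vector k.
    """
    out = np.empty(len(x))
    order = np.argsort(n, kind="stable")
    start = 0
    n_sorted = n[order]
    # group by n so each pmf vector is computed once
    while start < len(order):
        stop = start
        while stop < len(order) and n_sorted[stop] == n_sorted[start]:
            stop += 1
        nn = int(n_sorted[start])
        support = np.arange(nn + 1)
        probs = pmf(support, nn)
        idx = order[start:stop]
        obs = probs[x[idx].astype(int)]
        # rel tolerance absorbs roundoff in "equal" pmf values
        thresh = obs * (1 + 1e-7)
        csum = np.cumsum(np.sort(probs))
        ranks = np.searchsorted(np.sort(probs), thresh, side="right")
        out[idx] = np.minimum(csum[np.maximum(ranks - 1, 0)], 1.0)
        out[idx[ranks == 0]] = 0.0
        start = stop
    return out


def exact_binomial_pvalue(m: int, f: int) -> float:
    """Two-sided exact binomial p-value for marine count m of n = m + f."""
    n = m + f
    if n == 0:
        return np.nan
    return float(stats.binomtest(int(m), int(n), 0.5, alternative="two-sided").pvalue)


def estimate_overdispersion(counts: pd.DataFrame) -> float:
    """Method-of-moments beta-binomial correlation ``rho`` across replicates.

    For each gene with >= 2 replicates, compares the observed variance of
    replicate marine counts with the binomial expectation at the pooled
    fraction; excess variance is attributed to a common Beta(a, a) draw.
    Returns rho clipped to [1e-6, 0.5].
    """
    num = 0.0
    den = 0.0
    for _, g in counts.groupby("gene_id", sort=False):
        if len(g) < 2:
            continue
        m = g["marine_count"].to_numpy(dtype=float)
        n = m + g["freshwater_count"].to_numpy(dtype=float)
        if (n <= 0).any() or n.sum() < 20:
            continue
        p = m.sum() / n.sum()
        if p <= 0 or p >= 1:
            continue
        r = len(m)
        # r/(r-1) restores the df lost to the pooled fraction estimate
        resid = (r / (r - 1)) * (m - n * p) ** 2 - n * p * (1 - p)
        weight = n * (n - 1) * p * (1 - p)
        num += resid.sum()
        den += weight.sum()
    if den <= 0:
        return 1e-6
    return float(np.clip(num / den, 1e-6, 0.5))


def betabinomial_pvalue(m: int, f: int, rho: float) -> float:
    """Two-sided beta-binomial p-value (minimum-likelihood rule) at theta = 0.5."""
    n = m + f
    if n == 0:
        return np.nan
    a = 0.5 * (1.0 - rho) / rho
    support = np.arange(n + 1)
    probs = stats.betabinom.pmf(support, n, a, a)
    obs = probs[m]
    return float(min(probs[probs <= obs * (1 + 1e-7)].sum(), 1.0))


def log2_fold_change(m, f, pseudocount: float = LFC_PSEUDOCOUNT):
    """log2(marine/freshwater) with a pseudocount added to each allele."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f, dtype=float)
    return np.log2((m + pseudocount) / (f + pseudocount))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, capped at 1. NaN input is an error."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any():
        raise ValueError("bh_adjust: NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


@dataclass
class ASECallingResult:
    """Per-tissue-timepoint ASE test results plus the pooled count table."""

    results: pd.DataFrame
    fdr_threshold: float


def ase_test(
    counts: pd.DataFrame,
    fdr_threshold: float = 0.05,
    test: str = "binomial",
) -> pd.DataFrame:
    """Gene-level ASE tests for every (gene, tissue, timepoint) in a count table.

    Pools counts across replicates, applies the exact test per gene, and
    BH-adjusts within each tissue-timepoint. Genes with zero pooled depth
    in a tissue are flagged untestable and excluded from BH.

    Returns a table with columns ``gene_id, tissue, timepoint,
    marine_count, freshwater_count, lfc, p_value, fdr, is_ase, testable``.
    """
    if test not in {"binomial", "betabinomial"}:
        raise ValueError(f"unknown test {test!r}")
    pooled = (
        counts.groupby(["gene_id", "tissue", "timepoint"], sort=True)[
            ["marine_count", "freshwater_count"]
        ]
        .sum()
        .reset_index()
    )
    m = pooled["marine_count"].to_numpy(dtype=np.int64)
    f = pooled["freshwater_count"].to_numpy(dtype=np.int64)
    n = m + f
    pooled["lfc"] = log2_fold_change(m, f)
    pooled["testable"] = n > 0

    pvals = np.full(len(pooled), np.nan)
    if test == "binomial":
        testable = pooled["testable"].to_numpy()
        pvals[testable] = _minlike_two_sided_pvalues(
            m[testable], n[testable], lambda k, nn: stats.binom.pmf(k, nn, 0.5)
        )
    else:
        for (tissue, tp), idx in pooled.groupby(["tissue", "timepoint"]).groups.items():
            sub = counts[(counts["tissue"] == tissue) & (counts["timepoint"] == tp)]
            rho = estimate_overdispersion(sub)
            logger.info("tissue %s@%s: beta-binomial rho = %.3g", tissue, tp, rho)
            for i in idx:
                if n[i] > 0:
                    pvals[i] = betabinomial_pvalue(int(m[i]), int(f[i]), rho)
    pooled["p_value"] = pvals

    pooled["fdr"] = np.nan
    for _, idx in pooled.groupby(["tissue", "timepoint"]).groups.items():
        idx = np.asarray(idx)
        ok = idx[pooled["testable"].to_numpy()[idx]]
        if len(ok):
            pooled.loc[ok, "fdr"] = bh_adjust(pooled.loc[ok, "p_value"].to_numpy())
    pooled["is_ase"] = pooled["fdr"] < fdr_threshold
    pooled["is_ase"] = pooled["is_ase"].fillna(False).astype(bool)
    return pooled


def run_ase_calling(
    counts: pd.DataFrame, fdr_threshold: float = 0.05, test: str = "binomial"
) -> ASECallingResult:
    return ASECallingResult(
        results=ase_test(counts, fdr_threshold=fdr_threshold, test=test),
        fdr_threshold=fdr_threshold,
    )


def summarize_ase(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Summaries of an ASE result table.

    Returns per-tissue ASE counts/proportions, per-gene tissue-sharing
    membership strings (UpSet-style), and the number of genes whose lfc
    sign flips between ASE tissues.
    """
    work = results.copy()
    work["unit"] = [
        f"{t}@{tp}" for t, tp in zip(work["tissue"], work["timepoint"])
    ]
    units = sorted(work["unit"].unique())

    per_tissue = (
        work[work["testable"]]
        .groupby("unit")
        .agg(n_tested=("gene_id", "size"), n_ase=("is_ase", "sum"))
        .reset_index()
    )
    per_tissue["proportion_ase"] = per_tissue["n_ase"] / per_tissue["n_tested"]

    ase_rows = work[work["is_ase"]]
    memberships = []
    n_direction_change = 0
    for gene_id, g in ase_rows.groupby("gene_id", sort=True):
        present = set(g["unit"])
        flags = "".join("1" if u in present else "0" for u in units)
        signs = np.sign(g["lfc"].to_numpy())
        signs = signs[signs != 0]
        direction_change = bool(len(signs) and signs.min() != signs.max())
        n_direction_change += direction_change
        memberships.append(
            {
                "gene_id": gene_id,
                "n_ase_tissues": len(present),
                "membership": flags,
                "direction_change": direction_change,
            }
        )
    membership_df = pd.DataFrame(
        memberships, columns=["gene_id", "n_ase_tissues", "membership", "direction_change"]
    )
    overall = pd.DataFrame(
        {
            "n_ase_genes": [membership_df["gene_id"].nunique()],
            "n_single_tissue": [int((membership_df["n_ase_tissues"] == 1).sum()) if len(membership_df) else 0],
            "n_direction_change": [n_direction_change],
        }
    )
    return {
        "per_tissue": per_tissue,
        "membership": membership_df,
        "overall": overall,
        "unit_order": pd.DataFrame({"unit": units}),
    }
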