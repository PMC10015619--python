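"""Genomic context of ASE genes: divergence-score overlap and enrichment.

Genes are annotated with the median Z-score of overlapping divergence
windows, membership in divergence peaks (EcoPeaks), and SNP density
(informative het sites per bp of transcript). Because power to detect
ASE grows with SNP density, all comparisons between ASE and background
genes are density-controlled: genes are grouped into equal-frequency
density bins, Z-score differences are assessed with a within-bin
label-shuffling permutation test, and peak/chromosome enrichments use
density-matched resampled gene sets.

All intervals are 0-based half-open; an overlap is >= 1 bp.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TARGET_BIN_OCCUPANCY = 23
MIN_PER_CATEGORY = 5


def snp_density(n_het_sites: int, transcript_length: int) -> float:
    """Informative heterozygous sites per bp of transcript."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    if n_het_sites < 0:
        raise ValueError("n_het_sites must be non-negative")
    return n_het_sites / transcript_length


def _overlap_lists(genes: pd.DataFrame, intervals: pd.DataFrame) -> list[np.ndarray]:
    """For each gene row, the row indices of intervals overlapping it by >= 1 bp."""
    out: list[np.ndarray] = [np.array([], dtype=np.intp)] * len(genes)
    if len(intervals) == 0:
        return out
    gene_pos = np.arange(len(genes))
    for chrom, g in genes.groupby("chrom", sort=False):
        ivals = intervals[intervals["chrom"] == chrom]
        if ivals.empty:
            continue
        gs = g["start"].to_numpy()
        ge = g["end"].to_numpy()
        istart = ivals["start"].to_numpy()
        iend = ivals["end"].to_numpy()
        rows = ivals.index.to_numpy()
        mask = (gs[:, None] < iend[None, :]) & (ge[:, None] > istart[None, :])
        for local, orig in enumerate(gene_pos[genes["chrom"].to_numpy() == chrom]):
            out[orig] = rows[mask[local]]
    return out


def annotate_genes(
    genes: pd.DataFrame,
    css_windows: pd.DataFrame | None = None,
    ecopeaks: pd.DataFrame | None = None,
    site_counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-gene genomic summary.

    ``genes`` is an interval table (one row per gene, ``name`` = gene id).
    The summary records the median score of overlapping divergence
    windows (NaN when no window overlaps), EcoPeak membership and names,
    het-site counts from ``site_counts`` and the resulting SNP density
    over the gene interval length.
    """
    out = pd.DataFrame(
        {
            "gene_id": genes["name"].to_numpy(),
            "chrom": genes["chrom"].to_numpy(),
            "start": genes["start"].to_numpy(),
            "end": genes["end"].to_numpy(),
        }
    )
    out["length"] = out["end"] - out["start"]

    if site_counts is not None:
        per_gene = site_counts.groupby("gene_id").size()
        out["n_het_sites"] = out["gene_id"].map(per_gene).fillna(0).astype(int)
    else:
        out["n_het_sites"] = 0
    out["snp_density"] = [
        snp_density(n, length) for n, length in zip(out["n_het_sites"], out["length"])
    ]

    if css_windows is not None and len(css_windows):
        overlaps = _overlap_lists(genes.reset_index(drop=True), css_windows)
        scores = css_windows["score"].to_numpy()
        out["css_z"] = [
            float(np.median(scores[idx])) if len(idx) else np.nan for idx in overlaps
        ]
        out["n_css_windows"] = [len(idx) for idx in overlaps]
    else:
        out["css_z"] = np.nan
        out["n_css_windows"] = 0

    if ecopeaks is not None and len(ecopeaks):
        overlaps = _overlap_lists(genes.reset_index(drop=True), ecopeaks)
        names = ecopeaks["name"].to_numpy()
        out["in_ecopeak"] = [len(idx) > 0 for idx in overlaps]
        out["ecopeaks"] = [",".join(names[idx]) for idx in overlaps]
    else:
        out["in_ecopeak"] = False
        out["ecopeaks"] = ""
    return out


def bin_by_density(
    summaries: pd.DataFrame,
    ase_genes,
    target_bin_occupancy: int = TARGET_BIN_OCCUPANCY,
    min_per_category: int = MIN_PER_CATEGORY,
) -> pd.DataFrame:
    """Assign equal-frequency SNP-density bins and drop under-filled bins.

    Adds ``is_ase``, ``density_bin_raw`` (quantile bin, used for matched
    resampling) and ``density_bin`` (-1 for bins with fewer than
    ``min_per_category`` genes in either category, which are excluded
    from the Z-score permutation test).
    """
    out = summaries.copy()
    ase_genes = set(ase_genes)
    out["is_ase"] = out["gene_id"].isin(ase_genes)
    n = len(out)
    if n < 2 * min_per_category:
        raise ValueError("too few genes to form a single usable density bin")
    n_bins = max(1, int(round(n / target_bin_occupancy)))
    # rank-based qcut is deterministic and independent of row order
    ranks = out["snp_density"].rank(method="first")
    out["density_bin_raw"] = pd.qcut(ranks, q=n_bins, labels=False, duplicates="drop")
    out["density_bin_raw"] = out["density_bin_raw"].astype(int)

    out["density_bin"] = out["density_bin_raw"]
    counts = out.groupby(["density_bin_raw", "is_ase"]).size().unstack(fill_value=0)
    for bin_id, row in counts.iterrows():
        n_ase = int(row.get(True, 0))
        n_bg = int(row.get(False, 0))
        if n_ase < min_per_category or n_bg < min_per_category:
            out.loc[out["density_bin_raw"] == bin_id, "density_bin"] = -1
            logger.info(
                "density bin %d dropped (%d ASE, %d background genes)", bin_id, n_ase, n_bg
            )
    if (out["density_bin"] == -1).all():
        raise ValueError("all density bins were dropped; nothing to test")
    return out


def binned_permutation_test(
    binned: pd.DataFrame, n_perm: int = 10000, seed: int | None = None
) -> dict:
    """Within-bin label-shuffling test of ASE versus background Z-scores.

    The observed statistic is the median across surviving bins of
    (median Z of ASE genes - median Z of background genes); within each
    bin the ASE labels are shuffled, preserving category counts, and the
    statistic recomputed ``n_perm`` times. Two-sided
    ``perm_p = (b + 1) / (n_perm + 1)`` on ``|stat| >= |observed|``.
    """
    rng = np.random.default_rng(seed)
    usable = binned[(binned["density_bin"] >= 0) & binned["css_z"].notna()]
    bins = sorted(usable["density_bin"].unique())
    if not bins:
        raise ValueError("no usable density bin with Z-scores")

    per_bin_rows = []
    diffs = np.empty((n_perm, len(bins)))
    observed = np.empty(len(bins))
    for j, bin_id in enumerate(bins):
        sub = usable[usable["density_bin"] == bin_id]
        z = sub["css_z"].to_numpy(dtype=float)
        is_ase = sub["is_ase"].to_numpy(dtype=bool)
        k = int(is_ase.sum())
        obs_diff = float(np.median(z[is_ase]) - np.median(z[~is_ase]))
        observed[j] = obs_diff
        per_bin_rows.append(
            {
                "density_bin": bin_id,
                "n_ase": k,
                "n_background": int(len(z) - k),
                "median_z_ase": float(np.median(z[is_ase])),
                "median_z_background": float(np.median(z[~is_ase])),
                "median_diff": obs_diff,
            }
        )
        order = np.argsort(rng.random((n_perm, len(z))), axis=1)
        shuffled = z[order]
        diffs[:, j] = np.median(shuffled[:, :k], axis=1) - np.median(
            shuffled[:, k:], axis=1
        )

    observed_stat = float(np.median(observed))
    perm_stats = np.median(diffs, axis=1)
    b = int((np.abs(perm_stats) >= abs(observed_stat)).sum())
    return {
        "per_bin": pd.DataFrame(per_bin_rows),
        "observed_statistic": observed_stat,
        "perm_p": (b + 1) / (n_perm + 1),
        "n_permutations": n_perm,
    }


def _density_matched_samples(
    binned: pd.DataFrame,
    n_resample: int,
    rng: np.random.Generator,
    pool: str = "all",
) -> np.ndarray:
    """Indices (n_resample, n_ase_total) of density-matched control gene sets.

    For every raw density bin, draws as many genes as the bin has ASE
    genes. With ``pool='all'`` (default) controls are drawn from every
    gene in the bin, which makes the observed ASE set exchangeable with
    the controls under the no-enrichment null; ``pool='background'``
    draws from non-ASE genes only (with replacement when a bin has too
    few, logged). Row indices refer to ``binned``'s positional order.
    """
    if pool not in {"all", "background"}:
        raise ValueError(f"unknown resampling pool {pool!r}")
    pieces = []
    for bin_id, sub in binned.groupby("density_bin_raw", sort=True):
        pos = np.flatnonzero((binned["density_bin_raw"] == bin_id).to_numpy())
        is_ase = sub["is_ase"].to_numpy(dtype=bool)
        c = int(is_ase.sum())
        if c == 0:
            continue
        candidates = pos if pool == "all" else pos[~is_ase]
        if len(candidates) == 0:
            logger.warning(
                "density bin %s has no background genes; matched with its own ASE genes",
                bin_id,
            )
            candidates = pos[is_ase]
        if len(candidates) >= c:
            order = np.argsort(rng.random((n_resample, len(candidates))), axis=1)[:, :c]
            pieces.append(candidates[order])
        else:
            logger.info(
                "density bin %s: %d background genes for %d ASE genes; sampling with replacement",
                bin_id, len(candidates), c,
            )
            pieces.append(candidates[rng.integers(0, len(candidates), size=(n_resample, c))])
    if not pieces:
        raise ValueError("no ASE genes to match")
    return np.concatenate(pieces, axis=1)


def ecopeak_enrichment(
    binned: pd.DataFrame, n_resample: int = 1000, seed: int | None = None
) -> dict:
    """Fold enrichment of ASE genes inside EcoPeaks versus density-matched sets.

    Two resampling pools serve two different purposes:

    * the fold (and its CI) compares the observed in-peak ASE count with
      density-matched sets drawn from the *background* (non-ASE) genes, so
      it estimates how much more often ASE genes sit in peaks than
      comparable background genes;
    * the p-value compares against density-matched sets drawn from *all*
      genes, under which the observed ASE set is exchangeable with the
      controls, giving a valid ``p = (b + 1) / (n_resample + 1)`` on
      resampled in-peak count >= observed.
    """
    rng = np.random.default_rng(seed)
    in_peak = binned["in_ecopeak"].to_numpy(dtype=bool)
    is_ase = binned["is_ase"].to_numpy(dtype=bool)
    observed = int((in_peak & is_ase).sum())

    bg_samples = _density_matched_samples(binned, n_resample, rng, pool="background")
    bg_counts = in_peak[bg_samples].sum(axis=1)
    mean_bg = float(bg_counts.mean())
    fold = observed / mean_bg if mean_bg > 0 else np.inf
    q025, q975 = np.quantile(bg_counts, [0.025, 0.975])

    all_samples = _density_matched_samples(binned, n_resample, rng, pool="all")
    all_counts = in_peak[all_samples].sum(axis=1)
    b = int((all_counts >= observed).sum())

    return {
        "n_ase": int(is_ase.sum()),
        "observed_in_peak": observed,
        "expected_in_peak": mean_bg,
        "fold": float(fold),
        "fold_ci_low": float(observed / q975) if q975 > 0 else np.inf,
        "fold_ci_high": float(observed / q025) if q025 > 0 else np.inf,
        "p": (b + 1) / (n_resample + 1),
        "n_resample": n_resample,
    }


def chromosome_enrichment(
    binned: pd.DataFrame, n_resample: int = 1000, seed: int | None = None,
    pool: str = "all",
) -> pd.DataFrame:
    """Per-chromosome ASE gene counts versus density-matched resampled sets."""
    if binned["chrom"].nunique() < 2:
        raise ValueError("chromosome enrichment requires >= 2 chromosomes")
    rng = np.random.default_rng(seed)
    chrom_codes, chrom_names = pd.factorize(binned["chrom"], sort=True)
    is_ase = binned["is_ase"].to_numpy(dtype=bool)
    n_chrom = len(chrom_names)
    observed = np.bincount(chrom_codes[is_ase], minlength=n_chrom)
    samples = _density_matched_samples(binned, n_resample, rng, pool=pool)
    sample_codes = chrom_codes[samples]  # (n_resample, n_ase)
    counts = np.stack(
        [np.bincount(row, minlength=n_chrom) for row in sample_codes], axis=0
    )
    rows = []
    for j, chrom in enumerate(chrom_names):
        b = int((counts[:, j] >= observed[j]).sum())
        rows.append(
            {
                "chrom": chrom,
                "observed": int(observed[j]),
                "expected": float(counts[:, j].mean()),
                "p": (b + 1) / (n_resample + 1),
            }
        )
    return pd.DataFrame(rows)


def candidate_table(
    ase_results: pd.DataFrame,
    summaries: pd.DataFrame,
    qtl: pd.DataFrame,
) -> pd.DataFrame:
    """ASE genes inside an EcoPeak that also overlap >= 1 QTL interval.

    One row per candidate gene, listing the tissues (``tissue@timepoint``)
    in which ASE was called, the overlapping EcoPeak names, and the
    overlapping QTL names.
    """
    ase = ase_results[ase_results["is_ase"]].copy()
    ase["unit"] = [f"{t}@{tp}" for t, tp in zip(ase["tissue"], ase["timepoint"])]
    tissues_per_gene = ase.groupby("gene_id")["unit"].apply(lambda u: ",".join(sorted(u)))

    genes = summaries.rename(columns={"gene_id": "name"})[
        ["chrom", "start", "end", "name"]
    ].reset_index(drop=True)
    qtl_overlaps = _overlap_lists(genes, qtl)
    qtl_names = qtl["name"].to_numpy()

    rows = []
    for pos, row in summaries.reset_index(drop=True).iterrows():
        gene = row["gene_id"]
        if gene not in tissues_per_gene.index or not row["in_ecopeak"]:
            continue
        overlapping = qtl_overlaps[pos]
        if len(overlapping) == 0:
            continue
        rows.append(
            {
                "gene_id": gene,
                "chrom": row["chrom"],
                "start": row["start"],
                "end": row["end"],
                "ase_tissues": tissues_per_gene.loc[gene],
                "ecopeaks": row["ecopeaks"],
                "qtls": ",".join(sorted(qtl_names[overlapping])),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "ase_tissues", "ecopeaks", "qtls"]
    )
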