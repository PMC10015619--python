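"""Gene-set sign test for lineage-specific selection on cis-regulation.

ASE genes are assigned a direction (marine-up or freshwater-up) from the
sign of their log2 fold change; in grouped-tissue analyses genes whose
sign conflicts between member tissues are discarded. Each gene set is
tested for directional bias against the background of all
direction-assigned ASE genes with a two-sided Fisher's exact test, and
an empirical p-value is obtained by shuffling the gene-to-set assignment
(directions fixed) and re-testing. For grouped analyses, per-tissue
Fisher p-values can also be combined with Fisher's method, and
categories significant under both the permutation and combined tests are
reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from asekit.io import GeneSetCollection

logger = logging.getLogger(__name__)

MIN_SET_MEMBERS = 10

FRESHWATER_UP = "freshwater_up"
MARINE_UP = "marine_up"


def assign_directions(ase_results: pd.DataFrame, unit_tissues: list[str] | str) -> pd.DataFrame:
    """Assign one ASE direction per gene for a tissue or tissue group.

    ``ase_results`` is the per-tissue-timepoint table from
    :func:`asekit.calling.ase_test`; ``unit_tissues`` selects one
    ``tissue@timepoint`` unit or a list of them (a group). Under the
    marine/freshwater lfc convention, lfc > 0 means the marine allele is
    upregulated. Genes with conflicting signs across group tissues are
    discarded with reason ``sign-conflict``.
    """
    if isinstance(unit_tissues, str):
        unit_tissues = [unit_tissues]
    work = ase_results.copy()
    work["unit"] = [f"{t}@{tp}" for t, tp in zip(work["tissue"], work["timepoint"])]
    known = set(work["unit"])
    missing = [u for u in unit_tissues if u not in known]
    if missing:
        raise ValueError(f"unknown analysis unit(s): {missing}; available: {sorted(known)}")
    sub = work[work["unit"].isin(set(unit_tissues)) & work["is_ase"]]

    rows = []
    for gene_id, g in sub.groupby("gene_id", sort=True):
        signs = {int(np.sign(v)) for v in g["lfc"] if v != 0}
        if len(signs) != 1:
            reason = "sign-conflict" if len(signs) > 1 else "zero-lfc"
            rows.append({"gene_id": gene_id, "direction": "", "discarded": True, "reason": reason})
            continue
        direction = MARINE_UP if signs.pop() > 0 else FRESHWATER_UP
        rows.append({"gene_id": gene_id, "direction": direction, "discarded": False, "reason": ""})
    out = pd.DataFrame(rows, columns=["gene_id", "direction", "discarded", "reason"])
    n_disc = int(out["discarded"].sum()) if len(out) else 0
    if n_disc:
        logger.info("direction assignment: discarded %d sign-conflicted genes", n_disc)
    return out


def _direction_arrays(directions: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(gene_ids, is_freshwater_up) for the usable (non-discarded) genes."""
    usable = directions[~directions["discarded"]]
    genes = usable["gene_id"].to_numpy()
    is_fw = (usable["direction"] == FRESHWATER_UP).to_numpy()
    return genes, is_fw


def _two_sided_fisher_table(
    set_size: int, K_fw: int, K_m: int, exclude_set_from_background: bool
) -> np.ndarray:
    """Two-sided Fisher p for every possible in-set freshwater count.

    Entry k is the p-value of the 2x2 table [[k, m-k], [K_fw-k, K_m-(m-k)]]
    (minimum-likelihood rule, matching ``scipy.stats.fisher_exact``).
    The hypergeometric null is identical whether or not the set's own
    genes are subtracted from the background margins, so one table serves
    both conventions.
    """
    N = K_fw + K_m
    m = set_size
    support = np.arange(max(0, m - K_m), min(m, K_fw) + 1)
    pmf = stats.hypergeom.pmf(support, N, K_fw, m)
    out = np.full(m + 1, np.nan)
    order = np.sort(pmf)
    csum = np.cumsum(order)
    ranks = np.searchsorted(order, pmf * (1 + 1e-7), side="right")
    out[support] = np.minimum(csum[ranks - 1], 1.0)
    return out


@dataclass
class SignTestResult:
    set_id: str
    unit: str
    n_members: int
    k_freshwater_up: int
    k_marine_up: int
    K_freshwater_up: int
    K_marine_up: int
    fisher_p: float
    skipped: bool = False
    skip_reason: str = ""


def set_sign_test(
    members,
    directions: pd.DataFrame,
    min_members: int = MIN_SET_MEMBERS,
    exclude_set_from_background: bool = False,
    unit: str = "",
    set_id: str = "",
) -> SignTestResult:
    """Fisher's exact test of one gene set's direction bias against background.

    The background is all direction-assigned ASE genes in the unit; by
    default the set's own genes are included in the background margins
    (``exclude_set_from_background=True`` subtracts them). Sets with fewer
    than ``min_members`` direction-assigned members are skipped with
    reason ``min-members``.
    """
    genes, is_fw = _direction_arrays(directions)
    if len(genes) == 0:
        raise ValueError("empty background: no direction-assigned genes")
    member_mask = np.isin(genes, np.asarray(list(members), dtype=genes.dtype))
    k_fw = int(is_fw[member_mask].sum())
    k_m = int(member_mask.sum() - k_fw)
    K_fw = int(is_fw.sum())
    K_m = int(len(genes) - K_fw)
    n_members = k_fw + k_m
    result = SignTestResult(
        set_id=set_id,
        unit=unit,
        n_members=n_members,
        k_freshwater_up=k_fw,
        k_marine_up=k_m,
        K_freshwater_up=K_fw,
        K_marine_up=K_m,
        fisher_p=np.nan,
    )
    if n_members < min_members:
        result.skipped = True
        result.skip_reason = "min-members"
        return result
    # The 2x2 table is in-set versus out-of-set rows; whether the K totals
    # are quoted with or without the set's own genes, the table itself is
    # [[k_fw, k_m], [K_fw - k_fw, K_m - k_m]]. The flag only changes the
    # reported margins.
    table = [[k_fw, k_m], [K_fw - k_fw, K_m - k_m]]
    if exclude_set_from_background:
        result.K_freshwater_up = K_fw - k_fw
        result.K_marine_up = K_m - k_m
    result.fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    return result


def permutation_test(
    sets: GeneSetCollection | dict,
    directions: pd.DataFrame,
    n_perm: int = 10000,
    seed: int | None = None,
    min_members: int = MIN_SET_MEMBERS,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Category-shuffle permutation p-values for every eligible gene set.

    Gene-to-set assignment labels are shuffled jointly (one permuted gene
    map per iteration, shared by all sets, preserving inter-set overlap),
    directions stay fixed, and each set's Fisher p is recomputed;
    ``perm_p = (b + 1) / (n_perm + 1)`` where b counts permutations with a
    Fisher p at or below the observed one.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    set_items = sets.items() if hasattr(sets, "items") else dict(sets).items()
    genes, is_fw = _direction_arrays(directions)
    if len(genes) == 0:
        raise ValueError("empty background: no direction-assigned genes")
    K_fw = int(is_fw.sum())
    K_m = int(len(genes) - K_fw)
    gene_pos = {g: i for i, g in enumerate(genes)}

    eligible = []
    rows = []
    for set_id, members in sorted(set_items):
        idx = np.array([gene_pos[g] for g in members if g in gene_pos], dtype=np.intp)
        m = len(idx)
        if m < min_members:
            rows.append(
                {
                    "set_id": set_id,
                    "n_members": m,
                    "k_freshwater_up": int(is_fw[idx].sum()),
                    "k_marine_up": int(m - is_fw[idx].sum()),
                    "K_freshwater_up": K_fw,
                    "K_marine_up": K_m,
                    "fisher_p": np.nan,
                    "perm_p": np.nan,
                    "n_permutations": 0,
                    "skipped": True,
                    "skip_reason": "min-members",
                }
            )
            continue
        eligible.append((set_id, idx))

    if eligible:
        p_tables = {
            m: _two_sided_fisher_table(m, K_fw, K_m, exclude_set_from_background=False)
            for m in sorted({len(idx) for _, idx in eligible})
        }
        sizes = np.array([len(idx) for _, idx in eligible])
        # padded per-set lookup of Fisher p by in-set freshwater count
        lookup = np.full((len(eligible), int(sizes.max()) + 1), np.nan)
        for j, (_, idx) in enumerate(eligible):
            lookup[j, : sizes[j] + 1] = p_tables[sizes[j]]
        observed_k = np.array([int(is_fw[idx].sum()) for _, idx in eligible])
        observed_p = lookup[np.arange(len(eligible)), observed_k]

        all_idx = np.concatenate([idx for _, idx in eligible])
        offsets = np.concatenate([[0], np.cumsum(sizes[:-1])])
        fw_int = is_fw.astype(np.int64)
        exceed = np.zeros(len(eligible), dtype=np.int64)
        for _ in range(n_perm):
            permuted = fw_int[rng.permutation(len(genes))]
            ks = np.add.reduceat(permuted[all_idx], offsets)
            exceed += lookup[np.arange(len(eligible)), ks] <= observed_p
        for j, (set_id, idx) in enumerate(eligible):
            rows.append(
                {
                    "set_id": set_id,
                    "n_members": int(sizes[j]),
                    "k_freshwater_up": int(observed_k[j]),
                    "k_marine_up": int(sizes[j] - observed_k[j]),
                    "K_freshwater_up": K_fw,
                    "K_marine_up": K_m,
                    "fisher_p": float(observed_p[j]),
                    "perm_p": (int(exceed[j]) + 1) / (n_perm + 1),
                    "n_permutations": n_perm,
                    "skipped": False,
                    "skip_reason": "",
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_id",
            "n_members",
            "k_freshwater_up",
            "k_marine_up",
            "K_freshwater_up",
            "K_marine_up",
            "fisher_p",
            "perm_p",
            "n_permutations",
            "skipped",
            "skip_reason",
        ],
    )
    return out.sort_values("set_id").reset_index(drop=True)


def combine_group_pvalues(p_values) -> float:
    """Fisher's method: X^2 = -2 sum(ln p), df = 2k, upper-tail chi-square."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.isnan(p).any():
        raise ValueError("NaN p-values cannot be combined")
    if (p <= 0).any():
        raise ValueError("p-values must be > 0 (floor at machine epsilon upstream)")
    if (p > 1).any():
        raise ValueError("p-values must be <= 1")
    x2 = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x2, df=2 * p.size))


def combined_tissue_test(
    sets: GeneSetCollection | dict,
    ase_results: pd.DataFrame,
    group_tissues: list[str],
    min_members: int = MIN_SET_MEMBERS,
) -> pd.DataFrame:
    """Per-tissue Fisher tests combined across a tissue group.

    Each member tissue is tested separately; only categories eligible
    (>= ``min_members`` direction-assigned members) in every tissue of the
    group receive a combined p-value.
    """
    set_items = dict(sets.items() if hasattr(sets, "items") else dict(sets).items())
    per_tissue: dict[str, dict[str, float]] = {}
    for unit in group_tissues:
        directions = assign_directions(ase_results, unit)
        for set_id, members in set_items.items():
            res = set_sign_test(
                members, directions, min_members=min_members, unit=unit, set_id=set_id
            )
            if not res.skipped:
                per_tissue.setdefault(set_id, {})[unit] = max(
                    res.fisher_p, np.finfo(float).tiny
                )
    rows = []
    for set_id in sorted(set_items):
        tissue_ps = per_tissue.get(set_id, {})
        if len(tissue_ps) == len(group_tissues):
            combined = combine_group_pvalues(list(tissue_ps.values()))
            rows.append(
                {"set_id": set_id, "n_tissues": len(tissue_ps), "combined_p": combined}
            )
        else:
            rows.append({"set_id": set_id, "n_tissues": len(tissue_ps), "combined_p": np.nan})
    return pd.DataFrame(rows, columns=["set_id", "n_tissues", "combined_p"])


def dual_criterion_report(
    perm_results: pd.DataFrame, combined_results: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Flag categories significant under both the group permutation test and
    the combined per-tissue test at ``alpha``."""
    merged = perm_results.merge(combined_results, on="set_id", how="outer")
    merged["pass_permutation"] = merged["perm_p"] < alpha
    merged["pass_combined"] = merged["combined_p"] < alpha
    merged["pass_permutation"] = merged["pass_permutation"].fillna(False).astype(bool)
    merged["pass_combined"] = merged["pass_combined"].fillna(False).astype(bool)
    merged["flagged"] = merged["pass_permutation"] & merged["pass_combined"]
    return merged.sort_values("set_id").reset_index(drop=True)
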