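"""Bayesian multi-tissue classification of allele-specific expression.

Each gene's allelic counts (marine reads x out of n total, summed across
replicates per tissue) are scored under three allelic-fraction states:

* ``N`` — no ASE, theta ~ Beta(2000, 2000)
* ``M`` — moderate ASE, theta ~ 1/2 Beta(80, 36) + 1/2 Beta(36, 80)
* ``S`` — strong ASE, theta ~ 1/2 Beta(80, 7) + 1/2 Beta(7, 80)

A gene's multi-tissue configuration is a vector of states over its
included tissues; with a uniform prior over the 3^T configurations the
posterior factorizes across tissues, so class posteriors are computed
exactly without enumerating configurations. Classes partition all
configurations:

* ``NOASE``       — all tissues N
* ``UNIFORM_ASE`` — all tissues M, or all tissues S
* ``HET0``        — at least one ASE tissue and at least one N tissue
* ``HET1``        — all tissues ASE but not all the same state
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special

STATES = ("N", "M", "S")

CLASSES = ("NOASE", "UNIFORM_ASE", "HET0", "HET1")

_DEFAULT_COMPONENTS: dict[str, tuple[tuple[float, float, float], ...]] = {
    "N": ((1.0, 2000.0, 2000.0),),
    "M": ((0.5, 80.0, 36.0), (0.5, 36.0, 80.0)),
    "S": ((0.5, 80.0, 7.0), (0.5, 7.0, 80.0)),
}


@dataclass(frozen=True)
class PriorSpec:
    """Weighted Beta-mixture priors for the allelic fraction of each state.

    ``components[state]`` is a tuple of ``(weight, alpha, beta)`` triples;
    weights for each state must sum to 1.
    """

    components: dict[str, tuple[tuple[float, float, float], ...]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPONENTS)
    )

    def __post_init__(self):
        for state in STATES:
            if state not in self.components:
                raise ValueError(f"priors missing state {state!r}")
            comps = self.components[state]
            total = sum(w for w, _, _ in comps)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"state {state!r}: component weights sum to {total}, not 1")
            for w, a, b in comps:
                if not (w > 0 and a > 0 and b > 0):
                    raise ValueError(f"state {state!r}: weights and Beta parameters must be positive")

    @classmethod
    def from_file(cls, path) -> "PriorSpec":
        """Parse a priors file with one line per component: ``state weight alpha beta``."""
        components: dict[str, list[tuple[float, float, float]]] = {}
        with open(path) as handle:
            for raw in handle:
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                state, w, a, b = line.split()
                components.setdefault(state, []).append((float(w), float(a), float(b)))
        return cls({state: tuple(comps) for state, comps in components.items()})


def default_priors() -> PriorSpec:
    return PriorSpec()


def prior_density(theta, state: str, priors: PriorSpec | None = None):
    """Density of the Beta-mixture prior for ``state`` at allelic fraction ``theta``."""
    priors = priors or default_priors()
    theta = np.asarray(theta, dtype=float)
    if np.any(theta <= 0) or np.any(theta >= 1):
        raise ValueError("theta must lie strictly inside (0, 1)")
    log_parts = []
    for w, a, b in priors.components[state]:
        log_parts.append(
            np.log(w)
            + (a - 1) * np.log(theta)
            + (b - 1) * np.log1p(-theta)
            - special.betaln(a, b)
        )
    out = special.logsumexp(np.stack(log_parts, axis=0), axis=0)
    return np.exp(out)


def dominance_interval(
    priors: PriorSpec | None = None, state: str = "N", rounding: int | None = 2
) -> tuple[float, float]:
    """Contiguous interval around 0.5 where ``state``'s prior density strictly
    exceeds the densities of both other states.

    Endpoints are located by bisection to 1e-6 and then rounded
    (``rounding=None`` returns raw endpoints). Raises if the state does
    not dominate at 0.5.
    """
    priors = priors or default_priors()
    others = [s for s in STATES if s != state]

    def margin(theta: float) -> float:
        own = prior_density(theta, state, priors)
        best_other = max(float(prior_density(theta, s, priors)) for s in others)
        return float(own) - best_other

    center = 0.5
    if margin(center) <= 0:
        raise ValueError(f"state {state!r} does not dominate at theta=0.5")

    eps = 1e-9

    def crossing(lo: float, hi: float) -> float:
        return float(optimize.brentq(margin, lo, hi, xtol=1e-6))

    # scan outward for a sign change on each side before bisecting
    def find_bracket(direction: int) -> float:
        step = 0.01
        prev = center
        theta = center + direction * step
        while eps < theta < 1 - eps:
            if margin(theta) <= 0:
                return crossing(*sorted((prev, theta)))
            prev = theta
            theta += direction * step
        raise ValueError(f"state {state!r} dominates all the way to the boundary")

    low = find_bracket(-1)
    high = find_bracket(+1)
    if rounding is not None:
        low, high = round(low, rounding), round(high, rounding)
    return low, high


def log_marginal(x, n, state: str, priors: PriorSpec | None = None):
    """Log marginal likelihood of ``x`` marine reads out of ``n`` under a state.

    Computes ``log sum_k w_k C(n,x) B(x+a_k, n-x+b_k) / B(a_k, b_k)`` in
    log space via log-gamma; finite for all valid inputs (0 for n=0).
    """
    priors = priors or default_priors()
    x = np.asarray(x, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(x < 0) or np.any(n < 0) or np.any(x > n):
        raise ValueError("counts must satisfy 0 <= x <= n")
    log_choose = special.gammaln(n + 1) - special.gammaln(x + 1) - special.gammaln(n - x + 1)
    parts = []
    for w, a, b in priors.components[state]:
        parts.append(
            np.log(w) + special.betaln(x + a, n - x + b) - special.betaln(a, b)
        )
    out = log_choose + special.logsumexp(np.stack(parts, axis=0), axis=0)
    return out if out.shape else float(out)


def state_log_marginals(
    x, n, priors: PriorSpec | None = None
) -> np.ndarray:
    """Stack of log marginals for states (N, M, S); shape (3,) + shape(x)."""
    priors = priors or default_priors()
    return np.stack([log_marginal(x, n, s, priors) for s in STATES], axis=0)


@dataclass
class GeneClassification:
    """Posterior summary of a gene's multi-tissue ASE configuration."""

    gene_id: str
    tissues: list[str]
    state_posteriors: pd.DataFrame  # tissues x (N, M, S), rows sum to 1
    class_pp: dict[str, float]
    tissue_specific_pp: pd.Series  # PP(tissue t is the only ASE tissue)
    tissue_specific_noase_pp: pd.Series  # PP(tissue t is the only N tissue)
    map_configuration: tuple[str, ...]
    unclassifiable: bool = False

    @property
    def heterogeneity_pp(self) -> float:
        return self.class_pp["HET0"] + self.class_pp["HET1"]

    @property
    def map_class(self) -> str:
        return max(CLASSES, key=lambda c: self.class_pp[c])

    def configuration_posterior(self, config: tuple[str, ...]) -> float:
        """Posterior of one full state configuration (product across tissues)."""
        if len(config) != len(self.tissues):
            raise ValueError("configuration length must match included tissues")
        prob = 1.0
        for tissue, state in zip(self.tissues, config):
            prob *= float(self.state_posteriors.loc[tissue, state])
        return prob


def _classify_from_state_posteriors(
    gene_id: str, tissues: list[str], post: np.ndarray
) -> GeneClassification:
    """Derive class posteriors from per-tissue state posteriors.

    With a uniform configuration prior the joint posterior is the product
    of per-tissue posteriors, so class masses reduce to products:
    NOASE = prod p(N); UNIFORM = prod p(M) + prod p(S);
    HET1 = prod p(ASE) - prod p(M) - prod p(S); HET0 = remainder.
    """
    p_n = post[:, 0]
    p_m = post[:, 1]
    p_s = post[:, 2]
    p_ase = p_m + p_s
    noase = float(np.prod(p_n))
    uniform = float(np.prod(p_m) + np.prod(p_s))
    all_ase = float(np.prod(p_ase))
    het1 = max(all_ase - float(np.prod(p_m)) - float(np.prod(p_s)), 0.0)
    het0 = max(1.0 - noase - all_ase, 0.0)
    class_pp = {"NOASE": noase, "UNIFORM_ASE": uniform, "HET0": het0, "HET1": het1}

    n_tissues = len(tissues)
    ts_pp = np.empty(n_tissues)
    ts_noase_pp = np.empty(n_tissues)
    for t in range(n_tissues):
        others = np.delete(np.arange(n_tissues), t)
        ts_pp[t] = p_ase[t] * np.prod(p_n[others])
        ts_noase_pp[t] = p_n[t] * np.prod(p_ase[others])

    # MAP configuration maximizes the product => per-tissue argmax;
    # ties broken lexicographically N < M < S (the stack order).
    map_config = tuple(STATES[int(np.argmax(post[t]))] for t in range(n_tissues))

    return GeneClassification(
        gene_id=gene_id,
        tissues=list(tissues),
        state_posteriors=pd.DataFrame(post, index=list(tissues), columns=list(STATES)),
        class_pp=class_pp,
        tissue_specific_pp=pd.Series(ts_pp, index=list(tissues)),
        tissue_specific_noase_pp=pd.Series(ts_noase_pp, index=list(tissues)),
        map_configuration=map_config,
    )


def classify_gene(
    gene_id: str,
    counts: pd.DataFrame,
    priors: PriorSpec | None = None,
    min_reads: int = 10,
) -> GeneClassification:
    """Classify one gene from per-tissue summed allelic counts.

    ``counts`` needs columns ``tissue, marine_count, freshwater_count``
    (already summed across replicates). Tissues where either allele has
    <= ``min_reads`` reads are excluded; genes with fewer than two
    remaining tissues are flagged unclassifiable.
    """
    priors = priors or default_priors()
    keep = (counts["marine_count"] > min_reads) & (counts["freshwater_count"] > min_reads)
    included = counts.loc[keep]
    tissues = included["tissue"].tolist()
    if len(tissues) < 2:
        empty = pd.DataFrame(columns=list(STATES), dtype=float)
        return GeneClassification(
            gene_id=gene_id,
            tissues=tissues,
            state_posteriors=empty,
            class_pp={c: np.nan for c in CLASSES},
            tissue_specific_pp=pd.Series(dtype=float),
            tissue_specific_noase_pp=pd.Series(dtype=float),
            map_configuration=(),
            unclassifiable=True,
        )
    x = included["marine_count"].to_numpy(dtype=float)
    n = x + included["freshwater_count"].to_numpy(dtype=float)
    logm = state_log_marginals(x, n, priors)  # (3, T)
    logm = logm - logm.max(axis=0, keepdims=True)
    post = np.exp(logm)
    post /= post.sum(axis=0, keepdims=True)
    return _classify_from_state_posteriors(gene_id, tissues, post.T)


def classify_all(
    counts: pd.DataFrame,
    priors: PriorSpec | None = None,
    tissues: list[str] | None = None,
    min_reads: int = 10,
    thresholds: tuple[float, ...] = (0.9, 0.95),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every eligible gene in an allelic count table.

    Counts are summed across replicates per (gene, tissue, timepoint);
    tissue labels for analysis are ``tissue@timepoint`` when a tissue
    appears at more than one timepoint, plain tissue names otherwise.
    ``tissues`` optionally restricts the analysis to a subset of those
    labels (e.g. the late-timepoint preset).

    Returns ``(per_gene_table, summary_table)``; the per-gene table has
    one row per classified gene with class posteriors, MAP labels and
    per-threshold calls.
    """
    priors = priors or default_priors()
    work = counts.copy()
    multi_tp = work.groupby("tissue")["timepoint"].nunique()
    multi = set(multi_tp.index[multi_tp > 1])
    work["unit"] = [
        f"{t}@{tp}" if t in multi else t
        for t, tp in zip(work["tissue"], work["timepoint"])
    ]
    pooled = (
        work.groupby(["gene_id", "unit"], sort=True)[["marine_count", "freshwater_count"]]
        .sum()
        .reset_index()
    )
    if tissues is not None:
        pooled = pooled[pooled["unit"].isin(set(tissues))]
    pooled = pooled.rename(columns={"unit": "tissue"})

    rows = []
    for gene_id, gene_counts in pooled.groupby("gene_id", sort=True):
        cls = classify_gene(str(gene_id), gene_counts, priors, min_reads=min_reads)
        if cls.unclassifiable:
            continue
        best_ts = cls.tissue_specific_pp.idxmax()
        row = {
            "gene_id": gene_id,
            "n_tissues": len(cls.tissues),
            "tissues": ",".join(cls.tissues),
            "pp_noase": cls.class_pp["NOASE"],
            "pp_uniform_ase": cls.class_pp["UNIFORM_ASE"],
            "pp_het0": cls.class_pp["HET0"],
            "pp_het1": cls.class_pp["HET1"],
            "pp_heterogeneity": cls.heterogeneity_pp,
            "map_class": cls.map_class,
            "map_configuration": "".join(cls.map_configuration),
            "best_tissue_specific": best_ts,
            "pp_tissue_specific": float(cls.tissue_specific_pp.max()),
            "pp_tissue_specific_noase": float(cls.tissue_specific_noase_pp.max()),
        }
        for thr in thresholds:
            tag = f"{thr:g}".replace(".", "")
            row[f"het_call_pp{tag}"] = cls.heterogeneity_pp > thr
            row[f"tissue_specific_call_pp{tag}"] = float(cls.tissue_specific_pp.max()) > thr
        rows.append(row)
    if not rows:
        raise ValueError("no gene passed the eligibility filters; nothing to classify")
    table = pd.DataFrame(rows)

    summary_rows = []
    for thr in thresholds:
        for cls_name, col in [
            ("NOASE", "pp_noase"),
            ("UNIFORM_ASE", "pp_uniform_ase"),
            ("HET0", "pp_het0"),
            ("HET1", "pp_het1"),
            ("HETEROGENEITY", "pp_heterogeneity"),
        ]:
            summary_rows.append(
                {
                    "threshold": thr,
                    "class": cls_name,
                    "n_genes": int((table[col] > thr).sum()),
                }
            )
        summary_rows.append(
            {
                "threshold": thr,
                "class": "TISSUE_SPECIFIC",
                "n_genes": int((table["pp_tissue_specific"] > thr).sum()),
            }
        )
    summary = pd.DataFrame(summary_rows)
    return table, summary
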