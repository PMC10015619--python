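"""Synthetic ASE experiments with known ground truth.

Generates every input the pipeline consumes — gene-level allelic counts
with configurable per-gene ASE classes, site-level counts, a toy genome
with divergence-score windows, peaks and QTL intervals, and gene sets
including one direction-biased set — plus ground-truth tables for
recovery and calibration tests.

The count model: each gene-tissue draws its allelic fraction theta once
from the configured state prior (shared across replicates), total depth
per replicate is negative-binomial, and marine counts are binomial given
theta. A gene's direction (marine-up versus freshwater-up) is a single
Bernoulli draw applied to all of its ASE tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from asekit.heterogeneity import PriorSpec, default_priors
from asekit.io import GeneSetCollection

CLASS_NAMES = ("NOASE", "UNIFORM_ASE", "HET0", "HET1", "TISSUE_SPECIFIC")

DEFAULT_TISSUES: tuple[tuple[str, int], ...] = (
    ("brain", 2),
    ("eyes", 2),
    ("liver", 2),
    ("flank_skin", 2),
    ("VTP", 2),
    ("DTP", 2),
    ("mandible", 2),
    ("VTP", 1),
    ("DTP", 1),
    ("mandible", 1),
)

DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "NOASE": 0.55,
    "UNIFORM_ASE": 0.15,
    "HET0": 0.12,
    "HET1": 0.08,
    "TISSUE_SPECIFIC": 0.10,
}


@dataclass
class GenomeSpec:
    """Toy genome layout used to place genes, windows, peaks and QTL."""

    n_chromosomes: int = 4
    gene_length_log_mean: float = 8.0  # lognormal parameters of gene length (bp)
    gene_length_log_sigma: float = 0.5
    intergenic_mean: float = 2000.0  # exponential gap between genes (bp)
    het_density_mean: float = 0.01  # mean het sites per bp
    het_density_shape: float = 4.0  # gamma shape of per-gene density
    css_window_size: int = 2500
    ecopeak_fraction: float = 0.10  # fraction of each chromosome inside a peak
    z_shift: float = 1.0  # added to window Z-scores inside peaks
    ase_peak_enrichment: float = 1.0  # fold placement of ASE genes into peaks
    n_qtl: int = 6
    qtl_fraction: float = 0.05  # QTL length as a fraction of its chromosome


@dataclass
class BiasedSetSpec:
    size: int = 30
    direction_bias: float = 0.9  # probability a member is freshwater-up


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    tissues: tuple[tuple[str, int], ...] = DEFAULT_TISSUES
    n_replicates: int = 2
    depth_mean: float = 100.0  # mean total reads per gene per replicate
    depth_dispersion: float = 4.0  # negative-binomial shape; larger = less overdispersed
    class_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_PROPORTIONS)
    )
    fixed_theta: dict[str, float] | None = None  # per-state theta override
    timepoint_switch_prob: float = 0.2
    biased_set: BiasedSetSpec = field(default_factory=BiasedSetSpec)
    n_null_sets: int = 20
    null_set_size_range: tuple[int, int] = (10, 50)
    genome: GenomeSpec = field(default_factory=GenomeSpec)
    seed: int = 0

    def __post_init__(self):
        for name, p in self.class_proportions.items():
            if name not in CLASS_NAMES:
                raise ValueError(f"unknown ASE class {name!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"class proportion for {name} outside [0, 1]")
        total = sum(self.class_proportions.get(c, 0.0) for c in CLASS_NAMES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions sum to {total}, not 1")
        if not 0.0 <= self.timepoint_switch_prob <= 1.0:
            raise ValueError("timepoint_switch_prob outside [0, 1]")
        if not 0.0 <= self.biased_set.direction_bias <= 1.0:
            raise ValueError("direction_bias outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "tissues" in raw:
            raw["tissues"] = tuple((str(t), int(tp)) for t, tp in raw["tissues"])
        if "genome" in raw:
            raw["genome"] = GenomeSpec(**raw["genome"])
        if "biased_set" in raw:
            raw["biased_set"] = BiasedSetSpec(**raw["biased_set"])
        if "null_set_size_range" in raw:
            raw["null_set_size_range"] = tuple(raw["null_set_size_range"])
        return cls(**raw)


@dataclass
class SimulatedExperiment:
    """Bundle of everything one simulated experiment emits."""

    config: SimulationConfig
    allelic_counts: pd.DataFrame
    site_counts: pd.DataFrame
    genes: pd.DataFrame  # interval table, kind='gene'
    css_windows: pd.DataFrame
    ecopeaks: pd.DataFrame
    qtl: pd.DataFrame
    gene_sets: GeneSetCollection
    truth_genes: pd.DataFrame  # per-gene class, direction, placement, memberships
    truth_states: pd.DataFrame  # per gene x tissue-unit state and theta


def _sample_theta(
    state: str, marine_up: bool, rng: np.random.Generator,
    priors: PriorSpec, fixed: dict[str, float] | None,
) -> float:
    """One allelic fraction for a gene-tissue.

    For ASE states the mixture component matching the gene's direction is
    used (marine-up = the component with mass above 0.5); the N state is
    direction-free. A fixed_theta override is mirrored for freshwater-up.
    """
    if fixed is not None and state in fixed:
        theta = fixed[state]
        if state != "N" and not marine_up:
            theta = 1.0 - theta
        return float(theta)
    comps = priors.components[state]
    if state == "N":
        weights = np.array([w for w, _, _ in comps])
        idx = rng.choice(len(comps), p=weights / weights.sum())
    else:
        means = np.array([a / (a + b) for _, a, b in comps])
        idx = int(np.argmax(means)) if marine_up else int(np.argmin(means))
    _, a, b = comps[idx]
    return float(rng.beta(a, b))


def _late_states(cls: str, n_tissues: int, rng: np.random.Generator) -> list[str]:
    """Per-tissue states over the late tissues for one gene of class ``cls``."""
    if cls == "NOASE":
        return ["N"] * n_tissues
    if cls == "UNIFORM_ASE":
        state = "S" if rng.random() < 0.5 else "M"
        return [state] * n_tissues
    if cls == "TISSUE_SPECIFIC":
        states = ["N"] * n_tissues
        states[int(rng.integers(n_tissues))] = "S" if rng.random() < 0.5 else "M"
        return states
    if cls == "HET0":
        n_ase = int(rng.integers(1, n_tissues))  # 1 .. T-1 ASE tissues
        state = "S" if rng.random() < 0.5 else "M"
        states = ["N"] * n_tissues
        for t in rng.choice(n_tissues, size=n_ase, replace=False):
            states[int(t)] = state
        return states
    if cls == "HET1":
        n_strong = int(rng.integers(1, n_tissues))  # both M and S present
        states = ["M"] * n_tissues
        for t in rng.choice(n_tissues, size=n_strong, replace=False):
            states[int(t)] = "S"
        return states
    raise ValueError(f"unknown class {cls!r}")


def _simulate_genome(
    config: SimulationConfig,
    gene_ids: np.ndarray,
    is_ase_gene: np.ndarray,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place genes on chromosomes and emit CSS windows, EcoPeaks and QTL.

    Gene placement first lays out equal-count gene slots per chromosome,
    marks the slots inside each chromosome's single EcoPeak, then assigns
    ASE genes to in-peak slots at ``ase_peak_enrichment`` times the
    background in-peak rate.
    """
    g = config.genome
    n_genes = len(gene_ids)
    per_chrom = np.full(g.n_chromosomes, n_genes // g.n_chromosomes)
    per_chrom[: n_genes % g.n_chromosomes] += 1

    slot_rows = []
    css_rows = []
    peak_rows = []
    qtl_chroms = rng.integers(0, g.n_chromosomes, size=g.n_qtl)
    qtl_rows = []
    for c in range(g.n_chromosomes):
        chrom = f"chr{c + 1}"
        lengths = np.ceil(
            rng.lognormal(g.gene_length_log_mean, g.gene_length_log_sigma, per_chrom[c])
        ).astype(np.int64)
        gaps = np.ceil(rng.exponential(g.intergenic_mean, per_chrom[c] + 1)).astype(np.int64)
        starts = np.cumsum(gaps[:-1]) + np.concatenate([[0], np.cumsum(lengths[:-1])])
        ends = starts + lengths
        chrom_len = int(ends[-1] + gaps[-1]) if per_chrom[c] else int(gaps[-1])

        peak_len = int(chrom_len * g.ecopeak_fraction)
        peak_start = int(rng.integers(0, max(chrom_len - peak_len, 1)))
        peak_end = peak_start + peak_len
        if peak_len > 0:
            peak_rows.append(
                {"chrom": chrom, "start": peak_start, "end": peak_end,
                 "name": f"ecopeak_{chrom}", "score": np.nan, "kind": "ecopeak"}
            )

        for s, e in zip(starts, ends):
            in_peak = s < peak_end and e > peak_start
            slot_rows.append({"chrom": chrom, "start": int(s), "end": int(e), "in_peak": in_peak})

        n_windows = max(1, int(np.ceil(chrom_len / g.css_window_size)))
        w_starts = np.arange(n_windows, dtype=np.int64) * g.css_window_size
        w_ends = np.minimum(w_starts + g.css_window_size, chrom_len)
        scores = rng.normal(0.0, 1.0, n_windows)
        centers = (w_starts + w_ends) / 2
        scores = scores + g.z_shift * ((centers >= peak_start) & (centers < peak_end))
        for ws, we, sc in zip(w_starts, w_ends, scores):
            css_rows.append(
                {"chrom": chrom, "start": int(ws), "end": int(we),
                 "name": f"css_{chrom}_{int(ws)}", "score": float(sc), "kind": "css_window"}
            )

        for q in np.flatnonzero(qtl_chroms == c):
            q_len = max(int(chrom_len * g.qtl_fraction), 1)
            q_start = int(rng.integers(0, max(chrom_len - q_len, 1)))
            qtl_rows.append(
                {"chrom": chrom, "start": q_start, "end": q_start + q_len,
                 "name": f"qtl_{q + 1}", "score": np.nan, "kind": "qtl"}
            )

    slots = pd.DataFrame(slot_rows)
    in_peak = slots["in_peak"].to_numpy()
    n_peak_slots = int(in_peak.sum())
    n_ase = int(is_ase_gene.sum())
    n_bg = n_genes - n_ase
    # q_ase / q_bg = enrichment with total in-peak occupancy preserved
    q_bg = n_peak_slots / (g.ase_peak_enrichment * n_ase + n_bg) if n_genes else 0.0
    q_ase = g.ase_peak_enrichment * q_bg
    if q_ase > 1.0 + 1e-9:
        raise ValueError(
            f"infeasible placement: enrichment {g.ase_peak_enrichment} requires "
            f"{q_ase:.2f} of ASE genes inside peaks"
        )
    k_ase = min(int(round(q_ase * n_ase)), n_peak_slots)

    peak_slots = np.flatnonzero(in_peak)
    out_slots = np.flatnonzero(~in_peak)
    ase_idx = np.flatnonzero(is_ase_gene)
    bg_idx = np.flatnonzero(~is_ase_gene)
    ase_in_peak = rng.choice(ase_idx, size=k_ase, replace=False) if k_ase else np.array([], dtype=np.intp)
    ase_out = np.setdiff1d(ase_idx, ase_in_peak)
    k_bg = n_peak_slots - k_ase
    bg_in_peak = rng.choice(bg_idx, size=k_bg, replace=False) if k_bg else np.array([], dtype=np.intp)
    bg_out = np.setdiff1d(bg_idx, bg_in_peak)

    assignment = np.empty(n_genes, dtype=np.intp)  # gene index -> slot index
    in_peak_genes = np.concatenate([ase_in_peak, bg_in_peak])
    out_genes = np.concatenate([ase_out, bg_out])
    assignment[in_peak_genes] = rng.permutation(peak_slots)
    assignment[out_genes] = rng.permutation(out_slots)

    genes = pd.DataFrame(
        {
            "chrom": slots["chrom"].to_numpy()[assignment],
            "start": slots["start"].to_numpy()[assignment],
            "end": slots["end"].to_numpy()[assignment],
            "name": gene_ids,
            "score": np.nan,
            "kind": "gene",
        }
    )
    css = pd.DataFrame(css_rows)
    peaks = pd.DataFrame(peak_rows)
    qtl = pd.DataFrame(qtl_rows, columns=["chrom", "start", "end", "name", "score", "kind"])
    return genes, css, peaks, qtl


def simulate_experiment(config: SimulationConfig | None = None) -> SimulatedExperiment:
    """Simulate a complete experiment from a :class:`SimulationConfig`.

    Deterministic given ``config.seed``: the same config produces
    byte-identical tables.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    priors = default_priors()
    g = config

    gene_ids = np.array([f"gene{idx:05d}" for idx in range(g.n_genes)])
    class_names = list(CLASS_NAMES)
    probs = np.array([g.class_proportions.get(c, 0.0) for c in class_names])
    classes = rng.choice(class_names, size=g.n_genes, p=probs / probs.sum())
    marine_up = rng.random(g.n_genes) < 0.5

    late_units = [(t, tp) for t, tp in g.tissues if tp == 2]
    early_units = [(t, tp) for t, tp in g.tissues if tp != 2]
    late_names = [t for t, _ in late_units]
    n_late = len(late_units)

    # per-gene per-unit states and thetas
    state_rows = []
    for i, gene in enumerate(gene_ids):
        states = _late_states(classes[i], n_late, rng)
        by_tissue = dict(zip(late_names, states))
        for (tissue, tp), state in zip(late_units, states):
            theta = _sample_theta(state, marine_up[i], rng, priors, g.fixed_theta)
            state_rows.append(
                {"gene_id": gene, "tissue": tissue, "timepoint": tp,
                 "true_state": state, "true_theta": theta}
            )
        for tissue, tp in early_units:
            state = by_tissue.get(tissue, "N")
            if rng.random() < g.timepoint_switch_prob:
                state = ("S" if rng.random() < 0.5 else "M") if state == "N" else "N"
            theta = _sample_theta(state, marine_up[i], rng, priors, g.fixed_theta)
            state_rows.append(
                {"gene_id": gene, "tissue": tissue, "timepoint": tp,
                 "true_state": state, "true_theta": theta}
            )
    truth_states = pd.DataFrame(state_rows)

    # allelic counts: NB depth per replicate, binomial split at theta
    n_units = len(g.tissues)
    thetas = truth_states["true_theta"].to_numpy()
    count_frames = []
    p_nb = g.depth_dispersion / (g.depth_dispersion + g.depth_mean)
    for rep in range(1, g.n_replicates + 1):
        depth = rng.negative_binomial(g.depth_dispersion, p_nb, size=len(truth_states))
        marine = rng.binomial(depth, thetas)
        count_frames.append(
            pd.DataFrame(
                {
                    "gene_id": truth_states["gene_id"],
                    "tissue": truth_states["tissue"],
                    "timepoint": truth_states["timepoint"],
                    "replicate": rep,
                    "marine_count": marine,
                    "freshwater_count": depth - marine,
                }
            )
        )
    allelic_counts = (
        pd.concat(count_frames, ignore_index=True)
        .sort_values(["gene_id", "tissue", "timepoint", "replicate"])
        .reset_index(drop=True)
    )

    # genome and interval sets; peak placement enriches genes with ASE in
    # ANY unit (early-timepoint switches included), matching how ASE genes
    # are counted downstream
    any_ase = (
        truth_states.assign(ase=truth_states["true_state"].isin(["M", "S"]))
        .groupby("gene_id")["ase"]
        .any()
    )
    is_ase_gene = any_ase.reindex(gene_ids).to_numpy(dtype=bool)
    genes, css, peaks, qtl = _simulate_genome(config, gene_ids, is_ase_gene, rng)

    # het sites: Poisson placement at a gamma-distributed per-gene density
    spec = g.genome
    lengths = (genes["end"] - genes["start"]).to_numpy()
    densities = rng.gamma(
        spec.het_density_shape, spec.het_density_mean / spec.het_density_shape, g.n_genes
    )
    n_sites = rng.poisson(densities * lengths)
    pooled = (
        allelic_counts.groupby("gene_id")[["marine_count", "freshwater_count"]]
        .sum()
        .reindex(genes["name"])
    )
    site_rows = []
    for i in range(g.n_genes):
        k = int(n_sites[i])
        if k == 0:
            continue
        length = int(lengths[i])
        k = min(k, length)
        offsets = np.sort(rng.choice(length, size=k, replace=False))
        m_total = int(pooled.iloc[i]["marine_count"])
        f_total = int(pooled.iloc[i]["freshwater_count"])
        m_sites = rng.multinomial(m_total, np.full(k, 1.0 / k))
        f_sites = rng.multinomial(f_total, np.full(k, 1.0 / k))
        chrom = genes.iloc[i]["chrom"]
        start = int(genes.iloc[i]["start"])
        for j in range(k):
            site_rows.append(
                {
                    "chrom": chrom,
                    "pos": start + int(offsets[j]) + 1,  # site table is 1-based
                    "gene_id": genes.iloc[i]["name"],
                    "marine_count": int(m_sites[j]),
                    "freshwater_count": int(f_sites[j]),
                }
            )
    site_counts = pd.DataFrame(
        site_rows, columns=["chrom", "pos", "gene_id", "marine_count", "freshwater_count"]
    )

    # gene sets: one direction-biased set among ASE genes, the rest random
    fw_up_ase = gene_ids[is_ase_gene & ~marine_up]
    m_up_ase = gene_ids[is_ase_gene & marine_up]
    spec_set = g.biased_set
    n_fw = int(round(spec_set.size * spec_set.direction_bias))
    n_m = spec_set.size - n_fw
    if n_fw > len(fw_up_ase) or n_m > len(m_up_ase):
        raise ValueError("not enough ASE genes of each direction for the biased set")
    biased_members = np.concatenate(
        [
            rng.choice(fw_up_ase, size=n_fw, replace=False),
            rng.choice(m_up_ase, size=n_m, replace=False),
        ]
    )
    sets = GeneSetCollection()
    sets.sets["biased_set"] = frozenset(biased_members.tolist())
    sets.names["biased_set"] = "biased_set"
    lo, hi = g.null_set_size_range
    for s in range(g.n_null_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=min(size, g.n_genes), replace=False)
        set_id = f"null_set_{s + 1:03d}"
        sets.sets[set_id] = frozenset(members.tolist())
        sets.names[set_id] = set_id

    membership = {gene: [] for gene in gene_ids}
    for set_id, members in sets.items():
        for gene in members:
            membership[gene].append(set_id)
    gene_order = {gid: i for i, gid in enumerate(genes["name"])}
    peak_flags = np.zeros(g.n_genes, dtype=bool)
    gene_positions = genes.set_index("name")
    for i, gid in enumerate(gene_ids):
        row = gene_positions.loc[gid]
        peak_flags[i] = bool(
            (
                (peaks["chrom"] == row["chrom"])
                & (peaks["start"] < row["end"])
                & (peaks["end"] > row["start"])
            ).any()
        ) if len(peaks) else False
    truth_genes = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "true_class": classes,
            "any_ase": is_ase_gene,
            "direction": np.where(marine_up, "marine_up", "freshwater_up"),
            "chrom": gene_positions.loc[gene_ids, "chrom"].to_numpy(),
            "start": gene_positions.loc[gene_ids, "start"].to_numpy(),
            "end": gene_positions.loc[gene_ids, "end"].to_numpy(),
            "in_ecopeak": peak_flags,
            "n_het_sites": [int(n_sites[gene_order[gid]]) for gid in gene_ids],
            "set_memberships": [",".join(sorted(membership[gid])) for gid in gene_ids],
        }
    )

    return SimulatedExperiment(
        config=config,
        allelic_counts=allelic_counts,
        site_counts=site_counts,
        genes=genes,
        css_windows=css,
        ecopeaks=peaks,
        qtl=qtl,
        gene_sets=sets,
        truth_genes=truth_genes,
        truth_states=truth_states,
    )


def simulate_null_sets(
    n_sets: int,
    set_size_range: tuple[int, int],
    gene_directions: pd.DataFrame,
    seed: int | None = None,
) -> GeneSetCollection:
    """Gene sets drawn uniformly, blind to direction (a calibration null).

    ``gene_directions`` is a direction table (as from
    :func:`asekit.signtest.assign_directions`); sets are sampled from its
    non-discarded genes without replacement within each set.
    """
    rng = np.random.default_rng(seed)
    usable = gene_directions.loc[~gene_directions["discarded"], "gene_id"].to_numpy()
    lo, hi = set_size_range
    if not 0 < lo <= hi:
        raise ValueError("set_size_range must satisfy 0 < lo <= hi")
    if hi > len(usable):
        raise ValueError(
            f"set size {hi} exceeds the {len(usable)} direction-assigned genes"
        )
    collection = GeneSetCollection()
    for s in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(usable, size=size, replace=False)
        set_id = f"null_{s + 1:04d}"
        collection.sets[set_id] = frozenset(members.tolist())
        collection.names[set_id] = set_id
    return collection
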