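from itertools import product

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from asekit.heterogeneity import (
    PriorSpec,
    classify_all,
    classify_gene,
    default_priors,
    dominance_interval,
    log_marginal,
    prior_density,
    state_log_marginals,
    STATES,
)


def mixture_pdf(theta, components):
    return sum(w * stats.beta.pdf(theta, a, b) for w, a, b in components)


def brute_force_class_pp(x, n, priors):
    """Independent oracle: enumerate all 3^T configurations explicitly."""
    T = len(x)
    logm = np.array(
        [[log_marginal(x[t], n[t], s, priors) for s in STATES] for t in range(T)]
    )
    weights = {}
    for config in product(range(3), repeat=T):
        weights[config] = np.exp(sum(logm[t, s] for t, s in enumerate(config)))
    total = sum(weights.values())
    pp = {"NOASE": 0.0, "UNIFORM_ASE": 0.0, "HET0": 0.0, "HET1": 0.0}
    ts = np.zeros(T)
    for config, w in weights.items():
        p = w / total
        states = set(config)
        if states == {0}:
            pp["NOASE"] += p
        elif 0 in states:
            pp["HET0"] += p
        elif len(states) == 1:
            pp["UNIFORM_ASE"] += p
        else:
            pp["HET1"] += p
        for t in range(T):
            if config[t] != 0 and all(config[u] == 0 for u in range(T) if u != t):
                ts[t] += p
    return pp, ts


class TestPriorDensity:
    def test_beta_2000_density_at_mode(self):
        # closed form Beta(2000,2000) pdf at 0.5 via log-gamma
        expected = np.exp(
            -special.betaln(2000, 2000) + 3998 * np.log(0.5)
        )
        assert prior_density(0.5, "N") == pytest.approx(expected, rel=1e-12)
        assert prior_density(0.5, "N") == pytest.approx(50.4595, rel=1e-4)

    @pytest.mark.parametrize("state", ["N", "M", "S"])
    def test_symmetric_mixtures(self, state):
        thetas = np.linspace(0.01, 0.99, 23)
        np.testing.assert_allclose(
            prior_density(thetas, state), prior_density(1 - thetas, state), rtol=1e-10
        )

    def test_strong_state_dominates_at_extreme(self):
        d = {s: float(prior_density(0.92, s)) for s in STATES}
        assert d["S"] > d["M"] > d["N"]

    def test_matches_scipy_mixture(self):
        priors = default_priors()
        thetas = np.linspace(0.05, 0.95, 19)
        for state in STATES:
            np.testing.assert_allclose(
                prior_density(thetas, state),
                mixture_pdf(thetas, priors.components[state]),
                rtol=1e-10,
            )

    def test_theta_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            prior_density(0.0, "N")
        with pytest.raises(ValueError):
            prior_density(1.0, "S")


class TestDominanceInterval:
    def test_default_priors_interval(self):
        assert dominance_interval() == (0.47, 0.53)

    def test_n_density_greatest_at_half(self):
        d = {s: float(prior_density(0.5, s)) for s in STATES}
        assert d["N"] > d["M"] and d["N"] > d["S"]

    def test_symmetric_about_half(self):
        low, high = dominance_interval(rounding=None)
        assert low == pytest.approx(1 - high, abs=1e-6)


class TestLogMarginal:
    def test_empty_data_log_one(self):
        for state in STATES:
            assert log_marginal(0, 0, state) == pytest.approx(0.0, abs=1e-12)

    def test_quadrature_oracle(self):
        # numerical integration of Binomial(n, theta) against the prior pdf
        priors = default_priors()
        grid = np.linspace(1e-9, 1 - 1e-9, 100001)
        for state in STATES:
            pdf = mixture_pdf(grid, priors.components[state])
            for x, n in [(60, 100), (5, 10), (0, 50), (100, 200), (30, 60)]:
                quad = np.log(np.trapezoid(stats.binom.pmf(x, n, grid) * pdf, grid))
                assert log_marginal(x, n, state) == pytest.approx(quad, abs=1e-6)

    @pytest.mark.parametrize("state", ["N", "M", "S"])
    def test_symmetry(self, state):
        for x, n in [(0, 10), (3, 17), (40, 100), (999, 1000)]:
            assert log_marginal(x, n, state) == pytest.approx(
                log_marginal(n - x, n, state), rel=1e-12
            )

    def test_finite_at_extreme_depth(self):
        # no underflow for n up to 1e6
        for state in STATES:
            val = log_marginal(900_000, 1_000_000, state)
            assert np.isfinite(val)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_marginal(-1, 10, "N")
        with pytest.raises(ValueError):
            log_marginal(11, 10, "N")


class TestClassifyGene:
    @staticmethod
    def gene_counts(pairs, tissues=None):
        tissues = tissues or [f"t{i}" for i in range(len(pairs))]
        return pd.DataFrame(
            {
                "tissue": tissues,
                "marine_count": [m for m, _ in pairs],
                "freshwater_count": [f for _, f in pairs],
            }
        )

    def test_balanced_seven_tissues_noase(self):
        cls = classify_gene("g", self.gene_counts([(50, 50)] * 7))
        assert cls.class_pp["NOASE"] > 0.9
        oracle_pp, _ = brute_force_class_pp([50] * 7, [100] * 7, default_priors())
        assert cls.class_pp["NOASE"] == pytest.approx(oracle_pp["NOASE"], rel=1e-10)

    def test_low_minor_allele_tissue_excluded_entirely(self):
        # the coverage rule (either allele <= min_reads) removes the (95, 5)
        # tissue, so the remaining balanced tissues dominate
        cls = classify_gene("g", self.gene_counts([(95, 5)] + [(50, 50)] * 6))
        assert cls.tissues == [f"t{i}" for i in range(1, 7)]
        assert cls.map_class == "NOASE"

    def test_one_imbalanced_tissue_het0(self):
        pairs = [(95, 15)] + [(50, 50)] * 6
        cls = classify_gene("g", self.gene_counts(pairs))
        assert cls.map_class == "HET0"
        assert cls.tissue_specific_pp.idxmax() == "t0"
        oracle_pp, oracle_ts = brute_force_class_pp(
            [m for m, _ in pairs], [m + f for m, f in pairs], default_priors()
        )
        for name in ("NOASE", "UNIFORM_ASE", "HET0", "HET1"):
            assert cls.class_pp[name] == pytest.approx(oracle_pp[name], rel=1e-9, abs=1e-12)
        np.testing.assert_allclose(cls.tissue_specific_pp.to_numpy(), oracle_ts, rtol=1e-9, atol=1e-12)

    def test_single_expressed_tissue_unclassifiable(self):
        cls = classify_gene("g", self.gene_counts([(50, 50), (5, 5), (11, 3)]))
        # only t0 has > 10 reads on both alleles
        assert cls.unclassifiable

    def test_low_coverage_tissue_excluded(self):
        cls = classify_gene("g", self.gene_counts([(50, 50), (100, 100), (10, 200)]))
        assert cls.tissues == ["t0", "t1"]

    def test_enumeration_oracle_random_genes(self):
        # acceptance-grade check at T = 7 over 100 random genes
        rng = np.random.default_rng(99)
        priors = default_priors()
        for _ in range(100):
            n = rng.integers(25, 400, size=7)
            theta = rng.uniform(0.05, 0.95, size=7)
            # keep both alleles observed so min_reads=0 keeps all 7 tissues
            x = np.clip(rng.binomial(n, theta), 1, n - 1)
            counts = pd.DataFrame(
                {"tissue": [f"t{i}" for i in range(7)], "marine_count": x,
                 "freshwater_count": n - x}
            )
            cls = classify_gene("g", counts, priors, min_reads=0)
            oracle_pp, oracle_ts = brute_force_class_pp(x, n, priors)
            for name in ("NOASE", "UNIFORM_ASE", "HET0", "HET1"):
                assert cls.class_pp[name] == pytest.approx(
                    oracle_pp[name], rel=1e-10, abs=1e-13
                )
            np.testing.assert_allclose(
                cls.tissue_specific_pp.to_numpy(), oracle_ts, rtol=1e-10, atol=1e-13
            )

    def test_class_partition_sums_to_one(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(25, 300, size=5)
            x = rng.binomial(n, rng.uniform(0.1, 0.9, size=5))
            cls = classify_gene(
                "g",
                pd.DataFrame(
                    {"tissue": [f"t{i}" for i in range(5)], "marine_count": x,
                     "freshwater_count": n - x}
                ),
                min_reads=0,
            )
            assert sum(cls.class_pp.values()) == pytest.approx(1.0, abs=1e-9)
            np.testing.assert_allclose(
                cls.state_posteriors.sum(axis=1).to_numpy(), 1.0, atol=1e-9
            )

    def test_depth_monotonicity_at_half(self):
        priors = default_priors()
        previous = -np.inf
        for n in (30, 100, 300, 1000, 3000):
            logm = state_log_marginals(n // 2, n, priors)
            post = np.exp(logm - special.logsumexp(logm))
            assert post[0] > previous
            previous = post[0]


class TestClassifyAll:
    def test_threshold_nesting_and_normalization(self, small_sim):
        table, summary = classify_all(small_sim.allelic_counts)
        called_95 = table[table["het_call_pp095"]]
        assert called_95["het_call_pp09"].all()
        total = (
            table["pp_noase"] + table["pp_uniform_ase"] + table["pp_het0"] + table["pp_het1"]
        )
        np.testing.assert_allclose(total, 1.0, atol=1e-9)

    def test_empty_eligible_set_raises(self):
        counts = pd.DataFrame(
            {
                "gene_id": ["g1"],
                "tissue": ["liver"],
                "timepoint": [2],
                "replicate": [1],
                "marine_count": [1],
                "freshwater_count": [1],
            }
        )
        with pytest.raises(ValueError):
            classify_all(counts)

    def test_priors_file_roundtrip(self, tmp_path):
        path = tmp_path / "priors.txt"
        path.write_text(
            "N 1.0 2000 2000\n"
            "M 0.5 80 36\nM 0.5 36 80\n"
            "S 0.5 80 7\nS 0.5 7 80\n"
        )
        spec = PriorSpec.from_file(path)
        assert spec.components == default_priors().components
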