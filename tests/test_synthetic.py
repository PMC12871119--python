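"""Synthetic data generators: reproducibility, marginal and copula
structure, codon simulator behavior, and the low-level input generators."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crossdiv import ConfigError
from crossdiv.metrics import STOP_CODONS, nei_gojobori
from crossdiv.synthetic import (
    DEFAULT_TAXA,
    SyntheticConfig,
    generate_codon_alignment,
    generate_divergence_tables,
    generate_expression_pair,
    generate_structural_similarities,
)


def _uniform_config(**overrides) -> SyntheticConfig:
    """One-taxon config with plain gamma marginals (no zero inflation)."""
    taxa = overrides.pop("taxa", ("tx",))
    base = dict(
        taxa=taxa,
        genes_per_taxon=overrides.pop("genes_per_taxon", 500),
        marginal_shape={t: (2.0, 2.0, 2.0) for t in taxa},
        marginal_scale={t: (1.0, 1.0, 1.0) for t in taxa},
        zero_inflation={t: (0.0, 0.0, 0.0) for t in taxa},
        copula_corr={t: overrides.pop("corr", np.eye(3)) for t in taxa},
        seed=overrides.pop("seed", 0),
    )
    base.update(overrides)
    return SyntheticConfig(**base)


class TestConfigValidation:
    def test_non_psd_correlation_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99], [-0.99, 0.99, 1.0]])
        with pytest.raises(ConfigError, match="positive semidefinite"):
            _uniform_config(corr=bad)

    def test_asymmetric_correlation_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.5
        with pytest.raises(ConfigError, match="symmetric"):
            _uniform_config(corr=bad)

    def test_small_gene_count_rejected(self):
        with pytest.raises(ConfigError):
            _uniform_config(genes_per_taxon=5)

    def test_negative_shape_rejected(self):
        taxa = ("tx",)
        with pytest.raises(ConfigError):
            SyntheticConfig(
                taxa=taxa,
                genes_per_taxon=100,
                marginal_shape={"tx": (-1.0, 1.0, 1.0)},
                marginal_scale={"tx": (1.0, 1.0, 1.0)},
                zero_inflation={"tx": (0.0, 0.0, 0.0)},
                copula_corr={"tx": np.eye(3)},
            )

    def test_toml_round_trip(self, tmp_path):
        text = """
taxa = ["a", "b"]
genes_per_taxon = 100
seed = 3
copula_corr = 0.2

[marginal_shape]
a = [1.0, 1.0, 1.0]
b = [1.0, 1.0, 1.0]

[marginal_scale]
a = [1.0, 2.0, 3.0]
b = [1.0, 2.0, 3.0]

[zero_inflation]
a = [0.0, 0.1, 0.2]
b = [0.0, 0.1, 0.2]
"""
        path = tmp_path / "cfg.toml"
        path.write_text(text)
        cfg = SyntheticConfig.from_toml(path)
        assert cfg.taxa == ("a", "b")
        assert cfg.copula_corr["a"][0, 1] == pytest.approx(0.2)


class TestDivergenceTables:
    def test_reproducible_from_seed(self):
        cfg = _uniform_config(seed=7)
        t1 = generate_divergence_tables(cfg)["tx"]
        t2 = generate_divergence_tables(cfg)["tx"]
        assert t1.to_csv() == t2.to_csv()

    def test_structure_of_output(self, small_config, small_raw_table):
        n = small_config.genes_per_taxon
        for taxon in small_config.taxa:
            sub = small_raw_table[small_raw_table["taxon"] == taxon]
            assert len(sub) == 3 * n
            counts = sub.groupby("gene")["level"].nunique()
            assert (counts == 3).all()
        assert (small_raw_table["raw"] >= 0).all()

    def test_strictly_positive_without_zero_inflation(self):
        table = generate_divergence_tables(_uniform_config())["tx"]
        assert (table["raw"] > 0).all()

    def test_zero_fraction_matches_configured_mass(self):
        cfg = _uniform_config(genes_per_taxon=4000)
        cfg = replace(cfg, zero_inflation={"tx": (0.3, 0.0, 0.0)})
        table = generate_divergence_tables(cfg)["tx"]
        seq = table[table["level"] == "sequence"]["raw"]
        assert seq.eq(0).mean() == pytest.approx(0.3, abs=0.03)

    def test_identity_copula_gives_independent_levels(self):
        cfg = _uniform_config(genes_per_taxon=10_000, corr=np.eye(3))
        table = generate_divergence_tables(cfg)["tx"]
        wide = table.pivot_table(index="gene", columns="level", values="raw")
        corr = wide.corr().to_numpy()
        off = corr[~np.eye(3, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_copula_recovery_from_normal_scores(self):
        corr = np.full((3, 3), 0.30)
        np.fill_diagonal(corr, 1.0)
        cfg = _uniform_config(genes_per_taxon=5000, corr=corr)
        table = generate_divergence_tables(cfg)["tx"]
        wide = table.pivot_table(index="gene", columns="level", values="raw")
        n = len(wide)
        scores = pd.DataFrame(
            {
                c: stats.norm.ppf((stats.rankdata(wide[c]) - 0.5) / n)
                for c in wide.columns
            }
        )
        emp = scores.corr().to_numpy()
        off = emp[~np.eye(3, dtype=bool)]
        assert np.abs(off - 0.30).max() < 0.05


class TestCodonAlignmentGenerator:
    def test_zero_rates_identical_sequences(self):
        aln = generate_codon_alignment(50, t_syn=0.0, t_non=0.0, seed=0)
        assert aln.seq_a == aln.seq_b

    def test_length_and_stop_freedom(self):
        for seed in range(20):
            aln = generate_codon_alignment(30, t_syn=0.5, t_non=0.5, seed=seed)
            assert len(aln.seq_a) == 90 == len(aln.seq_b)
            for seq in (aln.seq_a, aln.seq_b):
                codons = {seq[i : i + 3] for i in range(0, len(seq), 3)}
                assert not (codons & STOP_CODONS)

    def test_mean_ka_recovers_target(self):
        target = 0.05
        estimates = [
            nei_gojobori(generate_codon_alignment(500, 0.0, target, seed=s)).ka
            for s in range(50)
        ]
        assert abs(np.mean(estimates) - target) <= 0.02

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ConfigError):
            generate_codon_alignment(0, 0.1, 0.1)
        with pytest.raises(ConfigError):
            generate_codon_alignment(10, -0.1, 0.1)


class TestExpressionPairGenerator:
    def test_zero_noise_zero_divergence(self):
        from crossdiv.metrics import expression_profile_divergence
        from crossdiv.synthetic import default_tissue_map

        a, b = generate_expression_pair(100, 5, noise_sd=0.0, seed=0)
        div = expression_profile_divergence(a, b, default_tissue_map(a, b))
        assert all(v == pytest.approx(0.0) for v in div.values())

    def test_tpm_nonnegative(self):
        a, b = generate_expression_pair(50, 4, noise_sd=1.0, seed=1)
        assert (a.tpm.to_numpy() >= 0).all()
        assert (b.tpm.to_numpy() >= 0).all()

    def test_noise_monotonicity(self):
        """Larger noise gives a larger mean divergence, every paired replicate."""
        from crossdiv.metrics import expression_profile_divergence
        from crossdiv.synthetic import default_tissue_map

        for seed in range(20):
            means = {}
            for sd in (0.1, 0.5):
                a, b = generate_expression_pair(100, 5, noise_sd=sd, seed=seed)
                div = expression_profile_divergence(a, b, default_tissue_map(a, b))
                means[sd] = np.mean(list(div.values()))
            assert means[0.5] > means[0.1]


class TestStructuralSimilarityGenerator:
    def test_degenerate_all_hundred(self):
        table = generate_structural_similarities(20, mean_divergence=0.0, sd=0.0, seed=0)
        assert all(table[g] == pytest.approx(100.0) for g in table)

    def test_bounds_respected(self):
        table = generate_structural_similarities(2000, mean_divergence=95.0, sd=30.0, seed=1)
        values = np.array([table[g] for g in table])
        assert values.min() >= 0.0 and values.max() <= 100.0

    def test_mean_recovered(self):
        table = generate_structural_similarities(10_000, mean_divergence=30.0, sd=5.0, seed=2)
        d = 100.0 - np.array([table[g] for g in table])
        se = d.std(ddof=1) / np.sqrt(d.size)
        assert abs(d.mean() - 30.0) <= 3 * se

    def test_out_of_range_mean_rejected(self):
        with pytest.raises(ConfigError):
            generate_structural_similarities(10, mean_divergence=150.0, sd=5.0)


class TestNullCalibration:
    def test_identical_marginals_give_null_taxon_differences(self):
        """With exchangeable taxa, cross-taxa U tests are null-distributed.

        Mann-Whitney on taxon-specific z between any two taxa should reject
        at most ~alpha; require p > 0.05 in >= 90% of seeded runs per pair.
        """
        from itertools import combinations

        from crossdiv.compare import mann_whitney_u
        from crossdiv.standardize import standardize_table

        taxa = ("t1", "t2", "t3")
        runs = 30
        level_checked = "sequence"
        reject = {pair: 0 for pair in combinations(taxa, 2)}
        for seed in range(runs):
            cfg = SyntheticConfig(
                taxa=taxa,
                genes_per_taxon=300,
                marginal_shape={t: (1.5, 1.5, 1.5) for t in taxa},
                marginal_scale={t: (1.0, 1.0, 1.0) for t in taxa},
                zero_inflation={t: (0.1, 0.1, 0.1) for t in taxa},
                copula_corr={t: np.eye(3) for t in taxa},
                seed=seed,
            )
            raw = pd.concat(generate_divergence_tables(cfg).values(), ignore_index=True)
            std = standardize_table(raw)
            sub = std[std["level"] == level_checked]
            for pair in reject:
                res = mann_whitney_u(
                    sub.loc[sub["taxon"] == pair[0], "z_taxon"],
                    sub.loc[sub["taxon"] == pair[1], "z_taxon"],
                )
                reject[pair] += res.p <= 0.05
        for pair, count in reject.items():
            assert count / runs <= 0.10, (pair, count)
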