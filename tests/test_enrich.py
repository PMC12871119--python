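"""Tail extraction, Venn overlaps, random baseline, enrichment, BH."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from crossdiv import ComputationError, ConfigError
from crossdiv.enrich import (
    AnnotationMap,
    benjamini_hochberg,
    extract_tails,
    hypergeometric_enrichment,
    random_overlap_baseline,
    venn_counts,
)


def _std_like(n: int, taxon="t", level="sequence", values=None, rng=None) -> pd.DataFrame:
    vals = values if values is not None else rng.normal(size=n)
    return pd.DataFrame(
        {
            "gene": [f"g{i:04d}" for i in range(n)],
            "taxon": taxon,
            "level": level,
            "raw": np.exp(vals),
            "z_level": vals,
        }
    )


class TestExtractTails:
    def test_k_from_fraction(self, rng):
        parts = extract_tails(_std_like(200, rng=rng), fraction=0.025)
        assert parts[0].k == 5
        assert len(parts[0].low_set) == len(parts[0].high_set) == 5

    def test_minimum_k_is_one(self, rng):
        parts = extract_tails(_std_like(43, rng=rng), fraction=0.025)
        assert parts[0].k == 1

    def test_low_and_high_disjoint(self, rng):
        parts = extract_tails(_std_like(100, rng=rng), fraction=0.1)
        assert not (parts[0].low_set & parts[0].high_set)

    def test_raw_and_z_ranking_agree(self, rng):
        frame = _std_like(120, rng=rng)
        by_z = extract_tails(frame, fraction=0.05, rank_column="z_level")[0]
        by_raw = extract_tails(frame, fraction=0.05, rank_column="raw")[0]
        assert by_z.low_set == by_raw.low_set
        assert by_z.high_set == by_raw.high_set

    def test_too_small_group_rejected(self, rng):
        with pytest.raises(ComputationError):
            extract_tails(_std_like(30, rng=rng), fraction=0.025)

    def test_bad_fraction_rejected(self, rng):
        with pytest.raises(ConfigError):
            extract_tails(_std_like(100, rng=rng), fraction=0.6)


class TestVennCounts:
    def test_disjoint_sets(self):
        s = venn_counts({"a", "b"}, {"c"}, {"d", "e", "f"})
        assert (s.seq_only, s.expr_only, s.struct_only) == (2, 1, 3)
        assert s.all_three == 0

    def test_identical_sets(self):
        s = venn_counts({"a", "b", "c"}, {"a", "b", "c"}, {"a", "b", "c"})
        assert s.all_three == 3
        assert s.seq_only == s.expr_only == s.struct_only == 0
        assert s.seq_expr == s.seq_struct == s.expr_struct == 0

    def test_region_sums_recover_set_sizes(self, rng):
        universe = [f"g{i}" for i in range(40)]
        for _ in range(50):
            a = set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            b = set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            c = set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            s = venn_counts(a, b, c)
            assert s.seq_only + s.seq_expr + s.seq_struct + s.all_three == len(a)
            assert s.expr_only + s.seq_expr + s.expr_struct + s.all_three == len(b)
            assert s.struct_only + s.seq_struct + s.expr_struct + s.all_three == len(c)

    def test_matches_per_element_classification(self, rng):
        """Brute-force oracle: classify every element of the union."""
        universe = [f"g{i}" for i in range(30)]
        for _ in range(100):
            a = set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            b = set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            c = set(rng.choice(universe, size=rng.integers(0, 20), replace=False))
            regions = {k: 0 for k in
                       ("100", "010", "001", "110", "101", "011", "111")}
            for e in a | b | c:
                key = f"{int(e in a)}{int(e in b)}{int(e in c)}"
                regions[key] += 1
            s = venn_counts(a, b, c)
            assert (s.seq_only, s.expr_only, s.struct_only) == (
                regions["100"], regions["010"], regions["001"])
            assert (s.seq_expr, s.seq_struct, s.expr_struct, s.all_three) == (
                regions["110"], regions["101"], regions["011"], regions["111"])


class TestRandomOverlapBaseline:
    def test_full_sets_always_overlap(self):
        base = random_overlap_baseline(10, 10, reps=5, seed=0)
        assert (base["counts"] == 10).all()

    def test_mean_matches_closed_form(self):
        n, k = 200, 20
        base = random_overlap_baseline(n, k, reps=10_000, seed=1)
        expected = k**3 / n**2
        se = base["counts"].std(ddof=1) / np.sqrt(len(base["counts"]))
        assert abs(base["mean"] - expected) <= 3 * se

    def test_expected_value_for_drosophila_sizes(self):
        base = random_overlap_baseline(4277, 106, reps=1, seed=0)
        assert base["expected"] == pytest.approx(0.0651, abs=5e-5)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ConfigError):
            random_overlap_baseline(5, 6, reps=1, seed=0)


class TestBenjaminiHochberg:
    def test_hand_step_up_example(self):
        q = benjamini_hochberg([0.005, 0.01, 0.03, 0.04])
        assert q == pytest.approx([0.02, 0.02, 0.04, 0.04])

    def test_all_ones(self):
        assert benjamini_hochberg([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.037]) == pytest.approx([0.037])

    def test_out_of_range_rejected(self):
        with pytest.raises(ComputationError):
            benjamini_hochberg([0.5, 1.5])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_monotone_and_dominates_raw_p(self, ps):
        q = benjamini_hochberg(ps)
        order = np.argsort(ps, kind="stable")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert (np.asarray(q) >= np.asarray(ps) - 1e-12).all()
        assert (np.asarray(q) <= 1.0 + 1e-12).all()

    def test_matches_hand_step_up_on_random_inputs(self, rng):
        """Independent oracle: literal step-up recursion."""
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 25))
            m = len(p)
            order = np.argsort(p)
            q_sorted = np.empty(m)
            running = 1.0
            for i in range(m - 1, -1, -1):
                running = min(running, p[order[i]] * m / (i + 1))
                q_sorted[i] = running
            expected = np.empty(m)
            expected[order] = q_sorted
            assert benjamini_hochberg(p) == pytest.approx(expected, abs=1e-12)


class TestHypergeometricEnrichment:
    def _map(self):
        background = [f"g{i}" for i in range(4)]
        return AnnotationMap({"g0": ["T1"], "g1": ["T1"], "g2": ["T2"]}, background)

    def test_term_with_no_study_hits_p_one(self):
        frame = hypergeometric_enrichment({"g3"}, self._map())
        assert (frame["p"] == 1.0).all()

    def test_two_of_two_in_background_four(self):
        frame = hypergeometric_enrichment({"g0", "g1"}, self._map())
        t1 = frame.set_index("term").loc["T1"]
        assert t1["p"] == pytest.approx(1 / 6, abs=1e-9)

    def test_study_gene_outside_background_rejected(self):
        with pytest.raises(ComputationError):
            hypergeometric_enrichment({"nope"}, self._map())

    def test_annotated_gene_outside_background_rejected(self):
        with pytest.raises(ConfigError):
            AnnotationMap({"gX": ["T1"]}, ["g0"])

    def test_matches_subset_enumeration(self, rng):
        """Exhaustive oracle for small backgrounds (M <= 12)."""
        for trial in range(10):
            m = int(rng.integers(5, 13))
            background = [f"g{i}" for i in range(m)]
            term_genes = set(rng.choice(background, size=rng.integers(1, m + 1), replace=False))
            anno = AnnotationMap({g: ["T"] for g in term_genes}, background)
            n = int(rng.integers(1, m + 1))
            study = set(rng.choice(background, size=n, replace=False))
            observed = len(study & term_genes)
            if observed == 0:
                expected = 1.0
            else:
                hits = total = 0
                for subset in combinations(background, n):
                    total += 1
                    if len(set(subset) & term_genes) >= observed:
                        hits += 1
                expected = hits / total
            frame = hypergeometric_enrichment(study, anno)
            assert frame.set_index("term").loc["T", "p"] == pytest.approx(expected, abs=1e-9)
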