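"""Tissue cohort: display transform, Pearson distances, complete linkage,
group contrasts, and biomarker triage."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from glycopattern.cohort import (CohortDesign, candidate_biomarkers,
                                 group_contrast, hierarchical_cluster,
                                 log_cap_transform, pairwise_pearson_distances,
                                 pearson_distance, read_design, write_design)
from glycopattern.patterns import PatternCode


def brute_force_complete_linkage(dist: np.ndarray) -> list[float]:
    """Hand agglomeration oracle: merge the closest pair, height = max
    cross-pair distance; returns merge heights in order."""
    n = dist.shape[0]
    clusters: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    heights = []
    next_id = n
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            h = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            if best is None or h < best[0]:
                best = (h, a, b)
        h, a, b = best
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
        heights.append(h)
    return heights


def square_from_condensed(condensed: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    pos = 0
    for i in range(n - 1):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = condensed[pos]
            pos += 1
    return out


class TestLogCapTransform:
    def test_missing_maps_to_zero(self):
        table = pd.DataFrame({"A": [np.nan, 10.0]}, index=["p", "q"])
        out = log_cap_transform(table)
        assert out.loc["p", "A"] == 0.0

    def test_values_cap_at_five(self):
        table = pd.DataFrame({"A": [1e12]}, index=["p"])
        assert log_cap_transform(table, pseudo_intensity=1.0).loc["p", "A"] == 5.0

    def test_default_anchor_is_detection_floor(self):
        table = pd.DataFrame({"A": [1e4, 1e7], "B": [np.nan, 1e9]},
                             index=["faint", "bright"])
        out = log_cap_transform(table)
        assert out.loc["faint", "A"] == pytest.approx(np.log10(2))
        assert out.loc["bright", "A"] == pytest.approx(3.0, abs=0.01)
        assert out.loc["bright", "B"] == 5.0

    def test_monotone_below_cap(self):
        table = pd.DataFrame({"A": [3.0], "B": [30.0]}, index=["p"])
        out = log_cap_transform(table)
        assert 0 < out.loc["p", "A"] < out.loc["p", "B"] < 5.0


class TestPearsonDistance:
    def test_identical_vectors_give_zero(self):
        assert pearson_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0)

    def test_negated_vectors_give_two(self):
        assert pearson_distance([1, 2, 3], [-1, -2, -3]) == pytest.approx(2.0)

    def test_hand_computed_half_correlation(self):
        assert pearson_distance([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    @given(a=st.floats(min_value=0.1, max_value=10),
           b=st.floats(min_value=-5, max_value=5))
    def test_invariant_under_positive_affine_transform(self, a, b):
        x = np.array([1.0, 4.0, 2.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 3.0])
        assert pearson_distance(a * x + b, y) == pytest.approx(
            pearson_distance(x, y), abs=1e-9)

    def test_pairwise_complete_positions_only(self):
        x = [1.0, 2.0, 3.0, np.nan]
        y = [1.0, 2.0, np.nan, 4.0]
        # complete positions are the first two -> perfectly correlated
        assert pearson_distance(x, y) == pytest.approx(0.0)

    def test_too_few_complete_pairs_is_error(self):
        with pytest.raises(ValueError, match="complete"):
            pearson_distance([1.0, np.nan, 3.0], [np.nan, 2.0, np.nan])

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_distance([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_pairwise_matrix_names_offending_pair(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]],
                              index=["ok", "flat"])
        with pytest.raises(ValueError, match="flat"):
            pairwise_pearson_distances(matrix)

    def test_loop_and_vectorized_paths_agree(self, rng):
        values = rng.normal(size=(6, 7))
        complete = pd.DataFrame(values)
        holey = complete.copy()
        holey.iloc[0, 0] = np.nan  # forces the pairwise-complete loop
        fast = pairwise_pearson_distances(complete)
        slow = pairwise_pearson_distances(holey)
        # distances not involving row 0 are identical across paths
        np.testing.assert_allclose(fast[5:], slow[5:], atol=1e-12)


class TestHierarchicalCluster:
    def test_two_items_single_merge_at_their_distance(self):
        matrix = pd.DataFrame([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]],
                              index=["a", "b"])
        d = pearson_distance(matrix.loc["a"], matrix.loc["b"])
        dendro = hierarchical_cluster(matrix)
        assert len(dendro.merges) == 1
        assert dendro.merges[0][2] == pytest.approx(d)

    @pytest.mark.parametrize("seed", range(5))
    def test_merge_heights_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        matrix = pd.DataFrame(rng.normal(size=(5, 8)),
                              index=[f"r{i}" for i in range(5)])
        condensed = pairwise_pearson_distances(matrix)
        oracle = brute_force_complete_linkage(square_from_condensed(condensed, 5))
        dendro = hierarchical_cluster(matrix)
        np.testing.assert_allclose(sorted(dendro.heights), sorted(oracle),
                                   atol=1e-12)

    def test_heights_non_decreasing(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(10, 6)))
        dendro = hierarchical_cluster(matrix)
        assert (np.diff(dendro.heights) >= -1e-12).all()

    def test_duplicate_item_adds_zero_merge_only(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(5, 6)),
                              index=[f"r{i}" for i in range(5)])
        dup = pd.concat([matrix, matrix.iloc[[0]].rename(index={"r0": "r0b"})])
        base = sorted(hierarchical_cluster(matrix).heights)
        with_dup = sorted(hierarchical_cluster(dup).heights)
        assert with_dup[0] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(with_dup[1:], base, atol=1e-12)

    def test_invariant_under_row_permutation(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(8, 6)),
                              index=[f"r{i}" for i in range(8)])
        shuffled = matrix.sample(frac=1.0, random_state=1)
        a = sorted(hierarchical_cluster(matrix).heights)
        b = sorted(hierarchical_cluster(shuffled).heights)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_newick_output_is_well_formed(self, rng):
        matrix = pd.DataFrame(rng.normal(size=(6, 5)),
                              index=[f"leaf{i}" for i in range(6)])
        text = hierarchical_cluster(matrix).to_newick()
        from io import StringIO

        from Bio import Phylo
        tree = Phylo.read(StringIO(text), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(
            matrix.index)


def toy_cohort():
    samples = {"NAT_1": "NAT", "BPH_1": "BPH", "BPH_2": "BPH",
               "PCa_1": "PCa", "mPCa_1": "mPCa"}
    design = CohortDesign(groups=samples, pairing={"PCa_1": "NAT_1"})
    table = pd.DataFrame(
        {
            "NAT_1": [10.0, 10.0, 10.0],
            "BPH_1": [10.0, 10.0, 10.0],
            "BPH_2": [10.0, 10.0, 10.0],
            "PCa_1": [100.0, 50.0, 10.0],
            "mPCa_1": [100.0, 50.0, 10.0],
        },
        index=["tumor_marker", "flat_pattern", "unregulated"])
    return table, design


class TestGroupContrast:
    def test_identical_groups_give_zero(self):
        table, design = toy_cohort()
        out = group_contrast(table, design, "BPH", "BPH", pseudo_intensity=0)
        np.testing.assert_allclose(out["log10_fc"], 0.0)

    def test_tenfold_gives_one_decade(self):
        table, design = toy_cohort()
        out = group_contrast(table, design, "PCa", "BPH", pseudo_intensity=0)
        assert out.loc["tumor_marker", "log10_fc"] == pytest.approx(1.0)

    def test_antisymmetric(self):
        table, design = toy_cohort()
        ab = group_contrast(table, design, "PCa", "BPH")["log10_fc"]
        ba = group_contrast(table, design, "BPH", "PCa")["log10_fc"]
        np.testing.assert_allclose(ab, -ba, atol=1e-12)

    def test_unknown_group_rejected(self):
        table, design = toy_cohort()
        with pytest.raises(ValueError, match="unknown group"):
            group_contrast(table, design, "PCa", "CRPC")

    def test_missing_samples_excluded_from_means(self):
        table, design = toy_cohort()
        table = table.copy()
        table.loc["tumor_marker", "BPH_2"] = np.nan
        out = group_contrast(table, design, "PCa", "BPH")
        assert out.loc["tumor_marker", "n_b"] == 1

    def test_planted_effect_recovered_on_simulated_cohort(self):
        from glycopattern.synthetic import simulate_tissue_cohort
        cohort = simulate_tissue_cohort(
            {"BPH": 10, "PCa": 5, "mPCa": 5}, n_markers=15,
            effect_log10=1.0, seed=5, noise_log10_sd=0.2)
        merged = CohortDesign(groups={
            s: ("tumor" if g in ("PCa", "mPCa") else g)
            for s, g in cohort.design.groups.items()})
        out = group_contrast(cohort.quant, merged, "tumor", "BPH",
                             pseudo_intensity=0)
        planted = [p for p, c in cohort.truth_markers.items()
                   if c == "tumor-up"]
        mean_fc = out.loc[planted, "log10_fc"].mean()
        # per-protein contrast sd = 0.2*sqrt(1/10 + 1/10); mean of 15
        se = 0.2 * np.sqrt(1 / 10 + 1 / 10) / np.sqrt(len(planted))
        assert abs(mean_fc - 1.0) <= 3 * se


class TestCandidateBiomarkers:
    def patterns_for(self, table):
        return {
            "tumor_marker": PatternCode(("up", "up", "down")),
            "flat_pattern": PatternCode(("same", "same", "same")),
            "unregulated": PatternCode(("up", "down", "up")),
        }

    def test_flat_cell_line_pattern_excluded(self):
        table, design = toy_cohort()
        table = table.copy()
        table.loc["flat_pattern", ["PCa_1", "mPCa_1"]] = 1000.0
        out = candidate_biomarkers(self.patterns_for(table), table, design)
        assert not out.loc["flat_pattern", "passes"]

    def test_tumor_upregulated_nonflat_passes_and_ranks_first(self):
        table, design = toy_cohort()
        out = candidate_biomarkers(self.patterns_for(table), table, design,
                                   min_log10_fc=0.5)
        assert out.index[0] == "tumor_marker"
        assert bool(out.loc["tumor_marker", "passes"])
        assert not out.loc["unregulated", "passes"]

    def test_infinite_threshold_passes_nothing(self):
        table, design = toy_cohort()
        out = candidate_biomarkers(self.patterns_for(table), table, design,
                                   min_log10_fc=np.inf)
        assert not out["passes"].any()

    def test_pairing_requirement_uses_median_paired_difference(self):
        table, design = toy_cohort()
        out = candidate_biomarkers(self.patterns_for(table), table, design,
                                   require_pairs=True)
        assert bool(out.loc["tumor_marker", "passes"])
        # make the paired NAT exceed the tumor -> candidate fails
        table2 = table.copy()
        table2.loc["tumor_marker", "NAT_1"] = 1e6
        out2 = candidate_biomarkers(self.patterns_for(table2), table2, design,
                                    require_pairs=True)
        assert not out2.loc["tumor_marker", "passes"]

    def test_no_overlap_rejected(self):
        table, design = toy_cohort()
        with pytest.raises(ValueError, match="overlap"):
            candidate_biomarkers({"other": PatternCode(("up", "up", "up"))},
                                 table, design)


class TestDesignIO:
    def test_round_trip(self, tmp_path):
        _, design = toy_cohort()
        path = tmp_path / "design.tsv"
        write_design(design, path)
        back = read_design(path)
        assert back.groups == design.groups
        assert back.pairing == design.pairing

    def test_double_booked_nat_rejected(self):
        with pytest.raises(ValueError, match="paired"):
            CohortDesign(groups={"t1": "PCa", "t2": "PCa", "n1": "NAT"},
                         pairing={"t1": "n1", "t2": "n1"})
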