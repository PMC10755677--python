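from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from ribopause import (
    AnalysisParams,
    TrackSet,
    average_pause_scores,
    average_replicates,
    compare_conditions,
    enumerate_motif_sites,
    mann_whitney_u,
    pause_score,
    residue_enrichment,
    score_sites,
    site_score_ratios,
    xip_score_shift_test,
)

from .conftest import uniform_tracks


def mwu_brute_force(a, b, alternative="two-sided"):
    """Independent oracle: exhaust every labeling of the pooled sample,
    counting (a > b) pairs (+1) and ties (+1/2) directly."""
    pooled = list(a) + list(b)
    n1 = len(a)

    def u_stat(group_a, group_b):
        u = Fraction(0)
        for x in group_a:
            for y in group_b:
                if x > y:
                    u += 1
                elif x == y:
                    u += Fraction(1, 2)
        return u

    u_obs = u_stat(list(a), list(b))
    us = []
    idx_all = set(range(len(pooled)))
    for chosen in combinations(range(len(pooled)), n1):
        ga = [pooled[i] for i in chosen]
        gb = [pooled[i] for i in idx_all - set(chosen)]
        us.append(u_stat(ga, gb))
    total = len(us)
    p_le = Fraction(sum(u <= u_obs for u in us), total)
    p_ge = Fraction(sum(u >= u_obs for u in us), total)
    if alternative == "less":
        return float(p_le)
    if alternative == "greater":
        return float(p_ge)
    return float(min(Fraction(1), 2 * min(p_le, p_ge)))


class TestEnumerateSites:
    def test_sliding_windows_of_toy_protein(self, toy_txome, loose_params):
        sites = enumerate_motif_sites(toy_txome, loose_params)
        assert list(sites["motif"]) == ["MKI", "KIP", "IPS"]
        assert list(sites["e_codon_index"]) == [0, 1, 2]
        # readout position = cds_start + 3e + 18
        assert list(sites["track_pos"]) == [28, 31, 34]

    def test_toy_gene_sites_ineligible_near_edges(self, toy_txome, loose_params):
        sites = enumerate_motif_sites(toy_txome, loose_params)
        assert not sites["eligible"].any()
        assert (sites["reason"] == "window_out_of_bounds").all()

    def test_occurrence_filter_flags(self, toy_txome):
        p100 = AnalysisParams()  # default threshold 100
        sites = enumerate_motif_sites(toy_txome, p100)
        assert not sites["motif_retained"].any()
        p1 = AnalysisParams(min_motif_occurrences=1)
        assert enumerate_motif_sites(toy_txome, p1)["motif_retained"].all()

    def test_eligible_window_inside_trimmed_orf(self, small_sim, loose_params):
        _, txome, _ = small_sim
        sites = enumerate_motif_sites(txome, loose_params)
        w, trim = loose_params.pause_window, loose_params.end_trim
        for row in sites[sites.eligible].sample(30, random_state=1).itertuples():
            g = txome[row.gene_id]
            assert row.track_pos - w >= g.cds_start + trim
            assert row.track_pos + w <= g.cds_end - trim - 1
            assert g.protein[row.e_codon_index : row.e_codon_index + 3] == row.motif


class TestPauseScore:
    def test_uniform_track_scores_exactly_one(self, loose_params):
        values = np.full(300, 1.0)
        assert pause_score(values, 150, loose_params) == 1.0

    def test_single_spike_direct_arithmetic(self, loose_params):
        # all-zero except 101 rpm at the site: window mean 1, score 101
        values = np.zeros(300)
        values[99] = 101.0
        assert pause_score(values, 99, loose_params) == 101.0

    def test_window_crossing_array_edge_is_nan(self, loose_params):
        values = np.ones(300)
        assert np.isnan(pause_score(values, 28, loose_params))

    def test_zero_window_is_nan_not_error(self, loose_params):
        assert np.isnan(pause_score(np.zeros(300), 150, loose_params))

    @given(seed=st.integers(0, 10_000))
    @settings(deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture], max_examples=60)
    def test_matches_independent_ratio_exactly(self, seed, loose_params):
        rng = np.random.default_rng(seed)
        L = int(rng.integers(101, 301))
        values = rng.poisson(2.0, L).astype(float)
        pos = int(rng.integers(50, L - 50))
        expected = (
            values[pos] / values[pos - 50 : pos + 51].mean()
            if values[pos - 50 : pos + 51].mean() > 0
            else np.nan
        )
        got = pause_score(values, pos, loose_params)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    @given(k=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    @settings(deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture], max_examples=40)
    def test_scale_invariance(self, k, seed, loose_params):
        rng = np.random.default_rng(seed)
        values = rng.poisson(3.0, 300).astype(float) + 1.0
        pos = 150
        s1 = pause_score(values, pos, loose_params)
        s2 = pause_score(values * k, pos, loose_params)
        assert s2 == pytest.approx(s1, rel=1e-9)

    def test_score_sites_bitwise_equals_scalar_definition(self, small_sim, loose_params):
        from ribopause import build_track, size_select, simulate_footprints

        _, txome, sim = small_sim
        tracks = build_track(
            size_select(sim.alignments, "monosome", loose_params), txome
        )
        sites = enumerate_motif_sites(txome, loose_params)
        scored = score_sites(tracks, sites, loose_params)
        ok = scored[scored["score"].notna()]
        for row in ok.sample(100, random_state=0).itertuples():
            assert row.score == pause_score(
                tracks.values[row.gene_id], row.track_pos, loose_params
            )


class TestAveragesAndComparison:
    def _scored(self, rows):
        df = pd.DataFrame(
            rows,
            columns=["gene_id", "motif", "e_codon_index", "score"],
        )
        df["motif_retained"] = True
        return df

    def test_motif_average_is_arithmetic_mean(self, loose_params):
        scored = self._scored([("g", "KIP", 1, 1.0), ("g", "KIP", 9, 3.0)])
        tbl = average_pause_scores(scored, loose_params)
        assert tbl.set_index("motif").loc["KIP", "avg_score"] == 2.0

    def test_single_site_average(self, loose_params):
        tbl = average_pause_scores(self._scored([("g", "AAA", 1, 2.0)]), loose_params)
        assert tbl.set_index("motif").loc["AAA", "avg_score"] == 2.0

    def test_nan_sites_excluded_from_average(self, loose_params):
        scored = self._scored(
            [("g", "KIP", 1, 4.0), ("g", "KIP", 9, float("nan"))]
        )
        tbl = average_pause_scores(scored, loose_params)
        row = tbl.set_index("motif").loc["KIP"]
        assert (row.n_sites, row.avg_score) == (1, 4.0)

    def test_replicates_averaged_at_motif_level(self):
        t1 = pd.DataFrame({"motif": ["KIP"], "n_sites": [5], "avg_score": [1.0]})
        t2 = pd.DataFrame({"motif": ["KIP"], "n_sites": [5], "avg_score": [3.0]})
        out = average_replicates([t1, t2])
        assert out.loc[0, "avg_score"] == 2.0

    def test_fold_and_foreground_split(self, params):
        a = pd.DataFrame({"motif": ["KIP", "AAA"], "n_sites": [2, 2], "avg_score": [3.0, 1.0]})
        b = pd.DataFrame({"motif": ["KIP", "AAA"], "n_sites": [2, 2], "avg_score": [1.5, 1.0]})
        cmp = compare_conditions(a, b, params)
        fg = set(cmp[cmp.foreground]["motif"])
        bg = set(cmp[~cmp.foreground]["motif"])
        assert fg == {"KIP"} and bg == {"AAA"}

    def test_partition_covers_universe(self, params):
        rng = np.random.default_rng(0)
        motifs = [f"M{i:03d}" for i in range(50)]
        a = pd.DataFrame({"motif": motifs, "n_sites": 3, "avg_score": rng.uniform(0.5, 2, 50)})
        b = pd.DataFrame({"motif": motifs, "n_sites": 3, "avg_score": rng.uniform(0.5, 2, 50)})
        cmp = compare_conditions(a, b, params)
        assert cmp.foreground.sum() + (~cmp.foreground).sum() == 50

    def test_identical_tables_give_empty_foreground(self, params):
        t = pd.DataFrame({"motif": ["KIP"], "n_sites": [2], "avg_score": [2.0]})
        assert not compare_conditions(t, t, params).foreground.any()

    def test_one_sided_motifs_reported_and_dropped(self, params):
        a = pd.DataFrame({"motif": ["KIP", "AAA"], "n_sites": [2, 2], "avg_score": [1.0, 1.0]})
        b = pd.DataFrame({"motif": ["KIP"], "n_sites": [2], "avg_score": [1.0]})
        cmp = compare_conditions(a, b, params)
        assert set(cmp["motif"]) == {"KIP"}
        assert cmp.attrs["dropped_motifs"] == ["AAA"]

    def test_site_ratios_drop_sites_ineligible_in_either(self):
        base = dict(motif="KIP")
        a = pd.DataFrame(
            [
                {"gene_id": "g", "e_codon_index": 1, "score": 2.0, **base},
                {"gene_id": "g", "e_codon_index": 9, "score": np.nan, **base},
            ]
        )
        b = pd.DataFrame(
            [
                {"gene_id": "g", "e_codon_index": 1, "score": 1.0, **base},
                {"gene_id": "g", "e_codon_index": 9, "score": 1.0, **base},
            ]
        )
        ratios, dropped = site_score_ratios(a, b)
        assert dropped == 1
        assert list(ratios["ratio"]) == [2.0]


class TestMannWhitney:
    def test_small_sample_exact_against_enumeration(self):
        res = mann_whitney_u([1, 2], [3, 4], alternative="less")
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(1 / 6)
        assert res.pvalue == pytest.approx(mwu_brute_force([1, 2], [3, 4], "less"))
        two = xip_score_shift_test([1, 2], [3, 4])
        assert two.pvalue == pytest.approx(1 / 3)

    def test_extreme_separation_exact_probability(self):
        a, b = list(range(1, 11)), list(range(11, 21))
        res = mann_whitney_u(a, b)
        assert res.pvalue == pytest.approx(2 / comb(20, 10))

    def test_identical_samples_p_one_with_ties(self):
        assert xip_score_shift_test([5, 5, 5], [5, 5, 5]).pvalue == 1.0
        big = [1.0] * 15
        assert mann_whitney_u(big, big, method="asymptotic").pvalue == 1.0

    @given(
        a=st.lists(st.integers(0, 8), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 8), min_size=1, max_size=5),
    )
    @settings(deadline=None, suppress_health_check=[HealthCheck.function_scoped_fixture], max_examples=30)
    def test_exact_path_matches_oracle_with_ties(self, a, b):
        res = mann_whitney_u(a, b)
        assert res.pvalue == pytest.approx(mwu_brute_force(a, b), abs=1e-12)

    def test_asymptotic_close_to_enumeration_at_n20(self):
        a, b = list(range(1, 11)), list(range(11, 21))
        exact = mann_whitney_u(a, b).pvalue
        approx = mann_whitney_u(a, b, method="asymptotic").pvalue
        assert abs(approx - exact) < 1e-3

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestResidueEnrichment:
    def test_log_odds_arithmetic(self):
        # fg: 8/10 motifs with P in the A site; bg: 5/100
        fg = ["AA" + ("P" if i < 8 else "G") for i in range(10)]
        bg = ["GA" + ("P" if i < 5 else "G") for i in range(100)]
        # raw (unpseudocounted) log2((8/10)/(5/100)) = 4.0; assert the
        # pseudocounted value by the same independent formula
        tbl = residue_enrichment(fg, bg).set_index(["position", "residue"])
        expected = np.log2(((8 + 0.5) / 11) / ((5 + 0.5) / 101))
        assert tbl.loc[("A", "P"), "log2_odds"] == pytest.approx(expected)
        assert np.log2((8 / 10) / (5 / 100)) == 4.0

    def test_equal_frequencies_give_near_zero_log_odds(self):
        # per-position residue counts identical between the two sets
        fg = ["KIP", "AGA"]
        bg = ["KIA", "AGP"]
        tbl = residue_enrichment(fg, bg)
        assert np.allclose(tbl["log2_odds"], 0.0, atol=1e-12)

    def test_residue_absent_from_both_is_zero_for_equal_sizes(self):
        tbl = residue_enrichment(["KIP"], ["AGA"]).set_index(["position", "residue"])
        assert tbl.loc[("E", "W"), "log2_odds"] == 0.0

    def test_empty_foreground_is_error(self):
        with pytest.raises(ValueError, match="foreground"):
            residue_enrichment([], ["AAA"])

    def test_overlapping_sets_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            residue_enrichment(["KIP"], ["KIP", "AAA"])
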