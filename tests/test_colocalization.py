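"""HRI cliques, hot windows, permutation null, intensity, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest

from recland import colocalization as co
from recland import synthetic_data as sd


def hri_frame(spans, chrom="1A", lam=5.0):
    return pd.DataFrame([
        {"chrom": chrom, "start": s, "end": e, "summary_lambda": lam}
        for s, e in spans])


def brute_force_cliques(hris_by_pop):
    """Subset enumeration oracle for maximal mutually-overlapping sets."""
    nodes = [(p, i) for p, df in hris_by_pop.items() for i in df.index]

    def overlap(a, b):
        ra = hris_by_pop[a[0]].loc[a[1]]
        rb = hris_by_pop[b[0]].loc[b[1]]
        return (a[0] != b[0] and ra.chrom == rb.chrom
                and max(ra.start, rb.start) < min(ra.end, rb.end))

    cliques = []
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(overlap(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    maximal = [c for c in cliques
               if not any(c < other for other in cliques)]
    return {frozenset(c) for c in maximal}


class TestCliques:
    def test_chain_of_three(self):
        hris = {"A": hri_frame([(0, 10)]), "B": hri_frame([(5, 15)]),
                "C": hri_frame([(12, 20)])}
        cliques = {frozenset(c) for c in co.build_overlap_cliques(hris)}
        assert cliques == {frozenset({("A", 0), ("B", 0)}),
                           frozenset({("B", 0), ("C", 0)})}

    def test_four_mutual_overlaps_single_clique(self):
        hris = {p: hri_frame([(0 + i, 20 + i)])
                for i, p in enumerate("ABCD")}
        cliques = co.build_overlap_cliques(hris)
        assert len(cliques) == 1 and len(cliques[0]) == 4

    def test_disjoint_singletons(self):
        hris = {"A": hri_frame([(0, 5)]), "B": hri_frame([(10, 15)])}
        cliques = co.build_overlap_cliques(hris)
        assert sorted(len(c) for c in cliques) == [1, 1]

    def test_agrees_with_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(0)
        for trial in range(60):
            hris = {}
            for p in "ABCD":
                n = rng.integers(1, 4)
                starts = np.sort(rng.integers(0, 60, n)) * 10
                # keep same-population HRIs disjoint (post-merge invariant)
                starts = np.unique(starts)
                ends = starts + rng.integers(1, 9, len(starts)) * 10
                ends = np.minimum(ends, np.append(starts[1:], 10_000))
                keep = ends > starts
                hris[p] = hri_frame(list(zip(starts[keep], ends[keep])))
            got = {frozenset(c) for c in co.build_overlap_cliques(hris)}
            assert got == brute_force_cliques(hris), f"trial {trial}"


class TestHotWindows:
    def test_intersection_for_pairs(self):
        hris = {"A": hri_frame([(0, 10)]), "B": hri_frame([(5, 15)])}
        win = co.hot_windows(co.build_overlap_cliques(hris), hris)
        assert (win.start.iloc[0], win.end.iloc[0]) == (5, 10)
        assert win.level.iloc[0] == 2

    def test_singleton_own_span(self):
        hris = {"A": hri_frame([(3, 7)])}
        win = co.hot_windows(co.build_overlap_cliques(hris), hris)
        assert (win.start.iloc[0], win.end.iloc[0]) == (3, 7)

    def test_nested_spans_innermost(self):
        hris = {p: hri_frame([(i, 100 - i)]) for i, p in enumerate("ABCD")}
        win = co.hot_windows(co.build_overlap_cliques(hris), hris)
        assert (win.start.iloc[0], win.end.iloc[0]) == (3, 97)

    def test_every_hri_in_some_window(self):
        rng = np.random.default_rng(3)
        hris = {}
        for p in "ABCD":
            starts = np.unique(np.sort(rng.integers(0, 50, 5)) * 20)
            hris[p] = hri_frame(list(zip(starts, starts + 15)))
        cliques = co.build_overlap_cliques(hris)
        covered = {n for c in cliques for n in c}
        expected = {(p, i) for p, df in hris.items() for i in df.index}
        assert covered == expected
        win = co.hot_windows(cliques, hris)
        assert len(win) == len(cliques)


class TestSharing:
    def test_proportions_by_level(self):
        win = pd.DataFrame({
            "chrom": "1A", "start": [0, 10, 20], "end": [5, 15, 25],
            "level": [4, 2, 1],
            "populations": ["A,B,C,D", "A,B", "C"],
            "lambdas": ["5,6,7,8", "4,9", "5"]})
        s = co.sharing_proportions(win)
        assert s.proportions == {4: 1 / 3, 2: 1 / 3, 1: 1 / 3}
        assert sum(s.counts.values()) == s.n_windows == 3
        assert s.median_lambda[4] == 6.5  # brute-force median of {5,6,7,8}
        assert np.isclose(s.shared_proportion, 2 / 3)

    def test_identical_hris_all_level4(self):
        hris = {p: hri_frame([(0, 10), (50, 60)]) for p in "ABCD"}
        win = co.hot_windows(co.build_overlap_cliques(hris), hris)
        s = co.sharing_proportions(win)
        assert s.proportions == {4: 1.0}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            co.sharing_proportions(pd.DataFrame(columns=["level", "lambdas"]))


class TestPermutationNull:
    def test_reproducible_under_seed(self, scheme):
        grid = sd.make_interval_grid(scheme, interval_bp=1_000_000)
        hris = {p: hri_frame([(0, 1_000_000), (30_000_000, 31_000_000)])
                for p in "AB"}
        n1 = co.permutation_null(hris, grid, scheme, n_sim=50, seed=4)
        n2 = co.permutation_null(hris, grid, scheme, n_sim=50, seed=4)
        assert (n1.level_proportions == n2.level_proportions).all()
        assert n1.p_value == n2.p_value

    def test_sparse_null_mostly_specific(self, scheme):
        # 1 HRI per population in a large region: collisions are rare
        grid = sd.make_interval_grid(scheme, interval_bp=20_000)  # 1000/region
        hris = {p: hri_frame([(0, 20_000)]) for p in "ABCD"}
        null = co.permutation_null(hris, grid, scheme, n_sim=400, seed=8)
        assert null.level_proportions[:, 0].mean() >= 0.99

    def test_fast_path_matches_generic_cliques(self, scheme):
        # permuted HRIs occupy single grid intervals; collision counting
        # must equal the full clique machinery on the same configuration
        grid = sd.make_interval_grid(scheme, interval_bp=1_000_000)
        ints = grid.intervals
        rng = np.random.default_rng(12)
        for _ in range(20):
            hris = {}
            for p in "ABCD":
                idx = rng.choice(len(ints), size=6, replace=False)
                df = ints.iloc[np.sort(idx)][["chrom", "start", "end"]].copy()
                df["summary_lambda"] = 5.0
                hris[p] = df.reset_index(drop=True)
            win = co.hot_windows(co.build_overlap_cliques(hris), hris)
            s = co.sharing_proportions(win)
            # recompute via interval-collision counting
            key = {}
            for p, df in hris.items():
                for _, r in df.iterrows():
                    key.setdefault((r.chrom, r.start), []).append(p)
            levels = pd.Series([len(v) for v in key.values()]).value_counts()
            assert s.counts == {int(k): int(v) for k, v in levels.items()}

    def test_too_many_hris_errors(self, small_scheme):
        grid = sd.make_interval_grid(small_scheme, interval_bp=5_000_000)
        hris = {"A": hri_frame([(0, 10), (20, 30), (40, 50)])}
        with pytest.raises(ValueError, match="more HRIs"):
            co.permutation_null(hris, grid, small_scheme, n_sim=5, seed=0)

    def test_pinned_degenerate_all_level4(self, small_scheme):
        # every population's single HRI in a region with a single interval
        grid = sd.make_interval_grid(small_scheme, interval_bp=5_000_000)
        hris = {p: hri_frame([(0, 2_000_000)]) for p in "ABCD"}
        null = co.permutation_null(hris, grid, small_scheme, n_sim=30, seed=1)
        assert (null.level_proportions[:, 3] == 1.0).all()


class TestIntensityProfile:
    def test_flat_field_flat_profile(self):
        hris = hri_frame([(100_000, 120_000)])
        prof = pd.DataFrame({
            "chrom": "1A",
            "start": np.arange(0, 300_000, 10_000),
            "end": np.arange(10_000, 310_000, 10_000)})
        prof["median_lambda"] = 1.0
        out = co.intensity_profile(hris, prof, max_dist=50_000, bin_bp=10_000)
        assert np.allclose(out["mean_lambda"].dropna(), 1.0)

    def test_planted_shared_spike_enriched_at_center(self, scheme):
        grid = sd.make_interval_grid(scheme, interval_bp=20_000)
        sigma = sd.equicorrelated_sigma(0.3, [0.25] * 4)
        design = sd.SharingDesign(n_spikes_per_region=6,
                                  level_probs=(0, 1.0, 0, 0))
        posts, truth = sd.simulate_lambda_profiles(
            grid, scheme, sigma, sharing=design, S=20, seed=21)
        from recland import ld_profiles as lp
        pops = list(sd.POPULATIONS)
        prof = {p: lp.median_lambda(posts[p]) for p in pops}
        hris_a = lp.call_hris(prof[pops[0]])
        # population b's intensity around a's HRIs: center above background
        out = co.intensity_profile(hris_a, prof[pops[1]],
                                   max_dist=100_000, bin_bp=20_000)
        center = out["mean_lambda"].iloc[len(out) // 2]
        background = (out["mean_lambda"].iloc[0] + out["mean_lambda"].iloc[-1]) / 2
        assert center > 2 * background

    def test_no_hris_errors(self):
        with pytest.raises(ValueError):
            co.intensity_profile(hri_frame([]), pd.DataFrame(), 10_000, 1000)


class TestFeatureEnrichment:
    def test_odds_ratio_known_table(self):
        # build interval sets realizing the table (10, 90; 100, 9800)
        step = 100
        test = [(i * step, i * step + 50) for i in range(100)]
        rest = [(100_000 + i * step, 100_000 + i * step + 50)
                for i in range(9900)]
        feats = [t for t in test[:10]] + [r for r in rest[:100]]
        universe = hri_frame(test + rest)
        out = co.feature_enrichment(hri_frame(test), hri_frame(feats), universe)
        assert out["table"] == (10, 90, 100, 9800)
        assert np.isclose(out["odds_ratio"], (10 * 9800) / (90 * 100))
        assert out["p_value"] < 0.01

    def test_equal_proportions_or_one(self):
        test = [(i * 100, i * 100 + 50) for i in range(20)]
        rest = [(10_000 + i * 100, 10_000 + i * 100 + 50) for i in range(20)]
        feats = test[:10] + rest[:10]
        out = co.feature_enrichment(hri_frame(test), hri_frame(feats),
                                    hri_frame(test + rest))
        assert np.isclose(out["odds_ratio"], 1.0)

    def test_zero_cell_corrected(self):
        test = [(0, 50), (100, 150)]
        rest = [(1000, 1050)]
        feats = test  # every test interval hit, none of the rest
        out = co.feature_enrichment(hri_frame(test), hri_frame(feats),
                                    hri_frame(test + rest))
        assert out["corrected"] and np.isfinite(out["odds_ratio"])

    def test_empty_universe_errors(self):
        with pytest.raises(ValueError):
            co.feature_enrichment(hri_frame([(0, 1)]), hri_frame([]),
                                  hri_frame([]))


class TestFeatureIO:
    def test_gff3_gene_reader_half_open(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(
            "##gff-version 3\n"
            "1A\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1;Name=alpha\n"
            "1A\tsrc\texon\t101\t150\t.\t+\t.\tID=g1.e1\n"
            "2A\tsrc\tgene\t1\t50\t.\t-\t.\tName=beta\n")
        genes = co.read_genes_gff3(p)
        assert len(genes) == 2  # exon row skipped
        assert (genes["start"].iloc[0], genes["end"].iloc[0]) == (100, 200)
        assert genes["gene"].iloc[0] == "g1"
        assert genes["gene"].iloc[1] == "beta"

    def test_bed_feature_reader(self, tmp_path):
        p = tmp_path / "f.bed"
        p.write_text("#c\ts\te\n1A\t0\t10\tx\n1A\t20\t30\ty\n")
        feats = co.read_features_bed(p)
        assert list(feats["end"]) == [10, 30]
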