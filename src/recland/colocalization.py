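"""Cross-population HRI comparison: cliques, hot windows, permutation null.

HRIs from up to four populations are compared on the interval-overlap
graph: a set of HRIs colocalizes if every pair overlaps (a clique; for 1-D
intervals pairwise overlap implies a common span). Each clique defines a
hot window — the smallest common overlapped area — whose sharing level is
the clique size; population-specific HRIs form level-1 windows spanning
the HRI itself. Chance colocalization is quantified by re-assigning each
HRI to a random interval within its genomic region and recomputing the
sharing proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .genome_model import IntervalGrid, RegionScheme


def build_overlap_cliques(hris_by_pop: dict[str, pd.DataFrame]) -> list[list[tuple[str, int]]]:
    """Maximal cliques of mutually overlapping HRIs across populations.

    Nodes are (population, row index); edges join overlapping HRIs (>= 1 bp
    shared, half-open) of *different* populations. A wide HRI may belong to
    several maximal cliques. Isolated HRIs come back as singleton cliques.
    """
    G = nx.Graph()
    pops = list(hris_by_pop)
    for pop in pops:
        for i in hris_by_pop[pop].index:
            G.add_node((pop, int(i)))
    for ia, pa in enumerate(pops):
        a = hris_by_pop[pa]
        for pb in pops[ia + 1:]:
            b = hris_by_pop[pb]
            for chrom in set(a["chrom"]) & set(b["chrom"]):
                ga = a[a["chrom"] == chrom]
                gb = b[b["chrom"] == chrom]
                tree = IntervalTree()
                for i, r in ga.iterrows():
                    tree[r.start:r.end] = int(i)
                for j, r in gb.iterrows():
                    for hit in tree[r.start:r.end]:
                        G.add_edge((pa, hit.data), (pb, int(j)))
    return [sorted(c) for c in nx.find_cliques(G)]


def hot_windows(cliques: list[list[tuple[str, int]]],
                hris_by_pop: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Smallest common overlapped area of each clique.

    Level >= 2 windows are the intersection of member spans; level-1 windows
    are bounded by the HRI's own limits. Columns: chrom, start, end, level,
    populations (comma list), lambdas (comma list of member summary lambdas).
    """
    rows = []
    for clique in cliques:
        spans = []
        lams = []
        pops = []
        for pop, idx in clique:
            r = hris_by_pop[pop].loc[idx]
            spans.append((r.chrom, int(r.start), int(r.end)))
            lams.append(float(r.get("summary_lambda", np.nan)))
            pops.append(pop)
        chrom = spans[0][0]
        start = max(s for _, s, _ in spans)
        end = min(e for _, _, e in spans)
        if start >= end:
            raise AssertionError(f"clique {clique} has empty intersection")
        rows.append((chrom, start, end, len(clique),
                     ",".join(pops), ",".join(f"{l:g}" for l in lams)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "level", "populations", "lambdas"])


@dataclass
class SharingSummary:
    """Hot-window counts/proportions and median member lambda by sharing level."""

    counts: dict[int, int]
    proportions: dict[int, float]
    median_lambda: dict[int, float]
    n_windows: int

    @property
    def shared_proportion(self) -> float:
        """Proportion of hot windows shared by two or more populations."""
        return sum(v for k, v in self.proportions.items() if k >= 2)


def sharing_proportions(windows: pd.DataFrame) -> SharingSummary:
    """Per-level hot-window counts divided by the total number of hot windows."""
    if windows.empty:
        raise ValueError("no hot windows")
    counts = {}
    med = {}
    for level, g in windows.groupby("level"):
        counts[int(level)] = len(g)
        lams = [float(x) for row in g["lambdas"] for x in str(row).split(",")
                if x not in ("", "nan")]
        med[int(level)] = float(np.median(lams)) if lams else float("nan")
    n = len(windows)
    props = {k: v / n for k, v in counts.items()}
    return SharingSummary(counts, props, med, n)


@dataclass
class PermutationNull:
    """Null distributions of sharing proportions under random HRI placement."""

    n_sim: int
    seed: int
    level_proportions: np.ndarray      # (n_sim, 4), proportion per level 1..4
    shared: np.ndarray                 # (n_sim,), proportion of level>=2 windows
    observed: SharingSummary
    p_value: float                     # exceedance of observed shared proportion

    def envelope(self, level: int, alpha: float = 0.05) -> tuple[float, float]:
        x = self.level_proportions[:, level - 1]
        return (float(np.quantile(x, alpha / 2)),
                float(np.quantile(x, 1 - alpha / 2)))


def _assign_intervals_to_regions(grid: IntervalGrid, scheme: RegionScheme) -> np.ndarray:
    ints = grid.intervals
    return np.array([
        f"{c}{scheme.assign(c, int(s))}"
        for c, s in zip(ints["chrom"], ints["start"])
    ])


def _null_level_proportions(counts_by_region: dict[str, dict[str, int]],
                            intervals_per_region: dict[str, int],
                            n_sim: int, n_pops: int,
                            rng: np.random.Generator) -> np.ndarray:
    """Fast exact null: permuted HRIs occupy one grid interval each.

    Grid intervals are disjoint, so two permuted HRIs overlap iff they land
    on the same interval; a clique is the set of populations hitting one
    interval and its hot window has level = that multiplicity. Sampling is
    without replacement within population x region.
    """
    level_counts = np.zeros((n_sim, n_pops), dtype=np.int32)
    sim_rows = np.arange(n_sim)[:, None]
    for region, pop_counts in counts_by_region.items():
        n_int = intervals_per_region[region]
        hits = np.zeros((n_sim, n_int), dtype=np.int8)
        for pop, m in pop_counts.items():
            if m == 0:
                continue
            u = rng.random((n_sim, n_int))
            idx = np.argpartition(u, m - 1, axis=1)[:, :m]
            hits[sim_rows, idx] += 1
        for k in range(1, n_pops + 1):
            level_counts[:, k - 1] += (hits == k).sum(axis=1, dtype=np.int32)
    totals = level_counts.sum(axis=1)
    totals = np.where(totals == 0, 1, totals)
    return level_counts / totals[:, None]


def permutation_null(hris_by_pop: dict[str, pd.DataFrame], grid: IntervalGrid,
                     scheme: RegionScheme, n_sim: int = 1000,
                     seed: int | None = None) -> PermutationNull:
    """Region-stratified permutation null for HRI sharing.

    Each HRI is re-assigned to a uniformly drawn grid interval within its
    genomic region (without replacement within population x region), and the
    sharing proportions are recomputed. The empirical exceedance p-value of
    the observed shared proportion carries the +1 correction
    (1 + #{null >= obs}) / (n_sim + 1).
    """
    rng = np.random.default_rng(seed)
    region_of_interval = _assign_intervals_to_regions(grid, scheme)
    intervals_per_region = pd.Series(region_of_interval).value_counts().to_dict()
    pops = list(hris_by_pop)
    counts_by_region: dict[str, dict[str, int]] = {}
    for pop, df in hris_by_pop.items():
        for _, r in df.iterrows():
            reg = f"{r.chrom}{scheme.assign(r.chrom, int(r.start))}"
            counts_by_region.setdefault(reg, {}).setdefault(pop, 0)
            counts_by_region[reg][pop] += 1
    for reg, pc in counts_by_region.items():
        if reg not in intervals_per_region:
            raise ValueError(f"region {reg}: no grid intervals")
        if max(pc.values()) > intervals_per_region[reg]:
            raise ValueError(f"region {reg}: more HRIs than grid intervals")
    observed = sharing_proportions(
        hot_windows(build_overlap_cliques(hris_by_pop), hris_by_pop))
    props = _null_level_proportions(
        counts_by_region, intervals_per_region, n_sim, len(pops), rng)
    shared = props[:, 1:].sum(axis=1)
    p = (1 + int(np.sum(shared >= observed.shared_proportion))) / (n_sim + 1)
    return PermutationNull(n_sim, -1 if seed is None else seed,
                           props, shared, observed, p)


def intensity_profile(hris_a: pd.DataFrame, profile_b: pd.DataFrame,
                      max_dist: int = 100_000, bin_bp: int = 10_000) -> pd.DataFrame:
    """Mean intensity of population b around the HRI centers of population a.

    For each HRI center (span midpoint), median-lambda values of b's
    intervals (at their midpoints) are averaged within signed distance bins;
    the profile is the per-bin mean across HRIs. The outermost bins serve as
    the background level.
    """
    if max_dist % bin_bp:
        raise ValueError("bin_bp must divide max_dist")
    if hris_a.empty:
        raise ValueError("no HRIs to profile around")
    edges = np.arange(-max_dist, max_dist + bin_bp, bin_bp)
    centers = (edges[:-1] + edges[1:]) / 2
    acc = np.zeros(len(centers))
    cnt = np.zeros(len(centers))
    for chrom, g in hris_a.groupby("chrom", sort=False):
        b = profile_b[profile_b["chrom"] == chrom]
        if b.empty:
            continue
        mid_b = ((b["start"] + b["end"]) / 2).to_numpy()
        lam_b = b["median_lambda"].to_numpy()
        order = np.argsort(mid_b)
        mid_b, lam_b = mid_b[order], lam_b[order]
        for _, r in g.iterrows():
            center = (r.start + r.end) / 2
            d = mid_b - center
            sel = (d >= -max_dist) & (d < max_dist)
            if not sel.any():
                continue
            which = ((d[sel] + max_dist) // bin_bp).astype(int)
            per_bin = np.full(len(centers), np.nan)
            for k in np.unique(which):
                per_bin[k] = lam_b[sel][which == k].mean()
            ok = ~np.isnan(per_bin)
            acc[ok] += per_bin[ok]
            cnt[ok] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(cnt > 0, acc / np.where(cnt > 0, cnt, 1), np.nan)
    return pd.DataFrame({"dist_bp": centers, "mean_lambda": mean, "n_hris": cnt.astype(int)})


def feature_enrichment(test: pd.DataFrame, features: pd.DataFrame,
                       universe: pd.DataFrame) -> dict:
    """Overlap enrichment of a test interval set against a feature set.

    2x2 table of (test vs rest-of-universe) x (overlapping a feature or
    not); odds ratio with the Haldane-Anscombe +0.5 correction on zero
    cells, and a two-sided Fisher exact p-value.
    """
    if universe.empty:
        raise ValueError("empty universe")
    trees: dict[str, IntervalTree] = {}
    for chrom, g in features.groupby("chrom", sort=False):
        t = IntervalTree()
        for _, r in g.iterrows():
            t[r.start:r.end] = True
        trees[chrom] = t

    def overlaps(df: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(df), dtype=bool)
        for i, (_, r) in enumerate(df.iterrows()):
            t = trees.get(r.chrom)
            out[i] = bool(t and t.overlap(r.start, r.end))
        return out

    test_keys = set(map(tuple, test[["chrom", "start", "end"]].itertuples(index=False)))
    uni_keys = list(map(tuple, universe[["chrom", "start", "end"]].itertuples(index=False)))
    comp = universe[[k not in test_keys for k in uni_keys]]
    t_hit = int(overlaps(test).sum())
    c_hit = int(overlaps(comp).sum())
    a, b_, c, d = t_hit, len(test) - t_hit, c_hit, len(comp) - c_hit
    corrected = 0 in (a, b_, c, d)
    if corrected:
        odds = ((a + .5) * (d + .5)) / ((b_ + .5) * (c + .5))
    else:
        odds = (a * d) / (b_ * c)
    _, p = stats.fisher_exact([[a, b_], [c, d]], alternative="two-sided")
    return {"table": (a, b_, c, d), "odds_ratio": float(odds),
            "p_value": float(p), "proportion": a / len(test) if len(test) else np.nan,
            "corrected": corrected}


def read_features_bed(path) -> pd.DataFrame:
    """Feature intervals from BED (first three columns used)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     dtype={0: str})
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    return out


def read_genes_gff3(path, feature_type: str = "gene") -> pd.DataFrame:
    """Gene intervals from a GFF3 subset (rows of the given type).

    GFF3 is 1-based inclusive; output is 0-based half-open. The ID
    attribute (or Name) becomes the ``gene`` column.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != feature_type:
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            name = attrs.get("ID", attrs.get("Name", f"{f[0]}:{f[3]}"))
            rows.append((str(f[0]), int(f[3]) - 1, int(f[4]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def write_hot_windows(windows: pd.DataFrame, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tlevel\tpopulations\tlambdas\n")
        windows.to_csv(fh, sep="\t", header=False, index=False)


def write_null_distributions(null: PermutationNull, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#sim_index\tlevel\tproportion\n")
        for s in range(null.n_sim):
            for lev in range(null.level_proportions.shape[1]):
                fh.write(f"{s}\t{lev + 1}\t{float(null.level_proportions[s, lev])!r}\n")
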