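"""Genomic coordinate system, chromosome region scheme, and interval grids.

All coordinates are 0-based, half-open, in base pairs; megabases appear only
in rate denominators. Chromosomes are partitioned into the five canonical
wheat regions: recombining telomeric R1/R3, low-recombining pericentromeric
R2a/R2b, and the suppressed centromeric C. Interval grids harmonize
per-population native interval sets (successive polymorphic markers) onto a
common breakpoint union so profiles can be compared position by position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGION_LABELS = ("R1", "R2a", "C", "R2b", "R3")


class FormatError(ValueError):
    """Malformed input file or interval set."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return (self.end - self.start) / 1e6


@dataclass
class RegionScheme:
    """Ordered R1/R2a/C/R2b/R3 segmentation of each chromosome.

    ``segments`` maps chromosome id to a DataFrame with columns
    ``start, end, label`` sorted by start; segments are contiguous and cover
    ``[0, chrom_length)``.
    """

    segments: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        for chrom, df in self.segments.items():
            df = df.sort_values("start").reset_index(drop=True)
            bad = set(df["label"]) - set(REGION_LABELS)
            if bad:
                raise FormatError(f"{chrom}: unknown region label(s) {sorted(bad)}")
            starts = df["start"].to_numpy()
            ends = df["end"].to_numpy()
            if starts[0] != 0:
                raise FormatError(f"{chrom}: scheme does not start at 0")
            if np.any(starts[1:] != ends[:-1]):
                raise FormatError(f"{chrom}: gapped or overlapping region segments")
            order = [REGION_LABELS.index(l) for l in df["label"]]
            if sorted(order) != order:
                raise FormatError(f"{chrom}: region labels out of R1,R2a,C,R2b,R3 order")
            self.segments[chrom] = df

    @property
    def chroms(self) -> list[str]:
        return list(self.segments)

    def chrom_length(self, chrom: str) -> int:
        return int(self.segments[chrom]["end"].iloc[-1])

    def assign(self, chrom: str, pos_bp: int) -> str:
        """Region label containing ``pos_bp`` (half-open segments)."""
        df = self.segments[chrom]
        if pos_bp < 0 or pos_bp >= self.chrom_length(chrom):
            raise ValueError(f"position {chrom}:{pos_bp} outside region scheme")
        idx = int(np.searchsorted(df["end"].to_numpy(), pos_bp, side="right"))
        return str(df["label"].iloc[idx])

    def region_ids(self) -> list[str]:
        """Genomic-region identifiers, e.g. '1AR1', in scheme order."""
        return [f"{c}{l}" for c in self.segments for l in self.segments[c]["label"]]


@dataclass
class GuideMap:
    """External genetic map (marker, chrom, pos_bp, cM) used to delimit windows.

    Genetic position must be non-decreasing with physical position within a
    chromosome.
    """

    markers: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"marker", "chrom", "pos_bp", "cM"}
        if not need <= set(self.markers.columns):
            raise FormatError(f"guide map needs columns {sorted(need)}")
        self.markers = self.markers.sort_values(["chrom", "pos_bp"]).reset_index(drop=True)
        for chrom, g in self.markers.groupby("chrom"):
            cm = g["cM"].to_numpy()
            if np.any(np.diff(cm) < 0):
                raise FormatError(f"{chrom}: genetic position decreases with bp")

    def chrom(self, chrom: str) -> pd.DataFrame:
        return self.markers[self.markers["chrom"] == chrom].reset_index(drop=True)


def read_guide_map(path) -> GuideMap:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["marker", "chrom", "pos_bp", "cM"], dtype={"chrom": str})
    return GuideMap(df)


def load_region_scheme(path) -> RegionScheme:
    """Read a region scheme from BED (chrom, start, end, label)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "label"], dtype={"chrom": str},
    )
    if df.empty:
        raise FormatError("empty region scheme BED")
    return RegionScheme(
        {str(c): g[["start", "end", "label"]].reset_index(drop=True)
         for c, g in df.groupby("chrom", sort=False)}
    )


def write_region_scheme(scheme: RegionScheme, path) -> None:
    rows = []
    for chrom, df in scheme.segments.items():
        for _, r in df.iterrows():
            rows.append((chrom, int(r.start), int(r.end), r.label))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tlabel\n")
        out.to_csv(fh, sep="\t", header=False, index=False)


def assign_region(chrom: str, pos_bp: int, scheme: RegionScheme) -> str:
    return scheme.assign(chrom, pos_bp)


@dataclass
class IntervalGrid:
    """Common interval grid over several populations' native interval sets.

    ``intervals`` has columns ``chrom, start, end`` plus one ``native_<pop>``
    column per population holding the row index of the containing native
    interval in that population's set.
    """

    intervals: pd.DataFrame
    populations: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()


def _check_native(df: pd.DataFrame, pop: str) -> pd.DataFrame:
    df = df.sort_values(["chrom", "start"]).reset_index(drop=False)
    for chrom, g in df.groupby("chrom"):
        if np.any(g["start"].to_numpy()[1:] < g["end"].to_numpy()[:-1]):
            raise FormatError(f"population {pop}: overlapping intervals on {chrom}")
    return df


def build_common_grid(native_sets: dict[str, pd.DataFrame]) -> IntervalGrid:
    """Union-of-breakpoints grid restricted to the span covered by all populations.

    Grid intervals not contained in a native interval of every population
    (uncovered chromosome extremities) are dropped. Each retained grid
    interval maps to exactly one native interval per population.
    """
    if not native_sets:
        raise ValueError("no native interval sets given")
    pops = list(native_sets)
    native = {p: _check_native(df, p) for p, df in native_sets.items()}
    chrom_sets = [set(df["chrom"]) for df in native.values()]
    chroms = sorted(set.union(*chrom_sets))
    pieces = []
    for chrom in chroms:
        if any(chrom not in s for s in chrom_sets):
            raise FormatError(f"chromosome {chrom} not covered by all populations")
        per_pop = {p: native[p][native[p]["chrom"] == chrom] for p in pops}
        bps = np.unique(np.concatenate(
            [np.concatenate([g["start"].to_numpy(), g["end"].to_numpy()])
             for g in per_pop.values()]
        ))
        grid = pd.DataFrame({"chrom": chrom, "start": bps[:-1], "end": bps[1:]})
        keep = np.ones(len(grid), dtype=bool)
        for p in pops:
            g = per_pop[p]
            starts, ends = g["start"].to_numpy(), g["end"].to_numpy()
            idx = np.searchsorted(starts, grid["start"].to_numpy(), side="right") - 1
            ok = (idx >= 0) & (grid["end"].to_numpy() <= ends[np.clip(idx, 0, None)])
            keep &= ok
            grid[f"native_{p}"] = np.where(ok, g["index"].to_numpy()[np.clip(idx, 0, None)], -1)
        grid = grid[keep]
        if grid.empty:
            raise FormatError(f"populations have disjoint coverage on chromosome {chrom}")
        pieces.append(grid)
    out = pd.concat(pieces, ignore_index=True)
    return IntervalGrid(out, pops)


def project_values(native_values: np.ndarray, grid: IntervalGrid, population: str) -> np.ndarray:
    """Carry per-native-interval values onto the grid (piecewise-constant rates).

    Rates are assumed constant within native intervals, so length-weighted
    sums (genetic distances) are conserved per native interval.
    """
    col = f"native_{population}"
    if col not in grid.intervals:
        raise KeyError(f"population {population!r} not in grid")
    idx = grid.intervals[col].to_numpy()
    if np.any(idx < 0):
        raise ValueError("grid interval without containing native interval")
    native_values = np.asarray(native_values)
    return native_values[idx]


def maf_filter(calls: pd.DataFrame, threshold: float, missing=("NA", "H", "-", "")) -> pd.Index:
    """Markers (rows) passing a within-population minor-allele-frequency filter.

    ``calls`` is markers x haplotypes; entries are allele codes (any hashable).
    Heterozygous ('H') and missing codes are excluded from the frequency
    denominator. MAF is the proportion of non-major alleles. Markers with
    MAF >= ``threshold`` are retained; threshold 0 retains all polymorphic
    markers.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    keep = []
    arr = calls.to_numpy()
    miss = set(missing)
    for i, row in enumerate(arr):
        vals = [v for v in row if v not in miss and not pd.isna(v)]
        if not vals:
            continue
        counts = pd.Series(vals).value_counts()
        if len(counts) < 2:
            continue  # monomorphic
        maf = 1.0 - counts.iloc[0] / counts.sum()
        if threshold == 0 or maf >= threshold - 1e-12:  # boundary inclusive
            keep.append(calls.index[i])
    if not keep:
        warnings.warn("no polymorphic markers retained by MAF filter")
    return pd.Index(keep)


def aggregate_windows(
    intervals: pd.DataFrame, values: np.ndarray, window_bp: int,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Length-weighted mean of per-interval rates over tiling windows.

    Intervals are clipped at window edges; windows with no interval coverage
    get NaN (missing), never zero. Returns columns
    ``chrom, start, end, value, covered_bp``.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    values = np.asarray(values, dtype=float)
    intervals = intervals.reset_index(drop=True)
    rows = []
    for chrom, g in intervals.groupby("chrom", sort=False):
        v = values[g.index.to_numpy()]
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        last = chrom_lengths[chrom] if chrom_lengths else int(ends.max())
        n_win = int(np.ceil(last / window_bp))
        num = np.zeros(n_win)
        den = np.zeros(n_win)
        w0 = starts // window_bp
        w1 = (ends - 1) // window_bp
        for i in range(len(starts)):
            for w in range(w0[i], w1[i] + 1):
                lo = max(starts[i], w * window_bp)
                hi = min(ends[i], (w + 1) * window_bp)
                num[w] += v[i] * (hi - lo)
                den[w] += hi - lo
        with np.errstate(invalid="ignore"):
            rate = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "start": np.arange(n_win) * window_bp,
            "end": np.minimum(np.arange(1, n_win + 1) * window_bp, last),
            "value": rate,
            "covered_bp": den.astype(int),
        }))
    return pd.concat(rows, ignore_index=True)
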