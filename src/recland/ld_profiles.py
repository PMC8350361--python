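"""LD-based recombination profiles: posterior ingestion, HRI calling, scaling.

An external coalescent-based sampler provides, per SNP window w, posterior
samples of a background population-scaled recombination rate rho_w (per kb)
and, per marker interval i, a multiplicative intensity lambda_i so that
rho_i = lambda_i * rho_w(i). Windows are laid out in genetic-distance units
on a guide map (central part ~1 cM, flanks ~0.5 cM overlapping neighbors to
absorb border effects; only central-part estimates are retained). Highly
recombining intervals (HRIs) are runs of adjacent intervals whose median
intensity reaches a threshold (default lambda >= 4), merged and
size-filtered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import FormatError, GuideMap, RegionScheme, aggregate_windows


@dataclass
class PhaseWindow:
    """SNP-index window: central span plus flanks overlapping the neighbors."""

    window_id: int
    chrom: str
    span: tuple[int, int]          # marker index range incl. flanks, half-open
    central: tuple[int, int]       # half-open marker index range
    left_flank: tuple[int, int]
    right_flank: tuple[int, int]

    @property
    def n_intervals(self) -> int:
        return self.span[1] - self.span[0] - 1


def build_phase_windows(guide: GuideMap, central_cM: float = 1.0,
                        flank_cM: float = 0.5) -> list[PhaseWindow]:
    """Tile each chromosome's markers into windows at cumulative-cM breakpoints.

    Central parts partition the markers at breakpoints of ``central_cM``
    (the marker closest to each cumulative-cM target); flanks extend
    ``flank_cM`` into the neighboring windows; the first/last windows lack
    outer flanks.
    """
    if central_cM <= 0 or flank_cM <= 0:
        raise ValueError("central_cM and flank_cM must be positive")
    windows: list[PhaseWindow] = []
    wid = 0
    for chrom in guide.markers["chrom"].unique():
        g = guide.chrom(chrom)
        cm = g["cM"].to_numpy()
        n = len(cm)
        total = cm[-1] - cm[0]
        if total < central_cM:
            warnings.warn(f"{chrom}: map shorter than one central window")
            breaks = [0, n - 1]
        else:
            targets = np.arange(central_cM, total, central_cM) + cm[0]
            idx = [0]
            for t in targets:
                k = int(np.argmin(np.abs(cm - t)))
                if k > idx[-1]:
                    idx.append(k)
            if idx[-1] != n - 1:
                idx.append(n - 1)
            breaks = idx
        for i in range(len(breaks) - 1):
            c0, c1 = breaks[i], breaks[i + 1]
            lf = c0
            if i > 0:
                t = cm[c0] - flank_cM
                lf = int(np.argmin(np.abs(cm - t)))
            rf = c1
            if i < len(breaks) - 2:
                t = cm[c1] + flank_cM
                rf = int(np.argmin(np.abs(cm - t)))
            windows.append(PhaseWindow(
                window_id=wid, chrom=chrom, span=(lf, rf + 1),
                central=(c0, c1 + 1), left_flank=(lf, c0), right_flank=(c1, rf + 1),
            ))
            wid += 1
    return windows


@dataclass
class LDPosterior:
    """Per-interval posterior samples of lambda and per-window rho_w, one population.

    ``intervals``: DataFrame (chrom, start, end, window_id) on this
    population's interval set. ``lam``: float array (n_intervals, S).
    ``rho_w``: float array (n_windows, S) indexed by window_id.
    """

    intervals: pd.DataFrame
    lam: np.ndarray
    rho_w: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = self.intervals.reset_index(drop=True)
        if self.lam.shape[0] != len(self.intervals):
            raise ValueError("lambda sample rows != intervals")
        if self.rho_w.shape[1] != self.lam.shape[1]:
            raise ValueError("rho_w and lambda sample counts differ")
        if np.any(self.lam <= 0) or np.any(self.rho_w <= 0):
            raise ValueError("lambda and rho_w samples must be strictly positive")

    @property
    def S(self) -> int:
        return self.lam.shape[1]

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.intervals["end"] - self.intervals["start"]).to_numpy()


def rho_samples(posterior: LDPosterior) -> np.ndarray:
    """Joint-draw product rho_i^(j) = lambda_i^(j) * rho_w(i)^(j), per kb."""
    widx = posterior.intervals["window_id"].to_numpy()
    return posterior.lam * posterior.rho_w[widx]


def median_lambda(posterior: LDPosterior) -> pd.DataFrame:
    """Per-interval sample median of lambda (robust to posterior outliers)."""
    out = posterior.intervals[["chrom", "start", "end"]].copy()
    out["median_lambda"] = np.median(posterior.lam, axis=1)
    return out


def read_phase_samples(files: dict[int, str], windows: list[PhaseWindow],
                       marker_pos: pd.DataFrame) -> LDPosterior:
    """Read native posterior samples (one file per window id).

    Each file holds one whitespace-separated record per MCMC sample: the
    window background rate rho_w followed by the per-interval factors
    lambda for every interval of the window span. Flank-interval estimates
    are discarded; only central-part intervals are retained.
    ``marker_pos``: DataFrame (chrom, pos_bp) giving window marker layout.
    """
    by_id = {w.window_id: w for w in windows}
    lam_parts, rows, rho_parts = [], [], []
    S_ref = None
    for wid, path in sorted(files.items()):
        w = by_id[wid]
        vals = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.split()
                if len(fields) != 1 + w.n_intervals:
                    raise FormatError(
                        f"{path}:{ln}: expected {1 + w.n_intervals} fields, got {len(fields)}")
                vals.append([float(x) for x in fields])
        if not vals:
            raise FormatError(f"{path}: no sample records")
        arr = np.asarray(vals)
        if S_ref is None:
            S_ref = len(arr)
        elif len(arr) != S_ref:
            raise FormatError(f"{path}: sample count {len(arr)} != {S_ref}")
        rho_parts.append(arr[:, 0])
        g = marker_pos[marker_pos["chrom"] == w.chrom].reset_index(drop=True)
        c0, c1 = w.central
        for k in range(c0, c1 - 1):  # central-part intervals only
            rows.append((w.chrom, int(g["pos_bp"].iloc[k]),
                         int(g["pos_bp"].iloc[k + 1]), wid))
            lam_parts.append(arr[:, 1 + (k - w.span[0])])
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "window_id"])
    # window_id remapped to dense row index of rho_w
    wid_map = {wid: i for i, wid in enumerate(sorted(files))}
    intervals["window_id"] = intervals["window_id"].map(wid_map)
    return LDPosterior(intervals, np.vstack(lam_parts), np.vstack(rho_parts))


def write_posterior_tsv(posterior: LDPosterior, path) -> None:
    """Internal dialect: chrom, start, end, sample_index, lambda, rho_w."""
    widx = posterior.intervals["window_id"].to_numpy()
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tsample_index\tlambda\trho_w\n")
        for i in range(len(posterior.intervals)):
            row = posterior.intervals.iloc[i]
            for j in range(posterior.S):
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{j}\t"
                         f"{float(posterior.lam[i, j])!r}\t"
                         f"{float(posterior.rho_w[widx[i], j])!r}\n")


def read_posterior_tsv(path) -> LDPosterior:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "sample_index", "lambda", "rho_w"],
                     dtype={"chrom": str}, float_precision="round_trip")
    if df.empty:
        raise FormatError(f"{path}: empty posterior file")
    key = df.groupby(["chrom", "start", "end"], sort=False)
    S = key.size().iloc[0]
    if not (key.size() == S).all():
        raise FormatError(f"{path}: sample count varies across intervals")
    intervals = key.first().reset_index()[["chrom", "start", "end"]]
    lam = df["lambda"].to_numpy().reshape(len(intervals), S)
    rho = df["rho_w"].to_numpy().reshape(len(intervals), S)
    # collapse identical rho_w rows into windows
    wids = np.zeros(len(intervals), dtype=int)
    rho_rows = [rho[0]]
    for i in range(1, len(intervals)):
        if np.array_equal(rho[i], rho_rows[-1]) and \
                intervals["chrom"].iloc[i] == intervals["chrom"].iloc[i - 1]:
            wids[i] = len(rho_rows) - 1
        else:
            rho_rows.append(rho[i])
            wids[i] = len(rho_rows) - 1
    intervals["window_id"] = wids
    return LDPosterior(intervals, lam, np.vstack(rho_rows))


def call_hris(profile: pd.DataFrame, threshold: float = 4.0,
              min_size_bp: int = 1_000, max_size_bp: int = 200_000) -> pd.DataFrame:
    """Merge runs of adjacent intervals with median lambda >= threshold into HRIs.

    ``profile``: DataFrame (chrom, start, end, median_lambda). Adjacency is
    a shared breakpoint (end == next start). Merged spans outside
    [min_size_bp, max_size_bp] are discarded. Summary lambda is the maximum
    of member medians.
    """
    if not 0 < min_size_bp < max_size_bp:
        raise ValueError("need 0 < min_size_bp < max_size_bp")
    out = []
    for chrom, g in profile.groupby("chrom", sort=False):
        g = g.sort_values("start")
        flag = g["median_lambda"].to_numpy() >= threshold
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        lams = g["median_lambda"].to_numpy()
        i = 0
        while i < len(g):
            if not flag[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(g) and flag[j + 1] and starts[j + 1] == ends[j]:
                j += 1
            span = (int(starts[i]), int(ends[j]))
            size = span[1] - span[0]
            if min_size_bp <= size <= max_size_bp:
                out.append((chrom, *span, j - i + 1, float(lams[i:j + 1].max()), size))
            i = j + 1
    return pd.DataFrame(
        out, columns=["chrom", "start", "end", "n_intervals", "summary_lambda", "size_bp"])


def write_hri_bed(hris: pd.DataFrame, population: str, path) -> None:
    """BED6; name = population, score = summary lambda x 100, truncated."""
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\n")
        for _, r in hris.iterrows():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{population}\t"
                     f"{int(r.summary_lambda * 100)}\t.\n")


def read_hri_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name", "score", "strand"],
                     dtype={"chrom": str})
    df["summary_lambda"] = df["score"] / 100.0
    return df[["chrom", "start", "end", "name", "summary_lambda"]]


def rescale_to_meiotic(intervals: pd.DataFrame, rho_per_kb: np.ndarray,
                       meiotic_region_means: dict[str, float],
                       scheme: RegionScheme) -> np.ndarray:
    """Scale LD rates to cM/Mb so region means match the meiotic map exactly.

    Per region r, factor = (meiotic length-weighted mean cM/Mb) /
    (LD length-weighted mean rho per Mb); every interval's rho is multiplied
    by its region's factor, preserving the within-region ranking.
    """
    intervals = intervals.reset_index(drop=True)
    rho_per_mb = np.asarray(rho_per_kb, dtype=float) * 1e3
    lengths = (intervals["end"] - intervals["start"]).to_numpy().astype(float)
    region = np.array([
        f"{c}{scheme.assign(c, int(s))}"
        for c, s in zip(intervals["chrom"], intervals["start"])
    ])
    out = np.empty_like(rho_per_mb)
    for reg in np.unique(region):
        sel = region == reg
        ld_mean = np.sum(rho_per_mb[sel] * lengths[sel]) / lengths[sel].sum()
        if ld_mean == 0:
            raise ValueError(f"region {reg}: zero LD genetic distance")
        if reg not in meiotic_region_means:
            raise KeyError(f"region {reg}: no meiotic region mean")
        out[sel] = rho_per_mb[sel] * (meiotic_region_means[reg] / ld_mean)
    return out


def aggregate_ld_windows(posterior: LDPosterior, window_bp: int = 4_000_000,
                         chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Sample-averaged, length-weighted rho per tiling window.

    Per window and sample j, total LD genetic distance over physical
    distance; then the mean over samples. The two averages commute (both
    linear), so the computation uses per-interval sample means.
    """
    rho = rho_samples(posterior)
    rho_mean = rho.mean(axis=1)
    return aggregate_windows(
        posterior.intervals[["chrom", "start", "end"]], rho_mean,
        window_bp, chrom_lengths,
    )


def genetic_concentration(rates: np.ndarray, lengths: np.ndarray,
                          genetic_fraction: float = 0.8) -> float:
    """Minimal physical proportion carrying ``genetic_fraction`` of genetic distance.

    Intervals are sorted by rate descending; genetic distance accumulates
    until the target fraction is reached, interpolating linearly inside the
    final interval.
    """
    if not 0 < genetic_fraction < 1:
        raise ValueError("genetic_fraction must be in (0,1)")
    rates = np.asarray(rates, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    gd = rates * lengths
    total_g = gd.sum()
    if total_g <= 0:
        raise ValueError("zero total genetic distance")
    order = np.argsort(-rates, kind="stable")
    cg = np.cumsum(gd[order])
    cl = np.cumsum(lengths[order])
    target = genetic_fraction * total_g
    k = int(np.searchsorted(cg, target))
    g_prev = cg[k - 1] if k > 0 else 0.0
    l_prev = cl[k - 1] if k > 0 else 0.0
    rate_k = rates[order][k]
    partial = (target - g_prev) / rate_k if rate_k > 0 else 0.0
    return float((l_prev + partial) / lengths.sum())
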