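"""Bayesian meiotic recombination map from recombinant-inbred-line genotypes.

The model: crossovers are detected as parental allele switches along each
RIL; a crossover flanked by missing calls cannot be placed in a single
marker interval, so it is assigned stochastically to one of its candidate
intervals with probability proportional to interval length, and the
assignment is replicated (default 1,000 times). Per interval i the count
y_i is Poisson with mean C_i * L_i * M (rate per Mb, interval length L_i
Mb, M lines). A per-region Gamma(alpha_r, beta_r) prior, set by empirical
Bayes from the frequentist rates y_i/(M*L_i), is conjugate, giving the
posterior Gamma(y_i + alpha_r, M*L_i + beta_r). Posterior-mean RIL rates
are converted to meiotic cM/Mb by inverting the Haldane-Waddington
relation R = 2r/(1+2r) for selfed RILs and applying the Morgan mapping
function (cM = 100 * r).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .genome_model import RegionScheme, aggregate_windows

# call codes
A, B, HET, MISSING = 0, 1, 2, -1
_CODE = {"A": A, "B": B, "H": HET, "NA": MISSING}
_DECODE = {A: "A", B: "B", HET: "H", MISSING: "NA"}


@dataclass
class RilGenotypes:
    """Marker x individual parental-call matrix with physical positions.

    ``markers``: DataFrame (marker, chrom, pos_bp) with strictly increasing
    positions within each chromosome. ``calls``: int8 array, codes
    A=0, B=1, H=2, missing=-1. ``individuals``: column labels.
    """

    markers: pd.DataFrame
    calls: np.ndarray
    individuals: list[str]

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.markers), len(self.individuals)):
            raise ValueError("call matrix shape does not match markers x individuals")
        for chrom, g in self.markers.groupby("chrom"):
            pos = g["pos_bp"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"{chrom}: marker positions not strictly increasing")
        bad = set(np.unique(self.calls)) - {A, B, HET, MISSING}
        if bad:
            raise ValueError(f"unknown call codes {sorted(bad)}")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def intervals(self) -> pd.DataFrame:
        """Marker intervals (chrom, start, end) between successive markers."""
        rows = []
        for chrom, g in self.markers.groupby("chrom", sort=False):
            pos = g["pos_bp"].to_numpy()
            rows.append(pd.DataFrame(
                {"chrom": chrom, "start": pos[:-1], "end": pos[1:]}))
        return pd.concat(rows, ignore_index=True)


def read_ril_genotypes(path) -> RilGenotypes:
    df = pd.read_csv(path, sep="\t")
    df.columns = ["marker", "chrom", "pos_bp", *df.columns[3:]]
    individuals = list(df.columns[3:])
    calls = np.full((len(df), len(individuals)), MISSING, dtype=np.int8)
    for j, ind in enumerate(individuals):
        col = df[ind].astype(str).str.strip()
        calls[:, j] = col.map(lambda s: _CODE.get(s, MISSING)).to_numpy()
    markers = df[["marker", "chrom", "pos_bp"]].copy()
    markers["chrom"] = markers["chrom"].astype(str)
    return RilGenotypes(markers, calls, individuals)


def write_ril_genotypes(geno: RilGenotypes, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#marker\tchrom\tpos_bp\t" + "\t".join(geno.individuals) + "\n")
        for i in range(len(geno.markers)):
            m = geno.markers.iloc[i]
            row = "\t".join(_DECODE[int(c)] for c in geno.calls[i])
            fh.write(f"{m.marker}\t{m.chrom}\t{m.pos_bp}\t{row}\n")


def impute_missing(geno: RilGenotypes) -> RilGenotypes:
    """Fill missing runs whose flanking informative calls agree.

    H calls are treated as missing and never used as flanks. Internal runs
    with disagreeing flanks are left missing (the crossover lies inside).
    Terminal runs are extended from their single informative neighbor.
    """
    calls = geno.calls.copy()
    chrom_codes = geno.markers["chrom"].to_numpy()
    for chrom in pd.unique(chrom_codes):
        sel = chrom_codes == chrom
        block = calls[sel].astype(float)
        block[(block == HET) | (block == MISSING)] = np.nan
        df = pd.DataFrame(block)
        fwd = df.ffill().to_numpy()
        bwd = df.bfill().to_numpy()
        agree = fwd == bwd  # False where either is NaN
        filled = np.where(agree, fwd, np.nan)
        filled = np.where(np.isnan(filled) & np.isnan(fwd), bwd, filled)
        filled = np.where(np.isnan(filled) & np.isnan(bwd), fwd, filled)
        out = np.where(np.isnan(filled), MISSING, filled).astype(np.int8)
        if np.any(np.isnan(block).all(axis=0)):
            warnings.warn(f"{chrom}: individual(s) with zero informative calls")
        calls[sel] = out
    return RilGenotypes(geno.markers, calls, list(geno.individuals))


def detect_crossovers(geno: RilGenotypes) -> pd.DataFrame:
    """One observation per parental allele switch between informative calls.

    Returns DataFrame (individual, chrom, left, right) where left/right are
    row indices of the flanking informative markers in ``geno.markers``;
    candidate marker intervals are left .. right-1 (interval k spans markers
    k to k+1).
    """
    rows = []
    chrom_codes = geno.markers["chrom"].to_numpy()
    offsets = {}
    for chrom in pd.unique(chrom_codes):
        offsets[chrom] = int(np.flatnonzero(chrom_codes == chrom)[0])
    for j, ind in enumerate(geno.individuals):
        col = geno.calls[:, j]
        for chrom in pd.unique(chrom_codes):
            sel = np.flatnonzero(chrom_codes == chrom)
            c = col[sel]
            inf = np.flatnonzero((c == A) | (c == B))
            if len(inf) < 2:
                continue
            vals = c[inf]
            switch = np.flatnonzero(vals[1:] != vals[:-1])
            for s in switch:
                rows.append((ind, chrom, int(sel[inf[s]]), int(sel[inf[s + 1]])))
    return pd.DataFrame(rows, columns=["individual", "chrom", "left", "right"])


def sample_crossover_assignments(
    observations: pd.DataFrame,
    geno: RilGenotypes,
    n_rep: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Replicate stochastic assignment of each crossover to one candidate interval.

    Assignment probability = interval length / crossover-area length, where
    the area is the bp span between the two flanking informative markers.
    Returns an int32 count array of shape (n_intervals, n_rep); interval k is
    the span between markers k and k+1 of the same chromosome (global
    indexing skips the last marker of each chromosome).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    pos = geno.markers["pos_bp"].to_numpy()
    chrom_codes = geno.markers["chrom"].to_numpy()
    # global interval index: marker row k -> interval k' skipping chromosome tails
    is_last = np.ones(len(pos), dtype=bool)
    is_last[:-1] = chrom_codes[:-1] != chrom_codes[1:]
    interval_of_marker = np.cumsum(~is_last) - 1  # valid where ~is_last
    n_intervals = int((~is_last).sum())
    counts = np.zeros((n_intervals, n_rep), dtype=np.int32)
    rep_idx = np.arange(n_rep)
    for _, o in observations.iterrows():
        lo, hi = int(o.left), int(o.right)
        area = pos[hi] - pos[lo]
        if area <= 0:
            raise ValueError(f"zero-length crossover area at markers {lo}-{hi}")
        if hi == lo + 1:
            counts[interval_of_marker[lo]] += 1
            continue
        cuts = np.cumsum(np.diff(pos[lo:hi + 1]))
        u = rng.random(n_rep) * area
        pick = np.searchsorted(cuts, u, side="right")
        np.add.at(counts, (interval_of_marker[lo] + pick, rep_idx), 1)
    return counts


def frequentist_rates(counts: np.ndarray, M: int, lengths_mb: np.ndarray) -> np.ndarray:
    """C_freq = y_i / (M * L_i), recombinants per Mb, per replicate."""
    if M < 1:
        raise ValueError("M must be >= 1")
    lengths_mb = np.asarray(lengths_mb, dtype=float)
    if np.any(lengths_mb <= 0):
        raise ValueError("interval with non-positive length")
    return counts / (M * lengths_mb[:, None])


@dataclass(frozen=True)
class GammaPrior:
    """Per-region empirical-Bayes Gamma prior (shape alpha, rate beta)."""

    region: str
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)
                and self.alpha > 0 and self.beta > 0):
            raise ValueError(f"{self.region}: Gamma parameters must be positive finite")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta

    @property
    def variance(self) -> float:
        return self.alpha / self.beta**2


def _gamma_ml(x: np.ndarray, rtol: float = 1e-8, max_iter: int = 200) -> tuple[float, float]:
    """Maximum-likelihood Gamma (shape, rate) via the digamma equation.

    Solves log(a) - psi(a) = log(mean) - mean(log x) by Newton iteration
    from the method-of-moments start.
    """
    m = x.mean()
    v = x.var()
    if v == 0:
        raise RuntimeError("degenerate (constant) rate sample: variance 0")
    s = np.log(m) - np.mean(np.log(x))
    if s <= 0:
        raise RuntimeError("non-convergent Gamma fit: non-positive ML statistic")
    from scipy import optimize

    def f(a):
        return np.log(a) - special.digamma(a) - s

    a0 = m * m / v  # moments start
    lo, hi = a0, a0
    for _ in range(max_iter):  # expand bracket: f is monotone decreasing
        if f(lo) > 0:
            break
        lo /= 4
    else:
        raise RuntimeError("Gamma ML bracket expansion failed (low)")
    for _ in range(max_iter):
        if f(hi) < 0:
            break
        hi *= 4
    else:
        raise RuntimeError("Gamma ML bracket expansion failed (high)")
    a = optimize.brentq(f, lo, hi, rtol=rtol)
    return float(a), float(a / m)


def fit_region_priors(
    rates: np.ndarray, regions: np.ndarray, min_intervals: int = 10
) -> dict[str, GammaPrior]:
    """Empirical-Bayes Gamma priors per region from frequentist rates.

    Zero rates are first replaced by the lowest non-null rate of the region.
    """
    rates = np.asarray(rates, dtype=float)
    regions = np.asarray(regions)
    priors = {}
    for region in pd.unique(regions):
        x = rates[regions == region].copy()
        if len(x) < min_intervals:
            raise ValueError(f"region {region}: fewer than {min_intervals} intervals")
        nz = x[x > 0]
        if len(nz) == 0:
            raise ValueError(f"region {region}: all rates zero")
        x[x == 0] = nz.min()
        try:
            alpha, beta = _gamma_ml(x)
        except RuntimeError as e:
            raise RuntimeError(f"region {region}: {e}") from e
        priors[str(region)] = GammaPrior(str(region), alpha, beta)
    return priors


def build_meiotic_map(
    geno: RilGenotypes,
    scheme: RegionScheme,
    n_rep: int = 1000,
    seed: int | None = None,
    pool_on_degenerate: tuple[str, ...] = ("C", "R2a", "R2b"),
) -> pd.DataFrame:
    """End-to-end meiotic map: impute, detect, assign, fit priors, update.

    Priors are fitted per region on the replicate-averaged frequentist
    rates. A region whose rate distribution is too data-poor for a Gamma
    fit (typically the centromere, which carries almost no crossovers)
    borrows its prior from the pooled low-recombining regions in
    ``pool_on_degenerate`` — a conservative shrinkage target for regions
    that cannot inform their own empirical prior.
    """
    geno = impute_missing(geno)
    obs = detect_crossovers(geno)
    counts = sample_crossover_assignments(obs, geno, n_rep=n_rep, seed=seed)
    intervals = geno.intervals()
    lengths_mb = (intervals["end"] - intervals["start"]).to_numpy() / 1e6
    rates = frequentist_rates(counts, geno.n_individuals, lengths_mb)
    rate_mean = rates.mean(axis=1)
    region = np.array([scheme.assign(c, int(s))
                       for c, s in zip(intervals["chrom"], intervals["start"])])
    priors: dict[str, GammaPrior] = {}
    failed = []
    for reg in pd.unique(region):
        try:
            priors.update(fit_region_priors(
                rate_mean[region == reg], region[region == reg]))
        except (RuntimeError, ValueError):
            failed.append(str(reg))
    if failed:
        pool_sel = np.isin(region, pool_on_degenerate)
        pooled = fit_region_priors(
            rate_mean[pool_sel], np.full(pool_sel.sum(), "pool"))["pool"]
        for reg in failed:
            warnings.warn(f"region {reg}: data-poor, prior pooled from "
                          f"{'+'.join(pool_on_degenerate)}")
            priors[reg] = GammaPrior(reg, pooled.alpha, pooled.beta)
    return posterior_rates(counts, priors, geno.n_individuals, intervals, scheme)


def posterior_rates(
    counts: np.ndarray,
    priors: dict[str, GammaPrior],
    M: int,
    intervals: pd.DataFrame,
    scheme: RegionScheme,
) -> pd.DataFrame:
    """Conjugate posterior Gamma(y_i + alpha_r, M*L_i + beta_r) per interval.

    Posterior means are computed per replicate and averaged over replicates.
    Returns the meiotic map frame with columns chrom, start, end, region,
    y_mean, post_shape, post_rate, C_bay (RIL recombinants/Mb), C_freq,
    cM_per_Mb.
    """
    intervals = intervals.reset_index(drop=True)
    lengths_mb = (intervals["end"] - intervals["start"]).to_numpy() / 1e6
    region = np.array([
        scheme.assign(c, int(s))
        for c, s in zip(intervals["chrom"], intervals["start"])
    ])
    missing = set(region) - set(priors)
    if missing:
        raise KeyError(f"no prior for region(s) {sorted(missing)}")
    alpha = np.array([priors[r].alpha for r in region])
    beta = np.array([priors[r].beta for r in region])
    y_mean = counts.mean(axis=1)
    post_rate = M * lengths_mb + beta
    # mean over replicates of (y + a)/(ML + b) is linear in y
    c_bay = (y_mean + alpha) / post_rate
    c_freq = y_mean / (M * lengths_mb)
    out = intervals[["chrom", "start", "end"]].copy()
    out["region"] = region
    out["y_mean"] = y_mean
    out["post_shape"] = y_mean + alpha
    out["post_rate"] = post_rate
    out["C_bay"] = c_bay
    out["C_freq"] = c_freq
    out["cM_per_Mb"] = ril_to_meiotic(c_bay, lengths_mb)
    return out


def haldane_waddington_forward(r: np.ndarray) -> np.ndarray:
    """Meiotic recombination fraction r -> selfed-RIL recombinant fraction R."""
    r = np.asarray(r, dtype=float)
    return 2 * r / (1 + 2 * r)


def haldane_waddington_inverse(R: np.ndarray) -> np.ndarray:
    """Selfed-RIL recombinant fraction R -> meiotic fraction r = R/(2(1-R))."""
    R = np.asarray(R, dtype=float)
    if np.any(R < 0) or np.any(R >= 0.5):
        raise ValueError("RIL recombinant fraction must lie in [0, 0.5)")
    return R / (2 * (1 - R))


def ril_to_meiotic(ril_rate_per_mb: np.ndarray, lengths_mb: np.ndarray) -> np.ndarray:
    """RIL recombinants/Mb -> meiotic cM/Mb, per interval.

    R_i = rate * L_i is inverted through Haldane-Waddington; the Morgan
    mapping function (cM = 100 r) then applies since intervals are small
    enough that one recombinant reflects a single crossover.
    """
    ril_rate_per_mb = np.asarray(ril_rate_per_mb, dtype=float)
    lengths_mb = np.asarray(lengths_mb, dtype=float)
    R = ril_rate_per_mb * lengths_mb
    r = haldane_waddington_inverse(R)
    return 100 * r / lengths_mb


def aggregate_map_windows(map_df: pd.DataFrame, window_bp: int,
                          value_col: str = "cM_per_Mb",
                          chrom_lengths: dict[str, int] | None = None) -> pd.DataFrame:
    """Length-weighted windowed rates of a meiotic map (clipped at window edges)."""
    return aggregate_windows(
        map_df[["chrom", "start", "end"]], map_df[value_col].to_numpy(),
        window_bp, chrom_lengths,
    )


def write_meiotic_map(map_df: pd.DataFrame, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#" + "\t".join(map_df.columns) + "\n")
        map_df.to_csv(fh, sep="\t", header=False, index=False)
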