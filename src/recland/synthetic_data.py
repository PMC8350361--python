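"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the statistical structure the analysis assumes:

* F6 RIL genotype mosaics along a region-structured true meiotic map —
  a two-state Markov chain over markers whose switch probability is the
  Haldane-Waddington forward transform R = 2r/(1+2r) of the map's
  recombination fraction (no crossover interference), with uniform missing
  and heterozygous call injection.
* Four populations' per-interval intensity posteriors — true log10 lambda
  drawn from a 4-variate normal with a controlled between-population
  correlation, sparse HRI spikes planted under a sharing design, and
  posterior samples emulated by lognormal noise around the truth (the
  pipeline consumes samples, not MCMC chains).
* Population haplotypes under the Balding-Nichols model: population allele
  frequencies Dirichlet-distributed around an ancestral draw with a drift
  parameter per population. For haploid Weir-Cockerham theta the pairwise
  estimand is exactly the mean of the two drift parameters, so pairwise
  F_ST targets are known analytically.

The coupled experiment ties the two worlds together: per genomic region,
pairwise profile correlations follow corr = a + b * F_ST, which the
divergence regression should recover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_model import IntervalGrid, RegionScheme
from .ld_profiles import LDPosterior
from .ril_meiotic_map import A, B, HET, MISSING, RilGenotypes, haldane_waddington_forward

POPULATIONS = ("WE", "EE", "WA", "EA")

# Region-level meiotic rates (cM/Mb): telomeric R1/R3 about ten-fold above
# the pericentromeres, the centromere about a hundred-fold below R1/R3.
DEFAULT_REGION_RATES = {"R1": 1.5, "R2a": 0.15, "C": 0.015, "R2b": 0.15, "R3": 1.5}
# Background population-scaled rates rho_w (/kb) by region.
DEFAULT_RHO_W = {"R1": 0.01, "R2a": 0.002, "C": 0.0002, "R2b": 0.002, "R3": 0.01}
DEFAULT_REGION_FRACTIONS = {"R1": 0.20, "R2a": 0.25, "C": 0.10, "R2b": 0.25, "R3": 0.20}


def default_region_scheme(n_chrom: int = 2, chrom_length: int = 100_000_000,
                          fractions: dict[str, float] | None = None) -> RegionScheme:
    """Desk-scale genome: ``n_chrom`` chromosomes with the five-region layout."""
    fr = fractions or DEFAULT_REGION_FRACTIONS
    segments = {}
    for c in range(1, n_chrom + 1):
        rows = []
        pos = 0
        for lab in ("R1", "R2a", "C", "R2b", "R3"):
            end = pos + int(round(fr[lab] * chrom_length))
            rows.append((pos, end, lab))
            pos = end
        rows[-1] = (rows[-1][0], chrom_length, "R3")
        segments[f"{c}A"] = pd.DataFrame(rows, columns=["start", "end", "label"])
    return RegionScheme(segments)


def region_rate_map(scheme: RegionScheme,
                    region_rates: dict[str, float] | None = None):
    """Piecewise-constant true meiotic map (cM/Mb) over the region scheme."""
    rates = region_rates or DEFAULT_REGION_RATES
    return {chrom: [(int(r.start), int(r.end), rates[r.label])
                    for _, r in df.iterrows()]
            for chrom, df in scheme.segments.items()}


def simulate_true_map(scheme: RegionScheme,
                      region_rates: dict[str, float] | None = None,
                      block_bp: int = 4_000_000, sigma_log10: float = 0.3,
                      seed: int | None = None) -> dict:
    """Region-structured true map with block-scale rate heterogeneity.

    Rates are piecewise-constant on ``block_bp`` blocks, lognormal around
    the region base rate (sd ``sigma_log10`` on log10). Real maps vary
    severalfold within a region at the megabase scale; a flat within-region
    map would make windowed profile comparisons degenerate.
    """
    rng = np.random.default_rng(seed)
    rates = region_rates or DEFAULT_REGION_RATES
    out = {}
    for chrom, df in scheme.segments.items():
        rows = []
        for _, seg in df.iterrows():
            pos = int(seg.start)
            while pos < seg.end:
                end = min(pos + block_bp, int(seg.end))
                mult = 10 ** rng.normal(0, sigma_log10)
                rows.append((pos, end, rates[seg.label] * mult))
                pos = end
        out[chrom] = rows
    return out


def _map_cm(true_map: dict, chrom: str, a: int, b: int) -> float:
    """Genetic distance (cM) of [a, b) under a piecewise-constant map."""
    cm = 0.0
    for s, e, rate in true_map[chrom]:
        lo, hi = max(a, s), min(b, e)
        if hi > lo:
            cm += rate * (hi - lo) / 1e6
    return cm


def simulate_ril_population(true_map: dict, scheme: RegionScheme,
                            n_markers_per_chrom: int = 2500, n_ril: int = 400,
                            missing_rate: float = 0.05, het_rate: float = 0.02,
                            seed: int | None = None):
    """F6 RIL genotypes from a true map; returns (RilGenotypes, truth frame).

    Markers are evenly spaced per chromosome. Along each RIL the parental
    state switches between adjacent markers with probability
    R = 2r/(1+2r), r the meiotic fraction implied by the map; missing and H
    calls are injected uniformly afterwards. Truth carries the per-interval
    true cM/Mb and expected recombinant counts.
    """
    rng = np.random.default_rng(seed)
    marker_rows = []
    call_blocks = []
    truth_rows = []
    for chrom in scheme.chroms:
        L = scheme.chrom_length(chrom)
        # markers at random positions (real SNP spacing is irregular)
        pos = np.sort(rng.choice(L, size=n_markers_per_chrom, replace=False))
        pos[0], pos[-1] = 0, L - 1
        r = np.array([_map_cm(true_map, chrom, int(a), int(b)) / 100
                      for a, b in zip(pos[:-1], pos[1:])])
        if np.any(r >= 0.5):
            raise ValueError(f"{chrom}: adjacent-marker r >= 0.5; add markers")
        R = haldane_waddington_forward(r)
        switches = rng.random((len(R), n_ril)) < R[:, None]
        start = rng.integers(0, 2, n_ril)
        states = np.empty((len(pos), n_ril), dtype=np.int8)
        states[0] = start
        states[1:] = np.cumsum(switches, axis=0) % 2
        states[1:] = (states[1:] + start) % 2
        call_blocks.append(states)
        for k, p in enumerate(pos):
            marker_rows.append((f"{chrom}_m{k}", chrom, int(p)))
        for a, b, rr, RR in zip(pos[:-1], pos[1:], r, R):
            truth_rows.append((chrom, int(a), int(b), rr * 100 / ((b - a) / 1e6),
                               n_ril * RR))
    calls = np.concatenate(call_blocks, axis=0)
    noise = rng.random(calls.shape)
    calls = np.where(noise < missing_rate, MISSING,
                     np.where(noise < missing_rate + het_rate, HET, calls)).astype(np.int8)
    markers = pd.DataFrame(marker_rows, columns=["marker", "chrom", "pos_bp"])
    truth = pd.DataFrame(
        truth_rows, columns=["chrom", "start", "end", "true_cM_per_Mb", "expected_recombinants"])
    geno = RilGenotypes(markers, calls,
                        [f"RIL{i:04d}" for i in range(n_ril)])
    return geno, truth


@dataclass
class SharingDesign:
    """Planted HRI spikes: how many, how shared, how strong.

    ``level_probs`` is the distribution over sharing levels 1..4;
    spike magnitudes are lognormal on base-10 around ``magnitude_median``
    (sd ``magnitude_sigma_log10``), truncated below at the calling
    threshold so every planted spike is in principle detectable.
    """

    n_spikes_per_region: int = 10
    level_probs: tuple[float, float, float, float] = (0.55, 0.25, 0.12, 0.08)
    magnitude_median: float = 8.0
    magnitude_sigma_log10: float = 0.3
    magnitude_floor: float = 4.0

    def __post_init__(self) -> None:
        if abs(sum(self.level_probs) - 1) > 1e-9:
            raise ValueError("level_probs must sum to 1")
        if self.magnitude_median < self.magnitude_floor:
            raise ValueError("spike magnitude median below the floor")


def make_interval_grid(scheme: RegionScheme, interval_bp: int = 20_000,
                       populations=POPULATIONS) -> IntervalGrid:
    """Uniform interval grid tiling the scheme, identical across populations."""
    rows = []
    for chrom in scheme.chroms:
        L = scheme.chrom_length(chrom)
        starts = np.arange(0, L, interval_bp)
        ends = np.minimum(starts + interval_bp, L)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    df = pd.concat(rows, ignore_index=True)
    for p in populations:
        df[f"native_{p}"] = np.arange(len(df))
    return IntervalGrid(df, list(populations))


def equicorrelated_sigma(rho: float, sds, p: int = 4) -> np.ndarray:
    sds = np.asarray(sds, dtype=float)
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    return np.outer(sds, sds) * R


def _check_psd(sigma: np.ndarray) -> None:
    w = np.linalg.eigvalsh(sigma)
    if w.min() < -1e-10:
        raise ValueError(f"covariance not positive semi-definite (min eig {w.min():.3g})")


def simulate_lambda_profiles(grid: IntervalGrid, scheme: RegionScheme,
                             sigma: np.ndarray,
                             sharing: SharingDesign | None = None,
                             posterior_noise_sd: float = 0.1,
                             S: int = 1000,
                             rho_w_rates: dict[str, float] | None = None,
                             rho_w_sigma_log10: float = 0.1,
                             intervals_per_window: int = 50,
                             populations=POPULATIONS,
                             seed: int | None = None):
    """Emulated intensity posteriors for four populations on a common grid.

    True log10 lambda per interval is MVN(0, sigma) across populations;
    spikes per the sharing design overwrite the baseline in the selected
    populations; posterior samples multiply the truth by 10^N(0, sd).
    Background rho_w per window is the region base rate with lognormal
    noise, shared by all samples' lambda via the joint product. Returns
    ({population: LDPosterior}, truth dict).
    """
    sigma = np.asarray(sigma, dtype=float)
    _check_psd(sigma)
    if posterior_noise_sd < 0:
        raise ValueError("posterior noise sd must be >= 0")
    rng = np.random.default_rng(seed)
    pops = list(populations)
    n = len(grid)
    ints = grid.intervals
    log_lam = rng.multivariate_normal(np.zeros(len(pops)), sigma, size=n,
                                      method="cholesky")
    region = np.array([f"{c}{scheme.assign(c, int(s))}"
                       for c, s in zip(ints["chrom"], ints["start"])])
    spikes = []
    if sharing is not None:
        levels = np.arange(1, len(pops) + 1)
        for reg in pd.unique(region):
            cand = np.flatnonzero(region == reg)
            take = min(sharing.n_spikes_per_region, len(cand))
            sites = rng.choice(cand, size=take, replace=False)
            for site in sites:
                k = rng.choice(levels, p=np.asarray(sharing.level_probs))
                members = rng.choice(len(pops), size=k, replace=False)
                mag = 0.0
                while mag < sharing.magnitude_floor:
                    mag = sharing.magnitude_median * 10 ** (
                        rng.normal(0, sharing.magnitude_sigma_log10))
                for m in members:
                    log_lam[site, m] = np.log10(mag)
                spikes.append((int(site), reg, k,
                               ",".join(pops[m] for m in sorted(members)), mag))
    spikes = pd.DataFrame(
        spikes, columns=["interval", "region", "level", "populations", "magnitude"])
    # window layout: fixed-size runs of intervals within a chromosome
    window_id = np.zeros(n, dtype=int)
    wid = 0
    for chrom in ints["chrom"].unique():
        sel = np.flatnonzero((ints["chrom"] == chrom).to_numpy())
        for k0 in range(0, len(sel), intervals_per_window):
            window_id[sel[k0:k0 + intervals_per_window]] = wid
            wid += 1
    base = rho_w_rates or DEFAULT_RHO_W
    chrom_arr = ints["chrom"].to_numpy()
    start_arr = ints["start"].to_numpy()
    win_base = np.empty(wid)
    for w in range(wid):
        k = int(np.flatnonzero(window_id == w)[0])
        win_base[w] = base[scheme.assign(chrom_arr[k], int(start_arr[k]))]
    posteriors = {}
    truth_lambda = pd.DataFrame(10 ** log_lam, columns=pops)
    for j, pop in enumerate(pops):
        noise = rng.normal(0, posterior_noise_sd, size=(n, S))
        lam = 10 ** (log_lam[:, [j]] + noise)
        rho_w = win_base[:, None] * 10 ** rng.normal(
            0, rho_w_sigma_log10, size=(wid, S))
        iv = ints[["chrom", "start", "end"]].copy()
        iv["window_id"] = window_id
        posteriors[pop] = LDPosterior(iv, lam, rho_w)
    truth = {"true_lambda": truth_lambda, "spikes": spikes, "sigma": sigma,
             "region": region}
    return posteriors, truth


def simulate_population_genotypes(drift: dict[str, float], n_haplotypes: int,
                                  n_loci: int, n_alleles: int = 2,
                                  seed: int | None = None):
    """Balding-Nichols haplotypes; returns ({pop: (loci, hap) array}, truth).

    Ancestral frequencies are symmetric-Dirichlet; each population's
    frequencies are Dirichlet(p * (1-F)/F) around them, with F its drift
    parameter (F = 0 reuses the ancestral frequencies; F = 1 fixes one
    allele per locus). The pairwise Weir-Cockerham estimand equals the mean
    of the two drift parameters, recorded in the truth.
    """
    for pop, f in drift.items():
        if not 0 <= f <= 1:
            raise ValueError(f"{pop}: drift parameter outside [0, 1]")
    rng = np.random.default_rng(seed)
    anc = rng.dirichlet(np.ones(n_alleles), size=n_loci)
    haplotypes = {}
    for pop, f in drift.items():
        if f == 0:
            freqs = anc
        elif f == 1:
            fixed = np.array([rng.choice(n_alleles, p=a) for a in anc])
            freqs = np.zeros((n_loci, n_alleles))
            freqs[np.arange(n_loci), fixed] = 1.0
        else:
            conc = np.maximum(anc * (1 - f) / f, 1e-9)
            g = rng.gamma(conc)  # Dirichlet via normalized Gamma draws
            tot = g.sum(axis=1, keepdims=True)
            redo = tot[:, 0] == 0
            if redo.any():  # all-zero draws at extreme concentrations
                g[redo, 0] = 1.0
                tot = g.sum(axis=1, keepdims=True)
            freqs = g / tot
        cum = np.cumsum(freqs, axis=1)
        u = rng.random((n_loci, n_haplotypes))
        haplotypes[pop] = (u[:, :, None] > cum[:, None, :-1]).sum(axis=2).astype(np.int16)
    pops = list(drift)
    fst_rows = [(a, b, (drift[a] + drift[b]) / 2)
                for i, a in enumerate(pops) for b in pops[i + 1:]]
    truth = {"pairwise_fst": pd.DataFrame(fst_rows, columns=["pop_a", "pop_b", "fst"]),
             "drift": dict(drift)}
    return haplotypes, truth


@dataclass
class CouplingDesign:
    """Linear coupling of pairwise profile correlation on pairwise F_ST."""

    intercept: float = 0.5
    slope: float = -2.0
    fst_range: tuple[float, float] = (0.01, 0.09)
    lambda_sd_log10: float = 0.25
    pair_noise_sd: float = 0.10  # biological scatter of regional correlation
    # around the F_ST trend; regional correlations never sit exactly on a line

    def correlation_matrix(self, drift: np.ndarray,
                           rng: np.random.Generator | None = None) -> np.ndarray:
        p = len(drift)
        R = np.eye(p)
        for i in range(p):
            for j in range(i + 1, p):
                f = (drift[i] + drift[j]) / 2
                eps = rng.normal(0, self.pair_noise_sd) if rng is not None else 0.0
                R[i, j] = R[j, i] = np.clip(self.intercept + self.slope * f + eps,
                                            -0.99, 0.99)
        return R


def simulate_coupled_experiment(coupling: CouplingDesign, n_regions: int = 50,
                                n_intervals: int = 600, n_loci: int = 5000,
                                n_haplotypes: int = 50, S: int = 60,
                                posterior_noise_sd: float = 0.1,
                                populations=POPULATIONS,
                                seed: int | None = None):
    """Per-region bundles tying profile correlation to F_ST; returns (bundle, truth).

    Per region: per-population drift parameters are drawn in ``fst_range``;
    the 4x4 log10-lambda correlation matrix is intercept + slope * F_pair
    (PSD-checked); profiles and Balding-Nichols biallelic allele counts are
    simulated (counts are sufficient for the F_ST estimator). The bundle
    holds, per region, the median log10-lambda matrix Y (n_intervals x 4)
    and per-population allele-count tables; the truth holds (a, b) and the
    per-region pairwise F targets.
    """
    rng = np.random.default_rng(seed)
    pops = list(populations)
    bundle = []
    fst_truth = []
    for reg in range(n_regions):
        drift = rng.uniform(*coupling.fst_range, size=len(pops))
        R = None
        for _ in range(20):  # pair scatter can break PSD; redraw jitter
            cand = coupling.correlation_matrix(drift, rng)
            try:
                _check_psd(cand)
            except ValueError:
                continue
            R = cand
            break
        if R is None:
            raise ValueError(f"region {reg}: infeasible correlation matrix")
        sigma = coupling.lambda_sd_log10 ** 2 * R
        log_lam = rng.multivariate_normal(np.zeros(len(pops)), sigma,
                                          size=n_intervals, method="cholesky")
        noise = rng.normal(0, posterior_noise_sd, size=(n_intervals, len(pops), S))
        med = np.median(log_lam[:, :, None] + noise, axis=2)
        anc = rng.uniform(0.05, 0.95, size=n_loci)  # ancestral biallelic freqs
        counts = {}
        for p, f in zip(pops, drift):
            a = anc * (1 - f) / f
            b = (1 - anc) * (1 - f) / f
            freq = rng.beta(a, b)
            c0 = rng.binomial(n_haplotypes, freq)
            counts[p] = np.stack([c0, n_haplotypes - c0], axis=1)
        bundle.append({"region": f"region{reg}", "Y": med, "allele_counts": counts})
        for i, a in enumerate(pops):
            for j in range(i + 1, len(pops)):
                fst_truth.append((f"region{reg}", a, pops[j],
                                  (drift[i] + drift[j]) / 2))
    truth = {"intercept": coupling.intercept, "slope": coupling.slope,
             "pairwise_fst": pd.DataFrame(
                 fst_truth, columns=["region", "pop_a", "pop_b", "fst"])}
    return bundle, truth
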