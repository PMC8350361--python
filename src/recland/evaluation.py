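"""Calibration and recovery experiments on synthetic data.

Self-contained experiments that exercise the pipeline end to end against
known ground truth: the conjugate-update quadrature oracle, meiotic-map
recovery from simulated RILs, covariance-structure selection, permutation
-null calibration, F_ST estimator recovery and the coupled
correlation-on-F_ST slope experiment. Each function is a pure function of
its parameters and seed and returns plain scalars/dicts, so the same code
backs both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, stats

from . import colocalization as co
from . import divergence as dv
from . import ld_profiles as lp
from . import ril_meiotic_map as rm
from . import synthetic_data as sd


def conjugacy_max_rel_error(n_tuples: int = 1000, seed: int = 0) -> float:
    """Max relative error of the closed-form posterior mean vs quadrature.

    Random (y, alpha, beta, M*L) tuples; the unnormalized Poisson x Gamma
    posterior is integrated on a log-spaced grid spanning the posterior's
    extreme quantiles.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_tuples):
        y = int(rng.integers(0, 30))
        alpha = rng.uniform(0.05, 5)
        beta = rng.uniform(0.05, 10)
        ml = rng.uniform(0.1, 100)
        closed = (y + alpha) / (ml + beta)
        lo = stats.gamma.ppf(1e-13, y + alpha, scale=1 / (ml + beta))
        hi = stats.gamma.isf(1e-13, y + alpha, scale=1 / (ml + beta))
        grid = np.logspace(np.log10(max(lo, 1e-300)), np.log10(hi), 20_000)
        post = stats.poisson.pmf(y, grid * ml) * stats.gamma.pdf(
            grid, alpha, scale=1 / beta)
        mean = integrate.trapezoid(grid * post, grid) / integrate.trapezoid(post, grid)
        worst = max(worst, abs(mean - closed) / closed)
    return float(worst)


def ril_map_recovery(seed: int = 0, n_markers_per_chrom: int = 2500,
                     n_ril: int = 400, n_rep: int = 1000) -> dict:
    """Correlate 4-Mb posterior-mean rates with the generating truth.

    Returns per-region Pearson correlations plus the posterior-shrinkage
    check for zero-count intervals (strictly between 0 and the prior mean).
    """
    scheme = sd.default_region_scheme()
    true_map = sd.simulate_true_map(scheme, seed=seed + 1)
    geno, truth = sd.simulate_ril_population(
        true_map, scheme, n_markers_per_chrom=n_markers_per_chrom,
        n_ril=n_ril, seed=seed + 2)
    map_df = rm.build_meiotic_map(geno, scheme, n_rep=n_rep, seed=seed + 3)
    w_est = rm.aggregate_map_windows(map_df, 4_000_000)
    w_true = rm.aggregate_map_windows(
        truth.rename(columns={"true_cM_per_Mb": "cM_per_Mb"}), 4_000_000)
    label = np.array([scheme.assign(c, int(s))
                      for c, s in zip(w_est["chrom"], w_est["start"])])
    out = {}
    for reg in ("R1", "R3"):
        selr = (label == reg) & w_est["value"].notna() & w_true["value"].notna()
        out[f"pearson_{reg}"] = float(np.corrcoef(
            w_est["value"][selr], w_true["value"][selr])[0, 1])
    # shrinkage for y = 0 intervals: prior (alpha_r, beta_r) reconstructed
    # from the posterior columns (shape - y_mean, rate - M*L)
    y0 = map_df["y_mean"].to_numpy() == 0
    post = map_df["C_bay"].to_numpy()
    alpha = (map_df["post_shape"] - map_df["y_mean"]).to_numpy()
    lengths_mb = (map_df["end"] - map_df["start"]).to_numpy() / 1e6
    beta = map_df["post_rate"].to_numpy() - n_ril * lengths_mb
    prior_mean = alpha / beta
    out["shrinkage_ok"] = bool(np.all((post[y0] > 0)
                                      & (post[y0] < prior_mean[y0])))
    out["n_y0"] = int(y0.sum())
    return out


def hw_roundtrip_max_error(n_points: int = 100_000) -> float:
    """Forward-then-inverse Haldane-Waddington identity over r in [0, 0.49]."""
    r = np.linspace(0, 0.49, n_points)
    back = rm.haldane_waddington_inverse(rm.haldane_waddington_forward(r))
    return float(np.abs(back - r).max())


def mvn_recovery_max_error(n: int = 5000, seed: int = 0) -> float:
    """Max absolute error of fitted pairwise correlations at sample size n."""
    rng = np.random.default_rng(seed)
    R = np.array([[1, .5, .3, .2], [.5, 1, .4, .25],
                  [.3, .4, 1, .35], [.2, .25, .35, 1.]])
    sds = np.array([.2, .25, .3, .22])
    Y = rng.multivariate_normal(np.full(4, 0.1), np.outer(sds, sds) * R, size=n)
    fit = dv.fit_profile_correlation(Y, "full")
    return float(np.abs(fit.correlation - R).max())


def bic_selection_rates(n_reps: int = 100, n: int = 2000, seed: int = 0) -> dict:
    """Fraction of replicates where BIC picks the generating structure."""
    R_full = np.array([[1, .5, .2, .2], [.5, 1, .3, .2],
                       [.2, .3, 1, .45], [.2, .2, .45, 1.]])
    out = {}
    for truth in ("equicorrelated", "full"):
        hits = 0
        for i in range(n_reps):
            rng = np.random.default_rng(seed + 1000 * (truth == "full") + i)
            sigma = (sd.equicorrelated_sigma(0.3, [0.8, 1.0, 1.2, 0.9])
                     if truth == "equicorrelated" else R_full)
            Y = rng.multivariate_normal(np.zeros(4), sigma, size=n)
            best, _ = dv.compare_structures(
                dv.fit_profile_correlation(Y, "full"),
                dv.fit_profile_correlation(Y, "equicorrelated"))
            hits += best == truth
        out[truth] = hits / n_reps
    return out


def permutation_calibration(n_reps: int = 500, n_sim: int = 399,
                            m_per_region: int = 16, interval_bp: int = 200_000,
                            seed: int = 0) -> dict:
    """Null-calibration of the HRI-sharing permutation p-value.

    Each replicate draws every population's HRIs uniformly within regions
    (the permutation's own null), computes the sharing p-value and checks
    the observed shared proportion against the 95% null envelope. Returns
    the KS statistic/p of the p-values against Uniform(0,1) and the
    envelope coverage.
    """
    scheme = sd.default_region_scheme()
    grid = sd.make_interval_grid(scheme, interval_bp=interval_bp)
    ints = grid.intervals
    region_of = co._assign_intervals_to_regions(grid, scheme)
    uniq = pd.unique(region_of)
    cand = {reg: np.flatnonzero(region_of == reg) for reg in uniq}
    ps = np.empty(n_reps)
    in_env = 0
    for rep in range(n_reps):
        rng = np.random.default_rng(seed + rep)
        hris = {}
        for pop in sd.POPULATIONS:
            idx = np.sort(np.concatenate([
                rng.choice(cand[reg], size=m_per_region, replace=False)
                for reg in uniq]))
            df = ints.iloc[idx][["chrom", "start", "end"]].copy()
            df["summary_lambda"] = 5.0
            hris[pop] = df.reset_index(drop=True)
        null = co.permutation_null(hris, grid, scheme, n_sim=n_sim,
                                   seed=seed + 100_000 + rep)
        ps[rep] = null.p_value
        lo, hi = np.quantile(null.shared, [0.025, 0.975])
        in_env += lo <= null.observed.shared_proportion <= hi
    ks = stats.kstest(ps, "uniform")
    return {"ks_stat": float(ks.statistic), "ks_p": float(ks.pvalue),
            "envelope_coverage": in_env / n_reps}


def gini_examples() -> dict:
    """The frozen Gini checks: identical maps, point mass, worked example."""
    x = np.array([0.3, 1.2, 0.5, 2.0])
    n = 8
    point = np.zeros(n)
    point[3] = 1.0
    return {
        "identical": dv.gini_pair(x, x),
        "point_mass_8": dv.gini_pair(point, np.full(n, 1.0)),
        "worked_example": dv.gini_pair(np.array([0.1, 0.1, 0.1, 0.7]),
                                       np.full(4, 0.25)),
    }


def fst_recovery(seed: int = 0, n_loci: int = 5000,
                 n_haplotypes: int = 100) -> float:
    """Weir-Cockerham estimate under Balding-Nichols drift F = 0.05."""
    haps, _ = sd.simulate_population_genotypes(
        {"A": 0.05, "B": 0.05}, n_haplotypes, n_loci, seed=seed)
    return float(dv.wc_fst_pair(haps["A"], haps["B"]))


def wc_oracle_max_error(n_tables: int = 1000, seed: int = 0) -> float:
    """Vectorized estimator vs per-locus loop on random two-allele tables."""

    def brute(ca, cb):
        num = den = 0.0
        for l in range(ca.shape[0]):
            n1, n2 = ca[l].sum(), cb[l].sum()
            nt = n1 + n2
            nc = nt - (n1**2 + n2**2) / nt
            for a in range(ca.shape[1]):
                p1, p2 = ca[l, a] / n1, cb[l, a] / n2
                pbar = (ca[l, a] + cb[l, a]) / nt
                msa = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
                msw = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (nt - 2)
                num += msa - msw
                den += msa + (nc - 1) * msw
        return num / den

    rng = np.random.default_rng(seed)
    worst = 0.0
    done = 0
    while done < n_tables:
        L = int(rng.integers(2, 8))
        n1, n2 = rng.integers(4, 40, 2)
        ca = np.zeros((L, 2))
        cb = np.zeros((L, 2))
        ca[:, 0] = rng.integers(0, n1 + 1, L)
        ca[:, 1] = n1 - ca[:, 0]
        cb[:, 0] = rng.integers(0, n2 + 1, L)
        cb[:, 1] = n2 - cb[:, 0]
        mono = ((ca[:, 0] + cb[:, 0] == 0) | (ca[:, 1] + cb[:, 1] == 0)).all()
        if mono:
            continue
        got = dv.wc_fst_from_counts(ca, cb)
        worst = max(worst, abs(got - brute(ca, cb)))
        done += 1
    return float(worst)


def coupled_slope_rep(seed: int, slope: float = -2.0) -> dv.RegressionResult:
    """One coupled experiment: simulate, estimate correlations and F_ST, regress."""
    bundle, _ = sd.simulate_coupled_experiment(
        sd.CouplingDesign(slope=slope), seed=seed)
    pops = list(sd.POPULATIONS)
    xs, ys = [], []
    for item in bundle:
        fit = dv.fit_profile_correlation(item["Y"], "full")
        counts = item["allele_counts"]
        for i in range(4):
            for j in range(i + 1, 4):
                xs.append(dv.wc_fst_from_counts(counts[pops[i]],
                                                counts[pops[j]]))
                ys.append(fit.correlation[i, j])
    return dv.fst_correlation_regression(np.array(xs), np.array(ys))


def slope_coverage(n_reps: int = 500, slope: float = -2.0,
                   seed: int = 0) -> dict:
    """Fraction of replicates whose 95% CI covers the true coupling slope."""
    cover = 0
    slopes = np.empty(n_reps)
    for rep in range(n_reps):
        res = coupled_slope_rep(seed + rep, slope=slope)
        cover += res.ci_low <= slope <= res.ci_high
        slopes[rep] = res.slope
    return {"coverage": cover / n_reps, "mean_slope": float(slopes.mean()),
            "sd_slope": float(slopes.std())}


def hri_spike_detection(seed: int = 0) -> dict:
    """Sensitivity/FDR of HRI calling on planted spikes (noise sd 0.1)."""
    scheme = sd.default_region_scheme()
    grid = sd.make_interval_grid(scheme, interval_bp=20_000)
    sigma = sd.equicorrelated_sigma(0.3, [0.1] * 4)
    design = sd.SharingDesign(n_spikes_per_region=8, magnitude_median=8.0)
    posts, truth = sd.simulate_lambda_profiles(
        grid, scheme, sigma, sharing=design, posterior_noise_sd=0.1,
        S=60, seed=seed)
    pop = "WE"
    hris = lp.call_hris(lp.median_lambda(posts[pop]), threshold=4.0)
    spikes = truth["spikes"]
    planted = set(spikes[spikes["populations"].str.contains(pop)]["interval"])
    ints = grid.intervals
    called = set()
    for _, h in hris.iterrows():
        hit = ints[(ints["chrom"] == h.chrom) & (ints["start"] >= h.start)
                   & (ints["end"] <= h.end)]
        called.update(hit.index)
    tp = len(planted & called)
    return {"sensitivity": tp / max(len(planted), 1),
            "fdr": 1 - tp / max(len(called), 1),
            "n_planted": len(planted), "n_called": len(called)}
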