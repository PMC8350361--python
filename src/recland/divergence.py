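"""Similarity and differentiation statistics between population profiles.

The core model treats the per-interval log10 intensity of the four
populations as draws from a 4-variate normal with a common mean mu and
either an unstructured covariance (each pair its own correlation; 11 free
parameters) or a heterogeneous-variance equicorrelated structure (one
correlation for all pairs; 6 parameters). Structures are compared by BIC.
Map divergence between two populations is a Gini coefficient of one
population's genetic distances accumulated along the other's map; genetic
differentiation is the Weir-Cockerham F_ST from (possibly multi-allelic)
haplotype data; and the coupling of profile similarity to differentiation
is estimated by OLS of pairwise correlation on pairwise F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------- MVN model

@dataclass
class CorrelationModelFit:
    structure: str                 # "full" | "equicorrelated"
    mu: float | np.ndarray
    variances: np.ndarray          # (p,)
    correlation: np.ndarray        # (p, p)
    loglik: float
    n_params: int
    n: int

    @property
    def bic(self) -> float:
        return -2 * self.loglik + self.n_params * np.log(self.n)

    def pairwise(self) -> dict[tuple[int, int], float]:
        p = len(self.variances)
        return {(i, j): float(self.correlation[i, j])
                for i in range(p) for j in range(i + 1, p)}


def _mvn_loglik(Y: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> float:
    n, p = Y.shape
    E = Y - mu
    sign, logdet = np.linalg.slogdet(sigma)
    if sign <= 0:
        return -np.inf
    quad = np.einsum("ij,jk,ik->", E, np.linalg.inv(sigma), E)
    return -0.5 * (n * p * np.log(2 * np.pi) + n * logdet + quad)


def _fit_full(Y: np.ndarray, common_mean: bool, tol: float = 1e-12,
              max_iter: int = 500) -> tuple[np.ndarray, np.ndarray, float, int]:
    n, p = Y.shape
    ybar = Y.mean(axis=0)
    if not common_mean:
        sigma = np.cov(Y.T, bias=True)
        return ybar, sigma, _mvn_loglik(Y, ybar, sigma), p + p * (p + 1) // 2
    mu = float(Y.mean())
    for _ in range(max_iter):
        E = Y - mu
        sigma = E.T @ E / n
        try:
            w = np.linalg.solve(sigma, np.ones(p))
        except np.linalg.LinAlgError:  # degenerate (e.g. duplicated profiles)
            w = np.linalg.pinv(sigma) @ np.ones(p)
        mu_new = float((ybar @ w) / w.sum())
        if abs(mu_new - mu) < tol * (1 + abs(mu)):
            mu = mu_new
            break
        mu = mu_new
    E = Y - mu
    sigma = E.T @ E / n
    return np.full(p, mu), sigma, _mvn_loglik(Y, np.full(p, mu), sigma), 1 + p * (p + 1) // 2


def _equi_sigma(log_sd: np.ndarray, z: float, p: int) -> np.ndarray:
    # rho in (-1/(p-1), 1) via a scaled logistic of z
    lo = -1.0 / (p - 1)
    rho = lo + (1 - lo) / (1 + np.exp(-z))
    sd = np.exp(log_sd)
    R = np.full((p, p), rho)
    np.fill_diagonal(R, 1.0)
    return np.outer(sd, sd) * R


def _fit_equicorrelated(Y: np.ndarray, common_mean: bool) -> tuple[np.ndarray, np.ndarray, float, int]:
    n, p = Y.shape

    def unpack(theta):
        if common_mean:
            mu = np.full(p, theta[0])
            rest = theta[1:]
        else:
            mu = theta[:p]
            rest = theta[p:]
        return mu, _equi_sigma(rest[:p], rest[p], p)

    def nll(theta):
        mu, sigma = unpack(theta)
        ll = _mvn_loglik(Y, mu, sigma)
        return np.inf if not np.isfinite(ll) else -ll

    sd0 = np.log(Y.std(axis=0) + 1e-12)
    r0 = np.clip(np.mean(np.corrcoef(Y.T)[np.triu_indices(p, 1)]), -1 / (p - 1) + 1e-3, 1 - 1e-3)
    lo = -1.0 / (p - 1)
    z0 = -np.log((1 - lo) / (r0 - lo) - 1)
    x0 = ([float(Y.mean())] if common_mean else list(Y.mean(axis=0))) + list(sd0) + [z0]
    res = optimize.minimize(nll, np.asarray(x0), method="L-BFGS-B")
    mu, sigma = unpack(res.x)
    k = (1 if common_mean else p) + p + 1
    return mu, sigma, -res.fun, k


def fit_profile_correlation(Y: np.ndarray, structure: str = "full",
                            common_mean: bool = True,
                            min_n: int = 20) -> CorrelationModelFit:
    """ML fit of the multivariate-normal profile model on log10 intensities.

    ``Y``: (n_intervals, n_populations) complete matrix of log10 lambda
    medians. ``structure``: "full" (unstructured covariance) or
    "equicorrelated" (one correlation for all pairs, heterogeneous
    variances). A common mean across populations is the default; population
    means are available behind ``common_mean=False``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (intervals x populations)")
    if np.isnan(Y).any():
        raise ValueError("Y must be complete (no missing cells)")
    n, p = Y.shape
    if n < min_n:
        raise ValueError(f"too few intervals (n={n} < {min_n})")
    if structure == "full":
        mu, sigma, ll, k = _fit_full(Y, common_mean)
    elif structure == "equicorrelated":
        mu, sigma, ll, k = _fit_equicorrelated(Y, common_mean)
    else:
        raise ValueError(f"unknown structure {structure!r}")
    sd = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(sd, sd)
    return CorrelationModelFit(structure, mu, np.diag(sigma).copy(), corr,
                               float(ll), k, n)


def compare_structures(fit_full: CorrelationModelFit,
                       fit_equi: CorrelationModelFit) -> tuple[str, float]:
    """Structure with the lower BIC wins; ties go to the simpler model."""
    if fit_full.n != fit_equi.n:
        raise ValueError("fits computed on different n")
    delta = fit_full.bic - fit_equi.bic
    if delta < 0:
        return "full", float(delta)
    return "equicorrelated", float(delta)


# ------------------------------------------------------ windowed correlation

def profile_correlation_windows(map_a: pd.DataFrame, map_b: pd.DataFrame,
                                groups: pd.Series | None = None,
                                min_points: int = 5) -> pd.DataFrame:
    """Pearson correlation of two windowed maps, per group (or genome-wide).

    Missing windows are dropped pairwise; groups with fewer than
    ``min_points`` complete windows are skipped; zero variance yields NaN.
    """
    a = map_a["value"].to_numpy(dtype=float)
    b = map_b["value"].to_numpy(dtype=float)
    if len(a) != len(b):
        raise ValueError("maps have different window counts")
    g = groups.to_numpy() if groups is not None else np.full(len(a), "genome")
    rows = []
    for grp in pd.unique(g):
        sel = (g == grp) & ~np.isnan(a) & ~np.isnan(b)
        n = int(sel.sum())
        if n < min_points:
            continue
        if a[sel].std() == 0 or b[sel].std() == 0:
            rows.append((grp, np.nan, n))
            continue
        rows.append((grp, float(np.corrcoef(a[sel], b[sel])[0, 1]), n))
    return pd.DataFrame(rows, columns=["group", "pearson_r", "n_windows"])


# ------------------------------------------------------------------- Gini

def gini_pair(d_a: np.ndarray, d_b: np.ndarray) -> float:
    """Gini divergence of profile a against the map of profile b.

    Intervals sorted by ascending d_a/d_b trace a Lorenz curve of cumulative
    normalized d_a against cumulative normalized d_b; the coefficient is
    1 - 2 x (trapezoidal area under the curve). 0 for proportional
    profiles, 1 - 1/n for a point mass against a uniform map.
    """
    d_a = np.asarray(d_a, dtype=float)
    d_b = np.asarray(d_b, dtype=float)
    if d_a.shape != d_b.shape:
        raise ValueError("profiles differ in length")
    if np.any(d_a < 0) or np.any(d_b < 0):
        raise ValueError("distances must be non-negative")
    ta, tb = d_a.sum(), d_b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("zero total genetic distance")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(d_b > 0, d_a / np.where(d_b > 0, d_b, 1), np.inf)
    order = np.argsort(ratio, kind="stable")
    x = np.concatenate([[0.0], np.cumsum(d_b[order]) / tb])
    y = np.concatenate([[0.0], np.cumsum(d_a[order]) / ta])
    area = float(np.trapezoid(y, x))
    return float(1 - 2 * area)


# -------------------------------------------------------------------- F_ST

def _wc_components(counts_a: np.ndarray, counts_b: np.ndarray):
    """Weir-Cockerham variance components for haploid allele-count tables.

    ``counts_x``: (n_loci, n_alleles) allele counts per population. Returns
    per-locus numerator and denominator sums over alleles.
    """
    n1 = counts_a.sum(axis=1).astype(float)
    n2 = counts_b.sum(axis=1).astype(float)
    nt = n1 + n2
    r = 2
    nc = (nt - (n1**2 + n2**2) / nt) / (r - 1)
    p1 = counts_a / n1[:, None]
    p2 = counts_b / n2[:, None]
    pbar = (counts_a + counts_b) / nt[:, None]
    msa = (n1[:, None] * (p1 - pbar) ** 2 + n2[:, None] * (p2 - pbar) ** 2) / (r - 1)
    msw = (n1[:, None] * p1 * (1 - p1) + n2[:, None] * p2 * (1 - p2)) / (nt - r)[:, None]
    num = (msa - msw).sum(axis=1)
    den = (msa + (nc[:, None] - 1) * msw).sum(axis=1)
    return num, den


def allele_counts(hap: np.ndarray, n_alleles: int | None = None,
                  missing: int = -1) -> np.ndarray:
    """Per-locus allele-count table (n_loci, n_alleles) from haplotype codes."""
    hap = np.asarray(hap)
    if n_alleles is None:
        n_alleles = int(hap.max(initial=0)) + 1
    return np.stack([(hap == a).sum(axis=1) for a in range(n_alleles)], axis=1)


def wc_fst_from_counts(ca: np.ndarray, cb: np.ndarray) -> float:
    """Ratio-of-averages Weir-Cockerham theta from allele-count tables."""
    if np.any(ca.sum(axis=1) < 2) or np.any(cb.sum(axis=1) < 2):
        raise ValueError("locus with fewer than 2 called haplotypes in a population")
    num, den = _wc_components(ca.astype(float), cb.astype(float))
    total_den = den.sum()
    if total_den == 0:
        raise ValueError("all loci monomorphic; F_ST undefined")
    return float(num.sum() / total_den)


def wc_fst_pair(hap_a: np.ndarray, hap_b: np.ndarray, missing: int = -1) -> float:
    """Weir-Cockerham theta between two populations of haplotypes.

    ``hap_x``: (n_loci, n_haplotypes) integer allele codes; ``missing``
    entries are dropped per locus. Multi-allelic loci contribute one
    component per allele; loci monomorphic across both populations drop out
    of both sums. Combined across loci as a ratio of averages; negative
    estimates are retained.
    """
    hap_a = np.asarray(hap_a)
    hap_b = np.asarray(hap_b)
    if hap_a.shape[0] != hap_b.shape[0]:
        raise ValueError("populations differ in locus count")
    n_alleles = int(max(hap_a.max(initial=0), hap_b.max(initial=0))) + 1
    return wc_fst_from_counts(allele_counts(hap_a, n_alleles, missing),
                              allele_counts(hap_b, n_alleles, missing))


def wc_fst(haplotypes: dict[str, np.ndarray], missing: int = -1) -> pd.DataFrame:
    """Symmetric pairwise Weir-Cockerham F_ST matrix over populations."""
    pops = list(haplotypes)
    n_alleles = 1 + max(int(np.asarray(h).max(initial=0))
                        for h in haplotypes.values())
    counts = {p: allele_counts(haplotypes[p], n_alleles, missing) for p in pops}
    rows = []
    for i, a in enumerate(pops):
        for b in pops[i + 1:]:
            rows.append((a, b, wc_fst_from_counts(counts[a], counts[b])))
    return pd.DataFrame(rows, columns=["pop_a", "pop_b", "fst"])


# --------------------------------------------------------------- regression

@dataclass
class RegressionResult:
    unit: str
    slope: float
    intercept: float
    ci_low: float
    ci_high: float
    n: int

    @property
    def significant_negative(self) -> bool:
        """Slope negative with a 95% CI excluding zero."""
        return self.slope < 0 and self.ci_high < 0


def fst_correlation_regression(fst: np.ndarray, correlation: np.ndarray,
                               unit: str = "region") -> RegressionResult:
    """OLS of profile correlation on pairwise F_ST with a t-based 95% CI."""
    fst = np.asarray(fst, dtype=float)
    correlation = np.asarray(correlation, dtype=float)
    n = len(fst)
    if n < 3:
        raise ValueError("need at least 3 points")
    x = fst - fst.mean()
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("F_ST values are constant; slope undefined")
    slope = float(x @ correlation) / sxx
    intercept = float(correlation.mean() - slope * fst.mean())
    resid = correlation - intercept - slope * fst
    se = np.sqrt(float(resid @ resid) / (n - 2) / sxx)
    tcrit = stats.t.ppf(0.975, df=n - 2)
    return RegressionResult(unit, slope, intercept,
                            slope - tcrit * se, slope + tcrit * se, n)


def meiotic_gene_test(gene_fst: pd.DataFrame, genomewide_corr: pd.DataFrame,
                      fdr_alpha: float = 1e-4, min_controls: int = 5) -> pd.DataFrame:
    """Differentiation-coupling contrast of meiotic genes against regional controls.

    ``gene_fst``: long DataFrame (gene, region, role in {meiotic, control},
    pop_a, pop_b, fst) with one F_ST per population pair per gene.
    ``genomewide_corr``: DataFrame (pop_a, pop_b, correlation) of
    genome-wide profile correlations. Per gene an OLS slope of gene-window
    F_ST on the pairwise correlations is fitted; the empirical one-sided
    (more-negative) p of each meiotic gene is its slope's rank among the
    control slopes of the same region, and Benjamini-Hochberg FDR is applied
    across meiotic genes.
    """
    corr_key = {tuple(sorted((r.pop_a, r.pop_b))): r.correlation
                for r in genomewide_corr.itertuples()}

    def slope_of(g: pd.DataFrame) -> float:
        x = np.array([corr_key[tuple(sorted((r.pop_a, r.pop_b)))]
                      for r in g.itertuples()])
        y = g["fst"].to_numpy(dtype=float)
        return float(stats.linregress(x, y).slope)

    slopes = gene_fst.groupby(["gene", "region", "role"]).apply(
        slope_of, include_groups=False).rename("slope").reset_index()
    rows = []
    for region, g in slopes.groupby("region"):
        controls = g[g["role"] == "control"]["slope"].to_numpy()
        meio = g[g["role"] == "meiotic"]
        if meio.empty:
            continue
        if len(controls) < min_controls:
            raise ValueError(f"region {region}: fewer than {min_controls} control genes")
        for r in meio.itertuples():
            p = (1 + int(np.sum(controls <= r.slope))) / (len(controls) + 1)
            rows.append((r.gene, region, r.slope, p))
    out = pd.DataFrame(rows, columns=["gene", "region", "slope", "p_emp"])
    if out.empty:
        return out.assign(fdr_significant=pd.Series(dtype=bool))
    # Benjamini-Hochberg
    m = len(out)
    order = np.argsort(out["p_emp"].to_numpy())
    thresh = np.zeros(m, dtype=bool)
    ps = out["p_emp"].to_numpy()[order]
    below = np.flatnonzero(ps <= (np.arange(1, m + 1) / m) * fdr_alpha)
    if len(below):
        thresh[order[: below.max() + 1]] = True
    out["fdr_significant"] = thresh
    return out
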