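"""Sample/variant QC and gene-based rare-variant association.

Implements the statistical layer of the case/control arm:

* exact Hardy-Weinberg equilibrium test (conditional on allele counts);
* variant QC by call rate, control-sample HWE and a MAF ceiling;
* method-of-moments identity-by-descent sharing (PI_HAT) for relatedness
  screening and PCA-based population outlier flagging;
* Cochran-Armitage trend statistics with the genomic inflation factor
  lambda_GC;
* the SKAT-O optimal unified rare-variant test: for each mixing value
  rho, Q_rho = (1-rho) Q_SKAT + rho Q_burden is a quadratic form in the
  score residuals whose null distribution is a positive mixture of 1-df
  chi-squares, evaluated by characteristic-function (Imhof) inversion
  with a moment-matching fallback; the omnibus p-value integrates the
  minimum-p statistic over the rho grid;
* Benjamini-Hochberg q-values for the per-gene results.

The SKAT-O null model here is an intercept-only binomial model (no
covariates), matching a case/control panel without measured confounders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .variant_model import (
    Annotation,
    FunctionalClass,
    Genotype,
    GenotypeTable,
    PolyPhen,
    Sift,
    VariantSite,
)

__all__ = [
    "GeneAssocResult",
    "hwe_exact",
    "variant_qc",
    "ibd_pi_hat",
    "pca_outliers",
    "trend_stat",
    "trend_lambda",
    "beta_maf_weights",
    "quadform_sf",
    "skato",
    "SkatoResult",
    "bh_fdr",
    "is_qualifying",
    "skato_by_gene",
]

DEFAULT_RHO_GRID = (0.0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1.0)

CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact HWE test p-value conditional on observed allele counts.

    Sums the conditional probabilities of all heterozygote counts that are
    as likely or less likely than the observed count, given the minor and
    major allele totals.  Symmetric in the two homozygote counts.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    # log P(het = h | allele counts) up to a constant:
    #   P ∝ n_rare! n_common! n! 2^h / ((n_rare-h)/2)! h! ((2n-n_rare-h)/2)! (2n)!
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    common_hom = (2 * n - n_rare - hets) // 2
    logp = hets * np.log(2.0) - (
        gammaln(rare_hom + 1) + gammaln(hets + 1) + gammaln(common_hom + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[np.where(hets == n_het)[0]]
    if obs.size == 0:
        raise ValueError(
            f"heterozygote count {n_het} impossible for allele counts (parity)"
        )
    p = probs[probs <= obs[0] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


# ---------------------------------------------------------------------------
# variant QC


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int, int]:
    return (
        int((col == Genotype.hom_ref).sum()),
        int((col == Genotype.het).sum()),
        int((col == Genotype.hom_alt).sum()),
        int((col == Genotype.missing).sum()),
    )


def site_maf(col: np.ndarray) -> float:
    """Minor allele frequency from non-missing genotypes (0 if all missing)."""
    called = col[col != Genotype.missing]
    if called.size == 0:
        return 0.0
    af = float(called.sum()) / (2 * called.size)
    return min(af, 1 - af)


def variant_qc(
    gt: GenotypeTable,
    case_labels: np.ndarray | None = None,
    call_rate_min: float = 0.80,
    hwe_min_p: float = 1e-6,
    maf_max: float | None = 0.005,
) -> tuple[list[int], pd.DataFrame]:
    """Apply call-rate, HWE and MAF filters; log which rule removed each site.

    HWE is evaluated in controls only when ``case_labels`` is given
    (case enrichment legitimately distorts HWE).  ``maf_max`` keeps sites
    with MAF strictly below the ceiling; pass None to disable.
    Returns (retained site indices, exclusion log).
    """
    labels = None if case_labels is None else np.asarray(case_labels)
    log_rows = []
    retained = []
    for j in range(gt.n_sites):
        col = gt.gt[:, j]
        n0, n1, n2, nmiss = _genotype_counts(col)
        called = n0 + n1 + n2
        call_rate = called / len(col) if len(col) else 0.0
        if call_rate < call_rate_min:
            log_rows.append({"site": j, "rule": "call_rate", "value": call_rate})
            continue
        hwe_col = col if labels is None else col[labels == 0]
        h0, h1, h2, _ = _genotype_counts(hwe_col)
        p_hwe = hwe_exact(h0, h1, h2)
        if p_hwe < hwe_min_p:
            log_rows.append({"site": j, "rule": "hwe", "value": p_hwe})
            continue
        maf = site_maf(col)
        if maf_max is not None and maf >= maf_max:
            log_rows.append({"site": j, "rule": "maf", "value": maf})
            continue
        retained.append(j)
    return retained, pd.DataFrame(log_rows, columns=["site", "rule", "value"])


# ---------------------------------------------------------------------------
# relatedness and stratification


def ibd_pi_hat(
    gt: GenotypeTable,
    pair: tuple[str, str],
    freqs: np.ndarray | None = None,
) -> float:
    """Method-of-moments PI_HAT = P(IBD=2) + 0.5 P(IBD=1) for a sample pair.

    Observed identity-by-state counts at informative sites (both called,
    polymorphic) are equated with their expectations under IBD state
    mixtures given allele frequencies (estimated from the whole table
    unless supplied).  Estimates are clamped to [0, 1]; fewer than 50
    informative sites triggers a warning.
    """
    i1, i2 = (gt.sample_index(s) for s in pair)
    g1 = gt.gt[i1, :].astype(float)
    g2 = gt.gt[i2, :].astype(float)
    if freqs is None:
        freqs = np.array(
            [
                (col[col != Genotype.missing].sum() / (2 * max((col != Genotype.missing).sum(), 1)))
                for col in gt.gt.T
            ]
        )
    p = np.asarray(freqs, dtype=float)
    ok = (g1 >= 0) & (g2 >= 0) & (p > 0) & (p < 1)
    if ok.sum() < 50:
        warnings.warn(
            f"only {int(ok.sum())} informative sites for pair {pair}; "
            "PI_HAT estimate is unreliable",
            stacklevel=2,
        )
    g1, g2, p = g1[ok], g2[ok], p[ok]
    q = 1 - p
    ibs = 2 - np.abs(g1 - g2)
    ibs0_obs = float((ibs == 0).sum())
    ibs1_obs = float((ibs == 1).sum())
    ibs2_obs = float((ibs == 2).sum())
    n = float(len(p))
    e0_ibd0 = float((2 * p**2 * q**2).sum())
    e1_ibd0 = float((4 * p**3 * q + 4 * p * q**3).sum())
    e2_ibd0 = float((p**4 + q**4 + 4 * p**2 * q**2).sum())
    e1_ibd1 = float((2 * p**2 * q + 2 * p * q**2).sum())
    e2_ibd1 = float((p**2 + q**2).sum())
    p0 = ibs0_obs / e0_ibd0 if e0_ibd0 > 0 else 0.0
    p1 = (ibs1_obs - p0 * e1_ibd0) / e1_ibd1 if e1_ibd1 > 0 else 0.0
    p2 = (ibs2_obs - p0 * e2_ibd0 - p1 * e2_ibd1) / n if n > 0 else 0.0
    # raw moment components are individually noisy and may stray outside
    # [0,1]; only the final combination is clamped, to avoid biasing
    # near-zero estimates upward
    return float(np.clip(p2 + 0.5 * p1, 0.0, 1.0))


def pca_outliers(
    gt: GenotypeTable, n_components: int = 2, sigma: float = 6.0
) -> list[str]:
    """Flag samples beyond ``sigma`` SDs on any of the first PCs of the
    standardized genotype matrix (missing imputed to the site mean)."""
    if n_components > gt.n_samples:
        raise ValueError("more components than samples")
    if n_components == 0 or gt.n_sites == 0:
        return []
    X = gt.gt.astype(float)
    X[X < 0] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        return []
    X = (X[:, keep] - X[:, keep].mean(axis=0)) / X[:, keep].std(axis=0)
    scores = PCA(n_components=n_components, random_state=0).fit_transform(X)
    flagged = set()
    for k in range(scores.shape[1]):
        s = scores[:, k]
        spread = s.std()
        if spread == 0:
            continue
        for i in np.where(np.abs(s - s.mean()) > sigma * spread)[0]:
            flagged.add(gt.sample_ids[i])
    return sorted(flagged)


# ---------------------------------------------------------------------------
# trend test and genomic inflation


def trend_stat(col: np.ndarray, labels: np.ndarray) -> float:
    """Cochran-Armitage trend chi-square (additive scores 0/1/2) for one site.

    Returns NaN for monomorphic sites (statistic undefined).
    """
    ok = col != Genotype.missing
    g = col[ok].astype(float)
    y = labels[ok].astype(float)
    n = len(g)
    r = y.sum()
    if n == 0 or r == 0 or r == n:
        raise ValueError("both cases and controls required")
    s1 = g.sum()
    s2 = (g**2).sum()
    var = (r / n) * (1 - r / n) * (s2 - s1**2 / n)
    if var <= 0:
        return float("nan")
    u = (g * y).sum() - r * s1 / n
    return float(u**2 / var)


def trend_lambda(
    gt: GenotypeTable, case_labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-site trend statistics and the genomic inflation factor.

    lambda_GC = median(chi-square) / median of the null 1-df chi-square.
    Monomorphic sites yield NaN statistics and are excluded from the
    median; if every site is monomorphic the factor is undefined.
    """
    labels = np.asarray(case_labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("both cases and controls required")
    stats_arr = np.array([trend_stat(gt.gt[:, j], labels) for j in range(gt.n_sites)])
    finite = stats_arr[np.isfinite(stats_arr)]
    if finite.size == 0:
        raise ValueError("all sites monomorphic; lambda_GC undefined")
    lam = float(np.median(finite) / CHI2_1_MEDIAN)
    return stats_arr, lam


# ---------------------------------------------------------------------------
# quadratic-form p-values


def _liu_params(lambdas: np.ndarray) -> tuple[float, float, float, float]:
    """Moment-matched noncentral chi-square parameters (l, delta, mu_Q, sigma_Q)."""
    c1 = lambdas.sum()
    c2 = (lambdas**2).sum()
    c3 = (lambdas**3).sum()
    c4 = (lambdas**4).sum()
    s1 = c3 / c2**1.5
    s2 = c4 / c2**2
    if s1**2 > s2:
        a = 1 / (s1 - np.sqrt(s1**2 - s2))
        delta = s1 * a**3 - a**2
        df = a**2 - 2 * delta
    else:
        delta = 0.0
        df = 1 / s2
    return float(df), float(delta), float(c1), float(np.sqrt(2 * c2))


def liu_sf(q: float, lambdas: np.ndarray) -> float:
    """Moment-matching survival probability for Q = sum lambda_i chi2_1."""
    df, delta, mu_q, sigma_q = _liu_params(lambdas)
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = (q - mu_q) / sigma_q * sigma_x + mu_x
    return float(stats.ncx2.sf(x, df, delta) if delta > 0 else stats.chi2.sf(x, df))


def _liu_quantile(p_tail: float, lambdas: np.ndarray) -> float:
    """Q such that P(Q > q) ~= p_tail under the moment-matched distribution."""
    df, delta, mu_q, sigma_q = _liu_params(lambdas)
    mu_x = df + delta
    sigma_x = np.sqrt(2 * (df + 2 * delta))
    x = stats.ncx2.isf(p_tail, df, delta) if delta > 0 else stats.chi2.isf(p_tail, df)
    return float((x - mu_x) / sigma_x * sigma_q + mu_q)


def quadform_sf(q: float, lambdas) -> float:
    """P(sum_i lambda_i chi2_1,i > q) by Imhof characteristic-function
    inversion, falling back to moment matching if the integral misbehaves."""
    lam = np.asarray([l for l in np.atleast_1d(lambdas) if l > 1e-12], dtype=float)
    if lam.size == 0:
        return 1.0 if q <= 0 else 0.0
    if q <= 0:
        return 1.0
    if lam.size == 1:
        return float(stats.chi2.sf(q / lam[0], 1))
    scale = lam.max()
    lam_s = lam / scale
    q_s = q / scale

    def integrand(u):
        theta = 0.5 * np.arctan(lam_s * u).sum() - 0.5 * q_s * u
        rho = np.exp(0.25 * np.log1p((lam_s * u) ** 2).sum())
        return np.sin(theta) / (u * rho)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            val, err = integrate.quad(
                integrand, 0, np.inf, limit=200, epsabs=1e-10, epsrel=1e-8
            )
            p = 0.5 + val / np.pi
        except Exception:
            return liu_sf(q, lam)
    if not np.isfinite(p) or p < -1e-6 or p > 1 + 1e-6 or (p < 1e-10):
        return liu_sf(q, lam)
    return float(np.clip(p, 0.0, 1.0))


# ---------------------------------------------------------------------------
# SKAT-O


def beta_maf_weights(mafs: np.ndarray, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Default SKAT variant weights: the Beta(a, b) density at each MAF."""
    return stats.beta.pdf(np.clip(mafs, 1e-12, 1 - 1e-12), a, b)


@dataclass
class SkatoResult:
    p_value: float
    p_rho: dict[float, float]
    q_rho: dict[float, float]
    n_variants: int


def skato(
    genotypes: np.ndarray,
    case_labels: np.ndarray,
    weights: np.ndarray | None = None,
    rho_grid=DEFAULT_RHO_GRID,
) -> SkatoResult:
    """SKAT-O test of one gene's variants against a binary phenotype.

    Parameters
    ----------
    genotypes : (n_samples, n_variants) array of alt-allele counts
        (missing entries coded -1 are imputed to the variant mean).
    case_labels : binary array (1 = case).
    weights : per-variant weights; default Beta(1, 25) density at the MAF.
    rho_grid : mixing values; {0} is SKAT, {1} the weighted burden test.

    The statistic for each rho, Q_rho = (1-rho) Q_SKAT + rho Q_burden, is
    a quadratic form in the null-model score residuals; its p-value comes
    from the mixture-of-chi-squares distribution with eigenvalues of
    R_rho^{1/2} Z' P Z R_rho^{1/2}.  The omnibus p-value of min-rho-p is a
    one-dimensional integral over the shared chi-square-1 component.
    """
    G = np.asarray(genotypes, dtype=float)
    y = np.asarray(case_labels, dtype=float)
    if G.ndim != 2 or G.shape[0] != y.shape[0]:
        raise ValueError("genotype matrix and labels are inconsistent")
    n, m = G.shape
    if m < 2:
        raise ValueError("SKAT-O requires at least two variants")
    # impute missing to variant mean
    Gm = np.where(G < 0, np.nan, G)
    col_mean = np.nanmean(Gm, axis=0)
    inds = np.where(np.isnan(Gm))
    Gm[inds] = np.take(col_mean, inds[1])
    if weights is None:
        mafs = col_mean / 2.0
        mafs = np.minimum(mafs, 1 - mafs)
        weights = beta_maf_weights(mafs)
    w = np.asarray(weights, dtype=float)

    mu = y.mean()
    if mu <= 0 or mu >= 1:
        raise ValueError("labels must include both cases and controls")
    v = mu * (1 - mu)
    resid = y - mu
    Z = Gm * w  # n x m weighted genotypes
    Zc = Z - Z.mean(axis=0)  # projection removing the intercept
    Z1 = np.sqrt(v) * Zc  # Z1'Z1 = Z' P Z
    s = Z.T @ resid  # score vector

    rho_list = [float(r) for r in rho_grid]
    p_rho: dict[float, float] = {}
    q_rho: dict[float, float] = {}
    lambdas_by_rho: dict[float, np.ndarray] = {}
    for rho in rho_list:
        q_stat = float((1 - rho) * (s**2).sum() + rho * s.sum() ** 2)
        # R_rho^{1/2} for R = (1-rho) I + rho 11'
        R = (1 - rho) * np.eye(m) + rho * np.ones((m, m))
        evals, evecs = np.linalg.eigh(R)
        R_half = evecs @ np.diag(np.sqrt(np.clip(evals, 0, None))) @ evecs.T
        K = R_half @ (Z1.T @ Z1) @ R_half
        lam = np.linalg.eigvalsh(K)
        lam = lam[lam > 1e-10 * max(lam.max(), 1e-300)]
        lambdas_by_rho[rho] = lam
        q_rho[rho] = q_stat
        # cheap moment-matched p first; the smallest are refined below by
        # characteristic-function inversion
        p_rho[rho] = liu_sf(q_stat, lam)
    for rho in sorted(rho_list, key=lambda r: p_rho[r])[:2]:
        p_rho[rho] = quadform_sf(q_rho[rho], lambdas_by_rho[rho])

    if len(rho_list) == 1:
        rho = rho_list[0]
        return SkatoResult(p_value=p_rho[rho], p_rho=p_rho, q_rho=q_rho, n_variants=m)

    p_min = min(p_rho.values())
    # omnibus parameters (Lee et al. decomposition of Z1 into the
    # direction of the row-mean vector and its orthogonal complement)
    z_mean = Z1.mean(axis=1)
    zbar2 = float((z_mean**2).sum())
    if zbar2 <= 0:
        return SkatoResult(
            p_value=min(1.0, p_min * len(rho_list)), p_rho=p_rho, q_rho=q_rho, n_variants=m
        )
    cof1 = (z_mean @ Z1) / zbar2
    Z_item1 = np.outer(z_mean, cof1)
    Z_item2 = Z1 - Z_item1
    W22 = Z_item2.T @ Z_item2
    lam_o = np.linalg.eigvalsh(W22)
    lam_o = lam_o[lam_o > 1e-10 * max(abs(lam_o).max(), 1e-300)]
    W11 = Z_item1.T @ Z_item1
    var_remain = 4.0 * float((W11 * W22).sum())
    mu_q = float(lam_o.sum())
    var_q = 2.0 * float((lam_o**2).sum()) + var_remain
    # per-rho quantile of Q at the minimum p (moment-matched inverse)
    rho_capped = [min(r, 0.999) for r in rho_list]
    tau = np.array([m**2 * r * zbar2 + (1 - r) * float((cof1**2).sum()) * zbar2 for r in rho_capped])
    qmin = np.array([_liu_quantile(p_min, lambdas_by_rho[r]) for r in rho_list])

    one_minus_rho = np.array([1 - r for r in rho_capped])
    # degrees of freedom for the moment-matched distribution of the
    # rho-independent component (kurtosis matching)
    ker_q = 12.0 * float((lam_o**4).sum()) / float((lam_o**2).sum()) ** 2
    df_o = max(12.0 / ker_q, 0.5)

    def integrand(x: np.ndarray) -> np.ndarray:
        x = np.atleast_1d(x)
        tvals = (qmin[:, None] - tau[:, None] * x[None, :]) / one_minus_rho[:, None]
        tmin = tvals.min(axis=0)
        # moment-matched chi-square CDF of the shared mixture component
        t_std = (tmin - mu_q) / np.sqrt(var_q) * np.sqrt(2 * df_o) + df_o
        cdf = stats.chi2.cdf(t_std, df_o)
        return cdf * stats.chi2.pdf(x, 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        nodes, weights_gl = np.polynomial.legendre.leggauss(256)
        lo, hi = 0.0, 40.0
        xs = 0.5 * (hi - lo) * (nodes + 1) + lo
        val = float(0.5 * (hi - lo) * (weights_gl * integrand(xs)).sum())
    p_value = 1.0 - val
    p_value = min(p_value, p_min * len(rho_list))
    p_value = float(np.clip(p_value, max(p_min * 1e-3, 1e-300), 1.0))
    return SkatoResult(p_value=p_value, p_rho=p_rho, q_rho=q_rho, n_variants=m)


# ---------------------------------------------------------------------------
# multiple testing and the per-gene driver


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (clamped to 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class GeneAssocResult:
    gene: str
    n_variants_tested: int
    p_skato: float
    q_value: float = float("nan")

    def __post_init__(self):
        if not 0 <= self.p_skato <= 1:
            raise ValueError("p outside [0,1]")


def is_qualifying(
    site: VariantSite, ann: Annotation, maf_max: float = 0.01
) -> bool:
    """Variant inclusion rule for the gene-based test: rare (MAF below the
    ceiling) and either a missense called damaging by SIFT *or* PolyPhen-2,
    or a canonical splice-site variant."""
    if ann.maf is not None and ann.maf >= maf_max:
        return False
    if site.functional_class is FunctionalClass.canonical_splice:
        return True
    if site.functional_class is not FunctionalClass.missense:
        return False
    return ann.sift is Sift.damaging or ann.polyphen in (
        PolyPhen.probably_damaging,
        PolyPhen.possibly_damaging,
    )


def skato_by_gene(
    gt: GenotypeTable,
    case_labels: np.ndarray,
    annotations: dict[tuple, Annotation] | None = None,
    maf_max: float = 0.01,
    rho_grid=DEFAULT_RHO_GRID,
    min_variants: int = 2,
) -> tuple[list[GeneAssocResult], pd.DataFrame]:
    """Run SKAT-O per gene over qualifying variants and attach BH q-values.

    Genes with fewer than ``min_variants`` qualifying variants are skipped
    with the reason recorded in the returned log.  When ``annotations`` is
    None every variant qualifies subject to the sample MAF ceiling.
    """
    labels = np.asarray(case_labels)
    by_gene: dict[str, list[int]] = {}
    for j, site in enumerate(gt.sites):
        if annotations is not None:
            ann = annotations.get(site.key)
            if ann is None or not is_qualifying(site, ann, maf_max):
                continue
        else:
            if site_maf(gt.gt[:, j]) >= maf_max:
                continue
        by_gene.setdefault(site.gene, []).append(j)
    results: list[GeneAssocResult] = []
    skipped = []
    for gene in sorted(by_gene):
        idx = by_gene[gene]
        if len(idx) < min_variants:
            skipped.append({"gene": gene, "reason": f"only {len(idx)} qualifying variant(s)"})
            continue
        res = skato(gt.gt[:, idx], labels, rho_grid=rho_grid)
        results.append(GeneAssocResult(gene=gene, n_variants_tested=len(idx), p_skato=res.p_value))
    if results:
        qs = bh_fdr([r.p_skato for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
    return results, pd.DataFrame(skipped, columns=["gene", "reason"])
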