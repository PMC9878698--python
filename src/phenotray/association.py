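"""Single-SNP association scans with and without kinship correction.

Implements the two scan models used for the chilling-tolerance trait: an
ordinary least-squares regression of the (log-transformed) phenotype on SNP
dosage, and an EMMAX-style mixed model in which the variance components of

    y = X beta + u + eps,   u ~ N(0, sigma2_g K),   eps ~ N(0, sigma2_e I)

are estimated once under the null by REML via an eigendecomposition of the
kinship matrix K, after which every SNP is tested by generalized least
squares with that fixed covariance.  Genomic-control diagnostics (lambda_GC
and QQ-plot coordinates) quantify residual inflation from population
structure, and candidate genes are called from scan hits falling in a
gene's exon/intron span or its 2-kb upstream promoter window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

__all__ = [
    "GenotypeMatrix",
    "GeneAnnotation",
    "AssociationResult",
    "maf_filter",
    "lr_scan",
    "kinship_matrix",
    "emmax_scan",
    "genomic_inflation",
    "qq_coordinates",
    "call_candidates",
]

# median of the chi-square distribution with 1 degree of freedom
_CHI2_1_MEDIAN = float(sps.chi2.ppf(0.5, df=1))


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for a panel of accessions.

    ``dosage`` is n_accessions x n_snps with entries 0/1/2 (alt-allele
    count) or NaN for missing calls.  Positions are 1-based and sorted
    within each chromosome.
    """

    samples: list
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        if self.dosage.shape != (len(self.samples), len(self.pos)):
            raise ValueError("dosage shape does not match samples x snps")
        for ch in pd.unique(np.asarray(self.chrom)):
            p = self.pos[np.asarray(self.chrom) == ch]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {ch}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def maf(self) -> np.ndarray:
        """Per-SNP minor allele frequency over non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            freq = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def take_snps(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=self.samples,
            chrom=np.asarray(self.chrom)[index],
            pos=self.pos[index],
            ref=np.asarray(self.ref)[index],
            alt=np.asarray(self.alt)[index],
            dosage=self.dosage[:, index],
        )

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean."""
        d = self.dosage.copy()
        if np.isnan(d).any():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=RuntimeWarning)
                col_mean = np.nanmean(d, axis=0)
            col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
            idx = np.nonzero(np.isnan(d))
            d[idx] = col_mean[idx[1]]
        return d


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene interval, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class AssociationResult:
    """Per-SNP scan output plus the genomic-control factor of the scan."""

    model: str  # "LR" or "EMMAX"
    chrom: np.ndarray
    pos: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    p: np.ndarray
    flagged: np.ndarray  # True where the SNP was untestable (zero variance)
    lambda_gc: float = np.nan
    extra: dict = field(default_factory=dict)

    @property
    def neg_log10_p(self) -> np.ndarray:
        return -np.log10(self.p)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "pos": self.pos,
                "beta": self.beta,
                "se": self.se,
                "p": self.p,
                "nlp": self.neg_log10_p,
                "flagged": self.flagged,
            }
        )


def maf_filter(G: GenotypeMatrix, threshold: float = 0.05) -> GenotypeMatrix:
    """Retain SNPs with minor allele frequency strictly above ``threshold``.

    Monomorphic SNPs (MAF 0) are always dropped.
    """
    if not (0.0 <= threshold < 0.5):
        raise ValueError("threshold must be in [0, 0.5)")
    maf = G.maf()
    keep = np.nan_to_num(maf, nan=0.0) > threshold
    keep &= maf > 0  # explicit monomorphic drop, also when threshold == 0
    return G.take_snps(np.flatnonzero(keep))


def _tiny_floor(p: np.ndarray) -> np.ndarray:
    """Clamp p-values into (0, 1] so -log10 stays finite."""
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _marginal_scans(X: np.ndarray, y: np.ndarray, covariate: np.ndarray):
    """Slope, SE and two-sided t-test p for y ~ covariate + x, per column of X.

    Vectorized across columns; df = n - 2.  Columns with zero residual
    variance after projecting out the covariate are flagged and get p = 1.
    """
    n = y.shape[0]
    c = covariate / np.linalg.norm(covariate)
    yr = y - c * (c @ y)
    Xr = X - np.outer(c, c @ X)
    sxx = np.einsum("ij,ij->j", Xr, Xr)
    flagged = sxx <= n * 1e-24
    sxx_safe = np.where(flagged, 1.0, sxx)
    beta = (Xr.T @ yr) / sxx_safe
    df = n - 2
    ss_res = np.maximum(yr @ yr - beta**2 * sxx_safe, 0.0)
    sigma2 = ss_res / df
    se = np.sqrt(sigma2 / sxx_safe)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    p = np.where(np.isnan(p) & ~flagged, 1.0, p)
    p = np.where(flagged, 1.0, _tiny_floor(p))
    beta = np.where(flagged, 0.0, beta)
    se = np.where(flagged, np.nan, se)
    return beta, se, p, flagged


def lr_scan(G: GenotypeMatrix, y: np.ndarray) -> AssociationResult:
    """Per-SNP ordinary least squares of the phenotype on dosage.

    Fits y = a + b * dosage for every SNP (missing dosages mean-imputed
    per SNP) and tests the slope with a two-sided t-test.  SNPs with zero
    dosage variance after imputation are flagged with p = 1.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != G.n_samples:
        raise ValueError("phenotype length does not match accession count")
    if y.var() == 0:
        raise ValueError("phenotype has zero variance")
    X = G.imputed_dosage()
    beta, se, p, flagged = _marginal_scans(X, y, np.ones_like(y))
    return AssociationResult(
        model="LR",
        chrom=np.asarray(G.chrom),
        pos=G.pos,
        beta=beta,
        se=se,
        p=p,
        flagged=flagged,
        lambda_gc=genomic_inflation(p) if len(p) >= 100 else np.nan,
    )


def kinship_matrix(G: GenotypeMatrix) -> np.ndarray:
    """Centered-and-scaled genomic relationship matrix K = Z Z' / n_snps.

    Columns of Z are dosages centered at 2p and scaled by sqrt(2 p (1-p)),
    the VanRaden standardization; monomorphic SNPs contribute nothing.
    """
    if G.n_snps < 2:
        raise ValueError("need at least 2 SNPs for a kinship estimate")
    d = G.imputed_dosage()
    p = d.mean(axis=0) / 2.0
    scale = np.sqrt(2.0 * p * (1.0 - p))
    ok = scale > 0
    Z = (d[:, ok] - 2.0 * p[ok]) / scale[ok]
    K = Z @ Z.T / Z.shape[1]
    return (K + K.T) / 2.0


def _check_kinship(K: np.ndarray, n: int) -> None:
    K = np.asarray(K, dtype=float)
    if K.shape != (n, n):
        raise ValueError("kinship dimension does not match phenotype length")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix is not symmetric")


def _reml_delta(xi: np.ndarray, eta2: np.ndarray, tol: float = 1e-8):
    """Maximize the EMMA restricted likelihood over delta = sigma2_e/sigma2_g.

    ``xi`` are the non-trivial eigenvalues of the covariate-projected
    kinship matrix and ``eta2`` the squared rotated phenotype.  The search
    runs over log10(delta) in [-10, 10]: a coarse grid locates the basin and
    Brent's method polishes it.
    """
    q = xi.shape[0]

    def neg_restricted_ll(log_delta):
        delta = 10.0**log_delta
        denom = xi + delta
        s = np.sum(eta2 / denom)
        return 0.5 * (q * np.log(s) + np.sum(np.log(denom)))

    grid = np.linspace(-10.0, 10.0, 81)
    vals = np.array([neg_restricted_ll(g) for g in grid])
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        neg_restricted_ll, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    if not res.success:
        raise RuntimeError(f"REML optimization did not converge: {res.message}")
    delta = float(10.0**res.x)
    sigma2_g = float(np.sum(eta2 / (xi + delta)) / q)
    return delta, sigma2_g


def emmax_scan(G: GenotypeMatrix, y: np.ndarray, K: np.ndarray) -> AssociationResult:
    """Kinship-corrected mixed-model scan (EMMAX approximation).

    Variance components are estimated once under the null (intercept-only)
    model by REML using the eigendecomposition of K; every SNP is then
    tested by GLS with the covariance sigma2_g * (K + delta I) held fixed.
    With K = I this collapses to the ordinary regression scan.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if y.var() == 0:
        raise ValueError("phenotype has zero variance")
    K = np.asarray(K, dtype=float)
    _check_kinship(K, n)
    evals, evecs = np.linalg.eigh(K)
    if evals.min() < -1e-8 * max(1.0, evals.max()):
        raise ValueError("kinship matrix is not positive semidefinite")

    # REML on the null model: project out the intercept, rotate by the
    # eigenvectors of the projected kinship.
    ones = np.ones(n) / np.sqrt(n)
    Kc = K - np.outer(ones, ones @ K)
    Kc = Kc - np.outer(Kc @ ones, ones)
    evals_c, evecs_c = np.linalg.eigh((Kc + Kc.T) / 2.0)
    order = np.argsort(evals_c)[::-1]
    xi = np.maximum(evals_c[order][: n - 1], 0.0)
    U = evecs_c[:, order][:, : n - 1]
    eta2 = (U.T @ y) ** 2
    delta, sigma2_g = _reml_delta(xi, eta2)

    # GLS whitening transform from the unprojected eigendecomposition
    w = 1.0 / np.sqrt(np.maximum(evals, 0.0) + delta)
    T = (evecs * w) @ evecs.T  # (K + delta I)^(-1/2)
    y_t = T @ y
    ones_t = T @ np.ones(n)
    X_t = T @ G.imputed_dosage()
    beta, se, p, flagged = _marginal_scans(X_t, y_t, ones_t)
    return AssociationResult(
        model="EMMAX",
        chrom=np.asarray(G.chrom),
        pos=G.pos,
        beta=beta,
        se=se,
        p=p,
        flagged=flagged,
        lambda_gc=genomic_inflation(p) if len(p) >= 100 else np.nan,
        extra={
            "delta": delta,
            "sigma2_g": sigma2_g,
            "sigma2_e": delta * sigma2_g,
            "pseudo_heritability": 1.0 / (1.0 + delta),
        },
    )


def genomic_inflation(pvals) -> float:
    """Genomic-control factor: median observed chi2(1) over its null median."""
    p = np.asarray(pvals, dtype=float)
    if p.size < 100:
        raise ValueError("need at least 100 p-values")
    if np.any(~((p > 0) & (p <= 1))):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def qq_coordinates(pvals) -> pd.DataFrame:
    """Expected vs observed -log10 p for a quantile-quantile plot."""
    p = np.sort(np.asarray(pvals, dtype=float))[::-1]  # largest p first
    n = p.size
    expected = -np.log10((np.arange(n, 0, -1) - 0.5) / n)
    observed = -np.log10(_tiny_floor(p))
    return pd.DataFrame({"expected": expected, "observed": observed})


def call_candidates(
    result: AssociationResult,
    genes,
    threshold_nlp: float = 4.5,
    promoter_bp: int = 2000,
) -> pd.DataFrame:
    """Candidate genes: scan hits inside a gene or its upstream promoter.

    A gene is a candidate iff some SNP with -log10 p >= ``threshold_nlp``
    falls within [start, end] or in the strand-aware promoter window
    ([start - promoter_bp, start - 1] for '+' genes,
    [end + 1, end + promoter_bp] for '-' genes).  Each candidate row
    reports its best (smallest-p) qualifying SNP.
    """
    if threshold_nlp <= 0:
        raise ValueError("threshold_nlp must be positive")
    if promoter_bp < 0:
        raise ValueError("promoter_bp must be non-negative")
    genes = list(genes)
    starts = [(g.chrom, g.start) for g in genes]
    if starts != sorted(starts):
        warnings.warn("gene annotations were unsorted; sorting internally")
        genes = sorted(genes, key=lambda g: (g.chrom, g.start, g.end))

    nlp = result.neg_log10_p
    hits = nlp >= threshold_nlp
    rows = []
    for g in genes:
        if g.strand == "+":
            w_start, w_end = g.start - promoter_bp, g.end
        else:
            w_start, w_end = g.start, g.end + promoter_bp
        sel = (
            hits
            & (np.asarray(result.chrom) == g.chrom)
            & (result.pos >= w_start)
            & (result.pos <= w_end)
        )
        if not np.any(sel):
            continue
        idx = np.flatnonzero(sel)
        best = idx[np.argmax(nlp[idx])]
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "n_hits": int(sel.sum()),
                "best_pos": int(result.pos[best]),
                "best_nlp": float(nlp[best]),
                "best_beta": float(result.beta[best]),
                "model": result.model,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "chrom",
            "start",
            "end",
            "strand",
            "n_hits",
            "best_pos",
            "best_nlp",
            "best_beta",
            "model",
        ],
    )
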