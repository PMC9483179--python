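"""Genotype QC, GRM/PCA and association scans (MLM and FarmCPU-style).

The response in these scans is a DIM-specific EBV from the random-regression
fit (phi(t)' a_hat).  Two methods are provided:

* :class:`MLMScan` — single-marker mixed linear model with a polygenic random
  effect u ~ N(0, G sigma_a2) (G a VanRaden genomic relationship matrix) and
  fixed covariates (intercept + top principal components).  Variance
  components are estimated once under the no-marker null and reused for every
  marker test (the P3D shortcut) via the spectral decomposition of the GRM.

* :class:`FarmCPU` — iterative multi-locus procedure alternating (i) a
  fixed-effect scan testing each marker with the current pseudo-QTNs as
  covariates (markers are never tested against pseudo-QTNs from their own
  genomic bin) and (ii) pseudo-QTN reselection, choosing the bin-size /
  QTN-count combination that maximizes the likelihood of a random-effect
  model whose kinship is built from the candidate QTNs.

Significance classes follow fixed thresholds: genome-wide 5e-8, suggestive
5e-6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix

GENOME_WIDE_P = 5e-8
SUGGESTIVE_P = 5e-6
CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.45493642...


def classify_significance(p: float) -> str:
    """genome_wide (< 5e-8), suggestive (< 5e-6) or ns."""
    if not (0 < p <= 1):
        raise ValueError("p-value must be in (0, 1]")
    if p < GENOME_WIDE_P:
        return "genome_wide"
    if p < SUGGESTIVE_P:
        return "suggestive"
    return "ns"


def genomic_lambda(p_values) -> float:
    """Genomic inflation factor: median chi2(1) quantile over its null median."""
    p = np.asarray(p_values, dtype=float)
    if len(p) < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / CHI2_1_MEDIAN)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy-Weinberg proportions.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts (same parity as observed) that are no more probable
    than the observed one.  Computed with the standard recurrence on the
    conditional distribution of heterozygote counts.
    """
    for v in (n_AA, n_Aa, n_aa):
        if v < 0:
            raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # possible heterozygote counts share the parity of n_rare
    het_min = n_rare % 2
    het_max = n_rare if n_rare <= n else 2 * n - n_rare  # rare allele count cap
    hets = np.arange(het_min, het_max + 1, 2)
    # unnormalized probabilities by recurrence:
    # P(h+2)/P(h) = 4*nAA(h)*naa(h) / ((h+2)*(h+1)) with nAA = (n_rare-h)/2 ...
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i - 1]
        n_r_hom = (n_rare - h) // 2
        n_c_hom = n - n_r_hom - h
        logp[i] = logp[i - 1] + np.log(4.0 * n_r_hom * n_c_hom) - np.log(
            (h + 2.0) * (h + 1.0)
        )
    w = np.exp(logp - logp.max())
    w /= w.sum()
    obs = np.searchsorted(hets, n_Aa)
    return float(min(1.0, w[w <= w[obs] * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC


@dataclass
class QCReport:
    n_samples_in: int = 0
    n_samples_out: int = 0
    n_snps_in: int = 0
    n_snps_out: int = 0
    removed: dict = field(default_factory=dict)

    def to_dict(self):
        return {
            "n_samples_in": self.n_samples_in,
            "n_samples_out": self.n_samples_out,
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "removed": dict(self.removed),
        }


class GenotypeQC(BaseEstimator):
    """Marker/sample quality control as a transformer.

    Removes samples with call rate < ``sample_call_rate`` (0.95), then SNPs
    with call rate < ``snp_call_rate`` (0.90), Hardy-Weinberg exact p below
    ``hwe_p`` (1e-6), or MAF below ``maf`` (0.05).
    """

    def __init__(self, sample_call_rate=0.95, snp_call_rate=0.90,
                 hwe_p=1e-6, maf=0.05):
        self.sample_call_rate = sample_call_rate
        self.snp_call_rate = snp_call_rate
        self.hwe_p = hwe_p
        self.maf = maf

    def fit_transform(self, g: GenotypeMatrix) -> GenotypeMatrix:
        report = QCReport(n_samples_in=g.n_samples, n_snps_in=g.n_variants)
        D = g.dosages
        s_rate = 1.0 - np.isnan(D).mean(axis=1)
        keep_s = s_rate >= self.sample_call_rate
        report.removed["sample_call_rate"] = int((~keep_s).sum())
        if not keep_s.any():
            raise ValueError("all samples removed by call-rate filter")
        g = g.subset(sample_idx=np.flatnonzero(keep_s))
        D = g.dosages

        v_rate = 1.0 - np.isnan(D).mean(axis=0)
        keep_rate = v_rate >= self.snp_call_rate
        freq = np.nanmean(D, axis=0) / 2.0
        maf = np.minimum(freq, 1.0 - freq)
        keep_maf = maf >= self.maf
        hwe_p = np.ones(g.n_variants)
        for j in range(g.n_variants):
            col = D[:, j]
            col = col[~np.isnan(col)]
            if len(col) == 0:
                hwe_p[j] = 0.0
                continue
            n_aa = int((col == 2).sum())
            n_het = int((col == 1).sum())
            n_AA = int((col == 0).sum())
            hwe_p[j] = hwe_exact_test(n_AA, n_het, n_aa)
        keep_hwe = hwe_p >= self.hwe_p
        report.removed["snp_call_rate"] = int((~keep_rate).sum())
        report.removed["hwe"] = int((keep_rate & ~keep_hwe).sum())
        report.removed["maf"] = int((keep_rate & keep_hwe & ~keep_maf).sum())
        keep_v = keep_rate & keep_hwe & keep_maf
        out = g.subset(variant_idx=np.flatnonzero(keep_v))
        report.n_samples_out = out.n_samples
        report.n_snps_out = out.n_variants
        self.report_ = report
        return out

    # alias so the object also composes as fit().transform()
    def fit(self, g: GenotypeMatrix):
        self._fitted_output = self.fit_transform(g)
        return self

    def transform(self, g: GenotypeMatrix) -> GenotypeMatrix:
        if hasattr(self, "_fitted_output"):
            out = self._fitted_output
            del self._fitted_output
            return out
        return self.fit_transform(g)


def genotype_qc(g: GenotypeMatrix, **thresholds):
    qc = GenotypeQC(**thresholds)
    out = qc.fit_transform(g)
    return out, qc.report_


# ---------------------------------------------------------------------------
# GRM / PCA


def _imputed_centered(g: GenotypeMatrix):
    D = g.dosages.copy()
    freq = np.nanmean(D, axis=0) / 2.0
    for j in np.flatnonzero(np.isnan(D).any(axis=0)):
        D[np.isnan(D[:, j]), j] = 2.0 * freq[j]
    return D - 2.0 * freq, freq


def grm_vanraden(g: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 GRM: ZZ' / (2 sum p(1-p)), Z frequency-centered."""
    Z, freq = _imputed_centered(g)
    denom = 2.0 * np.sum(freq * (1.0 - freq))
    if denom <= 0:
        raise ValueError("all markers monomorphic; GRM undefined")
    return (Z @ Z.T) / denom


class GenomicPCA(BaseEstimator):
    """Principal components of the genomic relationship matrix."""

    def __init__(self, n_components=3):
        self.n_components = n_components

    def fit(self, g: GenotypeMatrix):
        K = grm_vanraden(g) if isinstance(g, GenotypeMatrix) else np.asarray(g)
        if self.n_components > K.shape[0]:
            raise ValueError("more components requested than samples")
        w, V = np.linalg.eigh(K)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        self.eigenvalues_ = w
        total = w.clip(min=0).sum()
        self.proportions_ = w.clip(min=0) / total if total > 0 else w * 0
        self.coordinates_ = V[:, : self.n_components]
        self.grm_ = K
        return self

    def transform(self, g=None):
        return self.coordinates_


def pca_from_genotypes(g: GenotypeMatrix, n_components=3):
    """(eigenvalues, sample coordinates, variance proportions) of the GRM."""
    pca = GenomicPCA(n_components=n_components).fit(g)
    return pca.eigenvalues_, pca.coordinates_, pca.proportions_


# ---------------------------------------------------------------------------
# Mixed linear model scan (EMMA-style, P3D)


def _reml_delta_loglik(log_delta, lam, eta2):
    """Profile REML log-likelihood in delta = sigma_e2/sigma_a2 (rotated scale).

    lam: eigenvalues of the rotated GRM; eta2: squared rotated residuals."""
    delta = np.exp(log_delta)
    w = lam + delta
    n = len(lam)
    sigma = np.sum(eta2 / w) / n
    return -0.5 * (n * np.log(sigma) + np.sum(np.log(w)) + n)


def _fit_null_mlm(y, W, K):
    """REML of y = W b + u + e, u ~ N(0, K sigma_a2); returns (delta, sa2, se2, U, lam).

    Uses the eigendecomposition of K projected out of the covariate space."""
    n = len(y)
    # project covariates out: restricted likelihood on an orthonormal basis of
    # the complement of span(W)
    Q, _ = np.linalg.qr(W)
    M = np.eye(n) - Q @ Q.T
    KM = M @ K @ M
    w, U = np.linalg.eigh(KM)
    keep = np.argsort(w)[::-1][: n - W.shape[1]]
    lam = w[keep]
    Ur = U[:, keep]
    eta = Ur.T @ y
    res = optimize.minimize_scalar(
        lambda ld: -_reml_delta_loglik(ld, lam, eta**2),
        bounds=(-12.0, 12.0), method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = res.x
    delta = np.exp(log_delta)
    sa2 = float(np.sum(eta**2 / (lam + delta)) / len(lam))
    se2 = float(sa2 * delta)
    loglik = float(_reml_delta_loglik(log_delta, lam, eta**2))
    return delta, sa2, se2, loglik


@dataclass
class AssocModel:
    """Inputs of an association scan: response, covariates, kinship."""

    y: np.ndarray
    covariates: np.ndarray | None = None  # without intercept
    kinship: np.ndarray | None = None
    pseudo_qtns: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))


def _result_frame(variants, freq, effects, ses, pvals, method):
    cls = np.where(
        pvals < GENOME_WIDE_P, "genome_wide",
        np.where(pvals < SUGGESTIVE_P, "suggestive", "ns"),
    )
    out = variants.copy().reset_index(drop=True)
    out["maf"] = np.minimum(freq, 1 - freq)
    out["effect"] = effects
    out["se"] = ses
    out["p"] = pvals
    out["method"] = method
    out["class"] = cls
    return out


class MLMScan(BaseEstimator):
    """Single-marker mixed-model association scan with P3D variance reuse."""

    def __init__(self, n_pcs=3, p3d=True):
        self.n_pcs = n_pcs
        self.p3d = p3d

    def fit(self, g: GenotypeMatrix, y, covariates=None, kinship=None):
        y = np.asarray(y, dtype=float)
        if np.ptp(y) == 0:
            raise ValueError("response is constant")
        n = len(y)
        if n != g.n_samples:
            raise ValueError("response length != number of samples")
        K = grm_vanraden(g) if kinship is None else np.asarray(kinship)
        if covariates is None and self.n_pcs > 0:
            w, V = np.linalg.eigh(K)
            covariates = V[:, np.argsort(w)[::-1][: self.n_pcs]]
        W = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), covariates]
        )
        delta, sa2, se2, _ = _fit_null_mlm(y, W, K)
        self.delta_ = delta
        self.sigma_a2_ = sa2
        self.sigma_e2_ = se2

        # spectral rotation of the full model: V = sa2 (K + delta I)
        wK, U = np.linalg.eigh(K)
        weights = 1.0 / (wK + delta)  # inverse variance up to sa2
        yt = U.T @ y
        Wt = U.T @ W
        Z, freq = _imputed_centered(g)
        Mt = U.T @ (Z + 2.0 * freq)  # rotated raw dosages
        effects, ses, pvals = _gls_scan(yt, Wt, Mt, weights)
        self.results_ = _result_frame(g.variants, freq, effects, ses, pvals, "mlm")
        return self


def _gls_scan(yt, Wt, Mt, weights):
    """Per-marker GLS t-tests in a rotated (whitened) coordinate system.

    yt, Wt, Mt: rotated response, covariates, markers; weights: inverse
    eigen-variances.  Returns effect, SE and p per marker column of Mt.
    """
    n, p = Wt.shape
    sw = np.sqrt(weights)
    yw = yt * sw
    Ww = Wt * sw[:, None]
    Mw = Mt * sw[:, None]
    # residualize markers and response on covariates under the weighted metric
    WtWi = np.linalg.pinv(Ww.T @ Ww)
    H = WtWi @ (Ww.T @ Mw)
    Mr = Mw - Ww @ H
    yr = yw - Ww @ (WtWi @ (Ww.T @ yw))
    mm = np.einsum("ij,ij->j", Mr, Mr)
    my = Mr.T @ yr
    ok = mm > 1e-12
    effects = np.full(Mt.shape[1], np.nan)
    ses = np.full(Mt.shape[1], np.nan)
    pvals = np.ones(Mt.shape[1])
    df = n - p - 1
    effects[ok] = my[ok] / mm[ok]
    rss0 = float(yr @ yr)
    rss = rss0 - effects[ok] ** 2 * mm[ok]
    rss = np.maximum(rss, 1e-300)
    sigma2 = rss / df
    ses[ok] = np.sqrt(sigma2 / mm[ok])
    tstat = effects[ok] / ses[ok]
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return effects, ses, pvals


def mlm_scan(g: GenotypeMatrix, y, covariates=None, kinship=None, n_pcs=3):
    m = MLMScan(n_pcs=n_pcs).fit(g, y, covariates=covariates, kinship=kinship)
    return m.results_


# ---------------------------------------------------------------------------
# FarmCPU


class FarmCPU(BaseEstimator):
    """Iterative multi-locus scan with pseudo-QTN covariates.

    Parameters follow the published defaults of the method: candidate bin
    sizes {5e5, 5e6, 5e7} bp, up to n/10 pseudo-QTNs, a 0.01 screening
    threshold for QTN candidacy, at most 10 iterations.
    """

    def __init__(self, n_pcs=3, bin_sizes=(5e5, 5e6, 5e7),
                 qtn_counts=(2, 4, 8, 16, 32), screen_p=0.01, max_iter=10):
        self.n_pcs = n_pcs
        self.bin_sizes = bin_sizes
        self.qtn_counts = qtn_counts
        self.screen_p = screen_p
        self.max_iter = max_iter

    def fit(self, g: GenotypeMatrix, y, covariates=None):
        y = np.asarray(y, dtype=float)
        n, m = g.n_samples, g.n_variants
        if np.ptp(y) == 0:
            raise ValueError("response is constant")
        Z, freq = _imputed_centered(g)
        M = Z + 2.0 * freq
        if covariates is None and self.n_pcs > 0:
            covariates = GenomicPCA(n_components=self.n_pcs).fit(g).coordinates_
        W0 = np.ones((n, 1)) if covariates is None else np.column_stack(
            [np.ones(n), covariates]
        )
        chrom_codes = pd.Categorical(g.variants["chrom"]).codes.astype(np.int64)
        pos = g.variants["pos"].to_numpy(dtype=np.int64)

        qtns = np.array([], dtype=int)
        seen: list = []
        pvals = None
        for it in range(self.max_iter):
            effects, ses, pvals = self._scan(y, W0, M, qtns, chrom_codes, pos)
            new_qtns = self._select_qtns(y, W0, M, pvals, chrom_codes, pos, g)
            if it == 0 and len(new_qtns) == 0:
                warnings.warn(
                    "no marker passed the pseudo-QTN screen; "
                    "returning covariate-only scan results"
                )
                break
            key = tuple(sorted(new_qtns))
            if key in seen:
                qtns = np.array(sorted(new_qtns), dtype=int)
                effects, ses, pvals = self._scan(y, W0, M, qtns, chrom_codes, pos)
                break
            seen.append(key)
            qtns = np.array(sorted(new_qtns), dtype=int)
        self.pseudo_qtns_ = qtns
        self.results_ = _result_frame(g.variants, freq, effects, ses, pvals, "farmcpu")
        return self

    def _scan(self, y, W0, M, qtns, chrom_codes, pos):
        """Fixed-effect scan with pseudo-QTN covariates; markers sharing a bin
        with a pseudo-QTN are tested with that QTN left out."""
        n, m = M.shape
        ones = np.ones(n)
        if len(qtns) == 0:
            W = W0
            return _gls_scan(y, W, M, np.ones(n))
        W = np.column_stack([W0, M[:, qtns]])
        effects, ses, pvals = _gls_scan(y, W, M, np.ones(n))
        # leave-own-bin-out for markers in a pseudo-QTN's bin (smallest bin size)
        bs = int(min(self.bin_sizes))
        bins_q = {(chrom_codes[q], pos[q] // bs): i for i, q in enumerate(qtns)}
        marker_bins = list(zip(chrom_codes, pos // bs))
        redo = [j for j, b in enumerate(marker_bins) if b in bins_q]
        for j in redo:
            drop = bins_q[marker_bins[j]]
            keep = [i for i in range(len(qtns)) if i != drop]
            Wj = np.column_stack([W0, M[:, qtns[keep]]]) if keep else W0
            e, s, p = _gls_scan(y, Wj, M[:, [j]], np.ones(n))
            effects[j], ses[j], pvals[j] = e[0], s[0], p[0]
        return effects, ses, pvals

    def _select_qtns(self, y, W0, M, pvals, chrom_codes, pos, g):
        """Rank markers by p within bins; pick the (bin size, count) combo
        maximizing the random-model likelihood with QTN-derived kinship."""
        n = len(y)
        order = np.argsort(pvals, kind="stable")
        if pvals[order[0]] > self.screen_p:
            return np.array([], dtype=int)
        best = (-np.inf, None)
        max_qtn = max(2, n // 10)
        for bs in self.bin_sizes:
            bs = int(bs)
            reps = []
            used = set()
            for j in order:
                b = (chrom_codes[j], pos[j] // bs)
                if b in used or pvals[j] > self.screen_p:
                    continue
                used.add(b)
                reps.append(j)
                if len(reps) >= min(max_qtn, max(self.qtn_counts)):
                    break
            for t in self.qtn_counts:
                if t > len(reps) or t > max_qtn:
                    continue
                cand = np.array(reps[:t], dtype=int)
                ll = self._random_model_loglik(y, W0, M[:, cand])
                if ll > best[0]:
                    best = (ll, cand)
        return best[1] if best[1] is not None else np.array([], dtype=int)

    @staticmethod
    def _random_model_loglik(y, W0, Mq):
        """REML log-likelihood of y = u + e with kinship from the QTN set
        (factor 2 absorbed into the scale of sigma_u2)."""
        p = Mq - Mq.mean(axis=0)
        denom = max(np.sum(np.var(Mq, axis=0)) / 2.0, 1e-12)
        K = 2.0 * (p @ p.T) / (2.0 * denom)
        _, _, _, ll = _fit_null_mlm(y, W0, K)
        return ll


def farmcpu_scan(g: GenotypeMatrix, y, covariates=None, **opts):
    f = FarmCPU(**opts).fit(g, y, covariates=covariates)
    return f.results_
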