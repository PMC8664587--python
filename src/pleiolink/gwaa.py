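"""Association mapping on simulated samples.

The mapping stage takes a sample of individuals with biallelic marker
genotypes (neutral SNPs and, in QTN mode, the causal variants themselves)
and two phenotypes, and provides:

* a centered genetic relatedness matrix (GRM) from MAF-filtered markers;
* univariate scans: per-marker simple linear regression on one trait with
  Benjamini-Hochberg adjustment at a target FDR;
* a multivariate scan: a two-trait linear mixed model with a random
  polygenic effect (covariance K x Vg plus residual I x Ve). Vg and Ve are
  estimated once under the no-marker null by REML via the eigendecomposition
  of K, then held fixed while each marker is tested with a 2-df likelihood
  ratio; Storey q-values determine significance;
* truth-based discovery metrics: the proportion of segregating causal loci
  with a significant marker within a map-distance window, spurious- and
  missed-pleiotropy rates for QTN scans, and LD between significant SNPs
  and the nearest causal locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .genome import ArchitectureSpec, Role
from .popstats import multiallelic_r2

__all__ = [
    "GenotypeSample",
    "ScanResult",
    "DiscoveryReport",
    "build_sample_from_population",
    "compute_grm",
    "univariate_scan",
    "multivariate_scan",
    "storey_qvalues",
    "discovery_metrics",
]


@dataclass
class GenotypeSample:
    """Genotype/phenotype sample plus the truth table of causal loci.

    genotypes : (n, M) minor-allele dosages (0/1/2) of scannable markers.
    marker_map : per-marker chromosome, cM position, and role.
    truth : all causal loci with roles and a flag for whether they
        segregate *in this sample* (discovery-rate denominators).
    marker_haps / qtl_values : optional haplotype-level data enabling
        multiallelic LD against continuum-of-alleles QTL.
    """

    genotypes: np.ndarray
    phenotypes: np.ndarray
    marker_map: pd.DataFrame
    truth: pd.DataFrame
    marker_haps: np.ndarray | None = None
    qtl_values: np.ndarray | None = None
    qtl_map: pd.DataFrame | None = None

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def maf(self) -> np.ndarray:
        f = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class ScanResult:
    """Per-marker association results for one scan."""

    table: pd.DataFrame  # marker, chrom, cM, role, maf, beta1, beta2, stat, p, q, significant, reason
    kind: str  # "univariate" or "multivariate"
    fdr: float
    trait: int | None = None
    vg: np.ndarray | None = None
    ve: np.ndarray | None = None

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].astype(bool)]


@dataclass
class DiscoveryReport:
    """Truth-based detection metrics; fields are None when not applicable."""

    n_truth_segregating: int
    dr: float | None = None
    dr_pleio: float | None = None
    dr_single: float | None = None
    fpr: float | None = None
    fnr: float | None = None
    snp_sig: float | None = None
    snp_pleio: float | None = None
    mean_r2: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


# ---------------------------------------------------------------------------
# sample construction


def build_sample_from_population(pop, arch: ArchitectureSpec, idx) -> GenotypeSample:
    """Extract a GenotypeSample for individuals ``idx`` of a Population.

    Scannable markers are the neutral SNPs plus (in QTN mode) the causal
    biallelic variants; continuum-of-alleles QTL are not representable as
    SNPs and enter only the truth table (and the haplotype-level arrays
    used for LD). Dosages count the minor allele in the sample, ties at
    frequency 0.5 resolved toward the 1-labelled state.
    """
    idx = np.asarray(idx)
    n = idx.shape[0]
    causal_roles = arch.roles[arch.causal_idx]
    is_qtn = np.isin(causal_roles, Role.QTN)

    states_list, rows = [], []
    if arch.n_neutral:
        neu = pop.markers[idx]  # (n, 2, Lm)
        states_list.append(neu.astype(np.int8))
        for j, li in enumerate(arch.neutral_idx):
            l = arch.loci[li]
            rows.append((f"L{l.id}", l.chromosome, l.position_cM, l.role))
    if is_qtn.any():
        sub = pop.values[idx][:, :, is_qtn, :]  # (n, 2, Lq, 2)
        # allele state of a QTN = sign of its effect on its (first) trait
        eff = np.where(np.abs(sub[..., 0]) > 0, sub[..., 0], sub[..., 1])
        states_list.append((eff > 0).astype(np.int8))
        for li in arch.causal_idx[is_qtn]:
            l = arch.loci[li]
            rows.append((f"L{l.id}", l.chromosome, l.position_cM, l.role))
    if states_list:
        haps = np.concatenate(states_list, axis=2)  # (n, 2, M)
    else:  # continuum-only architecture: phenotypes + truth, no scan matrix
        haps = np.empty((n, 2, 0), dtype=np.int8)
    marker_map = pd.DataFrame(rows, columns=["marker", "chrom", "cM", "role"])
    order = np.lexsort((marker_map["cM"].to_numpy(), marker_map["chrom"].to_numpy()))
    haps = haps[:, :, order]
    marker_map = marker_map.iloc[order].reset_index(drop=True)

    freq1 = haps.mean(axis=(0, 1))
    minor_is_one = freq1 <= 0.5  # tie at 0.5 -> allele "1" is the minor allele
    dosage = haps.sum(axis=1).astype(np.int8)
    dosage = np.where(minor_is_one, dosage, 2 - dosage).astype(np.int8)

    # truth table with in-sample segregation flags
    vals = pop.values[idx]
    seg = (
        np.any(vals != vals[0, 0][None, None, :, :], axis=(0, 1, 3))
        if arch.n_causal
        else np.zeros(0, dtype=bool)
    )
    truth = pd.DataFrame(
        {
            "id": [f"L{arch.loci[li].id}" for li in arch.causal_idx],
            "chrom": [arch.loci[li].chromosome for li in arch.causal_idx],
            "cM": [arch.loci[li].position_cM for li in arch.causal_idx],
            "role": list(causal_roles),
            "segregating": seg,
        }
    )
    qtl_map = truth[["id", "chrom", "cM", "role"]].copy()
    return GenotypeSample(
        genotypes=dosage,
        phenotypes=pop.phenotypes[idx].copy(),
        marker_map=marker_map,
        truth=truth,
        marker_haps=haps,
        qtl_values=vals,
        qtl_map=qtl_map,
    )


# ---------------------------------------------------------------------------
# GRM


def compute_grm(G: np.ndarray, maf: float = 0.001) -> np.ndarray:
    """Centered genetic relatedness matrix K = (1/M) sum_m (g_m - gbar)(...)^T.

    Columns are centered but not variance-standardized. Markers below the
    MAF threshold are excluded.
    """
    G = np.asarray(G, dtype=float)
    f = G.mean(axis=0) / 2.0
    use = np.minimum(f, 1 - f) >= maf
    if not use.any():
        raise ValueError("no markers pass the MAF filter")
    X = G[:, use] - G[:, use].mean(axis=0)
    return X @ X.T / use.sum()


# ---------------------------------------------------------------------------
# scans


def _degenerate_trait(y: np.ndarray) -> bool:
    """True when a trait is (numerically) monomorphic.

    Identical phenotypes can leave a residual variance of order machine
    epsilon squared (rounding of the mean), so the test is scale-relative
    rather than an exact zero comparison.
    """
    return float(np.var(y)) <= 1e-12 * (1.0 + float(np.mean(y)) ** 2)


def univariate_scan(
    sample: GenotypeSample, trait: int, fdr: float = 0.1, maf: float = 0.001
) -> ScanResult:
    """Simple linear regression of one trait on each marker, BH-adjusted.

    Markers below the MAF threshold are skipped with a recorded reason and
    do not enter the multiple-testing family.
    """
    if trait not in (1, 2):
        raise ValueError("trait must be 1 or 2")
    y = sample.phenotypes[:, trait - 1].astype(float)
    if _degenerate_trait(y):  # monomorphic trait: nothing to regress on
        tab = sample.marker_map.copy()
        tab["maf"] = sample.maf()
        for c in ("beta1", "beta2", "stat", "p", "q"):
            tab[c] = np.nan
        tab["significant"] = False
        tab["reason"] = "trait_variance_zero"
        return ScanResult(tab, "univariate", fdr, trait=trait)
    G = sample.genotypes.astype(float)
    n, M = G.shape
    mafs = sample.maf()
    use = mafs >= maf

    tab = sample.marker_map.copy()
    tab["maf"] = mafs
    tab["beta1"] = np.nan
    tab["beta2"] = np.nan
    tab["stat"] = np.nan
    tab["p"] = np.nan
    tab["q"] = np.nan
    tab["significant"] = False
    tab["reason"] = np.where(use, "", "maf_below_threshold")

    if use.any():
        X = G[:, use]
        xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sxx = (xc**2).sum(axis=0)
        sxy = (xc * yc[:, None]).sum(axis=0)
        beta = sxy / sxx
        syy = float((yc**2).sum())
        r2 = np.clip(sxy**2 / (sxx * syy), 0.0, 1.0) if syy > 0 else np.zeros_like(sxx)
        with np.errstate(divide="ignore"):
            tstat = np.sign(beta) * np.sqrt(r2 * (n - 2) / np.maximum(1.0 - r2, 1e-300))
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        reject, p_adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
        cols = np.flatnonzero(use)
        tab.loc[cols, "beta1" if trait == 1 else "beta2"] = beta
        tab.loc[cols, "stat"] = tstat
        tab.loc[cols, "p"] = p
        tab.loc[cols, "q"] = p_adj
        tab.loc[cols, "significant"] = reject & (p_adj <= fdr)
    return ScanResult(tab, "univariate", fdr, trait=trait)


# ---------------------------------------------------------------------------
# multivariate mixed-model scan


def _pack_chol(V: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(V + 1e-10 * np.eye(2))
    return np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])


def _unpack_chol(p: np.ndarray) -> np.ndarray:
    L = np.array([[np.exp(p[0]), 0.0], [p[1], np.exp(p[2])]])
    return L @ L.T


def _reml_neg_loglik(params, d, Yt, xt):
    Vg = _unpack_chol(params[:3])
    Ve = _unpack_chol(params[3:])
    # per-individual 2x2 covariance d_i * Vg + Ve, inverted in closed form
    S = d[:, None, None] * Vg + Ve
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
    if np.any(det <= 0) or np.any(S[:, 0, 0] <= 0):
        return 1e12
    W = np.empty_like(S)
    W[:, 0, 0] = S[:, 1, 1]
    W[:, 1, 1] = S[:, 0, 0]
    W[:, 0, 1] = W[:, 1, 0] = -S[:, 0, 1]
    W /= det[:, None, None]
    A = np.einsum("i,iab->ab", xt**2, W)
    b = np.einsum("i,iab,ib->a", xt, W, Yt)
    sign, logdetA = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e12
    mu = np.linalg.solve(A, b)
    resid = Yt - xt[:, None] * mu
    quad = np.einsum("ia,iab,ib->", resid, W, resid)
    return 0.5 * (np.log(det).sum() + quad + logdetA)


def fit_null_mvlmm(Y: np.ndarray, K: np.ndarray):
    """REML fit of the no-marker bivariate mixed model via eigen(K).

    Returns (Vg, Ve, U, d, converged): 2x2 genetic and residual covariance
    components, the eigenvectors/values of K, and the optimizer status.
    """
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    K = np.asarray(K, dtype=float)
    d, U = np.linalg.eigh((K + K.T) / 2.0)
    if d.min() < -1e-6 * max(d.max(), 1.0):
        raise ValueError("kinship matrix is not positive semidefinite")
    d = np.clip(d, 0.0, None)
    Yt = U.T @ Y
    xt = U.T @ np.ones(n)
    S = np.cov(Y.T)
    x0 = np.concatenate([_pack_chol(S / 2.0 / max(d.mean(), 1e-8)), _pack_chol(S / 2.0)])
    res = optimize.minimize(
        _reml_neg_loglik,
        x0,
        args=(d, Yt, xt),
        method="Nelder-Mead",
        options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10},
    )
    Vg = _unpack_chol(res.x[:3])
    Ve = _unpack_chol(res.x[3:])
    return Vg, Ve, U, d, bool(res.success)


def multivariate_scan(
    sample: GenotypeSample,
    K: np.ndarray,
    fdr: float = 0.1,
    maf: float = 0.001,
) -> ScanResult:
    """Two-trait mixed-model likelihood-ratio scan with Storey q-values.

    The null variance components (Vg, Ve) are fitted once by REML and held
    fixed; each marker adds a fixed effect on both traits and is tested by
    a generalized-least-squares likelihood ratio on 2 df.
    """
    Y = sample.phenotypes.astype(float)
    G = sample.genotypes.astype(float)
    n = Y.shape[0]
    mafs = sample.maf()
    use = mafs >= maf

    tab = sample.marker_map.copy()
    tab["maf"] = mafs
    for c in ("beta1", "beta2", "stat", "p", "q"):
        tab[c] = np.nan
    tab["significant"] = False
    tab["reason"] = np.where(use, "", "maf_below_threshold")
    if not use.any():
        return ScanResult(tab, "multivariate", fdr)
    if any(_degenerate_trait(Y[:, t]) for t in (0, 1)):  # monomorphic trait
        tab["reason"] = "trait_variance_zero"
        return ScanResult(tab, "multivariate", fdr)

    Vg, Ve, U, d, converged = fit_null_mvlmm(Y, K)
    Yt = U.T @ Y
    xt = U.T @ np.ones(n)
    Gt = U.T @ G[:, use]

    S = d[:, None, None] * Vg + Ve
    det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
    W = np.empty_like(S)
    W[:, 0, 0] = S[:, 1, 1]
    W[:, 1, 1] = S[:, 0, 0]
    W[:, 0, 1] = W[:, 1, 0] = -S[:, 0, 1]
    W /= det[:, None, None]

    wy = np.einsum("iab,ib->ia", W, Yt)  # (n, 2)
    A_xx = np.einsum("i,iab->ab", xt**2, W)  # 2x2
    b_x = np.einsum("i,ia->a", xt, wy)  # 2
    # null GLS: intercept only
    mu0 = np.linalg.solve(A_xx, b_x)
    q_null = float(np.einsum("ia,ia->", Yt, wy) - b_x @ mu0)

    A_xg = np.einsum("i,im,iab->mab", xt, Gt, W)  # (M, 2, 2)
    A_gg = np.einsum("im,iab->mab", Gt**2, W)  # (M, 2, 2)
    b_g = np.einsum("im,ia->ma", Gt, wy)  # (M, 2)

    M_use = Gt.shape[1]
    A4 = np.zeros((M_use, 4, 4))
    A4[:, :2, :2] = A_xx
    A4[:, :2, 2:] = A_xg
    A4[:, 2:, :2] = np.swapaxes(A_xg, 1, 2)
    A4[:, 2:, 2:] = A_gg
    b4 = np.concatenate([np.broadcast_to(b_x, (M_use, 2)), b_g], axis=1)
    coef = np.linalg.solve(A4, b4[:, :, None])[:, :, 0]  # (M, 4)
    q_alt = np.einsum("ia,ia->", Yt, wy) - np.einsum("mk,mk->m", b4, coef)
    lrt = np.clip(q_null - q_alt, 0.0, None)
    p = stats.chi2.sf(lrt, df=2)
    q = storey_qvalues(p)

    cols = np.flatnonzero(use)
    tab.loc[cols, "beta1"] = coef[:, 2]
    tab.loc[cols, "beta2"] = coef[:, 3]
    tab.loc[cols, "stat"] = lrt
    tab.loc[cols, "p"] = p
    tab.loc[cols, "q"] = q
    tab.loc[cols, "significant"] = q <= fdr
    return ScanResult(tab, "multivariate", fdr, vg=Vg, ve=Ve)


# ---------------------------------------------------------------------------
# q-values


def storey_qvalues(pvalues, pi0: float | None = None) -> np.ndarray:
    """Storey q-values with the cubic-smoother pi0 estimate.

    pi0 is estimated on the lambda grid 0.05, 0.10, ..., 0.95 by fitting a
    cubic polynomial to pi0(lambda) and evaluating it at the largest lambda,
    clamped into (0, 1]; pass ``pi0`` explicitly to override (pi0=1
    reproduces Benjamini-Hochberg adjusted p-values exactly).
    q_i = min_{p_j >= p_i} pi0 * m * p_j / rank_j.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        lam = np.arange(0.05, 0.96, 0.05)
        pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
        if m < 100 or np.all(pi0_lam == pi0_lam[0]):
            pi0 = min(1.0, float(pi0_lam[-1]))
        else:
            coef = np.polyfit(lam, pi0_lam, 3)
            pi0 = float(np.polyval(coef, lam.max()))
    pi0 = min(max(pi0, 1.0 / m), 1.0)
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(qv, 1.0)
    return q


# ---------------------------------------------------------------------------
# discovery metrics


def _in_window(truth_row, sig_table, window_cM):
    hits = sig_table[
        (sig_table["chrom"] == truth_row["chrom"])
        & ((sig_table["cM"] - truth_row["cM"]).abs() <= window_cM)
    ]
    return len(hits) > 0


def _nearest_seg_causal(marker_row, truth_seg):
    cand = truth_seg[truth_seg["chrom"] == marker_row["chrom"]]
    if cand.empty:
        return None
    return (cand["cM"] - marker_row["cM"]).abs().idxmin()


def _mean_r2_significant(sig_markers: pd.DataFrame, sample: GenotypeSample, truth_seg):
    """Mean multiallelic r^2 of significant SNPs with their nearest
    segregating causal locus (nearest in cM on the same chromosome)."""
    if sample.marker_haps is None or sample.qtl_values is None or truth_seg.empty:
        return None
    marker_pos = {m: j for j, m in enumerate(sample.marker_map["marker"])}
    qtl_pos = {qid: j for j, qid in enumerate(sample.truth["id"])}
    vals = []
    for _, row in sig_markers.iterrows():
        t_idx = _nearest_seg_causal(row, truth_seg)
        if t_idx is None:
            continue
        snp_h = sample.marker_haps[:, :, marker_pos[row["marker"]]].reshape(-1)
        qcol = qtl_pos[truth_seg.loc[t_idx, "id"]]
        qtl_h = sample.qtl_values[:, :, qcol, :].reshape(-1, 2)
        vals.append(multiallelic_r2(snp_h, qtl_h))
    return float(np.mean(vals)) if vals else None


def discovery_metrics(
    scans,
    truth: pd.DataFrame,
    window_cM: float = 0.05,
    sample: GenotypeSample | None = None,
) -> DiscoveryReport:
    """Score scans against the truth table of causal loci.

    ``scans`` is a single multivariate ScanResult or a pair of univariate
    ScanResults (one per trait). A segregating causal locus is *discovered*
    when at least one significant marker lies on the same chromosome within
    ``window_cM`` on either side. For univariate pairs, pleiotropy requires
    discovery in both scans; for QTN genotype scans, the spurious-pleiotropy
    FPR is the fraction of segregating nonpleiotropic QTNs whose own
    genotype is significant for both traits, and the FNR the fraction of
    segregating pleiotropic QTNs that are not.
    """
    if truth.empty:
        raise ValueError("empty truth table")
    truth_seg = truth[truth["segregating"]]
    n_seg = len(truth_seg)
    report = DiscoveryReport(n_truth_segregating=n_seg)

    if isinstance(scans, ScanResult):
        if scans.kind != "multivariate":
            raise ValueError("a single scan must be multivariate")
        sig = scans.significant
        report.snp_sig = float(len(sig))
        report.snp_pleio = float(len(sig))  # joint test => associated with both
        if n_seg:
            report.dr = float(
                np.mean([_in_window(r, sig, window_cM) for _, r in truth_seg.iterrows()])
            )
        if sample is not None:
            report.mean_r2 = _mean_r2_significant(sig, sample, truth_seg)
        return report

    scan1, scan2 = scans
    if {scan1.trait, scan2.trait} != {1, 2}:
        raise ValueError("univariate pair must cover traits 1 and 2")
    sig1, sig2 = scan1.significant, scan2.significant
    both = set(sig1["marker"]) & set(sig2["marker"])
    report.snp_sig = 0.5 * (len(sig1) + len(sig2))
    report.snp_pleio = float(len(both))
    if n_seg:
        hit1 = np.array([_in_window(r, sig1, window_cM) for _, r in truth_seg.iterrows()])
        hit2 = np.array([_in_window(r, sig2, window_cM) for _, r in truth_seg.iterrows()])
        report.dr_pleio = float((hit1 & hit2).mean())
        report.dr_single = float(0.5 * (hit1.mean() + hit2.mean()))

    # QTN own-genotype pleiotropy rates
    qtn_roles = set(Role.QTN)
    tab1 = scan1.table.set_index("marker")
    tab2 = scan2.table.set_index("marker")
    qtn_seg = truth_seg[truth_seg["role"].isin(qtn_roles)]
    if not qtn_seg.empty:
        sig_both = []
        for qid in qtn_seg["id"]:
            s1 = qid in tab1.index and bool(tab1.loc[qid, "significant"])
            s2 = qid in tab2.index and bool(tab2.loc[qid, "significant"])
            sig_both.append(s1 and s2)
        sig_both = np.array(sig_both)
        is_pleio = qtn_seg["role"].isin(Role.PLEIO).to_numpy()
        if (~is_pleio).any():
            report.fpr = float(sig_both[~is_pleio].mean())
        if is_pleio.any():
            report.fnr = float((~sig_both[is_pleio]).mean())

    if sample is not None:
        union = pd.concat([sig1, sig2]).drop_duplicates(subset="marker")
        report.mean_r2 = _mean_r2_significant(union, sample, truth_seg)
    return report
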