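"""Population and sample statistics: G-matrix, covariance decomposition,
multiallelic LD r-squared, allelic kurtosis, segregating counts.

With no environmental effects on the traits, phenotypic (co)variances are
genetic (co)variances, so the G-matrix is estimated directly from the
phenotypes. The cross-trait genetic covariance decomposes into a *genic*
part (within-gamete, locus-by-locus covariance of allelic effects — nonzero
only with pleiotropy) and a *linkage-disequilibrium* part (between-locus,
within-gamete); the two sum exactly to the gametic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import ArchitectureSpec, Role

__all__ = [
    "GMatrixEstimate",
    "g_matrix",
    "genic_vs_gametic_covariance",
    "multiallelic_r2",
    "allelic_kurtosis",
    "segregating_counts",
]


@dataclass(frozen=True)
class GMatrixEstimate:
    var1: float
    var2: float
    cov: float
    gcor: float
    n_individuals: int
    degenerate: bool = False  # gcor forced to 0 because a variance is 0

    @property
    def matrix(self) -> np.ndarray:
        return np.array([[self.var1, self.cov], [self.cov, self.var2]])


def g_matrix(phenotypes) -> GMatrixEstimate:
    """Genetic (co)variances of breeding values from an (n, 2) phenotype set.

    Accepts a Population (uses its phenotypes) or an array. Sample
    covariance with denominator n-1; the genetic correlation is flagged and
    reported as 0 when either variance is 0 (e.g. a monomorphic population).
    """
    z = np.asarray(getattr(phenotypes, "phenotypes", phenotypes), dtype=float)
    if z.ndim != 2 or z.shape[1] != 2 or z.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) phenotype array")
    var = z.var(axis=0, ddof=1)
    cov = float(((z[:, 0] - z[:, 0].mean()) * (z[:, 1] - z[:, 1].mean())).sum()
                / (z.shape[0] - 1))
    denom = np.sqrt(var[0] * var[1])
    degenerate = not denom > 0
    gcor = 0.0 if degenerate else float(np.clip(cov / denom, -1.0, 1.0))
    return GMatrixEstimate(float(var[0]), float(var[1]), cov, gcor, z.shape[0], degenerate)


def genic_vs_gametic_covariance(pop, arch: ArchitectureSpec | None = None):
    """Decompose the cross-trait covariance of haplotype effects.

    Returns ``(gametic_cov, genic_cov, ld_cov)`` over the 2N haplotypes:
    gametic = cov(sum of trait-1 effects, sum of trait-2 effects);
    genic = sum over loci of that locus's own cross-trait covariance;
    ld = gametic - genic. Total phenotypic genetic covariance equals
    2 * gametic under random union of gametes.
    """
    values = getattr(pop, "values", pop)  # (N, 2, Lc, 2)
    if arch is not None and values.shape[2] != arch.n_causal:
        raise ValueError("haplotype array does not match architecture")
    v = np.asarray(values, dtype=float).reshape(-1, values.shape[2], 2)  # (2N, Lc, 2)
    h = v.sum(axis=1)  # (2N, 2)
    n = h.shape[0]
    hc = h - h.mean(axis=0)
    gametic = float((hc[:, 0] * hc[:, 1]).sum() / (n - 1))
    vc = v - v.mean(axis=0)
    genic = float((vc[:, :, 0] * vc[:, :, 1]).sum() / (n - 1))
    return gametic, genic, gametic - genic


def _allele_codes(haps: np.ndarray) -> np.ndarray:
    """Map haplotype states at one locus to integer allele labels.

    States may be scalars (marker 0/1, QTN sign) or rows (continuum locus
    effect vectors); two copies carry the same allele iff bit-identical.
    """
    h = np.asarray(haps)
    if h.ndim == 1:
        h = h[:, None]
    _, codes = np.unique(h, axis=0, return_inverse=True)
    return codes


def multiallelic_r2(locusA, locusB) -> float:
    """Multiallelic LD r^2 between two loci over aligned haplotypes.

    r^2 = sum_ij D_ij^2 / [(1 - sum_i p_i^2)(1 - sum_j q_j^2)] with
    D_ij = f(haplotype ij) - p_i q_j. Reduces to the squared Pearson
    correlation of allele indicators for diallelic loci; returns 0 when
    either locus is monomorphic (undefined, flagged as 0).
    """
    a = _allele_codes(locusA)
    b = _allele_codes(locusB)
    if a.shape[0] != b.shape[0]:
        raise ValueError("haplotype arrays differ in length")
    n = a.shape[0]
    ka, kb = a.max() + 1, b.max() + 1
    if ka < 2 or kb < 2:
        return 0.0
    joint = np.zeros((ka, kb))
    np.add.at(joint, (a, b), 1.0)
    joint /= n
    p = joint.sum(axis=1)
    q = joint.sum(axis=0)
    D = joint - np.outer(p, q)
    denom = (1.0 - (p**2).sum()) * (1.0 - (q**2).sum())
    return float((D**2).sum() / denom)


def allelic_kurtosis(values, weights=None) -> float:
    """Frequency-weighted excess kurtosis of allelic values at one locus.

    Population-moment formula m4/m2^2 - 3 with no small-sample correction.
    Raises on degenerate (zero-variance) distributions.
    """
    x = np.asarray(values, dtype=float)
    if weights is None:
        w = np.full(x.shape[0], 1.0 / x.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    mean = float((w * x).sum())
    m2 = float((w * (x - mean) ** 2).sum())
    if m2 == 0.0:
        raise ValueError("degenerate allelic distribution (zero variance)")
    m4 = float((w * (x - mean) ** 4).sum())
    return m4 / m2**2 - 3.0


def segregating_counts(pop_or_sample, arch: ArchitectureSpec) -> dict:
    """Counts of segregating loci per role class.

    A locus segregates iff >= 2 distinct alleles are present. Accepts a
    Population (haplotype-level) or anything with ``values``/``markers``
    arrays shaped like one. Keys: "qtl", "qtn", "neutral", "pleio",
    "nonpleio" (causal only) plus "causal" for the union.
    """
    values = pop_or_sample.values  # (N, 2, Lc, 2)
    markers = pop_or_sample.markers  # (N, 2, Lm)
    causal_roles = arch.roles[arch.causal_idx]
    seg_causal = np.zeros(arch.n_causal, dtype=bool)
    if arch.n_causal:
        ref = values[0, 0]
        seg_causal = np.any(values != ref[None, None, :, :], axis=(0, 1, 3))
    seg_neutral = np.zeros(arch.n_neutral, dtype=bool)
    if arch.n_neutral:
        ref = markers[0, 0]
        seg_neutral = np.any(markers != ref[None, None, :], axis=(0, 1))
    is_qtn = np.isin(causal_roles, Role.QTN)
    is_pleio = np.isin(causal_roles, Role.PLEIO)
    return {
        "causal": int(seg_causal.sum()),
        "qtl": int(seg_causal[~is_qtn].sum()),
        "qtn": int(seg_causal[is_qtn].sum()),
        "pleio": int(seg_causal[is_pleio].sum()),
        "nonpleio": int(seg_causal[~is_pleio].sum()),
        "neutral": int(seg_neutral.sum()),
    }
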