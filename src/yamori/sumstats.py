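"""Summary statistics for SNP datasets.

Per-population site-frequency spectra with expected-value hypergeometric
projection (the easySFS convention, which also absorbs missing genotypes),
minor-allele folding, and the pairwise differentiation statistics used as
ABC summaries: multi-locus F_ST (Hudson ratio-of-averages or diploid
Weir–Cockerham) and the AMOVA fixation index Phi_ST computed from per-site
allelic mismatch distances.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
from scipy.stats import hypergeom

from .data import MISSING, SFS, SNPDataset, SummaryVector

logger = logging.getLogger(__name__)

__all__ = [
    "site_allele_counts",
    "pop_allele_counts",
    "project_sfs",
    "observed_sfs",
    "fold_sfs",
    "pairwise_fst",
    "pairwise_phi_st",
    "hudson_fst_from_counts",
    "phi_st_from_counts",
    "summary_vector",
    "summary_vector_from_counts",
    "maf_filter",
]


# -- allele counts ----------------------------------------------------------


def site_allele_counts(dataset: SNPDataset, population: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-site allele count and called haploid size within ``population``.

    The count is the alternate/derived allele count when the dataset is
    polarized (``ancestral_known``), otherwise the minor-allele count within
    the population. Sites with no calls are reported with size 0 (dropped by
    downstream consumers, never silently).
    """
    mask = dataset.pop_mask(population)
    g = dataset.genotypes[mask]
    called = g != MISSING
    d = np.where(g > 0, g, 0).sum(axis=0).astype(np.int64)
    m = 2 * called.sum(axis=0).astype(np.int64)
    if not dataset.ancestral_known:
        d = np.minimum(d, m - d)
    return d, m


def pop_allele_counts(
    dataset: SNPDataset, populations: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Alternate-allele counts and called sizes, (n_sites, n_pops), for all
    populations at once. Counts are always alternate-allele oriented (a shared
    orientation across populations is required by every pairwise statistic)."""
    pops = populations if populations is not None else dataset.pop_names
    d = np.empty((dataset.n_sites, len(pops)), dtype=np.int64)
    m = np.empty_like(d)
    for j, p in enumerate(pops):
        mask = dataset.pop_mask(p)
        g = dataset.genotypes[mask]
        d[:, j] = np.where(g > 0, g, 0).sum(axis=0)
        m[:, j] = 2 * (g != MISSING).sum(axis=0)
    return d, m, list(pops)


# -- SFS --------------------------------------------------------------------


def project_sfs(counts: np.ndarray, sizes: np.ndarray, n_proj: int) -> SFS:
    """Expected-value hypergeometric projection of per-site allele counts to
    haploid size ``n_proj``.

    A site with ``d`` copies among ``m`` called alleles (``m >= n_proj``)
    contributes mass ``P(j | d, m, n_proj) = C(d,j) C(m-d, n_proj-j) / C(m,
    n_proj)`` to bin ``j``; sites with fewer called alleles than ``n_proj``
    are skipped. The projected spectrum's total mass equals the number of
    usable sites.
    """
    if n_proj < 2:
        raise ValueError("projection size must be >= 2")
    counts = np.asarray(counts, dtype=np.int64)
    sizes = np.asarray(sizes, dtype=np.int64)
    usable = sizes >= n_proj
    d = counts[usable]
    m = sizes[usable]
    out = np.zeros(n_proj + 1, dtype=float)
    if d.size:
        key = d * (m.max() + 1) + m
        uniq, inverse = np.unique(key, return_inverse=True)
        mult = np.bincount(inverse)
        j = np.arange(n_proj + 1)
        for u, w in zip(uniq, mult):
            du, mu = int(u // (m.max() + 1)), int(u % (m.max() + 1))
            out += w * hypergeom.pmf(j, mu, du, n_proj)
    return SFS(n=n_proj, counts=out, folded=False)


def observed_sfs(
    dataset: SNPDataset,
    population: str,
    n_proj: int | None = None,
    folded: bool = True,
) -> SFS:
    """Projected SFS of one population; the default projection is ``2N - 1``
    haploids (one fewer than the full sample, which keeps most sites with a
    single missing genotype usable)."""
    d, m = site_allele_counts(dataset, population)
    if n_proj is None:
        n_proj = int(m.max()) - 1
        if n_proj < 2:
            raise ValueError(f"population {population!r} has too few called alleles")
    sfs = project_sfs(d, m, n_proj)
    return fold_sfs(sfs) if folded else sfs


def fold_sfs(sfs: SFS) -> SFS:
    """Fold a derived-allele spectrum into a minor-allele spectrum:
    ``folded[j] = unfolded[j] + unfolded[n-j]`` for ``j < n/2``; the middle
    bin of an even-``n`` spectrum is carried over once."""
    if sfs.folded:
        raise ValueError("spectrum is already folded")
    n = sfs.n
    half = n // 2
    out = np.zeros(half + 1, dtype=float)
    for j in range(half + 1):
        if j == n - j:
            out[j] = sfs.counts[j]
        else:
            out[j] = sfs.counts[j] + sfs.counts[n - j]
    return SFS(n=n, counts=out, folded=True)


# -- F_ST -------------------------------------------------------------------


def hudson_fst_from_counts(
    dA: np.ndarray, nA: np.ndarray, dB: np.ndarray, nB: np.ndarray
) -> float:
    """Multi-locus Hudson F_ST, ratio of averages:
    ``1 - mean(H_within) / mean(H_between)`` with unbiased within-population
    heterozygosity ``2 d (n - d) / (n (n - 1))``. Sites with fewer than two
    called alleles in either population are dropped."""
    dA, nA, dB, nB = (np.asarray(x, dtype=float) for x in (dA, nA, dB, nB))
    ok = (nA >= 2) & (nB >= 2)
    if not ok.any():
        logger.warning("Hudson F_ST: no site has >= 2 called alleles in both populations")
        return float("nan")
    dA, nA, dB, nB = dA[ok], nA[ok], dB[ok], nB[ok]
    hw = 0.5 * (2 * dA * (nA - dA) / (nA * (nA - 1)) + 2 * dB * (nB - dB) / (nB * (nB - 1)))
    hb = (dA * (nB - dB) + dB * (nA - dA)) / (nA * nB)
    mean_hb = hb.mean()
    if mean_hb == 0:
        logger.warning("Hudson F_ST: zero between-population diversity at every usable site")
        return float("nan")
    return float(1.0 - hw.mean() / mean_hb)


def _wc_fst_genotypes(dataset: SNPDataset, popA: str, popB: str) -> float:
    """Diploid Weir–Cockerham theta for two populations: multi-locus
    ``sum(a) / sum(a + b + c)`` over the per-site variance components."""
    gA = dataset.genotypes[dataset.pop_mask(popA)]
    gB = dataset.genotypes[dataset.pop_mask(popB)]
    r = 2.0
    calledA = gA != MISSING
    calledB = gB != MISSING
    nA = calledA.sum(axis=0).astype(float)  # diploids
    nB = calledB.sum(axis=0).astype(float)
    ok = (nA >= 1) & (nB >= 1) & (nA + nB >= 3)
    if not ok.any():
        logger.warning("WC F_ST: no usable sites for %s vs %s", popA, popB)
        return float("nan")
    dA = np.where(gA > 0, gA, 0).sum(axis=0).astype(float)
    dB = np.where(gB > 0, gB, 0).sum(axis=0).astype(float)
    hetA = ((gA == 1).sum(axis=0)).astype(float)
    hetB = ((gB == 1).sum(axis=0)).astype(float)
    nA, nB, dA, dB, hetA, hetB = (x[ok] for x in (nA, nB, dA, dB, hetA, hetB))
    pA = dA / (2 * nA)
    pB = dB / (2 * nB)
    hA = hetA / nA
    hB = hetB / nB
    n_sum = nA + nB
    nbar = n_sum / r
    nc = (n_sum - (nA**2 + nB**2) / n_sum) / (r - 1)
    pbar = (nA * pA + nB * pB) / n_sum
    s2 = (nA * (pA - pbar) ** 2 + nB * (pB - pbar) ** 2) / ((r - 1) * nbar)
    hbar = (nA * hA + nB * hB) / n_sum
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2
    good = np.isfinite(a) & np.isfinite(b)
    denom = (a + b + c)[good].sum()
    if denom == 0:
        logger.warning("WC F_ST: zero total variance for %s vs %s", popA, popB)
        return float("nan")
    return float(a[good].sum() / denom)


def pairwise_fst(
    dataset: SNPDataset, popA: str, popB: str, estimator: str = "weir_cockerham"
) -> float:
    """Multi-locus pairwise F_ST between two populations."""
    if estimator == "weir_cockerham":
        return _wc_fst_genotypes(dataset, popA, popB)
    if estimator == "hudson":
        dA, nA = site_allele_counts_raw(dataset, popA)
        dB, nB = site_allele_counts_raw(dataset, popB)
        return hudson_fst_from_counts(dA, nA, dB, nB)
    raise ValueError(f"unknown estimator {estimator!r}")


def site_allele_counts_raw(dataset: SNPDataset, population: str):
    """Alternate-oriented per-site counts (never minor-folded) — pairwise
    statistics need a shared allele orientation across populations."""
    mask = dataset.pop_mask(population)
    g = dataset.genotypes[mask]
    d = np.where(g > 0, g, 0).sum(axis=0).astype(np.int64)
    m = 2 * (g != MISSING).sum(axis=0).astype(np.int64)
    return d, m


# -- Phi_ST -----------------------------------------------------------------


def phi_st_from_counts(
    dA: np.ndarray, nA: np.ndarray, dB: np.ndarray, nB: np.ndarray
) -> float:
    """Two-level AMOVA fixation index Phi_ST from per-site allele counts.

    Haploid alleles are the units and the distance between two alleles at a
    site is the mismatch indicator; squared deviations therefore reduce to
    ``d (n - d) / n`` terms. Per-site sums of squares and degrees of freedom
    are accumulated across sites (for complete data this is exactly the
    textbook AMOVA on the summed mismatch distance matrix), and
    ``Phi_ST = sigma2_among / (sigma2_among + sigma2_within)``.
    """
    dA, nA, dB, nB = (np.asarray(x, dtype=float) for x in (dA, nA, dB, nB))
    ok = (nA >= 1) & (nB >= 1) & (nA + nB >= 3)
    if not ok.any():
        logger.warning("Phi_ST: no usable sites")
        return float("nan")
    dA, nA, dB, nB = dA[ok], nA[ok], dB[ok], nB[ok]
    N = nA + nB
    D = dA + dB
    ssd_total = D * (N - D) / N
    ssd_within = dA * (nA - dA) / nA + dB * (nB - dB) / nB
    ssd_among = ssd_total - ssd_within
    df_among = float(len(N))          # (G - 1) per site, G = 2
    df_within = float((N - 2).sum())
    n_prime = N - (nA**2 + nB**2) / N  # per-site coefficient of sigma2_among
    if df_within <= 0:
        logger.warning("Phi_ST: no within-population degrees of freedom")
        return float("nan")
    sigma_w = ssd_within.sum() / df_within
    sigma_a = (ssd_among.sum() - df_among * sigma_w) / n_prime.sum()
    denom = sigma_a + sigma_w
    if denom == 0:
        logger.warning("Phi_ST: zero total variance")
        return float("nan")
    return float(sigma_a / denom)


def pairwise_phi_st(dataset: SNPDataset, popA: str, popB: str) -> float:
    """AMOVA Phi_ST between two populations over all sites jointly."""
    dA, nA = site_allele_counts_raw(dataset, popA)
    dB, nB = site_allele_counts_raw(dataset, popB)
    return phi_st_from_counts(dA, nA, dB, nB)


# -- summary vector ---------------------------------------------------------


def summary_vector_from_counts(
    d: np.ndarray, m: np.ndarray, population_order: list[str], fst_estimator: str = "hudson"
) -> SummaryVector:
    """Assemble the ABC summary vector from (n_sites, n_pops) allele-count
    matrices: all pairwise F_ST values then all pairwise Phi_ST values, pairs
    enumerated as combinations in ``population_order``. Only the count-based
    Hudson estimator is available on this path."""
    if fst_estimator != "hudson":
        raise ValueError("count-based summary vectors support only the Hudson estimator")
    pairs = list(combinations(range(len(population_order)), 2))
    values = []
    labels = []
    for i, j in pairs:
        values.append(hudson_fst_from_counts(d[:, i], m[:, i], d[:, j], m[:, j]))
        labels.append(f"fst:{population_order[i]}|{population_order[j]}")
    for i, j in pairs:
        values.append(phi_st_from_counts(d[:, i], m[:, i], d[:, j], m[:, j]))
        labels.append(f"phi:{population_order[i]}|{population_order[j]}")
    return SummaryVector(
        values=np.array(values),
        labels=labels,
        population_order=list(population_order),
        fst_estimator=fst_estimator,
    )


def summary_vector(
    dataset: SNPDataset,
    population_order: list[str] | None = None,
    fst_estimator: str = "hudson",
) -> SummaryVector:
    """ABC summary vector of a dataset (see
    :func:`summary_vector_from_counts` for layout). ABC requires the observed
    and simulated sides to share the estimator; the vector carries it as
    metadata so mismatches are structural errors, not silent bias."""
    pops = population_order if population_order is not None else dataset.pop_names
    if len(pops) < 2:
        raise ValueError("summary vector needs at least two populations")
    if fst_estimator == "hudson":
        d, m, pops = pop_allele_counts(dataset, list(pops))
        return summary_vector_from_counts(d, m, pops, fst_estimator)
    # genotype-based estimator: assemble pair by pair
    pairs = list(combinations(pops, 2))
    values = [pairwise_fst(dataset, a, b, estimator=fst_estimator) for a, b in pairs]
    labels = [f"fst:{a}|{b}" for a, b in pairs]
    values += [pairwise_phi_st(dataset, a, b) for a, b in pairs]
    labels += [f"phi:{a}|{b}" for a, b in pairs]
    return SummaryVector(
        values=np.array(values),
        labels=labels,
        population_order=list(pops),
        fst_estimator=fst_estimator,
    )


# -- filters ----------------------------------------------------------------


def maf_filter(dataset: SNPDataset, threshold: float) -> SNPDataset:
    """Keep sites whose total-sample minor-allele frequency among called
    alleles is at least ``threshold`` (in [0, 0.5))."""
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must lie in [0, 0.5)")
    g = dataset.genotypes
    called = g != MISSING
    m = 2 * called.sum(axis=0)
    d = np.where(g > 0, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore"):
        maf = np.minimum(d, m - d) / np.where(m > 0, m, 1)
    keep = (m > 0) & (maf >= threshold)
    return dataset.subset_sites(keep)
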