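"""Independent textbook AMOVA oracle shared by the test modules."""

import numpy as np

from yamori.data import MISSING, SNPDataset


def brute_force_amova_phi(ds: SNPDataset, popA: str, popB: str) -> float:
    """Independent textbook AMOVA on the explicit allele-by-allele mismatch
    distance matrix (complete data only): SSD from distance sums, variance
    components from the standard two-level decomposition."""
    alleles = []
    groups = []
    for i, pop in enumerate(ds.populations):
        if pop not in (popA, popB):
            continue
        g = ds.genotypes[i]
        assert (g != MISSING).all(), "oracle handles complete data only"
        a = np.zeros((2, ds.n_sites), dtype=int)
        a[0] = (g >= 1).astype(int)
        a[1] = (g == 2).astype(int)
        alleles.extend([a[0], a[1]])
        groups.extend([pop, pop])
    X = np.array(alleles)
    groups = np.array(groups)
    N = len(X)
    D = ((X[:, None, :] != X[None, :, :]).sum(axis=2)).astype(float)  # squared distance
    ssd_total = D.sum() / (2 * N)
    ssd_within = 0.0
    sizes = []
    for pop in (popA, popB):
        idx = np.flatnonzero(groups == pop)
        sizes.append(len(idx))
        ssd_within += D[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ssd_among = ssd_total - ssd_within
    df_among, df_within = 1, N - 2
    ms_within = ssd_within / df_within
    n_prime = (N - sum(s**2 for s in sizes) / N) / df_among
    sigma_a = (ssd_among / df_among - ms_within) / n_prime
    return sigma_a / (sigma_a + ms_within)
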