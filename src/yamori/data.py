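"""Core in-memory containers: genotype matrices, site-frequency spectra and
ABC summary vectors."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MISSING", "SNPDataset", "SFS", "SummaryVector"]

#: Sentinel for a missing diploid genotype call.
MISSING = -1


@dataclass
class SNPDataset:
    """Biallelic SNP genotypes for a set of diploid individuals.

    ``genotypes`` is an ``(n_individuals, n_sites)`` int8 matrix of alternate
    (or derived, when ``ancestral_known``) allele dosages in {0, 1, 2}, with
    ``MISSING`` (-1) for no-calls. Every individual carries a population label.
    """

    genotypes: np.ndarray
    individuals: list[str]
    populations: list[str]
    site_ids: list[str] | None = None
    ancestral_known: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D (individuals x sites) matrix")
        n_ind, n_sites = self.genotypes.shape
        if len(self.individuals) != n_ind or len(self.populations) != n_ind:
            raise ValueError("individual / population label length mismatch")
        bad = ~np.isin(self.genotypes, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype values must be in {missing, 0, 1, 2}")
        if self.site_ids is None:
            self.site_ids = [f"snp{i}" for i in range(n_sites)]
        elif len(self.site_ids) != n_sites:
            raise ValueError("site_ids length mismatch")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def pop_names(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def pop_mask(self, population: str) -> np.ndarray:
        mask = np.asarray([p == population for p in self.populations])
        if not mask.any():
            raise KeyError(f"unknown population {population!r}")
        return mask

    def subset_sites(self, keep: np.ndarray) -> "SNPDataset":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return SNPDataset(
            genotypes=self.genotypes[:, idx],
            individuals=list(self.individuals),
            populations=list(self.populations),
            site_ids=[self.site_ids[i] for i in idx],
            ancestral_known=self.ancestral_known,
        )

    def subset_individuals(self, keep: np.ndarray) -> "SNPDataset":
        keep = np.asarray(keep)
        idx = np.flatnonzero(keep) if keep.dtype == bool else keep
        return SNPDataset(
            genotypes=self.genotypes[idx, :],
            individuals=[self.individuals[i] for i in idx],
            populations=[self.populations[i] for i in idx],
            site_ids=list(self.site_ids),
            ancestral_known=self.ancestral_known,
        )


@dataclass
class SFS:
    """A one-dimensional site-frequency spectrum at haploid sample size ``n``.

    Unfolded spectra have ``n + 1`` bins (0..n, derived/alternate allele
    count); folded (minor-allele) spectra have ``n // 2 + 1`` bins
    (0..floor(n/2)). Counts may be fractional (hypergeometric projection
    distributes per-site mass over bins).
    """

    n: int
    counts: np.ndarray
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (self.n // 2 + 1) if self.folded else (self.n + 1)
        if self.counts.shape != (expected,):
            raise ValueError(
                f"{'folded' if self.folded else 'unfolded'} SFS at n={self.n} "
                f"needs {expected} bins, got {self.counts.shape}"
            )
        if (self.counts < -1e-9).any():
            raise ValueError("SFS counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def segregating(self) -> np.ndarray:
        """Counts of the polymorphic bins (excludes bin 0 and, unfolded, bin n)."""
        return self.counts[1:-1] if not self.folded else self.counts[1:]


@dataclass
class SummaryVector:
    """Ordered vector of pairwise differentiation statistics for ABC.

    Layout: all pairwise F_ST values, then all pairwise Phi_ST values, pairs
    enumerated as combinations in the order of ``population_order``.
    """

    values: np.ndarray
    labels: list[str]
    population_order: list[str]
    fst_estimator: str = "hudson"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),):
            raise ValueError("labels/values length mismatch")
        k = len(self.population_order)
        if len(self.values) != k * (k - 1):
            raise ValueError("expected 2 * C(k, 2) statistics")

    def compatible_with(self, other: "SummaryVector") -> bool:
        return (
            self.labels == other.labels
            and self.population_order == other.population_order
            and self.fst_estimator == other.fst_estimator
        )
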