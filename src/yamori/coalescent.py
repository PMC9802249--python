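"""Structured-coalescent simulation of unlinked SNPs under a
:class:`~yamori.models.DemographicModel`.

Each SNP is an independent genealogy (ddRAD loci are effectively unlinked)
carrying exactly one infinite-sites mutation placed proportionally to branch
length, so every simulated site segregates in the total sample — the same
ascertainment as SNP-count-parameterized simulation. Diploid genotypes are
formed by pairing consecutive lineages within each population (random union
of gametes under exchangeability).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .data import SFS, SNPDataset
from .models import DemographicModel

__all__ = ["SampleConfig", "Genealogy", "simulate_genealogy", "simulate_snps",
           "simulate_snp_counts", "simulate_sfs"]


@dataclass(frozen=True)
class SampleConfig:
    """Per-population haploid lineage counts (2 x sampled diploids)."""

    haploids: dict[str, int]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.haploids.values()):
            raise ValueError("lineage counts must be >= 0")
        if sum(self.haploids.values()) < 2:
            raise ValueError("need at least 2 lineages in total")

    @classmethod
    def from_model(cls, model: DemographicModel) -> "SampleConfig":
        return cls({p.name: 2 * p.sample_diploids for p in model.populations})

    @classmethod
    def from_diploids(cls, diploids: dict[str, int]) -> "SampleConfig":
        return cls({k: 2 * v for k, v in diploids.items()})

    def validate_against(self, model: DemographicModel) -> None:
        unknown = set(self.haploids) - set(model.pop_names)
        if unknown:
            raise ValueError(f"samples reference unknown populations {sorted(unknown)}")

    def counts_array(self, model: DemographicModel) -> np.ndarray:
        self.validate_against(model)
        return np.array([self.haploids.get(n, 0) for n in model.pop_names], dtype=np.int32)


@dataclass
class Genealogy:
    """A coalescent tree over sampled lineages.

    Leaves are ``0..n_leaves-1`` (contiguous by population in model order);
    internal nodes follow in coalescence order, the last being the root.
    """

    node_time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    leaf_population: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_population)

    @property
    def n_nodes(self) -> int:
        return len(self.node_time)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    @property
    def total_branch_length(self) -> float:
        parent = self.parents()
        has_parent = parent >= 0
        return float(
            np.sum(self.node_time[parent[has_parent]] - self.node_time[has_parent])
        )

    def parents(self) -> np.ndarray:
        parent = np.full(self.n_nodes, -1, dtype=np.int32)
        for m in range(self.n_leaves, self.n_nodes):
            parent[self.left[m]] = m
            parent[self.right[m]] = m
        return parent

    def __post_init__(self) -> None:
        # node times must increase root-ward along every branch
        for m in range(self.n_leaves, self.n_nodes):
            if not (
                self.node_time[m] >= self.node_time[self.left[m]]
                and self.node_time[m] >= self.node_time[self.right[m]]
            ):
                raise ValueError("node times must be non-decreasing toward the root")


def _encode(model: DemographicModel, samples: SampleConfig):
    """Flatten a model into the kernel's array encoding."""
    counts = samples.counts_array(model)
    ne0 = np.array([p.ne for p in model.populations], dtype=np.float64)
    events = []
    for s in model.splits:
        events.append((s.time_generations, _kernels.EV_SPLIT,
                       model.pop_index(s.derived), model.pop_index(s.ancestral), 0.0))
    for c in model.size_changes:
        events.append((c.time_generations, _kernels.EV_SIZE,
                       model.pop_index(c.population), -1, c.ne))
    events.sort(key=lambda e: (e[0], e[1]))
    n_ev = len(events)
    ev_time = np.array([e[0] for e in events], dtype=np.float64)
    ev_kind = np.array([e[1] for e in events], dtype=np.int8).reshape(n_ev)
    ev_a = np.array([e[2] for e in events], dtype=np.int32).reshape(n_ev)
    ev_b = np.array([e[3] for e in events], dtype=np.int32).reshape(n_ev)
    ev_ne = np.array([e[4] for e in events], dtype=np.float64).reshape(n_ev)
    n_pops = len(model.populations)
    mig = np.zeros((n_pops, n_pops), dtype=np.float64)
    for m in model.migrations:
        mig[model.pop_index(m.source), model.pop_index(m.dest)] += m.rate_per_generation
    use_mig = bool(len(model.migrations) > 0)
    _check_reachability(model, counts)
    return counts, ne0, ev_time, ev_kind, ev_a, ev_b, ev_ne, mig, use_mig


def _check_reachability(model: DemographicModel, counts: np.ndarray) -> None:
    """Every sampled population must reach the root through splits (migration
    aside); guaranteed by the model's tree invariant, but sampled populations
    must exist in the model."""
    for name, c in zip(model.pop_names, counts):
        if c > 0 and name not in model.pop_names:  # pragma: no cover
            raise ValueError(f"stranded samples in unknown population {name}")


def _kernel_seed(seed) -> int:
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))


def simulate_genealogy(
    model: DemographicModel, samples: SampleConfig | None = None, seed: int = 0
) -> Genealogy:
    """Draw one genealogy under the structured coalescent."""
    if samples is None:
        samples = SampleConfig.from_model(model)
    enc = _encode(model, samples)
    node_time, left, right, root = _kernels.sim_one_tree(_kernel_seed(seed), *enc)
    if root < 0:
        raise RuntimeError("lineages stranded: model leaves lineages that can never coalesce")
    counts = enc[0]
    leaf_pop = [
        name for name, c in zip(model.pop_names, counts) for _ in range(int(c))
    ]
    n = root + 1
    return Genealogy(node_time[:n].copy(), left[:n].copy(), right[:n].copy(), leaf_pop)


def simulate_snp_counts(
    model: DemographicModel,
    samples: SampleConfig | None = None,
    n_snps: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast path: per-SNP derived-allele counts per population.

    Returns ``(counts, sizes)`` where ``counts`` is (n_snps, n_pops) and
    ``sizes`` the haploid sample size per population (model population order;
    zero-sample populations are dropped from the output columns).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if samples is None:
        samples = SampleConfig.from_model(model)
    enc = _encode(model, samples)
    out = _kernels.sim_snp_pop_counts(_kernel_seed(seed), *enc, n_snps)
    if out.shape[0] == 0:
        raise RuntimeError("lineages stranded: model leaves lineages that can never coalesce")
    sizes = enc[0]
    keep = sizes > 0
    return out[:, keep], sizes[keep].astype(np.int64)


def _sampled_pop_names(model: DemographicModel, samples: SampleConfig) -> list[str]:
    counts = samples.counts_array(model)
    return [n for n, c in zip(model.pop_names, counts) if c > 0]


def simulate_snps(
    model: DemographicModel,
    samples: SampleConfig | None = None,
    n_snps: int = 1000,
    ascertained: bool = True,
    seed: int = 0,
) -> SNPDataset:
    """Simulate a diploid genotype matrix of ``n_snps`` unlinked SNPs.

    Requires an even haploid count per population; consecutive lineage pairs
    (2k, 2k+1) form diploid individual k.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not ascertained:
        raise ValueError(
            "one mutation per genealogy makes every site polymorphic in the "
            "total sample; unascertained output is not defined in SNP mode"
        )
    if samples is None:
        samples = SampleConfig.from_model(model)
    if any(v % 2 for v in samples.haploids.values()):
        raise ValueError("diploid genotypes need an even lineage count per population")
    enc = _encode(model, samples)
    hap = _kernels.sim_snp_haplotypes(_kernel_seed(seed), *enc, n_snps)
    if hap.shape[0] == 0:
        raise RuntimeError("lineages stranded: model leaves lineages that can never coalesce")
    # pair consecutive lineages into diploids
    n_tot = hap.shape[1]
    geno = (hap[:, 0::2] + hap[:, 1::2]).astype(np.int8).T  # (individuals, sites)
    counts = enc[0]
    individuals: list[str] = []
    populations: list[str] = []
    for name, c in zip(model.pop_names, counts):
        for i in range(int(c) // 2):
            individuals.append(f"{name}_{i}")
            populations.append(name)
    return SNPDataset(
        genotypes=geno,
        individuals=individuals,
        populations=populations,
        ancestral_known=True,
    )


def simulate_sfs(
    model: DemographicModel,
    samples: SampleConfig | None = None,
    n_snps: int = 1000,
    folded: bool = True,
    seed: int = 0,
) -> dict[str, SFS]:
    """Per-population (and total-sample) site-frequency spectra of a
    SNP-mode simulation; distributionally identical to computing the
    observed SFS of :func:`simulate_snps` output."""
    if samples is None:
        samples = SampleConfig.from_model(model)
    counts, sizes = simulate_snp_counts(model, samples, n_snps, seed)
    names = _sampled_pop_names(model, samples)
    out: dict[str, SFS] = {}
    for j, (name, n) in enumerate(zip(names, sizes)):
        spec = np.bincount(counts[:, j], minlength=int(n) + 1).astype(float)
        out[name] = _maybe_fold(SFS(int(n), spec, folded=False), folded)
    n_tot = int(sizes.sum())
    total = np.bincount(counts.sum(axis=1), minlength=n_tot + 1).astype(float)
    out["total"] = _maybe_fold(SFS(n_tot, total, folded=False), folded)
    return out


def _maybe_fold(sfs: SFS, folded: bool) -> SFS:
    if not folded:
        return sfs
    from .sumstats import fold_sfs

    return fold_sfs(sfs)
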