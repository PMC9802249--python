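"""Study-shaped synthetic data.

Generates SNP matrices + population maps with the shape of the published
regional ddRAD dataset — 11 regional groups, ~30,477 biallelic SNPs, ~2.43%
missing genotypes — by structured-coalescent simulation under the adopted
divergence scenario, so every downstream stage (SFS projection, stairway,
ABC) is testable without any sequencing data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coalescent import SampleConfig, simulate_snps
from .data import MISSING, SNPDataset
from .models import DemographicModel, build_m1

__all__ = ["StudyDesign", "study_design", "generate_dataset"]

#: The 11 regional groups and diploid sample sizes, in the study's listed
#: order. Kyushu-T is the Tsushima-strait monophyletic clade used in the
#: divergence analysis; Kyushu-F holds the remaining Kyushu individuals.
STUDY_GROUPS = (
    ("Tohoku", 15),
    ("Kanto", 15),
    ("Tokai", 31),
    ("Hokuriku", 39),
    ("Kinki", 16),
    ("Chugoku", 16),
    ("Shikoku", 12),
    ("Kyushu-T", 16),
    ("Fukue", 6),
    ("Kyushu-F", 13),
    ("Nanjing", 3),
)

#: Groups that are not distinct populations of the divergence scenario are
#: drawn from their nearest modeled population.
GROUP_TO_MODEL_POP = {
    "Kyushu-T": "Kyushu",
    "Kyushu-F": "Kyushu",
}


@dataclass(frozen=True)
class StudyDesign:
    """Shape of a synthetic SNP dataset: group sizes, SNP count, missing
    fraction, and the generating demographic model."""

    groups: tuple[tuple[str, int], ...]
    n_snps: int
    missing_fraction: float
    model: DemographicModel
    group_to_pop: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(n <= 0 for _, n in self.groups):
            raise ValueError("group sizes must be > 0")
        if not (0 <= self.missing_fraction < 0.5):
            raise ValueError("missing fraction must lie in [0, 0.5)")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for g, _ in self.groups:
            pop = self.group_to_pop.get(g, g)
            if pop not in self.model.pop_names:
                raise ValueError(
                    f"group {g!r} maps to population {pop!r} absent from the model"
                )

    @property
    def total_diploids(self) -> int:
        return sum(n for _, n in self.groups)

    def model_sample_sizes(self) -> dict[str, int]:
        """Diploids to simulate per model population (groups sharing a
        population are pooled)."""
        sizes: dict[str, int] = {}
        for g, n in self.groups:
            pop = self.group_to_pop.get(g, g)
            sizes[pop] = sizes.get(pop, 0) + n
        return sizes


def study_design(
    n_snps: int = 30_477,
    missing_fraction: float = 0.0243,
    model: DemographicModel | None = None,
) -> StudyDesign:
    """The study's regional sampling design: 11 groups, 182 diploids in
    total, generated under the adopted divergence scenario by default."""
    return StudyDesign(
        groups=STUDY_GROUPS,
        n_snps=n_snps,
        missing_fraction=missing_fraction,
        model=model if model is not None else build_m1(),
        group_to_pop=dict(GROUP_TO_MODEL_POP),
    )


def generate_dataset(design: StudyDesign, seed: int = 0) -> tuple[SNPDataset, pd.DataFrame]:
    """Simulate a dataset of ``design.n_snps`` SNPs under the design's model,
    then mask genotypes independently at the missing fraction (never emptying
    a site entirely). Returns the dataset and its two-column popmap.

    Fully deterministic given ``seed``: the same seed yields a byte-identical
    VCF when written.
    """
    sizes = design.model_sample_sizes()
    samples = SampleConfig.from_diploids(sizes)
    ss = np.random.SeedSequence(seed)
    sim_seed, mask_seed = (int(s % (2**31 - 1)) for s in ss.generate_state(2))
    ds = simulate_snps(design.model, samples, n_snps=design.n_snps, seed=sim_seed)

    # relabel simulated individuals group by group (groups sharing a model
    # population take consecutive individuals of that population)
    offsets = {pop: 0 for pop in sizes}
    individuals: list[str] = []
    populations: list[str] = []
    rows: list[int] = []
    pop_rows = {pop: [i for i, p in enumerate(ds.populations) if p == pop] for pop in sizes}
    for g, n in design.groups:
        pop = design.group_to_pop.get(g, g)
        start = offsets[pop]
        take = pop_rows[pop][start : start + n]
        offsets[pop] = start + n
        for j, row in enumerate(take):
            rows.append(row)
            individuals.append(f"{g}_{j}")
            populations.append(g)
    geno = ds.genotypes[rows, :].copy()

    if design.missing_fraction > 0:
        rng = np.random.default_rng(mask_seed)
        mask = rng.random(geno.shape) < design.missing_fraction
        # a site must keep at least one call: redraw offending columns
        empty = mask.all(axis=0)
        while empty.any():
            mask[:, empty] = rng.random((geno.shape[0], int(empty.sum()))) < design.missing_fraction
            empty = mask.all(axis=0)
        geno[mask] = MISSING

    out = SNPDataset(
        genotypes=geno,
        individuals=individuals,
        populations=populations,
        site_ids=list(ds.site_ids),
        ancestral_known=True,
    )
    popmap = pd.DataFrame({"individual": individuals, "population": populations})
    return out, popmap


def toy_phi_table() -> SNPDataset:
    """A small fixed two-population genotype table (4 + 4 diploids, 3 sites)
    used to pin the AMOVA Phi_ST computation against an independently coded
    textbook AMOVA in the test suite."""
    geno = np.array(
        [
            # popA
            [0, 1, 2],
            [1, 0, 1],
            [0, 0, 2],
            [1, 1, 1],
            # popB
            [2, 2, 0],
            [2, 1, 0],
            [1, 2, 1],
            [2, 2, 0],
        ],
        dtype=np.int8,
    )
    return SNPDataset(
        genotypes=geno,
        individuals=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
        populations=["A"] * 4 + ["B"] * 4,
        ancestral_known=True,
    )
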