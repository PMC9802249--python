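"""Standard-format I/O: VCF 4.2 genotype matrices, two-column popmaps, and
the 1-D SFS text formats (dadi-style and fastsimcoal-style ``.obs``)."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MISSING, SFS, SNPDataset

logger = logging.getLogger(__name__)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_popmap",
    "write_popmap",
    "read_sfs",
    "write_sfs",
    "write_sfs_obs",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(dataset: SNPDataset, path) -> None:
    """Minimal valid VCF 4.2: synthetic CHROM/POS, GT-only FORMAT, ``./.``
    for missing calls; deterministic ordering."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=yamori\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dataset.individuals)
            + "\n"
        )
        g = dataset.genotypes
        for j in range(dataset.n_sites):
            fields = [
                "1",
                str(j + 1),
                dataset.site_ids[j],
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ]
            fields += [_GT_STRINGS[int(v)] for v in g[:, j]]
            fh.write("\t".join(fields) + "\n")


def read_popmap(path) -> pd.DataFrame:
    """Two-column TSV (individual, population), no header."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"popmap {path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["individual", "population"]
    return df


def write_popmap(popmap: pd.DataFrame, path) -> None:
    popmap[["individual", "population"]].to_csv(path, sep="\t", header=False, index=False)


def read_vcf(path, popmap_path) -> SNPDataset:
    """Read biallelic SNP records into a genotype matrix.

    Multi-allelic and non-SNP records are skipped (counts logged). Every VCF
    sample must appear in the popmap; an empty intersection is a hard error.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    pop_of = dict(zip(popmap["individual"], popmap["population"]))
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    known = [s for s in samples if s in pop_of]
    if not known:
        raise ValueError("no overlap between VCF samples and popmap individuals")
    missing_from_popmap = [s for s in samples if s not in pop_of]
    if missing_from_popmap:
        raise ValueError(
            f"{len(missing_from_popmap)} VCF sample(s) missing from popmap, "
            f"e.g. {missing_from_popmap[:3]}"
        )
    cols: list[np.ndarray] = []
    ids: list[str] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = var.gt_types.astype(np.int8)  # 0,1,2, 3=missing under gts012
        gt[gt == 3] = MISSING
        cols.append(gt)
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
    if n_skipped:
        logger.warning("skipped %d multi-allelic / non-SNP record(s)", n_skipped)
    geno = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    ds = SNPDataset(
        genotypes=geno,
        individuals=samples,
        populations=[pop_of[s] for s in samples],
        site_ids=ids,
    )
    ds.n_skipped_records = n_skipped
    return ds


# -- SFS text ---------------------------------------------------------------


def write_sfs(sfs: SFS, path) -> None:
    """dadi-style 1-D spectrum: header ``<n> <folded|unfolded>``, then the
    whitespace-separated counts."""
    with Path(path).open("w") as fh:
        fh.write(f"{sfs.n} {'folded' if sfs.folded else 'unfolded'}\n")
        fh.write(" ".join(f"{c:.6g}" for c in sfs.counts) + "\n")


def read_sfs(path) -> SFS:
    with Path(path).open() as fh:
        header = fh.readline().split()
        if len(header) != 2 or header[1] not in ("folded", "unfolded"):
            raise ValueError(f"{path}: malformed SFS header {header!r}")
        n = int(header[0])
        counts = np.array([float(x) for x in fh.readline().split()])
    return SFS(n=n, counts=counts, folded=header[1] == "folded")


def write_sfs_obs(sfs: SFS, path, name: str = "pop") -> None:
    """fastsimcoal-style ``.obs`` minor-allele spectrum (one observation)."""
    labels = [f"d0_{i}" for i in range(len(sfs.counts))]
    with Path(path).open("w") as fh:
        fh.write(f"1 observations. No. of demes and sample sizes are on next line\n")
        fh.write(f"1 {sfs.n}\n")
        fh.write("\t".join(labels) + "\n")
        fh.write("\t".join(f"{c:.6g}" for c in sfs.counts) + "\n")
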