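"""Genotype containers, I/O, and locus filtering.

The central container is :class:`SNPMatrix`: an individuals x loci matrix of
alternate-allele copy counts (0/1/2, ``MISSING`` = -1) for biallelic SNPs,
carrying sample ids, locus ids and the RAD locus each SNP belongs to.
Filtering follows the usual RADseq hygiene rules: within-population presence,
overall sample coverage, minor-allele-frequency cutoff, and one SNP per RAD
locus to avoid tightly linked markers.

All statistics downstream are invariant to which allele is labelled
"alternate"; the orientation is simply taken from the input file.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "SNPMatrix",
    "PopulationMap",
    "load_genotypes",
    "write_genotypes",
    "load_population_map",
    "write_population_map",
    "filter_within_pop_presence",
    "filter_sample_coverage",
    "filter_maf",
    "one_snp_per_radlocus",
]


@dataclass
class SNPMatrix:
    """Individuals x biallelic loci, entries in {0, 1, 2, MISSING}.

    ``radlocus_ids`` maps each SNP column to the RAD locus it came from;
    ``positions`` (optional) orders SNPs within a RAD locus.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    locus_ids: list[str]
    radlocus_ids: list[str] | None = None
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n_ind, n_loci = self.genotypes.shape
        if len(self.sample_ids) != n_ind:
            raise ValueError("sample_ids length mismatch")
        if len(self.locus_ids) != n_loci:
            raise ValueError("locus_ids length mismatch")
        if len(set(self.locus_ids)) != n_loci:
            raise ValueError("locus_ids must be unique")
        if self.radlocus_ids is None:
            self.radlocus_ids = list(self.locus_ids)
        if len(self.radlocus_ids) != n_loci:
            raise ValueError("radlocus_ids must align with locus_ids")
        valid = np.isin(self.genotypes, (0, 1, 2, MISSING))
        if not valid.all():
            raise ValueError("genotype entries must be in {0,1,2,MISSING}")
        if n_loci and (self.genotypes == MISSING).all(axis=0).any():
            raise ValueError("every locus needs at least one non-missing call")
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.shape != (n_loci,):
                raise ValueError("positions must align with locus_ids")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def take_loci(self, idx) -> "SNPMatrix":
        """New matrix keeping loci ``idx`` (order preserved as given)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SNPMatrix(
            genotypes=self.genotypes[:, idx],
            sample_ids=list(self.sample_ids),
            locus_ids=[self.locus_ids[i] for i in idx],
            radlocus_ids=[self.radlocus_ids[i] for i in idx],
            positions=None if self.positions is None else self.positions[idx],
        )

    def take_samples(self, idx) -> "SNPMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return SNPMatrix(
            genotypes=self.genotypes[idx, :],
            sample_ids=[self.sample_ids[i] for i in idx],
            locus_ids=list(self.locus_ids),
            radlocus_ids=list(self.radlocus_ids),
            positions=None if self.positions is None else self.positions.copy(),
        )

    def allele_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-locus (alternate-allele count, observed gene count)."""
        obs = self.genotypes != MISSING
        alt = np.where(obs, self.genotypes, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * obs.sum(axis=0).astype(np.int64)

    def maf(self) -> np.ndarray:
        alt, n = self.allele_counts()
        with np.errstate(invalid="ignore"):
            p = alt / n
        return np.minimum(p, 1.0 - p)


@dataclass
class PopulationMap:
    """sample -> population -> group mapping with population coordinates."""

    sample_to_pop: dict[str, str]
    pop_to_group: dict[str, str]
    pop_coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(self.sample_to_pop.values()) - set(self.pop_to_group)
        if missing:
            raise ValueError(f"populations without group: {sorted(missing)}")

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.sample_to_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.pop_to_group.values():
            seen.setdefault(g, None)
        return list(seen)

    def samples_of(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def pop_indices(self, m: SNPMatrix) -> dict[str, np.ndarray]:
        """Row indices of each population's samples in ``m`` (mapped samples only)."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(m.sample_ids):
            pop = self.sample_to_pop.get(s)
            if pop is None:
                raise ValueError(f"sample {s!r} not in population map")
            out.setdefault(pop, []).append(i)
        return {p: np.asarray(v, dtype=np.int64) for p, v in out.items()}

    def group_indices(self, m: SNPMatrix) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {}
        for i, s in enumerate(m.sample_ids):
            g = self.pop_to_group[self.sample_to_pop[s]]
            out.setdefault(g, []).append(i)
        return {g: np.asarray(v, dtype=np.int64) for g, v in out.items()}


# ---------------------------------------------------------------------------
# I/O


def load_genotypes(path, fmt: str = "vcf") -> SNPMatrix:
    """Read genotypes from a VCF 4.x file or a samples x loci table.

    VCF records must be biallelic SNPs (multiallelic records raise).  Table
    format: tab-separated, first column = sample id, header row = locus ids,
    entries 0/1/2 or NA.  Missing calls map to :data:`MISSING`.
    """
    if fmt == "vcf":
        return _load_vcf(path)
    if fmt == "table":
        return _load_table(path)
    raise ValueError(f"unknown format {fmt!r}")


def _load_vcf(path) -> SNPMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: list[np.ndarray] = []
    locus_ids: list[str] = []
    rad_ids: list[str] = []
    positions: list[int] = []
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            raise ValueError(
                f"non-biallelic or non-SNP record at {rec.CHROM}:{rec.POS}"
            )
        gt = np.asarray(rec.genotype.array())[:, :2]
        col = np.where((gt < 0).any(axis=1), MISSING, (gt > 0).sum(axis=1))
        cols.append(col.astype(np.int8))
        locus_ids.append(
            rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        )
        rad_ids.append(rec.CHROM)
        positions.append(rec.POS)
    vcf.close()
    geno = np.column_stack(cols) if cols else np.zeros((len(samples), 0), np.int8)
    return SNPMatrix(geno, samples, locus_ids, rad_ids, np.asarray(positions))


def _load_table(path) -> SNPMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    geno = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    geno = np.where(np.isnan(geno), MISSING, geno).astype(np.int8)
    return SNPMatrix(geno, [str(s) for s in df.index], [str(c) for c in df.columns])


def write_genotypes(m: SNPMatrix, path, fmt: str = "vcf") -> None:
    """Write ``m`` as a minimal VCF 4.2 (REF=A, ALT=T placeholders) or table."""
    if fmt == "table":
        df = pd.DataFrame(
            m.genotypes.astype(object), index=m.sample_ids, columns=m.locus_ids
        )
        df = df.where(m.genotypes != MISSING, "NA")
        df.to_csv(path, sep="\t", index_label="sample")
        return
    if fmt != "vcf":
        raise ValueError(f"unknown format {fmt!r}")
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for rad in dict.fromkeys(m.radlocus_ids):
            fh.write(f"##contig=<ID={rad}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        pos_of = {}
        for j, locus in enumerate(m.locus_ids):
            rad = m.radlocus_ids[j]
            if m.positions is not None:
                pos = int(m.positions[j])
            else:
                pos_of[rad] = pos_of.get(rad, 0) + 1
                pos = pos_of[rad]
            gts = "\t".join(code[int(g)] for g in m.genotypes[:, j])
            fh.write(f"{rad}\t{pos}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def load_population_map(path) -> PopulationMap:
    """CSV with columns sample,population,group,lat,lon."""
    s2p: dict[str, str] = {}
    p2g: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            s2p[row["sample"]] = row["population"]
            p2g[row["population"]] = row["group"]
            coords[row["population"]] = (float(row["lat"]), float(row["lon"]))
    return PopulationMap(s2p, p2g, coords)


def write_population_map(pmap: PopulationMap, path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "population", "group", "lat", "lon"])
        for s, p in pmap.sample_to_pop.items():
            lat, lon = pmap.pop_coords.get(p, (float("nan"), float("nan")))
            w.writerow([s, p, pmap.pop_to_group[p], lat, lon])


# ---------------------------------------------------------------------------
# Filters


def filter_within_pop_presence(
    m: SNPMatrix, pmap: PopulationMap, min_frac: float = 0.6
) -> SNPMatrix:
    """Keep loci genotyped in >= ceil(min_frac * n_p) samples of every population.

    Ties at exactly the fraction are kept ("at least").
    """
    if not 0 < min_frac <= 1:
        raise ValueError("min_frac must be in (0, 1]")
    keep = np.ones(m.n_loci, dtype=bool)
    obs = m.genotypes != MISSING
    for pop, idx in pmap.pop_indices(m).items():
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has zero samples")
        need = math.ceil(min_frac * len(idx))
        keep &= obs[idx].sum(axis=0) >= need
    return m.take_loci(keep)


def filter_sample_coverage(m: SNPMatrix, min_samples: int) -> SNPMatrix:
    """Keep loci with >= ``min_samples`` non-missing genotypes overall.

    The study-style "maximum"/"median"/"minimum" datasets correspond to
    thresholds of 85/120/160 out of 171 samples.
    """
    if min_samples > m.n_individuals:
        raise ValueError("min_samples exceeds number of individuals")
    n_called = (m.genotypes != MISSING).sum(axis=0)
    return m.take_loci(n_called >= min_samples)


def filter_maf(m: SNPMatrix, threshold: float = 0.01) -> SNPMatrix:
    """Drop loci with minor allele frequency strictly below ``threshold``.

    MAF is computed over observed (non-missing) alleles only; a locus at
    exactly the threshold is kept.
    """
    if not 0 <= threshold <= 0.5:
        raise ValueError("threshold must be in [0, 0.5]")
    return m.take_loci(m.maf() >= threshold)


def one_snp_per_radlocus(m: SNPMatrix, rule: str = "first", seed: int | None = None) -> SNPMatrix:
    """Retain exactly one SNP per RAD locus.

    ``rule='first'`` keeps the lowest-position SNP (column order when no
    positions are present); ``rule='random'`` picks uniformly under ``seed``.
    """
    groups: dict[str, list[int]] = {}
    for j, rad in enumerate(m.radlocus_ids):
        groups.setdefault(rad, []).append(j)
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    for rad, js in groups.items():
        if rule == "first":
            if m.positions is not None:
                keep.append(js[int(np.argmin(m.positions[js]))])
            else:
                keep.append(js[0])
        elif rule == "random":
            keep.append(js[rng.integers(len(js))])
        else:
            raise ValueError(f"unknown rule {rule!r}")
    keep.sort()
    return m.take_loci(np.asarray(keep))
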