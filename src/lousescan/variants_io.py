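"""Readers/writers and transformations between genotype VCF, pooled-count VCF,
and popoolation2-style sync allele-count tables, plus site filters.

The sync dialect is the popoolation2 de-facto standard: tab-separated,
1-based positions, per-population count strings in A:T:C:G:N:del order.
Internally, interval work elsewhere in the package is 0-based half-open;
sync and VCF coordinates are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

log = logging.getLogger(__name__)

SYNC_ALLELES = "ATCGN*"  # '*' = deletion, last column of a sync cell
_ALLELE_INDEX = {b: i for i, b in enumerate(SYNC_ALLELES)}


@dataclass
class SyncTable:
    """Per-site, per-population nucleotide counts (reads or allele copies).

    ``counts`` has shape (n_sites, n_pops, 6) in A,T,C,G,N,del order.
    """

    chroms: np.ndarray
    positions: np.ndarray          # 1-based
    refs: np.ndarray
    pops: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.refs = np.asarray(self.refs, dtype=object)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.positions)
        if self.counts.shape != (n, len(self.pops), 6):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n}, {len(self.pops)}, 6)"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative allele counts")
        if n and np.any(self.positions < 1):
            raise ValueError("sync positions are 1-based; position < 1 found")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def subset(self, mask: np.ndarray) -> "SyncTable":
        return SyncTable(
            self.chroms[mask], self.positions[mask], self.refs[mask],
            list(self.pops), self.counts[mask],
        )

    def select_pops(self, pops: Sequence[str]) -> "SyncTable":
        idx = [self.pops.index(p) for p in pops]
        return SyncTable(
            self.chroms, self.positions, self.refs, list(pops),
            self.counts[:, idx, :],
        )

    def depth(self) -> np.ndarray:
        """Total reads per site per population, shape (n_sites, n_pops)."""
        return self.counts.sum(axis=2)

    def biallelic_counts(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ref_counts, alt_counts, alt_bases) treating each row as biallelic.

        The alternative allele is the highest-count non-reference nucleotide
        summed over populations (the vcf2sync convention); N/del never count
        as the alternative.
        """
        totals = self.counts.sum(axis=1)            # (n_sites, 6)
        ref_idx = np.array([_ALLELE_INDEX[r] for r in self.refs], dtype=int)
        nuc = totals[:, :4].astype(float)
        rows = np.arange(self.n_sites)
        valid_ref = ref_idx < 4
        nuc[rows[valid_ref], ref_idx[valid_ref]] = -1.0  # mask ref out of argmax
        alt_idx = np.argmax(nuc, axis=1)
        alt_bases = np.array([SYNC_ALLELES[i] for i in alt_idx], dtype=object)
        ref_counts = self.counts[rows[:, None], np.arange(len(self.pops))[None, :], ref_idx[:, None]]
        alt_counts = self.counts[rows[:, None], np.arange(len(self.pops))[None, :], alt_idx[:, None]]
        return ref_counts, alt_counts, alt_bases

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele read frequency per site per population (NaN at zero depth)."""
        ref_c, alt_c, _ = self.biallelic_counts()
        tot = ref_c + alt_c
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, alt_c / np.maximum(tot, 1), np.nan)

    # -- sync text format --------------------------------------------------

    def write(self, path: "str | Path") -> None:
        with open(path, "w") as fh:
            for i in range(self.n_sites):
                cells = "\t".join(
                    ":".join(str(c) for c in self.counts[i, j])
                    for j in range(len(self.pops))
                )
                fh.write(f"{self.chroms[i]}\t{self.positions[i]}\t{self.refs[i]}\t{cells}\n")

    @classmethod
    def read(cls, path: "str | Path", pops: "Sequence[str] | None" = None) -> "SyncTable":
        chroms, positions, refs, count_rows = [], [], [], []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: expected >=4 tab-separated fields")
                chroms.append(fields[0])
                positions.append(int(fields[1]))
                refs.append(fields[2])
                try:
                    count_rows.append(
                        [[int(x) for x in cell.split(":")] for cell in fields[3:]]
                    )
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed count cell") from exc
        n_pops = len(count_rows[0]) if count_rows else 0
        pop_ids = list(pops) if pops is not None else [f"pop{i+1}" for i in range(n_pops)]
        counts = np.asarray(count_rows, dtype=np.int64).reshape(len(positions), n_pops, 6)
        return cls(np.array(chroms, dtype=object), np.array(positions),
                   np.array(refs, dtype=object), pop_ids, counts)


@dataclass
class BiallelicSite:
    chrom: str
    position: int
    ref: str
    alt: str
    ref_counts: np.ndarray   # per population
    alt_counts: np.ndarray

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")


def pool_genotypes_to_counts(
    genotypes: Iterable["tuple[str, str] | None"],
    site_id: str = "?",
) -> np.ndarray:
    """Tally diploid genotype calls into pooled allele counts (sync order).

    Each non-missing genotype contributes exactly 2 allele copies, so e.g.
    GA, GG, GA pools to 4 G and 2 A.  Missing calls (None) contribute
    nothing; non-diploid calls are rejected with the site id in the message.
    """
    counts = np.zeros(6, dtype=np.int64)
    for gt in genotypes:
        if gt is None:
            continue
        if len(gt) != 2:
            raise ValueError(f"site {site_id}: non-diploid genotype {gt!r}")
        for allele in gt:
            if allele is None:
                continue
            idx = _ALLELE_INDEX.get(allele)
            if idx is None:
                raise ValueError(f"site {site_id}: ambiguous allele {allele!r}")
            counts[idx] += 1
    return counts


def _record_sample_counts(
    rec, sample: str, alleles: Sequence[str]
) -> "np.ndarray | None":
    """6-vector of counts for one VCF sample: AD read depths if present,
    otherwise 2 copies per non-missing genotype allele."""
    counts = np.zeros(6, dtype=np.int64)
    smp = rec.samples[sample]
    ad = smp.get("AD")
    if ad is not None and not all(a is None for a in ad):
        for allele, depth in zip(alleles, ad):
            if depth is None or allele not in _ALLELE_INDEX:
                continue
            counts[_ALLELE_INDEX[allele]] += int(depth)
        return counts
    gt = smp.get("GT")
    if gt is None or all(a is None for a in gt):
        return None
    if len(gt) != 2:
        raise ValueError(
            f"site {rec.chrom}:{rec.pos}: non-diploid genotype in sample {sample}"
        )
    for ai in gt:
        if ai is None:
            continue
        allele = alleles[ai]
        if allele in _ALLELE_INDEX:
            counts[_ALLELE_INDEX[allele]] += 1
    return counts


def vcf_to_sync(
    vcf_path: "str | Path",
    pop_map: "Mapping[str, str] | None" = None,
) -> SyncTable:
    """Convert a VCF into a sync table of biallelic SNPs.

    Counts come from per-sample AD read depths when present, else from
    genotypes (2 copies per individual).  With ``pop_map`` (sample id ->
    population id), individual samples are pooled into population columns;
    otherwise each sample is its own population.  The alternative allele is
    the highest-frequency alternative summed over populations; sites that
    are monomorphic, tied between alternatives, or non-SNP are excluded.
    """
    vf = pysam.VariantFile(str(vcf_path))
    samples = list(vf.header.samples)
    if pop_map is None:
        pops = samples
        sample_pop_idx = list(range(len(samples)))
    else:
        pops = sorted(set(pop_map.values()))
        sample_pop_idx = [pops.index(pop_map[s]) for s in samples]

    chroms, positions, refs, rows = [], [], [], []
    n_indel = n_tie = n_mono = 0
    for rec in vf:
        alleles = [a.upper() for a in rec.alleles]
        if any(len(a) != 1 or a not in "ATCG" for a in alleles):
            n_indel += 1
            continue
        per_pop = np.zeros((len(pops), 6), dtype=np.int64)
        for sample, pidx in zip(samples, sample_pop_idx):
            c = _record_sample_counts(rec, sample, alleles)
            if c is not None:
                per_pop[pidx] += c
        totals = per_pop.sum(axis=0)
        ref_idx = _ALLELE_INDEX[alleles[0]]
        nonref = totals[:4].copy()
        nonref[ref_idx] = 0
        best = nonref.max()
        if best == 0 or (totals[:4] > 0).sum() < 2:
            n_mono += 1
            continue
        if (nonref == best).sum() > 1:
            n_tie += 1
            continue
        alt_idx = int(np.argmax(nonref))
        cell = np.zeros((len(pops), 6), dtype=np.int64)
        cell[:, ref_idx] = per_pop[:, ref_idx]
        cell[:, alt_idx] = per_pop[:, alt_idx]
        chroms.append(rec.chrom)
        positions.append(rec.pos)
        refs.append(alleles[0])
        rows.append(cell)
    vf.close()
    if n_indel:
        log.info("vcf_to_sync: skipped %d indel/non-SNP records", n_indel)
    if n_tie:
        log.info("vcf_to_sync: excluded %d alt-tie sites", n_tie)
    if n_mono:
        log.info("vcf_to_sync: excluded %d monomorphic sites", n_mono)
    counts = (np.asarray(rows, dtype=np.int64) if rows
              else np.zeros((0, len(pops), 6), dtype=np.int64))
    return SyncTable(np.array(chroms, dtype=object), np.array(positions, dtype=np.int64),
                     np.array(refs, dtype=object), list(pops), counts)


def filter_sites(table: SyncTable, maf_min: float = 0.10, cov_min: float = 10.0) -> SyncTable:
    """Keep sites with pooled minor-allele frequency >= maf_min and read
    depth > cov_min in at least one population.

    MAF is computed from counts summed across all populations, over the two
    highest-count nucleotides of the row.  Comparisons are >= for MAF and
    strictly > for coverage.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if cov_min < 0:
        raise ValueError("cov_min must be >= 0")
    if table.n_sites == 0:
        return table
    totals = table.counts.sum(axis=1)[:, :4].astype(float)     # nucleotides only
    top2 = np.sort(totals, axis=1)[:, -2:]
    pair_tot = top2.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(pair_tot > 0, top2[:, 0] / np.maximum(pair_tot, 1), 0.0)
    cov_ok = (table.depth() > cov_min).any(axis=1)
    return table.subset((maf >= maf_min) & cov_ok)


def space_snps(table: SyncTable, min_distance: int) -> SyncTable:
    """Greedy left-to-right thinning: keep a site only if it is more than
    ``min_distance`` bp from the previously kept site on the same chromosome.
    Input must be sorted by (chromosome, position)."""
    if min_distance < 0:
        raise ValueError("min_distance must be >= 0")
    if table.n_sites == 0 or min_distance == 0:
        return table
    for i in range(1, table.n_sites):
        if table.chroms[i] == table.chroms[i - 1] and table.positions[i] < table.positions[i - 1]:
            raise ValueError("sync table must be sorted by (chromosome, position)")
    keep = np.zeros(table.n_sites, dtype=bool)
    last_chrom, last_pos = None, None
    for i in range(table.n_sites):
        if table.chroms[i] != last_chrom or table.positions[i] - last_pos > min_distance:
            keep[i] = True
            last_chrom, last_pos = table.chroms[i], table.positions[i]
    return table.subset(keep)


# -- VCF writing (simulator output) ---------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=lousescan
{contigs}##INFO=<ID=NS,Number=1,Type=Integer,Description="Number of samples with data">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele read depths">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def write_pooled_vcf(
    path: "str | Path",
    chroms: Sequence[str],
    positions: Sequence[int],
    refs: Sequence[str],
    alts: Sequence[str],
    ref_counts: np.ndarray,      # (n_sites, n_pops) read counts
    alt_counts: np.ndarray,
    pops: Sequence[str],
    contig_sizes: "Mapping[str, int] | None" = None,
) -> None:
    """Write pooled populations as VCF samples carrying AD/DP fields."""
    contigs = "".join(
        f"##contig=<ID={c},length={l}>\n" for c, l in (contig_sizes or {}).items()
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, samples="\t".join(pops)))
        for i in range(len(positions)):
            cells = []
            for j in range(len(pops)):
                r, a = int(ref_counts[i, j]), int(alt_counts[i, j])
                cells.append(f"./.:{r},{a}:{r + a}")
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t"
                f"NS={len(pops)}\tGT:AD:DP\t" + "\t".join(cells) + "\n"
            )


def write_individual_vcf(
    path: "str | Path",
    chroms: Sequence[str],
    positions: Sequence[int],
    refs: Sequence[str],
    alts: Sequence[str],
    genotypes: np.ndarray,       # (n_sites, n_individuals) alt-allele dosage 0/1/2, -1 missing
    sample_ids: Sequence[str],
    contig_sizes: "Mapping[str, int] | None" = None,
) -> None:
    """Write per-individual diploid genotypes as GT fields."""
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    contigs = "".join(
        f"##contig=<ID={c},length={l}>\n" for c, l in (contig_sizes or {}).items()
    )
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER.format(contigs=contigs, samples="\t".join(sample_ids)))
        for i in range(len(positions)):
            cells = [gt_code[int(d)] for d in genotypes[i]]
            fh.write(
                f"{chroms[i]}\t{positions[i]}\t.\t{refs[i]}\t{alts[i]}\t.\tPASS\t"
                f"NS={len(sample_ids)}\tGT\t" + "\t".join(cells) + "\n"
            )
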