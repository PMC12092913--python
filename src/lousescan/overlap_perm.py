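"""Replicate-sharing statistics for putatively selected loci.

The permutation overlap test re-places each query interval uniformly at
random on its own chromosome (position permuted, size preserved) and asks
how often a random placement overlaps the target set at least as much as
the observed data.  The add-one estimator p = (b + 1)/(n + 1) never
returns zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass
class IntervalSet:
    """Labeled genomic intervals, 0-based half-open, with chromosome bounds."""

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    chrom_sizes: dict
    label: str = ""

    def __post_init__(self) -> None:
        self.chroms = np.asarray(self.chroms, dtype=object)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("interval columns must align")
        if np.any(self.starts < 0) or np.any(self.ends <= self.starts):
            raise ValueError("intervals must satisfy 0 <= start < end")
        for c, s, e in zip(self.chroms, self.starts, self.ends):
            size = self.chrom_sizes.get(c)
            if size is None:
                raise ValueError(f"chromosome {c!r} missing from size table")
            if e > size:
                raise ValueError(f"interval {c}:{s}-{e} exceeds chromosome size {size}")

    def __len__(self) -> int:
        return len(self.starts)

    def lengths(self) -> np.ndarray:
        return self.ends - self.starts

    def to_bed(self, path, name_prefix: str = "locus") -> None:
        with open(path, "w") as fh:
            for i, (c, s, e) in enumerate(zip(self.chroms, self.starts, self.ends), 1):
                fh.write(f"{c}\t{s}\t{e}\t{name_prefix}{i}\n")

    @classmethod
    def from_bed(cls, path, chrom_sizes: Mapping[str, int], label: str = "") -> "IntervalSet":
        chroms, starts, ends = [], [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                chroms.append(f[0]); starts.append(int(f[1])); ends.append(int(f[2]))
        return cls(np.array(chroms, dtype=object), np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64), dict(chrom_sizes), label)


def _merged_by_chrom(iv: IntervalSet) -> dict:
    """chrom -> (sorted merged starts, ends) for fast membership queries."""
    out = {}
    for c in dict.fromkeys(iv.chroms):
        m = iv.chroms == c
        s = np.sort(iv.starts[m]); order = np.argsort(iv.starts[m])
        e = iv.ends[m][order]
        ms, me = [], []
        for a, b in zip(s, e):
            if ms and a < me[-1]:
                me[-1] = max(me[-1], b)
            else:
                ms.append(a); me.append(b)
        out[c] = (np.array(ms), np.array(me))
    return out


def overlaps_any(iv: IntervalSet, target: IntervalSet) -> np.ndarray:
    """Boolean per interval of ``iv``: does it share >= 1 base with target?"""
    merged = _merged_by_chrom(target)
    hit = np.zeros(len(iv), dtype=bool)
    for i, (c, s, e) in enumerate(zip(iv.chroms, iv.starts, iv.ends)):
        if c not in merged:
            continue
        ms, me = merged[c]
        j = np.searchsorted(ms, e) - 1  # last target starting before this end
        hit[i] = j >= 0 and me[j] > s
    return hit


def count_overlaps(a: IntervalSet, b: IntervalSet) -> int:
    """Number of A-intervals overlapping at least one B-interval."""
    if a.chrom_sizes != b.chrom_sizes:
        raise ValueError("interval sets must share a chromosome-size table")
    return int(overlaps_any(a, b).sum())


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p_value: float
    n_permutations: int

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts))


def _random_placement(iv: IntervalSet, rng: np.random.Generator) -> IntervalSet:
    lengths = iv.lengths()
    sizes = np.array([iv.chrom_sizes[c] for c in iv.chroms], dtype=np.int64)
    if np.any(lengths > sizes):
        raise ValueError("interval longer than its chromosome")
    starts = rng.integers(0, sizes - lengths + 1)
    return IntervalSet(iv.chroms, starts, starts + lengths, iv.chrom_sizes, iv.label)


def permutation_overlap_test(
    a: IntervalSet,
    b: IntervalSet,
    n_permutations: int = 2000,
    seed: "int | None" = None,
    permute: str = "a",
    strict: bool = False,
) -> PermutationResult:
    """Empirical p for the overlap of A with B under random re-placement.

    Each permutation re-places every interval (of A, or of both sets with
    ``permute='both'``) uniformly on its own chromosome, size preserved;
    permuted intervals may overlap each other.  The default comparison is
    overlap >= observed with the add-one correction; ``strict`` uses >.
    """
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    if permute not in ("a", "both"):
        raise ValueError("permute must be 'a' or 'both'")
    rng = np.random.default_rng(seed)
    observed = count_overlaps(a, b)
    null = np.empty(n_permutations, dtype=np.int64)
    for i in range(n_permutations):
        pa = _random_placement(a, rng)
        pb = _random_placement(b, rng) if permute == "both" else b
        null[i] = count_overlaps(pa, pb)
    exceed = (null > observed).sum() if strict else (null >= observed).sum()
    p = (exceed + 1) / (n_permutations + 1)
    return PermutationResult(observed, null, float(p), n_permutations)


def replicate_sharing_histogram(locus_sets: Sequence[IntervalSet]) -> np.ndarray:
    """Counts of locus clusters shared by exactly 1..R replicates.

    Intervals from all replicates are clustered by transitive overlap; each
    cluster counts once, binned by how many distinct replicates contribute
    to it.  Returns an array of length R (index 0 = private loci).
    """
    r = len(locus_sets)
    if r < 2:
        raise ValueError("need >= 2 replicate locus sets")
    recs = []
    for rep, iv in enumerate(locus_sets):
        for c, s, e in zip(iv.chroms, iv.starts, iv.ends):
            recs.append((str(c), int(s), int(e), rep))
    hist = np.zeros(r, dtype=np.int64)
    recs.sort()
    i = 0
    while i < len(recs):
        c0, s0, e0, rep0 = recs[i]
        members = {rep0}
        end = e0
        j = i + 1
        while j < len(recs) and recs[j][0] == c0 and recs[j][1] < end:
            members.add(recs[j][3])
            end = max(end, recs[j][2])
            j += 1
        hist[len(members) - 1] += 1
        i = j
    return hist


def fisher_exact_overlap(
    treatment1: tuple, treatment2: tuple
) -> tuple[float, float]:
    """Two-sided Fisher exact comparison of replicate-overlap rates.

    Each treatment is (total significant sites, pairwise-overlapped
    significant sites); returns (odds ratio, p).
    """
    (tot1, sh1), (tot2, sh2) = treatment1, treatment2
    for tot, sh in ((tot1, sh1), (tot2, sh2)):
        if tot < 0 or sh < 0:
            raise ValueError("negative contingency entries")
        if sh > tot:
            raise ValueError("shared sites cannot exceed total sites")
    odds, p = stats.fisher_exact(
        [[sh1, tot1 - sh1], [sh2, tot2 - sh2]], alternative="two-sided"
    )
    return float(odds), float(p)
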