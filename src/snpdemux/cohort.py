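"""Cohort SNP diversity evaluation and genomic-region stratification.

Before pooling patients for multiplexed single-cell sequencing it pays to
check, from each patient's bulk variant calls, whether the cohort carries
enough discriminating SNPs: two patients with near-identical profiles cannot
be told apart downstream no matter how good the deconvolution is. This module
computes per-sample and patient-unique SNP counts, exclusive intersection
counts (upset-plot style), pairwise discriminatory locus counts, a bottleneck
pool selection, and a stratification of recovered SNPs by genomic region
(CDS / 5'UTR / 3'UTR / intron / intergenic).

A SNP is "present" in a sample when its genotype code is 1 or 2 — a variant
call record only exists where an ALT allele was observed — while the pairwise
discriminatory count uses every locus typed in both samples, hom-ref included.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .profiles import ProfileMatrix, VariantKey, normalize_chrom

__all__ = [
    "CohortReport",
    "RegionCounts",
    "RegionInterval",
    "AnnotationFormatError",
    "cohort_diversity",
    "select_pool",
    "annotate_regions",
    "read_region_bed",
    "read_region_gtf",
]

#: classification priority when feature intervals overlap a position
REGION_PRIORITY = ("CDS", "5'UTR", "3'UTR", "intron", "other")
REGION_CATEGORIES = REGION_PRIORITY + ("intergenic",)

_CLASS_ALIASES = {
    "cds": "CDS",
    "five_prime_utr": "5'UTR",
    "5utr": "5'UTR",
    "utr5": "5'UTR",
    "5'utr": "5'UTR",
    "three_prime_utr": "3'UTR",
    "3utr": "3'UTR",
    "utr3": "3'UTR",
    "3'utr": "3'UTR",
    "intron": "intron",
}


class AnnotationFormatError(ValueError):
    """Malformed annotation interval input."""


@dataclass(frozen=True)
class RegionInterval:
    """One annotated interval, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    feature_class: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise AnnotationFormatError(
                f"interval end < start: {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class CohortReport:
    """SNP diversity summary of a harmonized cohort.

    ``exclusive_intersections`` maps each realized non-empty subset of samples
    to the number of variants found in exactly that subset; their sum equals
    the size of the union variant set. ``pairwise_discriminatory`` counts, for
    each sample pair, the loci typed in both where the genotypes differ.
    """

    samples: list
    per_sample_counts: dict
    unique_counts: dict
    exclusive_intersections: dict
    pairwise_discriminatory: pd.DataFrame

    def intersections_frame(self) -> pd.DataFrame:
        """Exclusive intersections in upset-style long format (subset, count)."""
        rows = [
            {"subset": "&".join(sorted(sub)), "degree": len(sub), "count": n}
            for sub, n in sorted(
                self.exclusive_intersections.items(),
                key=lambda kv: (len(kv[0]), tuple(sorted(kv[0]))),
            )
        ]
        return pd.DataFrame(rows, columns=["subset", "degree", "count"])


@dataclass
class RegionCounts:
    """Variant counts per genomic region category."""

    counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        full = {cat: 0 for cat in REGION_CATEGORIES}
        full.update(self.counts)
        self.counts = full

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"region": k, "count": v} for k, v in self.counts.items()]
        )


# ----------------------------------------------------------------------
def cohort_diversity(matrix: ProfileMatrix) -> CohortReport:
    """Per-sample, unique, exclusive-intersection and discriminatory SNP counts.

    Expects a union-mode harmonized matrix of at least two samples. Variants
    are "present" where the code is 1 or 2; discriminatory counts for a pair
    use only loci typed (non-missing) in both members.
    """
    if matrix.n_samples < 2:
        raise ValueError("cohort diversity needs at least 2 samples")
    presence = (matrix.codes == 1) | (matrix.codes == 2)  # (loci, samples)
    samples = list(matrix.samples)

    per_sample = {s: int(presence[:, j].sum()) for j, s in enumerate(samples)}

    patterns, counts = np.unique(presence, axis=0, return_counts=True)
    exclusive: dict = {}
    for pat, n in zip(patterns, counts):
        members = frozenset(samples[j] for j in np.flatnonzero(pat))
        if members:
            exclusive[members] = exclusive.get(members, 0) + int(n)
    unique = {s: exclusive.get(frozenset({s}), 0) for s in samples}

    mask = matrix.mask
    disc = np.zeros((len(samples), len(samples)), dtype=np.int64)
    for i, j in itertools.combinations(range(len(samples)), 2):
        both = mask[:, i] & mask[:, j]
        n = int((both & (matrix.codes[:, i] != matrix.codes[:, j])).sum())
        disc[i, j] = disc[j, i] = n
    return CohortReport(
        samples=samples,
        per_sample_counts=per_sample,
        unique_counts=unique,
        exclusive_intersections=exclusive,
        pairwise_discriminatory=pd.DataFrame(disc, index=samples, columns=samples),
    )


def select_pool(report: CohortReport, k: int) -> list:
    """Pick k samples maximizing the minimum pairwise discriminatory count.

    The bottleneck (max-min) criterion protects the worst-separated pair,
    which is what limits demultiplexing. Exact search over all subsets for
    cohorts of up to 12 samples; greedy (best pair, then argmax-of-min
    additions) above. Ties break toward the lexicographically first subset of
    sample ids; the returned pool is id-sorted.
    """
    samples = sorted(report.samples)
    n = len(samples)
    if not 2 <= k <= n:
        raise ValueError(f"k must be in [2, {n}], got {k}")
    disc = report.pairwise_discriminatory

    def pool_min(pool: Sequence[str]) -> int:
        return min(disc.loc[a, b] for a, b in itertools.combinations(pool, 2))

    if n <= 12:
        best, best_val = None, -1
        for combo in itertools.combinations(samples, k):
            val = pool_min(combo)
            if val > best_val:
                best, best_val = combo, val
        return list(best)

    # greedy: seed with the best-separated pair, then grow by argmax-of-min
    pair, pair_val = None, -1
    for a, b in itertools.combinations(samples, 2):
        if disc.loc[a, b] > pair_val:
            pair, pair_val = (a, b), disc.loc[a, b]
    pool = list(pair)
    while len(pool) < k:
        cand_best, cand_val = None, -1
        for s in samples:
            if s in pool:
                continue
            val = min(disc.loc[s, p] for p in pool)
            if val > cand_val:
                cand_best, cand_val = s, val
        pool.append(cand_best)
    return sorted(pool)


# ----------------------------------------------------------------------
def annotate_regions(
    loci: Iterable[VariantKey], annotation: Iterable[RegionInterval]
) -> RegionCounts:
    """Classify variant positions by genomic region.

    Each variant lands in exactly one category with priority
    CDS > 5'UTR > 3'UTR > intron > other; positions outside all annotated
    intervals are intergenic.
    """
    trees: dict = {}
    for iv in annotation:
        cls = iv.feature_class if iv.feature_class in REGION_PRIORITY else "other"
        key = (normalize_chrom(iv.chrom), cls)
        trees.setdefault(key, IntervalTree()).addi(iv.start, iv.end + 1)
    counts = {cat: 0 for cat in REGION_CATEGORIES}
    for key in loci:
        for cls in REGION_PRIORITY:
            tree = trees.get((key.chrom, cls))
            if tree is not None and tree.overlaps_point(key.pos):
                counts[cls] += 1
                break
        else:
            counts["intergenic"] += 1
    return RegionCounts(counts=counts)


def _canon_class(raw: str) -> str:
    return _CLASS_ALIASES.get(raw.strip().lower(), "other")


def read_region_bed(path) -> list:
    """Read intervals from BED (0-based half-open; 4th column = feature class)."""
    intervals = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise AnnotationFormatError(
                    f"{path}:{line_no}: BED needs >= 4 columns (class in column 4)"
                )
            chrom, start, end, cls = fields[:4]
            start, end = int(start), int(end)
            if end <= start:
                raise AnnotationFormatError(
                    f"{path}:{line_no}: empty or inverted interval {start}-{end}"
                )
            # BED 0-based half-open -> 1-based inclusive
            intervals.append(
                RegionInterval(chrom, start + 1, end, _canon_class(cls))
            )
    return intervals


def read_region_gtf(path) -> list:
    """Read a minimal GTF subset (gene/exon/CDS/five_prime_utr/three_prime_utr).

    Introns, when not annotated, are derived per gene as the gene span minus
    the union of its exon spans.
    """
    keep = {"gene", "exon", "cds", "five_prime_utr", "three_prime_utr", "intron"}
    intervals: list = []
    genes: dict = {}  # gene_id -> (chrom, start, end)
    exons: dict = {}  # gene_id -> list[(start, end)]
    saw_intron = False
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise AnnotationFormatError(f"{path}:{line_no}: GTF needs 9 columns")
            chrom, _, feature, start, end = fields[0], fields[1], fields[2], fields[3], fields[4]
            feature = feature.lower()
            if feature not in keep:
                continue
            start, end = int(start), int(end)
            if end < start:
                raise AnnotationFormatError(
                    f"{path}:{line_no}: interval end < start ({start}-{end})"
                )
            gene_id = _gtf_attr(fields[8], "gene_id") or f"_line{line_no}"
            if feature == "gene":
                genes[gene_id] = (chrom, start, end)
            elif feature == "exon":
                exons.setdefault(gene_id, []).append((start, end))
            else:
                cls = _canon_class(feature) if feature != "intron" else "intron"
                saw_intron = saw_intron or feature == "intron"
                intervals.append(RegionInterval(chrom, start, end, cls))
    if not saw_intron:
        for gene_id, (chrom, gstart, gend) in genes.items():
            covered = sorted(exons.get(gene_id, []))
            pos = gstart
            for estart, eend in covered:
                if estart > pos:
                    intervals.append(
                        RegionInterval(chrom, pos, min(estart - 1, gend), "intron")
                    )
                pos = max(pos, eend + 1)
            if pos <= gend:
                intervals.append(RegionInterval(chrom, pos, gend, "intron"))
    return intervals


def _gtf_attr(attributes: str, name: str):
    for chunk in attributes.split(";"):
        chunk = chunk.strip()
        if chunk.startswith(name):
            return chunk.split(" ", 1)[1].strip().strip('"')
    return None
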