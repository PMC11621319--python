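"""VCF and table I/O.

Reads bulk per-patient VCFs and multi-column cluster VCFs (e.g. Souporcell's
``cluster_genotypes.vcf``) into :class:`~snpdemux.profiles.GenotypeProfile`
objects, harmonizes loci across files, reads Souporcell-style ``clusters.tsv``
barcode tables, and writes/reads the per-barcode assignment table.

All writers are deterministic: rows are key- or barcode-sorted and no
timestamps or hashes leak into output, so identical inputs give byte-identical
files.
"""

from __future__ import annotations

import sys
from typing import Sequence

import pandas as pd
from cyvcf2 import VCF

from .profiles import (
    MISSING,
    GenotypeProfile,
    ProfileMatrix,
    VariantKey,
)

__all__ = [
    "VcfFormatError",
    "read_vcf_profiles",
    "harmonize_loci",
    "write_vcf",
    "read_clusters_tsv",
    "write_assignment_table",
    "read_assignment_table",
]

#: statuses a barcode can carry in a Souporcell-style clusters table
CELL_STATUSES = ("singlet", "doublet", "unassigned")


class VcfFormatError(ValueError):
    """Malformed or unusable VCF / table content."""


# ----------------------------------------------------------------------
# VCF reading
# ----------------------------------------------------------------------
def _code_from_alleles(alleles: Sequence[int], alt_index: int) -> int:
    """ALT dosage code for one sample against one split-out ALT allele.

    Any ploidy is accepted; phase is ignored. All alleles equal to the ALT
    gives 2, none gives 0, a mixture gives 1; any uncalled allele gives
    MISSING.
    """
    if len(alleles) == 0 or any(a < 0 for a in alleles):
        return MISSING
    n_alt = sum(1 for a in alleles if a == alt_index)
    if n_alt == 0:
        return 0
    if n_alt == len(alleles):
        return 2
    return 1


def read_vcf_profiles(
    path: str,
    min_qual: float = 20.0,
    min_depth: int = 5,
    snps_only: bool = True,
) -> list:
    """Read a VCF into one :class:`GenotypeProfile` per sample column.

    Parameters
    ----------
    path
        Plain or bgzipped VCF with at least one sample column and GT fields.
    min_qual
        Records with ``QUAL < min_qual`` are skipped (records with missing
        QUAL, e.g. Souporcell cluster VCFs, are kept).
    min_depth
        Records with ``INFO/DP < min_depth`` are skipped when DP is present.
    snps_only
        Restrict to single-nucleotide substitutions (the default: indel keys
        are only retained when this is disabled).

    Multi-allelic records are split into one :class:`VariantKey` per ALT with
    the genotype recoded against that ALT; ``./.`` becomes MISSING, and phased
    and unphased genotypes are treated identically.
    """
    try:
        vcf = VCF(path)
    except (OSError, IOError, Exception) as exc:  # cyvcf2 raises plain Exception
        raise OSError(f"cannot read VCF file {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfFormatError(f"VCF {path!r} has no sample columns")
    if len(set(samples)) != len(samples):
        raise VcfFormatError(f"VCF {path!r} has duplicate sample names")
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise VcfFormatError(f"VCF {path!r} has no GT FORMAT field")

    profiles = [GenotypeProfile(sample_id=s) for s in samples]
    for variant in vcf:
        if variant.QUAL is not None and variant.QUAL < min_qual:
            continue
        dp = variant.INFO.get("DP")
        if dp is not None and dp < min_depth:
            continue
        ref = variant.REF.upper()
        genotypes = variant.genotypes  # [[a1, a2, phased], ...]
        for alt_index, alt in enumerate(variant.ALT, start=1):
            alt = alt.upper()
            if alt in (".", "*", "<NON_REF>") or not alt.isalpha():
                continue
            try:
                key = VariantKey.make(variant.CHROM, variant.POS, ref, alt)
            except ValueError:
                continue
            if snps_only and not key.is_snp:
                continue
            for j, gt in enumerate(genotypes):
                profiles[j].genotypes[key] = _code_from_alleles(gt[:-1], alt_index)
    return profiles


def harmonize_loci(
    profiles: Sequence[GenotypeProfile], mode: str = "union"
) -> ProfileMatrix:
    """Harmonize profiles from one or several VCFs onto a common locus set.

    ``intersection`` keeps only loci typed (or MISSING) in every profile's
    source file; ``union`` keeps all loci and marks untyped pairs MISSING.
    Chromosome names are already normalized at key construction, so ``chr1``
    and ``1`` harmonize to the same loci.
    """
    return ProfileMatrix.from_profiles(profiles, mode=mode)


# ----------------------------------------------------------------------
# VCF writing
# ----------------------------------------------------------------------
_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(matrix: ProfileMatrix, path: str) -> None:
    """Write a genotype matrix as an uncompressed VCFv4.2 file.

    One record per locus, one sample column per matrix sample; GT is the only
    FORMAT field. Output is byte-identical across runs on identical input.
    """
    chroms = []
    for key in matrix.loci:
        if key.chrom not in chroms:
            chroms.append(key.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in chroms]
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(matrix.samples)
    )
    for i, key in enumerate(matrix.loci):
        gts = "\t".join(_GT_STRINGS[int(c)] for c in matrix.codes[i])
        lines.append(
            f"{key.chrom}\t{key.pos}\t.\t{key.ref}\t{key.alt}\t100\tPASS\t.\tGT\t{gts}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# Souporcell-style barcode table
# ----------------------------------------------------------------------
def read_clusters_tsv(path) -> pd.DataFrame:
    """Read a Souporcell-format ``clusters.tsv`` into a cell-assignment table.

    Only the first three columns (barcode, status, assignment) are used;
    log-likelihood and per-cluster columns are ignored. Returns a DataFrame
    with columns ``barcode``, ``status``, ``cluster`` (nullable integer; NA
    for doublets/unassigned) and an empty ``patient`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"barcode", "status", "assignment"}
    if not required.issubset(df.columns):
        raise VcfFormatError(
            f"clusters table {path!r} lacks required columns {sorted(required)}"
        )
    bad = set(df["status"]) - set(CELL_STATUSES)
    if bad:
        raise VcfFormatError(f"unknown cell statuses {sorted(bad)} in {path!r}")
    if df["barcode"].duplicated().any():
        raise VcfFormatError(f"duplicate barcodes in {path!r}")
    cluster = pd.array(
        [
            int(a) if s == "singlet" else None
            for s, a in zip(df["status"], df["assignment"])
        ],
        dtype="Int64",
    )
    return pd.DataFrame(
        {
            "barcode": df["barcode"],
            "status": df["status"],
            "cluster": cluster,
            "patient": pd.array([None] * len(df), dtype="string"),
        }
    )


# ----------------------------------------------------------------------
# Assignment table
# ----------------------------------------------------------------------
def write_assignment_table(assignments: pd.DataFrame, path) -> None:
    """Write per-barcode labels as a TSV with columns barcode/status/cluster/patient.

    Additional metadata columns are appended after the four required ones.
    Rows are barcode-sorted; doublet rows carry ``doublet`` and unassigned
    rows ``unassigned`` in the patient field. Round-trips losslessly through
    :func:`read_assignment_table`.
    """
    if assignments is None or len(assignments) == 0:
        raise ValueError("empty assignment set: nothing to write")
    required = ["barcode", "status", "cluster", "patient"]
    missing_cols = [c for c in required if c not in assignments.columns]
    if missing_cols:
        raise ValueError(f"assignment table lacks columns {missing_cols}")
    extra = [c for c in assignments.columns if c not in required]
    out = assignments[required + extra].copy()
    out["patient"] = [
        p if (isinstance(p, str) and p) else s if s != "singlet" else ""
        for p, s in zip(out["patient"].astype("object"), out["status"])
    ]
    out = out.sort_values("barcode", kind="mergesort").reset_index(drop=True)
    handle = sys.stdout if path == "-" else open(path, "w")
    try:
        out.to_csv(handle, sep="\t", index=False, na_rep="", lineterminator="\n")
    finally:
        if handle is not sys.stdout:
            handle.close()


def read_assignment_table(path) -> pd.DataFrame:
    """Read a table written by :func:`write_assignment_table`."""
    handle = sys.stdin if path == "-" else path
    df = pd.read_csv(handle, sep="\t", dtype=str, keep_default_na=False)
    required = ["barcode", "status", "cluster", "patient"]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise VcfFormatError(f"assignment table {path!r} lacks columns {missing_cols}")
    df["cluster"] = pd.array(
        [int(c) if c != "" else None for c in df["cluster"]], dtype="Int64"
    )
    return df
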