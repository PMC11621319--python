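"""Shared fixtures: tiny hand-written VCFs and small simulated cohorts."""

import pytest

import snpdemux as sd


def write_vcf_text(path, samples, records, gt_format=True):
    """Write a minimal VCF from (chrom, pos, ref, alt, qual, info, gts) tuples."""
    lines = ["##fileformat=VCFv4.2", "##contig=<ID=1>", "##contig=<ID=2>"]
    if gt_format:
        lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">')
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    )
    for chrom, pos, ref, alt, qual, info, gts in records:
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\tGT\t" + "\t".join(gts)
        )
    path.write_text("\n".join(lines) + "\n")
    return str(path)


@pytest.fixture
def vcf_writer():
    return write_vcf_text


@pytest.fixture(scope="session")
def clean_truth():
    """Noise-free five-patient cohort (small, for unit tests)."""
    return sd.simulate_cohort(
        sd.SimConfig(n_patients=5, n_loci=1000, n_cells=200, seed=11)
    )


@pytest.fixture(scope="session")
def noisy_truth():
    """Cohort with missingness and genotype error."""
    return sd.simulate_cohort(
        sd.SimConfig(
            n_patients=5,
            n_loci=2000,
            n_cells=200,
            cluster_missing_rate=0.5,
            genotype_error_rate=0.05,
            bulk_missing_rate=0.1,
            seed=23,
        )
    )
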