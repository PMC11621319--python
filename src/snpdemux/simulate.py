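"""Synthetic multiplexed cohorts with ground truth.

Generates everything the demultiplexing pipeline consumes — per-patient bulk
VCFs, a multi-column cluster VCF, a Souporcell-style ``clusters.tsv`` and a
reference-label table — from a compact parametric model:

* per locus, an alternate-allele frequency ``p ~ Uniform(maf_range)``;
* patient genotypes drawn under Hardy–Weinberg equilibrium,
  ``P(0) = (1-p)^2``, ``P(1) = 2p(1-p)``, ``P(2) = p^2``, independently per
  patient;
* cluster profiles are the (permuted) patient genotypes degraded by
  independent per-entry missingness and a symmetric genotype error that
  replaces a typed code by one of the other two codes with equal probability;
* barcodes (deterministic 16-mers over ACGT, 10x-style) are allocated to
  patients uniformly; a configurable fraction become doublets, which only
  affects ``clusters.tsv`` statuses — cluster genotypes come from singlet
  members, as in Souporcell output.

Everything is deterministic given the seed, and the written files are
byte-identical across runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .profiles import MISSING, ProfileMatrix, VariantKey
from .vcf_io import write_vcf

__all__ = ["SimConfig", "GroundTruth", "simulate_cohort", "perturb_profiles"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a synthetic multiplexed cohort.

    Defaults describe a five-patient pool typed at 10,000 SNP loci with
    intermediate allele frequencies, half of the cluster genotypes missing
    (sparse single-cell SNP recovery) and otherwise noise-free calls; a 5%
    doublet rate is typical of droplet loading at moderate cell numbers.
    """

    n_patients: int = 5
    n_loci: int = 10_000
    maf_range: tuple = (0.05, 0.5)
    n_cells: int = 1000
    doublet_rate: float = 0.05
    cluster_missing_rate: float = 0.5
    bulk_missing_rate: float = 0.0
    genotype_error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_patients < 2:
            problems.append("n_patients must be >= 2")
        if self.n_loci < 1:
            problems.append("n_loci must be >= 1")
        if self.n_cells < 1:
            problems.append("n_cells must be >= 1")
        low, high = self.maf_range
        if not (0 < low <= high <= 0.5):
            problems.append("maf_range must satisfy 0 < low <= high <= 0.5")
        for name in ("doublet_rate", "cluster_missing_rate", "bulk_missing_rate",
                     "genotype_error_rate"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                problems.append(f"{name} must be in [0, 1)")
        if problems:
            raise ValueError("invalid SimConfig: " + "; ".join(problems))


@dataclass
class GroundTruth:
    """Simulated cohort with its generating truth.

    ``cluster_to_patient`` is a bijection from cluster ids (strings "0"...)
    onto patient ids; ``cells`` has one row per barcode with the true patient
    (or patient pair for doublets).
    """

    config: SimConfig
    bulk: ProfileMatrix
    clusters: ProfileMatrix
    cluster_to_patient: dict
    cells: pd.DataFrame
    doublet_barcodes: set

    @property
    def reference_labels(self) -> dict:
        """barcode → true patient, over singlet barcodes only."""
        singlets = self.cells[self.cells["status"] == "singlet"]
        return dict(zip(singlets["barcode"], singlets["true_patient"]))


# ----------------------------------------------------------------------
def _draw_hw_genotypes(rng: np.random.Generator, p: np.ndarray, n: int) -> np.ndarray:
    """Hardy–Weinberg genotype codes, shape (loci, n)."""
    u = rng.random((p.size, n))
    p2 = (p**2)[:, None]
    het = (2 * p * (1 - p))[:, None]
    return np.where(u < p2, 2, np.where(u < p2 + het, 1, 0)).astype(np.int8)


def _apply_noise(
    rng: np.random.Generator, codes: np.ndarray, missing_rate: float, error_rate: float
) -> np.ndarray:
    """Independent missingness then symmetric genotype error on typed entries."""
    out = codes.copy()
    if missing_rate > 0:
        out[rng.random(out.shape) < missing_rate] = MISSING
    if error_rate > 0:
        typed = out != MISSING
        flip = typed & (rng.random(out.shape) < error_rate)
        # replace by one of the two other codes with equal probability
        shift = rng.integers(1, 3, size=out.shape)
        out[flip] = (out[flip] + shift[flip]) % 3
    return out


def _make_barcodes(rng: np.random.Generator, n: int) -> list:
    seen: set = set()
    barcodes: list = []
    while len(barcodes) < n:
        draw = _BASES[rng.integers(0, 4, size=(n - len(barcodes), 16))]
        for row in draw:
            bc = "".join(row) + "-1"
            if bc not in seen:
                seen.add(bc)
                barcodes.append(bc)
    return barcodes


def simulate_cohort(config: SimConfig, out_dir: Optional[str] = None) -> GroundTruth:
    """Simulate a pooled cohort; optionally write all pipeline input files.

    When ``out_dir`` is given, writes ``bulk_<patient>.vcf`` per patient, a
    multi-column ``cluster_genotypes.vcf``, ``clusters.tsv``,
    ``reference_labels.tsv`` and ``ground_truth.json``.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    # loci on a single synthetic chromosome, unique sorted positions
    positions = np.sort(
        rng.choice(np.arange(1, config.n_loci * 50 + 1), size=config.n_loci, replace=False)
    )
    refs = rng.integers(0, 4, size=config.n_loci)
    alts = (refs + rng.integers(1, 4, size=config.n_loci)) % 4
    loci = [
        VariantKey("1", int(pos), _BASES[r], _BASES[a])
        for pos, r, a in zip(positions, refs, alts)
    ]

    p = rng.uniform(config.maf_range[0], config.maf_range[1], size=config.n_loci)
    patient_ids = [f"P{i + 1}" for i in range(config.n_patients)]
    genotypes = _draw_hw_genotypes(rng, p, config.n_patients)

    bulk_codes = _apply_noise(rng, genotypes, config.bulk_missing_rate, 0.0)
    bulk = ProfileMatrix(loci=list(loci), samples=list(patient_ids), codes=bulk_codes)

    # clusters: random bijection onto patients, then degradation
    perm = rng.permutation(config.n_patients)
    cluster_ids = [str(j) for j in range(config.n_patients)]
    cluster_to_patient = {cid: patient_ids[perm[j]] for j, cid in enumerate(cluster_ids)}
    cluster_codes = _apply_noise(
        rng,
        genotypes[:, perm],
        config.cluster_missing_rate,
        config.genotype_error_rate,
    )
    clusters = ProfileMatrix(
        loci=list(loci), samples=list(cluster_ids), codes=cluster_codes
    )

    # barcodes
    barcodes = _make_barcodes(rng, config.n_cells)
    is_doublet = rng.random(config.n_cells) < config.doublet_rate
    cell_cluster = rng.integers(0, config.n_patients, size=config.n_cells)
    patient_of = {int(cid): pid for cid, pid in
                  ((int(c), cluster_to_patient[c]) for c in cluster_ids)}
    rows = []
    for bc, dbl, cl in zip(barcodes, is_doublet, cell_cluster):
        if dbl:
            other = int((cl + rng.integers(1, config.n_patients)) % config.n_patients)
            pair = sorted((int(cl), other))
            rows.append(
                {
                    "barcode": bc,
                    "status": "doublet",
                    "assignment": f"{pair[0]}/{pair[1]}",
                    "cluster": None,
                    "true_patient": f"{patient_of[pair[0]]}/{patient_of[pair[1]]}",
                }
            )
        else:
            rows.append(
                {
                    "barcode": bc,
                    "status": "singlet",
                    "assignment": str(int(cl)),
                    "cluster": int(cl),
                    "true_patient": patient_of[int(cl)],
                }
            )
    cells = pd.DataFrame(rows)
    cells["cluster"] = pd.array(cells["cluster"], dtype="Int64")

    truth = GroundTruth(
        config=config,
        bulk=bulk,
        clusters=clusters,
        cluster_to_patient=cluster_to_patient,
        cells=cells,
        doublet_barcodes=set(cells.loc[cells["status"] == "doublet", "barcode"]),
    )
    if out_dir is not None:
        write_truth_files(truth, out_dir)
    return truth


def write_truth_files(truth: GroundTruth, out_dir) -> None:
    """Write all pipeline input files plus the ground-truth JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for j, pid in enumerate(truth.bulk.samples):
        single = ProfileMatrix(
            loci=list(truth.bulk.loci),
            samples=[pid],
            codes=truth.bulk.codes[:, [j]].copy(),
        )
        write_vcf(single, out / f"bulk_{pid}.vcf")
    write_vcf(truth.clusters, out / "cluster_genotypes.vcf")

    sc = truth.cells.copy()
    # plausible Souporcell-style log-likelihood columns (constant, ignored by readers)
    sc["log_prob_singleton"] = np.where(sc["status"] == "singlet", -10.0, -300.0)
    sc["log_prob_doublet"] = np.where(sc["status"] == "doublet", -10.0, -300.0)
    sc[["barcode", "status", "assignment", "log_prob_singleton", "log_prob_doublet"]].to_csv(
        out / "clusters.tsv", sep="\t", index=False, lineterminator="\n"
    )

    singlets = sc[sc["status"] == "singlet"]
    singlets[["barcode", "true_patient"]].rename(
        columns={"true_patient": "label"}
    ).to_csv(out / "reference_labels.tsv", sep="\t", index=False, lineterminator="\n")

    gt = {
        "config": {**asdict(truth.config), "maf_range": list(truth.config.maf_range)},
        "cluster_to_patient": truth.cluster_to_patient,
        "doublet_barcodes": sorted(truth.doublet_barcodes),
    }
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
        fh.write("\n")


# ----------------------------------------------------------------------
def perturb_profiles(
    truth: GroundTruth,
    swap_patients: tuple,
    n_diff_loci: int = 0,
    out_dir: Optional[str] = None,
) -> GroundTruth:
    """Make one patient a near-copy of another to stress SNP heterogeneity.

    Overwrites patient ``swap_patients[1]``'s genotypes with a copy of
    ``swap_patients[0]``'s except at ``n_diff_loci`` loci (kept from the
    original), then rebuilds the cluster profiles from the modified patient
    genotypes with freshly seeded (deterministic) missingness and error.
    Other patients' data — and their written files — are unchanged.
    """
    a, b = swap_patients
    if a == b:
        raise ValueError("swap_patients must name two distinct patients")
    samples = truth.bulk.samples
    if a not in samples or b not in samples:
        raise ValueError(f"unknown patient in {swap_patients!r}")
    ia, ib = samples.index(a), samples.index(b)
    cfg = truth.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(901, ia, ib)))

    bulk_codes = truth.bulk.codes.copy()
    keep = np.zeros(cfg.n_loci, dtype=bool)
    if n_diff_loci > 0:
        keep[rng.choice(cfg.n_loci, size=min(n_diff_loci, cfg.n_loci), replace=False)] = True
    bulk_codes[~keep, ib] = bulk_codes[~keep, ia]
    bulk = ProfileMatrix(loci=list(truth.bulk.loci), samples=list(samples),
                         codes=bulk_codes)

    # rebuild the cluster carrying patient b from the perturbed genotypes
    cluster_codes = truth.clusters.codes.copy()
    inv = {pid: cid for cid, pid in truth.cluster_to_patient.items()}
    jb = truth.clusters.samples.index(inv[b])
    cluster_codes[:, jb] = _apply_noise(
        rng,
        bulk_codes[:, [ib]],
        cfg.cluster_missing_rate,
        cfg.genotype_error_rate,
    )[:, 0]
    clusters = ProfileMatrix(
        loci=list(truth.clusters.loci),
        samples=list(truth.clusters.samples),
        codes=cluster_codes,
    )
    new_truth = GroundTruth(
        config=cfg,
        bulk=bulk,
        clusters=clusters,
        cluster_to_patient=dict(truth.cluster_to_patient),
        cells=truth.cells.copy(),
        doublet_barcodes=set(truth.doublet_barcodes),
    )
    if out_dir is not None:
        write_truth_files(new_truth, out_dir)
    return new_truth
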