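"""Cluster-to-patient assignment.

The core demultiplexing step: compare each genotype-deconvoluted single-cell
cluster against each patient's bulk SNP profile with a *normalized hamming
distance* — the fraction of co-typed loci at which the two genotype codes
disagree — and solve the one-to-one cluster→patient assignment that minimizes
the total distance with the Kuhn–Munkres (Hungarian) algorithm. Per-cell
labels are then propagated to singlet barcodes; doublet and unassigned
barcodes pass through untouched.

Normalization is per pair (division by the pair's co-typed locus count), so a
cluster with heavy missingness is not artificially close to every patient.
Pairs supported by fewer than ``min_support`` co-typed loci are flagged
invalid and enter the assignment with a finite penalty larger than any valid
distance, keeping the problem solvable while making such pairings last-resort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .profiles import ProfileMatrix, align_union

__all__ = [
    "DistanceMatrix",
    "AssignmentResult",
    "AssignmentError",
    "hamming_matrix",
    "kuhn_munkres",
    "assign_cells",
    "assign_to_groups",
    "INVALID_PENALTY",
]

#: cost substituted for pairs with insufficient co-typed support; larger than
#: any valid normalized distance (which lies in [0, 1]) but finite so the
#: assignment stays solvable.
INVALID_PENALTY = 2.0


class AssignmentError(ValueError):
    """Assignment is impossible or ill-posed for the given inputs."""


@dataclass
class DistanceMatrix:
    """Clusters × patients normalized hamming distances with per-pair support.

    ``dist[c, p]`` is NaN where ``support[c, p] < min_support`` (flagged in
    ``valid``); elsewhere it lies in [0, 1].
    """

    clusters: list
    patients: list
    dist: np.ndarray
    support: np.ndarray
    valid: np.ndarray
    min_support: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dist, index=self.clusters, columns=self.patients)

    def support_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.support, index=self.clusters, columns=self.patients)


@dataclass
class AssignmentResult:
    """Injective cluster → patient mapping with audit quantities.

    ``margin`` is the second-best distance in a cluster's row minus the
    chosen distance. Kuhn–Munkres optimizes the *total* cost, not per-row
    minima, so a margin can be negative; it is reported as-is so users can
    audit rows where the global optimum overrides the row argmin.
    """

    mapping: dict
    per_cluster_distance: dict
    margin: dict
    total_cost: float
    unmatched_patients: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cluster": c,
                "patient": p,
                "distance": self.per_cluster_distance[c],
                "margin": self.margin[c],
            }
            for c, p in self.mapping.items()
        ]
        return pd.DataFrame(rows)


# ----------------------------------------------------------------------
def hamming_matrix(
    cluster_profiles: ProfileMatrix,
    bulk_profiles: ProfileMatrix,
    min_support: int = 50,
    dosage_weighted: bool = False,
) -> DistanceMatrix:
    """Normalized hamming distances between cluster and patient profiles.

    For each (cluster, patient) pair the distance is computed over loci where
    both are typed: ``(# loci with unequal codes) / (# co-typed loci)``. With
    ``dosage_weighted=True`` a mismatch instead costs ``|code_c - code_p| / 2``
    (so het vs hom counts half of hom-ref vs hom-alt); the default is plain
    hamming semantics where any inequality costs 1.

    Raises
    ------
    AssignmentError
        If the two matrices share no loci at all, or if some cluster has
        fewer than ``min_support`` co-typed loci against *every* patient.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    if not set(cluster_profiles.loci) & set(bulk_profiles.loci):
        raise AssignmentError("cluster and bulk profiles share no loci")
    cm, bm = align_union(cluster_profiles, bulk_profiles)

    c_codes, b_codes = cm.codes, bm.codes
    c_mask, b_mask = cm.mask, bm.mask
    n_c, n_p = cm.n_samples, bm.n_samples
    support = np.zeros((n_c, n_p), dtype=np.int64)
    dist = np.full((n_c, n_p), np.nan)
    for i in range(n_c):
        co = c_mask[:, i, None] & b_mask  # (loci, patients)
        support[i] = co.sum(axis=0)
        if dosage_weighted:
            cost = np.abs(
                c_codes[:, i, None].astype(np.int16) - b_codes.astype(np.int16)
            ) / 2.0
        else:
            cost = (c_codes[:, i, None] != b_codes).astype(float)
        mism = np.where(co, cost, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist[i] = np.where(support[i] > 0, mism / support[i], np.nan)

    valid = support >= min_support
    dist[~valid] = np.nan
    dead = ~valid.any(axis=1)
    if dead.any():
        names = [cm.samples[i] for i in np.flatnonzero(dead)]
        raise AssignmentError(
            f"cluster(s) {names} have < {min_support} co-typed loci against "
            "every patient; lower --min-support or check locus harmonization"
        )
    return DistanceMatrix(
        clusters=list(cm.samples),
        patients=list(bm.samples),
        dist=dist,
        support=support,
        valid=valid,
        min_support=min_support,
    )


def kuhn_munkres(dm: DistanceMatrix, penalty: float = INVALID_PENALTY) -> AssignmentResult:
    """Minimum-total-cost injective cluster → patient assignment.

    Invalid (under-supported) cells enter with the finite ``penalty`` cost.
    Requires no more clusters than patients; with more patients than clusters
    the unmatched patients are listed in the result. Ties are resolved
    deterministically (lowest-index solution of the solver).
    """
    n_c, n_p = len(dm.clusters), len(dm.patients)
    if n_c > n_p:
        raise AssignmentError(
            f"{n_c} clusters but only {n_p} patients: every cluster needs a "
            "distinct patient — check the pool composition or the cluster VCF"
        )
    cost = np.where(np.isnan(dm.dist), penalty, dm.dist)
    rows, cols = linear_sum_assignment(cost)
    mapping = {dm.clusters[r]: dm.patients[c] for r, c in zip(rows, cols)}
    per_dist, margin = {}, {}
    for r, c in zip(rows, cols):
        chosen = dm.dist[r, c]
        per_dist[dm.clusters[r]] = float(chosen) if not np.isnan(chosen) else float("nan")
        others = np.delete(dm.dist[r], c)
        others = others[~np.isnan(others)]
        if np.isnan(chosen) or others.size == 0:
            margin[dm.clusters[r]] = float("nan")
        else:
            margin[dm.clusters[r]] = float(others.min() - chosen)
    matched = set(cols)
    return AssignmentResult(
        mapping=mapping,
        per_cluster_distance=per_dist,
        margin=margin,
        total_cost=float(cost[rows, cols].sum()),
        unmatched_patients=[p for j, p in enumerate(dm.patients) if j not in matched],
    )


# ----------------------------------------------------------------------
def assign_cells(result: AssignmentResult, cells: pd.DataFrame) -> pd.DataFrame:
    """Propagate the cluster → patient mapping to singlet barcodes.

    Doublet and unassigned rows pass through with their status recorded in
    the patient field; the output has exactly the input's rows.
    """
    mapping = {str(k): v for k, v in result.mapping.items()}
    out = cells.copy()
    patients = []
    for status, cluster in zip(out["status"], out["cluster"]):
        if status == "singlet":
            key = str(int(cluster)) if pd.notna(cluster) else None
            if key is None or key not in mapping:
                raise AssignmentError(
                    f"singlet cluster {cluster!r} absent from the assignment mapping"
                )
            patients.append(mapping[key])
        else:
            patients.append(status)
    out["patient"] = pd.array(patients, dtype="string")
    return out


def assign_to_groups(
    cells: pd.DataFrame, reference: Mapping[str, str]
) -> dict:
    """Assign clusters to known groups (e.g. reference cell clusters or tags).

    Builds the clusters × groups contingency table over singlet barcodes
    shared with ``reference`` and solves the injective mapping maximizing the
    total overlap with the same Kuhn–Munkres core (negated counts). With more
    clusters than groups, the surplus clusters stay unmapped and a warning is
    issued; ties are resolved by index order and flagged with a warning.
    """
    singlets = cells[cells["status"] == "singlet"]
    shared = singlets[singlets["barcode"].isin(reference.keys())]
    if shared.empty:
        raise AssignmentError("no singlet barcodes shared with the reference labels")
    groups = pd.Series(
        [reference[b] for b in shared["barcode"]], index=shared.index, name="group"
    )
    table = pd.crosstab(shared["cluster"].astype(int), groups)
    counts = table.to_numpy()
    rows, cols = linear_sum_assignment(-counts)
    mapping = {int(table.index[r]): str(table.columns[c]) for r, c in zip(rows, cols)}
    if len(mapping) < len(table.index):
        unmapped = sorted(set(table.index.astype(int)) - set(mapping))
        warnings.warn(
            f"more clusters than groups: cluster(s) {unmapped} left unmapped",
            stacklevel=2,
        )
    # flag ties: a row whose chosen count is matched by another column admits
    # an alternative optimum; the solver's index-order choice stands
    for r, c in zip(rows, cols):
        alt = [j for j in range(counts.shape[1]) if j != c and counts[r, j] == counts[r, c]]
        if alt:
            warnings.warn(
                f"overlap tie for cluster {table.index[r]}; resolved by index order",
                stacklevel=2,
            )
            break
    return mapping
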