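"""Benchmarking of demultiplexing assignments.

Precision/recall of per-cell patient labels against reference labels, the
bulk-SNP downsampling experiment (re-running the full match with random locus
subsets), the paired Wilcoxon signed-rank comparison of two method/metric
vectors, and doublet-set overlap analysis.

Definitions (per-cell, over barcodes carrying a reference label):

* TP — predicted label equals the reference label;
* FP — predicted label is any *valid* reference label value, minus TP;
* FN — reference-labeled cells minus TP (doublet/unassigned predictions are
  not valid label values and therefore contribute to FN only);
* precision = TP/(TP+FP), recall = TP/(TP+FN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assign import assign_cells, hamming_matrix, kuhn_munkres
from .profiles import ProfileMatrix

__all__ = [
    "BenchmarkResult",
    "DownsampleRun",
    "WilcoxonComparison",
    "precision_recall",
    "assigned_fraction",
    "downsample_experiment",
    "compare_runs",
    "doublet_overlap",
]


@dataclass
class BenchmarkResult:
    """TP/FP/FN counts and derived precision/recall for one method."""

    method: str
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    assigned_fraction: float = float("nan")

    def to_row(self) -> dict:
        return {
            "method": self.method,
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "assigned_fraction": self.assigned_fraction,
        }


@dataclass
class DownsampleRun:
    """One (fraction, replicate) run of the downsampling experiment."""

    fraction: float
    replicate: int
    seed: int
    n_loci: int
    assigned_cells: int
    precision: float
    recall: float
    mean_margin: float
    failed: bool = False
    failure_reason: str = ""


@dataclass
class WilcoxonComparison:
    """Two-sided paired signed-rank test result.

    Zero-difference pairs are dropped (reported in ``n_dropped``); when every
    pair is zero the test is degenerate and ``p = 1`` is reported with
    ``all_zero`` set rather than raising.
    """

    statistic: float
    pvalue: float
    n_pairs: int
    n_dropped: int
    all_zero: bool


# ----------------------------------------------------------------------
def precision_recall(
    predicted: Mapping[str, str],
    reference: Mapping[str, str],
    method: str = "",
    assigned_frac: float = float("nan"),
) -> BenchmarkResult:
    """Per-cell precision and recall of predicted labels against a reference.

    ``reference`` must cover all evaluated barcodes; ``predicted`` may omit
    barcodes (unassigned). When nothing is assigned, precision is undefined
    and reported as NaN.
    """
    if not reference:
        raise ValueError("reference labels are empty")
    valid_labels = set(reference.values())
    tp = fp = 0
    for bc, ref_label in reference.items():
        pred = predicted.get(bc)
        if pred is None or pred not in valid_labels:
            continue
        if pred == ref_label:
            tp += 1
        else:
            fp += 1
    fn = len(reference) - tp
    precision = tp / (tp + fp) if tp + fp > 0 else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return BenchmarkResult(
        method=method,
        tp=tp,
        fp=fp,
        fn=fn,
        precision=precision,
        recall=recall,
        assigned_fraction=assigned_frac,
    )


def assigned_fraction(cells: pd.DataFrame) -> float:
    """Fraction of all cells assigned: patient-assigned singlets plus doublet calls."""
    if len(cells) == 0:
        return float("nan")
    singlet_assigned = (
        (cells["status"] == "singlet")
        & cells["patient"].notna()
        & ~cells["patient"].isin(["doublet", "unassigned", ""])
    ).sum()
    doublets = (cells["status"] == "doublet").sum()
    return float(singlet_assigned + doublets) / len(cells)


# ----------------------------------------------------------------------
def _run_seed(master: int, fraction_index: int, replicate: int) -> np.random.SeedSequence:
    # keyed substreams: adding fractions or replicates never perturbs others
    return np.random.SeedSequence(master, spawn_key=(fraction_index, replicate))


def downsample_experiment(
    bulk: ProfileMatrix,
    cluster_profiles: ProfileMatrix,
    cells: pd.DataFrame,
    reference: Mapping[str, str],
    fractions: Sequence[float] = (1.0, 0.8, 0.6, 0.4, 0.2),
    reps: int = 10,
    seed: int = 0,
    min_support: int = 50,
) -> list:
    """Re-run the full assignment on random subsets of the bulk SNP loci.

    For each fraction × replicate a uniform random locus subset (without
    replacement, size ``round(fraction * n_loci)``) is drawn from the bulk
    matrix, then hamming distance → Kuhn–Munkres → per-cell propagation →
    precision/recall are recomputed. Fraction 1.0 uses all loci, so its
    replicates are identical by construction. A fraction leaving fewer than
    ``min_support`` usable loci is recorded as a failed run, never silently
    dropped. RNG substreams are keyed by (fraction index, replicate).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if any(not (0 < f <= 1) for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    runs: list = []
    n_loci = bulk.n_loci
    for fi, fraction in enumerate(fractions):
        n_sub = int(round(fraction * n_loci))
        for rep in range(reps):
            ss = _run_seed(seed, fi, rep)
            rng = np.random.default_rng(ss)
            run_seed = int(rng.integers(0, 2**31 - 1))
            if fraction >= 1.0:
                sub = bulk
            else:
                idx = rng.choice(n_loci, size=n_sub, replace=False)
                sub = bulk.select_loci(idx)
            try:
                dm = hamming_matrix(cluster_profiles, sub, min_support=min_support)
                result = kuhn_munkres(dm)
                assigned = assign_cells(result, cells)
                pred = dict(zip(assigned["barcode"], assigned["patient"]))
                br = precision_recall(
                    pred, reference, assigned_frac=assigned_fraction(assigned)
                )
                margins = [m for m in result.margin.values() if not math.isnan(m)]
                runs.append(
                    DownsampleRun(
                        fraction=fraction,
                        replicate=rep,
                        seed=run_seed,
                        n_loci=sub.n_loci,
                        assigned_cells=int(round(br.assigned_fraction * len(cells))),
                        precision=br.precision,
                        recall=br.recall,
                        mean_margin=float(np.mean(margins)) if margins else float("nan"),
                    )
                )
            except ValueError as exc:
                runs.append(
                    DownsampleRun(
                        fraction=fraction,
                        replicate=rep,
                        seed=run_seed,
                        n_loci=n_sub,
                        assigned_cells=0,
                        precision=float("nan"),
                        recall=float("nan"),
                        mean_margin=float("nan"),
                        failed=True,
                        failure_reason=str(exc),
                    )
                )
    return runs


def runs_to_frame(runs: Iterable[DownsampleRun]) -> pd.DataFrame:
    """Tidy table (method-agnostic) of downsampling runs."""
    return pd.DataFrame(
        [
            {
                "fraction": r.fraction,
                "replicate": r.replicate,
                "seed": r.seed,
                "n_loci": r.n_loci,
                "assigned_cells": r.assigned_cells,
                "precision": r.precision,
                "recall": r.recall,
                "mean_margin": r.mean_margin,
                "failed": r.failed,
                "failure_reason": r.failure_reason,
            }
            for r in runs
        ]
    )


# ----------------------------------------------------------------------
def compare_runs(a: Sequence[float], b: Sequence[float]) -> WilcoxonComparison:
    """Two-sided paired Wilcoxon signed-rank test on per-replicate differences.

    Inputs must be paired (same fraction × replicate order) and of equal
    length >= 5. Zero differences are dropped; an all-zero difference vector
    yields a flagged ``p = 1`` instead of an exception.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 5:
        raise ValueError("need at least 5 pairs for the signed-rank test")
    diffs = a - b
    nonzero = diffs != 0
    n_dropped = int((~nonzero).sum())
    if not nonzero.any():
        return WilcoxonComparison(
            statistic=float("nan"),
            pvalue=1.0,
            n_pairs=a.size,
            n_dropped=n_dropped,
            all_zero=True,
        )
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return WilcoxonComparison(
        statistic=float(stat),
        pvalue=float(p),
        n_pairs=a.size,
        n_dropped=n_dropped,
        all_zero=False,
    )


# ----------------------------------------------------------------------
def doublet_overlap(
    method_doublets: Mapping[str, set],
    reference_doublets: set,
) -> tuple:
    """Doublet-call overlap with a reference set, plus pairwise Jaccard.

    Returns ``(overlaps, jaccard)`` where ``overlaps[method]`` is
    ``|method ∩ reference| / |reference|`` and ``jaccard`` is the full
    method × method Jaccard table.
    """
    if not reference_doublets:
        raise ValueError("reference doublet set is empty")
    ref = set(reference_doublets)
    overlaps = {
        m: len(set(s) & ref) / len(ref) for m, s in method_doublets.items()
    }
    methods = list(method_doublets)
    jac = np.zeros((len(methods), len(methods)))
    for i, mi in enumerate(methods):
        si = set(method_doublets[mi])
        for j, mj in enumerate(methods):
            sj = set(method_doublets[mj])
            union = si | sj
            jac[i, j] = len(si & sj) / len(union) if union else 1.0
    return overlaps, pd.DataFrame(jac, index=methods, columns=methods)
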