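"""Core genotype containers.

Genotypes are stored as diploid ALT-allele dosage codes:

* ``0`` — homozygous reference,
* ``1`` — heterozygous (at least one ALT copy together with another allele),
* ``2`` — homozygous alternate,
* :data:`MISSING` (``-1``) — the locus was typed in the source file but the
  genotype could not be called (``./.``).

A locus that is *absent* from a sample's source file is distinct from a
:data:`MISSING` call; :class:`GenotypeProfile` keeps MISSING loci as explicit
dictionary entries so that intersection-mode harmonization can distinguish
"typed but uncalled" from "never typed".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "VariantKey",
    "GenotypeProfile",
    "ProfileMatrix",
    "NoSharedLociError",
    "normalize_chrom",
]

MISSING: int = -1
_VALID_CODES = frozenset({0, 1, 2, MISSING})


class NoSharedLociError(ValueError):
    """Raised when intersection-mode harmonization yields no shared loci."""


def normalize_chrom(name: str) -> str:
    """Strip a leading ``chr`` prefix (case-insensitive) from a chromosome name.

    References with and without the ``chr`` prefix (e.g. GRCh38 from different
    pipelines) must compare equal.
    """
    name = str(name).strip()
    if name[:3].lower() == "chr":
        name = name[3:]
    return name


class VariantKey(NamedTuple):
    """Canonical identity of one biallelic REF→ALT substitution.

    Multi-allelic VCF records are split into one key per ALT allele before a
    key is ever constructed. Keys order lexicographically by
    ``(chrom, pos, ref, alt)`` which makes every downstream output
    deterministic.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        pos = int(pos)
        ref = str(ref).upper()
        alt = str(alt).upper()
        if pos < 1:
            raise ValueError(f"variant position must be >= 1, got {pos}")
        if not ref or not alt:
            raise ValueError("REF and ALT alleles must be non-empty")
        if ref == alt:
            raise ValueError(f"REF and ALT must differ, got {ref!r} at pos {pos}")
        return cls(normalize_chrom(chrom), pos, ref, alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class GenotypeProfile:
    """One sample's (patient or cluster) genotype map.

    Parameters
    ----------
    sample_id
        Unique sample name within any collection of profiles.
    genotypes
        Mapping from :class:`VariantKey` to a code in ``{0, 1, 2, MISSING}``.
    """

    sample_id: str
    genotypes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.genotypes.values() if c not in _VALID_CODES}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)} in {self.sample_id}")

    @property
    def loci(self) -> set:
        """All loci typed in this profile's source (including MISSING calls)."""
        return set(self.genotypes)

    def __len__(self) -> int:
        return len(self.genotypes)


@dataclass
class ProfileMatrix:
    """Harmonized loci × samples genotype table with explicit missingness.

    ``codes`` is an ``(n_loci, n_samples)`` int8 array over
    ``{0, 1, 2, MISSING}``; the boolean ``mask`` (``codes != MISSING``) marks
    observed entries. Loci are sorted by :class:`VariantKey` order and both
    loci and samples are unique.
    """

    loci: list
    samples: list
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.loci), len(self.samples)):
            raise ValueError(
                f"codes shape {self.codes.shape} != "
                f"({len(self.loci)}, {len(self.samples)})"
            )
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample ids")
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("duplicate loci")
        if any(self.loci[i] > self.loci[i + 1] for i in range(len(self.loci) - 1)):
            order = np.array(sorted(range(len(self.loci)), key=self.loci.__getitem__))
            self.loci = [self.loci[i] for i in order]
            self.codes = self.codes[order]
        bad = set(np.unique(self.codes)) - {0, 1, 2, MISSING}
        if bad:
            raise ValueError(f"invalid genotype codes {sorted(bad)}")

    # ------------------------------------------------------------------
    @property
    def mask(self) -> np.ndarray:
        """Boolean (loci × samples) table, True where a genotype was observed."""
        return self.codes != MISSING

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, sample_id: str) -> int:
        return self.samples.index(sample_id)

    # ------------------------------------------------------------------
    @classmethod
    def from_profiles(
        cls, profiles: Sequence[GenotypeProfile], mode: str = "union"
    ) -> "ProfileMatrix":
        """Harmonize a list of profiles onto a common, sorted locus set.

        ``mode="intersection"`` keeps only loci present (typed or MISSING) in
        every profile's source; ``mode="union"`` keeps all loci and marks
        untyped sample/locus pairs MISSING.
        """
        if len(profiles) < 2:
            raise ValueError("harmonization requires at least 2 profiles")
        ids = [p.sample_id for p in profiles]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample ids among profiles: {ids}")
        if mode not in ("union", "intersection"):
            raise ValueError(f"unknown harmonization mode {mode!r}")

        key_sets = [p.loci for p in profiles]
        if mode == "intersection":
            keys = set.intersection(*key_sets)
            if not keys:
                raise NoSharedLociError(
                    "no shared loci across profiles in intersection mode"
                )
        else:
            keys = set.union(*key_sets)
        loci = sorted(keys)
        index = {k: i for i, k in enumerate(loci)}
        codes = np.full((len(loci), len(profiles)), MISSING, dtype=np.int8)
        for j, prof in enumerate(profiles):
            for key, code in prof.genotypes.items():
                i = index.get(key)
                if i is not None:
                    codes[i, j] = code
        return cls(loci=loci, samples=list(ids), codes=codes)

    def to_profiles(self) -> list:
        """Inverse of :meth:`from_profiles` (every locus typed-or-missing in all)."""
        return [
            GenotypeProfile(
                sample_id=s,
                genotypes={k: int(c) for k, c in zip(self.loci, self.codes[:, j])},
            )
            for j, s in enumerate(self.samples)
        ]

    def select_loci(self, indices: np.ndarray) -> "ProfileMatrix":
        """Row subset by integer locus indices (re-sorted by key order)."""
        indices = np.sort(np.asarray(indices, dtype=int))
        return ProfileMatrix(
            loci=[self.loci[i] for i in indices],
            samples=list(self.samples),
            codes=self.codes[indices].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index([str(k) for k in self.loci], name="locus")
        return pd.DataFrame(self.codes, index=idx, columns=self.samples)


def align_union(a: ProfileMatrix, b: ProfileMatrix) -> tuple:
    """Align two matrices onto the sorted union of their loci.

    Loci absent from one matrix become MISSING there. Returns the pair of
    re-indexed matrices over identical locus lists.
    """
    keys = sorted(set(a.loci) | set(b.loci))
    index = {k: i for i, k in enumerate(keys)}

    def _expand(m: ProfileMatrix) -> ProfileMatrix:
        codes = np.full((len(keys), m.n_samples), MISSING, dtype=np.int8)
        rows = np.array([index[k] for k in m.loci], dtype=int)
        codes[rows] = m.codes
        return ProfileMatrix(loci=list(keys), samples=list(m.samples), codes=codes)

    return _expand(a), _expand(b)
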