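"""Applicability domain: where model predictions can be trusted.

A query is in-domain iff (a) every physicochemical descriptor lies within
the [min, max] range observed in training (optionally widened by a fractional
tolerance of the range), and (b) the fraction of the query's fingerprint
on-bits that were ever set by a training compound is at least the coverage
threshold.  Out-of-domain predictions are not suppressed elsewhere in the
pipeline — they are annotated as a warning, mirroring how practitioners
treat domain violations as advice rather than a hard veto.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import CompoundRecord
from .descriptors import PHYSCHEM_NAMES, Featurizer, compute_fingerprint, compute_physchem


@dataclass
class ApplicabilityDomain:
    names: tuple[str, ...]
    mins: np.ndarray
    maxs: np.ndarray
    train_bits: frozenset[int]
    n_bits: int
    radius: int
    tolerance: float = 0.0  # fraction of each descriptor's training range
    coverage_threshold: float = 0.95

    @classmethod
    def fit(
        cls,
        train_records: list[CompoundRecord],
        radius: int = 2,
        n_bits: int = 1024,
        tolerance: float = 0.0,
        coverage_threshold: float = 0.95,
    ) -> "ApplicabilityDomain":
        """Learn descriptor ranges and fingerprint-bit coverage from training rows only."""
        phys = np.array([compute_physchem(r).physchem for r in train_records])
        bits: set[int] = set()
        for r in train_records:
            bits |= compute_fingerprint(r, radius=radius, n_bits=n_bits).bits
        return cls(
            names=PHYSCHEM_NAMES,
            mins=phys.min(axis=0),
            maxs=phys.max(axis=0),
            train_bits=frozenset(bits),
            n_bits=n_bits,
            radius=radius,
            tolerance=tolerance,
            coverage_threshold=coverage_threshold,
        )

    def in_domain(self, record: CompoundRecord) -> tuple[bool, list[str]]:
        """Return (verdict, reasons); reasons list every violated condition."""
        phys = compute_physchem(record).physchem
        span = self.maxs - self.mins
        lo = self.mins - self.tolerance * span
        hi = self.maxs + self.tolerance * span
        reasons = []
        for name, v, a, b in zip(self.names, phys, lo, hi):
            if v < a or v > b:
                reasons.append(
                    f"{name}={v:.3g} outside training range [{a:.3g}, {b:.3g}]"
                )
        fp = compute_fingerprint(record, radius=self.radius, n_bits=self.n_bits)
        if fp.bits:
            coverage = len(fp.bits & self.train_bits) / len(fp.bits)
            if coverage < self.coverage_threshold:
                reasons.append(
                    f"fingerprint coverage {coverage:.3f} < {self.coverage_threshold}"
                )
        return (not reasons, reasons)

    def filter(self, records: list[CompoundRecord]) -> dict[str, tuple[bool, list[str]]]:
        return {r.id: self.in_domain(r) for r in records}


def intersect_in_domain(
    ads: list[ApplicabilityDomain], record: CompoundRecord
) -> tuple[bool, list[str]]:
    """In-domain for ALL supplied domains (consensus-model intersection rule)."""
    all_reasons: list[str] = []
    for ad in ads:
        ok, reasons = ad.in_domain(record)
        if not ok:
            all_reasons.extend(reasons)
    return (not all_reasons, sorted(set(all_reasons)))
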