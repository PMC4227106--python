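"""Strand-specific dRNA-seq read integration.

Two libraries per experiment: the TEX-treated "(+)" library (``plus_lib``),
in which 5'-monophosphate (processed) transcripts are depleted so primary
transcripts are enriched, and the untreated "(-)" library (``minus_lib``).
A locus whose (+)-library count clearly exceeds its (-)-library count is
called primary-enriched: its reads predominantly carry native 5'-triphosphate
ends.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import FeatureAnnotation, GenomeSequence, ReadAlignment

__all__ = [
    "CoverageProfile",
    "LocusExpression",
    "build_coverage",
    "count_locus",
    "enrichment_call",
    "antisense_pairing",
    "overlap_class",
]

LIBRARIES = ("plus_lib", "minus_lib")
STRANDS = ("+", "-")


@dataclass
class CoverageProfile:
    """Per-position read coverage, one vector per (strand, library)."""

    genome_id: str
    cov: dict[tuple[str, str], np.ndarray]  # (strand, library) -> int vector

    def __getitem__(self, key: tuple[str, str]) -> np.ndarray:
        return self.cov[key]

    def strand_total(self, strand: str) -> np.ndarray:
        """Coverage on one strand summed over both libraries."""
        return self.cov[(strand, "plus_lib")] + self.cov[(strand, "minus_lib")]


@dataclass
class LocusExpression:
    """Read counts of one stranded locus, split by library, with the
    opposite-strand (antisense) counts alongside."""

    start: int
    end: int
    strand: str
    reads_plus_lib: int = 0
    reads_minus_lib: int = 0
    antisense_reads_plus_lib: int = 0
    antisense_reads_minus_lib: int = 0

    @property
    def total_sense(self) -> int:
        return self.reads_plus_lib + self.reads_minus_lib

    @property
    def total_antisense(self) -> int:
        return self.antisense_reads_plus_lib + self.antisense_reads_minus_lib


def build_coverage(reads: list[ReadAlignment], genome: GenomeSequence) -> CoverageProfile:
    """Per-position coverage: number of reads whose interval contains the
    position, separately per strand and library."""
    n = len(genome)
    cov = {
        (s, l): np.zeros(n, dtype=np.int64) for s in STRANDS for l in LIBRARIES
    }
    for r in reads:
        if r.end > n:
            raise ValueError(f"read {r.read_id!r} [{r.start},{r.end}) exceeds genome length {n}")
        diff = cov[(r.strand, r.library)]
        diff[r.start] += 1
        if r.end < n:
            diff[r.end] -= 1
    for key in cov:
        cov[key] = np.cumsum(cov[key])
    return CoverageProfile(genome_id=genome.identifier, cov=cov)


def write_coverage_tsv(profile: CoverageProfile, path_prefix: str) -> list[str]:
    """Write the four (strand, library) coverage vectors as wiggle-style TSV
    files ``<prefix>.<strand_tag>.<library>.tsv``; returns the paths."""
    paths = []
    for (strand, lib), vec in profile.cov.items():
        tag = "fwd" if strand == "+" else "rev"
        path = f"{path_prefix}.{tag}.{lib}.tsv"
        with open(path, "w") as fh:
            fh.write(f"# coverage {profile.genome_id} strand={strand} library={lib}\n")
            for i, v in enumerate(vec):
                if v:
                    fh.write(f"{i}\t{v}\n")
        paths.append(path)
    return paths


def count_locus(
    reads: list[ReadAlignment],
    start: int,
    end: int,
    strand: str,
    min_overlap_frac: float = 0.5,
) -> LocusExpression:
    """Count reads per library for a stranded locus.

    A read is assigned to the locus when at least ``min_overlap_frac`` of its
    length lies inside the interval (default half) — robust to ragged
    454-style read ends. Opposite-strand reads passing the same rule fill the
    antisense counts.
    """
    expr = LocusExpression(start=start, end=end, strand=strand)
    for r in reads:
        ov = min(end, r.end) - max(start, r.start)
        if ov <= 0 or ov < min_overlap_frac * len(r):
            continue
        sense = r.strand == strand
        if r.library == "plus_lib":
            if sense:
                expr.reads_plus_lib += 1
            else:
                expr.antisense_reads_plus_lib += 1
        else:
            if sense:
                expr.reads_minus_lib += 1
            else:
                expr.antisense_reads_minus_lib += 1
    return expr


def enrichment_call(
    locus: LocusExpression, min_reads: int = 10, ratio_threshold: float = 2.0
) -> str:
    """Classify a locus by the (+)/(-) library ratio.

    ``primary_enriched``: TEX-resistant reads dominate, i.e. the locus is
    covered mostly by primary (5'-PPP) transcripts; ``processed_enriched``:
    the untreated library dominates; ``undetermined`` otherwise (including
    too few reads).
    """
    if min_reads <= 0 or ratio_threshold <= 0:
        raise ValueError("thresholds must be > 0")
    p, m = locus.reads_plus_lib, locus.reads_minus_lib
    if p + m < min_reads:
        return "undetermined"
    if p / max(m, 1) >= ratio_threshold:
        return "primary_enriched"
    if m / max(p, 1) >= ratio_threshold:
        return "processed_enriched"
    return "undetermined"


def antisense_pairing(
    total_sense: int, total_antisense: int, comparability_factor: float = 10.0
) -> str:
    """Decide whether a locus is transcribed on one strand or comparably on
    both: ``paired`` when the smaller strand total, scaled by
    ``comparability_factor``, still reaches the larger one (both non-zero);
    otherwise the dominant strand's class."""
    if comparability_factor < 1:
        raise ValueError("comparability_factor must be >= 1")
    lo, hi = sorted((total_sense, total_antisense))
    if lo > 0 and lo * comparability_factor >= hi:
        return "paired"
    return "sense_only" if total_sense >= total_antisense else "antisense_only"


def overlap_class(a: FeatureAnnotation, b: FeatureAnnotation) -> str:
    """Classify an opposite-strand gene-pair overlap.

    ``h2h`` (head-to-head): the two 5' ends / upstream regions overlap;
    ``t2t`` (tail-to-tail): the two 3' UTR-side ends overlap; ``none`` for
    same-strand pairs, disjoint pairs, and full containment (where the outer
    feature contributes neither terminus to the overlap). Symmetric.
    """
    if a.strand == b.strand:
        return "none"
    lo = max(a.start, b.start)
    hi = min(a.end, b.end)
    if lo >= hi:
        return "none"

    def in_overlap(coord: int) -> bool:
        return lo <= coord <= hi

    if in_overlap(a.five_prime) and in_overlap(b.five_prime):
        return "h2h"
    if in_overlap(a.three_prime) and in_overlap(b.three_prime):
        return "t2t"
    return "none"
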