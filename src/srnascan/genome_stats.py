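"""Descriptive genome statistics reported alongside the discovery analysis:
codon usage, annotation-set comparison and merge, whole-genome alignment
quality, tRNA wobble-position distribution, and tmRNA typing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_formats import AnnotationSet, GenomeSequence, MsaBlock
from .tracks import conservation_track, coverage_fraction_track

__all__ = [
    "CodonUsageTable",
    "AnnotationComparison",
    "MsaQuality",
    "WobbleDistribution",
    "codon_usage",
    "codon_fractions_from_percents",
    "compare_annotations",
    "msa_quality",
    "wobble_distribution",
    "classify_tmrna_type",
]

_STANDARD = CodonTable.unambiguous_rna_by_id[1]

#: RNA codon -> amino acid (3-letter style not needed; "*" = stop family)
CODON_TO_AA = {**_STANDARD.forward_table, **{c: "*" for c in _STANDARD.stop_codons}}
ALL_CODONS = sorted(CODON_TO_AA)


@dataclass
class CodonUsageTable:
    """64-row table: per-codon overall usage percent and within-family
    fraction (stop codons grouped as one family)."""

    table: pd.DataFrame  # columns: codon, aa, count, percent, fraction

    def row(self, codon: str) -> pd.Series:
        codon = codon.upper().replace("T", "U")
        return self.table.set_index("codon").loc[codon]


def codon_usage(cds_sequences: list[str]) -> CodonUsageTable:
    """Codon usage over a set of coding sequences given 5'->3' on the coding
    strand. Percent = 100 x count / total codons; fraction = count / count of
    its synonymous family."""
    counts = dict.fromkeys(ALL_CODONS, 0)
    total = 0
    for i, seq in enumerate(cds_sequences):
        s = seq.upper().replace("T", "U")
        if len(s) % 3:
            raise ValueError(f"CDS #{i} length {len(s)} not divisible by 3")
        for k in range(0, len(s), 3):
            codon = s[k : k + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
    if total == 0:
        raise ValueError("no codons counted")
    fam_tot: dict[str, int] = {}
    for c, n in counts.items():
        fam_tot[CODON_TO_AA[c]] = fam_tot.get(CODON_TO_AA[c], 0) + n
    rows = [
        {
            "codon": c,
            "aa": CODON_TO_AA[c],
            "count": counts[c],
            "percent": 100.0 * counts[c] / total,
            "fraction": counts[c] / fam_tot[CODON_TO_AA[c]] if fam_tot[CODON_TO_AA[c]] else 0.0,
        }
        for c in ALL_CODONS
    ]
    return CodonUsageTable(pd.DataFrame(rows))


def codon_fractions_from_percents(percents: dict[str, float]) -> dict[str, float]:
    """Recover within-family fractions from a printed percent column.

    The fraction column of a codon-usage table is the percent of a codon
    divided by the summed percent of its synonymous family, so it can be
    recomputed from the printed percents alone."""
    percents = {c.upper().replace("T", "U"): v for c, v in percents.items()}
    fam: dict[str, float] = {}
    for c, v in percents.items():
        fam[CODON_TO_AA[c]] = fam.get(CODON_TO_AA[c], 0.0) + v
    return {c: (v / fam[CODON_TO_AA[c]] if fam[CODON_TO_AA[c]] else 0.0) for c, v in percents.items()}


# ---------------------------------------------------------------------------
# annotation comparison


@dataclass
class AnnotationComparison:
    """Partition of two gene annotations of one genome.

    Matching keys on strand plus stop (3') coordinate — bacterial gene
    callers disagree mostly on start codons. ``extended`` is the merged
    annotation size: everything in A plus the B-only genes.
    """

    n_a: int
    n_b: int
    equal: int
    start_shifted: int
    end_shifted: int
    a_only: int
    b_only: int

    @property
    def extended(self) -> int:
        return self.n_a + self.b_only

    def check_identities(self) -> None:
        assert self.equal + self.start_shifted + self.end_shifted + self.a_only == self.n_a
        assert self.equal + self.start_shifted + self.end_shifted + self.b_only == self.n_b


def compare_annotations(a: AnnotationSet, b: AnnotationSet) -> AnnotationComparison:
    """Compare two annotations of the same genome.

    Two features match when they share strand and stop (3') coordinate:
    same start too -> equal, different start -> start_shifted. A features
    then sharing strand+start (5') with a leftover B feature -> end_shifted.
    Everything else is a_only / b_only. Matching is one-to-one, start-shift
    evaluated before end-shift.
    """
    fa = list(a.features)
    fb = list(b.features)
    by_stop: dict[tuple[str, int], list[int]] = {}
    for j, f in enumerate(fb):
        by_stop.setdefault((f.strand, f.three_prime), []).append(j)
    used_b: set[int] = set()
    equal = start_shifted = 0
    unmatched_a = []
    for f in fa:
        cands = [j for j in by_stop.get((f.strand, f.three_prime), []) if j not in used_b]
        if cands:
            exact = [j for j in cands if fb[j].five_prime == f.five_prime]
            j = exact[0] if exact else cands[0]
            used_b.add(j)
            if fb[j].five_prime == f.five_prime:
                equal += 1
            else:
                start_shifted += 1
        else:
            unmatched_a.append(f)
    by_start: dict[tuple[str, int], list[int]] = {}
    for j, f in enumerate(fb):
        if j not in used_b:
            by_start.setdefault((f.strand, f.five_prime), []).append(j)
    end_shifted = 0
    a_only = 0
    for f in unmatched_a:
        cands = [j for j in by_start.get((f.strand, f.five_prime), []) if j not in used_b]
        if cands:
            used_b.add(cands[0])
            end_shifted += 1
        else:
            a_only += 1
    cmp = AnnotationComparison(
        n_a=len(fa),
        n_b=len(fb),
        equal=equal,
        start_shifted=start_shifted,
        end_shifted=end_shifted,
        a_only=a_only,
        b_only=len(fb) - len(used_b),
    )
    cmp.check_identities()
    return cmp


# ---------------------------------------------------------------------------
# MSA quality


@dataclass
class MsaQuality:
    coverage: float  # % of reference positions covered by >= 1 block
    gap_ratio: float  # % gap characters in the block matrices
    wsop: float  # mean per-position count of OTHER species matching the reference


def msa_quality(blocks: list[MsaBlock], genome: GenomeSequence) -> MsaQuality:
    """Coverage, gap ratio and sum-of-pairs-style conservation of a
    reference-projected whole-genome alignment.

    ``wsop`` counts identity among the non-reference species only (unit
    weights), averaged over all reference positions with uncovered positions
    contributing 0.
    """
    cov = coverage_fraction_track(blocks, genome).values
    cons = conservation_track(blocks, genome).values
    n = len(genome)
    wsop = float(np.where(cov > 0, cons - 1, 0.0).mean()) if n else 0.0
    gap_chars = 0
    total_chars = 0
    for b in blocks:
        for r in b.rows:
            gap_chars += r.aligned.count("-")
            total_chars += len(r.aligned)
    return MsaQuality(
        coverage=100.0 * float(cov.mean()) if n else 0.0,
        gap_ratio=100.0 * gap_chars / total_chars if total_chars else 0.0,
        wsop=wsop,
    )


# ---------------------------------------------------------------------------
# tRNA wobble distribution


@dataclass
class WobbleDistribution:
    """Fraction of distinct anticodon families whose 5' (wobble) base is
    U, G, C or A."""

    U: float
    G: float
    C: float
    A: float


def wobble_distribution(anticodons: list[str]) -> WobbleDistribution:
    """Distribution of the anticodon 5' wobble base over distinct anticodon
    families (gene copies collapse to one family)."""
    if not anticodons:
        raise ValueError("empty anticodon set")
    families = set()
    for ac in anticodons:
        a = ac.upper().replace("T", "U")
        if len(a) != 3 or set(a) - set("ACGU"):
            raise ValueError(f"invalid anticodon {ac!r}")
        families.add(a)
    n = len(families)
    frac = {b: sum(1 for a in families if a[0] == b) / n for b in "UGCA"}
    return WobbleDistribution(**frac)


# ---------------------------------------------------------------------------
# tmRNA typing


def classify_tmrna_type(pk1_lower_stem_bp: int) -> str:
    """Type a transfer-messenger RNA by the length of pseudoknot 1's lower
    stem: 4-5 bp -> "A", 2-3 bp -> "B", anything else "unclassified"."""
    if pk1_lower_stem_bp < 0:
        raise ValueError("stem length must be >= 0")
    if 4 <= pk1_lower_stem_bp <= 5:
        return "A"
    if 2 <= pk1_lower_stem_bp <= 3:
        return "B"
    return "unclassified"
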