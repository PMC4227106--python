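"""Integrative ncRNA candidate calling.

Seeds come from strand-specific read-coverage runs and from locally stable
structure hits; seeds overlapping protein-coding sequences, rRNA operons or
tRNAs are removed from the novel set (with tRNA sense/antisense loci and
mRNA h2h/t2t overlap loci rerouted to their own classes); survivors are
annotated with every evidence track and kept when the evidence combination
rule holds. Antisense partners with comparable read totals share one ID.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import AnnotationSet, FormatError, GenomeSequence, ReadAlignment
from .rnaseq import (
    CoverageProfile,
    LocusExpression,
    antisense_pairing,
    build_coverage,
    count_locus,
    overlap_class,
)
from .tracks import (
    EvidenceTrack,
    LocalStructure,
    StructureScanConfig,
    conservation_track,
    local_gc_track,
    scan_local_structures,
)

__all__ = [
    "CallerConfig",
    "NcRNACandidate",
    "seed_loci",
    "filter_candidates",
    "annotate_candidate",
    "import_external_evidence",
    "assign_ids",
    "call_candidates",
]


@dataclass
class CallerConfig:
    """Candidate-calling thresholds.

    ``min_len`` and the CDS/rRNA/tRNA exclusion implement the hard filter;
    retention of a filtered seed requires read support (>= ``expression_min_reads``
    sense reads) OR at least ``min_evidence_count`` in-silico evidences among
    {structure hit, conservation >= conservation_min, external evidence}.
    """

    min_len: int = 25
    expression_min_reads: int = 5
    conservation_min: int = 9
    min_evidence_count: int = 2
    seed_merge_gap: int = 20
    comparability_factor: float = 10.0
    ratio_threshold: float = 2.0
    min_reads: int = 10

    def __post_init__(self):
        if self.min_len < 1 or self.min_evidence_count < 1:
            raise ValueError("min_len and min_evidence_count must be >= 1")


@dataclass
class NcRNACandidate:
    """One row of the candidate table."""

    candidate_id: str
    start: int  # 0-based half-open internally; table output is 1-based
    end: int
    strand: str
    mean_local_gc: float = 0.0
    expression: LocusExpression | None = None
    structure: LocalStructure | None = None
    structure_energy: float | None = None
    cons_p: int = 0
    cons_t: int = 0
    ext_evidence_p: float | None = None
    ext_evidence_t: float | None = None
    annotation_overlap: str = "No"
    cls: str = "novel"
    remarks: str = ""

    def __post_init__(self):
        if self.structure is not None and self.structure_energy is None:
            self.structure_energy = self.structure.mfe

    @property
    def length(self) -> int:
        return self.end - self.start

    def to_row(self) -> list[str]:
        e = self.expression
        return [
            self.candidate_id,
            str(self.start + 1),
            str(self.end),
            self.strand,
            f"{self.mean_local_gc:.2f}",
            str(e.reads_plus_lib if e else 0),
            str(e.reads_minus_lib if e else 0),
            self.annotation_overlap,
            "No" if self.structure_energy is None else f"{self.structure_energy:.2f}",
            str(self.cons_p),
            str(self.cons_t),
            "No" if self.ext_evidence_p is None else f"{self.ext_evidence_p:.4f}",
            "No" if self.ext_evidence_t is None else f"{self.ext_evidence_t:.4f}",
            self.cls,
            self.remarks,
        ]

    @classmethod
    def from_row(cls, row: list[str]) -> "NcRNACandidate":
        def opt(x):
            return None if x == "No" else float(x)

        return cls(
            candidate_id=row[0],
            start=int(row[1]) - 1,
            end=int(row[2]),
            strand=row[3],
            mean_local_gc=float(row[4]),
            expression=LocusExpression(
                start=int(row[1]) - 1,
                end=int(row[2]),
                strand=row[3],
                reads_plus_lib=int(row[5]),
                reads_minus_lib=int(row[6]),
            ),
            annotation_overlap=row[7],
            structure_energy=opt(row[8]),
            cons_p=int(row[9]),
            cons_t=int(row[10]),
            ext_evidence_p=opt(row[11]),
            ext_evidence_t=opt(row[12]),
            cls=row[13],
            remarks=row[14],
        )


# ---------------------------------------------------------------------------
# seeding


def _coverage_runs(cov: np.ndarray, threshold: int, merge_gap: int) -> list[tuple[int, int]]:
    above = cov >= threshold
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    runs = []
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i > prev + 1:
            runs.append((int(run_start), int(prev) + 1))
            run_start = i
        prev = i
    runs.append((int(run_start), int(prev) + 1))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= merge_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(iv):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def seed_loci(
    coverage: CoverageProfile,
    structures: list[LocalStructure],
    config: CallerConfig,
) -> list[tuple[int, int, str]]:
    """Stranded seed intervals: maximal coverage runs >= expression_min_reads
    (runs separated by <= seed_merge_gap nt merged) unioned with structure-hit
    intervals; overlapping same-strand seeds merged."""
    seeds: list[tuple[int, int, str]] = []
    for strand in "+-":
        iv = _coverage_runs(
            coverage.strand_total(strand), config.expression_min_reads, config.seed_merge_gap
        )
        iv += [(h.start, h.end) for h in structures if h.strand == strand]
        seeds += [(s, e, strand) for s, e in _merge_intervals(iv)]
    return sorted(seeds)


# ---------------------------------------------------------------------------
# filtering


def filter_candidates(
    seeds: list[tuple[int, int, str]],
    annotations: AnnotationSet,
    config: CallerConfig,
    coverage: CoverageProfile | None = None,
) -> list[tuple[int, int, str, str, str]]:
    """Apply the hard filters. Returns ``(start, end, strand, class, overlap_names)``.

    Seeds shorter than ``min_len`` are removed. Seeds overlapping (>= 1 nt,
    either strand) a CDS, rRNA or tRNA leave the novel set: tRNA overlaps
    with read support become class ``tRNA_locus``; seeds inside the overlap
    region of a head-to-head / tail-to-tail mRNA pair become ``h2h``/``t2t``;
    the rest are dropped. Seeds overlapping an annotated ncRNA are kept as
    ``known_ncRNA``.
    """
    blocking = annotations.of_type("CDS", "rRNA", "tRNA")
    known = annotations.of_type("ncRNA")
    pair_regions = _opposite_pair_regions(annotations)
    out = []
    for start, end, strand in seeds:
        if end - start < config.min_len:
            continue
        hits = [f for f in blocking if f.overlaps(start, end)]
        names = "/".join(dict.fromkeys(f.feature_id for f in hits)) or "No"
        if hits:
            trnas = [f for f in hits if f.feature_type == "tRNA"]
            if trnas and all(f.feature_type == "tRNA" for f in hits):
                expressed = coverage is None or bool(
                    (coverage.strand_total(strand)[start:end] > 0).any()
                )
                if expressed:
                    out.append((start, end, strand, "tRNA_locus", names))
                continue
            pair_cls = _pair_region_class(start, end, pair_regions)
            if pair_cls is not None:
                out.append((start, end, strand, pair_cls, names))
            continue
        overlaps_known = [f for f in known if f.overlaps(start, end)]
        if overlaps_known:
            names = "/".join(dict.fromkeys(f.feature_id for f in overlaps_known))
            out.append((start, end, strand, "known_ncRNA", names))
        else:
            out.append((start, end, strand, "novel", "No"))
    return out


def _opposite_pair_regions(annotations: AnnotationSet) -> list[tuple[int, int, str]]:
    """Overlap regions of opposite-strand CDS pairs, tagged h2h/t2t."""
    cds = annotations.of_type("CDS")
    regions = []
    for i, a in enumerate(cds):
        for b in cds[i + 1 :]:
            cls = overlap_class(a, b)
            if cls != "none":
                regions.append((max(a.start, b.start), min(a.end, b.end), cls))
    return regions


def _pair_region_class(start, end, regions) -> str | None:
    for s, e, cls in regions:
        if start < e and s < end:
            return cls
    return None


# ---------------------------------------------------------------------------
# annotation


def import_external_evidence(path) -> list[tuple[int, int, float]]:
    """Import probability-scored windows (e.g. a structure-conservation
    screen) from TSV: columns start(1-based), end, probability. Windows with
    p < 0.5 are kept but will render as non-significant ("No")."""
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            start1, end1, p = int(cols[0]), int(cols[1]), float(cols[2])
            if not (0.0 <= p <= 1.0):
                raise FormatError(f"{path}:{lineno}: probability {p} outside [0,1]")
            out.append((start1 - 1, end1, p))
    return out


def external_evidence_for(
    interval: tuple[int, int], windows: list[tuple[int, int, float]] | None
) -> float | None:
    """Best overlapping probability, or None when absent / below the 0.5
    significance call threshold."""
    if not windows:
        return None
    s, e = interval
    probs = [p for ws, we, p in windows if ws < e and s < we]
    best = max(probs, default=None)
    if best is None or best < 0.5:
        return None
    return best


def annotate_candidate(
    interval: tuple[int, int, str],
    gc_track: EvidenceTrack,
    cons_tracks: dict[str, EvidenceTrack],
    reads: list[ReadAlignment],
    cls: str = "novel",
    annotation_overlap: str = "No",
    structures: list[LocalStructure] | None = None,
    external: dict[str, list[tuple[int, int, float]]] | None = None,
    candidate_id: str = "",
) -> NcRNACandidate:
    """Assemble one candidate row: mean local GC, median conservation per
    alignment source, per-library read counts, best-z overlapping structure
    hit, imported external evidence."""
    start, end, strand = interval
    expr = count_locus(reads, start, end, strand)
    overlapping = [h for h in (structures or []) if h.overlaps(start, end)]
    best = min(overlapping, key=lambda h: (h.zscore, h.start)) if overlapping else None

    def med(track: EvidenceTrack | None) -> int:
        if track is None:
            return 0
        return int(np.median(track.values[start:end]))

    ext = external or {}
    return NcRNACandidate(
        candidate_id=candidate_id,
        start=start,
        end=end,
        strand=strand,
        mean_local_gc=float(np.mean(gc_track.values[start:end])),
        expression=expr,
        structure=best,
        cons_p=med(cons_tracks.get("p")),
        cons_t=med(cons_tracks.get("t")),
        ext_evidence_p=external_evidence_for((start, end), ext.get("p")),
        ext_evidence_t=external_evidence_for((start, end), ext.get("t")),
        annotation_overlap=annotation_overlap,
        cls=cls,
    )


def _passes_evidence(c: NcRNACandidate, config: CallerConfig) -> bool:
    if c.expression and c.expression.total_sense >= config.expression_min_reads:
        return True
    n_insilico = sum(
        [
            c.structure is not None,
            max(c.cons_p, c.cons_t) >= config.conservation_min,
            c.ext_evidence_p is not None or c.ext_evidence_t is not None,
        ]
    )
    return n_insilico >= config.min_evidence_count


# ---------------------------------------------------------------------------
# IDs


def assign_ids(
    candidates: list[NcRNACandidate],
    annotations: AnnotationSet | None = None,
    comparability_factor: float = 10.0,
) -> list[NcRNACandidate]:
    """Number candidates in genome order: novel/known loci get n1..;
    opposite-strand overlapping partners with comparable read totals share
    one ID; h2h/t2t loci are numbered h2h1../t2t1..; tRNA sense/antisense
    loci are named t<tRNA ordinal>;<locus ordinal>."""
    candidates = sorted(candidates, key=lambda c: (c.start, c.strand))
    trna_ord = {}
    if annotations is not None:
        for i, f in enumerate(annotations.of_type("tRNA"), 1):
            trna_ord[f.feature_id] = i

    # group novel/known into antisense-paired clusters
    n_idx = 0
    cls_counters = {"t2t": 0, "h2h": 0}
    trna_locus_idx = 0
    assigned: set[int] = set()
    for i, c in enumerate(candidates):
        if i in assigned:
            continue
        if c.cls in ("novel", "known_ncRNA"):
            n_idx += 1
            cid = f"n{n_idx}"
            c.candidate_id = cid
            assigned.add(i)
            for j in range(i + 1, len(candidates)):
                d = candidates[j]
                if j in assigned or d.cls not in ("novel", "known_ncRNA"):
                    continue
                if d.start >= c.end:
                    break
                if d.strand == c.strand or not (c.start < d.end and d.start < c.end):
                    continue
                ts = c.expression.total_sense if c.expression else 0
                ta = d.expression.total_sense if d.expression else 0
                if antisense_pairing(ts, ta, comparability_factor) == "paired":
                    d.candidate_id = cid
                    assigned.add(j)
        elif c.cls in ("t2t", "h2h"):
            cls_counters[c.cls] += 1
            cid = f"{c.cls}{cls_counters[c.cls]}"
            c.candidate_id = cid
            assigned.add(i)
            for j in range(i + 1, len(candidates)):
                d = candidates[j]
                if j in assigned or d.cls != c.cls:
                    continue
                if d.start >= c.end:
                    break
                d.candidate_id = cid
                assigned.add(j)
        elif c.cls == "tRNA_locus":
            trna_locus_idx += 1
            first = c.annotation_overlap.split("/")[0]
            ordinal = trna_ord.get(first, 0)
            c.candidate_id = f"t{ordinal};{trna_locus_idx}"
            assigned.add(i)
        else:
            assigned.add(i)
    return candidates


# ---------------------------------------------------------------------------
# pipeline


def call_candidates(
    genome: GenomeSequence,
    annotations: AnnotationSet,
    reads: list[ReadAlignment],
    maf_blocks: dict[str, list] | None = None,
    config: CallerConfig | None = None,
    scan_config: StructureScanConfig | None = None,
    structures: list[LocalStructure] | None = None,
    external: dict[str, list[tuple[int, int, float]]] | None = None,
) -> list[NcRNACandidate]:
    """End-to-end candidate calling.

    ``maf_blocks`` maps an alignment-source label ("p"/"t") to its MAF
    blocks. A precomputed ``structures`` list skips the genome scan (the
    scan is the expensive step; callers that already ran it can reuse it).
    """
    config = config or CallerConfig()
    if structures is None:
        structures = scan_local_structures(genome, scan_config)
    coverage = build_coverage(reads, genome)
    gc = local_gc_track(genome)
    cons = {
        label: conservation_track(blocks, genome)
        for label, blocks in (maf_blocks or {}).items()
    }
    seeds = seed_loci(coverage, structures, config)
    kept = filter_candidates(seeds, annotations, config, coverage)
    out = []
    for start, end, strand, cls, names in kept:
        cand = annotate_candidate(
            (start, end, strand),
            gc,
            cons,
            reads,
            cls=cls,
            annotation_overlap=names,
            structures=structures,
            external=external,
        )
        if cand.cls == "novel" and not _passes_evidence(cand, config):
            continue
        out.append(cand)
    # hard invariants of the novel set
    blocking = annotations.of_type("CDS", "rRNA", "tRNA")
    for c in out:
        if c.cls == "novel":
            assert c.length >= config.min_len
            assert not any(f.overlaps(c.start, c.end) for f in blocking)
    return assign_ids(out, annotations, config.comparability_factor)
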