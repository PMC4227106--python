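"""Readers/writers for the external formats the pipeline touches, plus the
unified internal coordinate model.

All internal coordinates are 0-based half-open on the forward strand;
conversion to/from 1-based inclusive (GFF, candidate table) happens only at
the I/O boundary.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import AlignIO, SeqIO

__all__ = [
    "FormatError",
    "GenomeSequence",
    "FeatureAnnotation",
    "AnnotationSet",
    "MsaBlock",
    "MsaRow",
    "ReadAlignment",
    "read_fasta",
    "read_gff",
    "write_gff",
    "read_maf",
    "read_reads_bed",
    "write_reads_bed",
    "write_candidate_table",
    "read_candidate_table",
    "CANDIDATE_COLUMNS",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


_VALID_RESIDUES = set("ACGTN")

#: GFF3 type column -> internal feature_type. Unknown types map to "other".
GFF_TYPE_MAP = {
    "CDS": "CDS",
    "gene": "CDS",
    "protein_coding_gene": "CDS",
    "rRNA": "rRNA",
    "tRNA": "tRNA",
    "ncRNA": "ncRNA",
    "sRNA": "ncRNA",
    "tmRNA": "ncRNA",
    "SRP_RNA": "ncRNA",
    "RNase_P_RNA": "ncRNA",
    "antisense_RNA": "ncRNA",
}

FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "ncRNA", "other")

#: types whose strand is required because the overlap filters depend on it
_STRAND_REQUIRED = {"CDS", "rRNA", "tRNA"}


@dataclass(frozen=True)
class GenomeSequence:
    """A genome (or contig): identifier plus residues over {A,C,G,T,N}."""

    identifier: str
    residues: str

    def __post_init__(self):
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"genome {self.identifier!r}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureAnnotation:
    """A typed, stranded genome feature.

    ``start``/``end`` are internal coordinates (0-based half-open, forward
    strand); readers convert from the 1-based inclusive GFF convention.
    """

    feature_id: str
    feature_type: str
    start: int
    end: int
    strand: str
    source: str = ""

    def __post_init__(self):
        if self.feature_type not in FEATURE_TYPES:
            raise FormatError(f"unknown feature_type {self.feature_type!r}")
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"feature {self.feature_id!r}: bad interval [{self.start},{self.end})"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")

    @property
    def five_prime(self) -> int:
        """5' terminus as a forward-strand coordinate (half-open convention:
        the rightmost coordinate ``end`` stands for the - strand 5' end)."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        return self.end if self.strand == "+" else self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class AnnotationSet:
    """Ordered collection of features on one genome, unique feature_ids."""

    genome_id: str
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self):
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate feature_ids: {dup[:5]}")

    def __iter__(self):
        return iter(self.features)

    def __len__(self):
        return len(self.features)

    def of_type(self, *types: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.feature_type in types]


@dataclass(frozen=True)
class MsaRow:
    species: str
    aligned: str  # aligned text incl. '-' gaps, reference-forward orientation
    start: int  # forward-strand start on that species' genome (0-based)
    strand: str
    size: int  # ungapped length


@dataclass
class MsaBlock:
    """One alignment block, projected to the reference species.

    Row texts all share one length; the reference row is gap-free only if the
    aligner emitted it so — reference gap columns do not consume reference
    coordinates.
    """

    rows: list[MsaRow]
    reference_species: str

    def __post_init__(self):
        lengths = {len(r.aligned) for r in self.rows}
        if len(lengths) > 1:
            raise FormatError(f"inconsistent row lengths in MAF block: {lengths}")
        if self.reference is None:
            raise FormatError("reference row missing from MAF block")

    @property
    def reference(self) -> MsaRow | None:
        for r in self.rows:
            if r.species == self.reference_species:
                return r
        return None

    @property
    def ref_start(self) -> int:
        return self.reference.start

    @property
    def ref_end(self) -> int:
        return self.reference.start + self.reference.size


@dataclass(frozen=True)
class ReadAlignment:
    """One mapped read: 0-based half-open interval, strand, library tag."""

    chrom: str
    start: int
    end: int
    strand: str
    library: str  # "plus_lib" (TEX-treated) or "minus_lib" (untreated)
    read_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise FormatError(f"read {self.read_id!r}: empty interval")
        if self.library not in {"plus_lib", "minus_lib"}:
            raise FormatError(f"read {self.read_id!r}: bad library {self.library!r}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"read {self.read_id!r}: bad strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read FASTA; residues upper-cased, U converted to T."""
    records = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            seq = str(rec.seq).upper().replace("U", "T")
            records.append(GenomeSequence(rec.id, seq))
    except ValueError as exc:  # biopython signals malformed FASTA this way
        raise FormatError(f"{path}: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    return records


def write_fasta(genomes: Iterable[GenomeSequence], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.identifier}\n")
            for i in range(0, len(g.residues), width):
                fh.write(g.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff(path, genome_id: str | None = None) -> AnnotationSet:
    """Read a GFF3 file into an AnnotationSet.

    Types are mapped through :data:`GFF_TYPE_MAP`; unknown types become
    "other". '.' strand is rejected for CDS/rRNA/tRNA because the overlap
    filters require strand; for other types it is kept as '+' with the
    original '.' noted in the source tag.
    """
    features: list[FeatureAnnotation] = []
    gid = genome_id
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            seqid, source, ftype, start_s, end_s, _score, strand, _frame, attrs = cols[:9]
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            mapped = GFF_TYPE_MAP.get(ftype, "other")
            if strand not in {"+", "-", "."}:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if strand == ".":
                if mapped in _STRAND_REQUIRED:
                    raise FormatError(
                        f"{path}:{lineno}: '.' strand not allowed for {ftype}"
                    )
                strand = "+"
            fid = _gff_attr(attrs, "ID") or f"{ftype}_{lineno}"
            if gid is None:
                gid = seqid
            features.append(
                FeatureAnnotation(
                    feature_id=fid,
                    feature_type=mapped,
                    start=start1 - 1,  # GFF 1-based inclusive -> half-open
                    end=end1,
                    strand=strand,
                    source=source,
                )
            )
    return AnnotationSet(genome_id=gid or "", features=features)


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in annotations:
            fh.write(
                "\t".join(
                    [
                        annotations.genome_id,
                        f.source or "srnascan",
                        f.feature_type,
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# MAF


def read_maf(path, reference: str) -> tuple[list[MsaBlock], int]:
    """Read MAF blocks, keeping those that contain the reference species.

    Returns ``(blocks, n_dropped)`` where ``n_dropped`` counts blocks lacking
    the reference. Blocks whose reference row is on the - strand are flipped
    (all rows reverse-complemented) so every returned block is
    reference-forward; non-reference - strand rows keep their strand tag but
    their ``start`` is converted to a forward-strand coordinate.
    """
    blocks: list[MsaBlock] = []
    dropped = 0
    try:
        alignments = list(AlignIO.parse(str(path), "maf"))
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    for aln in alignments:
        rows = []
        for rec in aln:
            ann = rec.annotations
            species = rec.id.split(".")[0]
            strand = "+" if ann.get("strand", 1) == 1 else "-"
            start = int(ann["start"])
            size = int(ann["size"])
            src_size = int(ann["srcSize"])
            if strand == "-":  # MAF stores strand-local starts
                fwd_start = src_size - start - size
            else:
                fwd_start = start
            rows.append(MsaRow(species, str(rec.seq).upper(), fwd_start, strand, size))
        ref_rows = [r for r in rows if r.species == reference]
        if not ref_rows:
            dropped += 1
            continue
        if ref_rows[0].strand == "-":
            rows = [
                MsaRow(
                    r.species,
                    reverse_complement(r.aligned.replace("-", "x"))
                    .replace("x", "-"),
                    r.start,
                    "+" if r.strand == "-" else "-",
                    r.size,
                )
                for r in rows
            ]
        blocks.append(MsaBlock(rows=rows, reference_species=reference))
    return blocks, dropped


def write_maf(blocks: Sequence[MsaBlock], path, src_sizes: dict[str, int]) -> None:
    """Write reference-forward blocks back to MAF (forward strand rows)."""
    with open(path, "w") as fh:
        fh.write("##maf version=1\n")
        for b in blocks:
            fh.write("a\n")
            for r in b.rows:
                fh.write(
                    f"s {r.species} {r.start} {r.size} {r.strand} "
                    f"{src_sizes[r.species]} {r.aligned}\n"
                )
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED6 reads


def read_reads_bed(path, library: str) -> list[ReadAlignment]:
    """Read BED6 mapped reads, tagging every record with ``library``."""
    reads: list[ReadAlignment] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start_s, end_s, name, _score, strand = cols[:6]
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise FormatError(f"{path}:{lineno}: zero/negative length read")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            reads.append(ReadAlignment(chrom, start, end, strand, library, name))
    return reads


def write_reads_bed(reads: Iterable[ReadAlignment], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.read_id}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# Candidate table

CANDIDATE_COLUMNS = [
    "ID",
    "start",
    "end",
    "strand",
    "GC",
    "reads_plus_lib",
    "reads_minus_lib",
    "annotation_overlap",
    "structure_energy",
    "cons_p",
    "cons_t",
    "ext_evidence_p",
    "ext_evidence_t",
    "class",
    "remarks",
]


def write_candidate_table(candidates, path) -> None:
    """Write the candidate table as TSV (start/end 1-based inclusive).

    Rows are ordered by start, then strand; this is deterministic for a fixed
    candidate list.
    """
    rows = sorted(candidates, key=lambda c: (c.start, c.strand))
    with open(path, "w") as fh:
        fh.write("\t".join(CANDIDATE_COLUMNS) + "\n")
        for c in rows:
            fh.write("\t".join(c.to_row()) + "\n")


def read_candidate_table(path):
    """Read a candidate table written by :func:`write_candidate_table`."""
    from .candidates import NcRNACandidate  # local import to avoid a cycle

    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != CANDIDATE_COLUMNS:
            raise FormatError(f"{path}: unexpected candidate-table header")
        for line in fh:
            out.append(NcRNACandidate.from_row(line.rstrip("\n").split("\t")))
    return out
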