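"""Per-nucleotide evidence tracks: local GC, locally stable secondary
structures with a dinucleotide-shuffle Z-score null, and multi-genome
conservation.

The structure scan slides a window of ``max_span`` nucleotides over both
strands, folds each window with the internal MFE engine, trims the fold to
its outermost paired extent, and standardizes the trimmed sequence's energy
against dinucleotide-preserving shuffles. Strongly negative Z-scores flag
sequences folding more stably than their composition predicts — the
classical signature of structured ncRNAs in AT-rich genomes.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from . import _fold
from .io_formats import GenomeSequence, MsaBlock, reverse_complement

__all__ = [
    "EvidenceTrack",
    "LocalStructure",
    "StructureScanConfig",
    "local_gc_track",
    "dinucleotide_shuffle",
    "fold_mfe",
    "structure_zscore",
    "scan_local_structures",
    "conservation_track",
    "coverage_fraction_track",
]


@dataclass
class EvidenceTrack:
    """One real number per genome position (optionally one vector per strand)."""

    name: str
    values: np.ndarray
    values_minus: np.ndarray | None = None

    @property
    def strand_specific(self) -> bool:
        return self.values_minus is not None

    def __len__(self):
        return len(self.values)


@dataclass(frozen=True)
class LocalStructure:
    """A locally stable structure hit in forward genome coordinates.

    ``structure`` is the dot-bracket of the transcript read 5'->3' (i.e. of
    the reverse complement for minus-strand hits).
    """

    start: int
    end: int
    strand: str
    mfe: float
    structure: str
    zscore: float

    @property
    def span(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class StructureScanConfig:
    """Knobs of the locally-stable-structure scan.

    max_span limits both the window length and the base-pair span; hits whose
    paired extent is shorter than ``min_struct_len`` are discarded; the final
    Z uses ``n_shuffles`` dinucleotide-preserving shuffles and hits require
    z <= z_cutoff. ``screen_stages`` is a sequence of (n_drawn, z_threshold)
    checkpoints: windows whose provisional z misses a (deliberately generous)
    checkpoint threshold stop early; survivors continue to the full
    ``n_shuffles`` depth, from which the reported z is computed.
    """

    max_span: int = 120
    min_struct_len: int = 50
    n_shuffles: int = 1000
    z_cutoff: float = -3.0
    rng_seed: int = 0
    step: int = 40
    screen_stages: tuple = ((20, -2.5), (100, -2.85))

    def __post_init__(self):
        if not (self.max_span >= self.min_struct_len >= 1):
            raise ValueError("need max_span >= min_struct_len >= 1")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles >= 1")


# ---------------------------------------------------------------------------
# local GC


def local_gc_track(genome: GenomeSequence, flank: int = 15) -> EvidenceTrack:
    """G+C fraction in a window of +-``flank`` nt around each position.

    N residues are excluded from both numerator and denominator; a window of
    only N scores 0. Windows are clipped at the genome ends.
    """
    if len(genome) == 0:
        raise ValueError("empty genome")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    arr = np.frombuffer(genome.residues.encode(), dtype=np.uint8)
    is_gc = ((arr == ord("G")) | (arr == ord("C"))).astype(np.int64)
    is_acgt = (arr != ord("N")).astype(np.int64)
    w = 2 * flank + 1
    kernel = np.ones(w, dtype=np.int64)
    gc = np.convolve(is_gc, kernel, mode="same")
    valid = np.convolve(is_acgt, kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = np.where(valid > 0, gc / np.maximum(valid, 1), 0.0)
    return EvidenceTrack(name="local_gc", values=vals)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (uniform Eulerian-path sampler)


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle ``seq`` preserving its exact multiset of overlapping
    dinucleotides (hence mononucleotide counts and both terminal residues).

    Sampling is uniform over all valid arrangements: a uniformly random
    last-exit-edge arborescence towards the final residue is drawn by
    rejection, the remaining out-edges are uniformly permuted, and the
    Eulerian path is read off the dinucleotide multigraph.
    """
    if len(seq) < 2:
        raise ValueError("sequence too short to shuffle")
    if "N" in seq:
        raise ValueError("sequence contains N; pre-filter before shuffling")
    seq = seq.upper().replace("U", "T")
    first, last = seq[0], seq[-1]
    out: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        out.setdefault(a, []).append(b)
    vertices = list(out)
    if len(vertices) == 1 and all(b == first for b in out[first]):
        return seq  # homopolymer: unique arrangement
    for _ in range(100000):
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last and len(out[v]) == 0:
                continue
            if v != last:
                last_edge[v] = out[v][rng.integers(len(out[v]))]
        if _is_arborescence(last_edge, last):
            break
    else:  # pragma: no cover - astronomically unlikely
        raise RuntimeError("arborescence sampling did not converge")
    order: dict[str, list[str]] = {}
    for v in vertices:
        edges = list(out[v])
        if v in last_edge:
            edges.remove(last_edge[v])
        perm = [edges[i] for i in rng.permutation(len(edges))]
        if v in last_edge:
            perm.append(last_edge[v])
        order[v] = perm
    ptr = {v: 0 for v in vertices}
    result = [first]
    cur = first
    for _ in range(len(seq) - 1):
        nxt = order[cur][ptr[cur]]
        ptr[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def _is_arborescence(last_edge: dict[str, str], root: str) -> bool:
    for v in last_edge:
        seen = {v}
        cur = v
        while cur != root:
            cur = last_edge.get(cur)
            if cur is None or cur in seen:
                return False
            seen.add(cur)
    return True


# ---------------------------------------------------------------------------
# folding


def fold_mfe(seq: str, max_span: int) -> tuple[float, str]:
    """Minimum free energy (kcal/mol, <= 0) and dot-bracket structure of
    ``seq`` under the internal nearest-neighbour model; no base pair spans
    more than ``max_span`` nt."""
    if len(seq) < 1:
        raise ValueError("empty sequence")
    if max_span < 1:
        raise ValueError("max_span must be >= 1")
    seq = seq.upper().replace("U", "T")
    return _fold.fold_encoded(_fold.encode(seq), max_span)


def fold_energy(seq: str, max_span: int) -> float:
    seq = seq.upper().replace("U", "T")
    return _fold.fold_energy_encoded(_fold.encode(seq), max_span)


def structure_zscore(
    seq: str,
    config: StructureScanConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_shuffles: int | None = None,
) -> float:
    """Standardize the MFE of ``seq`` against dinucleotide-preserving
    shuffles: z = (E_native - mean E_shuffled) / sd(E_shuffled).

    A zero shuffle-energy spread (e.g. homopolymers) yields z = 0, so
    unstructured sequences can never clear a negative cutoff through a
    degenerate denominator.
    """
    config = config or StructureScanConfig()
    n = n_shuffles if n_shuffles is not None else config.n_shuffles
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    e_native = fold_energy(seq, config.max_span)
    energies = np.empty(n)
    for k in range(n):
        energies[k] = fold_energy(dinucleotide_shuffle(seq, rng), config.max_span)
    sd = float(np.std(energies, ddof=1)) if n > 1 else 0.0
    if sd == 0.0:
        return 0.0
    return float((e_native - float(np.mean(energies))) / sd)


# ---------------------------------------------------------------------------
# genome scan


def _staged_zscore(seq: str, config: StructureScanConfig, seed: int) -> float | None:
    """Z-score with early stopping for the genome scan.

    Shuffle energies are drawn incrementally from one seeded stream; at each
    ``screen_stages`` checkpoint the window is abandoned (None) when its
    provisional z misses the checkpoint threshold. The returned z for
    survivors always uses the full ``n_shuffles`` draws, so early stopping
    only ever removes windows that could not have reached the cutoff — it
    never changes a reported value.
    """
    rng = np.random.default_rng(seed)
    e_native = fold_energy(seq, config.max_span)
    if e_native >= 0:
        return None
    energies: list[float] = []
    checkpoints = [
        (n, thr) for n, thr in config.screen_stages if n < config.n_shuffles
    ] + [(config.n_shuffles, None)]
    for n_target, threshold in checkpoints:
        while len(energies) < n_target:
            energies.append(fold_energy(dinucleotide_shuffle(seq, rng), config.max_span))
        arr = np.asarray(energies)
        sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
        z = 0.0 if sd == 0.0 else float((e_native - arr.mean()) / sd)
        if threshold is not None and z > threshold:
            return None
    return z


def _window_starts(n: int, window: int, step: int) -> list[int]:
    """Window start ladder, symmetric under reverse complement so that
    scanning the reverse-complemented genome visits the mirror windows."""
    if n <= window:
        return [0]
    top = n - window
    fwd = set(range(0, top + 1, step))
    fwd.add(top)
    mirrored = {top - s for s in fwd}
    return sorted(fwd | mirrored)


def _window_seed(subseq: str, rng_seed: int) -> int:
    # content-derived substream: identical sequence -> identical shuffles,
    # which makes the scan exactly strand-symmetric
    return (zlib.crc32(subseq.encode()) ^ (rng_seed * 2654435761)) % (2**31)


def scan_local_structures(
    genome: GenomeSequence, config: StructureScanConfig | None = None
) -> list[LocalStructure]:
    """Scan both strands for locally stable structures.

    Windows containing N are skipped. Each window's fold is trimmed to its
    outermost paired extent; trimmed spans shorter than ``min_struct_len``
    are discarded; surviving spans are Z-scored (two-stage: screen, then the
    full ``n_shuffles``) and reported when z <= z_cutoff. Overlapping hits on
    one strand are merged into the lowest-z representative (ties: lower
    start).
    """
    config = config or StructureScanConfig()
    if len(genome) == 0:
        raise ValueError("empty genome")
    n = len(genome)
    window = config.max_span
    starts = _window_starts(n, window, config.step)
    hits: list[LocalStructure] = []
    for strand, seq in (("+", genome.residues), ("-", reverse_complement(genome.residues))):
        for s in starts:
            sub = seq[s : s + window]
            if "N" in sub:
                continue
            mfe, struct = fold_mfe(sub, config.max_span)
            if mfe >= 0:
                continue
            a = struct.find("(")
            b = struct.rfind(")") + 1
            if b - a < config.min_struct_len:
                continue
            core = sub[a:b]
            seed = _window_seed(core, config.rng_seed)
            z = _staged_zscore(core, config, seed)
            if z is None or z > config.z_cutoff:
                continue
            core_mfe, core_struct = fold_mfe(core, config.max_span)
            lo, hi = s + a, s + b
            if strand == "-":
                lo, hi = n - (s + b), n - (s + a)
            hits.append(
                LocalStructure(
                    start=lo, end=hi, strand=strand,
                    mfe=core_mfe, structure=core_struct, zscore=z,
                )
            )
    return merge_structure_hits(hits)


def merge_structure_hits(hits: list[LocalStructure]) -> list[LocalStructure]:
    """Merge same-strand overlapping hits, keeping the lowest-z (tie: lower
    start) representative of each overlap cluster."""
    out: list[LocalStructure] = []
    for strand in "+-":
        group = sorted(
            (h for h in hits if h.strand == strand), key=lambda h: (h.start, h.end)
        )
        cluster: list[LocalStructure] = []
        cluster_end = -1
        for h in group:
            if cluster and h.start >= cluster_end:
                out.append(min(cluster, key=lambda x: (x.zscore, x.start)))
                cluster = []
                cluster_end = -1
            cluster.append(h)
            cluster_end = max(cluster_end, h.end)
        if cluster:
            out.append(min(cluster, key=lambda x: (x.zscore, x.start)))
    return sorted(out, key=lambda h: (h.start, h.strand))


# ---------------------------------------------------------------------------
# conservation


def conservation_track(
    blocks: list[MsaBlock], genome: GenomeSequence, count_identity: bool = True
) -> EvidenceTrack:
    """Per-position count of species (including the reference) whose aligned
    residue is non-gap and identical to the reference residue; 0 where no
    block covers the position. Overlapping blocks: the maximum count wins.

    With ``count_identity=False`` the track instead counts species merely
    aligned (non-gap) at the position, whatever the residue.
    """
    vals = np.zeros(len(genome), dtype=np.int64)
    for block in blocks:
        ref = block.reference
        counts = _block_counts(block, count_identity)
        pos = ref.start
        col_of_ref = np.flatnonzero(
            np.frombuffer(ref.aligned.encode(), dtype=np.uint8) != ord("-")
        )
        idx = np.arange(pos, pos + len(col_of_ref))
        inside = (idx >= 0) & (idx < len(genome))
        np.maximum.at(vals, idx[inside], counts[col_of_ref][inside])
    return EvidenceTrack(name="conservation", values=vals.astype(float))


def _block_counts(block: MsaBlock, count_identity: bool) -> np.ndarray:
    mat = np.array(
        [np.frombuffer(r.aligned.encode(), dtype=np.uint8) for r in block.rows]
    )
    ref_row = [i for i, r in enumerate(block.rows) if r.species == block.reference_species][0]
    ref = mat[ref_row]
    nongap = mat != ord("-")
    if count_identity:
        match = (mat == ref[None, :]) & nongap & (ref[None, :] != ord("-"))
    else:
        match = nongap & (ref[None, :] != ord("-"))
    return match.sum(axis=0)


# ---------------------------------------------------------------------------
# exports


def write_structure_bed(hits: list[LocalStructure], path, chrom: str) -> None:
    """Structure hits as BED6; score column = round(-100 x z)."""
    with open(path, "w") as fh:
        for k, h in enumerate(hits, 1):
            score = int(round(-100 * h.zscore))
            fh.write(f"{chrom}\t{h.start}\t{h.end}\tstruct_{k}\t{score}\t{h.strand}\n")


def write_structure_tsv(hits: list[LocalStructure], path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tstrand\tmfe\tzscore\tstructure\n")
        for h in hits:
            fh.write(
                f"{h.start}\t{h.end}\t{h.strand}\t{h.mfe:.2f}\t{h.zscore:.3f}\t{h.structure}\n"
            )


def write_track_tsv(track: EvidenceTrack, path) -> None:
    """Wiggle-style TSV: position (0-based), value."""
    with open(path, "w") as fh:
        fh.write(f"# track {track.name}\n")
        for i, v in enumerate(track.values):
            fh.write(f"{i}\t{v:.4g}\n")


def coverage_fraction_track(blocks: list[MsaBlock], genome: GenomeSequence) -> EvidenceTrack:
    """0/1 track: reference positions covered by at least one block."""
    vals = np.zeros(len(genome))
    for b in blocks:
        vals[max(0, b.ref_start) : min(len(genome), b.ref_end)] = 1.0
    return EvidenceTrack(name="msa_coverage", values=vals)
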