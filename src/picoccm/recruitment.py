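"""Metagenomic read recruitment and the RPKG abundance statistic.

Reads are placed on reference genomes by exact k-mer seeding plus ungapped
extension (substitution-only alignment over the full read length), then
filtered with the recruitment thresholds: identity strictly greater than 95%
and alignment length strictly greater than 50 bp. Passing hits are counted
as reads per kilobase of genome per gigabase of metagenome:

    RPKG_g = hits_g / (genome_length_g / 10^3) / (metagenome_bases / 10^9)

and a genome is considered detected in a metagenome only when its RPKG is
strictly greater than 2. Per-metagenome alpha and beta RPKG sums feed the
dominance summary (fraction of metagenomes where alpha > beta, ratio of
median sums, paired Wilcoxon signed-rank test).

For real data, pre-computed alignments can be imported from BLAST outfmt-6
TSV or SAM instead of using the built-in matcher (see ``load_hits_table``).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotyping import GenomeRecord, revcomp
from .io import InputError
from .synthetic import ReadSet

__all__ = [
    "ReadHit",
    "RecruitmentProfile",
    "DominanceSummary",
    "ReferenceIndex",
    "map_reads",
    "filter_hits",
    "assign_multimappers",
    "compute_rpkg",
    "apply_detection_threshold",
    "summarize_dominance",
    "load_hits_table",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 95.0
DEFAULT_MIN_ALN_BP = 50
DEFAULT_DETECTION_RPKG = 2.0
DEFAULT_SEED_K = 21


@dataclass
class ReadHit:
    """One placement of a read on a genome (ungapped, full read length)."""

    read_id: str
    genome_id: str
    identity: float  # percent matching bases over the alignment
    aln_length: int  # bp
    position: int  # 0-based start on the (concatenated) genome
    strand: str  # + | -

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be within [0, 100]")


class ReferenceIndex:
    """Exact k-mer index over a set of reference genomes.

    Building the index is the expensive step; reuse one instance across the
    metagenomes of a study.
    """

    def __init__(self, genomes: list[GenomeRecord], k: int = DEFAULT_SEED_K):
        if k < 11:
            raise InputError("seed length k must be >= 11")
        if not genomes:
            raise InputError("no reference genomes")
        self.k = k
        self.genome_ids = [g.genome_id for g in genomes]
        self.lengths = {g.genome_id: g.genome_length_bp for g in genomes}
        self.arrays: list[np.ndarray] = []
        self.index: dict[bytes, list[tuple[int, int]]] = {}
        for gi, genome in enumerate(genomes):
            seq = "".join(s for _, s in genome.contigs).upper().encode()
            arr = np.frombuffer(seq, dtype=np.uint8)
            self.arrays.append(arr)
            for pos in range(len(seq) - k + 1):
                self.index.setdefault(seq[pos : pos + k], []).append((gi, pos))

    def candidates(self, read: bytes, dense: bool) -> set[tuple[int, int]]:
        k = self.k
        out: set[tuple[int, int]] = set()
        stride = 1 if dense else k
        for off in range(0, len(read) - k + 1, stride):
            for gi, pos in self.index.get(read[off : off + k], ()):
                start = pos - off
                if 0 <= start <= len(self.arrays[gi]) - len(read):
                    out.add((gi, start))
        return out


def map_reads(
    reads: ReadSet | list[tuple[str, str]],
    genomes: list[GenomeRecord] | ReferenceIndex,
    k: int = DEFAULT_SEED_K,
) -> list[ReadHit]:
    """Place every read on every genome it matches (best placement per genome).

    Seeding is exact-k-mer on both strands: a sparse pass (every k-th k-mer)
    followed by a dense fallback when the sparse pass finds nothing, then
    ungapped evaluation of each candidate placement over the full read
    length. ``aln_length`` equals the read length (substitution-only model).
    """
    index = genomes if isinstance(genomes, ReferenceIndex) else ReferenceIndex(genomes, k)
    read_list = reads.reads if isinstance(reads, ReadSet) else [(r[0], r[1], None, None) for r in reads]
    if not read_list:
        raise InputError("map_reads: no reads")
    hits: list[ReadHit] = []
    for rec in read_list:
        rid, seq = rec[0], rec[1]
        if len(seq) < index.k:
            raise InputError(f"map_reads: read {rid} shorter than seed length k={index.k}")
        best: dict[int, tuple[float, int, str]] = {}  # gi -> (identity, pos, strand)
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            rb = oriented.encode()
            rarr = np.frombuffer(rb, dtype=np.uint8)
            cand = index.candidates(rb, dense=False)
            if not cand:
                cand = index.candidates(rb, dense=True)
            for gi, start in cand:
                garr = index.arrays[gi]
                mismatches = int(np.count_nonzero(garr[start : start + len(rb)] != rarr))
                identity = 100.0 * (len(rb) - mismatches) / len(rb)
                cur = best.get(gi)
                if cur is None or identity > cur[0] or (identity == cur[0] and start < cur[1]):
                    best[gi] = (identity, start, strand)
        for gi, (identity, start, strand) in sorted(best.items()):
            hits.append(
                ReadHit(
                    read_id=rid,
                    genome_id=index.genome_ids[gi],
                    identity=identity,
                    aln_length=len(seq),
                    position=start,
                    strand=strand,
                )
            )
    return hits


def filter_hits(
    hits: list[ReadHit],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_aln_bp: int = DEFAULT_MIN_ALN_BP,
) -> list[ReadHit]:
    """Keep hits with identity strictly > ``min_identity`` and alignment
    length strictly > ``min_aln_bp``; input order is preserved."""
    if min_identity <= 0 or min_aln_bp <= 0:
        raise InputError("filter thresholds must be positive")
    return [h for h in hits if h.identity > min_identity and h.aln_length > min_aln_bp]


def assign_multimappers(hits: list[ReadHit], mode: str = "best") -> list[ReadHit]:
    """Resolve reads hitting several genomes.

    ``best`` keeps the single hit with the highest identity per read (ties:
    longer alignment, then lexicographically smallest genome id); ``all``
    keeps every hit — equivalent to mapping each genome independently.
    """
    if mode == "all":
        return list(hits)
    if mode != "best":
        raise InputError(f"unknown multimapper mode {mode!r}")
    best: dict[str, ReadHit] = {}
    for h in hits:
        cur = best.get(h.read_id)
        if cur is None or (-h.identity, -h.aln_length, h.genome_id) < (
            -cur.identity,
            -cur.aln_length,
            cur.genome_id,
        ):
            best[h.read_id] = h
    # preserve first-appearance order of reads
    seen: set[str] = set()
    out: list[ReadHit] = []
    for h in hits:
        if h.read_id not in seen:
            seen.add(h.read_id)
            out.append(best[h.read_id])
    return out


@dataclass
class RecruitmentProfile:
    """Per-genome RPKG values for one metagenome, with filters recorded."""

    metagenome_id: str
    metagenome_gb: float
    genome_kb: dict[str, float]
    hit_count: dict[str, int]
    rpkg: dict[str, float]
    raw_rpkg: dict[str, float] = field(default_factory=dict)
    filters_applied: dict = field(default_factory=dict)


def compute_rpkg(
    hit_counts: dict[str, int],
    genome_lengths_bp: dict[str, int],
    metagenome_bases: int,
    metagenome_id: str = "metagenome",
    filters: dict | None = None,
) -> RecruitmentProfile:
    """RPKG per genome: hits / (genome kb) / (metagenome Gb)."""
    if metagenome_bases <= 0:
        raise InputError("compute_rpkg: metagenome_bases must be positive")
    for gid, length in genome_lengths_bp.items():
        if length <= 0:
            raise InputError(f"compute_rpkg: non-positive length for {gid}")
    gb = metagenome_bases / 1e9
    kb = {gid: length / 1e3 for gid, length in genome_lengths_bp.items()}
    rpkg = {gid: hit_counts.get(gid, 0) / kb[gid] / gb for gid in genome_lengths_bp}
    return RecruitmentProfile(
        metagenome_id=metagenome_id,
        metagenome_gb=gb,
        genome_kb=kb,
        hit_count={gid: int(hit_counts.get(gid, 0)) for gid in genome_lengths_bp},
        rpkg=rpkg,
        raw_rpkg=dict(rpkg),
        filters_applied=dict(filters or {}),
    )


def apply_detection_threshold(
    profile: RecruitmentProfile, threshold: float = DEFAULT_DETECTION_RPKG
) -> RecruitmentProfile:
    """Zero out genomes at RPKG <= threshold (strict ``>`` retained).

    Raw values stay available in ``raw_rpkg``.
    """
    if threshold < 0:
        raise InputError("detection threshold must be >= 0")
    rpkg = {gid: (v if v > threshold else 0.0) for gid, v in profile.rpkg.items()}
    filters = dict(profile.filters_applied)
    filters["detection_rpkg"] = threshold
    return RecruitmentProfile(
        metagenome_id=profile.metagenome_id,
        metagenome_gb=profile.metagenome_gb,
        genome_kb=dict(profile.genome_kb),
        hit_count=dict(profile.hit_count),
        rpkg=rpkg,
        raw_rpkg=dict(profile.raw_rpkg),
        filters_applied=filters,
    )


@dataclass
class DominanceSummary:
    """Alpha-vs-beta dominance across metagenomes."""

    per_metagenome: pd.DataFrame  # metagenome_id, alpha_sum_rpkg, beta_sum_rpkg, alpha_dominant
    fraction_alpha_dominant: float
    median_ratio: float  # median alpha sum / median beta sum
    wilcoxon: "object"  # WilcoxonResult from ordination


def summarize_dominance(
    profiles: list[RecruitmentProfile],
    genotypes: dict[str, str],
) -> DominanceSummary:
    """Per-metagenome alpha/beta RPKG sums and overall dominance statistics.

    ``genotypes`` maps genome ids to ``alpha`` or ``beta``; genomes with any
    other call are excluded with a warning. The Wilcoxon signed-rank test is
    paired on (alpha_sum, beta_sum) per metagenome.
    """
    from .ordination import wilcoxon_signed_rank

    if not profiles:
        raise InputError("summarize_dominance: no profiles")
    excluded = sorted(
        {gid for p in profiles for gid in p.rpkg if genotypes.get(gid) not in ("alpha", "beta")}
    )
    if excluded:
        logger.warning("excluding genomes with ambiguous genotype: %s", excluded)
    rows = []
    for p in profiles:
        alpha = sum(v for gid, v in p.rpkg.items() if genotypes.get(gid) == "alpha")
        beta = sum(v for gid, v in p.rpkg.items() if genotypes.get(gid) == "beta")
        rows.append(
            dict(
                metagenome_id=p.metagenome_id,
                alpha_sum_rpkg=alpha,
                beta_sum_rpkg=beta,
                alpha_dominant=alpha > beta,
            )
        )
    table = pd.DataFrame(rows)
    fraction = float(table["alpha_dominant"].mean())
    med_alpha = float(table["alpha_sum_rpkg"].median())
    med_beta = float(table["beta_sum_rpkg"].median())
    ratio = med_alpha / med_beta if med_beta > 0 else float("inf")
    wilcoxon = wilcoxon_signed_rank(
        list(zip(table["alpha_sum_rpkg"], table["beta_sum_rpkg"]))
    )
    return DominanceSummary(
        per_metagenome=table,
        fraction_alpha_dominant=fraction,
        median_ratio=ratio,
        wilcoxon=wilcoxon,
    )


def load_hits_table(path: str | Path, format: str = "blast6") -> list[ReadHit]:
    """Import pre-computed alignments.

    ``blast6``: tabular BLAST outfmt-6 (qseqid, sseqid, pident, length,
    mismatch, gapopen, qstart, qend, sstart, send, evalue, bitscore) — only
    the first four columns are required. ``sam``: identity is derived from
    the NM tag over the aligned length.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"file not found: {path}")
    hits: list[ReadHit] = []
    if format == "blast6":
        df = pd.read_csv(path, sep="\t", header=None)
        if df.shape[1] < 4:
            raise InputError(f"{path}: expected >= 4 BLAST outfmt-6 columns")
        for _, row in df.iterrows():
            sstart = int(row[8]) if df.shape[1] > 9 else 1
            send = int(row[9]) if df.shape[1] > 9 else int(row[3])
            strand = "+" if send >= sstart else "-"
            hits.append(
                ReadHit(
                    read_id=str(row[0]),
                    genome_id=str(row[1]),
                    identity=float(row[2]),
                    aln_length=int(row[3]),
                    position=min(sstart, send) - 1,
                    strand=strand,
                )
            )
    elif format == "sam":
        for line_no, line in enumerate(path.read_text().splitlines(), 1):
            if not line or line.startswith("@"):
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise InputError(f"{path}: malformed SAM line {line_no}")
            flag = int(fields[1])
            if flag & 0x4:  # unmapped
                continue
            nm = 0
            for tag in fields[11:]:
                if tag.startswith("NM:i:"):
                    nm = int(tag[5:])
            aln_len = len(fields[9]) if fields[9] != "*" else 0
            if aln_len == 0:
                continue
            hits.append(
                ReadHit(
                    read_id=fields[0],
                    genome_id=fields[2],
                    identity=100.0 * (aln_len - nm) / aln_len,
                    aln_length=aln_len,
                    position=int(fields[3]) - 1,
                    strand="-" if flag & 0x10 else "+",
                )
            )
    else:
        raise InputError(f"unknown hits format {format!r}")
    return hits
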