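"""Synthetic genomes and metagenomes with known ground truth.

Every downstream stage (ORF calling, marker detection, read recruitment,
dominance statistics) is validated by parameter recovery on data from this
module: genomes carry planted CCM marker ORFs at controlled protein identity
to the panel references, and read sets are drawn from genome mixtures with
known abundance weights and a substitution-only error model.

Determinism: every operation takes a single integer seed and derives all of
its randomness from it; identical seeds give byte-identical output.

Deliberate simplifications (see the methods note): uniform codon choice in
reverse translation, no indels in reads, reads drawn from the forward strand,
planted ORFs non-overlapping with >= 100 bp spacers and an in-frame TAA
guard immediately upstream of each planted start codon so the six-frame
caller recovers exactly the planted span.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotyping import GenomeRecord, revcomp
from .io import InputError
from .panel import MarkerPanel, canonical_family_id

__all__ = [
    "GenotypeSpec",
    "CommunitySpec",
    "ReadSet",
    "PlantedLocus",
    "generate_marker_variant",
    "generate_genome",
    "simulate_metagenome",
    "generate_pa_fixture",
    "alpha_marker_set",
    "beta_marker_set",
]

AA = "ACDEFGHIKLMNPQRSTVWY"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MIN_SPACER_BP = 100

# aa -> codons (standard code, stops excluded), stable order
from Bio.Data.CodonTable import standard_dna_table as _STD

_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STD.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


@dataclass
class GenotypeSpec:
    """Blueprint for one synthetic genome.

    ``markers`` lists (family_id, copy_number, target_identity) triples;
    the planted protein for each copy is a variant of the family's first
    panel reference at the requested identity.
    """

    label: str
    ccm_class: str  # alpha | beta
    markers: list[tuple[str, int, float]]
    genome_length: int = 50_000
    gc_content: float = 0.55

    def __post_init__(self) -> None:
        if self.ccm_class not in ("alpha", "beta"):
            raise InputError(f"ccm_class must be alpha or beta, got {self.ccm_class!r}")
        if not (0.0 < self.gc_content < 1.0):
            raise InputError("gc_content must be in (0, 1)")
        for fid, copies, ident in self.markers:
            canonical_family_id(fid)
            if copies < 1:
                raise InputError(f"{fid}: copy_number must be >= 1")
            if not (0.0 < ident <= 1.0):
                raise InputError(f"{fid}: target_identity must be in (0, 1]")


@dataclass
class CommunitySpec:
    """Composition of one simulated metagenome."""

    members: list[tuple[str, float]]  # (genome_id, abundance weight >= 0)
    n_reads: int
    read_length: int = 150
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise InputError("n_reads must be positive")
        if not self.members or all(w <= 0 for _, w in self.members):
            raise InputError("at least one member weight must be positive")
        if any(w < 0 for _, w in self.members):
            raise InputError("weights must be non-negative")
        if not (0.0 <= self.error_rate < 1.0):
            raise InputError("error_rate must be in [0, 1)")

    @property
    def normalized_weights(self) -> list[tuple[str, float]]:
        total = sum(w for _, w in self.members)
        return [(gid, w / total) for gid, w in self.members]


@dataclass
class ReadSet:
    """Simulated reads plus their ground truth."""

    reads: list[tuple[str, str, str, int]]  # (read_id, seq, source genome, 0-based start)
    total_bases: int

    def __post_init__(self) -> None:
        assert self.total_bases == sum(len(r[1]) for r in self.reads)


@dataclass
class PlantedLocus:
    """Truth-table entry for one planted marker ORF (forward-strand coords,
    0-based half-open, spanning start codon through stop codon)."""

    genome_id: str
    family_id: str
    contig: str
    start: int
    end: int
    strand: str
    planted_identity: float
    protein: str = ""


def generate_marker_variant(reference: str, target_identity: float, seed: int) -> str:
    """A same-length variant of ``reference`` at a controlled identity.

    Exactly ``round((1 - target_identity) * L)`` positions, chosen uniformly
    without replacement, are substituted by a residue drawn uniformly from
    the 19 alternatives.
    """
    if not reference:
        raise InputError("generate_marker_variant: empty reference")
    if not (0.0 < target_identity <= 1.0):
        raise InputError("generate_marker_variant: target_identity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    L = len(reference)
    n_sub = round((1.0 - target_identity) * L)
    positions = rng.choice(L, size=n_sub, replace=False)
    out = list(reference)
    for pos in positions:
        alternatives = [a for a in AA if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = []
    for aa in protein:
        options = _AA_TO_CODONS.get(aa)
        if options is None:  # non-standard residue: encode as alanine
            options = _AA_TO_CODONS["A"]
        codons.append(options[rng.integers(len(options))])
    return "".join(codons)


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def generate_genome(
    spec: GenotypeSpec, seed: int, panel: MarkerPanel | None = None
) -> tuple[GenomeRecord, list[PlantedLocus]]:
    """Random background DNA with the requested marker ORFs planted.

    Each planted cassette is ``TAA + ATG + codons(variant[1:]) + TAA`` (the
    leading in-frame TAA guard stops upstream extension); cassettes are
    non-overlapping, separated by at least 100 bp, and placed on a uniformly
    chosen strand. Returns the genome plus a truth table of planted loci.
    """
    panel = panel if panel is not None else MarkerPanel.default()
    rng = np.random.default_rng(seed)

    cassettes: list[tuple[str, str, float, str]] = []  # (family, orf_nt, identity, protein)
    for fid, copies, ident in spec.markers:
        fid = canonical_family_id(fid)
        ref = panel[fid].representative
        for _ in range(copies):
            variant = generate_marker_variant(ref, ident, int(rng.integers(2**31)))
            protein = "M" + variant[1:]
            orf = "ATG" + _reverse_translate(variant[1:], rng) + "TAA"
            cassettes.append((fid, orf, ident, protein))

    total_cassette = sum(len(orf) + 3 for _, orf, _, _ in cassettes)  # +3 guard TAA
    n_gaps = len(cassettes) + 1
    background = spec.genome_length - total_cassette
    if background < n_gaps * MIN_SPACER_BP:
        raise InputError(
            f"genome_length {spec.genome_length} too small for "
            f"{len(cassettes)} planted ORFs plus spacers"
        )
    # distribute the background among gaps, each >= MIN_SPACER_BP
    free = background - n_gaps * MIN_SPACER_BP
    cuts = np.sort(rng.integers(0, free + 1, size=n_gaps - 1))
    gap_sizes = np.diff(np.concatenate(([0], cuts, [free]))) + MIN_SPACER_BP

    order = rng.permutation(len(cassettes))
    parts: list[np.ndarray] = []
    loci: list[PlantedLocus] = []
    pos = 0
    for k, idx in enumerate(order):
        gap = int(gap_sizes[k])
        parts.append(_random_dna(gap, spec.gc_content, rng))
        pos += gap
        fid, orf, ident, protein = cassettes[idx]
        strand = "+" if rng.random() < 0.5 else "-"
        cassette = "TAA" + orf if strand == "+" else revcomp("TAA" + orf)
        parts.append(np.frombuffer(cassette.encode(), dtype=np.uint8))
        if strand == "+":
            start, end = pos + 3, pos + 3 + len(orf)
        else:  # guard TAA sits at the downstream end on the forward strand
            start, end = pos, pos + len(orf)
        loci.append(
            PlantedLocus(
                genome_id=spec.label,
                family_id=fid,
                contig="contig_1",
                start=start,
                end=end,
                strand=strand,
                planted_identity=ident,
                protein=protein,
            )
        )
        pos += len(cassette)
    parts.append(_random_dna(int(gap_sizes[-1]), spec.gc_content, rng))
    sequence = b"".join(p.tobytes() for p in parts).decode()
    assert len(sequence) == spec.genome_length

    genome = GenomeRecord(
        genome_id=spec.label,
        contigs=[("contig_1", sequence)],
        habitat="unknown",
        lineage="beta" if spec.ccm_class == "beta" else "unknown",
    )
    loci.sort(key=lambda l: l.start)
    return genome, loci


def simulate_metagenome(community: CommunitySpec, genomes: list[GenomeRecord]) -> ReadSet:
    """Draw reads from a genome mixture (length-weighted abundance).

    A read's source genome is chosen with probability proportional to
    ``weight_i * length_i`` (abundance weights are per-copy; longer genomes
    shed proportionally more reads), its start uniformly, and substitutions
    applied i.i.d. at ``error_rate``. Reads come from the forward strand.
    """
    by_id = {g.genome_id: g for g in genomes}
    for gid, _ in community.members:
        if gid not in by_id:
            raise InputError(f"simulate_metagenome: unknown genome_id {gid!r}")
    rng = np.random.default_rng(community.seed)
    read_len = community.read_length
    member_ids = [gid for gid, _ in community.members]
    lengths = np.array([by_id[gid].genome_length_bp for gid in member_ids], dtype=float)
    if read_len > lengths.min():
        raise InputError("read_length exceeds the shortest member genome")
    weights = np.array([w for _, w in community.normalized_weights])
    p = weights * lengths
    p /= p.sum()

    counts = rng.multinomial(community.n_reads, p)
    seqs: list[np.ndarray] = []
    sources: list[str] = []
    starts_all: list[np.ndarray] = []
    for gid, count in zip(member_ids, counts):
        if count == 0:
            continue
        full = "".join(seq for _, seq in by_id[gid].contigs)
        arr = np.frombuffer(full.encode(), dtype=np.uint8)
        starts = rng.integers(0, len(arr) - read_len + 1, size=count)
        block = arr[starts[:, None] + np.arange(read_len)]
        if community.error_rate > 0:
            mask = rng.random(block.shape) < community.error_rate
            # substitute with one of the 3 other bases
            base_idx = np.searchsorted(_BASES, block)
            shift = rng.integers(1, 4, size=block.shape)
            block = np.where(mask, _BASES[(base_idx + shift) % 4], block)
        seqs.append(block)
        sources.extend([gid] * count)
        starts_all.append(starts)

    block = np.concatenate(seqs) if seqs else np.empty((0, read_len), dtype=np.uint8)
    starts = np.concatenate(starts_all) if starts_all else np.empty(0, dtype=int)
    order = rng.permutation(len(sources))
    reads = [
        (
            f"read_{i:06d}",
            block[idx].tobytes().decode(),
            sources[idx],
            int(starts[idx]),
        )
        for i, idx in enumerate(order)
    ]
    return ReadSet(reads=reads, total_bases=read_len * len(reads))


def alpha_marker_set(identity: float = 0.9) -> list[tuple[str, int, float]]:
    """The alpha-diagnostic marker complement for synthetic genomes."""
    fams = ["rbcL_1A", "rbcS", "cbbX", "raf2", "csoS1", "csoS2", "csoS4A", "ca_epsilon"]
    return [(fid, 1, identity) for fid in fams]


def beta_marker_set(identity: float = 0.9) -> list[tuple[str, int, float]]:
    """The beta-diagnostic marker complement for synthetic genomes."""
    fams = ["rbcL_1B", "rbcS", "rbcX", "raf1", "ccmK", "ccmL", "ccmM", "ccmN", "ccmO", "ca_beta_B"]
    return [(fid, 1, identity) for fid in fams]


def generate_pa_fixture(
    n_alpha: int,
    n_beta: int,
    flip_rate: float,
    seed: int,
    panel: MarkerPanel | None = None,
):
    """A presence/absence matrix with planted alpha/beta block structure.

    Alpha rows carry the alpha-diagnostic complement, beta rows the beta
    complement, shared families are present in both, and every cell is then
    flipped independently with probability ``flip_rate``. Returns a
    :class:`~picoccm.genotyping.GeneMatrix`.
    """
    from .genotyping import GeneMatrix
    from .panel import ALPHA_DIAGNOSTIC, BETA_DIAGNOSTIC, SHARED_FAMILIES
    import pandas as pd

    if n_alpha + n_beta < 3:
        raise InputError("generate_pa_fixture: need at least 3 genomes")
    if not (0.0 <= flip_rate < 0.5):
        raise InputError("generate_pa_fixture: flip_rate must be in [0, 0.5)")
    panel = panel if panel is not None else MarkerPanel.default()
    fids = panel.family_ids
    rng = np.random.default_rng(seed)
    rows = []
    index = []
    for i in range(n_alpha):
        present = ALPHA_DIAGNOSTIC | SHARED_FAMILIES
        rows.append([1 if fid in present else 0 for fid in fids])
        index.append(f"alpha_{i:02d}")
    for i in range(n_beta):
        present = BETA_DIAGNOSTIC | SHARED_FAMILIES
        rows.append([1 if fid in present else 0 for fid in fids])
        index.append(f"beta_{i:02d}")
    data = np.array(rows, dtype=int)
    if flip_rate > 0:
        flips = rng.random(data.shape) < flip_rate
        data = np.where(flips, 1 - data, data)
    df = pd.DataFrame(data, index=index, columns=fids)
    return GeneMatrix(df=df, provenance={"fixture": "generate_pa_fixture", "flip_rate": flip_rate, "seed": seed})
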