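"""CCM marker genotyping: from genome sequences to an alpha/beta call.

The chain is: six-frame ORF extraction -> homology search of every protein
against the marker panel (Smith-Waterman for conserved families, profile
search for divergent ones) -> a genomes x families copy-number matrix ->
a genotype call per genome:

* alpha: form 1A RuBisCO (``rbcL_1A``) plus an alpha-carboxysome
  (``csoS1`` shell and ``csoS2`` assembly protein);
* beta: form 1B RuBisCO (``rbcL_1B``) plus a beta-carboxysome
  (``ccmK`` shell and ``ccmM`` core);
* anything else is ``ambiguous``.

Thresholds are strict ``>`` comparisons (a hit at exactly 30% identity or
75% coverage does not count); both are configurable per family.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import DEFAULT_GAP_EXTEND, DEFAULT_GAP_OPEN, HomologyHit, evalue, local_align
from .io import InputError
from .panel import MarkerPanel
from .profile import ProfileModel, build_profile, profile_search

__all__ = [
    "GenomeRecord",
    "GeneMatrix",
    "CCMGenotype",
    "extract_orfs",
    "build_gene_matrix",
    "classify_ccm",
    "summarize_inventory",
    "INVENTORY_RULES",
]

logger = logging.getLogger(__name__)

HABITATS = ("marine", "brackish", "freshwater", "unknown")
LINEAGES = ("SC5.1", "SC5.2", "SC5.3", "Prochlorococcus", "spongiarum", "beta", "unknown")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# minimal standard-code translation table (codon -> residue)
from Bio.Data.CodonTable import standard_dna_table as _STD

_CODON_TO_AA = dict(_STD.forward_table)


def _translate(codons: list[str]) -> str:
    return "".join(_CODON_TO_AA.get(c, "X") for c in codons)


@dataclass
class GenomeRecord:
    """A genome: contigs, an optional proteome, and study metadata."""

    genome_id: str
    contigs: list[tuple[str, str]]
    proteome: list[tuple[str, str]] = field(default_factory=list)
    habitat: str = "unknown"
    lineage: str = "unknown"
    orf_coords: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.habitat not in HABITATS:
            raise ValueError(f"unknown habitat {self.habitat!r}")
        if self.lineage not in LINEAGES:
            raise ValueError(f"unknown lineage {self.lineage!r}")

    @property
    def genome_length_bp(self) -> int:
        return sum(len(seq) for _, seq in self.contigs)


def extract_orfs(
    genome: GenomeRecord,
    min_len_codons: int = 60,
    max_n_fraction: float = 0.01,
) -> GenomeRecord:
    """Populate the proteome by a six-frame open-reading-frame scan.

    An ORF runs from a start codon (ATG/GTG/TTG) to the next in-frame stop;
    within each stop-bounded segment only the longest ORF (the first start)
    is kept, and unterminated runs are discarded. Coordinates are recorded
    0-based half-open on the forward strand, spanning start codon through
    stop codon. The initiator residue is reported as M regardless of the
    start codon, following the usual gene-calling convention.
    """
    if not genome.contigs:
        raise InputError("extract_orfs: genome has no contigs")
    if min_len_codons < 1:
        raise InputError("extract_orfs: min_len_codons must be >= 1")
    proteome: list[tuple[str, str]] = []
    coords: dict[str, tuple[str, int, int, str]] = {}
    for contig_id, seq in genome.contigs:
        seq = seq.upper()
        n_bad = sum(1 for c in seq if c not in "ACGT")
        if len(seq) and n_bad / len(seq) > max_n_fraction:
            raise InputError(
                f"extract_orfs: contig {contig_id} has {n_bad}/{len(seq)} "
                "non-ACGT characters (exceeds allowed fraction)"
            )
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for frame in range(3):
                start_idx: int | None = None
                for pos in range(frame, len(s) - 2, 3):
                    codon = s[pos : pos + 3]
                    if codon in STOP_CODONS:
                        if start_idx is not None:
                            n_codons = (pos - start_idx) // 3
                            if n_codons >= min_len_codons:
                                codons = [s[i : i + 3] for i in range(start_idx, pos, 3)]
                                protein = "M" + _translate(codons[1:])
                                span = (start_idx, pos + 3)  # incl. stop codon
                                if strand == "+":
                                    fwd = span
                                else:
                                    fwd = (L - span[1], L - span[0])
                                pid = f"{contig_id}_{fwd[0]}_{fwd[1]}_{strand}"
                                proteome.append((pid, protein))
                                coords[pid] = (contig_id, fwd[0], fwd[1], strand)
                            start_idx = None
                    elif start_idx is None and codon in START_CODONS:
                        start_idx = pos
    proteome.sort(key=lambda rec: (coords[rec[0]][0], coords[rec[0]][1]))
    return GenomeRecord(
        genome_id=genome.genome_id,
        contigs=genome.contigs,
        proteome=proteome,
        habitat=genome.habitat,
        lineage=genome.lineage,
        orf_coords=coords,
    )


@dataclass
class GeneMatrix:
    """Genomes x marker-families copy-number matrix (binarizable)."""

    df: pd.DataFrame  # integer copy numbers, rows = genomes, cols = families
    provenance: dict = field(default_factory=dict)

    def binarized(self) -> pd.DataFrame:
        return (self.df >= 1).astype(int)

    def row(self, genome_id: str) -> pd.Series:
        return self.df.loc[genome_id]


def _best_score_hit(protein: str, pid: str, family, gap_open: float, gap_extend: float) -> HomologyHit:
    best = None
    for _, ref in family.reference_seqs:
        hit = local_align(
            protein, ref, gap_open=gap_open, gap_extend=gap_extend,
            query_id=pid, family_id=family.family_id,
        )
        if best is None or hit.score > best.score:
            best = hit
    return best


def search_proteome(
    proteome: list[tuple[str, str]],
    panel: MarkerPanel,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_identity: float | None = None,
    min_coverage: float | None = None,
    profiles: dict[str, ProfileModel] | None = None,
    max_evalue: float = 1e-3,
) -> dict[str, HomologyHit]:
    """Best passing family per protein (best-hit assignment).

    Score-mode hits must first be significant (e-value over the panel's
    score-reference search space at most ``max_evalue``, the customary
    protein-search reporting cutoff) and then pass the family's identity and
    coverage thresholds; without the significance gate, short spurious local
    alignments of background ORFs can clear a bare 30%/75% rule. Among
    passing hits the single best is kept per protein, ranked by score, then
    identity, then lexicographic family id, so one protein never counts for
    two families (prevents double counting of paralogous shell proteins).
    """
    if len(panel) == 0:
        raise InputError("search_proteome: empty panel")
    if profiles is None:
        profiles = {
            fam.family_id: build_profile(fam)
            for fam in panel
            if fam.search_mode == "profile"
        }
    db_len = sum(
        len(seq) for fam in panel if fam.search_mode == "score" for _, seq in fam.reference_seqs
    )
    assignments: dict[str, HomologyHit] = {}
    for pid, protein in proteome:
        passing: list[HomologyHit] = []
        for fam in panel:
            if fam.search_mode == "score":
                hit = _best_score_hit(protein, pid, fam, gap_open, gap_extend)
                min_id = fam.min_identity if min_identity is None else min_identity
                min_cov = fam.min_query_coverage if min_coverage is None else min_coverage
                if (
                    evalue(hit.score, len(protein), db_len) <= max_evalue
                    and hit.identity > min_id
                    and hit.query_coverage > min_cov
                ):
                    passing.append(hit)
            else:
                hit = profile_search(protein, profiles[fam.family_id], query_id=pid)
                if hit is not None:
                    passing.append(hit)
        if passing:
            passing.sort(key=lambda h: (-h.score, -h.identity, h.family_id))
            assignments[pid] = passing[0]
    return assignments


def build_gene_matrix(
    genomes: list[GenomeRecord],
    panel: MarkerPanel,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    min_identity: float | None = None,
    min_coverage: float | None = None,
    max_evalue: float = 1e-3,
) -> GeneMatrix:
    """Count detected marker copies for every genome and family."""
    if len(panel) == 0:
        raise InputError("build_gene_matrix: empty panel")
    for g in genomes:
        if not g.proteome:
            raise InputError(f"build_gene_matrix: genome {g.genome_id} has an empty proteome")
    profiles = {
        fam.family_id: build_profile(fam) for fam in panel if fam.search_mode == "profile"
    }
    family_ids = panel.family_ids
    data = np.zeros((len(genomes), len(family_ids)), dtype=int)
    col = {fid: i for i, fid in enumerate(family_ids)}
    for gi, genome in enumerate(genomes):
        assigned = search_proteome(
            genome.proteome, panel, gap_open, gap_extend,
            min_identity, min_coverage, profiles, max_evalue,
        )
        for hit in assigned.values():
            data[gi, col[hit.family_id]] += 1
    df = pd.DataFrame(data, index=[g.genome_id for g in genomes], columns=family_ids)
    return GeneMatrix(
        df=df,
        provenance={
            "min_identity": min_identity if min_identity is not None else "per-family (default 30)",
            "min_coverage": min_coverage if min_coverage is not None else "per-family (default 75)",
            "gap_open": gap_open,
            "gap_extend": gap_extend,
            "max_evalue": max_evalue,
            "comparison": "strict >",
        },
    )


@dataclass
class CCMGenotype:
    """Per-genome CCM genotype call with supporting evidence."""

    genome_id: str
    call: str  # alpha | beta | ambiguous
    rubisco_form: str  # 1A | 1B | none
    carboxysome_type: str  # alpha | beta | none
    evidence: list[str] = field(default_factory=list)


def classify_ccm(row: pd.Series, genome_id: str | None = None) -> CCMGenotype:
    """Call a genome alpha/beta/ambiguous from its marker copy numbers."""
    get = lambda fid: int(row.get(fid, 0))
    if get("rbcL_1A") >= 1 and get("rbcL_1B") == 0:
        rubisco = "1A"
    elif get("rbcL_1B") >= 1 and get("rbcL_1A") == 0:
        rubisco = "1B"
    else:
        rubisco = "none"
    if get("csoS1") >= 1 and get("csoS2") >= 1:
        carboxysome = "alpha"
    elif get("ccmK") >= 1 and get("ccmM") >= 1:
        carboxysome = "beta"
    else:
        carboxysome = "none"
    if rubisco == "1A" and carboxysome == "alpha":
        call = "alpha"
        evidence = ["rbcL_1A", "csoS1", "csoS2"]
    elif rubisco == "1B" and carboxysome == "beta":
        call = "beta"
        evidence = ["rbcL_1B", "ccmK", "ccmM"]
    else:
        call = "ambiguous"
        evidence = []
    evidence = [fid for fid in evidence if get(fid) >= 1]
    gid = genome_id if genome_id is not None else str(row.name)
    return CCMGenotype(
        genome_id=gid,
        call=call,
        rubisco_form=rubisco,
        carboxysome_type=carboxysome,
        evidence=evidence,
    )


def classify_matrix(matrix: GeneMatrix) -> dict[str, CCMGenotype]:
    return {gid: classify_ccm(matrix.df.loc[gid], gid) for gid in matrix.df.index}


#: Named completeness rules over binarized rows.
INVENTORY_RULES: dict[str, tuple[str, ...]] = {
    "cmp_complete": ("cmpA", "cmpB", "cmpC", "cmpD"),
}


def summarize_inventory(
    matrix: GeneMatrix,
    grouping: dict[str, str],
    rule: str,
) -> pd.DataFrame:
    """Per-group counts of genomes whose binarized row satisfies ``rule``.

    ``rule`` is either a named rule (e.g. ``cmp_complete`` = presence of all
    four Cmp ABC-transporter subunits) or ``has_<family_id>`` for a single
    family.
    """
    if rule in INVENTORY_RULES:
        required = INVENTORY_RULES[rule]
    elif rule.startswith("has_"):
        required = (rule[4:],)
    else:
        raise InputError(f"unknown inventory rule: {rule!r}")
    missing = [fid for fid in required if fid not in matrix.df.columns]
    if missing:
        raise InputError(f"rule {rule!r} references unknown families: {missing}")
    unlabeled = [gid for gid in matrix.df.index if gid not in grouping]
    if unlabeled:
        raise InputError(f"genomes without a group label: {unlabeled}")
    binary = matrix.binarized()
    satisfied = binary[list(required)].all(axis=1)
    rows = []
    groups = sorted(set(grouping[gid] for gid in matrix.df.index))
    for group in groups:
        members = [gid for gid in matrix.df.index if grouping[gid] == group]
        rows.append(
            dict(
                group=group,
                n_satisfying=int(satisfied.loc[members].sum()),
                n_total=len(members),
            )
        )
    return pd.DataFrame(rows)
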