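"""Exact Smith-Waterman local protein alignment with affine gaps.

This is the workhorse behind score-mode marker detection: each candidate
protein is aligned against family reference sequences and the resulting
identity / query-coverage pair is compared against the family thresholds
(strict ``>`` comparisons by default).

Conventions (documented because they change the numbers):

* identity = matched columns / alignment length, where alignment length
  counts gap columns (BLAST-style percent identity);
* query coverage = query residues inside the aligned region / query length;
* a gap of length k costs ``gap_open + k * gap_extend``; defaults 11/1
  mirror the de facto protein-search defaults with BLOSUM62.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

from ._align import ALPHABET, encode, sw_kernel
from .io import InputError

__all__ = ["HomologyHit", "local_align", "blosum_matrix", "bit_score", "evalue"]

DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0

# Karlin-Altschul parameters for gapped BLOSUM62 with gap costs 11/1 (the
# values protein-search tools ship for this scoring system). Used only to
# turn raw scores into bit scores / e-values for the significance gate; a
# custom matrix falls back to these as an approximation.
KA_LAMBDA = 0.267
KA_K = 0.041


def bit_score(raw_score: float) -> float:
    """Normalized (bit) score of a raw alignment score."""
    return (KA_LAMBDA * raw_score - np.log(KA_K)) / np.log(2.0)


def evalue(raw_score: float, query_len: int, db_len: int) -> float:
    """Expected number of chance alignments at this score in an
    ``query_len x db_len`` search space."""
    return float(query_len) * float(db_len) * 2.0 ** (-bit_score(raw_score))


@dataclass
class HomologyHit:
    """A local-alignment hit of a query protein against a family reference."""

    query_id: str
    family_id: str
    score: float
    identity: float  # percent of alignment columns that match
    query_coverage: float  # percent of query residues inside the alignment
    aln_length: int  # alignment columns, gaps included
    query_start: int = 0  # 0-based half-open on the query
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0

    def __post_init__(self) -> None:
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be within [0, 100]")
        if not (0.0 <= self.query_coverage <= 100.0):
            raise ValueError("query_coverage must be within [0, 100]")


@lru_cache(maxsize=4)
def blosum_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """A substitution matrix as a dense array over :data:`ALPHABET`."""
    mat = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a][b]
    return out


def local_align(
    query: str,
    target: str,
    substitution_matrix: np.ndarray | str = "BLOSUM62",
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
    query_id: str = "query",
    family_id: str = "target",
) -> HomologyHit:
    """Optimal local alignment of two protein sequences.

    Ties between equally scoring alignments resolve to the one ending at the
    smallest ``(target_end, query_end)``.
    """
    if not query or not target:
        raise InputError("local_align: empty sequence")
    if not (gap_open >= gap_extend > 0):
        raise InputError("local_align: require gap_open >= gap_extend > 0")
    sub = blosum_matrix(substitution_matrix) if isinstance(substitution_matrix, str) else substitution_matrix
    q = encode(query)
    t = encode(target)
    score, q_start, q_end, t_start, t_end, matches, columns, q_cols = sw_kernel(
        q, t, sub, float(gap_open), float(gap_extend)
    )
    return HomologyHit(
        query_id=query_id,
        family_id=family_id,
        score=float(score),
        identity=100.0 * matches / columns,
        query_coverage=100.0 * q_cols / len(query),
        aln_length=int(columns),
        query_start=int(q_start),
        query_end=int(q_end),
        target_start=int(t_start),
        target_end=int(t_end),
    )
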