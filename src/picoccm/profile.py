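"""Position-specific scoring profile search for poorly conserved families.

Carbonic anhydrases and inorganic-carbon transporters diverge too far for a
fixed identity threshold to be meaningful, so those families are detected
with a per-column log-odds profile built from a pre-aligned reference block:

    score(column c, residue a) = log2( p_c(a) / bg(a) )

with ``p_c(a) = (n_c(a) + bg(a)) / (N + 1)`` — counts plus one pseudocount
distributed by the background — and a uniform background over the 20
standard residues. A query is reported as a hit when its best local
alignment to the profile covers at least half of the profile columns at a
mean score of at least 0.5 bits per covered column.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._align import ALPHABET, encode, profile_kernel
from .align import HomologyHit
from .io import InputError
from .panel import MarkerFamily

__all__ = ["ProfileModel", "profile_search"]

_N_STANDARD = 20  # the first 20 ALPHABET entries are the standard residues
_BG = 1.0 / _N_STANDARD

#: Gap penalties in bits for query-vs-profile alignment (length-k gap costs
#: ``open + k * extend``).
PROFILE_GAP_OPEN = 4.0
PROFILE_GAP_EXTEND = 1.0

DEFAULT_MIN_BITS_PER_COLUMN = 0.5
DEFAULT_MIN_PROFILE_COVERAGE = 0.5


@dataclass
class ProfileModel:
    """Log-odds profile over alignment columns plus the column consensus."""

    family_id: str
    scores: np.ndarray  # (columns, len(ALPHABET)) bits
    consensus: np.ndarray  # column-consensus residue codes

    @property
    def n_columns(self) -> int:
        return int(self.scores.shape[0])

    @classmethod
    def from_block(cls, family_id: str, block: list[tuple[str, str]]) -> "ProfileModel":
        if len(block) < 2:
            raise InputError(f"profile {family_id}: need >= 2 aligned sequences")
        lengths = {len(s) for _, s in block}
        if len(lengths) != 1:
            raise InputError(f"profile {family_id}: ragged reference block")
        codes = np.stack([encode(seq) for _, seq in block])
        n_seqs, n_cols = codes.shape
        counts = np.zeros((n_cols, _N_STANDARD))
        for c in range(n_cols):
            for code in codes[:, c]:
                if code < _N_STANDARD:
                    counts[c, code] += 1
        probs = (counts + _BG) / (n_seqs + 1.0)
        bits = np.log2(probs / _BG)
        scores = np.zeros((n_cols, len(ALPHABET)))
        scores[:, :_N_STANDARD] = bits
        # ambiguity codes (B, Z, X) score as the background expectation
        scores[:, _N_STANDARD:] = (bits * _BG).sum(axis=1, keepdims=True)
        return cls(family_id=family_id, scores=scores, consensus=counts.argmax(axis=1))


def build_profile(family: MarkerFamily) -> ProfileModel:
    if family.search_mode != "profile":
        raise InputError(f"family {family.family_id} is not a profile family")
    return ProfileModel.from_block(family.family_id, family.aligned_block)


def profile_search(
    query: str,
    family: MarkerFamily | ProfileModel,
    min_bits_per_column: float = DEFAULT_MIN_BITS_PER_COLUMN,
    min_profile_coverage: float = DEFAULT_MIN_PROFILE_COVERAGE,
    query_id: str = "query",
) -> HomologyHit | None:
    """Search one query against one profile family.

    Returns a :class:`HomologyHit` (score in total bits, identity measured
    against the column consensus) or ``None`` when the hit rule is not met.
    A query shorter than the required covered-column count can never qualify
    and is rejected outright.
    """
    model = family if isinstance(family, ProfileModel) else build_profile(family)
    if not query:
        raise InputError("profile_search: empty query")
    q = encode(query)
    min_cols = int(np.ceil(min_profile_coverage * model.n_columns))
    if len(q) < min_cols:
        return None
    score, covered, q_cols, q_start, q_end, p_start, p_end = profile_kernel(
        q, model.scores, PROFILE_GAP_OPEN, PROFILE_GAP_EXTEND
    )
    if covered < min_cols or score < min_bits_per_column * covered:
        return None
    matches = int((q[q_start:q_end][: p_end - p_start] == model.consensus[p_start:p_end][: q_end - q_start]).sum())
    aln_len = max(covered, q_cols)
    return HomologyHit(
        query_id=query_id,
        family_id=model.family_id,
        score=float(score),
        identity=100.0 * min(matches, aln_len) / aln_len,
        query_coverage=100.0 * q_cols / len(query),
        aln_length=int(aln_len),
        query_start=int(q_start),
        query_end=int(q_end),
        target_start=int(p_start),
        target_end=int(p_end),
    )
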