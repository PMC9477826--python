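"""Marker reference panel for CO2-concentrating-mechanism (CCM) gene families.

The panel covers the gene inventory used to genotype unicellular cyanobacteria
as alpha (form 1A RuBisCO + alpha-carboxysome, ``cso`` cluster) or beta
(form 1B RuBisCO + beta-carboxysome, ``ccm`` cluster): RuBisCO subunits,
activases/chaperones, Ci-responsive transcriptional regulators, carboxysome
shell components, the carbonic-anhydrase families (alpha, beta clades A-D,
gamma, epsilon/CsoSCA) and inorganic-carbon transporters (CmpABCD, BicA,
SbtA1/2, IctB, NDH-1 ChpX/ChpY).

Well-conserved families are searched by pairwise Smith-Waterman against
reference sequences (``search_mode='score'``); poorly conserved families
(carbonic anhydrases, Ci transporters) by a position-specific scoring profile
built from a pre-aligned reference block (``search_mode='profile'``).

The packaged panel under ``data/synthetic_panel`` is a simulated stand-in for
a curated orthologue collection: its sequences are generated, not biological.
It preserves the family structure, thresholds and alpha/beta diagnostics, which
is what the downstream machinery and its tests depend on.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "MarkerFamily",
    "MarkerPanel",
    "FAMILY_TABLE",
    "FAMILY_IDS",
    "FAMILY_ALIASES",
    "ALPHA_DIAGNOSTIC",
    "BETA_DIAGNOSTIC",
    "SHARED_FAMILIES",
    "CATEGORIES",
]

CATEGORIES = (
    "rubisco",
    "activase_chaperone",
    "regulator",
    "carboxysome",
    "carbonic_anhydrase",
    "ci_transporter",
)

# family_id -> (category, search_mode)
FAMILY_TABLE: dict[str, tuple[str, str]] = {
    "rbcL_1A": ("rubisco", "score"),
    "rbcL_1B": ("rubisco", "score"),
    "rbcS": ("rubisco", "score"),
    "cbbX": ("activase_chaperone", "score"),
    "rbcX": ("activase_chaperone", "score"),
    "raf1": ("activase_chaperone", "score"),
    "raf2": ("activase_chaperone", "score"),
    "cmpR": ("regulator", "score"),
    "cyaAbr2": ("regulator", "score"),
    "csoS1": ("carboxysome", "score"),
    "csoS2": ("carboxysome", "score"),
    "csoS4A": ("carboxysome", "score"),
    "csoS4B": ("carboxysome", "score"),
    "ccmK": ("carboxysome", "score"),
    "ccmL": ("carboxysome", "score"),
    "ccmM": ("carboxysome", "score"),
    "ccmN": ("carboxysome", "score"),
    "ccmO": ("carboxysome", "score"),
    "ccmP": ("carboxysome", "score"),
    "ca_alpha": ("carbonic_anhydrase", "profile"),
    "ca_beta_A": ("carbonic_anhydrase", "profile"),
    "ca_beta_B": ("carbonic_anhydrase", "profile"),
    "ca_beta_C": ("carbonic_anhydrase", "profile"),
    "ca_beta_D": ("carbonic_anhydrase", "profile"),
    "ca_gamma": ("carbonic_anhydrase", "profile"),
    "ca_epsilon": ("carbonic_anhydrase", "profile"),
    "cmpA": ("ci_transporter", "profile"),
    "cmpB": ("ci_transporter", "profile"),
    "cmpC": ("ci_transporter", "profile"),
    "cmpD": ("ci_transporter", "profile"),
    "bicA": ("ci_transporter", "profile"),
    "sbtA1": ("ci_transporter", "profile"),
    "sbtA2": ("ci_transporter", "profile"),
    "ictB": ("ci_transporter", "profile"),
    "chpX": ("ci_transporter", "profile"),
    "chpY": ("ci_transporter", "profile"),
}

FAMILY_IDS: tuple[str, ...] = tuple(FAMILY_TABLE)

#: Accepted synonyms for family ids (gene-name spellings used in the field).
FAMILY_ALIASES: dict[str, str] = {
    "csoSCA": "ca_epsilon",
    "csoS3": "ca_epsilon",
    "rbcS_1A": "rbcS",
    "rbcS_1B": "rbcS",
}

#: Families diagnostic of the alpha genotype (form 1A RuBisCO, cso carboxysome,
#: CbbX/Raf2 activase-chaperone pair, epsilon and beta-A carbonic anhydrases).
ALPHA_DIAGNOSTIC = frozenset(
    {"rbcL_1A", "cbbX", "raf2", "csoS1", "csoS2", "csoS4A", "csoS4B",
     "ca_epsilon", "ca_beta_A"}
)

#: Families diagnostic of the beta genotype (form 1B RuBisCO, ccm carboxysome,
#: RbcX/Raf1, Ci regulators, beta-B/beta-D carbonic anhydrases).
BETA_DIAGNOSTIC = frozenset(
    {"rbcL_1B", "rbcX", "raf1", "cmpR", "cyaAbr2", "ccmK", "ccmL", "ccmM",
     "ccmN", "ccmO", "ccmP", "ca_beta_B", "ca_beta_D"}
)

#: Families found in both groups (shared small subunit, beta-C/gamma CAs, Ci
#: transporters that cross the alpha/beta divide).
SHARED_FAMILIES = frozenset(FAMILY_TABLE) - ALPHA_DIAGNOSTIC - BETA_DIAGNOSTIC


def canonical_family_id(family_id: str) -> str:
    """Resolve aliases (e.g. ``csoSCA``) to the canonical family id."""
    from .io import InputError

    fid = FAMILY_ALIASES.get(family_id, family_id)
    if fid not in FAMILY_TABLE:
        raise InputError(f"unknown marker family: {family_id!r}")
    return fid


@dataclass
class MarkerFamily:
    """One CCM gene family: reference sequences plus detection thresholds.

    ``min_query_coverage`` and ``min_identity`` are percentages applied with a
    strict ``>`` comparison in score mode. Profile mode instead requires a
    bit-score of at least ``min_bits_per_column`` over at least
    ``min_profile_coverage`` of profile columns.
    """

    family_id: str
    category: str
    reference_seqs: list[tuple[str, str]]  # (seq_id, amino-acid sequence)
    min_query_coverage: float = 75.0
    min_identity: float = 30.0
    search_mode: str = "score"
    aligned_block: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.search_mode not in ("score", "profile"):
            raise ValueError(f"unknown search_mode {self.search_mode!r}")
        if not self.reference_seqs:
            raise ValueError(f"family {self.family_id}: no reference sequences")
        if self.search_mode == "profile":
            block = self.aligned_block or self.reference_seqs
            lengths = {len(s) for _, s in block}
            if len(block) < 2:
                raise ValueError(
                    f"family {self.family_id}: profile mode needs >=2 aligned "
                    "reference sequences"
                )
            if len(lengths) != 1:
                raise ValueError(
                    f"family {self.family_id}: ragged reference block"
                )
            if not self.aligned_block:
                self.aligned_block = list(self.reference_seqs)

    @property
    def representative(self) -> str:
        """The first reference sequence (used when planting synthetic genes)."""
        return self.reference_seqs[0][1]


class MarkerPanel:
    """An ordered collection of :class:`MarkerFamily` keyed by family id."""

    def __init__(self, families: list[MarkerFamily]):
        if not families:
            raise ValueError("empty marker panel")
        self.families: dict[str, MarkerFamily] = {}
        for fam in families:
            if fam.family_id in self.families:
                raise ValueError(f"duplicate family {fam.family_id}")
            self.families[fam.family_id] = fam

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families.values())

    def __contains__(self, family_id: str) -> bool:
        return family_id in self.families

    def __getitem__(self, family_id: str) -> MarkerFamily:
        return self.families[canonical_family_id(family_id)]

    @property
    def family_ids(self) -> list[str]:
        return list(self.families)

    @classmethod
    def load(cls, panel_dir: str | Path) -> "MarkerPanel":
        """Load a panel from a directory with ``families.tsv``, a reference
        FASTA (``refs.faa``) and per-family aligned blocks ``blocks/<id>.afa``.
        """
        from .io import read_fasta  # local import to avoid a cycle

        panel_dir = Path(panel_dir)
        tsv = panel_dir / "families.tsv"
        if not tsv.exists():
            raise FileNotFoundError(f"panel schema not found: {tsv}")
        refs: dict[str, list[tuple[str, str]]] = {}
        for rid, seq in read_fasta(panel_dir / "refs.faa"):
            fid = rid.split("|")[0]
            refs.setdefault(fid, []).append((rid, seq))
        families = []
        with open(tsv, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                fid = row["family_id"]
                mode = row["search_mode"]
                block: list[tuple[str, str]] = []
                if mode == "profile":
                    block_path = panel_dir / "blocks" / f"{fid}.afa"
                    if not block_path.exists():
                        raise FileNotFoundError(
                            f"profile family {fid}: missing aligned block "
                            f"{block_path}"
                        )
                    block = list(read_fasta(block_path))
                families.append(
                    MarkerFamily(
                        family_id=fid,
                        category=row["category"],
                        reference_seqs=refs.get(fid) or block,
                        min_query_coverage=float(row["min_query_coverage"]),
                        min_identity=float(row["min_identity"]),
                        search_mode=mode,
                        aligned_block=block,
                    )
                )
        return cls(families)

    @classmethod
    def default(cls) -> "MarkerPanel":
        """The packaged synthetic panel (simulated reference sequences)."""
        root = resources.files("picoccm.data") / "synthetic_panel"
        with resources.as_file(root) as path:
            return cls.load(path)
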