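"""Regenerate the packaged synthetic marker panel.

The panel is a simulated stand-in for a curated CCM orthologue collection:
every sequence here is drawn from a fixed-seed random process, not from a
biological database. Family structure, thresholds and search modes are the
real content; the residues only need to be mutually unrelated across families
and internally related within a family.

Run from the repository root:

    python scripts/build_panel.py
"""
from __future__ import annotations

import csv
import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from picoccm.panel import FAMILY_TABLE  # noqa: E402

AA = "ACDEFGHIKLMNPQRSTVWY"
PANEL_SEED = 20220718
OUT = ROOT / "src" / "picoccm" / "data" / "synthetic_panel"


def mutate(seq: str, identity: float, rng: np.random.Generator) -> str:
    """Substitute round((1-identity)*L) positions, keeping position 0 ('M')."""
    n_sub = round((1.0 - identity) * len(seq))
    positions = rng.choice(np.arange(1, len(seq)), size=n_sub, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AA if a != out[pos]]
        out[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def main() -> None:
    rng = np.random.default_rng(PANEL_SEED)
    (OUT / "blocks").mkdir(parents=True, exist_ok=True)

    refs_fasta: list[str] = []
    rows = []
    for fid, (category, mode) in FAMILY_TABLE.items():
        length = int(rng.integers(160, 300))
        master = "M" + "".join(rng.choice(list(AA), size=length - 1))
        if mode == "score":
            seqs = [master, mutate(master, 0.85, rng)]
            for i, seq in enumerate(seqs, 1):
                refs_fasta.append(f">{fid}|ref{i}\n{seq}")
        else:
            block = [master] + [mutate(master, ident, rng) for ident in (0.85, 0.80, 0.75)]
            with open(OUT / "blocks" / f"{fid}.afa", "w") as fh:
                for i, seq in enumerate(block, 1):
                    fh.write(f">{fid}|aln{i}\n{seq}\n")
            # profile families also expose their first sequence as a plain
            # reference so synthetic genomes can plant variants of it
            refs_fasta.append(f">{fid}|ref1\n{master}")
        rows.append(
            dict(
                family_id=fid,
                category=category,
                search_mode=mode,
                min_query_coverage=75.0,
                min_identity=30.0,
                length=length,
            )
        )

    with open(OUT / "refs.faa", "w") as fh:
        fh.write("\n".join(refs_fasta) + "\n")
    with open(OUT / "families.tsv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0]), delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)
    print(f"wrote {len(rows)} families to {OUT}")


if __name__ == "__main__":
    main()
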