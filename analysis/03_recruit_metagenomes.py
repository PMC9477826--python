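"""Recruit the simulated metagenomes against the reference genomes.

Maps every metagenome against the 2 alpha + 2 beta recruitment references,
applies the >95% identity / >50 bp filters and the >2 RPKG detection
threshold, and writes the genomes x metagenomes RPKG matrix.
"""
from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

import common as C
from picoccm.genotyping import GenomeRecord
from picoccm.io import read_fasta, read_sequences, write_matrix
from picoccm.recruitment import (
    ReferenceIndex,
    apply_detection_threshold,
    assign_multimappers,
    compute_rpkg,
    filter_hits,
    map_reads,
)


def main() -> None:
    refs = [
        GenomeRecord(genome_id=name, contigs=read_fasta(C.GENOMES_DIR / f"{name}.fna"))
        for name in C.RECRUIT_REFS
    ]
    index = ReferenceIndex(refs)
    lengths = {g.genome_id: g.genome_length_bp for g in refs}
    columns = {}
    for path in sorted(C.READS_DIR.glob("lake_*.fastq")):
        reads = read_sequences(path, "fastq")
        hits = assign_multimappers(filter_hits(map_reads(reads, index)))
        counts: dict[str, int] = {}
        for h in hits:
            counts[h.genome_id] = counts.get(h.genome_id, 0) + 1
        profile = compute_rpkg(
            counts, lengths, sum(len(s) for _, s in reads), metagenome_id=path.stem,
            filters=dict(min_identity=95.0, min_aln_bp=50),
        )
        profile = apply_detection_threshold(profile)
        columns[path.stem] = pd.Series(profile.rpkg)
        print(f"{path.stem}: {sum(counts.values())} passing reads")
    rpkg = pd.DataFrame(columns).fillna(0.0)
    rpkg.index.name = "genome_id"
    write_matrix(C.RPKG_TSV, rpkg)
    print(f"RPKG matrix ({rpkg.shape[0]} genomes x {rpkg.shape[1]} metagenomes) -> {C.RPKG_TSV}")


if __name__ == "__main__":
    main()
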