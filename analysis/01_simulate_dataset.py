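"""Simulate the study stand-in: isolate genomes and lake metagenomes.

Writes 20 mini-genomes (10 alpha, 10 beta; diagnostic CCM marker
complements planted at 60% protein identity to the panel references) and 20
metagenomes drawn from a 2-alpha + 2-beta mixture with a summed alpha:beta
abundance of 7:1. Ground truth (planted loci) goes to results/.
"""
from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

import common as C
from picoccm.io import write_fasta, write_fastq
from picoccm.panel import MarkerPanel
from picoccm.synthetic import (
    CommunitySpec,
    GenotypeSpec,
    alpha_marker_set,
    beta_marker_set,
    generate_genome,
    simulate_metagenome,
)


def main() -> None:
    panel = MarkerPanel.default()
    C.GENOMES_DIR.mkdir(parents=True, exist_ok=True)
    C.READS_DIR.mkdir(parents=True, exist_ok=True)
    C.RESULTS.mkdir(parents=True, exist_ok=True)

    genomes, rows = [], []
    for i in range(C.N_ALPHA + C.N_BETA):
        ccm_class = "alpha" if i < C.N_ALPHA else "beta"
        markers = (
            alpha_marker_set(C.PLANTED_IDENTITY)
            if ccm_class == "alpha"
            else beta_marker_set(C.PLANTED_IDENTITY)
        )
        spec = GenotypeSpec(
            label=f"{ccm_class}_{i:02d}", ccm_class=ccm_class,
            markers=markers, genome_length=C.GENOME_LENGTH,
        )
        genome, loci = generate_genome(spec, seed=C.SEED * 100 + i, panel=panel)
        write_fasta(C.GENOMES_DIR / f"{genome.genome_id}.fna", genome.contigs)
        genomes.append(genome)
        rows += [
            dict(
                genome_id=l.genome_id, family_id=l.family_id, contig=l.contig,
                start=l.start, end=l.end, strand=l.strand,
                planted_identity=l.planted_identity,
            )
            for l in loci
        ]
    truth = pd.DataFrame(rows)
    truth.to_csv(C.TRUTH_TSV, sep="\t", index=False)
    print(f"wrote {len(genomes)} genomes ({C.GENOME_LENGTH} bp each), "
          f"{len(truth)} planted loci -> {C.TRUTH_TSV}")

    refs = [g for g in genomes if g.genome_id in C.RECRUIT_REFS]
    members = [
        (g.genome_id, C.ALPHA_TO_BETA / 2 if g.genome_id.startswith("alpha") else 0.5)
        for g in refs
    ]
    for m in range(C.N_METAGENOMES):
        community = CommunitySpec(
            members=members, n_reads=C.N_READS, read_length=C.READ_LENGTH,
            error_rate=C.ERROR_RATE, seed=C.SEED * 1000 + m,
        )
        read_set = simulate_metagenome(community, refs)
        write_fastq(
            C.READS_DIR / f"lake_{m:02d}.fastq",
            [(rid, seq) for rid, seq, _, _ in read_set.reads],
        )
    print(f"wrote {C.N_METAGENOMES} metagenomes x {C.N_READS} reads -> {C.READS_DIR}")


if __name__ == "__main__":
    main()
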