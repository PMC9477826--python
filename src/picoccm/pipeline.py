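"""End-to-end pipeline: simulate -> genotype -> recruit -> ordinate -> dominance.

The pipeline is deterministic given the config seed and records a provenance
JSON (package version, thresholds, seeds, input paths) sufficient to re-run
it to identical results.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .genotyping import GenomeRecord, build_gene_matrix, classify_matrix, extract_orfs
from .io import InputError, read_fasta, write_fastq, write_matrix, _iter_reads
from .ordination import bray_curtis, kulczynski_binary, nmds, pco
from .panel import MarkerPanel
from .recruitment import (
    DEFAULT_DETECTION_RPKG,
    DEFAULT_MIN_ALN_BP,
    DEFAULT_MIN_IDENTITY,
    ReferenceIndex,
    apply_detection_threshold,
    assign_multimappers,
    compute_rpkg,
    filter_hits,
    map_reads,
    summarize_dominance,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "build_demo_dataset"]


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; round-trips through YAML losslessly."""

    genomes_dir: str
    reads: list[str]
    out_dir: str
    panel_dir: str | None = None  # None -> packaged synthetic panel
    min_identity_pct: float = DEFAULT_MIN_IDENTITY
    min_aln_bp: int = DEFAULT_MIN_ALN_BP
    detection_rpkg: float = DEFAULT_DETECTION_RPKG
    multimap: str = "best"
    ordination_method: str = "pco"
    dims: int = 2
    min_orf_codons: int = 60
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if not Path(self.genomes_dir).is_dir():
            raise InputError(f"genomes dir not found: {self.genomes_dir}")
        for path in self.reads:
            if not Path(path).exists():
                raise InputError(f"reads file not found: {path}")
        if self.panel_dir is not None and not Path(self.panel_dir).is_dir():
            raise InputError(f"panel dir not found: {self.panel_dir}")
        if self.multimap not in ("best", "all"):
            raise InputError(f"multimap must be best|all, got {self.multimap!r}")
        if self.ordination_method not in ("pco", "nmds"):
            raise InputError(f"ordination_method must be pco|nmds")
        if not (0 < self.min_identity_pct <= 100) or self.min_aln_bp <= 0 or self.detection_rpkg < 0:
            raise InputError("thresholds out of range")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _load_genomes(genomes_dir: str | Path) -> list[GenomeRecord]:
    paths = sorted(Path(genomes_dir).glob("*.fna")) + sorted(Path(genomes_dir).glob("*.fasta"))
    if not paths:
        raise InputError(f"no genome FASTA files (*.fna, *.fasta) in {genomes_dir}")
    genomes = []
    for path in paths:
        contigs = read_fasta(path)
        genomes.append(GenomeRecord(genome_id=path.stem, contigs=contigs))
    return genomes


def run_pipeline(config: PipelineConfig) -> dict[str, str]:
    """Run all stages; returns a mapping of artifact name -> path.

    Any stage failure leaves prior outputs on disk alongside a
    ``FAILED_<stage>`` marker file and re-raises.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        panel = MarkerPanel.load(config.panel_dir) if config.panel_dir else MarkerPanel.default()

        stage = "genotype"
        genomes = _load_genomes(config.genomes_dir)
        genomes = [extract_orfs(g, min_len_codons=config.min_orf_codons) for g in genomes]
        matrix = build_gene_matrix(genomes, panel)
        write_matrix(out / "gene_matrix.tsv", matrix.df)
        artifacts["gene_matrix"] = str(out / "gene_matrix.tsv")
        calls = classify_matrix(matrix)
        calls_df = pd.DataFrame(
            [
                dict(
                    genome_id=c.genome_id,
                    call=c.call,
                    rubisco_form=c.rubisco_form,
                    carboxysome_type=c.carboxysome_type,
                    evidence=",".join(c.evidence),
                )
                for c in calls.values()
            ]
        ).set_index("genome_id")
        calls_df.to_csv(out / "genotype_calls.tsv", sep="\t")
        artifacts["genotype_calls"] = str(out / "genotype_calls.tsv")

        stage = "recruit"
        index = ReferenceIndex(genomes)
        profiles = []
        for reads_path in config.reads:
            reads = list(_iter_reads(reads_path))
            hits = map_reads(reads, index)
            hits = filter_hits(hits, config.min_identity_pct, config.min_aln_bp)
            hits = assign_multimappers(hits, config.multimap)
            counts: dict[str, int] = {}
            for h in hits:
                counts[h.genome_id] = counts.get(h.genome_id, 0) + 1
            total_bases = sum(len(seq) for _, seq in reads)
            profile = compute_rpkg(
                counts,
                {g.genome_id: g.genome_length_bp for g in genomes},
                total_bases,
                metagenome_id=Path(reads_path).stem,
                filters=dict(
                    min_identity=config.min_identity_pct, min_aln_bp=config.min_aln_bp
                ),
            )
            profiles.append(apply_detection_threshold(profile, config.detection_rpkg))
        rpkg_df = pd.DataFrame(
            {p.metagenome_id: pd.Series(p.rpkg) for p in profiles}
        ).fillna(0.0)
        rpkg_df.index.name = "genome_id"
        write_matrix(out / "rpkg_matrix.tsv", rpkg_df)
        artifacts["rpkg_matrix"] = str(out / "rpkg_matrix.tsv")

        stage = "dominance"
        genotype_map = {gid: c.call for gid, c in calls.items()}
        dominance = summarize_dominance(profiles, genotype_map)
        dominance.per_metagenome.set_index("metagenome_id").to_csv(
            out / "dominance_summary.tsv", sep="\t"
        )
        summary = dict(
            fraction_alpha_dominant=dominance.fraction_alpha_dominant,
            median_ratio=dominance.median_ratio,
            wilcoxon_W=dominance.wilcoxon.W,
            wilcoxon_z=dominance.wilcoxon.z,
            wilcoxon_p=dominance.wilcoxon.p,
            wilcoxon_n=dominance.wilcoxon.n_effective,
        )
        with open(out / "dominance_overall.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        artifacts["dominance_summary"] = str(out / "dominance_summary.tsv")
        artifacts["dominance_overall"] = str(out / "dominance_overall.json")

        stage = "ordinate"
        D_genes = kulczynski_binary(matrix)
        if config.ordination_method == "pco":
            ord_genes = pco(D_genes)
            eig = pd.DataFrame(
                dict(
                    eigenvalue=ord_genes.eigenvalues,
                    variance_explained=list(ord_genes.variance_explained)
                    + [float("nan")] * (len(ord_genes.eigenvalues) - len(ord_genes.variance_explained)),
                )
            )
            eig.index.name = "axis"
            eig.to_csv(out / "ordination_eigenvalues.tsv", sep="\t")
            artifacts["ordination_eigenvalues"] = str(out / "ordination_eigenvalues.tsv")
        else:
            ord_genes = nmds(D_genes, dims=config.dims, seed=config.seed)
            with open(out / "ordination_stress.tsv", "w") as fh:
                fh.write(f"stress\t{ord_genes.stress}\n")
            artifacts["ordination_stress"] = str(out / "ordination_stress.tsv")
        ord_genes.coordinates_frame().to_csv(out / "ordination_coordinates.tsv", sep="\t")
        artifacts["ordination_coordinates"] = str(out / "ordination_coordinates.tsv")

        if rpkg_df.to_numpy().sum() > 0 and rpkg_df.shape[0] >= 2:
            D_rpkg = bray_curtis(rpkg_df)
            pco(D_rpkg).coordinates_frame().to_csv(
                out / "rpkg_ordination_coordinates.tsv", sep="\t"
            )
            artifacts["rpkg_ordination_coordinates"] = str(
                out / "rpkg_ordination_coordinates.tsv"
            )

        stage = "provenance"
        provenance = dict(
            picoccm_version=__version__,
            config=dataclasses.asdict(config),
            artifacts=sorted(artifacts),
        )
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=2, sort_keys=True)
        artifacts["provenance"] = str(out / "provenance.json")
    except Exception:
        (out / f"FAILED_{stage}").write_text(f"pipeline failed during stage: {stage}\n")
        logger.exception("pipeline failed during stage %s", stage)
        raise
    return artifacts


def build_demo_dataset(
    target_dir: str | Path,
    seed: int = 1,
    n_alpha: int = 2,
    n_beta: int = 2,
    n_metagenomes: int = 2,
    n_reads: int = 4000,
    genome_length: int = 30_000,
    alpha_to_beta: float = 7.0,
) -> PipelineConfig:
    """Write a small synthetic alpha-dominant dataset and return its config.

    Genomes carry the alpha/beta diagnostic marker complements at planted
    identity 0.9; each metagenome mixes all genomes with alpha:beta summed
    abundance ``alpha_to_beta``.
    """
    from .io import write_fasta
    from .synthetic import (
        CommunitySpec,
        GenotypeSpec,
        alpha_marker_set,
        beta_marker_set,
        generate_genome,
        simulate_metagenome,
    )

    target = Path(target_dir)
    genomes_dir = target / "genomes"
    reads_dir = target / "reads"
    genomes_dir.mkdir(parents=True, exist_ok=True)
    reads_dir.mkdir(parents=True, exist_ok=True)

    genomes = []
    for i in range(n_alpha):
        spec = GenotypeSpec(
            label=f"alpha_{i:02d}", ccm_class="alpha",
            markers=alpha_marker_set(0.9), genome_length=genome_length,
        )
        genome, _ = generate_genome(spec, seed=seed * 1000 + i)
        genomes.append(genome)
    for i in range(n_beta):
        spec = GenotypeSpec(
            label=f"beta_{i:02d}", ccm_class="beta",
            markers=beta_marker_set(0.9), genome_length=genome_length,
        )
        genome, _ = generate_genome(spec, seed=seed * 2000 + i)
        genomes.append(genome)
    for g in genomes:
        write_fasta(genomes_dir / f"{g.genome_id}.fna", g.contigs)

    alpha_w = alpha_to_beta / n_alpha
    beta_w = 1.0 / n_beta
    members = [(g.genome_id, alpha_w if g.genome_id.startswith("alpha") else beta_w) for g in genomes]
    reads_paths = []
    for m in range(n_metagenomes):
        community = CommunitySpec(
            members=members, n_reads=n_reads, read_length=150,
            error_rate=0.005, seed=seed * 3000 + m,
        )
        read_set = simulate_metagenome(community, genomes)
        path = reads_dir / f"lake_{m:02d}.fastq"
        write_fastq(path, [(rid, seq) for rid, seq, _, _ in read_set.reads])
        reads_paths.append(str(path))

    config = PipelineConfig(
        genomes_dir=str(genomes_dir),
        reads=reads_paths,
        out_dir=str(target / "out"),
        seed=seed,
    )
    config.to_yaml(target / "config.yaml")
    return config
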