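"""Ordinations: gene-content PCO, per-gene axis drivers, RPKG PCO, CA nMDS.

Findings on the shipped conditions: the first principal coordinate of the
Kulczynski gene-content matrix separates alpha from beta genomes; the
top-ranked genes on that axis are the carboxysome/RuBisCO diagnostics; the
Bray-Curtis PCO of RPKG profiles separates alpha from beta references; and
the nMDS restricted to carbonic-anhydrase content reaches low stress.
"""
from __future__ import annotations

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
import pandas as pd

import common as C
from picoccm.io import read_matrix, write_matrix
from picoccm.ordination import axis_gene_association, bray_curtis, kulczynski_binary, nmds, pco
from picoccm.panel import FAMILY_TABLE


def main() -> None:
    genes = read_matrix(C.GENE_MATRIX_TSV)
    D = kulczynski_binary(genes)
    result = pco(D)
    coords = result.coordinates_frame()
    coords.index.name = "genome_id"
    write_matrix(C.RESULTS / "pco_gene_content_coordinates.tsv", coords)
    eig = pd.DataFrame(
        dict(
            eigenvalue=result.eigenvalues,
            variance_explained=list(result.variance_explained)
            + [float("nan")] * (len(result.eigenvalues) - len(result.variance_explained)),
        )
    )
    eig.index.name = "axis"
    eig.to_csv(C.RESULTS / "pco_gene_content_eigenvalues.tsv", sep="\t")
    print(f"gene-content PCO: axis 1 explains {result.variance_explained[0]:.0%} of the variation")

    from picoccm.genotyping import GeneMatrix

    ranking = axis_gene_association(GeneMatrix(df=genes.astype(int)), result, axis=0, top_n=20)
    ranking.to_csv(C.RESULTS / "pco_axis1_gene_drivers.tsv", sep="\t", index=False)
    print("top-5 axis-1 driver genes:", ", ".join(ranking["gene"].head(5)))

    rpkg = read_matrix(C.RPKG_TSV)
    if rpkg.to_numpy().sum() > 0:
        result_rpkg = pco(bray_curtis(rpkg))
        coords = result_rpkg.coordinates_frame()
        coords.index.name = "genome_id"
        write_matrix(C.RESULTS / "pco_rpkg_coordinates.tsv", coords)
        print(f"RPKG Bray-Curtis PCO: axis 1 explains {result_rpkg.variance_explained[0]:.0%}")

    ca_families = [f for f, (cat, _) in FAMILY_TABLE.items() if cat == "carbonic_anhydrase"]
    ca = genes[[c for c in genes.columns if c in ca_families]]
    result_ca = nmds(kulczynski_binary(ca), dims=2, seed=C.SEED)
    coords = result_ca.coordinates_frame()
    coords.index.name = "genome_id"
    write_matrix(C.RESULTS / "nmds_carbonic_anhydrase_coordinates.tsv", coords)
    (C.RESULTS / "nmds_carbonic_anhydrase_stress.tsv").write_text(
        f"stress\t{result_ca.stress}\n"
    )
    print(f"carbonic-anhydrase nMDS stress: {result_ca.stress:.4f}")


if __name__ == "__main__":
    main()
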