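"""End-to-end orchestration of the CNV differentiation analysis.

Ties the stages together with the package's standard settings: copy-number
calling with the width-3 running-median segmentation surrogate, CNV
segmentation and the population summary, the V_ST scan over the K largest
scaffolds with top-1% outliers, annotation tallies, structure ordination and
concordance, GO enrichment of top-outlier genes, and the candidate-gene
Fisher analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import calling, candidates, structure
from .calling import CnvSummary, CopyNumberMatrix, DepthMatrix
from .candidates import GeneSet, HeatmapExport
from .genome import Feature, GenomeModel
from .structure import Concordance, Ordination
from .vst import VstTrack, scan, tally_top_annotations, top_genes

DEFAULT_KEYWORDS = ["Na+", "sodium"]


@dataclass
class AnalysisResult:
    cnm: CopyNumberMatrix
    segments: list
    summary: CnvSummary
    vst_track: VstTrack
    annotation_tally: dict[str, int]
    top_gene_ids: set[str]
    matrix: pd.DataFrame
    dist: pd.DataFrame
    ordination: Ordination
    tree_newick: str
    concordance: Concordance
    enrichment: pd.DataFrame
    candidate_set: GeneSet
    gene_tests: pd.DataFrame | None
    heatmap: HeatmapExport | None
    notes: list[str] = field(default_factory=list)


def run_analysis(
    genome: GenomeModel,
    features: list[Feature],
    go_map: pd.DataFrame,
    depths: DepthMatrix,
    keywords: list[str] = None,
    K: int = 100,
    q: float = 0.01,
    median_filter: int = 3,
    scheme: str = "all_cds",
    n_permutations: int = 999,
    seed: int | None = None,
    highlight: str | None = None,
) -> AnalysisResult:
    """Run the full analysis on a depth matrix and annotation.

    Returns an :class:`AnalysisResult` with every intermediate product;
    callers needing finer control use the stage functions directly.
    """
    keywords = keywords if keywords is not None else list(DEFAULT_KEYWORDS)
    notes: list[str] = []

    cnm = calling.call_copy_number(depths, median_filter=median_filter)
    segments = calling.segment(cnm)
    summary = calling.summarize(segments, genome, features, depths.labels)

    track = scan(cnm, depths.labels, K=K, q=q)
    tally = tally_top_annotations(track, features)
    top_ids = top_genes(track, features)

    matrix = structure.build_matrix(cnm, scheme, features=features, vst_track=track)
    dist = structure.distance(matrix)
    ordination = structure.pcoa(dist)
    tree = structure.cluster_tree(dist, method="nj")
    concordance = structure.label_concordance(dist, depths.labels,
                                              n_permutations=n_permutations, seed=seed)

    universe = set(go_map[go_map.columns[0]])
    selection = GeneSet(frozenset(top_ids & universe),
                        provenance=f"V_ST top {q:.0%} windows -> genes")
    if len(top_ids) and len(selection) < len(top_ids):
        notes.append(
            f"{len(top_ids) - len(selection)} top-outlier genes lack GO "
            "annotations and are outside the enrichment universe"
        )
    enrichment = candidates.go_enrichment(selection, go_map)

    candidate_set = candidates.keyword_search(features, keywords)
    gene_tests = None
    heatmap = None
    if candidate_set.gene_ids:
        gene_feats = [f for f in features if f.type == "gene"
                      and f.gene_id in candidate_set.gene_ids]
        gcn = candidates.gene_cn(cnm, gene_feats)
        states = candidates.score_states(gcn)
        gene_tests = candidates.fisher_per_gene(states, depths.labels)
        heatmap = candidates.heatmap_matrix(gcn, depths.labels, highlight=highlight)
    else:
        notes.append("keyword search matched no genes; candidate analysis skipped")

    return AnalysisResult(
        cnm=cnm, segments=segments, summary=summary,
        vst_track=track, annotation_tally=tally, top_gene_ids=top_ids,
        matrix=matrix, dist=dist, ordination=ordination, tree_newick=tree,
        concordance=concordance, enrichment=enrichment,
        candidate_set=candidate_set, gene_tests=gene_tests, heatmap=heatmap,
        notes=notes,
    )
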