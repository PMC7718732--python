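"""Replicated synthetic-cohort experiments validating the pipeline.

These functions run the full analysis over many simulated cohorts under the
study design the package targets (two populations of 11 and 16 individuals)
and measure: power to recover a planted copy-number-differentiated region
(V_ST top-1% membership and Bonferroni-significant per-gene Fisher test),
the behavior under the null of no population differentiation (uniform
concordance p-values, no significant genes, no enriched GO terms), and the
caller's per-window class accuracy against simulated truth.

Replicates use a deliberately reduced genome (a few hundred kb) so that a
hundred cohorts run in seconds while keeping >=1000 windows per scan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .calling import call_copy_number
from .candidates import fisher_per_gene, gene_cn, go_enrichment, keyword_search, score_states
from .pipeline import GeneSet
from .simulate import CohortSpec, PlantedRegion, simulate_cohort, simulate_genome
from .structure import build_matrix, distance, label_concordance
from .vst import scan, top_genes

logger = logging.getLogger(__name__)

# reduced-size replicate genome: ~0.25 Mb over 3 scaffolds (~1000 windows)
REPLICATE_GENOME_KWARGS = dict(n_scaffolds=3, mean_scaffold_length=80_000,
                               gene_density=0.15)
# CNV event sizes scaled with the reduced genome so the per-sample fraction
# of genome inside CNVs (a few percent, losses >> gains) matches the
# full-scale conditions; unscaled 60 kb losses on a 0.25 Mb genome can wipe
# out most of a sample's windows and break median normalization
REPLICATE_COHORT_KWARGS = dict(shared_loss_rate=6.0, loss_size_mean=4_000.0,
                               shared_gain_rate=1.0, gain_size_mean=1_000.0)
#: Bonferroni multiplier for the planted-gene test, sized to the candidate
#: panel a genome-wide keyword search typically yields
CANDIDATE_PANEL_SIZE = 83


def _spec_seed(base_seed: int, replicate: int) -> int:
    return (base_seed * 100_003 + replicate) % (2**31 - 1)


def _replicate_genome(seed: int):
    return simulate_genome(seed=seed, **REPLICATE_GENOME_KWARGS)


def planted_recovery(
    n_replicates: int = 100,
    seed: int = 0,
    pop2_cn: int = 4,
) -> pd.DataFrame:
    """Power study: plant a CN 2-vs-4 region over a gene, measure recovery.

    Per replicate: does any V_ST top-1% window overlap the planted region,
    and is the planted gene's Fisher test Bonferroni-significant at
    m = 83 (the candidate-panel size)?
    """
    genome, features, _ = _replicate_genome(seed)
    genes = [f for f in features if f.type == "gene"]
    w = genome.window_size
    # plant over the first sufficiently long gene, snapped to window bounds
    target = next(g for g in genes if g.length >= 4 * w)
    region = PlantedRegion(
        target.scaffold,
        (target.start // w) * w,
        -(-target.end // w) * w,
        pop1_cn=2,
        pop2_cn=pop2_cn,
    )
    rows = []
    for rep in range(n_replicates):
        spec = CohortSpec(seed=_spec_seed(seed, rep), planted_regions=(region,),
                          **REPLICATE_COHORT_KWARGS)
        _, _, _, truth, depths = simulate_cohort(spec, genome=genome,
                                                 features=features, go_map=None)
        cnm = call_copy_number(depths, median_filter=3)
        track = scan(cnm, depths.labels, K=len(genome.scaffolds), q=0.01)
        in_top = any(
            win.scaffold == region.scaffold
            and win.start < region.end and region.start < win.end
            for win in track.flagged_windows
        )
        gcn = gene_cn(cnm, [target])
        states = score_states(gcn)
        tests = fisher_per_gene(states, depths.labels,
                                bonferroni_m=CANDIDATE_PANEL_SIZE)
        significant = bool(tests.loc[target.gene_id, "p_bonferroni_all"] < 0.05)
        rows.append({"replicate": rep, "in_top1pct": in_top,
                     "bonferroni_significant": significant})
    return pd.DataFrame(rows)


def null_replicates(
    n_replicates: int = 100,
    seed: int = 0,
    n_permutations: int = 299,
) -> pd.DataFrame:
    """Null study: no planted differentiation; both populations exchangeable.

    Per replicate: the label-concordance permutation p-value on the all-CDS
    distance matrix, the number of candidate genes passing Bonferroni, and
    the number of GO terms with BH q < 0.05 among V_ST top-1% genes.
    """
    genome, features, go_map = _replicate_genome(seed)
    universe = set(go_map.gene_id) if len(go_map) else set()
    rows = []
    for rep in range(n_replicates):
        spec = CohortSpec(seed=_spec_seed(seed, rep), **REPLICATE_COHORT_KWARGS)
        _, _, _, truth, depths = simulate_cohort(spec, genome=genome,
                                                 features=features, go_map=go_map)
        cnm = call_copy_number(depths, median_filter=3)
        track = scan(cnm, depths.labels, K=len(genome.scaffolds), q=0.01)

        matrix = build_matrix(cnm, "all_cds", features=features, vst_track=track)
        dist = distance(matrix)
        conc = label_concordance(dist, depths.labels,
                                 n_permutations=n_permutations,
                                 seed=_spec_seed(seed, rep) + 1)

        candidate = keyword_search(features, ["Na+", "sodium"])
        n_sig = 0
        if candidate.gene_ids:
            cand_genes = [f for f in features
                          if f.type == "gene" and f.gene_id in candidate.gene_ids]
            tests = fisher_per_gene(score_states(gene_cn(cnm, cand_genes)),
                                    depths.labels,
                                    bonferroni_m=CANDIDATE_PANEL_SIZE)
            n_sig = int((tests.p_bonferroni_all < 0.05).sum())

        n_enriched = 0
        selection = GeneSet(frozenset(top_genes(track, features) & universe))
        if universe:
            enr = go_enrichment(selection, go_map)
            if len(enr):
                n_enriched = int((enr.q < 0.05).sum())

        rows.append({"replicate": rep, "concordance_p": conc.permutation_p,
                     "n_bonferroni_genes": n_sig, "n_enriched_terms": n_enriched})
    return pd.DataFrame(rows)


def caller_accuracy(seed: int = 0, coverage_mean: float = 50.0,
                    median_filter: int = 3) -> float:
    """Per-window CN-class (loss/neutral/gain) accuracy vs simulated truth."""
    genome, features, go_map = _replicate_genome(seed)
    spec = CohortSpec(seed=_spec_seed(seed, 0), coverage_mean=coverage_mean,
                      **REPLICATE_COHORT_KWARGS)
    _, _, _, truth, depths = simulate_cohort(spec, genome=genome,
                                             features=features, go_map=go_map)
    cnm = call_copy_number(depths, median_filter=median_filter)
    return float((cnm.classes() == truth.classes()).mean())


def ks_uniformity(pvalues) -> float:
    """Kolmogorov–Smirnov p-value against the uniform [0, 1] null."""
    return float(stats.kstest(np.asarray(pvalues, dtype=float), "uniform").pvalue)
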