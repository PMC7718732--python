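"""GO enrichment and candidate-gene copy-number differentiation tests.

Enrichment of a selected gene set (typically genes hit by V_ST top-outlier
windows) against a gene->GO map uses a two-sided hypergeometric test by the
point-probability (minimum-likelihood) method — the sum of all tail point
probabilities no larger than that of the observed overlap — with
Benjamini–Hochberg correction across terms.

Candidate genes (e.g. from a keyword search over annotation descriptions)
get a per-gene, per-sample copy number (length-weighted mean of overlapping
window CN, rounded half away from zero), a gain/absence/neutral state, and
a per-gene Fisher exact test of population vs variant-state with a
Bonferroni correction and a conditional-MLE odds ratio with 95% CI.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .calling import CopyNumberMatrix, round_half_away
from .genome import Feature

logger = logging.getLogger(__name__)

HEATMAP_MAX_CN = 12

# relative tolerance when comparing point probabilities, absorbing float
# noise in "P(x) <= P(observed)" comparisons (standard in two-sided exact tests)
_REL_TOL = 1 + 1e-7


@dataclass(frozen=True)
class GeneSet:
    """A selected set of genes with a record of how it was selected."""

    gene_ids: frozenset[str]
    provenance: str = ""
    matched: dict = field(default_factory=dict, hash=False, compare=False)

    def __len__(self) -> int:
        return len(self.gene_ids)


def keyword_search(features: list[Feature], keywords: list[str]) -> GeneSet:
    """Case-insensitive literal substring search over gene descriptions.

    ``+`` and other characters are matched literally (``Na+`` matches
    "Na+/solute symporter"). Raises on an empty keyword list.
    """
    if not keywords:
        raise ValueError("keyword list must not be empty")
    lowered = [(k, k.lower()) for k in keywords]
    matched: dict[str, str] = {}
    for f in features:
        if f.type != "gene":
            continue
        text = f.description().lower()
        for orig, low in lowered:
            if low in text:
                matched.setdefault(f.gene_id, orig)
                break
    return GeneSet(
        gene_ids=frozenset(matched),
        provenance=f"keyword search: {', '.join(keywords)}",
        matched=matched,
    )


# ---------------------------------------------------------------------------
# per-gene copy number and states


def gene_cn(cnm: CopyNumberMatrix, gene_features: list[Feature]) -> pd.DataFrame:
    """Genes-by-samples integer copy numbers.

    A gene's copy number is the overlap-length-weighted mean of the copy
    states of the windows it intersects, rounded half away from zero.
    A gene overlapping no window raises.
    """
    genes = [f for f in gene_features if f.type == "gene"]
    # per-scaffold window arrays for fast interval math
    by_scaf: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for scaf in {w.scaffold for w in cnm.windows}:
        idx = np.array([i for i, w in enumerate(cnm.windows) if w.scaffold == scaf])
        starts = np.array([cnm.windows[i].start for i in idx])
        ends = np.array([cnm.windows[i].end for i in idx])
        by_scaf[scaf] = (idx, starts, ends)

    rows = {}
    for gene in genes:
        if gene.scaffold not in by_scaf:
            raise ValueError(f"gene {gene.gene_id} on scaffold {gene.scaffold!r} "
                             "has no windows")
        idx, starts, ends = by_scaf[gene.scaffold]
        ov = np.minimum(ends, gene.end) - np.maximum(starts, gene.start)
        hit = ov > 0
        if not hit.any():
            raise ValueError(f"gene {gene.gene_id} overlaps no window")
        weights = ov[hit].astype(float)
        cols = idx[hit]
        mean = (cnm.cn[:, cols] * weights).sum(axis=1) / weights.sum()
        rows[gene.gene_id] = round_half_away(mean).astype(int)
    return pd.DataFrame(rows, index=cnm.samples).T


def score_states(gene_cn_table: pd.DataFrame) -> pd.DataFrame:
    """Gain (CN>2) / absence (CN<=1) / neutral (CN=2) per gene and sample."""
    cn = gene_cn_table.to_numpy()
    states = np.where(cn > 2, "gain", np.where(cn <= 1, "absence", "neutral"))
    return pd.DataFrame(states, index=gene_cn_table.index,
                        columns=gene_cn_table.columns)


# ---------------------------------------------------------------------------
# Fisher exact tests per gene


def fisher_per_gene(
    states: pd.DataFrame,
    labels: dict[str, str],
    collapse: str = "variant",
    bonferroni_m: int | None = None,
) -> pd.DataFrame:
    """Per-gene 2x2 (or 2x3) exact test of copy-state vs population.

    ``collapse`` chooses the contingency: ``"variant"`` (default) pools gain
    and absence against neutral; ``"gain"`` / ``"absence"`` test that state
    against the rest; ``"freeman_halton"`` runs the 2x3 exact test on the
    full gain/absence/neutral partition. Two-sided p-values use the
    point-probability method. Genes whose samples all share one state are
    degenerate: p = 1, flagged, excluded from the tested-gene Bonferroni
    count. ``bonferroni_m`` overrides the multiplier (e.g. the size of a
    larger candidate panel); columns for both tested-m and all-m
    corrections are reported.
    """
    pops = sorted(set(labels.values()))
    if len(pops) != 2:
        raise ValueError(f"need exactly 2 populations, got {pops}")
    samples = list(states.columns)
    in_pop1 = np.array([labels[s] == pops[0] for s in samples])

    records = []
    for gene, row in states.iterrows():
        vals = row.to_numpy()
        degenerate = len(set(vals)) == 1
        if collapse == "freeman_halton":
            table = np.array(
                [[np.sum((vals == st) & mask) for st in ("gain", "absence", "neutral")]
                 for mask in (in_pop1, ~in_pop1)]
            )
            p = 1.0 if degenerate else fisher_freeman_halton(table)
            a = b = c = d = np.nan
            odds = lo = hi = np.nan
        else:
            if collapse == "variant":
                variant = (vals == "gain") | (vals == "absence")
            elif collapse in ("gain", "absence"):
                variant = vals == collapse
            else:
                raise ValueError(f"unknown collapse {collapse!r}")
            a = int(np.sum(variant & in_pop1))
            b = int(np.sum(~variant & in_pop1))
            c = int(np.sum(variant & ~in_pop1))
            d = int(np.sum(~variant & ~in_pop1))
            table22 = np.array([[a, b], [c, d]])
            if degenerate:
                p, odds, lo, hi = 1.0, np.nan, np.nan, np.nan
            else:
                p = float(stats.fisher_exact(table22, alternative="two-sided")[1])
                orr = stats.contingency.odds_ratio(table22, kind="conditional")
                ci = orr.confidence_interval(confidence_level=0.95)
                odds, lo, hi = float(orr.statistic), float(ci.low), float(ci.high)
        records.append(
            {
                "gene_id": gene,
                "pop1_variant": a, "pop1_neutral": b,
                "pop2_variant": c, "pop2_neutral": d,
                "odds_ratio": odds, "ci_low": lo, "ci_high": hi,
                "p": p, "degenerate": degenerate,
            }
        )
    out = pd.DataFrame(records).set_index("gene_id")
    m_tested = int((~out.degenerate).sum())
    m_all = bonferroni_m if bonferroni_m is not None else len(out)
    out["p_bonferroni"] = np.minimum(1.0, out.p * max(m_tested, 1))
    out["p_bonferroni_all"] = np.minimum(1.0, out.p * max(m_all, 1))
    out.attrs["m_tested"] = m_tested
    out.attrs["m_all"] = m_all
    return out


def fisher_freeman_halton(table: np.ndarray) -> float:
    """Exact p for an R x C table: total probability of tables (same margins)
    whose conditional probability does not exceed the observed one."""
    table = np.asarray(table, dtype=int)
    row_sums = table.sum(axis=1)
    col_sums = table.sum(axis=0)
    n = table.sum()
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])

    def log_prob(t):
        return (
            log_fact[row_sums].sum() + log_fact[col_sums].sum()
            - log_fact[n] - sum(log_fact[x] for x in np.ravel(t))
        )

    observed = log_prob(table)
    total = 0.0
    # enumerate 2xC tables by the first row; second row forced by margins
    assert table.shape[0] == 2, "enumeration implemented for 2 rows"
    ranges = [range(min(row_sums[0], c) + 1) for c in col_sums]
    for first_row in product(*ranges):
        if sum(first_row) != row_sums[0]:
            continue
        second = col_sums - np.array(first_row)
        if (second < 0).any():
            continue
        cand = np.array([first_row, second])
        lp = log_prob(cand)
        if lp <= observed + math.log(_REL_TOL):
            total += math.exp(lp)
    return min(1.0, total)


# ---------------------------------------------------------------------------
# GO enrichment


def hypergeom_two_sided(k: int, n: int, K_t: int, N: int) -> float:
    """Two-sided hypergeometric p by the point-probability method.

    ``k`` genes of a selection of size ``n`` carry a term annotating ``K_t``
    of ``N`` universe genes; the p-value sums hypergeometric point
    probabilities over the support that do not exceed P(k)."""
    support = np.arange(max(0, n + K_t - N), min(n, K_t) + 1)
    pmf = stats.hypergeom.pmf(support, N, K_t, n)
    p_obs = stats.hypergeom.pmf(k, N, K_t, n)
    return float(min(1.0, pmf[pmf <= p_obs * _REL_TOL].sum()))


def go_enrichment(
    selection: GeneSet,
    go_map: pd.DataFrame,
    universe: set[str] | None = None,
) -> pd.DataFrame:
    """Per-term two-sided hypergeometric enrichment with BH correction.

    ``go_map`` is a two-column gene_id/go_term table. The universe defaults
    to all genes in the map; the selection must be a subset of it.
    Returns a frame (term, k, K_t, n, N, p, q) sorted by p.
    """
    go_map = go_map.rename(columns=dict(zip(go_map.columns[:2], ["gene_id", "go_term"])))
    if universe is None:
        universe = set(go_map.gene_id)
    sel = set(selection.gene_ids)
    offenders = sel - universe
    if offenders:
        raise ValueError(f"selection genes outside the universe: {sorted(offenders)}")
    mapped = go_map[go_map.gene_id.isin(universe)]
    N = len(universe)
    n = len(sel)
    rows = []
    for term, genes in mapped.groupby("go_term").gene_id:
        term_genes = set(genes)
        K_t = len(term_genes)
        k = len(term_genes & sel)
        rows.append({"term": term, "k": k, "K_t": K_t, "n": n, "N": N,
                     "p": hypergeom_two_sided(k, n, K_t, N)})
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = multipletests(result.p, method="fdr_bh")[1]
        result = result.sort_values("p", kind="stable").reset_index(drop=True)
    else:
        result["q"] = []
    return result


# ---------------------------------------------------------------------------
# heatmap export


@dataclass
class HeatmapExport:
    """Genes-by-samples CN matrix ordered for plotting, clipped to [0, 12]."""

    matrix: pd.DataFrame
    highlight: str | None
    above_scale: list[tuple[str, str, int]]   # (gene, sample, original CN)
    population_order: list[str]

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")

    @staticmethod
    def read_tsv(path) -> pd.DataFrame:
        return pd.read_csv(path, sep="\t", index_col=0)


def heatmap_matrix(
    gene_cn_table: pd.DataFrame,
    labels: dict[str, str],
    highlight: str | None = None,
    cn_max: int = HEATMAP_MAX_CN,
) -> HeatmapExport:
    """Order samples by population, clip CN to the 0..``cn_max`` color scale.

    Values above the scale are clipped and recorded in ``above_scale``; an
    unknown highlight gene warns and is unset.
    """
    pops = list(dict.fromkeys(labels[s] for s in gene_cn_table.columns))
    ordered = [s for p in pops for s in gene_cn_table.columns if labels[s] == p]
    mat = gene_cn_table[ordered]
    above = [
        (g, s, int(mat.at[g, s]))
        for g in mat.index for s in mat.columns
        if mat.at[g, s] > cn_max
    ]
    clipped = mat.clip(upper=cn_max)
    if highlight is not None and highlight not in clipped.index:
        logger.warning("highlight gene %r not in matrix; ignoring", highlight)
        highlight = None
    return HeatmapExport(matrix=clipped, highlight=highlight,
                         above_scale=above, population_order=pops)
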