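"""Per-window V_ST genome scan and top-outlier annotation tally.

V_ST partitions copy-number variance between two populations exactly as
F_ST partitions allele-frequency variance:

    V_ST = (V_T - V_S) / V_T

where V_T is the variance of the pooled copy numbers and V_S the
population-size-weighted mean of the within-population variances,
V_S = (n1*V1 + n2*V2) / (n1 + n2). All variances use denominator n
(population variance), which by the law of total variance guarantees
V_S <= V_T and hence 0 <= V_ST <= 1. Windows with V_T = 0 carry no
information and are undefined (NaN), excluded from the outlier quantile
and never flagged.

The scan is restricted to the K largest scaffolds (default 100) before
any quantile is computed; the top fraction q (default 1%) of defined
windows is flagged, with all ties at the threshold included.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calling import CopyNumberMatrix
from .genome import Feature, GenomeModel, Window, overlap

logger = logging.getLogger(__name__)

ANNOTATION_TYPES = ("CDS", "exon", "start_codon", "stop_codon")


def vst(values_pop1, values_pop2, ddof: int = 0) -> float:
    """V_ST between two groups of copy numbers; NaN when pooled variance is 0.

    ``ddof=0`` (population variance) is the default and keeps the statistic
    in [0, 1]; ``ddof=1`` is exposed for comparison but can leave the range.
    """
    x = np.asarray(values_pop1, dtype=float)
    y = np.asarray(values_pop2, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each population needs >= 2 values")
    v1 = np.var(x, ddof=ddof)
    v2 = np.var(y, ddof=ddof)
    vt = np.var(np.concatenate([x, y]), ddof=ddof)
    if vt == 0:
        return float("nan")
    vs = (len(x) * v1 + len(y) * v2) / (len(x) + len(y))
    return float((vt - vs) / vt)


@dataclass
class VstTrack:
    """Per-window V_ST values with variance components and top-quantile flags."""

    frame: pd.DataFrame      # scaffold, start, end, v_total, v_within, vst, top_flag
    q: float
    scaffold_limit: int
    threshold: float         # NaN when no window is defined

    @property
    def flagged_windows(self) -> list[Window]:
        out = []
        counters: dict[str, int] = {}
        for row in self.frame.itertuples():
            i = counters.get(row.scaffold, 0)
            counters[row.scaffold] = i + 1
            if row.top_flag:
                out.append(Window(row.scaffold, i, row.start, row.end))
        return out

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False, na_rep="NA")


def scan(
    cnm: CopyNumberMatrix,
    labels: dict[str, str] | None = None,
    K: int = 100,
    q: float = 0.01,
) -> VstTrack:
    """V_ST over every window of the K largest scaffolds, flagging the top q.

    The outlier threshold is the ceil(q * n_defined)-th largest defined V_ST
    value; every window at or above it is flagged (ties at the threshold all
    flag, so slightly more than q may be selected). An all-undefined track
    flags nothing.
    """
    labels = labels or cnm.labels
    if not (0 < q < 1):
        raise ValueError("q must be in (0, 1)")
    pops = sorted(set(labels.values()))
    if len(pops) != 2:
        raise ValueError(f"need exactly 2 populations, got {pops}")
    mask1 = np.array([labels[s] == pops[0] for s in cnm.samples])
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each population needs >= 2 samples")

    scaffolds = _largest_scaffolds(cnm, K)
    sub = cnm.restrict(scaffolds)

    x = sub.cn[mask1].astype(float)
    y = sub.cn[~mask1].astype(float)
    n1, n2 = x.shape[0], y.shape[0]
    v1 = x.var(axis=0)
    v2 = y.var(axis=0)
    vt = np.vstack([x, y]).var(axis=0)
    vs = (n1 * v1 + n2 * v2) / (n1 + n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(vt > 0, (vt - vs) / np.where(vt > 0, vt, 1.0), np.nan)

    defined = ~np.isnan(values)
    n_def = int(defined.sum())
    flags = np.zeros(len(values), dtype=bool)
    threshold = float("nan")
    if n_def:
        k = max(1, math.ceil(q * n_def))
        order = np.sort(values[defined])[::-1]
        threshold = float(order[k - 1])
        flags = defined & (values >= threshold)

    frame = pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in sub.windows],
            "start": [w.start for w in sub.windows],
            "end": [w.end for w in sub.windows],
            "v_total": vt,
            "v_within": vs,
            "vst": values,
            "top_flag": flags,
        }
    )
    return VstTrack(frame=frame, q=q, scaffold_limit=K, threshold=threshold)


def _largest_scaffolds(cnm: CopyNumberMatrix, K: int) -> list[str]:
    lengths: dict[str, int] = {}
    for w in cnm.windows:
        lengths[w.scaffold] = max(lengths.get(w.scaffold, 0), w.end)
    ordered = sorted(lengths, key=lambda s: -lengths[s])
    if K > len(ordered):
        logger.warning("K=%d exceeds %d scaffolds; using all", K, len(ordered))
        K = len(ordered)
    return ordered[:K]


def tally_top_annotations(track: VstTrack, features: list[Feature]) -> dict[str, int]:
    """Count (flagged window, feature) overlap pairs per annotation type.

    Returns a mapping with one entry per type in CDS/exon/start_codon/
    stop_codon plus ``"total"``, the sum over types.
    """
    flagged = track.flagged_windows
    if not flagged:
        counts = {t: 0 for t in ANNOTATION_TYPES}
    else:
        _, counts = overlap(flagged, features, ANNOTATION_TYPES)
    counts = dict(counts)
    counts["total"] = sum(counts[t] for t in ANNOTATION_TYPES)
    return counts


def top_genes(track: VstTrack, features: list[Feature]) -> set[str]:
    """Gene IDs whose gene body overlaps at least one flagged window."""
    flagged = track.flagged_windows
    genes = [f for f in features if f.type == "gene"]
    if not flagged or not genes:
        return set()
    hits, _ = overlap(flagged, genes, ["gene"])
    return {f.gene_id for hit in hits for f in hit}


def gene_vst(track: VstTrack, features: list[Feature]) -> pd.Series:
    """Per-gene aggregation: max window V_ST over each gene's CDS intervals.

    Exposed as an alternative to window-level outlier selection for users
    who prefer ranking genes directly.
    """
    cds = [f for f in features if f.type == "CDS"]
    wins = [Window(r.scaffold, i, r.start, r.end)
            for i, r in enumerate(track.frame.itertuples())]
    hits, _ = overlap(wins, cds, ["CDS"]) if cds else ([[] for _ in wins], {})
    best: dict[str, float] = {}
    for row, hit in zip(track.frame.itertuples(), hits):
        if np.isnan(row.vst):
            continue
        for f in hit:
            if row.vst > best.get(f.gene_id, -np.inf):
                best[f.gene_id] = row.vst
    return pd.Series(best, name="vst").sort_values(ascending=False)
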