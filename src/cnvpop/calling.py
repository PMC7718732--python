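"""Windowed copy-number calling, CNV segmentation and cohort summaries.

The caller is a deliberately simple read-depth method: per sample, window
counts are divided by the sample's median window count (robust to CNVs being
a minority of windows), multiplied by the assumed ploidy of 2 (dikaryotic
baseline) and rounded half-away-from-zero to an integer copy state. GC-bias
and mappability corrections are out of scope. An optional per-scaffold
running-median filter stands in for the segmentation step full read-depth
callers perform; it defaults off so that calls are purely per-window.

Gains are copy states above 2; losses (absences) are states of 1 or 0.
Segments are maximal runs of same-class windows within one scaffold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .genome import Feature, GenomeModel, Window, overlap

logger = logging.getLogger(__name__)

PLOIDY = 2


@dataclass
class DepthMatrix:
    """Per-sample, per-window raw read counts."""

    windows: list[Window]
    samples: list[str]
    labels: dict[str, str]
    counts: np.ndarray          # samples x windows
    window_size: int = 250

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.samples), len(self.windows)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.samples)}, {len(self.windows)})"
            )
        if (self.counts < 0).any():
            raise ValueError("read counts must be non-negative")
        dead = [s for s, row in zip(self.samples, self.counts) if not (row > 0).any()]
        if dead:
            raise ValueError(f"samples with no covered windows: {dead}")


@dataclass
class CopyNumberMatrix:
    """Integer copy states on the same axes as the depth matrix (ploidy 2)."""

    windows: list[Window]
    samples: list[str]
    labels: dict[str, str]
    cn: np.ndarray
    ploidy: int = PLOIDY
    window_size: int = 250

    def __post_init__(self) -> None:
        self.cn = np.asarray(self.cn)
        if (self.cn < 0).any():
            raise ValueError("copy numbers must be >= 0")

    def classes(self) -> np.ndarray:
        """-1 loss (CN<=1), 0 neutral (CN=2), +1 gain (CN>2)."""
        cls = np.zeros_like(self.cn, dtype=np.int8)
        cls[self.cn <= 1] = -1
        cls[self.cn > 2] = 1
        return cls

    def restrict(self, scaffold_names) -> "CopyNumberMatrix":
        keep = set(scaffold_names)
        idx = [i for i, w in enumerate(self.windows) if w.scaffold in keep]
        return CopyNumberMatrix(
            windows=[self.windows[i] for i in idx],
            samples=self.samples,
            labels=self.labels,
            cn=self.cn[:, idx],
            ploidy=self.ploidy,
            window_size=self.window_size,
        )


@dataclass(frozen=True)
class CnvSegment:
    """Maximal run of same-class windows in one sample (0-based half-open)."""

    sample: str
    scaffold: str
    start: int
    end: int
    cls: str                 # "gain" | "loss"
    cn: int                  # mode of member-window copy states (ties -> smaller)
    n_windows: int
    partial: bool = False    # contains a trailing sub-window-size window

    @property
    def size(self) -> int:
        return self.end - self.start


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (2.5 -> 3), unlike numpy's banker's rounding."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


# ---------------------------------------------------------------------------
# calling


def call_copy_number(
    depths: DepthMatrix, ploidy: int = PLOIDY, median_filter: int = 1
) -> CopyNumberMatrix:
    """Call integer copy states from window read counts.

    Per sample: ``ratio = count / median(counts)`` over the analyzed windows,
    then ``cn = round_half_away(ploidy * ratio)`` clipped below at 0.
    ``median_filter`` > 1 applies a per-scaffold running median of that width
    to the ratio track before rounding (a minimal segmentation surrogate;
    see the pipeline documentation). A sample whose median count is zero
    cannot be normalized and raises.
    """
    medians = np.median(depths.counts, axis=1)
    zero = [s for s, m in zip(depths.samples, medians) if m <= 0]
    if zero:
        raise ValueError(f"zero median read count for samples: {zero}")
    ratios = depths.counts / medians[:, None]
    if median_filter > 1:
        ratios = _per_scaffold_median(ratios, depths.windows, median_filter)
    cn = round_half_away(ploidy * ratios)
    cn = np.clip(cn, 0, None).astype(np.int16)
    return CopyNumberMatrix(
        windows=depths.windows,
        samples=depths.samples,
        labels=depths.labels,
        cn=cn,
        ploidy=ploidy,
        window_size=depths.window_size,
    )


def _scaffold_runs(windows: list[Window]):
    """Yield (scaffold, lo, hi) slices of the window vector per scaffold."""
    lo = 0
    for i in range(1, len(windows) + 1):
        if i == len(windows) or windows[i].scaffold != windows[lo].scaffold:
            yield windows[lo].scaffold, lo, i
            lo = i


def _per_scaffold_median(ratios: np.ndarray, windows: list[Window], width: int) -> np.ndarray:
    out = np.empty_like(ratios)
    for _scaf, lo, hi in _scaffold_runs(windows):
        out[:, lo:hi] = ndimage.median_filter(
            ratios[:, lo:hi], size=(1, width), mode="nearest"
        )
    return out


# ---------------------------------------------------------------------------
# segmentation


def segment(cnm: CopyNumberMatrix) -> list[CnvSegment]:
    """Merge consecutive same-class windows into maximal CNV segments.

    Neutral (CN=2) windows emit nothing; segments never span scaffolds;
    the representative copy number is the mode of the member windows with
    ties broken toward the smaller value. Segments containing a trailing
    partial window are flagged.
    """
    classes = cnm.classes()
    segments: list[CnvSegment] = []
    for si, sample in enumerate(cnm.samples):
        row_cls = classes[si]
        row_cn = cnm.cn[si]
        for _scaf, lo, hi in _scaffold_runs(cnm.windows):
            j = lo
            while j < hi:
                c = row_cls[j]
                if c == 0:
                    j += 1
                    continue
                k = j
                while k < hi and row_cls[k] == c:
                    k += 1
                member_cn = row_cn[j:k]
                counts = np.bincount(member_cn)
                rep = int(np.argmax(counts))  # first max -> smallest value on ties
                wins = cnm.windows[j:k]
                segments.append(
                    CnvSegment(
                        sample=sample,
                        scaffold=wins[0].scaffold,
                        start=wins[0].start,
                        end=wins[-1].end,
                        cls="gain" if c > 0 else "loss",
                        cn=rep,
                        n_windows=k - j,
                        partial=any(w.length < cnm.window_size for w in wins),
                    )
                )
                j = k
    return segments


# ---------------------------------------------------------------------------
# Wilcoxon comparison and the per-population summary table


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum p: exact when combined n <= 20 and
    tie-free, otherwise normal approximation with continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("Wilcoxon comparison needs >= 2 observations per group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0  # all tied: no evidence either way (tie-corrected z is 0/0)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(pooled) <= 20 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


@dataclass
class CnvSummary:
    """Cohort-level CNV summary: counts/mean sizes per population and class,
    for the whole genome and for segments overlapping predicted genes, with
    Wilcoxon comparisons of per-individual counts and mean sizes."""

    table: pd.DataFrame   # region, cls, population, count, mean_size_bp
    tests: pd.DataFrame   # region, cls, metric, p
    per_individual: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def summarize(
    segments: list[CnvSegment],
    genome: GenomeModel,
    gene_features: list[Feature],
    labels: dict[str, str],
) -> CnvSummary:
    """Build the per-population CNV count/size summary.

    Whole-genome rows use all segments; predicted-gene rows use segments
    overlapping at least one ``gene`` feature. Counts are totals across
    individuals; mean sizes are means across segments (partial-window
    segments excluded from size statistics, flagged in ``notes``); a class
    with zero segments reports its mean size as missing. Wilcoxon rank-sum
    tests compare per-individual segment counts and per-individual mean
    sizes between the two populations.
    """
    samples = sorted({s for s in labels})
    missing = {seg.sample for seg in segments} - set(labels)
    if missing:
        raise ValueError(f"segments from unlabeled samples: {sorted(missing)}")
    pops = list(dict.fromkeys(labels[s] for s in labels))

    genes = [f for f in gene_features if f.type == "gene"]
    if genes and segments:
        hits, _ = overlap(segments, genes, ["gene"])
        genic = [bool(h) for h in hits]
    else:
        genic = [False] * len(segments)

    notes: list[str] = []
    n_partial = sum(1 for seg in segments if seg.partial)
    if n_partial:
        notes.append(
            f"{n_partial} segments contain a trailing partial window and are "
            "excluded from mean-size statistics"
        )

    frames = []
    per_ind_rows = []
    for region, keep in (("whole_genome", [True] * len(segments)),
                         ("predicted_genes", genic)):
        region_segs = [s for s, k in zip(segments, keep) if k]
        for cls in ("gain", "loss"):
            cls_segs = [s for s in region_segs if s.cls == cls]
            for pop in pops:
                pop_segs = [s for s in cls_segs if labels[s.sample] == pop]
                sizes = [s.size for s in pop_segs if not s.partial]
                frames.append(
                    {
                        "region": region,
                        "cls": cls,
                        "population": pop,
                        "count": len(pop_segs),
                        "mean_size_bp": float(np.mean(sizes)) if sizes else np.nan,
                    }
                )
            for sample in samples:
                own = [s for s in cls_segs if s.sample == sample]
                own_sizes = [s.size for s in own if not s.partial]
                per_ind_rows.append(
                    {
                        "region": region,
                        "cls": cls,
                        "sample": sample,
                        "population": labels[sample],
                        "count": len(own),
                        "mean_size_bp": float(np.mean(own_sizes)) if own_sizes else np.nan,
                    }
                )

    per_individual = pd.DataFrame(per_ind_rows)
    test_rows = []
    pop_sizes = {p: sum(1 for s in labels if labels[s] == p) for p in pops}
    wilcoxon_ok = len(pops) == 2 and all(n >= 2 for n in pop_sizes.values())
    if not wilcoxon_ok:
        notes.append(
            "Wilcoxon comparisons skipped: need exactly 2 populations with "
            ">= 2 individuals each"
        )
    for region in ("whole_genome", "predicted_genes"):
        for cls in ("gain", "loss"):
            sub = per_individual[(per_individual.region == region) & (per_individual.cls == cls)]
            for metric in ("count", "mean_size_bp"):
                p = np.nan
                if wilcoxon_ok:
                    a = sub[sub.population == pops[0]][metric].dropna()
                    b = sub[sub.population == pops[1]][metric].dropna()
                    if len(a) >= 2 and len(b) >= 2:
                        p = wilcoxon_rank_sum(a, b)
                test_rows.append({"region": region, "cls": cls, "metric": metric, "p": p})

    return CnvSummary(
        table=pd.DataFrame(frames),
        tests=pd.DataFrame(test_rows),
        per_individual=per_individual,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# depth-matrix TSV adapter (also the hook for real caller ratio files)


def read_depth_tsv(path, labels: dict[str, str], window_size: int = 250) -> DepthMatrix:
    """Read a depth matrix TSV (scaffold, start, end, one column per sample)."""
    df = pd.read_csv(path, sep="\t")
    meta = ["scaffold", "start", "end"]
    if df.columns[:3].tolist() != meta:
        raise ValueError(f"{path}: expected leading columns {meta}")
    samples = [c for c in df.columns if c not in meta]
    windows = []
    index_counter: dict[str, int] = {}
    for scaf, start, end in zip(df.scaffold, df.start, df.end):
        i = index_counter.get(scaf, 0)
        windows.append(Window(str(scaf), i, int(start), int(end)))
        index_counter[str(scaf)] = i + 1
    return DepthMatrix(
        windows=windows,
        samples=samples,
        labels={s: labels[s] for s in samples},
        counts=df[samples].to_numpy().T,
        window_size=window_size,
    )


def summary_to_tsv(summary: CnvSummary, path) -> None:
    summary.table.to_csv(path, sep="\t", index=False, na_rep="NA")
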