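"""Genome coordinate system, annotation I/O and the interval-overlap engine.

All coordinates inside the package are 0-based half-open. GFF3 (1-based
closed) is converted on read and write; BED passes through unchanged.
Scaffolds are stored largest-first, so "the first K scaffolds" always means
the K largest — the convention used by size-ranked draft assemblies.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

#: feature types the pipeline understands; anything else in a GFF3 is skipped
FEATURE_TYPES = ("gene", "CDS", "exon", "start_codon", "stop_codon")

DEFAULT_WINDOW_SIZE = 250


@dataclass(frozen=True)
class Window:
    """One tile of the fixed-width window grid (0-based half-open)."""

    scaffold: str
    index: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Feature:
    """A genomic annotation interval (0-based half-open).

    ``attributes`` keeps the raw GFF3 key→value map; free-text gene
    descriptions are expected under one of ``product``/``description``/
    ``Note`` and protein identifiers under ``proteinId``.
    """

    scaffold: str
    start: int
    end: int
    type: str
    gene_id: str
    strand: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.type not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.type!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.scaffold}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def description(self) -> str:
        for key in ("product", "description", "Note"):
            if key in self.attributes:
                return self.attributes[key]
        return ""


class GenomeModel:
    """Ordered scaffolds (largest first) plus the window grid they define.

    Parameters
    ----------
    scaffolds : sequence of (name, length)
        Scaffold names must be unique and lengths positive. Stored sorted
        by decreasing length (stable for ties) regardless of input order.
    window_size : int
        Width of the non-overlapping window grid in bp (default 250).
    """

    def __init__(self, scaffolds: Sequence[tuple[str, int]], window_size: int = DEFAULT_WINDOW_SIZE):
        names = [n for n, _ in scaffolds]
        if len(set(names)) != len(names):
            raise ValueError("scaffold names must be unique")
        for name, length in scaffolds:
            if length <= 0:
                raise ValueError(f"scaffold {name!r} has non-positive length {length}")
        if window_size <= 0:
            raise ValueError("window_size must be positive")
        self.scaffolds: list[tuple[str, int]] = sorted(
            ((str(n), int(l)) for n, l in scaffolds), key=lambda s: -s[1]
        )
        self.window_size = int(window_size)
        self._lengths = dict(self.scaffolds)

    # -- basic queries -----------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.scaffolds]

    def length_of(self, scaffold: str) -> int:
        try:
            return self._lengths[scaffold]
        except KeyError:
            raise KeyError(f"unknown scaffold {scaffold!r}") from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def largest(self, k: int) -> list[str]:
        """Names of the ``k`` largest scaffolds; warns and returns all if
        ``k`` exceeds the scaffold count."""
        if k > len(self.scaffolds):
            logger.warning(
                "requested %d largest scaffolds but genome has %d; using all",
                k, len(self.scaffolds),
            )
            k = len(self.scaffolds)
        return self.names[:k]

    # -- window grid -------------------------------------------------------

    def windows_of(self, scaffold_subset: Iterable[str] | None = None) -> list[Window]:
        """The full window grid over ``scaffold_subset`` (default: all).

        Windows tile each scaffold exactly: consecutive, non-overlapping,
        0-based half-open; the last window of a scaffold may be shorter
        than ``window_size`` (it is kept, not dropped).
        """
        names = self.names if scaffold_subset is None else list(scaffold_subset)
        w = self.window_size
        out: list[Window] = []
        for name in names:
            length = self.length_of(name)  # raises on unknown scaffold
            for i in range(0, (length + w - 1) // w):
                out.append(Window(name, i, i * w, min((i + 1) * w, length)))
        return out

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeModel({len(self.scaffolds)} scaffolds, "
            f"{self.total_length} bp, window_size={self.window_size})"
        )


# ---------------------------------------------------------------------------
# genome description TSV


def read_genome_tsv(path, window_size: int = DEFAULT_WINDOW_SIZE) -> GenomeModel:
    """Read a two-column ``scaffold<TAB>length`` description file."""
    scaffolds = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns, got {len(parts)}")
            scaffolds.append((parts[0], int(parts[1])))
    return GenomeModel(scaffolds, window_size=window_size)


def write_genome_tsv(genome: GenomeModel, path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.scaffolds:
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# GFF3 I/O

_GFF_COLUMNS = 9


def read_gff(path) -> list[Feature]:
    """Read a GFF3 file into :class:`Feature` records.

    Input coordinates (1-based closed) are converted to 0-based half-open.
    Rows whose type is outside :data:`FEATURE_TYPES` are skipped; the number
    skipped is logged. ``gene_id`` is the ``ID`` attribute for genes and the
    ``Parent`` (falling back to ``ID``) for child features.
    """
    features: list[Feature] = []
    skipped: Counter[str] = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _GFF_COLUMNS:
                raise ValueError(
                    f"{path}: line {lineno}: expected {_GFF_COLUMNS} tab-separated "
                    f"columns, got {len(parts)}"
                )
            scaffold, _source, ftype, start_s, end_s, _score, strand, _frame, attr_s = parts
            if ftype not in FEATURE_TYPES:
                skipped[ftype] += 1
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinates") from None
            if end1 < start1:
                raise ValueError(f"{path}: line {lineno}: end {end1} < start {start1}")
            attributes = _parse_attributes(attr_s)
            if ftype == "gene":
                gene_id = attributes.get("ID", "")
            else:
                gene_id = attributes.get("Parent", attributes.get("ID", ""))
            if not gene_id:
                raise ValueError(f"{path}: line {lineno}: no ID/Parent attribute")
            features.append(
                Feature(
                    scaffold=scaffold,
                    start=start1 - 1,  # to 0-based half-open
                    end=end1,
                    type=ftype,
                    gene_id=gene_id,
                    strand=strand,
                    attributes=attributes,
                )
            )
    if skipped:
        logger.info(
            "read_gff: skipped %d rows of unknown types (%s)",
            sum(skipped.values()),
            ", ".join(f"{t}: {c}" for t, c in sorted(skipped.items())),
        )
    return features


def write_gff(features: Iterable[Feature], path, source: str = "cnvpop") -> None:
    """Write features as GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                f"{f.scaffold}\t{source}\t{f.type}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def _parse_attributes(text: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for item in text.split(";"):
        item = item.strip()
        if not item:
            continue
        if "=" not in item:
            raise ValueError(f"malformed attribute {item!r}")
        key, value = item.split("=", 1)
        attrs[key.strip()] = value.strip()
    return attrs


# ---------------------------------------------------------------------------
# BED I/O (0-based half-open, pass-through)


def write_bed(intervals: Iterable, path) -> None:
    """Write objects with scaffold/start/end (+ optional cls, cn) as BED."""
    with open(path, "w") as fh:
        for iv in intervals:
            name = getattr(iv, "cls", getattr(iv, "gene_id", "."))
            score = getattr(iv, "cn", 0)
            fh.write(f"{iv.scaffold}\t{iv.start}\t{iv.end}\t{name}\t{score}\n")


def read_bed(path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else "."
            score = parts[4] if len(parts) > 4 else "."
            rows.append((chrom, start, end, name, score))
    return rows


# ---------------------------------------------------------------------------
# interval overlap engine


def overlap(
    queries: Sequence,
    features: Sequence[Feature],
    feature_types: Iterable[str],
):
    """Intersect query intervals with annotation features.

    A query (anything with ``scaffold``/``start``/``end``, half-open) hits a
    feature iff the two intervals share at least one base. Returns
    ``(hits, type_counts)`` where ``hits[i]`` is the list of features hit by
    ``queries[i]`` and ``type_counts`` maps each requested feature type to
    the number of (query, feature) overlap pairs of that type.
    """
    types = list(feature_types)
    if not types:
        raise ValueError("feature_types must not be empty")
    unknown = set(types) - set(FEATURE_TYPES)
    if unknown:
        raise ValueError(f"unknown feature types: {sorted(unknown)}")
    type_set = set(types)

    trees: dict[str, IntervalTree] = {}
    for f in features:
        if f.type not in type_set:
            continue
        trees.setdefault(f.scaffold, IntervalTree()).addi(f.start, f.end, f)

    hits: list[list[Feature]] = []
    counts: Counter[str] = Counter({t: 0 for t in types})
    for q in queries:
        tree = trees.get(q.scaffold)
        if tree is None:
            hits.append([])
            continue
        found = [iv.data for iv in tree.overlap(q.start, q.end)]
        found.sort(key=lambda f: (f.start, f.end, f.type, f.gene_id))
        hits.append(found)
        for f in found:
            counts[f.type] += 1
    return hits, dict(counts)
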