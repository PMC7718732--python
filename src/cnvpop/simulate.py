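"""Two-population synthetic CNV cohort generator.

Emulates the data structure the analysis assumes: a fragmented multi-scaffold
genome with gene annotation and GO terms, two populations of configurable
sizes (defaults 11 and 16, the coastal/montane study design), a shared
baseline of CNV polymorphism in which losses are common and large while
gains are rare and small, optional planted population-differentiated
regions, and per-window read counts whose mean is proportional to the true
copy number (Poisson noise; optional negative-binomial overdispersion,
off by default).

Everything is deterministic given the seed: identical (spec, seed) pairs
produce byte-identical output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Feature, GenomeModel, Window, write_genome_tsv, write_gff

logger = logging.getLogger(__name__)

# Default per-sample event rates (events per Mb) and size means (bp), set so
# a 27-sample cohort reproduces the broad shape of the study's CNV summary:
# losses outnumber gains ~6:1 and are ~15x larger.
DEFAULT_LOSS_RATE = 1.3
DEFAULT_GAIN_RATE = 0.22
DEFAULT_LOSS_SIZE = 60_000.0
DEFAULT_GAIN_SIZE = 4_000.0

# free-text product descriptions sampled for synthetic genes; a few
# sodium-related entries so keyword searches have realistic targets
PRODUCT_VOCABULARY: tuple[tuple[str, float], ...] = (
    ("hypothetical protein", 0.40),
    ("ubiquitin-protein ligase", 0.08),
    ("ABC transporter", 0.08),
    ("cytochrome P450 monooxygenase", 0.08),
    ("MFS general substrate transporter", 0.08),
    ("protein kinase domain protein", 0.08),
    ("potassium channel subunit", 0.05),
    ("glycoside hydrolase family protein", 0.05),
    ("Sodium/hydrogen exchanger family", 0.03),
    ("sodium/calcium exchanger protein", 0.03),
    ("Na+/dicarboxylate, Na+/tricarboxylate and phosphate transporters", 0.02),
    ("Na+/solute symporter", 0.02),
)


@dataclass(frozen=True)
class PlantedRegion:
    """A region whose copy number is drawn per population rather than shared.

    ``pop1_cn``/``pop2_cn`` are either a fixed integer copy number or a
    {cn: probability} distribution sampled independently per individual.
    """

    scaffold: str
    start: int
    end: int
    pop1_cn: int | dict[int, float]
    pop2_cn: int | dict[int, float]


@dataclass
class CohortSpec:
    """Study-design parameters of a simulated two-population cohort."""

    n_pop1: int = 11
    n_pop2: int = 16
    coverage_mean: float = 50.0          # mean reads per full window at CN=2
    shared_loss_rate: float = DEFAULT_LOSS_RATE   # events / sample / Mb
    shared_gain_rate: float = DEFAULT_GAIN_RATE
    loss_size_mean: float = DEFAULT_LOSS_SIZE     # bp
    gain_size_mean: float = DEFAULT_GAIN_SIZE
    planted_regions: tuple[PlantedRegion, ...] = ()
    max_cn: int = 12
    nb_dispersion: float | None = None   # negative-binomial overdispersion, off by default
    seed: int = 0
    pop1_name: str = "pop1"
    pop2_name: str = "pop2"

    def __post_init__(self) -> None:
        if self.n_pop1 < 2 or self.n_pop2 < 2:
            raise ValueError("population sizes must be >= 2")
        if min(self.shared_loss_rate, self.shared_gain_rate) < 0:
            raise ValueError("event rates must be >= 0")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be > 0")
        for region in self.planted_regions:
            for dist in (region.pop1_cn, region.pop2_cn):
                states = [dist] if isinstance(dist, int) else list(dist)
                for cn in states:
                    if not (0 <= cn <= self.max_cn):
                        raise ValueError(f"planted CN {cn} outside [0, {self.max_cn}]")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{self.pop1_name}_{i + 1:02d}" for i in range(self.n_pop1)] + [
            f"{self.pop2_name}_{i + 1:02d}" for i in range(self.n_pop2)
        ]

    @property
    def labels(self) -> dict[str, str]:
        return {
            s: (self.pop1_name if i < self.n_pop1 else self.pop2_name)
            for i, s in enumerate(self.sample_ids)
        }


@dataclass
class TruthSet:
    """Ground-truth copy states underlying an emitted depth matrix."""

    genome: GenomeModel
    windows: list[Window]
    samples: list[str]
    labels: dict[str, str]
    cn: np.ndarray                     # samples x windows, int
    planted_draws: list[dict] = field(default_factory=list)

    def classes(self) -> np.ndarray:
        """Per-window truth class: -1 loss (CN<=1), 0 neutral (CN=2), +1 gain."""
        cls = np.zeros_like(self.cn, dtype=np.int8)
        cls[self.cn <= 1] = -1
        cls[self.cn > 2] = 1
        return cls


# ---------------------------------------------------------------------------
# genome + annotation simulation


def simulate_genome(
    n_scaffolds: int = 8,
    length_distribution: Sequence[int] | None = None,
    gene_density: float = 0.15,
    seed: int = 0,
    window_size: int = 250,
    go_vocabulary_size: int = 25,
    mean_scaffold_length: float = 250_000.0,
):
    """Simulate a fragmented genome with genes, child features and GO terms.

    Parameters
    ----------
    n_scaffolds : int
        Number of scaffolds (>= 1).
    length_distribution : sequence of int, optional
        Explicit scaffold lengths; by default lengths are log-normal around
        ``mean_scaffold_length``. Lengths are always sorted descending.
    gene_density : float
        Expected genes per kb. Genes are placed without overlap by rejection
        sampling; an impossible density raises.
    seed : int
        Seeds all randomness; identical seeds give byte-identical output.

    Returns
    -------
    (GenomeModel, list[Feature], DataFrame)
        The genome, the gene/CDS/exon/start_codon/stop_codon features, and a
        two-column ``gene_id``/``go_term`` map (0-3 terms per gene).
    """
    if n_scaffolds < 1:
        raise ValueError("n_scaffolds must be >= 1")
    rng = np.random.default_rng(seed)
    if length_distribution is None:
        lengths = np.asarray(
            rng.lognormal(np.log(mean_scaffold_length), 0.6, size=n_scaffolds), dtype=np.int64
        )
        lengths = np.maximum(lengths, 10 * window_size)
    else:
        lengths = np.asarray(list(length_distribution), dtype=np.int64)
        if len(lengths) != n_scaffolds:
            raise ValueError("length_distribution size mismatch")
    lengths = np.sort(lengths)[::-1]
    genome = GenomeModel(
        [(f"scaffold_{i + 1}", int(L)) for i, L in enumerate(lengths)],
        window_size=window_size,
    )

    products, weights = zip(*PRODUCT_VOCABULARY)
    weights = np.asarray(weights) / sum(weights)
    go_vocab = [f"GO:{i + 1:07d}" for i in range(go_vocabulary_size)]

    features: list[Feature] = []
    go_rows: list[tuple[str, str]] = []
    protein_id = 1_000_000
    for name, length in genome.scaffolds:
        n_genes = rng.poisson(gene_density * length / 1000)
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < n_genes:
            attempts += 1
            if attempts > 200 * max(n_genes, 1):
                raise ValueError(
                    f"gene_density {gene_density} too high to place {n_genes} "
                    f"non-overlapping genes on {name} ({length} bp)"
                )
            size = int(rng.integers(600, 3001))
            if size + 10 >= length:
                continue
            start = int(rng.integers(0, length - size))
            if any(start < e and s < start + size for s, e in placed):
                continue
            placed.append((start, start + size))
        placed.sort()
        for gi, (gstart, gend) in enumerate(placed):
            protein_id += 1
            gene_id = f"gene_{name}_{gi + 1:04d}"
            product = str(rng.choice(products, p=weights))
            strand = "+" if rng.random() < 0.5 else "-"
            attrs = {
                "ID": gene_id,
                "proteinId": str(protein_id),
                "product": product,
            }
            features.append(Feature(name, gstart, gend, "gene", gene_id, strand, attrs))
            n_exons = int(rng.integers(1, 4))
            bounds = np.linspace(gstart, gend, n_exons + 1).astype(int)
            for ei in range(n_exons):
                estart, eend = int(bounds[ei]), int(bounds[ei + 1])
                for ftype in ("exon", "CDS"):
                    features.append(
                        Feature(
                            name, estart, eend, ftype, gene_id, strand,
                            {"Parent": gene_id},
                        )
                    )
            features.append(
                Feature(name, gstart, gstart + 3, "start_codon", gene_id, strand,
                        {"Parent": gene_id})
            )
            features.append(
                Feature(name, gend - 3, gend, "stop_codon", gene_id, strand,
                        {"Parent": gene_id})
            )
            for term in rng.choice(go_vocab, size=int(rng.integers(0, 4)), replace=False):
                go_rows.append((gene_id, str(term)))

    go_map = pd.DataFrame(go_rows, columns=["gene_id", "go_term"])
    return genome, features, go_map


# ---------------------------------------------------------------------------
# truth simulation


def _draw_cn(rng: np.random.Generator, dist: int | dict[int, float]) -> int:
    if isinstance(dist, int):
        return dist
    states = sorted(dist)
    probs = np.asarray([dist[s] for s in states], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(states, p=probs))


def simulate_truth(genome: GenomeModel, spec: CohortSpec) -> TruthSet:
    """Place shared CNV polymorphism and planted regions on the window grid.

    Per sample, loss and gain events are Poisson processes along the genome
    (rates per Mb from ``spec``) with exponentially distributed sizes; loss
    events draw CN uniformly from {0, 1}, gains uniformly from
    {3, ..., max_cn}. Planted regions then overwrite the baseline with
    independent per-sample draws from the population-specific distribution.
    Baseline copy number is 2 everywhere else (assumed diploid).
    """
    rng = np.random.default_rng(spec.seed)
    windows = genome.windows_of()
    w = genome.window_size
    # per-scaffold slice of the global window vector
    offsets: dict[str, tuple[int, int]] = {}
    pos = 0
    for name, length in genome.scaffolds:
        n_win = (length + w - 1) // w
        offsets[name] = (pos, n_win)
        pos += n_win

    samples = spec.sample_ids
    labels = spec.labels
    cn = np.full((len(samples), pos), 2, dtype=np.int16)

    scaf_names = genome.names
    scaf_lengths = np.asarray([genome.length_of(n) for n in scaf_names], dtype=float)
    scaf_probs = scaf_lengths / scaf_lengths.sum()
    genome_mb = scaf_lengths.sum() / 1e6

    for si in range(len(samples)):
        for cls, rate, size_mean in (
            ("loss", spec.shared_loss_rate, spec.loss_size_mean),
            ("gain", spec.shared_gain_rate, spec.gain_size_mean),
        ):
            n_events = rng.poisson(rate * genome_mb)
            for _ in range(n_events):
                scaf_i = int(rng.choice(len(scaf_names), p=scaf_probs))
                name = scaf_names[scaf_i]
                length = int(scaf_lengths[scaf_i])
                start = int(rng.integers(0, length))
                size = max(1, int(rng.exponential(size_mean)))
                end = min(start + size, length)
                if cls == "loss":
                    event_cn = int(rng.integers(0, 2))
                else:
                    event_cn = int(rng.integers(3, spec.max_cn + 1))
                off, n_win = offsets[name]
                lo = start // w
                hi = min((end + w - 1) // w, n_win)
                cn[si, off + lo : off + hi] = event_cn

    planted_draws: list[dict] = []
    for region in spec.planted_regions:
        if region.scaffold not in offsets:
            raise ValueError(f"planted region on unknown scaffold {region.scaffold!r}")
        length = genome.length_of(region.scaffold)
        if not (0 <= region.start < region.end <= length):
            raise ValueError(
                f"planted region [{region.start}, {region.end}) outside "
                f"{region.scaffold} (length {length})"
            )
        off, n_win = offsets[region.scaffold]
        lo = region.start // w
        hi = min((region.end + w - 1) // w, n_win)
        draws = {}
        for si, sample in enumerate(samples):
            dist = region.pop1_cn if labels[sample] == spec.pop1_name else region.pop2_cn
            value = _draw_cn(rng, dist)
            cn[si, off + lo : off + hi] = value
            draws[sample] = value
        planted_draws.append({"region": region, "draws": draws})

    return TruthSet(genome, windows, samples, labels, cn, planted_draws)


# ---------------------------------------------------------------------------
# depth emission


def emit_depths(truth: TruthSet, spec: CohortSpec):
    """Draw per-window read counts from the true copy states.

    Counts are Poisson with mean ``coverage_mean * CN / 2`` scaled by the
    window's length fraction (trailing partial windows receive
    proportionally fewer reads). With ``nb_dispersion`` set, a gamma
    multiplier of that dispersion adds negative-binomial overdispersion.
    """
    from .calling import DepthMatrix  # local import to avoid a cycle

    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1]))
    lengths = np.asarray([win.length for win in truth.windows], dtype=float)
    mean = spec.coverage_mean * truth.cn / 2.0 * (lengths / truth.genome.window_size)
    if spec.nb_dispersion:
        mean = mean * rng.gamma(spec.nb_dispersion, 1.0 / spec.nb_dispersion, size=mean.shape)
    counts = rng.poisson(mean).astype(np.int64)
    return DepthMatrix(
        windows=truth.windows,
        samples=truth.samples,
        labels=truth.labels,
        counts=counts,
        window_size=truth.genome.window_size,
    )


def simulate_cohort(spec: CohortSpec, genome: GenomeModel | None = None,
                    features: list[Feature] | None = None,
                    go_map: pd.DataFrame | None = None,
                    genome_kwargs: dict | None = None):
    """Convenience wrapper: genome + truth + depths in one call.

    Returns ``(genome, features, go_map, truth, depths)``. Pass a prebuilt
    genome/annotation to hold the genome fixed across cohort replicates.
    """
    if genome is None:
        genome, features, go_map = simulate_genome(seed=spec.seed, **(genome_kwargs or {}))
    truth = simulate_truth(genome, spec)
    depths = emit_depths(truth, spec)
    return genome, features, go_map, truth, depths


# ---------------------------------------------------------------------------
# plain-text emission


def write_matrix_tsv(windows: list[Window], samples: list[str], values: np.ndarray, path) -> None:
    """Write a windows-by-samples matrix as TSV (scaffold, start, end, samples...)."""
    df = pd.DataFrame(
        {
            "scaffold": [w.scaffold for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )
    for i, sample in enumerate(samples):
        df[sample] = values[i]
    df.to_csv(path, sep="\t", index=False)


def write_labels_tsv(labels: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for sample, pop in labels.items():
            fh.write(f"{sample}\t{pop}\n")


def read_labels_tsv(path) -> dict[str, str]:
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            sample, pop = line.split("\t")
            labels[sample] = pop
    return labels


def write_cohort(outdir, spec: CohortSpec, genome, features, go_map, truth, depths) -> None:
    """Emit the full file set: genome TSV, GFF3, GO map, depths, truth, labels."""
    import os

    os.makedirs(outdir, exist_ok=True)
    write_genome_tsv(genome, os.path.join(outdir, "genome.tsv"))
    write_gff(features, os.path.join(outdir, "annotation.gff3"))
    go_map.to_csv(os.path.join(outdir, "go_map.tsv"), sep="\t", index=False, header=False)
    write_matrix_tsv(depths.windows, depths.samples, depths.counts,
                     os.path.join(outdir, "depths.tsv"))
    write_matrix_tsv(truth.windows, truth.samples, truth.cn,
                     os.path.join(outdir, "truth.tsv"))
    write_labels_tsv(truth.labels, os.path.join(outdir, "labels.tsv"))
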