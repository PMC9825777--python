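"""Synthetic fixture generation.

Produces a fully structured input bundle — genome, per-cell peak calls and
read placements, 15 signal tracks per cell type, 5 kb contact maps and a
JASPAR PWM file — with known ground-truth site classes:

- A-specific sites carry elevated accessibility and read counts in cell A
  only (and mirrored for B-specific sites);
- shared sites carry a planted sequence motif plus correlated accessibility
  enrichment in both cell types;
- read counts are negative-binomial with class-consistent fold changes and
  contacts decay exponentially with genomic distance.

All randomness flows from a single seed through named substreams, so any
stage regenerates identically on its own.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import PWM, ContactMap, GenomicInterval, SignalTrack
from .peak_selection import Label

__all__ = ["FixtureConfig", "Bundle", "ASSAYS", "CELL_TYPES", "default_pwms",
           "make_genome", "make_peaks", "make_signals_counts_contacts",
           "make_bundle", "write_bundle"]

ASSAYS = (
    "DNase", "H2AZ", "H3K4me1", "H3K4me2", "H3K4me3", "H3K9ac", "H3K9me3",
    "H3K27ac", "H3K27me3", "H3K36me3", "H3K79me2", "H4K20me1", "MNase",
    "RNA", "Methyl",
)
CELL_TYPES = ("cellA", "cellB")

_SUBSTREAMS = {"genome": 11, "peaks": 23, "signals": 37, "reads": 41,
               "contacts": 53}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _SUBSTREAMS[stage]])


def _consensus_counts(consensus: str, strength: int = 40) -> np.ndarray:
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.ones((4, len(consensus)))
    for j, base in enumerate(consensus):
        counts[base_index[base], j] += strength
    return counts


def default_motif() -> PWM:
    """The PWM planted in shared sites (count matrix, strong consensus)."""
    return PWM("MOTIF_SHARED", _consensus_counts("TGACGTCA"))


def default_pwms() -> list[PWM]:
    """A 5-motif cofactor panel: the planted motif plus four decoys."""
    return [
        default_motif(),
        PWM("COFACTOR_1", _consensus_counts("CACGTG")),
        PWM("COFACTOR_2", _consensus_counts("TTGCGCAA")),
        PWM("COFACTOR_3", _consensus_counts("GGGGCGGG")),
        PWM("COFACTOR_4", _consensus_counts("TGACTCA")),
    ]


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_peaks: tuple[int, int, int] = (100, 100, 100)  # A-specific, B-specific, shared
    chromosomes: tuple[str, ...] = (
        "chr1", "chr2", "chr3", "chr8", "chr16", "chr18"
    )
    genome_size: int = 250_000  # bp per chromosome
    peak_len: int = 600
    motif: PWM = field(default_factory=default_motif)
    plant_motif: bool = True
    accessibility_effect: float = 5.0
    count_fold_change: float = 8.0
    nb_dispersion: float = 0.05
    contact_decay: float = 2e-5  # per bp
    contact_boost: float = 2.0  # class-linked contact enrichment
    base_read_mean: float = 300.0
    read_length: int = 100
    signal_bin: int = 50
    resolution: int = 5000

    def __post_init__(self) -> None:
        if self.genome_size <= 0 or self.peak_len <= 0:
            raise ValueError("sizes must be positive")
        if any(n < 0 for n in self.n_peaks):
            raise ValueError("peak counts must be non-negative")
        if (self.accessibility_effect < 1 or self.count_fold_change < 1
                or self.contact_boost < 1):
            raise ValueError("effect sizes must be >= 1")


@dataclass
class Bundle:
    config: FixtureConfig
    genome: dict[str, str]
    peaks: list[GenomicInterval]
    labels: list[Label]
    tracks: dict[tuple[str, str], SignalTrack]
    reads: dict[str, list[GenomicInterval]]
    contacts: dict[str, ContactMap]
    pwms: list[PWM]

    def peak_calls(self, cell: str) -> list[GenomicInterval]:
        """The peaks 'called' in one cell type: its specific sites + shared."""
        wanted = {
            "cellA": {Label.A_SPECIFIC, Label.SHARED},
            "cellB": {Label.B_SPECIFIC, Label.SHARED},
        }[cell]
        return [p for p, l in zip(self.peaks, self.labels) if l in wanted]


def make_genome(config: FixtureConfig) -> dict[str, str]:
    """I.i.d. uniform ACGT per chromosome, reproducible from the seed."""
    rng = _rng(config.seed, "genome")
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(bases[rng.integers(0, 4, config.genome_size)])
        for chrom in config.chromosomes
    }


def make_peaks(
    config: FixtureConfig, genome: dict[str, str]
) -> tuple[list[GenomicInterval], list[Label], dict[str, str]]:
    """Place non-overlapping fixed-length peaks and assign ground-truth
    classes; shared peaks get the configured motif planted in the genome."""
    rng = _rng(config.seed, "peaks")
    margin = 2 * config.resolution
    step = config.peak_len * 3
    slots = [
        (chrom, start)
        for chrom in config.chromosomes
        for start in range(margin, config.genome_size - margin - config.peak_len, step)
    ]
    total = sum(config.n_peaks)
    if total > len(slots):
        raise ValueError(
            f"genome too small: {len(slots)} slots for {total} requested peaks"
        )
    chosen = rng.choice(len(slots), size=total, replace=False)
    chosen.sort()
    class_labels = (
        [Label.A_SPECIFIC] * config.n_peaks[0]
        + [Label.B_SPECIFIC] * config.n_peaks[1]
        + [Label.SHARED] * config.n_peaks[2]
    )
    rng.shuffle(class_labels)  # type: ignore[arg-type]
    peaks, labels = [], []
    mutable = {chrom: list(seq) for chrom, seq in genome.items()}
    consensus_idx = config.motif.weights.argmax(axis=0)
    consensus = "".join("ACGT"[i] for i in consensus_idx)
    for slot_idx, label in zip(chosen, class_labels):
        chrom, start = slots[slot_idx]
        peak = GenomicInterval(chrom, start, start + config.peak_len)
        if label is Label.SHARED and config.plant_motif:
            offset = int(rng.integers(0, config.peak_len - len(consensus)))
            mutable[chrom][start + offset : start + offset + len(consensus)] = consensus
        peaks.append(peak)
        labels.append(label)
    return peaks, labels, {chrom: "".join(s) for chrom, s in mutable.items()}


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float) -> int:
    if mean <= 0:
        return 0
    if dispersion <= 1e-12:
        return int(rng.poisson(mean))
    n = 1.0 / dispersion
    p = n / (n + mean)
    return int(rng.negative_binomial(n, p))


def make_signals_counts_contacts(
    config: FixtureConfig,
    peaks: list[GenomicInterval],
    labels: list[Label],
) -> tuple[
    dict[tuple[str, str], SignalTrack],
    dict[str, list[GenomicInterval]],
    dict[str, ContactMap],
]:
    """Generate the signal tracks, read placements and contact maps."""
    tracks = _make_signals(config, peaks, labels)
    reads = _make_reads(config, peaks, labels)
    contacts = _make_contacts(config, peaks, labels)
    return tracks, reads, contacts


def _enrichment_cells(label: Label) -> tuple[float, float]:
    """Which cells an enriched site lights up in (multipliers per cell)."""
    if label is Label.A_SPECIFIC:
        return 1.0, 0.0
    if label is Label.B_SPECIFIC:
        return 0.0, 1.0
    return 1.0, 1.0  # shared


def _make_signals(config, peaks, labels):
    rng = _rng(config.seed, "signals")
    nbins = config.genome_size // config.signal_bin
    tracks: dict[tuple[str, str], SignalTrack] = {}
    effect = config.accessibility_effect - 1.0
    for assay in ASSAYS:
        values = {
            cell: {
                chrom: rng.gamma(2.0, 0.5, nbins)
                for chrom in config.chromosomes
            }
            for cell in CELL_TYPES
        }
        for peak, label in zip(peaks, labels):
            lo = peak.start // config.signal_bin
            hi = -(-peak.end // config.signal_bin)
            profile = rng.gamma(3.0, 1.0, hi - lo)
            if assay == "DNase":
                on_a, on_b = _enrichment_cells(label)
                boost = effect * profile
                values["cellA"][peak.chrom][lo:hi] += on_a * boost
                values["cellB"][peak.chrom][lo:hi] += on_b * boost
            else:
                # generic mild enrichment in every peak, both cells
                for cell in CELL_TYPES:
                    values[cell][peak.chrom][lo:hi] += 0.5 * profile
        for cell in CELL_TYPES:
            records = []
            for chrom in config.chromosomes:
                vals = values[cell][chrom]
                edges = np.arange(nbins) * config.signal_bin
                records.extend(
                    (chrom, int(s), int(s + config.signal_bin), float(v))
                    for s, v in zip(edges, vals)
                )
            tracks[(cell, assay)] = SignalTrack.from_records(cell, assay, records)
    return tracks


def _make_reads(config, peaks, labels):
    rng = _rng(config.seed, "reads")
    reads: dict[str, list[GenomicInterval]] = {cell: [] for cell in CELL_TYPES}
    half = config.read_length // 2
    for peak, label in zip(peaks, labels):
        on_a, on_b = _enrichment_cells(label)
        low_mean = config.base_read_mean / config.count_fold_change
        means = {
            "cellA": config.base_read_mean if on_a else low_mean,
            "cellB": config.base_read_mean if on_b else low_mean,
        }
        for cell in CELL_TYPES:
            count = _nb_draw(rng, means[cell], config.nb_dispersion)
            mids = rng.integers(peak.start, peak.end, count)
            for mid in mids:
                start = max(int(mid) - half, 0)
                reads[cell].append(
                    GenomicInterval(peak.chrom, start, start + config.read_length)
                )
    return reads


def _make_contacts(config, peaks, labels):
    rng = _rng(config.seed, "contacts")
    res = config.resolution
    max_bin = (config.genome_size // res - 1) * res
    entries: dict[str, dict[tuple[str, int, int], float]] = {
        cell: {} for cell in CELL_TYPES
    }
    for peak, label in zip(peaks, labels):
        peak_bin = (peak.midpoint // res) * res
        on_a, on_b = _enrichment_cells(label)
        boost = {
            "cellA": config.contact_boost if on_a else 1.0,
            "cellB": config.contact_boost if on_b else 1.0,
        }
        n_partners = 15
        sides = rng.choice([-1, 1], n_partners)
        dists = np.arange(1, n_partners + 1) * res
        noise = rng.lognormal(0.0, 0.3, (len(CELL_TYPES), n_partners))
        for side, dist, noise_col in zip(sides, dists, noise.T):
            partner = peak_bin + side * int(dist)
            if partner < 0 or partner > max_bin:
                partner = peak_bin - side * int(dist)
            if partner < 0 or partner > max_bin or partner == peak_bin:
                continue
            base = 50.0 * np.exp(-config.contact_decay * dist)
            for cell, nz in zip(CELL_TYPES, noise_col):
                count = base * nz * boost[cell]
                key = (peak.chrom, min(peak_bin, partner), max(peak_bin, partner))
                prev = entries[cell].get(key, 0.0)
                entries[cell][key] = max(prev, float(count))
    contacts = {}
    for cell in CELL_TYPES:
        cmap = ContactMap(cell, res)
        for (chrom, i, j), count in entries[cell].items():
            cmap.set(chrom, i, j, count)
        contacts[cell] = cmap
    return contacts


def make_bundle(config: FixtureConfig | None = None) -> Bundle:
    """Generate the full in-memory bundle."""
    config = config or FixtureConfig()
    genome = make_genome(config)
    peaks, labels, genome = make_peaks(config, genome)
    tracks, reads, contacts = make_signals_counts_contacts(config, peaks, labels)
    return Bundle(
        config=config,
        genome=genome,
        peaks=peaks,
        labels=labels,
        tracks=tracks,
        reads=reads,
        contacts=contacts,
        pwms=default_pwms(),
    )


def write_bundle(bundle: Bundle, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write the bundle as standard-format files the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    fasta = out / "genome.fa"
    with open(fasta, "w") as fh:
        for chrom, seq in bundle.genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["genome"] = fasta

    for cell in CELL_TYPES:
        bed = out / f"peaks_{cell}.bed"
        with open(bed, "w") as fh:
            for p in bundle.peak_calls(cell):
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
        paths[f"peaks_{cell}"] = bed

        reads_bed = out / f"reads_{cell}.bed"
        with open(reads_bed, "w") as fh:
            for r in bundle.reads[cell]:
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
        paths[f"reads_{cell}"] = reads_bed

        triplets = out / f"contacts_{cell}.tsv"
        with open(triplets, "w") as fh:
            seen = set()
            for (chrom, i, j), count in sorted(bundle.contacts[cell].items()):
                key = (chrom, min(i, j), max(i, j))
                if key in seen:
                    continue
                seen.add(key)
                fh.write(f"{chrom}\t{key[1]}\t{key[2]}\t{count:.6g}\n")
        paths[f"contacts_{cell}"] = triplets

    signal_dir = out / "signals"
    signal_dir.mkdir(exist_ok=True)
    for (cell, assay), track in bundle.tracks.items():
        path = signal_dir / f"{assay}_{cell}.bedGraph"
        with open(path, "w") as fh:
            for chrom in bundle.config.chromosomes:
                if chrom not in track._starts:
                    continue
                for s, e, v in zip(
                    track._starts[chrom], track._ends[chrom], track._values[chrom]
                ):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")
        paths[f"signal_{assay}_{cell}"] = path

    pwm_path = out / "pwms.jaspar"
    with open(pwm_path, "w") as fh:
        for pwm in bundle.pwms:
            fh.write(f">{pwm.id}\n")
            for base, row in zip("ACGT", pwm.weights):
                fh.write(f"{base} [ " + " ".join(f"{v:g}" for v in row) + " ]\n")
    paths["pwms"] = pwm_path

    truth = out / "truth.tsv"
    with open(truth, "w") as fh:
        fh.write("chrom\tstart\tend\tlabel\n")
        for peak, label in zip(bundle.peaks, bundle.labels):
            fh.write(f"{peak.chrom}\t{peak.start}\t{peak.end}\t{label.value}\n")
    paths["truth"] = truth
    return paths
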