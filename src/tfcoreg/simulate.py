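"""Synthetic data with the statistical structure the pipeline assumes.

Four generators stand in for the study-scale raw data that desk-scale runs
cannot carry:

* ``simulate_chipseq`` — Poisson-background read-start tracks with planted
  enriched peaks and a ChIP/control depth ratio (the real libraries were
  roughly 15M ChIP vs 9M control reads; defaults here are scaled down);
* ``simulate_expression`` — paired knockdown fold-change tables with the
  replicate layout of the arrays (6 MITF-side experiments M1,M2,U1,U2,G1,G2;
  4 YY1-side) and planted gene classes (co-activated, co-repressed,
  single-factor, antagonistic, null);
* ``simulate_sequences`` — i.i.d.-background region sets with motif
  instances planted at controlled rates in foreground vs background;
* ``simulate_peak_sets`` — paired interval sets with an exact overlap
  fraction by construction.

Every generator is a pure function of (spec, seed): identical inputs give
byte-identical outputs, and each returns truth objects sufficient to score
the downstream stage without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motif import BASES, PositionWeightMatrix, reverse_complement
from .types import FoldChangeTable, GenomicInterval, ReadStartTrack

DEFAULT_GENOME = [("chr1", 1_000_000), ("chr2", 1_000_000)]


# --- ChIP-seq ---------------------------------------------------------------

@dataclass
class ChipSimSpec:
    genome: list[tuple[str, int]] = field(default_factory=lambda: list(DEFAULT_GENOME))
    n_peaks: int = 50
    peak_width: int = 300
    enrichment: float = 8.0
    chip_depth: int = 400_000
    ctrl_depth: int = 250_000
    seed: int = 0
    excluded: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.enrichment <= 1:
            raise ValueError("enrichment must exceed 1")
        if self.chip_depth <= 0 or self.ctrl_depth <= 0:
            raise ValueError("depths must be positive")
        if self.n_peaks < 0 or self.peak_width <= 0:
            raise ValueError("invalid peak parameters")


def _place_disjoint(rng, genome, n, width, min_gap=1, forbidden=None,
                    max_tries_factor=200):
    """Place n non-overlapping width-bp intervals uniformly; error when the
    genome cannot hold them."""
    total_needed = n * (width + min_gap)
    capacity = sum(max(L - width, 0) for _, L in genome)
    if total_needed > sum(L for _, L in genome) or capacity == 0 and n > 0:
        raise ValueError(f"genome too small to place {n} disjoint {width} bp peaks")
    placed: list[GenomicInterval] = []
    forb = list(forbidden or [])
    tries = 0
    lengths = np.array([L for _, L in genome], dtype=float)
    weights = np.maximum(lengths - width, 0)
    weights = weights / weights.sum()
    while len(placed) < n:
        tries += 1
        if tries > max_tries_factor * max(n, 1):
            raise ValueError(f"could not place {n} disjoint {width} bp peaks")
        ci = int(rng.choice(len(genome), p=weights))
        chrom, L = genome[ci]
        start = int(rng.integers(0, L - width + 1))
        cand = GenomicInterval(chrom, start, start + width, name=f"peak_{len(placed)}")
        near = [p for p in placed + forb if p.chrom == chrom]
        if any(max(p.start - min_gap, 0) < cand.end and cand.start < p.end + min_gap
               for p in near):
            continue
        placed.append(cand)
    return placed


def simulate_chipseq(spec: ChipSimSpec
                     ) -> tuple[ReadStartTrack, ReadStartTrack, list[GenomicInterval]]:
    """Simulate ChIP and control read-start tracks with planted peaks.

    Control read starts are uniform over the genome.  ChIP starts follow a
    piecewise-uniform density: baseline everywhere, ``enrichment`` times
    the baseline inside the planted peaks, renormalized so that exactly
    ``chip_depth`` reads are drawn.
    """
    rng = np.random.default_rng(spec.seed)
    chrom_lengths = dict(spec.genome)
    genome_len = sum(chrom_lengths.values())

    truth = _place_disjoint(rng, spec.genome, spec.n_peaks, spec.peak_width,
                            min_gap=spec.peak_width, forbidden=spec.excluded)

    # control: uniform positions
    ctrl_pos: dict[str, list] = {c: [] for c, _ in spec.genome}
    offsets = np.cumsum([0] + [L for _, L in spec.genome])
    flat = rng.integers(0, genome_len, size=spec.ctrl_depth)
    for (chrom, L), lo, hi in zip(spec.genome, offsets[:-1], offsets[1:]):
        sel = flat[(flat >= lo) & (flat < hi)] - lo
        ctrl_pos[chrom] = sel

    # ChIP: mixture of background (uniform) and peak (uniform within peaks,
    # weight = enrichment per bp)
    peak_bp = sum(p.length for p in truth)
    w_peak = spec.enrichment * peak_bp
    w_bg = genome_len - peak_bp
    p_in_peak = w_peak / (w_peak + w_bg)
    n_in_peak = rng.binomial(spec.chip_depth, p_in_peak)
    chip_pos: dict[str, list[np.ndarray]] = {c: [] for c, _ in spec.genome}
    # background reads: uniform over the genome excluding peaks would be
    # exact; uniform over the whole genome is equivalent in distribution
    # when combined with per-peak uniform draws at the right expected total
    flat_bg = rng.integers(0, genome_len, size=spec.chip_depth - n_in_peak)
    for (chrom, L), lo, hi in zip(spec.genome, offsets[:-1], offsets[1:]):
        sel = flat_bg[(flat_bg >= lo) & (flat_bg < hi)] - lo
        chip_pos[chrom].append(sel)
    # but background-in-peak reads are already covered by the peak weight
    # including the 1x baseline; remove the double count by drawing peak
    # reads at (enrichment) x and having placed background over the full
    # genome minus peaks: correct by rejecting background reads in peaks
    peak_mask = {c: np.zeros(0, dtype=np.int64) for c, _ in spec.genome}
    for c, _L in spec.genome:
        ivs = [p for p in truth if p.chrom == c]
        if ivs:
            starts = np.array([p.start for p in ivs])
            ends = np.array([p.end for p in ivs])
            keep_parts = []
            for arr in chip_pos[c]:
                idx = np.searchsorted(starts, arr, "right") - 1
                in_peak = (idx >= 0) & (arr < ends[np.clip(idx, 0, None)])
                keep_parts.append(arr[~in_peak])
            chip_pos[c] = keep_parts
    n_rejected = (spec.chip_depth - n_in_peak
                  - sum(sum(a.size for a in chip_pos[c]) for c, _ in spec.genome))
    # redraw rejected background reads outside peaks (rejection sampling)
    while n_rejected > 0:
        flat_new = rng.integers(0, genome_len, size=n_rejected)
        accepted = 0
        for (chrom, L), lo, hi in zip(spec.genome, offsets[:-1], offsets[1:]):
            arr = flat_new[(flat_new >= lo) & (flat_new < hi)] - lo
            ivs = [p for p in truth if p.chrom == chrom]
            if ivs:
                starts = np.array([p.start for p in ivs])
                ends = np.array([p.end for p in ivs])
                idx = np.searchsorted(starts, arr, "right") - 1
                in_peak = (idx >= 0) & (arr < ends[np.clip(idx, 0, None)])
                arr = arr[~in_peak]
            chip_pos[chrom].append(arr)
            accepted += arr.size
        n_rejected -= accepted

    # peak reads: pick a peak proportional to its length, uniform inside
    if truth and n_in_peak > 0:
        lens = np.array([p.length for p in truth], dtype=float)
        which = rng.choice(len(truth), size=n_in_peak, p=lens / lens.sum())
        offs = rng.integers(0, spec.peak_width, size=n_in_peak)
        for i, p in enumerate(truth):
            sel = offs[which == i]
            chip_pos[p.chrom].append(p.start + sel % p.length)

    chip = ReadStartTrack(
        {c: np.concatenate(v) if v else np.empty(0, dtype=np.int64)
         for c, v in chip_pos.items()},
        chrom_lengths)
    ctrl = ReadStartTrack({c: np.asarray(v) for c, v in ctrl_pos.items()}, chrom_lengths)
    return chip, ctrl, truth


# --- expression -------------------------------------------------------------

GENE_CLASSES = ("co_activated", "co_repressed", "mitf_only", "yy1_only",
                "antagonistic", "null")

DEFAULT_CLASS_SIZES = {
    "co_activated": 200,
    "co_repressed": 150,
    "mitf_only": 100,
    "yy1_only": 100,
    "antagonistic": 0,
}

# per-class mean log fold-change sign in the (MITF-side, YY1-side) tables;
# knocking down a shared activator lowers the target in both experiments
_CLASS_SIGNS = {
    "co_activated": (-1.0, -1.0),
    "co_repressed": (+1.0, +1.0),
    "mitf_only": (-1.0, 0.0),
    "yy1_only": (0.0, -1.0),
    "antagonistic": (-1.0, +1.0),
    "null": (0.0, 0.0),
}


@dataclass
class ExprSimSpec:
    n_genes: int = 2000
    class_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIZES))
    effect: float = 1.5
    noise_sd: float = 0.3
    mitf_experiments: tuple[str, ...] = ("M1", "M2", "U1", "U2", "G1", "G2")
    yy1_experiments: tuple[str, ...] = ("Y_M1", "Y_M2", "Y_U1", "Y_U2")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.class_sizes) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene classes: {sorted(unknown)}")
        if sum(self.class_sizes.values()) > self.n_genes:
            raise ValueError("class sizes exceed n_genes")


def simulate_expression(spec: ExprSimSpec
                        ) -> tuple[FoldChangeTable, FoldChangeTable, dict[str, str]]:
    """Paired knockdown fold-change tables with planted gene classes.

    Each replicate value is the class mean (+-effect by class and side, 0
    for null/absent) plus Normal(0, noise_sd) noise.  Returns the
    MITF-side table, the YY1-side table, and {gene_id: class} truth labels.
    """
    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"gene_{i:05d}" for i in range(spec.n_genes)]
    labels: dict[str, str] = {}
    i = 0
    for cls in GENE_CLASSES:
        if cls == "null":
            continue
        for _ in range(spec.class_sizes.get(cls, 0)):
            labels[gene_ids[i]] = cls
            i += 1
    for g in gene_ids[i:]:
        labels[g] = "null"

    m_mitf = len(spec.mitf_experiments)
    m_yy1 = len(spec.yy1_experiments)
    signs = np.array([_CLASS_SIGNS[labels[g]] for g in gene_ids])
    mean_mitf = spec.effect * signs[:, 0]
    mean_yy1 = spec.effect * signs[:, 1]
    vals_mitf = mean_mitf[:, None] + rng.normal(0, spec.noise_sd,
                                                (spec.n_genes, m_mitf))
    vals_yy1 = mean_yy1[:, None] + rng.normal(0, spec.noise_sd,
                                              (spec.n_genes, m_yy1))
    t_mitf = FoldChangeTable(vals_mitf, gene_ids, list(spec.mitf_experiments))
    t_yy1 = FoldChangeTable(vals_yy1, gene_ids, list(spec.yy1_experiments))
    return t_mitf, t_yy1, labels


# --- sequences --------------------------------------------------------------

@dataclass
class MotifSimSpec:
    n_fg: int = 300
    n_bg: int = 300
    region_length: int = 200
    gc: float = 0.41  # human genome-wide GC content
    pwm: PositionWeightMatrix | None = None
    plant_rate_fg: float = 0.4
    plant_rate_bg: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.plant_rate_fg <= 1 and 0 <= self.plant_rate_bg <= 1):
            raise ValueError("plant rates must lie in [0, 1]")
        if not (0 < self.gc < 1):
            raise ValueError("gc must lie in (0, 1)")
        if self.pwm is not None and self.region_length < self.pwm.width:
            raise ValueError("region_length shorter than the motif")


def _random_seqs(rng, n, length, gc):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    mat = rng.choice(4, size=(n, length), p=p)
    lookup = np.array(list(BASES))
    return ["".join(lookup[row]) for row in mat]


def _sample_motif_instance(rng, pwm: PositionWeightMatrix) -> str:
    cols = [rng.choice(4, p=pwm.probs[:, j]) for j in range(pwm.width)]
    return "".join(BASES[c] for c in cols)


def simulate_sequences(spec: MotifSimSpec
                       ) -> tuple[dict[str, str], dict[str, str], list[dict]]:
    """Foreground/background region sets with motif instances planted at
    controlled rates.

    Backgrounds are i.i.d. with the stated GC; a planted instance is drawn
    column-wise from the PWM, inserted at a uniform offset on a uniformly
    chosen strand.  Truth records region, offset and strand per plant.
    """
    if spec.pwm is None:
        raise ValueError("spec.pwm is required")
    rng = np.random.default_rng(spec.seed)
    truth: list[dict] = []
    out = []
    for side, n, rate in (("fg", spec.n_fg, spec.plant_rate_fg),
                          ("bg", spec.n_bg, spec.plant_rate_bg)):
        seqs = {}
        raw = _random_seqs(rng, n, spec.region_length, spec.gc)
        planted = rng.random(n) < rate
        for i, seq in enumerate(raw):
            name = f"{side}_{i:04d}"
            if planted[i]:
                inst = _sample_motif_instance(rng, spec.pwm)
                strand = "+" if rng.random() < 0.5 else "-"
                if strand == "-":
                    inst = reverse_complement(inst)
                off = int(rng.integers(0, spec.region_length - spec.pwm.width + 1))
                seq = seq[:off] + inst + seq[off + spec.pwm.width:]
                truth.append({"region": name, "offset": off, "strand": strand})
            seqs[name] = seq
        out.append(seqs)
    return out[0], out[1], truth


# --- paired peak sets -------------------------------------------------------

def simulate_peak_sets(n_a: int, n_b: int, overlap_target: float,
                       genome: list[tuple[str, int]] | None = None,
                       width: int = 300, seed: int = 0
                       ) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Two interval sets where exactly round(overlap_target * n_a) of A
    intersect B by >= 1 bp and the rest are disjoint from B."""
    if not (0 <= overlap_target <= 1):
        raise ValueError("overlap_target must lie in [0, 1]")
    genome = genome or DEFAULT_GENOME
    rng = np.random.default_rng(seed)
    set_b = _place_disjoint(rng, genome, n_b, width, min_gap=3 * width)
    n_overlap = round(overlap_target * n_a)
    set_a: list[GenomicInterval] = []
    for i in range(n_overlap):
        b = set_b[i % len(set_b)] if set_b else None
        if b is None:
            raise ValueError("cannot overlap an empty B set")
        # shift by less than one width: guaranteed >= 1 bp intersection
        shift = int(rng.integers(-(width - 1), width))
        start = max(b.start + shift, 0)
        set_a.append(GenomicInterval(b.chrom, start, start + width, name=f"a_{i}"))
    non = _place_disjoint(rng, genome, n_a - n_overlap, width, min_gap=width,
                          forbidden=set_b + set_a)
    for j, iv in enumerate(non):
        set_a.append(GenomicInterval(iv.chrom, iv.start, iv.end,
                                     name=f"a_{n_overlap + j}"))
    return set_a, set_b
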