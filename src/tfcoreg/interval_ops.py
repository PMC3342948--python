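"""Binding-site set comparisons and peak-to-gene assignment.

Implements the interval arithmetic behind four recurring questions about
ChIP peak sets: what fraction of set A overlaps set B; which sites in a
target set are specific to it (no other-set site within a distance of the
summit); which peak is nearest a gene's TSS (signed in gene orientation);
and which genes a peak regulates under the "within 5 kb of the TSS or in
an intron / the gene body" rule.

Overlap queries use sorted coordinate arrays with binary search; exactness
against brute-force all-pairs checks is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import GeneModel, GenomicInterval


@dataclass(frozen=True)
class OverlapReport:
    set_a_id: str
    set_b_id: str
    n_a: int
    n_b: int
    n_a_overlapping: int

    @property
    def fraction(self) -> float:
        return self.n_a_overlapping / self.n_a


@dataclass(frozen=True)
class PeakGeneAssignment:
    peak: GenomicInterval
    gene_id: str
    relation: str  # tss_window | intron | exon | gene_body
    signed_distance_to_tss: int


def _by_chrom(intervals) -> dict[str, list[GenomicInterval]]:
    out: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    return out


class _IntervalIndex:
    """Max-end-prefix trick over start-sorted intervals for overlap tests."""

    def __init__(self, intervals: list[GenomicInterval]):
        ivs = sorted(intervals, key=lambda v: v.start)
        self.starts = np.array([v.start for v in ivs], dtype=np.int64)
        ends = np.array([v.end for v in ivs], dtype=np.int64)
        self.max_end_prefix = np.maximum.accumulate(ends) if ends.size else ends
        self.ivs = ivs

    def any_overlap(self, start: int, end: int, min_overlap_bp: int = 1) -> bool:
        # candidates: intervals with iv.start <= end - min_overlap
        hi = int(np.searchsorted(self.starts, end - min_overlap_bp, "right"))
        if hi == 0:
            return False
        # need some candidate with iv.end >= start + min_overlap
        if self.max_end_prefix[hi - 1] < start + min_overlap_bp:
            return False
        # the prefix-max guarantees existence only when overlap length is
        # measured against a single interval; verify by scanning candidates
        for iv in self.ivs[:hi]:
            if min(iv.end, end) - max(iv.start, start) >= min_overlap_bp:
                return True
        return False


def overlap_fraction(set_a: list[GenomicInterval], set_b: list[GenomicInterval],
                     min_overlap_bp: int = 1, set_a_id: str = "A",
                     set_b_id: str = "B") -> OverlapReport:
    """Fraction of A intervals sharing >= min_overlap_bp with any B interval.

    Each A interval counts at most once, however many B intervals it hits.
    """
    if not set_a:
        raise ValueError("set A is empty: overlap fraction undefined")
    b_index = {chrom: _IntervalIndex(ivs) for chrom, ivs in _by_chrom(set_b).items()}
    n_hit = 0
    for iv in set_a:
        idx = b_index.get(iv.chrom)
        if idx is not None and idx.any_overlap(iv.start, iv.end, min_overlap_bp):
            n_hit += 1
    return OverlapReport(set_a_id, set_b_id, len(set_a), len(set_b), n_hit)


def _summit(iv: GenomicInterval) -> int:
    # a caller-provided summit rides in .score only for PeakCall objects;
    # for plain intervals the midpoint stands in
    return iv.midpoint


def specific_sites(target_set: list[GenomicInterval],
                   other_sets: list[list[GenomicInterval]],
                   distance: int = 5000) -> list[GenomicInterval]:
    """Target sites with no other-set site within ``distance`` of the summit.

    Distances are summit-to-summit (midpoints when no summit is recorded)
    and the boundary is inclusive: a site exactly ``distance`` away removes
    the target ("within 5 kb").
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    other_summits: dict[str, np.ndarray] = {}
    for s in other_sets:
        for iv in s:
            other_summits.setdefault(iv.chrom, [])
    for s in other_sets:
        for iv in s:
            other_summits[iv.chrom].append(_summit(iv))
    other_summits = {c: np.sort(np.array(v, dtype=np.int64))
                     for c, v in other_summits.items()}
    kept = []
    for iv in target_set:
        summits = other_summits.get(iv.chrom)
        if summits is None or summits.size == 0:
            kept.append(iv)
            continue
        s = _summit(iv)
        i = int(np.searchsorted(summits, s))
        near = min(
            [abs(s - int(summits[j])) for j in (i - 1, i) if 0 <= j < summits.size]
        )
        if near > distance:
            kept.append(iv)
    return kept


def nearest_peak_to_tss(peaks: list[GenomicInterval], gene: GeneModel,
                        summits: list[int] | None = None
                        ) -> tuple[GenomicInterval, int]:
    """Peak whose summit minimizes |summit - TSS|; distance signed
    downstream-positive in gene orientation.

    Ties break toward the smaller absolute summit coordinate.
    """
    if not peaks:
        raise ValueError("peak list is empty")
    if summits is None:
        summits = [_summit(p) for p in peaks]
    candidates = [(abs(s - gene.tss), s, p) for p, s in zip(peaks, summits)
                  if p.chrom == gene.chrom]
    if not candidates:
        raise ValueError(f"no peaks on chromosome {gene.chrom}")
    dist, summit, peak = min(candidates, key=lambda t: (t[0], t[1]))
    return peak, gene.signed_distance_to_tss(summit)


def assign_peaks_to_genes(peaks: list[GenomicInterval], genes: list[GeneModel],
                          tss_window: int = 5000, mode: str = "intron",
                          summits: list[int] | None = None
                          ) -> list[PeakGeneAssignment]:
    """Assign peaks to genes by the TSS-window-or-body rule.

    A peak is assigned to a gene when its summit lies within ``tss_window``
    bp of the TSS (inclusive; relation ``tss_window``) or inside an intron
    (``mode='intron'``) or anywhere in the gene span (``mode='gene_body'``).
    A peak may be assigned to several genes; every qualifying assignment is
    emitted, with TSS assignments taking precedence for the relation label.
    """
    if mode not in ("intron", "gene_body"):
        raise ValueError("mode must be 'intron' or 'gene_body'")
    if summits is None:
        summits = [_summit(p) for p in peaks]
    genes_by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for peak, summit in zip(peaks, summits):
        for g in genes_by_chrom.get(peak.chrom, []):
            d = g.signed_distance_to_tss(summit)
            if abs(summit - g.tss) <= tss_window:
                out.append(PeakGeneAssignment(peak, g.gene_id, "tss_window", d))
                continue
            if mode == "gene_body":
                if g.gene_start <= summit < g.gene_end:
                    out.append(PeakGeneAssignment(peak, g.gene_id, "gene_body", d))
            else:
                if any(s <= summit < e for s, e in g.introns):
                    out.append(PeakGeneAssignment(peak, g.gene_id, "intron", d))
    return out
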