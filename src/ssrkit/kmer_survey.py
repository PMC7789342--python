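"""Read filtering, k-mer spectrum survey and assembly summary statistics.

The survey estimates genome size as (total k-mer occurrences) / (peak
depth), where the peak is the modal depth of the spectrum after excluding
the low-depth sequencing-error region.  Heterozygosity and repeat content
are window heuristics on the same spectrum: the half-peak subpeak carries
heterozygous k-mers, depths well above the peak carry repeats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

from .seqio import FastqRecord, phred_to_scores

# Illumina TruSeq universal adapter stem
DEFAULT_ADAPTER = "AGATCGGAAGAGC"


@dataclass
class ReadFilterParams:
    """Clean-read criteria.

    A read fails if it has >= ``max_n_fraction`` ambiguous bases, more than
    ``max_adapter_overlap`` bases aligned to the adapter at <=
    ``max_mismatch_fraction`` mismatches, or more than ``max_lowq_fraction``
    of its bases below ``phred_threshold``.  A pair is dropped when either
    mate fails; exact duplicate pairs are removed when ``dedupe`` is set.
    """

    max_n_fraction: float = 0.10
    max_adapter_overlap: int = 10
    max_mismatch_fraction: float = 0.10
    max_lowq_fraction: float = 0.50
    phred_threshold: int = 5
    dedupe: bool = True
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self):
        for f in (self.max_n_fraction, self.max_mismatch_fraction, self.max_lowq_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("filter fractions must be within [0, 1]")


def _n_fraction(seq: str) -> float:
    return seq.count("N") / len(seq) if seq else 0.0


def _adapter_contaminated(seq: str, params: ReadFilterParams) -> bool:
    """Ungapped scan for the adapter starting anywhere in the read and
    running to the read's 3' end (or the adapter's end)."""
    ad = params.adapter
    n, a = len(seq), len(ad)
    for start in range(n):
        overlap = min(a, n - start)
        if overlap <= params.max_adapter_overlap:
            break  # overlaps only shrink from here
        mm = sum(1 for i in range(overlap) if seq[start + i] != ad[i])
        if mm <= params.max_mismatch_fraction * overlap:
            return True
    return False


def _lowq_fraction(qual: str, threshold: int) -> float:
    scores = phred_to_scores(qual)
    return sum(s < threshold for s in scores) / len(scores) if scores else 0.0


def _read_fails(seq: str, qual: str, params: ReadFilterParams) -> str | None:
    if _n_fraction(seq) >= params.max_n_fraction:
        return "n_excess"
    if _adapter_contaminated(seq, params):
        return "adapter"
    if _lowq_fraction(qual, params.phred_threshold) > params.max_lowq_fraction:
        return "low_quality"
    return None


def filter_reads(
    pairs: Sequence[tuple[FastqRecord, FastqRecord]],
    params: ReadFilterParams | None = None,
) -> tuple[list[tuple[FastqRecord, FastqRecord]], dict[str, int]]:
    """Apply the clean-read criteria to mate pairs.

    Returns the kept pairs and per-rule rejection counts; a rejected pair is
    counted once, under the first rule violated by either mate (rule order:
    N excess, adapter, low quality, duplicate).
    """
    params = params or ReadFilterParams()
    counts = {"n_excess": 0, "adapter": 0, "low_quality": 0, "duplicate": 0, "kept": 0}
    seen: set[tuple[str, str]] = set()
    kept: list[tuple[FastqRecord, FastqRecord]] = []
    for r1, r2 in pairs:
        rule = _read_fails(r1[1], r1[2], params) or _read_fails(r2[1], r2[2], params)
        if rule:
            counts[rule] += 1
            continue
        if params.dedupe:
            key = (r1[1], r2[1])
            if key in seen:
                counts["duplicate"] += 1
                continue
            seen.add(key)
        kept.append((r1, r2))
        counts["kept"] += 1
    return kept, counts


# ---------------------------------------------------------------------------
# k-mer spectrum


@dataclass
class KmerHistogram:
    """k-mer depth spectrum: ``counts[d]`` distinct canonical k-mers seen d times."""

    k: int
    counts: dict[int, int]

    @property
    def kmer_num(self) -> int:
        """Total k-mer occurrences, sum(depth * count)."""
        return int(sum(d * c for d, c in self.counts.items()))

    def dense(self) -> np.ndarray:
        """Counts as a dense array indexed by depth (index 0 unused)."""
        dmax = max(self.counts) if self.counts else 0
        arr = np.zeros(dmax + 2, dtype=np.int64)
        for d, c in self.counts.items():
            arr[d] = c
        return arr

    def to_frame(self) -> pd.DataFrame:
        depths = sorted(self.counts)
        return pd.DataFrame({"depth": depths, "count": [self.counts[d] for d in depths]})


_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _canonical_kmer_codes(seq: str, k: int) -> np.ndarray:
    a = _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
    if len(a) < k:
        return np.empty(0, dtype=np.int64)
    wins = sliding_window_view(a, k)
    valid = sliding_window_view(a >= 0, k).all(axis=1)
    wins = wins[valid]
    if not len(wins):
        return np.empty(0, dtype=np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = wins @ powers
    rev = (3 - wins)[:, ::-1] @ powers
    return np.minimum(fwd, rev)


def kmer_histogram(reads: Iterable[str | FastqRecord], k: int) -> KmerHistogram:
    """Count canonical (strand-collapsed) k-mers across reads.

    k-mers containing ambiguous bases are skipped.  Raises if no read is at
    least k bases long or k is out of the supported 1..31 range.
    """
    if not 1 <= k <= 31:
        raise ValueError("k must be within 1..31")
    chunks: list[np.ndarray] = []
    longest = 0
    for read in reads:
        seq = read if isinstance(read, str) else read[1]
        longest = max(longest, len(seq))
        codes = _canonical_kmer_codes(seq, k)
        if len(codes):
            chunks.append(codes)
    if longest < k:
        raise ValueError(f"k={k} exceeds the longest read length {longest}")
    if not chunks:
        return KmerHistogram(k=k, counts={})
    _, occ = np.unique(np.concatenate(chunks), return_counts=True)
    depths, ncounts = np.unique(occ, return_counts=True)
    return KmerHistogram(k=k, counts={int(d): int(c) for d, c in zip(depths, ncounts)})


def find_peak(hist: KmerHistogram) -> tuple[int, int]:
    """Locate (error_boundary, peak_depth).

    The error boundary is the first depth d (from 1) where the spectrum stops
    decreasing; the peak is the depth of maximal count beyond it.  A
    monotonically decreasing spectrum has no coverage peak.
    """
    arr = hist.dense()
    dmax = len(arr) - 2
    boundary = None
    for d in range(1, dmax):
        if arr[d] <= arr[d + 1]:
            boundary = d
            break
    if boundary is None or boundary >= dmax:
        raise ValueError("no coverage peak: k-mer spectrum is monotonically decreasing")
    peak = boundary + 1 + int(np.argmax(arr[boundary + 1 : dmax + 1]))
    return boundary, peak


def estimate_genome_size(hist: KmerHistogram) -> float:
    """Genome size = total k-mer occurrences / peak depth."""
    _, peak = find_peak(hist)
    return hist.kmer_num / peak


@dataclass
class HetRepeatWindows:
    het_lo: float = 0.4
    het_hi: float = 0.6
    repeat_lo: float = 1.8


def estimate_het_repeat(
    hist: KmerHistogram, windows: HetRepeatWindows | None = None
) -> tuple[float, float]:
    """Heuristic (het_rate, repeat_fraction) from the spectrum shape.

    het_rate: share of non-error distinct k-mers in the half-peak window
    [het_lo, het_hi] x peak, converted to a per-base rate by dividing by 2k
    (each heterozygous site contributes ~2k half-depth k-mers).
    repeat_fraction: share of non-error distinct k-mers at depths above
    repeat_lo x peak.
    """
    w = windows or HetRepeatWindows()
    boundary, peak = find_peak(hist)
    total = het_mass = rep_mass = 0
    for d, c in hist.counts.items():
        if d <= boundary:
            continue
        total += c
        if w.het_lo * peak <= d <= w.het_hi * peak:
            het_mass += c
        if d > w.repeat_lo * peak:
            rep_mass += c
    if total == 0:
        return 0.0, 0.0
    het_rate = (het_mass / total) / (2 * hist.k)
    return het_rate, rep_mass / total


# ---------------------------------------------------------------------------
# assembly statistics


@dataclass
class AssemblyStats:
    n50: int
    n90: int
    total_size: int
    total_number: int
    counts_at_thresholds: dict[int, int]
    base_counts: dict[str, int] = field(default_factory=dict)
    gc_content: float = 0.0  # percent of ACGT


def _nx(lengths: np.ndarray, frac: float) -> int:
    order = np.sort(lengths)[::-1]
    target = frac * order.sum()
    csum = np.cumsum(order)
    return int(order[np.searchsorted(csum, target)])


def assembly_stats(
    sequences: Mapping[str, str] | Sequence[str],
    thresholds: Sequence[int] = (500, 1000, 10000),
) -> AssemblyStats:
    """N50/N90, size-threshold counts, base composition and GC% over ACGT."""
    seqs = list(sequences.values()) if isinstance(sequences, Mapping) else list(sequences)
    if not seqs:
        raise ValueError("assembly has no sequences")
    lengths = np.array([len(s) for s in seqs], dtype=np.int64)
    base_counts = {b: 0 for b in "ATCGN"}
    for s in seqs:
        up = s.upper()
        for b in "ATCGN":
            base_counts[b] += up.count(b)
    acgt = sum(base_counts[b] for b in "ACGT")
    gc = 100.0 * (base_counts["G"] + base_counts["C"]) / acgt if acgt else 0.0
    return AssemblyStats(
        n50=_nx(lengths, 0.5),
        n90=_nx(lengths, 0.9),
        total_size=int(lengths.sum()),
        total_number=len(seqs),
        counts_at_thresholds={t: int((lengths >= t).sum()) for t in thresholds},
        base_counts=base_counts,
        gc_content=gc,
    )


def library_depth(clean_length: float, genome_size: float) -> float:
    """Per-library sequencing depth = clean yield / genome size, 2 decimals."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if clean_length < 0:
        raise ValueError("clean length must be non-negative")
    return round(clean_length / genome_size, 2)
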