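"""Primer candidate design around SSRs and in-silico PCR classification.

Design enumerates flanking windows and filters them by size, GC, melting
temperature (nearest-neighbor thermodynamics at 50 mM monovalent salt and
50 nM oligo) and a homopolymer cap; in-silico PCR scans the assembly for
convergent binding sites with a 3'-terminal exact-match anchor and calls a
marker single-locus when exactly one site amplifies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio.SeqUtils import MeltingTemp
from numpy.lib.stride_tricks import sliding_window_view

from .ssr_mining import SSRLocus, revcomp


@dataclass
class PrimerConstraints:
    min_size: int = 18
    max_size: int = 27
    min_tm: float = 55.0
    max_tm: float = 65.0
    min_gc: float = 30.0
    max_gc: float = 70.0
    min_product: int = 100
    max_product: int = 300
    max_homopolymer: int = 4

    def __post_init__(self):
        for lo, hi, what in (
            (self.min_size, self.max_size, "size"),
            (self.min_tm, self.max_tm, "tm"),
            (self.min_gc, self.max_gc, "gc"),
            (self.min_product, self.max_product, "product"),
        ):
            if lo > hi:
                raise ValueError(f"{what} range is inverted ({lo} > {hi})")


def melting_temp(seq: str, monovalent_mm: float = 50.0, oligo_nm: float = 50.0) -> float:
    """Nearest-neighbor Tm (degrees C) at the documented salt/oligo defaults."""
    return float(MeltingTemp.Tm_NN(seq, Na=monovalent_mm, dnac1=oligo_nm, dnac2=0))


def gc_percent(seq: str) -> float:
    return 100.0 * sum(1 for c in seq.upper() if c in "GC") / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def primer_ok(seq: str, constraints: PrimerConstraints) -> bool:
    """Single-primer admissibility under the size/GC/Tm/homopolymer rules."""
    if not constraints.min_size <= len(seq) <= constraints.max_size:
        return False
    if any(c not in "ACGT" for c in seq.upper()):
        return False
    if not constraints.min_gc <= gc_percent(seq) <= constraints.max_gc:
        return False
    if max_homopolymer(seq) > constraints.max_homopolymer:
        return False
    return constraints.min_tm <= melting_temp(seq) <= constraints.max_tm


@dataclass
class PrimerPair:
    forward: str
    reverse: str  # 5'->3' on the opposite strand
    tm_forward: float
    tm_reverse: float
    gc_forward: float
    gc_reverse: float
    product_length: int
    forward_start: int  # 1-based position of the forward primer 5' end
    ssr_id: str = ""


def _windows(seq: str, region: tuple[int, int], constraints: PrimerConstraints):
    """All (start0, window) candidates fully inside region [a, b)."""
    a, b = region
    for size in range(constraints.min_size, constraints.max_size + 1):
        for start in range(a, b - size + 1):
            yield start, seq[start : start + size]


def design_primers(
    scaffold_seq: str,
    ssr: SSRLocus,
    constraints: PrimerConstraints | None = None,
    n_candidates: int = 3,
    max_side_candidates: int = 40,
) -> list[PrimerPair]:
    """Enumerate admissible primer pairs flanking one SSR.

    Pairs are ranked by |Tm_f - Tm_r|, then closeness of the product length
    to the middle of the product range, then leftmost forward position.
    Returns at most ``n_candidates`` pairs (empty when nothing satisfies the
    constraints).
    """
    c = constraints or PrimerConstraints()
    seq = scaffold_seq.upper()
    s0, e0 = ssr.start - 1, ssr.end  # 0-based half-open SSR interval
    reach = c.max_product - (e0 - s0)
    left = (max(0, s0 - reach), s0)
    right = (e0, min(len(seq), e0 + reach))
    fwd_cands = [
        (st, w, melting_temp(w)) for st, w in _windows(seq, left, c) if primer_ok(w, c)
    ]
    rev_cands = [
        (st, revcomp(w), melting_temp(revcomp(w)))
        for st, w in _windows(seq, right, c)
        if primer_ok(revcomp(w), c)
    ]
    mid_tm = (c.min_tm + c.max_tm) / 2
    fwd_cands.sort(key=lambda t: (abs(t[2] - mid_tm), t[0]))
    rev_cands.sort(key=lambda t: (abs(t[2] - mid_tm), t[0]))
    fwd_cands = fwd_cands[:max_side_candidates]
    rev_cands = rev_cands[:max_side_candidates]
    mid_prod = (c.min_product + c.max_product) / 2
    scored = []
    for (fs, fw, ftm), (rs, rv, rtm) in itertools.product(fwd_cands, rev_cands):
        product = (rs + len(rv)) - fs
        if not c.min_product <= product <= c.max_product:
            continue
        scored.append(
            (
                abs(ftm - rtm),
                abs(product - mid_prod),
                fs,
                PrimerPair(
                    forward=fw,
                    reverse=rv,
                    tm_forward=ftm,
                    tm_reverse=rtm,
                    gc_forward=gc_percent(fw),
                    gc_reverse=gc_percent(rv),
                    product_length=product,
                    forward_start=fs + 1,
                    ssr_id=f"{ssr.scaffold}:{ssr.start}-{ssr.end}",
                ),
            )
        )
    scored.sort(key=lambda t: t[:3])
    return [p for *_, p in scored[:n_candidates]]


@dataclass
class AmpliconHit:
    scaffold: str
    forward_position: int  # 1-based 5' end of the plus-strand-binding primer
    reverse_position: int  # 1-based 5' end of the minus-strand-binding primer
    product_length: int
    mismatches_forward: int
    mismatches_reverse: int
    strand: str = "+"  # orientation of the forward primer


_SITE_CODE = np.full(256, -9, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _SITE_CODE[ord(_b)] = _i


def _find_sites(
    template: np.ndarray, primer: str, max_mismatches: int, anchor_at_end: bool, anchor: int = 3
) -> tuple[np.ndarray, np.ndarray]:
    """Start positions (0-based) and mismatch counts of primer matches.

    ``anchor_at_end`` selects which side of the plus-strand pattern carries
    the primer's 3' terminus, which must match exactly; degenerate template
    bases never match.
    """
    p = _SITE_CODE[np.frombuffer(primer.upper().encode(), dtype=np.uint8)]
    m = len(p)
    if len(template) < m:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    wins = sliding_window_view(template, m)
    mm = (wins != p).sum(axis=1)
    anchor_sl = slice(m - anchor, m) if anchor_at_end else slice(0, anchor)
    exact = (wins[:, anchor_sl] == p[anchor_sl]).all(axis=1)
    hit = (mm <= max_mismatches) & exact
    return np.flatnonzero(hit), mm[hit]


def in_silico_pcr(
    pair: PrimerPair,
    assembly: Mapping[str, str],
    max_mismatches: int = 0,
    product_cap: int = 1000,
) -> list[AmpliconHit]:
    """Exhaustive electronic PCR of one primer pair against an assembly.

    Reports every site where the two primers bind opposite strands with
    converging 3' ends, each with at most ``max_mismatches`` mismatches and
    an exactly matching 3'-terminal 3 bases, and an amplicon no longer than
    ``product_cap``.
    """
    hits: list[AmpliconHit] = []
    fwd = pair.forward.upper()
    rev = pair.reverse.upper()
    for name, seq in assembly.items():
        template = _SITE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]
        # orientation +: forward on plus strand, reverse complement downstream
        f_pos, f_mm = _find_sites(template, fwd, max_mismatches, anchor_at_end=True)
        r_pos, r_mm = _find_sites(template, revcomp(rev), max_mismatches, anchor_at_end=False)
        for (i, mf), (j, mr) in itertools.product(zip(f_pos, f_mm), zip(r_pos, r_mm)):
            product = (j + len(rev)) - i
            if i <= j and max(len(fwd), len(rev)) <= product <= product_cap:
                hits.append(
                    AmpliconHit(name, int(i) + 1, int(j + len(rev)), int(product), int(mf), int(mr), "+")
                )
        # orientation -: reverse primer binds plus strand, forward downstream
        if fwd != rev:
            r2_pos, r2_mm = _find_sites(template, rev, max_mismatches, anchor_at_end=True)
            f2_pos, f2_mm = _find_sites(template, revcomp(fwd), max_mismatches, anchor_at_end=False)
            for (i, mr), (j, mf) in itertools.product(zip(r2_pos, r2_mm), zip(f2_pos, f2_mm)):
                product = (j + len(fwd)) - i
                if i <= j and max(len(fwd), len(rev)) <= product <= product_cap:
                    hits.append(
                        AmpliconHit(name, int(j + len(fwd)), int(i) + 1, int(product), int(mf), int(mr), "-")
                    )
    return hits


@dataclass
class LocusClass:
    verdict: str  # "single" | "multi" | "none" | "discarded"
    site_count: int = 0
    band_count: int | None = None
    polymorphic: bool | None = None


def classify_in_silico(hits: Sequence[AmpliconHit]) -> LocusClass:
    """1 amplification site -> single; >=2 -> multi; 0 -> none."""
    n = len(hits)
    verdict = "single" if n == 1 else ("multi" if n > 1 else "none")
    return LocusClass(verdict=verdict, site_count=n)


def classify_by_bands(band_counts: Sequence[int], polymorphic: bool) -> LocusClass:
    """Gel rule: <=2 bands and polymorphic -> single-locus marker; more than
    2 bands and polymorphic -> multi-locus; monomorphic -> discarded."""
    if any(b < 0 for b in band_counts):
        raise ValueError("band counts must be non-negative")
    mx = max(band_counts) if band_counts else 0
    if not polymorphic:
        return LocusClass(verdict="discarded", band_count=mx, polymorphic=False)
    verdict = "single" if mx <= 2 else "multi"
    return LocusClass(verdict=verdict, band_count=mx, polymorphic=True)
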