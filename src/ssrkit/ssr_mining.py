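"""Perfect-microsatellite detection, motif canonicalization and summaries.

Detection reports maximal perfect runs of a primitive 1-6 nt motif whose
full-unit repeat count meets a per-motif-length threshold (defaults: 8 for
mononucleotides, 5 for everything else).  Coordinates are 1-based inclusive
and runs never span an ambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: full-unit repeat-count minimum per motif length
DEFAULT_THRESHOLDS: dict[int, int] = {1: 8, 2: 5, 3: 5, 4: 5, 5: 5, 6: 5}

REPEAT_BINS = [str(r) for r in range(5, 21)] + [">20"]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter motif."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def canonical_motif(motif: str) -> str:
    """Canonical strand/rotation class label for a repeat motif.

    The class representative is the lexicographically smallest string among
    all cyclic rotations of the motif and of its reverse complement; the
    label pairs it with its own reverse complement, e.g. ``GA -> "AG/CT"``.

    Parameters
    ----------
    motif : str
        Primitive motif over ACGT, length 1-6.

    Raises
    ------
    ValueError
        If the motif contains non-ACGT characters, has length outside 1-6,
        or is itself a repetition of a shorter motif.
    """
    motif = motif.upper()
    if not motif or len(motif) > 6 or any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif must be 1-6 nt over ACGT, got {motif!r}")
    if not is_primitive(motif):
        raise ValueError(f"motif {motif!r} is not primitive")
    rc = revcomp(motif)
    rotations = {motif[i:] + motif[:i] for i in range(len(motif))}
    rotations |= {rc[i:] + rc[:i] for i in range(len(rc))}
    # self-complementary classes are labelled by a palindromic rotation
    # (e.g. CATG -> "CATG/CATG"), everything else by the smallest rotation
    selfcomp = {r for r in rotations if r == revcomp(r)}
    rep = min(selfcomp) if selfcomp else min(rotations)
    return f"{rep}/{revcomp(rep)}"


@dataclass(frozen=True)
class SSRLocus:
    """One detected perfect repeat (1-based inclusive coordinates)."""

    scaffold: str
    start: int
    end: int
    motif: str
    canonical_class: str
    repeats: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __post_init__(self):
        if self.length != self.repeats * len(self.motif):
            raise ValueError("locus length must equal repeats * motif length")


_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _encode(seq: str) -> np.ndarray:
    """ACGT -> 0..3; every ambiguous base gets a distinct negative code so
    that no two ambiguous positions ever compare equal."""
    arr = _CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)].copy()
    bad = arr < 0
    if bad.any():
        arr[bad] = -np.arange(1, int(bad.sum()) + 1)
    return arr


def detect_ssrs(
    sequence: str,
    thresholds: Mapping[int, int] | None = None,
    scaffold: str = "seq",
) -> list[SSRLocus]:
    """Find all maximal perfect SSR runs in one sequence.

    A run is reported once, under its primitive motif and leftmost phase;
    trailing partial motif units are trimmed so that the reported length is
    always a whole number of units.
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    arr = _encode(sequence)
    n = len(arr)
    loci: list[SSRLocus] = []
    for m, min_rep in sorted(thr.items()):
        if min_rep < 2:
            raise ValueError("repeat thresholds must be >= 2")
        if n < m * min_rep:
            continue
        eq = arr[: n - m] == arr[m:]
        # maximal stretches of consecutive True in eq: a stretch of length t
        # starting at i is a periodic region [i, i + t + m) with period m
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)  # exclusive in eq coordinates
        for s, e in zip(starts, ends):
            region_len = (e - s) + m
            repeats = region_len // m
            if repeats < min_rep:
                continue
            motif = sequence[s : s + m].upper()
            if not is_primitive(motif):
                continue  # the run belongs to a shorter motif length
            loci.append(
                SSRLocus(
                    scaffold=scaffold,
                    start=int(s) + 1,
                    end=int(s) + int(repeats) * m,
                    motif=motif,
                    canonical_class=canonical_motif(motif),
                    repeats=int(repeats),
                )
            )
    loci.sort(key=lambda L: (L.start, len(L.motif)))
    return loci


def detect_in_assembly(
    assembly: Mapping[str, str], thresholds: Mapping[int, int] | None = None
) -> list[SSRLocus]:
    out: list[SSRLocus] = []
    for name, seq in assembly.items():
        out.extend(detect_ssrs(seq, thresholds, scaffold=name))
    return out


def loci_to_frame(loci: Iterable[SSRLocus]) -> pd.DataFrame:
    rows = [
        (L.scaffold, L.start, L.end, L.motif, L.canonical_class, L.repeats, L.length)
        for L in loci
    ]
    return pd.DataFrame(
        rows,
        columns=["scaffold", "start", "end", "motif", "canonical_class", "repeats", "length"],
    )


_LENGTH_CLASS = {
    1: "Mono-nucleotide",
    2: "Di-nucleotide",
    3: "Tri-nucleotide",
    4: "Tetra-nucleotide",
    5: "Penta-nucleotide",
    6: "Hexa-nucleotide",
}


def class_count_table(counts_by_length: Mapping[int, int]) -> pd.DataFrame:
    """Motif-length-class counts -> Number / Ratio / Accumulate Ratio table.

    Ratios are percentages of the total over all classes, rounded to 2
    decimals; the accumulate column is the running sum of the rounded ratios.
    """
    total = sum(counts_by_length.values())
    rows = []
    acc = 0.0
    for m in range(1, 7):
        n = int(counts_by_length.get(m, 0))
        ratio = round(100.0 * n / total, 2) if total else 0.0
        acc = round(acc + ratio, 2)
        rows.append((_LENGTH_CLASS[m], n, ratio, acc))
    df = pd.DataFrame(rows, columns=["Motif", "Number", "Ratio", "Accumulate Ratio"])
    df.attrs["total"] = total
    return df


@dataclass
class MotifSummary:
    counts_by_length: dict[int, int]
    total: int
    class_table: pd.DataFrame
    repeat_matrix: pd.DataFrame  # canonical class x repeat-number bin
    scaffolds_with_ssr: int
    n_scaffolds: int
    single_candidate_scaffolds: int | None = None
    top_class_by_length: dict[int, tuple[str, float]] = field(default_factory=dict)


def _repeat_bin(r: int) -> str:
    return str(r) if r <= 20 else ">20"


def summarize_ssrs(loci: Sequence[SSRLocus], n_scaffolds: int) -> MotifSummary:
    """Aggregate detected loci into the motif-class summary."""
    counts_by_length: dict[int, int] = {m: 0 for m in range(1, 7)}
    cells: dict[tuple[str, str], int] = {}
    scaffolds = set()
    by_len_class: dict[int, dict[str, int]] = {m: {} for m in range(1, 7)}
    for L in loci:
        m = len(L.motif)
        counts_by_length[m] += 1
        key = (L.canonical_class, _repeat_bin(L.repeats))
        cells[key] = cells.get(key, 0) + 1
        scaffolds.add(L.scaffold)
        d = by_len_class[m]
        d[L.canonical_class] = d.get(L.canonical_class, 0) + 1
    classes = sorted({c for c, _ in cells})
    mat = pd.DataFrame(0, index=classes, columns=REPEAT_BINS, dtype=int)
    for (c, b), v in cells.items():
        mat.loc[c, b] = v
    top = {}
    for m, d in by_len_class.items():
        if d:
            best = max(d, key=lambda c: (d[c], c))
            top[m] = (best, round(100.0 * d[best] / counts_by_length[m], 2))
    return MotifSummary(
        counts_by_length=counts_by_length,
        total=len(loci),
        class_table=class_count_table(counts_by_length),
        repeat_matrix=mat,
        scaffolds_with_ssr=len(scaffolds),
        n_scaffolds=n_scaffolds,
        top_class_by_length=top,
    )


def _count_occurrences(haystack: str, needle: str) -> int:
    """Overlapping occurrence count."""
    count = start = 0
    while True:
        i = haystack.find(needle, start)
        if i < 0:
            return count
        count += 1
        start = i + 1


def single_ssr_scaffolds(
    loci: Sequence[SSRLocus],
    assembly: Mapping[str, str],
    flank: int = 100,
    both_strands: bool = True,
) -> list[str]:
    """Scaffolds carrying exactly one SSR whose flanks are assembly-unique.

    A candidate scaffold contains a single detected SSR and both of its
    flanking windows (``flank`` bases each side, truncated at scaffold ends)
    occur at exactly one position in the whole assembly by exact matching.
    """
    per_scaffold: dict[str, list[SSRLocus]] = {}
    for L in loci:
        per_scaffold.setdefault(L.scaffold, []).append(L)
    candidates = []
    for name, ssrs in per_scaffold.items():
        if len(ssrs) != 1:
            continue
        L = ssrs[0]
        seq = assembly[name].upper()
        left = seq[max(0, L.start - 1 - flank) : L.start - 1]
        right = seq[L.end : L.end + flank]
        if not left or not right:
            continue
        unique = True
        for probe in (left, right):
            hits = sum(_count_occurrences(s.upper(), probe) for s in assembly.values())
            if both_strands:
                rc = revcomp(probe)
                hits += sum(_count_occurrences(s.upper(), rc) for s in assembly.values())
            if hits != 1:
                unique = False
                break
        if unique:
            candidates.append(name)
    return sorted(candidates)
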