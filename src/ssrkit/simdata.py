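"""Synthetic inputs with known ground truth for every pipeline stage.

Genomes carry planted perfect SSRs on a rejection-sampled background (no
accidental threshold-passing repeat, and planting never extends into the
flanks), so truth tables are exact.  Populations follow a Balding-Nichols
island model parameterized directly by the target Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import ssr_mining
from .seqio import FastqRecord

MISSING = "."


@dataclass
class SyntheticGenomeSpec:
    n_scaffolds: int
    scaffold_length: int
    gc_fraction: float = 0.45
    planted_ssrs: list[tuple[str, int, int, int]] = field(default_factory=list)
    #: (motif, repeat_count, scaffold_index, 1-based start position)
    duplication_fraction: float = 0.0
    seed: int = 0
    thresholds: dict[int, int] | None = None

    def __post_init__(self):
        if self.n_scaffolds < 1 or self.scaffold_length < 1:
            raise ValueError("n_scaffolds and scaffold_length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.duplication_fraction <= 1.0:
            raise ValueError("duplication_fraction must be in [0, 1]")
        intervals: dict[int, list[tuple[int, int]]] = {}
        for motif, reps, scaf, pos in self.planted_ssrs:
            if not 1 <= len(motif) <= 6:
                raise ValueError(f"motif length must be 1-6, got {motif!r}")
            if not ssr_mining.is_primitive(motif.upper()):
                raise ValueError(f"planted motif {motif!r} is not primitive")
            if not 0 <= scaf < self.n_scaffolds:
                raise ValueError(f"scaffold index {scaf} out of range")
            end = pos + reps * len(motif) - 1
            if pos < 1 or end > self.scaffold_length:
                raise ValueError(
                    f"planted SSR ({motif} x{reps} at {pos}) does not fit in a "
                    f"{self.scaffold_length} bp scaffold"
                )
            for a, b in intervals.get(scaf, []):
                if pos <= b and end >= a:
                    raise ValueError("planted SSR intervals overlap")
            intervals.setdefault(scaf, []).append((pos, end))


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=probs)


def _scrub(
    arr: np.ndarray,
    rng: np.random.Generator,
    gc: float,
    thresholds: Mapping[int, int] | None,
    frozen: list[tuple[int, int]],
    truth: list[tuple[int, int, str, int]] | None = None,
    max_iter: int = 200,
) -> None:
    """Resample background bases until detection matches the truth exactly.

    ``frozen`` are 0-based half-open planted intervals that must never be
    touched; everything else may be redrawn.  ``truth`` lists the expected
    (start0, end0, motif, repeats) records.
    """
    expected = {(s, e, m, r) for s, e, m, r in (truth or [])}
    for _ in range(max_iter):
        seq = arr.tobytes().decode()
        found = ssr_mining.detect_ssrs(seq, thresholds)
        got = {(L.start - 1, L.end, L.motif, L.repeats) for L in found}
        if got == expected:
            return
        dirty = [rec for rec in got if rec not in expected]
        for s, e, _m, _r in dirty:
            # redraw the run plus one flank base on each side, sparing planted bases
            for i in range(max(0, s - 1), min(len(arr), e + 1)):
                if any(a <= i < b for a, b in frozen):
                    continue
                arr[i] = _random_bases(rng, 1, gc)[0]
    raise RuntimeError("could not scrub accidental repeats from background")


def simulate_genome(
    spec: SyntheticGenomeSpec,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate scaffolds plus an exact truth table of planted SSRs.

    Returns FASTA-ready ``(name, sequence)`` pairs and a table with 1-based
    inclusive coordinates.  Detection on the output recovers exactly the
    truth records (scrubbed background, non-extendable planted runs).
    """
    rng = np.random.default_rng(spec.seed)
    planted_by_scaffold: dict[int, list[tuple[str, int, int]]] = {}
    for motif, reps, scaf, pos in spec.planted_ssrs:
        planted_by_scaffold.setdefault(scaf, []).append((motif.upper(), reps, pos))
    scaffolds: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, int, int, str, int]] = []
    for i in range(spec.n_scaffolds):
        name = f"scaffold_{i + 1}"
        arr = _random_bases(rng, spec.scaffold_length, spec.gc_fraction)
        frozen: list[tuple[int, int]] = []
        truth: list[tuple[int, int, str, int]] = []
        for motif, reps, pos in planted_by_scaffold.get(i, []):
            s0 = pos - 1
            run = (motif * reps).encode()
            arr[s0 : s0 + len(run)] = np.frombuffer(run, dtype="S1")
            frozen.append((s0, s0 + len(run)))
            truth.append((s0, s0 + len(run), motif, reps))
        thr = dict(ssr_mining.DEFAULT_THRESHOLDS)
        if spec.thresholds:
            thr.update(spec.thresholds)
        detectable = [t for t in truth if t[3] >= thr[len(t[2])]]
        _scrub(arr, rng, spec.gc_fraction, spec.thresholds, frozen, detectable)
        scaffolds.append((name, arr.tobytes().decode()))
        for s0, e0, motif, reps in sorted(truth):
            truth_rows.append((name, s0 + 1, e0, motif, reps))
    n_dup = int(round(spec.duplication_fraction * spec.n_scaffolds))
    for j in range(n_dup):
        src_name, src_seq = scaffolds[j]
        dup_name = f"{src_name}_dup"
        scaffolds.append((dup_name, src_seq))
        for row in [r for r in truth_rows if r[0] == src_name]:
            truth_rows.append((dup_name, *row[1:]))
    table = pd.DataFrame(
        truth_rows, columns=["scaffold", "start", "end", "motif", "repeats"]
    )
    return scaffolds, table


@dataclass
class ReadSimSpec:
    read_length: int = 150
    insert_size: int = 270
    depth: float = 50.0
    error_rate: float = 0.0
    n_rate: float = 0.0
    duplicate_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.insert_size < self.read_length:
            raise ValueError("insert_size must be >= read_length")
        for r in (self.error_rate, self.n_rate, self.duplicate_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be within [0, 1]")


_HIGH_Q = chr(37 + 33)  # phred 37
_LOW_Q = chr(2 + 33)  # phred 2, below the <5 filter

_OTHER = {b: [c for c in "ACGT" if c != b] for b in "ACGT"}


def _mutate(seq: str, spec: ReadSimSpec, rng: np.random.Generator) -> tuple[str, str]:
    """Apply the two-state error model: substituted or N bases get low phred."""
    bases = list(seq)
    qual = [_HIGH_Q] * len(bases)
    if spec.n_rate > 0 or spec.error_rate > 0:
        u = rng.random(len(bases))
        for i, b in enumerate(bases):
            if u[i] < spec.n_rate:
                bases[i] = "N"
                qual[i] = _LOW_Q
            elif u[i] < spec.n_rate + spec.error_rate * (1 - spec.n_rate):
                bases[i] = _OTHER.get(b, ["N"])[rng.integers(3)] if b in _OTHER else "N"
                qual[i] = _LOW_Q
    return "".join(bases), "".join(qual)


def simulate_reads(
    genome: Sequence[tuple[str, str]] | Mapping[str, str], spec: ReadSimSpec
) -> list[tuple[FastqRecord, FastqRecord]]:
    """Uniform-coverage paired reads from opposite ends of fixed-size inserts."""
    items = list(genome.items()) if isinstance(genome, Mapping) else list(genome)
    if not items:
        raise ValueError("genome is empty")
    rng = np.random.default_rng(spec.seed)
    lengths = np.array([len(s) for _, s in items], dtype=float)
    usable = np.maximum(lengths - spec.insert_size + 1, 0)
    if usable.sum() == 0:
        raise ValueError("no scaffold is long enough for the insert size")
    total_len = lengths.sum()
    n_pairs = int(round(spec.depth * total_len / (2 * spec.read_length)))
    probs = usable / usable.sum()
    scaffold_idx = rng.choice(len(items), size=n_pairs, p=probs)
    pairs: list[tuple[FastqRecord, FastqRecord]] = []
    for pi in range(n_pairs):
        _, seq = items[scaffold_idx[pi]]
        start = int(rng.integers(0, len(seq) - spec.insert_size + 1))
        frag = seq[start : start + spec.insert_size]
        fwd = frag[: spec.read_length]
        rev = ssr_mining.revcomp(frag)[: spec.read_length]
        s1, q1 = _mutate(fwd, spec, rng)
        s2, q2 = _mutate(rev, spec, rng)
        name = f"pair_{pi + 1}"
        pairs.append(((f"{name}/1", s1, q1), (f"{name}/2", s2, q2)))
    n_dup = int(round(spec.duplicate_fraction * n_pairs))
    if n_dup:
        dup_idx = rng.choice(n_pairs, size=n_dup, replace=False)
        for j, pi in enumerate(sorted(dup_idx)):
            r1, r2 = pairs[pi]
            dn = f"dup_{j + 1}"
            pairs.append(((f"{dn}/1", r1[1], r1[2]), (f"{dn}/2", r2[1], r2[2])))
    return pairs


@dataclass
class PopSimSpec:
    group_sizes: Sequence[int] = (8, 6, 13)
    n_loci: int = 10
    alleles_per_locus: int = 3
    target_fst: float = 0.25
    missing_rate: float = 0.0
    seed: int = 0
    group_names: Sequence[str] | None = None

    def __post_init__(self):
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("every group must have at least 2 members")
        if not 2 <= self.alleles_per_locus <= 5:
            raise ValueError("alleles_per_locus must be within 2..5")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target_fst must be in [0, 1)")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0, 1]")


def simulate_population(
    spec: PopSimSpec,
) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    """Structured diploid genotype panel under a Balding-Nichols island model.

    Per-group allele frequencies are Dirichlet draws around the ancestral
    frequencies with variance parameter phi, Dirichlet concentration
    p * (1 - phi) / phi.  For the genotypic squared distance used by the
    AMOVA, the expected among-group PhiPT of such a panel is
    2*phi / (1 + phi), so phi is set to t / (2 - t) for ``target_fst`` t and
    the AMOVA estimate recovers the target.  Returns the genotype matrix
    (cells "a1/a2" or "."), the group assignment series, and the per-group
    allele frequency array of shape (groups, loci, alleles).
    """
    rng = np.random.default_rng(spec.seed)
    k, a = len(spec.group_sizes), spec.alleles_per_locus
    names = list(spec.group_names or [f"G{i + 1}" for i in range(k)])
    # ancestral frequencies kept away from fixation so all alleles are observable
    anc = rng.dirichlet(np.full(a, 5.0), size=spec.n_loci)
    anc = np.clip(anc, 0.05, None)
    anc /= anc.sum(axis=1, keepdims=True)
    t = spec.target_fst
    phi = t / (2.0 - t)  # inverts E[PhiPT] = 2*phi/(1+phi)
    group_freqs = np.empty((k, spec.n_loci, a))
    for g in range(k):
        for l in range(spec.n_loci):
            if phi == 0.0:
                group_freqs[g, l] = anc[l]
            else:
                group_freqs[g, l] = rng.dirichlet(anc[l] * (1 - phi) / phi)
    accessions, groups, rows = [], [], []
    alleles = [str(i + 1) for i in range(a)]
    for g, (gname, size) in enumerate(zip(names, spec.group_sizes)):
        for ind in range(size):
            acc = f"{gname}_{ind + 1}"
            accessions.append(acc)
            groups.append(gname)
            cells = []
            for l in range(spec.n_loci):
                pair = rng.choice(a, size=2, p=group_freqs[g, l])
                cells.append("/".join(sorted(alleles[x] for x in pair)))
            rows.append(cells)
    matrix = pd.DataFrame(
        rows, index=accessions, columns=[f"locus_{l + 1}" for l in range(spec.n_loci)]
    )
    matrix.index.name = "accession"
    if spec.missing_rate > 0:
        mask = rng.random(matrix.shape) < spec.missing_rate
        matrix = matrix.mask(pd.DataFrame(mask, index=matrix.index, columns=matrix.columns), MISSING)
    return matrix, pd.Series(groups, index=accessions, name="group"), group_freqs


def simulate_bands(
    pop: pd.DataFrame, extra_bands: int = 0, seed: int = 0
) -> pd.DataFrame:
    """Codominant genotypes -> dominant presence/absence band matrix.

    Each (locus, allele) pair becomes one 0/1 column; missing genotypes score
    0 everywhere at that locus.  ``extra_bands`` appends monomorphic all-one
    noise columns, diluting the polymorphism percentage.
    """
    if extra_bands < 0:
        raise ValueError("extra_bands must be non-negative")
    cols: dict[str, list[int]] = {}
    for locus in pop.columns:
        alleles = sorted(
            {a for cell in pop[locus] if cell != MISSING for a in str(cell).split("/")}
        )
        for allele in alleles:
            name = f"{locus}_band{allele}"
            cols[name] = [
                0 if cell == MISSING else int(allele in str(cell).split("/"))
                for cell in pop[locus]
            ]
    for j in range(extra_bands):
        cols[f"noise_band{j + 1}"] = [1] * len(pop)
    bands = pd.DataFrame(cols, index=pop.index)
    bands.index.name = "accession"
    return bands
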