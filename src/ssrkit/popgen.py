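"""Marker evaluation: diversity indices, distances, clustering and AMOVA.

Codominant genotype matrices hold cells "a1/a2" (unordered allele pair) or
"." for missing; dominant matrices are 0/1 band tables.  Conventions:

* expected heterozygosity is the uncorrected gene diversity 1 - sum(p^2)
  (an ``unbiased`` flag applies the 2n/(2n-1) correction);
* PIC uses the codominant formula 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2;
* missing genotypes are excluded per locus (pairwise deletion);
* AMOVA follows the squared-distance partition with components
  sigma2_among = (MS_among - MS_within) / n0, n0 = (N - sum n_i^2/N)/(k-1),
  and PhiPT/Fst = sigma2_among / (sigma2_among + sigma2_within);
* negative variance components are truncated at zero.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

MISSING = "."


# ---------------------------------------------------------------------------
# codominant genotype handling


def _split(cell: str) -> tuple[str, str] | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == MISSING:
        return None
    a, b = str(cell).split("/")
    return (a, b) if a <= b else (b, a)


def allele_frequencies(column: Sequence[str]) -> tuple[dict[str, float], int]:
    """Allele frequency dict and the non-missing sample size for one locus."""
    counts: dict[str, int] = {}
    n = 0
    for cell in column:
        pair = _split(cell)
        if pair is None:
            continue
        n += 1
        for a in pair:
            counts[a] = counts.get(a, 0) + 1
    total = 2 * n
    return ({a: c / total for a, c in counts.items()} if total else {}), n


@dataclass
class LocusStats:
    locus: str
    n: int  # non-missing individuals
    na: int
    ne: float
    shannon: float
    ho: float
    he: float
    pic: float


def _pic_from_freqs(p: np.ndarray) -> float:
    s2, s4 = float(np.sum(p**2)), float(np.sum(p**4))
    he = 1.0 - s2
    return he - (s2**2 - s4)  # sum_{i<j} 2 p_i^2 p_j^2 = (sum p^2)^2 - sum p^4


def locus_stats(matrix: pd.DataFrame, locus: str, unbiased: bool = False) -> LocusStats:
    """Na, Ne, Shannon I, Ho, He and PIC for one locus (pairwise deletion)."""
    freqs, n = allele_frequencies(matrix[locus])
    if n == 0:
        raise ValueError(f"locus {locus!r} has no non-missing genotypes")
    p = np.array(list(freqs.values()))
    het = sum(
        1 for cell in matrix[locus] if (pr := _split(cell)) is not None and pr[0] != pr[1]
    )
    he = 1.0 - float(np.sum(p**2))
    if unbiased and n > 0:
        he *= 2 * n / (2 * n - 1)
    return LocusStats(
        locus=locus,
        n=n,
        na=len(p),
        ne=1.0 / float(np.sum(p**2)),
        shannon=float(-np.sum(p * np.log(p))),
        ho=het / n,
        he=he,
        pic=_pic_from_freqs(p),
    )


def diversity_table(matrix: pd.DataFrame, unbiased: bool = False) -> pd.DataFrame:
    """Per-locus diversity statistics; all-missing loci are flagged and skipped."""
    rows, skipped = [], []
    for locus in matrix.columns:
        try:
            s = locus_stats(matrix, locus, unbiased=unbiased)
        except ValueError:
            skipped.append(locus)
            continue
        rows.append((s.locus, s.n, s.na, s.ne, s.shannon, s.ho, s.he, s.pic))
    df = pd.DataFrame(rows, columns=["locus", "n", "Na", "Ne", "I", "Ho", "He", "PIC"])
    df.attrs["skipped"] = skipped
    return df


def marker_table_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Append Total / Minimum / Maximum / Mean rows to a per-marker table.

    Total is populated for allele counts only; the remaining summary rows are
    column-wise extrema and arithmetic means.
    """
    num = table.select_dtypes("number")
    rows = {
        "Total": {c: (num[c].sum() if c == "Na" else np.nan) for c in num.columns},
        "Minimum": num.min(),
        "Maximum": num.max(),
        "Mean": num.mean(),
    }
    out = table.copy()
    for name, vals in rows.items():
        out.loc[name] = pd.Series(vals)
        if "locus" in out.columns:
            out.loc[name, "locus"] = name
    return out


def group_diversity(
    matrix: pd.DataFrame, groups: pd.Series, unbiased: bool = False
) -> pd.DataFrame:
    """Per-group means of the per-locus indices plus % polymorphic loci.

    The final ``Mean`` row is the unweighted average over groups.
    """
    if not matrix.index.equals(groups.index) and set(matrix.index) != set(groups.index):
        raise ValueError("every accession needs exactly one group assignment")
    rows = []
    for gname in pd.unique(groups):
        sub = matrix.loc[groups[groups == gname].index]
        per_locus = diversity_table(sub, unbiased=unbiased)
        pp = 100.0 * float((per_locus["Na"] >= 2).mean()) if len(per_locus) else 0.0
        rows.append(
            {
                "group": gname,
                "N": len(sub),
                "Na": per_locus["Na"].mean(),
                "Ne": per_locus["Ne"].mean(),
                "I": per_locus["I"].mean(),
                "Ho": per_locus["Ho"].mean(),
                "He": per_locus["He"].mean(),
                "PP": pp,
            }
        )
    df = pd.DataFrame(rows).set_index("group")
    df.loc["Mean"] = df.mean()  # unweighted over groups
    return df


# ---------------------------------------------------------------------------
# dominant (band) statistics


@dataclass
class MultiLocusStats:
    n_bands: int
    polymorphic_bands: int
    polymorphism_pct: float
    pic: float  # mean over bands of 2 f (1 - f)
    bi: float  # mean band informativeness 1 - 2|0.5 - f|
    rp: float  # resolving power, sum over bands of 1 - 2|0.5 - f|
    mi: float  # marker index = pic * polymorphic band count
    band_frequencies: pd.Series = field(repr=False, default=None)


def dominant_stats(bands: pd.DataFrame) -> MultiLocusStats:
    """Band-based indices for a 0/1 dominant matrix."""
    vals = bands.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("dominant matrix must be strictly 0/1")
    f = bands.mean(axis=0)
    poly = int(((f > 0) & (f < 1)).sum())
    ib = 1.0 - 2.0 * (0.5 - f).abs()
    pic = float((2.0 * f * (1.0 - f)).mean())
    return MultiLocusStats(
        n_bands=bands.shape[1],
        polymorphic_bands=poly,
        polymorphism_pct=100.0 * poly / bands.shape[1] if bands.shape[1] else 0.0,
        pic=pic,
        bi=float(ib.mean()),
        rp=float(ib.sum()),
        mi=pic * poly,
        band_frequencies=f,
    )


# ---------------------------------------------------------------------------
# distances


def _codominant_profile(matrix: pd.DataFrame) -> tuple[np.ndarray, list[slice]]:
    """Per-individual allele dosage frequencies (0, .5, 1); NaN where missing.

    Returns an (N, total_alleles) array plus per-locus column slices.
    """
    blocks, slices, col0 = [], [], 0
    for locus in matrix.columns:
        alleles = sorted(
            {a for cell in matrix[locus] if (pr := _split(cell)) for a in pr}
        )
        if not alleles:  # all-missing locus carries no information
            continue
        idx = {a: i for i, a in enumerate(alleles)}
        block = np.full((len(matrix), len(alleles)), np.nan)
        for r, cell in enumerate(matrix[locus]):
            pair = _split(cell)
            if pair is None:
                continue
            block[r] = 0.0
            for a in pair:
                block[r, idx[a]] += 0.5
        blocks.append(block)
        slices.append(slice(col0, col0 + len(alleles)))
        col0 += len(alleles)
    return np.hstack(blocks) if blocks else np.empty((len(matrix), 0)), slices


def nei_distance(data: pd.DataFrame, kind: str | None = None) -> pd.DataFrame:
    """Pairwise genetic distance matrix between accessions.

    Codominant input uses Nei's (1972) standard distance on per-accession
    allele profiles; dominant 0/1 input uses one minus the Dice similarity.
    ``kind`` overrides the automatic detection ("codominant"/"dominant").
    """
    if kind is None:
        kind = "dominant" if data.map(lambda v: v in (0, 1)).all().all() else "codominant"
    n = len(data)
    D = np.zeros((n, n))
    if kind == "codominant":
        prof, slices = _codominant_profile(data)
        for i, j in itertools.combinations(range(n), 2):
            jxy = jx = jy = 0.0
            nloc = 0
            for sl in slices:
                x, y = prof[i, sl], prof[j, sl]
                if np.isnan(x).any() or np.isnan(y).any():
                    continue
                nloc += 1
                jxy += float(x @ y)
                jx += float(x @ x)
                jy += float(y @ y)
            if nloc == 0:
                raise ValueError(f"accessions {i} and {j} share no scored locus")
            ident = (jxy / nloc) / math.sqrt((jx / nloc) * (jy / nloc))
            D[i, j] = D[j, i] = -math.log(max(ident, 1e-12))
    elif kind == "dominant":
        B = data.to_numpy(dtype=float)
        for i, j in itertools.combinations(range(n), 2):
            shared = float((B[i] * B[j]).sum())
            tot = float(B[i].sum() + B[j].sum())
            dice = 2 * shared / tot if tot else 1.0
            D[i, j] = D[j, i] = 1.0 - dice
    else:
        raise ValueError(f"unknown matrix kind {kind!r}")
    return pd.DataFrame(D, index=data.index, columns=data.index)


# ---------------------------------------------------------------------------
# UPGMA and bootstrap


@dataclass
class TreeNode:
    height: float
    name: str | None = None
    children: tuple["TreeNode", ...] = ()
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.name])
        return frozenset().union(*(c.leaves() for c in self.children))

    def clades(self) -> list[frozenset[str]]:
        out = []
        if not self.is_leaf:
            out.append(self.leaves())
            for c in self.children:
                out.extend(c.clades())
        return out

    def newick(self, include_support: bool = False) -> str:
        return self._nwk(None, include_support) + ";"

    def _nwk(self, parent_height: float | None, sup: bool) -> str:
        bl = "" if parent_height is None else f":{parent_height - self.height:g}"
        if self.is_leaf:
            return f"{self.name}{bl}"
        inner = ",".join(c._nwk(self.height, sup) for c in self.children)
        label = f"{self.support:g}" if (sup and self.support is not None) else ""
        return f"({inner}){label}{bl}"


def upgma(dist: pd.DataFrame) -> TreeNode:
    """Average-linkage agglomeration of a symmetric distance matrix.

    Node heights are half the merge distance, so the tree is ultrametric;
    ties break on the smallest cluster indices for determinism.
    """
    labels = list(dist.index)
    D = dist.to_numpy(dtype=float).copy()
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    nodes: dict[int, TreeNode] = {
        i: TreeNode(height=0.0, name=str(lab)) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in nodes}
    active = sorted(nodes)
    Dw = {(i, j): D[i, j] for i, j in itertools.combinations(active, 2)}
    next_id = len(active)
    while len(active) > 1:
        (i, j), dmin = min(Dw.items(), key=lambda kv: (kv[1], kv[0]))
        kids = tuple(sorted((nodes[i], nodes[j]), key=lambda nd: min(nd.leaves())))
        node = TreeNode(height=dmin / 2.0, children=kids)
        ni, nj = sizes[i], sizes[j]
        nodes[next_id] = node
        sizes[next_id] = ni + nj
        active = [a for a in active if a not in (i, j)]
        for a in active:
            da = Dw[(min(a, i), max(a, i))]
            db = Dw[(min(a, j), max(a, j))]
            Dw[(a, next_id)] = (ni * da + nj * db) / (ni + nj)
        Dw = {k: v for k, v in Dw.items() if i not in k and j not in k}
        active.append(next_id)
        next_id += 1
    return nodes[active[0]]


def upgma_with_bootstrap(
    data: pd.DataFrame,
    distance: Callable[[pd.DataFrame], pd.DataFrame] = nei_distance,
    replicates: int = 100,
    seed: int | None = None,
) -> TreeNode:
    """UPGMA tree from the full data with clade support from locus resampling.

    Each replicate resamples data columns (loci/bands) with replacement,
    recomputes the distance and tree, and scores every clade of the main
    tree by the percentage of replicates containing it.
    """
    tree = upgma(distance(data))
    if replicates <= 0:
        return tree
    rng = np.random.default_rng(seed)
    ncols = data.shape[1]
    counts: dict[frozenset[str], int] = {c: 0 for c in tree.clades()}
    for _ in range(replicates):
        cols = rng.integers(0, ncols, size=ncols)
        boot = data.iloc[:, cols]
        boot.columns = [f"c{t}" for t in range(ncols)]
        try:
            bt = upgma(distance(boot))
        except ValueError:  # resample may drop all shared loci for a pair
            continue
        present = set(bt.clades())
        for c in counts:
            if c in present:
                counts[c] += 1

    def annotate(node: TreeNode) -> None:
        if not node.is_leaf:
            node.support = 100.0 * counts[node.leaves()] / replicates
            for ch in node.children:
                annotate(ch)

    annotate(tree)
    return tree


# ---------------------------------------------------------------------------
# PCoA


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(dist: pd.DataFrame) -> PcoaResult:
    """Classical metric scaling (Gower double-centering + eigendecomposition).

    Coordinates are eigenvectors scaled by sqrt(eigenvalue) for the positive
    eigenvalues; negative eigenvalues are reported unchanged.
    """
    D = dist.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > 1e-10
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    pos_sum = eigvals[pos].sum()
    prop = np.where(eigvals > 0, eigvals / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    cols = [f"PCo{i + 1}" for i in range(coords.shape[1])]
    return PcoaResult(
        coordinates=pd.DataFrame(coords, index=dist.index, columns=cols),
        eigenvalues=eigvals,
        proportion_explained=prop,
    )


# ---------------------------------------------------------------------------
# AMOVA


@dataclass
class AmovaResult:
    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    ms_among: float
    ms_within: float
    n0: float
    sigma2_among: float
    sigma2_within: float
    pmv_among: float  # percent
    pmv_within: float  # percent
    fst: float
    nm: float
    p_value: float | None = None


def amova_from_ss(
    group_sizes: Sequence[int], ss_among: float, ss_within: float
) -> AmovaResult:
    """Variance components, PMV, Fst and Nm from sums of squares alone."""
    sizes = [int(s) for s in group_sizes]
    N, k = sum(sizes), len(sizes)
    if k < 2:
        raise ValueError("need at least two groups")
    df_a, df_w = k - 1, N - k
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (N - sum(s * s for s in sizes) / N) / (k - 1)
    s2a = (ms_a - ms_w) / n0
    if s2a < 0:
        warnings.warn("negative among-group variance component truncated to 0")
        s2a = 0.0
    s2w = ms_w
    total = s2a + s2w
    fst = s2a / total if total > 0 else 0.0
    nm = gene_flow(fst) if 0.0 < fst < 1.0 else math.inf
    return AmovaResult(
        df_among=df_a,
        df_within=df_w,
        ss_among=ss_among,
        ss_within=ss_within,
        ms_among=ms_a,
        ms_within=ms_w,
        n0=n0,
        sigma2_among=s2a,
        sigma2_within=s2w,
        pmv_among=100.0 * fst,
        pmv_within=100.0 * (1.0 - fst),
        fst=fst,
        nm=nm,
    )


def squared_distance_matrix(data: pd.DataFrame, kind: str | None = None) -> np.ndarray:
    """Pairwise squared distances used by AMOVA.

    Codominant: half the squared Euclidean distance between allele-count
    vectors (counts 0/1/2 per allele), which matches the standard
    codominant-genotypic distance (identical 0, one allele shared 1,
    AA vs BB 4, ...); loci missing in either member are skipped and the
    remaining sum is rescaled by L / L_shared.  Dominant: squared Euclidean
    distance on band vectors.
    """
    if kind is None:
        kind = "dominant" if data.map(lambda v: v in (0, 1)).all().all() else "codominant"
    n = len(data)
    D2 = np.zeros((n, n))
    if kind == "dominant":
        B = data.to_numpy(dtype=float)
        diff = B[:, None, :] - B[None, :, :]
        D2 = np.einsum("ijk,ijk->ij", diff, diff)
        return D2
    prof, slices = _codominant_profile(data)
    counts = 2.0 * prof  # dosage counts 0/1/2, NaN when missing
    L = len(slices)
    locus_of_col = np.concatenate(
        [np.full(sl.stop - sl.start, li) for li, sl in enumerate(slices)]
    ) if L else np.empty(0, dtype=int)
    valid = ~np.isnan(prof[:, [sl.start for sl in slices]]) if L else np.empty((n, 0))
    for i, j in itertools.combinations(range(n), 2):
        shared = valid[i] & valid[j]
        ns = int(shared.sum())
        if ns == 0:
            raise ValueError(f"accessions {i} and {j} share no scored locus")
        colmask = shared[locus_of_col]
        d = counts[i, colmask] - counts[j, colmask]
        D2[i, j] = D2[j, i] = 0.5 * float(d @ d) * (L / ns)
    return D2


def _ss_partition(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    N = len(labels)
    ss_total = float(np.triu(D2, 1).sum()) / N
    ss_within = 0.0
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += float(np.triu(sub, 1).sum()) / len(idx)
    return ss_total - ss_within, ss_within


def amova(
    data: pd.DataFrame,
    groups: pd.Series,
    permutations: int = 999,
    seed: int | None = None,
    kind: str | None = None,
) -> AmovaResult:
    """Distance-based AMOVA of accessions partitioned into groups.

    The p-value is the proportion of label permutations (plus the observed
    arrangement) reaching an Fst at least as large as observed.
    """
    groups = groups.loc[data.index]
    labels, counts = np.unique(groups.to_numpy(), return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least two members")
    D2 = squared_distance_matrix(data, kind=kind)
    lab = groups.to_numpy()
    ss_a, ss_w = _ss_partition(D2, lab)
    result = amova_from_ss(counts, ss_a, ss_w)
    if permutations > 0:
        rng = np.random.default_rng(seed)
        hits = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # truncation is routine under permutation
            for _ in range(permutations):
                perm = rng.permutation(lab)
                pa, pw = _ss_partition(D2, perm)
                pr = amova_from_ss(counts, pa, pw)
                if pr.fst >= result.fst - 1e-12:
                    hits += 1
        result.p_value = (hits + 1) / (permutations + 1)
    return result


def gene_flow(fst: float) -> float:
    """Island-model gene flow Nm = (1 - Fst) / (4 Fst)."""
    if not 0.0 < fst < 1.0:
        raise ValueError("Fst must be strictly between 0 and 1")
    return (1.0 - fst) / (4.0 * fst)


# ---------------------------------------------------------------------------
# Mann-Whitney


def mann_whitney(sample_a: Sequence[float], sample_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all rank arrangements when both samples have at
    most 10 observations (ties included); otherwise the tie-corrected normal
    approximation.  Returns (U of the first sample, p-value); the exact
    two-sided p is P(min(U_a, U_b) <= observed minimum).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    na, nb = len(a), len(b)
    ranks = sps.rankdata(np.concatenate([a, b]))
    ra = float(ranks[:na].sum())
    u_a = ra - na * (na + 1) / 2.0
    u_b = na * nb - u_a
    if na <= 10 and nb <= 10:
        obs = min(u_a, u_b)
        total = hits = 0
        ranks_arr = np.asarray(ranks)
        base = na * (na + 1) / 2.0
        for idx in itertools.combinations(range(na + nb), na):
            u = float(ranks_arr[list(idx)].sum()) - base
            total += 1
            if min(u, na * nb - u) <= obs + 1e-9:
                hits += 1
        return u_a, hits / total
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_a, float(res.pvalue)
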