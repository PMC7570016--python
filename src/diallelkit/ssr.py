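"""SSR marker diversity, genetic distance and UPGMA clustering.

Inbred lines are treated as homozygous, so each line carries exactly one
allele per locus and allele frequencies are exact multiples of 1/n_lines
(always computed from counts, never from rounded frequencies). Band
scoring follows the presence/absence convention: the binary band matrix
is the one-hot expansion of the allele calls, one column per locus:allele
combination.

Gene diversity (expected heterozygosity) is 1 - sum(p_i^2); marker
informativeness uses Botstein's polymorphic information content,

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2.

Pairwise genetic distance is Jaccard on band vectors (joint absences
ignored); clustering is UPGMA — size-weighted average linkage with merge
height d/2 and a deterministic lexicographic tie-break — producing an
ultrametric dendrogram serializable to Newick.
"""

from __future__ import annotations

import itertools
import json
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MarkerPanel",
    "LocusSummary",
    "DistanceMatrix",
    "Node",
    "gene_diversity",
    "pic",
    "locus_summaries",
    "panel_summary",
    "jaccard_distance_matrix",
    "dice_distance_matrix",
    "upgma",
    "summarize_distances",
    "DistanceSummary",
    "to_newick",
    "depth1_leafsets",
    "is_ultrametric",
    "cophenetic_matrix",
]


# ---------------------------------------------------------------------------
# panel


@dataclass
class MarkerPanel:
    """Allele calls for a set of inbred lines at a set of SSR loci."""

    lines: tuple[str, ...]
    loci: tuple[str, ...]
    alleles: dict[tuple[str, str], str]  # (line, locus) -> allele id

    def __post_init__(self):
        for line in self.lines:
            for locus in self.loci:
                if (line, locus) not in self.alleles:
                    raise ValueError(f"missing allele call for line {line!r} at {locus!r}")
        extra = set(self.alleles) - {(l, m) for l in self.lines for m in self.loci}
        if extra:
            raise ValueError(f"allele calls outside the panel: {sorted(extra)[:5]}")

    def allele_counts(self, locus: str) -> Counter:
        return Counter(self.alleles[(line, locus)] for line in self.lines)

    def band_matrix(self) -> pd.DataFrame:
        """Binary lines x bands table; band columns are 'locus:allele',
        ordered by locus then allele id. Row sums equal the locus count."""
        cols = []
        for locus in self.loci:
            for allele in sorted(self.allele_counts(locus)):
                cols.append(f"{locus}:{allele}")
        data = np.zeros((len(self.lines), len(cols)), dtype=int)
        pos = {c: k for k, c in enumerate(cols)}
        for i, line in enumerate(self.lines):
            for locus in self.loci:
                data[i, pos[f"{locus}:{self.alleles[(line, locus)]}"]] = 1
        return pd.DataFrame(data, index=list(self.lines), columns=cols)

    def to_band_csv(self, path) -> None:
        self.band_matrix().rename_axis("line").to_csv(path)

    @classmethod
    def from_band_csv(cls, path) -> "MarkerPanel":
        df = pd.read_csv(path, index_col=0)
        alleles: dict[tuple[str, str], str] = {}
        loci: list[str] = []
        for col in df.columns:
            locus, allele = col.split(":", 1)
            if locus not in loci:
                loci.append(locus)
            hit = df[col] == 1
            for line in df.index[hit]:
                key = (str(line), locus)
                if key in alleles:
                    raise ValueError(f"line {line!r} carries two alleles at {locus!r}")
                alleles[key] = allele
        return cls(lines=tuple(map(str, df.index)), loci=tuple(loci), alleles=alleles)

    def to_json(self, path=None) -> str:
        payload = {
            "lines": list(self.lines),
            "loci": list(self.loci),
            "alleles": {f"{l}|{m}": a for (l, m), a in self.alleles.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source: str) -> "MarkerPanel":
        try:
            payload = json.loads(source)
        except json.JSONDecodeError:
            with open(source) as fh:
                payload = json.load(fh)
        alleles = {tuple(k.split("|", 1)): v for k, v in payload["alleles"].items()}
        return cls(tuple(payload["lines"]), tuple(payload["loci"]), alleles)


# ---------------------------------------------------------------------------
# per-locus statistics


def _check_freqs(freqs) -> np.ndarray:
    p = np.asarray(freqs, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("frequencies must be a non-empty vector")
    if np.any(p < 0):
        raise ValueError("frequencies must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies must sum to 1 (got {p.sum()})")
    return p


def gene_diversity(freqs) -> float:
    """Expected heterozygosity 1 - sum(p_i^2)."""
    p = _check_freqs(freqs)
    return float(1.0 - np.sum(p**2))


def pic(freqs) -> float:
    """Botstein polymorphic information content,
    1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2."""
    p = _check_freqs(freqs)
    p2 = p**2
    cross = (np.sum(p2) ** 2 - np.sum(p2**2)) / 2.0  # sum_{i<j} p_i^2 p_j^2
    return float(1.0 - np.sum(p2) - 2.0 * cross)


@dataclass
class LocusSummary:
    locus: str
    n_alleles: int
    major_allele_freq: float
    gene_diversity: float
    pic: float


def locus_summaries(panel: MarkerPanel) -> list[LocusSummary]:
    """Allele counts -> frequencies -> diversity statistics per locus."""
    out = []
    for locus in panel.loci:
        counts = panel.allele_counts(locus)
        total = sum(counts.values())
        if total == 0:
            raise ValueError(f"locus {locus!r} has no typed lines")
        freqs = np.array(sorted(counts.values(), reverse=True), dtype=float) / total
        out.append(
            LocusSummary(
                locus=locus,
                n_alleles=len(counts),
                major_allele_freq=float(freqs[0]),
                gene_diversity=gene_diversity(freqs),
                pic=pic(freqs),
            )
        )
    return out


def panel_summary(panel: MarkerPanel) -> pd.DataFrame:
    """Per-locus table plus a 'Mean' row of column averages."""
    rows = locus_summaries(panel)
    df = pd.DataFrame(
        {
            "locus": [r.locus for r in rows],
            "n_alleles": [r.n_alleles for r in rows],
            "major_allele_freq": [r.major_allele_freq for r in rows],
            "gene_diversity": [r.gene_diversity for r in rows],
            "pic": [r.pic for r in rows],
        }
    )
    mean = pd.DataFrame(
        {
            "locus": ["Mean"],
            "n_alleles": [df["n_alleles"].mean()],
            "major_allele_freq": [df["major_allele_freq"].mean()],
            "gene_diversity": [df["gene_diversity"].mean()],
            "pic": [df["pic"].mean()],
        }
    )
    return pd.concat([df, mean], ignore_index=True)


# ---------------------------------------------------------------------------
# distances


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 1.0 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)

    def between(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))

    def to_csv(self, path) -> None:
        self.to_frame().rename_axis("label").to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(map(str, df.index)), df.to_numpy(dtype=float))


def _binary_matrix(band_matrix) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(band_matrix, MarkerPanel):
        band_matrix = band_matrix.band_matrix()
    if isinstance(band_matrix, pd.DataFrame):
        labels = tuple(map(str, band_matrix.index))
        x = band_matrix.to_numpy()
    else:
        x = np.asarray(band_matrix)
        labels = tuple(str(i) for i in range(x.shape[0]))
    if not np.isin(x, (0, 1)).all():
        raise ValueError("band matrix must be binary")
    empty = np.asarray(x).sum(axis=1) == 0
    if empty.any():
        raise ValueError(f"line(s) {[labels[i] for i in np.flatnonzero(empty)]} carry no scored band")
    return x.astype(float), labels


def jaccard_distance_matrix(band_matrix) -> DistanceMatrix:
    """d(x, y) = 1 - a / (a + b + c): shared presences over union of
    presences; joint absences carry no information about band identity."""
    x, labels = _binary_matrix(band_matrix)
    a = x @ x.T
    totals = x.sum(axis=1)
    union = totals[:, None] + totals[None, :] - a
    off = ~np.eye(len(labels), dtype=bool)
    if np.any(union[off] == 0):
        raise ValueError("a pair of lines shares no scored band (a+b+c = 0)")
    with np.errstate(invalid="ignore"):
        d = 1.0 - a / union
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


def dice_distance_matrix(band_matrix) -> DistanceMatrix:
    """Dice/Nei-Li alternative: d = 1 - 2a / (2a + b + c)."""
    x, labels = _binary_matrix(band_matrix)
    a = x @ x.T
    totals = x.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    off = ~np.eye(len(labels), dtype=bool)
    if np.any(denom[off] == 0):
        raise ValueError("a pair of lines shares no scored band")
    with np.errstate(invalid="ignore"):
        d = 1.0 - 2.0 * a / denom
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels, d)


@dataclass
class DistanceSummary:
    min: float
    max: float
    mean: float
    argmin_pairs: list[tuple[str, str]]
    argmax_pairs: list[tuple[str, str]]


def summarize_distances(d: DistanceMatrix, atol: float = 1e-12) -> DistanceSummary:
    """Min / max / mean over the strictly-upper-triangle entries, with the
    pairs attaining the extremes (all of them, sorted)."""
    if d.n < 2:
        raise ValueError("need at least two labels")
    iu = np.triu_indices(d.n, k=1)
    vals = d.values[iu]
    lo, hi = float(vals.min()), float(vals.max())
    pairs = list(zip(iu[0], iu[1]))
    argmin = sorted((d.labels[i], d.labels[j]) for i, j in pairs if abs(d.values[i, j] - lo) <= atol)
    argmax = sorted((d.labels[i], d.labels[j]) for i, j in pairs if abs(d.values[i, j] - hi) <= atol)
    return DistanceSummary(lo, hi, float(vals.mean()), argmin, argmax)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class Node:
    """Dendrogram node: a leaf (label set, height 0) or a merge."""

    height: float
    label: str | None = None
    children: tuple["Node", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        out: list[str] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def upgma(d: DistanceMatrix) -> Node:
    """Size-weighted average-linkage agglomeration with height d/2.

    Ties in the minimum distance are broken lexicographically on the
    smallest member label of each cluster, and children of every merge are
    ordered by their smallest leaf label, so the tree (and its Newick
    form) is fully deterministic.
    """
    if d.n < 2:
        raise ValueError("need at least two leaves")
    clusters: dict[int, Node] = {i: Node(0.0, label=lab) for i, lab in enumerate(d.labels)}
    sizes = {i: 1 for i in clusters}
    minlab = {i: lab for i, lab in enumerate(d.labels)}
    dist = {
        frozenset((i, j)): float(d.values[i, j])
        for i, j in itertools.combinations(range(d.n), 2)
    }
    next_id = d.n
    while len(clusters) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted(minlab[i] for i in kv[0]))),
        )
        (i, j), dij = tuple(best[0]), best[1]
        a, b = clusters[i], clusters[j]
        first, second = sorted((a, b), key=lambda nd: min(nd.leaves()))
        merged = Node(height=dij / 2.0, children=(first, second))
        ni, nj = sizes[i], sizes[j]
        new_min = min(minlab[i], minlab[j])
        del clusters[i], clusters[j], sizes[i], sizes[j], minlab[i], minlab[j]
        new_dist = {}
        for key, val in dist.items():
            if i in key or j in key:
                continue
            new_dist[key] = val
        for k in clusters:
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            new_dist[frozenset((next_id, k))] = (ni * dik + nj * djk) / (ni + nj)
        dist = new_dist
        clusters[next_id] = merged
        sizes[next_id] = ni + nj
        minlab[next_id] = new_min
        next_id += 1
    return next(iter(clusters.values()))


def to_newick(tree: Node) -> str:
    """Newick string with branch lengths parent_height - child_height."""

    def render(node: Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{length:.10g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:.10g}"

    if tree.is_leaf:
        return f"{tree.label}:0;"
    inner = ",".join(render(c, tree.height) for c in tree.children)
    return f"({inner});"


def depth1_leafsets(tree: Node) -> tuple[frozenset, frozenset]:
    """Leaf sets of the two subtrees below the root."""
    if tree.is_leaf or len(tree.children) != 2:
        raise ValueError("tree root must be a binary merge")
    a, b = tree.children
    return frozenset(a.leaves()), frozenset(b.leaves())


def is_ultrametric(tree: Node) -> bool:
    """Heights must be non-increasing from root to leaves."""

    def ok(node: Node) -> bool:
        return all(c.height <= node.height + 1e-12 and ok(c) for c in node.children)

    return ok(tree)


def cophenetic_matrix(tree: Node) -> DistanceMatrix:
    """Pairwise cophenetic distances (2 x merge height) implied by the tree."""
    labels = sorted(tree.leaves())
    pos = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    out = np.zeros((n, n))

    def walk(node: Node):
        if node.is_leaf:
            return [node.label]
        groups = [walk(c) for c in node.children]
        for ga, gb in itertools.combinations(groups, 2):
            for la in ga:
                for lb in gb:
                    out[pos[la], pos[lb]] = out[pos[lb], pos[la]] = 2.0 * node.height
        return [lab for g in groups for lab in g]

    walk(tree)
    return DistanceMatrix(tuple(labels), np.clip(out, 0.0, 1.0))
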