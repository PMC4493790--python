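"""TE profiles, Nei-Li distances and UPGMA clustering with bootstrap support.

A sample's TE profile is its vector of presence scores (0-10) over a panel
of insertion loci.  Scores are turned into binary "band ladders": with bin
width ``w`` each locus contributes 10/w ordered indicators, indicator ``i``
set iff the score reaches ``i*w``.  Profiles are then compared with the
Nei-Li (Dice) distance D = 1 - 2*n_ab/(n_a + n_b) and clustered by UPGMA.
Support values come from resampling loci with replacement and counting how
often each clade of the full-data tree recurs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dosage import DosageCall
from .errors import ConfigurationError, MalformedInputError, UndefinedDistanceError

DEFAULT_BIN_WIDTH = 1.0


@dataclass(frozen=True)
class MarkerProfile:
    """Per-sample presence scores over an ordered locus panel.

    ``scores[locus]`` is the presence score in [0, 10], or None when the
    call at that locus was inconclusive.
    """

    sample_id: str
    loci: tuple[str, ...]
    scores: Mapping[str, float | None]

    def __post_init__(self) -> None:
        missing = [l for l in self.loci if l not in self.scores]
        if missing:
            raise MalformedInputError(f"profile {self.sample_id!r} lacks loci {missing}")


@dataclass(frozen=True)
class BinaryEncoding:
    """Concatenated band-ladder indicators for one profile."""

    sample_id: str
    loci: tuple[str, ...]
    bin_width: float
    blocks: tuple[tuple[int, ...], ...]  # one indicator block per locus
    present: tuple[bool, ...]  # False where the underlying call was missing

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([np.asarray(b, dtype=int) for b in self.blocks])

    def subset(self, locus_indices: Sequence[int]) -> np.ndarray:
        """Indicator vector restricted to (possibly repeated) locus indices."""
        return np.concatenate([np.asarray(self.blocks[i], dtype=int) for i in locus_indices])


def _n_bins(bin_width: float) -> int:
    if not 0.0 < bin_width <= 10.0:
        raise ConfigurationError("bin_width must lie in (0, 10]")
    n = 10.0 / bin_width
    if abs(n - round(n)) > 1e-9:
        raise ConfigurationError("bin_width must divide 10 evenly")
    return int(round(n))


def encode_profile(profile: MarkerProfile, bin_width: float = DEFAULT_BIN_WIDTH) -> BinaryEncoding:
    """Cumulative band-ladder encoding of a profile.

    Indicator ``i`` (1-based) of a locus block is 1 iff the presence score
    is at least ``i * bin_width``; a missing locus yields an all-zero block
    and is flagged absent so distances can skip it.
    """
    n = _n_bins(bin_width)
    blocks: list[tuple[int, ...]] = []
    present: list[bool] = []
    for locus in profile.loci:
        score = profile.scores[locus]
        if score is None:
            blocks.append((0,) * n)
            present.append(False)
            continue
        if not 0.0 <= score <= 10.0:
            raise MalformedInputError(f"score {score} at {locus!r} outside [0, 10]")
        # tiny tolerance so a score of exactly i*w (up to float dust) sets bit i
        blocks.append(tuple(1 if score >= i * bin_width - 1e-9 else 0 for i in range(1, n + 1)))
        present.append(True)
    return BinaryEncoding(profile.sample_id, profile.loci, bin_width, tuple(blocks), tuple(present))


def nei_li_distance(a: BinaryEncoding | np.ndarray, b: BinaryEncoding | np.ndarray) -> float:
    """Nei-Li (Dice) distance: 1 - 2*shared/(n_a + n_b).

    When both arguments are encodings, loci missing from either profile are
    excluded pairwise.  Raises when neither vector carries a band (the
    similarity is undefined; the caller should exclude the sample).
    """
    if isinstance(a, BinaryEncoding) and isinstance(b, BinaryEncoding):
        if a.loci != b.loci or a.bin_width != b.bin_width:
            raise MalformedInputError("encodings built over different panels")
        keep = [i for i in range(len(a.loci)) if a.present[i] and b.present[i]]
        if not keep:
            raise UndefinedDistanceError("no loci shared between the two profiles")
        va, vb = a.subset(keep), b.subset(keep)
    else:
        va = np.asarray(a, dtype=int)
        vb = np.asarray(b, dtype=int)
        if va.shape != vb.shape:
            raise MalformedInputError("indicator vectors differ in length")
    n_a = int(va.sum())
    n_b = int(vb.sum())
    if n_a + n_b == 0:
        raise UndefinedDistanceError("both encodings are all-zero; Dice similarity undefined")
    n_ab = int((va & vb).sum())
    return 1.0 - 2.0 * n_ab / (n_a + n_b)


def informative(encoding: BinaryEncoding) -> bool:
    """Whether an encoding can enter the distance matrix.

    A profile with no scored locus, or a score of zero at every scored
    locus, can pair with another such profile to an undefined Dice
    similarity; such samples are excluded from clustering and reported.
    """
    return any(encoding.present) and int(encoding.vector.sum()) > 0


def filter_informative(
    profiles: Sequence[MarkerProfile], bin_width: float = DEFAULT_BIN_WIDTH
) -> tuple[list[MarkerProfile], list[str]]:
    """Split profiles into (clusterable, excluded sample ids)."""
    kept: list[MarkerProfile] = []
    dropped: list[str] = []
    for p in profiles:
        if informative(encode_profile(p, bin_width)):
            kept.append(p)
        else:
            dropped.append(p.sample_id)
    return kept, dropped


def distance_matrix(
    encodings: Sequence[BinaryEncoding],
) -> tuple[np.ndarray, list[str]]:
    """Symmetric Nei-Li distance matrix over a set of encodings."""
    labels = [e.sample_id for e in encodings]
    if len(set(labels)) != len(labels):
        raise MalformedInputError("duplicate sample ids in profile set")
    n = len(encodings)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = nei_li_distance(encodings[i], encodings[j])
    return d, labels


@dataclass
class Node:
    """Dendrogram node; leaves have height 0 and a label."""

    height: float
    children: tuple["Node", "Node"] | None = None
    label: str | None = None
    support: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return self.children[0].leaves() | self.children[1].leaves()

    def internal_nodes(self) -> list["Node"]:
        if self.is_leaf:
            return []
        return [self] + self.children[0].internal_nodes() + self.children[1].internal_nodes()


def upgma(d: np.ndarray, labels: Sequence[str]) -> Node:
    """Size-weighted average-linkage (UPGMA) clustering of a distance matrix.

    At each step the closest pair of clusters merges at height d/2; the new
    cluster's distance to any other is the size-weighted mean of its parts.
    Ties are broken by the lowest (row, column) index pair in the current
    cluster list, which makes the tree fully reproducible.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.ndim != 2 or d.shape[1] != n or n < 2 or len(labels) != n:
        raise MalformedInputError("distance matrix must be square and match labels")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0.0):
        raise MalformedInputError("distance matrix must be symmetric with zero diagonal")

    nodes = [Node(0.0, label=str(l)) for l in labels]
    sizes = [1] * n
    work = [list(row) for row in d]
    while len(nodes) > 1:
        m = len(nodes)
        bi, bj, bd = 0, 1, math.inf
        for i in range(m):
            for j in range(i + 1, m):
                if work[i][j] < bd:
                    bi, bj, bd = i, j, work[i][j]
        merged = Node(bd / 2.0, children=(nodes[bi], nodes[bj]))
        si, sj = sizes[bi], sizes[bj]
        new_row = [
            (si * work[bi][k] + sj * work[bj][k]) / (si + sj)
            for k in range(m)
            if k not in (bi, bj)
        ]
        keep = [k for k in range(m) if k not in (bi, bj)]
        work = [[work[a][b] for b in keep] for a in keep]
        nodes = [nodes[k] for k in keep]
        sizes = [sizes[k] for k in keep]
        for row, v in zip(work, new_row):
            row.append(v)
        work.append(new_row + [0.0])
        nodes.append(merged)
        sizes.append(si + sj)
    return nodes[0]


def bootstrap_support(
    profiles: Sequence[MarkerProfile],
    n_replicates: int,
    seed: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> Node:
    """UPGMA tree of the full data with locus-resampling clade support.

    Loci are drawn with replacement ``n_replicates`` times; each draw is
    re-encoded and re-clustered and a clade of the full-data tree scores a
    hit when the replicate tree contains the same leaf set.  Support is the
    hit percentage; the root (trivial clade) and single-locus panels carry
    no support.
    """
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    encodings = [encode_profile(p, bin_width) for p in profiles]
    d, labels = distance_matrix(encodings)
    tree = upgma(d, labels)
    loci = profiles[0].loci
    if len(loci) < 2:
        return tree  # support undefined, left absent

    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {
        node.leaves(): 0 for node in tree.internal_nodes()
    }
    n_loci = len(loci)
    for _ in range(n_replicates):
        idx = rng.integers(0, n_loci, size=n_loci)
        vecs = [e.subset(idx) for e in encodings]
        m = len(vecs)
        db = np.zeros((m, m))
        ok = True
        for i in range(m):
            for j in range(i + 1, m):
                try:
                    db[i, j] = db[j, i] = nei_li_distance(vecs[i], vecs[j])
                except UndefinedDistanceError:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue  # replicate uninformative for some pair; skip it
        rep_tree = upgma(db, labels)
        rep_clades = {node.leaves() for node in rep_tree.internal_nodes()}
        for clade in counts:
            if clade in rep_clades:
                counts[clade] += 1
    root_clade = tree.leaves()
    for node in tree.internal_nodes():
        clade = node.leaves()
        if clade == root_clade:
            continue  # trivial split
        node.support = 100.0 * counts[clade] / n_replicates
    return tree


def to_newick(root: Node, support_digits: int = 0) -> str:
    """Serialise a dendrogram to Newick with heights as branch lengths."""

    def fmt(node: Node, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{node.label}:{length:.6g}"
        inner = ",".join(fmt(c, node.height) for c in node.children)
        label = "" if node.support is None else f"{node.support:.{support_digits}f}"
        return f"({inner}){label}:{length:.6g}"

    if root.is_leaf:
        return f"{root.label};"
    inner = ",".join(fmt(c, root.height) for c in root.children)
    return f"({inner});"


def profiles_from_calls(
    calls: Iterable[DosageCall], loci: Sequence[str] | None = None
) -> list[MarkerProfile]:
    """Assemble MarkerProfiles from dosage calls.

    Calls whose status yields no score (repeat_needed, inconclusive) enter
    the profile as missing.  The locus panel defaults to the sorted union of
    loci seen in the calls; every profile spans the full panel.
    """
    by_sample: dict[str, dict[str, float | None]] = {}
    seen_loci: list[str] = []
    for c in calls:
        if c.locus_id not in seen_loci:
            seen_loci.append(c.locus_id)
        by_sample.setdefault(c.sample_id, {})[c.locus_id] = c.presence_score
    panel = tuple(loci) if loci is not None else tuple(sorted(seen_loci))
    return [
        MarkerProfile(sample, panel, {l: scores.get(l) for l in panel})
        for sample, scores in sorted(by_sample.items())
    ]


def distance_frame(d: np.ndarray, labels: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame(d, index=list(labels), columns=list(labels))
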