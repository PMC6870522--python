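"""Alpha/beta diversity metrics and exact rarefaction.

Shannon entropy uses natural log by default. Rarefaction is exact
without-replacement subsampling (multivariate hypergeometric), never a
with-replacement approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from neutralcomm.core_io import CountTable, Tree, ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric non-negative dissimilarity matrix with a zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        n = len(self.ids)
        if data.shape != (n, n):
            raise ValidationError(f"distance matrix shape {data.shape} != ({n}, {n})")
        if not np.allclose(data, data.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(data), 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (data < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.data = np.clip(data, 0, None)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, keep_ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in keep_ids]
        return DistanceMatrix(list(keep_ids), self.data[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)


@dataclass
class RarefactionResult:
    """Per-sample mean and sd of a metric at one rarefaction depth."""

    depth: int
    sample_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    iterations: int
    seed: int | None
    too_shallow: list[str]


def shannon(counts: np.ndarray, base: float | None = None) -> float:
    """Shannon diversity H = -sum p_i log p_i over nonzero proportions."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("Shannon diversity undefined for a zero-total sample")
    p = counts[counts > 0] / total
    h = float(-(p * np.log(p)).sum())
    if base is not None:
        h /= np.log(base)
    return h


def richness(counts: np.ndarray) -> int:
    """Number of OTUs with count > 0."""
    return int((np.asarray(counts) > 0).sum())


def whittaker_beta(a_counts: np.ndarray, b_counts: np.ndarray) -> float:
    """Pairwise incidence dissimilarity (b + c) / (2a + b + c) (Koleff form)."""
    pa = np.asarray(a_counts) > 0
    pb = np.asarray(b_counts) > 0
    a = int((pa & pb).sum())
    b = int((pa & ~pb).sum())
    c = int((~pa & pb).sum())
    if a + b + c == 0:
        raise ValidationError("both samples are empty")
    return (b + c) / (2 * a + b + c)


def clr_transform(counts: np.ndarray, zero_replacement: float = 0.5) -> np.ndarray:
    """Centered log-ratio transform of a zero-replaced, closed composition."""
    x = np.asarray(counts, dtype=float).copy()
    if x.sum() <= 0:
        raise ValidationError("cannot transform a zero-total composition")
    x[x == 0] = zero_replacement
    x = x / x.sum()
    logx = np.log(x)
    return logx - logx.mean()


def aitchison_distance(
    a_counts: np.ndarray, b_counts: np.ndarray, zero_replacement: float = 0.5
) -> float:
    """Euclidean distance between clr-transformed compositions."""
    ca = clr_transform(a_counts, zero_replacement)
    cb = clr_transform(b_counts, zero_replacement)
    return float(np.linalg.norm(ca - cb))


def bray_curtis(a_counts: np.ndarray, b_counts: np.ndarray) -> float:
    """Bray-Curtis dissimilarity sum|a-b| / sum(a+b)."""
    a = np.asarray(a_counts, dtype=float)
    b = np.asarray(b_counts, dtype=float)
    denom = (a + b).sum()
    if denom == 0:
        raise ValidationError("both samples have zero total")
    return float(np.abs(a - b).sum() / denom)


_PAIRWISE = {
    "braycurtis": bray_curtis,
    "betaw": whittaker_beta,
    "aitchison": aitchison_distance,
}


def distance_matrix(table: CountTable, metric: str = "braycurtis", **kwargs) -> DistanceMatrix:
    """All-pairs distance matrix over samples for a named metric."""
    if metric not in _PAIRWISE:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(_PAIRWISE)}")
    fn = _PAIRWISE[metric]
    n = table.n_samples
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = fn(table.counts[i], table.counts[j], **kwargs)
    return DistanceMatrix(list(table.sample_ids), out)


def rarefy(counts: np.ndarray, depth: int, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Exact without-replacement subsample of one sample to ``depth`` reads."""
    counts = np.asarray(counts)
    total = int(counts.sum())
    if depth > total:
        raise ValidationError(f"depth {depth} exceeds sample total {total}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts.astype(np.int64), int(depth))


def rarefy_table(table: CountTable, depth: int, seed: int | None = None) -> CountTable:
    """Rarefy every sample of a table to a common depth (samples too shallow error)."""
    rng = np.random.default_rng(seed)
    rows = [rarefy(table.counts[i], depth, rng) for i in range(table.n_samples)]
    return CountTable(list(table.sample_ids), list(table.otu_ids), np.vstack(rows))


def faith_pd(present_otus: set[str], tree: Tree) -> float:
    """Faith's phylogenetic diversity: total branch length of the minimal
    subtree connecting the present leaves and the root."""
    if not present_otus:
        warnings.warn("empty OTU set; Faith's PD is 0", stacklevel=2)
        return 0.0
    leaves = {tip.name: tip for tip in tree.root.tips()}
    missing = sorted(present_otus - set(leaves))
    if missing:
        raise ValidationError(f"OTUs absent from tree: {missing}")
    counted: set[int] = set()
    total = 0.0
    for name in present_otus:
        node = leaves[name]
        while node.parent is not None:
            if id(node) in counted:
                break
            counted.add(id(node))
            total += node.length or 0.0
            node = node.parent
    return float(total)


def rarefaction_curve(
    table: CountTable,
    depths: list[int],
    metric: str = "richness",
    iterations: int = 100,
    seed: int | None = None,
    tree: Tree | None = None,
) -> list[RarefactionResult]:
    """Mean +/- sd of a metric per sample at each depth over rarefaction draws.

    Samples shallower than a depth are flagged in ``too_shallow`` and carry
    NaN at that depth rather than being silently dropped.
    """
    if not depths:
        raise ValidationError("empty depth list")
    if sorted(depths) != list(depths):
        raise ValidationError("depths must be sorted ascending")
    if metric == "richness":
        def measure(c: np.ndarray) -> float:
            return float(richness(c))
    elif metric == "faith_pd":
        if tree is None:
            raise ValidationError("faith_pd metric requires a tree")
        def measure(c: np.ndarray) -> float:
            present = {o for o, v in zip(table.otu_ids, c) if v > 0}
            return faith_pd(present, tree)
    else:
        raise ValueError(f"unknown rarefaction metric {metric!r}")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    results = []
    for depth in depths:
        means = np.full(table.n_samples, np.nan)
        sds = np.full(table.n_samples, np.nan)
        shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
        for i in range(table.n_samples):
            if totals[i] < depth:
                continue
            vals = [measure(rarefy(table.counts[i], depth, rng)) for _ in range(iterations)]
            means[i] = float(np.mean(vals))
            sds[i] = float(np.std(vals))
        results.append(
            RarefactionResult(int(depth), list(table.sample_ids), means, sds, iterations, seed, shallow)
        )
    return results
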