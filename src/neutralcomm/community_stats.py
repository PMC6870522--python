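"""Permutation-based multivariate statistics and rank tests.

PERMANOVA follows Anderson's partitioning of a Gower-centered distance
matrix with sequential (Type-I) sums of squares; term order is the caller's
design order. CAP ordination is PCoA followed by linear discriminant
analysis with leave-one-out classification success.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from neutralcomm.core_io import CountTable, TaxonomyMap, RANKS, ValidationError
from neutralcomm.diversity import DistanceMatrix


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass
class PermanovaTable:
    """Per-term partition of distance-matrix variation."""

    terms: list[str]
    df: dict[str, int]
    ss: dict[str, float]
    ms: dict[str, float]
    f: dict[str, float]
    r2: dict[str, float]
    p: dict[str, float]
    df_residual: int
    ss_residual: float
    ss_total: float
    nperm: int

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for t in self.terms:
            rows.append(
                {
                    "term": t,
                    "Df": self.df[t],
                    "SSq": self.ss[t],
                    "MeanSSq": self.ms[t],
                    "Fstat": self.f[t],
                    "R2": self.r2[t],
                    "P": self.p[t],
                }
            )
        rows.append(
            {
                "term": "Residuals",
                "Df": self.df_residual,
                "SSq": self.ss_residual,
                "MeanSSq": self.ss_residual / self.df_residual if self.df_residual else np.nan,
                "Fstat": np.nan,
                "R2": self.ss_residual / self.ss_total,
                "P": np.nan,
            }
        )
        rows.append(
            {
                "term": "Total",
                "Df": self.df_residual + sum(self.df.values()),
                "SSq": self.ss_total,
                "MeanSSq": np.nan,
                "Fstat": np.nan,
                "R2": 1.0,
                "P": np.nan,
            }
        )
        return pd.DataFrame(rows)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered matrix G = (I - 11'/n)(-d^2/2)(I - 11'/n)."""
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _dummy(values: Sequence[str]) -> np.ndarray:
    levels = sorted(set(values))
    return np.column_stack([[1.0 if v == lv else 0.0 for v in values] for lv in levels])


def _term_columns(term: str, factors: Mapping[str, Sequence[str]], n: int) -> np.ndarray:
    parts = term.split(":")
    for p in parts:
        if p not in factors:
            raise ValidationError(f"unknown factor {p!r} in term {term!r}")
        if len(set(factors[p])) < 2:
            raise ValidationError(f"factor {p!r} has a single level")
    blocks = [_dummy(factors[p]) for p in parts]
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.einsum("ij,ik->ijk", cols, b).reshape(n, -1)
    return cols


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of x, and its rank."""
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if len(s) else 0)
    rank = int((s > tol).sum())
    basis = u[:, :rank]
    return basis @ basis.T, rank


def permanova(
    dist: DistanceMatrix,
    factors: Mapping[str, Sequence[str]],
    terms: list[str] | None = None,
    nperm: int = 10000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermanovaTable:
    """Sequential PERMANOVA of a distance matrix on categorical factors.

    Parameters
    ----------
    dist : DistanceMatrix
    factors : mapping of factor name -> per-sample labels (dist order)
    terms : design terms in fitting order; interactions as ``"A:B"``.
        Defaults to the factors in mapping order, no interactions.
    nperm : number of free label permutations for the p values.
    exhaustive : enumerate all n! permutations instead of sampling (only
        sensible for very small n); p is then the exact fraction of
        permutations with F >= observed, identity included.
    """
    n = len(dist)
    for name, vals in factors.items():
        if len(vals) != n:
            raise ValidationError(f"factor {name!r} has {len(vals)} values for {n} samples")
    if terms is None:
        terms = list(factors)
    if not terms:
        raise ValidationError("no design terms")

    g = gower_center(dist.data)
    ss_total = float(np.trace(g))

    x = np.ones((n, 1))
    hats = []
    ranks = []
    for term in terms:
        x = np.hstack([x, _term_columns(term, factors, n)])
        h, r = _hat(x)
        hats.append(h)
        ranks.append(r)
    df = {}
    projectors = {}
    prev_h, prev_r = _hat(np.ones((n, 1)))
    for term, h, r in zip(terms, hats, ranks):
        df[term] = r - prev_r
        if df[term] <= 0:
            raise ValidationError(f"term {term!r} is aliased with earlier terms (singular design)")
        projectors[term] = h - prev_h
        prev_h, prev_r = h, r
    h_full = hats[-1]
    df_res = n - ranks[-1]
    if df_res <= 0:
        raise ValidationError("no residual degrees of freedom")
    resid_proj = np.eye(n) - h_full

    def term_stats(gmat: np.ndarray) -> tuple[dict[str, float], float]:
        ss_res = float((resid_proj * gmat).sum())
        fs = {}
        for term in terms:
            ss_t = float((projectors[term] * gmat).sum())
            fs[term] = (ss_t / df[term]) / (ss_res / df_res)
        return fs, ss_res

    f_obs, ss_res = term_stats(g)
    ss = {t: float((projectors[t] * g).sum()) for t in terms}
    ms = {t: ss[t] / df[t] for t in terms}
    r2 = {t: ss[t] / ss_total for t in terms}

    # ties between permuted and observed F must count as exceedances
    eps = {t: 1e-12 * max(1.0, abs(f_obs[t])) for t in terms}
    exceed = {t: 0 for t in terms}
    if exhaustive:
        if n > 9:
            raise ValidationError("exhaustive enumeration only supported for n <= 9 samples")
        perms = list(itertools.permutations(range(n)))
        for perm in perms:
            f_perm, _ = term_stats(g[np.ix_(perm, perm)])
            for t in terms:
                if f_perm[t] >= f_obs[t] - eps[t]:
                    exceed[t] += 1
        p = {t: exceed[t] / len(perms) for t in terms}
        nperm = len(perms)
    else:
        rng = np.random.default_rng(seed)
        for _ in range(nperm):
            perm = rng.permutation(n)
            f_perm, _ = term_stats(g[np.ix_(perm, perm)])
            for t in terms:
                if f_perm[t] >= f_obs[t] - eps[t]:
                    exceed[t] += 1
        p = {t: (exceed[t] + 1) / (nperm + 1) for t in terms}

    return PermanovaTable(
        terms=terms, df=df, ss=ss, ms=ms, f=f_obs, r2=r2, p=p,
        df_residual=df_res, ss_residual=ss_res, ss_total=ss_total, nperm=nperm,
    )


# ---------------------------------------------------------------------------
# PCoA and CAP


@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray  # samples x positive axes, eigenvalue order
    eigenvalues: np.ndarray  # all, descending (negatives reported, excluded from coords)

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum()


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinates: eigendecomposition of the Gower-centered matrix."""
    g = gower_center(dist.data)
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    tol = 1e-10 * max(1.0, abs(eigval[0]))
    pos = eigval > tol
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    return PcoaResult(list(dist.ids), coords, eigval)


@dataclass
class CapResult:
    """CAP ordination outcome: discriminant scores and classification success."""

    n_axes: int
    ld_scores: np.ndarray
    groups: list[str]
    group_success: dict[str, float]
    overall_success: float
    p_value: float
    proportion_of_trace: np.ndarray
    nperm: int


def _loo_success(coords: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    n = len(labels)
    correct = np.zeros(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        lda = LinearDiscriminantAnalysis()
        lda.fit(coords[mask], labels[mask])
        correct[i] = lda.predict(coords[i : i + 1])[0] == labels[i]
    return float(correct.mean()), correct


def cap_discrim(
    dist: DistanceMatrix,
    groups: Sequence[str],
    max_axes: int | None = None,
    fixed_axes: int | None = None,
    nperm: int = 1000,
    seed: int | None = None,
) -> CapResult:
    """PCoA + linear discriminant analysis with leave-one-out success.

    The number of PCoA axes fed to the LDA is chosen to maximize
    leave-one-out classification success (searched from 2 up to
    ``samples - groups - 1``), unless ``fixed_axes`` is given. The p value is
    the fraction of label permutations achieving at least the observed
    success.
    """
    labels = np.asarray([str(gp) for gp in groups])
    n = len(labels)
    if n != len(dist):
        raise ValidationError("groups length must match distance matrix")
    level_names, level_counts = np.unique(labels, return_counts=True)
    if len(level_names) < 2:
        raise ValidationError("need at least 2 groups")
    if (level_counts < 2).any():
        bad = [str(g) for g, c in zip(level_names, level_counts) if c < 2]
        raise ValidationError(f"groups with a single sample: {bad}")
    ord_res = pcoa(dist)
    coords = ord_res.coordinates
    upper = n - len(level_names) - 1
    upper = min(upper, coords.shape[1])
    if upper < 2:
        upper = min(2, coords.shape[1])
    if fixed_axes is not None:
        best_m = min(fixed_axes, coords.shape[1])
        best_success, best_correct = _loo_success(coords[:, :best_m], labels)
    else:
        best_m, best_success, best_correct = 2, -1.0, None
        for m in range(2, upper + 1):
            success, correct = _loo_success(coords[:, :m], labels)
            if success > best_success:
                best_m, best_success, best_correct = m, success, correct
    group_success = {
        str(gp): float(best_correct[labels == gp].mean()) for gp in level_names
    }
    lda = LinearDiscriminantAnalysis()
    lda.fit(coords[:, :best_m], labels)
    scores = lda.transform(coords[:, :best_m])
    ev = getattr(lda, "explained_variance_ratio_", np.ones(scores.shape[1]) / scores.shape[1])
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(nperm):
        perm_labels = rng.permutation(labels)
        s, _ = _loo_success(coords[:, :best_m], perm_labels)
        if s >= best_success:
            exceed += 1
    p = (exceed + 1) / (nperm + 1)
    return CapResult(
        n_axes=best_m,
        ld_scores=scores,
        groups=[str(g) for g in level_names],
        group_success=group_success,
        overall_success=best_success,
        p_value=p,
        proportion_of_trace=np.asarray(ev),
        nperm=nperm,
    )


# ---------------------------------------------------------------------------
# rank tests


def _rank_with_ties(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Midranks plus the tie-correction factor 1 - sum(t^3 - t)/(N^3 - N)."""
    ranks = stats.rankdata(values)
    n = len(values)
    _, counts = np.unique(values, return_counts=True)
    denom = n**3 - n
    correction = 1.0 - ((counts**3 - counts).sum() / denom if denom else 0.0)
    return ranks, correction


def kruskal_wallis(values: Sequence[float], groups: Sequence[str]) -> tuple[float, int, float]:
    """Tie-corrected Kruskal-Wallis H with chi-square p value.

    Returns (H, df, p). All-identical values give H = 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(gp) for gp in groups])
    if len(values) != len(labels):
        raise ValidationError("values and groups differ in length")
    level_names = np.unique(labels)
    if len(level_names) < 2:
        raise ValidationError("need at least 2 groups")
    n = len(values)
    ranks, correction = _rank_with_ties(values)
    h = 12.0 / (n * (n + 1)) * sum(
        ranks[labels == gp].sum() ** 2 / (labels == gp).sum() for gp in level_names
    ) - 3 * (n + 1)
    if correction == 0:
        h = 0.0
    else:
        h /= correction
    df = len(level_names) - 1
    p = float(stats.chi2.sf(h, df)) if h > 0 else 1.0
    return float(h), df, p


def conover_posthoc(
    values: Sequence[float],
    groups: Sequence[str],
    p_adjust: str = "none",
) -> pd.DataFrame:
    """Conover-Iman pairwise comparisons after Kruskal-Wallis.

    Statistics use rank means with the pooled tie-corrected variance; p
    values are two-sided from Student's t with N - k degrees of freedom, then
    adjusted with the requested method ("none", "bonferroni", "holm", "bh").
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray([str(gp) for gp in groups])
    level_names = np.unique(labels)
    sizes = {gp: int((labels == gp).sum()) for gp in level_names}
    empty = [gp for gp, sz in sizes.items() if sz == 0]
    if empty:
        raise ValidationError(f"empty groups: {empty}")
    n = len(values)
    k = len(level_names)
    h, _, _ = kruskal_wallis(values, labels)
    ranks, _ = _rank_with_ties(values)
    s2 = ((ranks**2).sum() - n * (n + 1) ** 2 / 4.0) / (n - 1)
    df = n - k
    rank_means = {gp: ranks[labels == gp].mean() for gp in level_names}
    rows = []
    for g1, g2 in itertools.combinations(level_names, 2):
        se = np.sqrt(s2 * ((n - 1 - h) / df) * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        t = (rank_means[g1] - rank_means[g2]) / se if se > 0 else 0.0
        p = 2 * float(stats.t.sf(abs(t), df)) if se > 0 else 1.0
        rows.append({"group1": str(g1), "group2": str(g2), "t": float(t), "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if p_adjust != "none":
        method = {"bonferroni": "bonferroni", "holm": "holm", "bh": "fdr_bh"}[p_adjust]
        out["p_adjusted"] = multipletests(out["p"], method=method)[1]
    else:
        out["p_adjusted"] = out["p"]
    return out


# ---------------------------------------------------------------------------
# incidence summaries and taxonomy aggregation


def shared_otu_counts(table: CountTable, grouping: Sequence[str]) -> dict:
    """Incidence intersections of OTUs across sample groups.

    An OTU is present in a group when it has a nonzero count in at least one
    sample of that group. Returns per-group presence totals, pairwise shared
    counts, unique-to-group counts, and the shared-by-all count.
    """
    labels = np.asarray([str(gp) for gp in grouping])
    if len(labels) != table.n_samples:
        raise ValidationError("grouping must cover all samples")
    level_names = np.unique(labels)
    presence = {}
    for gp in level_names:
        mask = labels == gp
        if not mask.any():
            raise ValidationError(f"empty group {gp!r}")
        presence[gp] = (table.counts[mask] > 0).any(axis=0)
    any_present = np.zeros(table.n_otus, dtype=bool)
    for v in presence.values():
        any_present |= v
    all_present = np.ones(table.n_otus, dtype=bool)
    for v in presence.values():
        all_present &= v
    per_group = {str(gp): int(presence[gp].sum()) for gp in level_names}
    pairwise = {
        (str(g1), str(g2)): int((presence[g1] & presence[g2]).sum())
        for g1, g2 in itertools.combinations(level_names, 2)
    }
    unique = {}
    for gp in level_names:
        others = np.zeros(table.n_otus, dtype=bool)
        for other in level_names:
            if other != gp:
                others |= presence[other]
        unique[str(gp)] = int((presence[gp] & ~others).sum())
    return {
        "per_group": per_group,
        "pairwise_shared": pairwise,
        "unique_to_group": unique,
        "shared_by_all": int(all_present.sum()),
        "total_present": int(any_present.sum()),
    }


def aggregate_taxonomy(
    table: CountTable, taxonomy: TaxonomyMap, rank: str
) -> tuple[CountTable, pd.Series]:
    """Sum counts over OTUs sharing a rank-level name.

    OTUs without an assignment at ``rank`` are pooled as "Unassigned".
    Returns the aggregated table and global proportions per taxon.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    names = []
    for otu in table.otu_ids:
        name = taxonomy.name_at(otu, rank) if otu in taxonomy else ""
        names.append(name if name else "Unassigned")
    taxa = list(dict.fromkeys(names))
    agg = np.zeros((table.n_samples, len(taxa)), dtype=np.int64)
    for j, name in enumerate(names):
        agg[:, taxa.index(name)] += table.counts[:, j]
    out = CountTable(list(table.sample_ids), taxa, agg)
    totals = out.otu_totals()
    global_props = pd.Series(totals / totals.sum(), index=taxa)
    return out, global_props
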