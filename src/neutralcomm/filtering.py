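"""OTU-retention filters and host-OTU removal for diet tables.

Three retention rules are supported, matching common amplicon practice:

* ``pruned``   — keep OTUs with >= 0.005% relative abundance over the whole
  dataset (reads-based by default).
* ``dominant`` — keep OTUs reaching >= 5% relative abundance in at least one
  sample.
* ``minreads`` — keep OTUs with >= 20 reads in at least one sample
  (optionally a per-cell zeroing variant).

Relative abundances are recomputed after each filter, not inherited.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from neutralcomm.core_io import CountTable, TaxonomyMap, ValidationError


@dataclass
class FilterReport:
    """Outcome of one filter application."""

    name: str
    n_before: int
    n_after: int
    removed_ids: list[str]
    threshold: float
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_after > self.n_before:
            raise ValueError("filter cannot add OTUs")
        if len(self.removed_ids) != self.n_before - self.n_after:
            raise ValueError("removed set size must equal before - after")

    def to_dict(self) -> dict:
        return {
            "filter": self.name,
            "otus_before": self.n_before,
            "otus_after": self.n_after,
            "threshold": self.threshold,
            "removed_ids": list(self.removed_ids),
            **self.extra,
        }


def relative_abundance(table: CountTable, scope: str = "per-sample") -> np.ndarray:
    """Relative abundances at the requested scope.

    ``per-sample`` returns a samples x OTUs matrix whose rows sum to 1;
    ``global`` returns one proportion per OTU (OTU reads / grand total).
    """
    if scope == "global":
        total = table.grand_total()
        if total == 0:
            raise ValidationError("cannot compute global proportions of an all-zero table")
        return table.otu_totals() / total
    if scope == "per-sample":
        totals = table.sample_totals()
        zero = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        if zero:
            raise ValidationError(f"zero-total samples under per-sample scope: {zero}")
        return table.counts / totals[:, None]
    raise ValueError(f"unknown scope {scope!r}")


def _apply_otu_mask(table: CountTable, keep: np.ndarray, name: str, threshold: float) -> tuple[CountTable, FilterReport]:
    removed = [o for o, k in zip(table.otu_ids, keep) if not k]
    if keep.sum() == 0:
        raise ValidationError(f"filter {name!r} would remove every OTU")
    kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    out = table.subset_otus(kept_ids)
    report = FilterReport(name, table.n_otus, out.n_otus, removed, threshold)
    return out, report


def filter_pruned(
    table: CountTable, threshold: float = 0.00005, basis: str = "reads"
) -> tuple[CountTable, FilterReport]:
    """Keep OTUs whose whole-dataset relative abundance is >= ``threshold``.

    ``basis="reads"`` pools reads (OTU total / grand total); ``basis="mean"``
    averages per-sample proportions instead.
    """
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    if basis == "reads":
        props = relative_abundance(table, "global")
    elif basis == "mean":
        props = relative_abundance(table, "per-sample").mean(axis=0)
    else:
        raise ValueError(f"unknown basis {basis!r}")
    return _apply_otu_mask(table, props >= threshold, "pruned", threshold)


def filter_dominant(table: CountTable, threshold: float = 0.05) -> tuple[CountTable, FilterReport]:
    """Keep OTUs reaching >= ``threshold`` relative abundance in >= 1 sample."""
    if not 0 < threshold < 1:
        raise ValidationError(f"threshold must be in (0, 1), got {threshold}")
    totals = table.sample_totals()
    zero = totals == 0
    if zero.any():
        warnings.warn(
            f"excluding zero-total samples from the dominant criterion: "
            f"{[s for s, z in zip(table.sample_ids, zero) if z]}",
            stacklevel=2,
        )
    props = np.zeros_like(table.counts, dtype=float)
    nz = ~zero
    props[nz] = table.counts[nz] / totals[nz, None]
    keep = (props >= threshold).any(axis=0)
    return _apply_otu_mask(table, keep, "dominant", threshold)


def filter_min_reads(
    table: CountTable, min_reads: int = 20, mode: str = "otu"
) -> tuple[CountTable, FilterReport]:
    """Keep OTUs with >= ``min_reads`` reads in at least one sample.

    ``mode="otu"`` retains whole OTUs (default). ``mode="cell"`` first zeroes
    cells below ``min_reads`` and then drops OTUs left with no reads.
    """
    if min_reads < 1 or int(min_reads) != min_reads:
        raise ValidationError(f"min_reads must be a positive integer, got {min_reads}")
    min_reads = int(min_reads)
    if mode == "otu":
        keep = (table.counts >= min_reads).any(axis=0)
        return _apply_otu_mask(table, keep, "minreads", min_reads)
    if mode == "cell":
        counts = table.counts.copy()
        counts[counts < min_reads] = 0
        keep = counts.sum(axis=0) > 0
        removed = [o for o, k in zip(table.otu_ids, keep) if not k]
        kept_ids = [o for o, k in zip(table.otu_ids, keep) if k]
        idx = [table.otu_ids.index(o) for o in kept_ids]
        out = CountTable(list(table.sample_ids), kept_ids, counts[:, idx])
        report = FilterReport("minreads-cell", table.n_otus, out.n_otus, removed, min_reads)
        return out, report
    raise ValueError(f"unknown mode {mode!r}")


def remove_host_otu(
    table: CountTable,
    taxonomy: TaxonomyMap,
    host_rank: str = "order",
    host_name: str = "Odonata",
) -> tuple[CountTable, FilterReport]:
    """Remove the single most abundant OTU assigned to the host taxon.

    The OTU assigned to ``host_name`` at ``host_rank`` with the greatest
    total read count is removed table-wide. If no OTU matches, the table is
    returned unchanged with a warning.
    """
    matches = [o for o in taxonomy.otus_at(host_rank, host_name) if o in set(table.otu_ids)]
    if not matches:
        warnings.warn(f"no OTU assigned to {host_rank}={host_name!r}; nothing removed", stacklevel=2)
        return table, FilterReport("host-otu", table.n_otus, table.n_otus, [], 0.0)
    totals = {o: int(table.counts[:, table.otu_index(o)].sum()) for o in matches}
    host_otu = max(totals, key=totals.get)  # type: ignore[arg-type]
    j = table.otu_index(host_otu)
    per_sample = {s: int(c) for s, c in zip(table.sample_ids, table.counts[:, j])}
    out = table.subset_otus([o for o in table.otu_ids if o != host_otu])
    report = FilterReport(
        "host-otu",
        table.n_otus,
        out.n_otus,
        [host_otu],
        0.0,
        extra={"host_otu": host_otu, "host_reads_per_sample": per_sample, "host_total_reads": totals[host_otu]},
    )
    return out, report


def near_zero_variance_filter(
    matrix: np.ndarray,
    column_ids: list[str] | None = None,
    freq_ratio_cutoff: float = 19.0,
    unique_cutoff: float = 0.10,
) -> tuple[np.ndarray, list[str]]:
    """Drop near-zero-variance columns from a samples x features matrix.

    A column is removed when it is constant, or when the frequency ratio of
    its most common to second most common value exceeds ``freq_ratio_cutoff``
    AND its fraction of distinct values is below ``unique_cutoff``.
    """
    matrix = np.asarray(matrix)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 samples")
    n, p = matrix.shape
    ids = column_ids if column_ids is not None else [str(j) for j in range(p)]
    keep = np.ones(p, dtype=bool)
    for j in range(p):
        values, freqs = np.unique(matrix[:, j], return_counts=True)
        if len(values) == 1:
            keep[j] = False
            continue
        freqs = np.sort(freqs)[::-1]
        ratio = freqs[0] / freqs[1]
        pct_unique = len(values) / n
        if ratio > freq_ratio_cutoff and pct_unique < unique_cutoff:
            keep[j] = False
    removed = [ids[j] for j in range(p) if not keep[j]]
    return matrix[:, keep], removed
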