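"""Data model and readers/writers for count tables, metadata, taxonomy and trees.

Supported formats: classic tab-separated OTU tables (QIIME-style, OTU rows x
sample columns, optional trailing taxonomy column), BIOM-JSON 1.0 (dense and
sparse), metadata TSV/CSV, and Newick trees (via scikit-bio).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import skbio

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = {"k": 0, "p": 1, "c": 2, "o": 3, "f": 4, "g": 5, "s": 6}
_TAXONOMY_COLUMN_NAMES = {"taxonomy", "consensus lineage", "consensuslineage", "lineage"}


class ParseError(ValueError):
    """Raised when a file cannot be parsed in its declared dialect."""


class ValidationError(ValueError):
    """Raised when parsed content violates a data-model invariant."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
    if dups:
        raise ValidationError(f"duplicate {what} identifiers: {sorted(set(dups))}")


@dataclass
class CountTable:
    """Sample-by-OTU matrix of non-negative integer read counts.

    ``counts[i, j]`` is the number of reads of OTU ``otu_ids[j]`` in sample
    ``sample_ids[i]``. Order is preserved from the source file; all joins are
    by identifier, never by position.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if counts.size == 0:
            raise ValidationError("table must have at least one sample and one OTU")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise ValidationError(
                    f"fractional count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = np.round(counts).astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        self.counts = counts.astype(np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        """Per-sample library sizes."""
        return self.counts.sum(axis=1)

    def otu_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def grand_total(self) -> int:
        return int(self.counts.sum())

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def otu_index(self, otu_id: str) -> int:
        return self.otu_ids.index(otu_id)

    def subset_otus(self, keep: Iterable[str]) -> "CountTable":
        keep_set = set(keep)
        idx = [j for j, o in enumerate(self.otu_ids) if o in keep_set]
        return CountTable(
            list(self.sample_ids),
            [self.otu_ids[j] for j in idx],
            self.counts[:, idx].copy(),
        )

    def subset_samples(self, keep: Iterable[str]) -> "CountTable":
        keep_set = set(keep)
        idx = [i for i, s in enumerate(self.sample_ids) if s in keep_set]
        return CountTable(
            [self.sample_ids[i] for i in idx],
            list(self.otu_ids),
            self.counts[idx, :].copy(),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.otu_ids == other.otu_ids
            and np.array_equal(self.counts, other.counts)
        )


def parse_lineage(text: str) -> list[tuple[str, str]]:
    """Parse a GreenGenes-style lineage string into (rank, name) pairs.

    ``"k__Bacteria; p__Proteobacteria"`` yields kingdom=Bacteria,
    phylum=Proteobacteria and empty names for the remaining five ranks.
    Un-prefixed fields are assigned to ranks in order.
    """
    names = [""] * len(RANKS)
    fields = [f.strip() for f in str(text).split(";") if f.strip()]
    next_rank = 0
    for fld in fields:
        if len(fld) >= 3 and fld[1:3] == "__" and fld[0].lower() in _RANK_PREFIXES:
            pos = _RANK_PREFIXES[fld[0].lower()]
            names[pos] = fld[3:].strip()
            next_rank = pos + 1
        else:
            if next_rank < len(RANKS):
                names[next_rank] = fld
                next_rank += 1
    return list(zip(RANKS, names))


def format_lineage(lineage: Sequence[tuple[str, str]]) -> str:
    return "; ".join(f"{rank[0]}__{name}" for rank, name in lineage)


@dataclass
class TaxonomyMap:
    """OTU id -> ordered (rank, name) lineage over the seven canonical ranks."""

    lineages: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for otu, lin in self.lineages.items():
            ranks = [r for r, _ in lin]
            if tuple(ranks) != RANKS[: len(ranks)]:
                raise ValidationError(f"lineage ranks out of canonical order for OTU {otu!r}")

    def __contains__(self, otu_id: str) -> bool:
        return otu_id in self.lineages

    def __getitem__(self, otu_id: str) -> list[tuple[str, str]]:
        return self.lineages[otu_id]

    def __len__(self) -> int:
        return len(self.lineages)

    def name_at(self, otu_id: str, rank: str) -> str:
        """Rank-level name for one OTU; empty string if unassigned/unknown."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        lin = self.lineages.get(otu_id)
        if lin is None:
            return ""
        idx = RANKS.index(rank)
        return lin[idx][1] if idx < len(lin) else ""

    def otus_at(self, rank: str, name: str) -> list[str]:
        """All OTUs assigned ``name`` at ``rank``."""
        return [o for o in self.lineages if self.name_at(o, rank) == name]


@dataclass
class SampleMetadata:
    """Per-sample factor table (host species, location, ...)."""

    records: dict[str, dict[str, str]]

    def __post_init__(self) -> None:
        _check_unique(list(self.records), "sample")

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.records

    def __getitem__(self, sample_id: str) -> dict[str, str]:
        return self.records[sample_id]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.records)

    def factor(self, name: str, sample_ids: Sequence[str] | None = None) -> list[str]:
        """Factor values, in table order, for the given (or all) samples."""
        ids = self.sample_ids if sample_ids is None else list(sample_ids)
        missing = [s for s in ids if s not in self.records]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return [self.records[s][name] for s in ids]

    def align(self, table: CountTable) -> tuple[CountTable, "SampleMetadata", dict[str, list[str]]]:
        """Intersect a count table with this metadata on sample id.

        Returns the restricted table and metadata plus a report of samples
        dropped from each side.
        """
        common = [s for s in table.sample_ids if s in self.records]
        dropped_from_table = [s for s in table.sample_ids if s not in self.records]
        dropped_from_meta = [s for s in self.records if s not in set(table.sample_ids)]
        if not common:
            raise ValidationError("no samples shared between table and metadata")
        sub = table.subset_samples(common)
        meta = SampleMetadata({s: dict(self.records[s]) for s in common})
        report = {"dropped_from_table": dropped_from_table, "dropped_from_metadata": dropped_from_meta}
        return sub, meta, report


@dataclass
class Tree:
    """Rooted tree with uniquely named leaves and non-negative branch lengths."""

    root: skbio.TreeNode

    def __post_init__(self) -> None:
        names = self.leaf_names()
        _check_unique(names, "leaf")
        n_missing = 0
        for node in self.root.traverse(include_self=False):
            if node.length is None:
                node.length = 0.0
                n_missing += 1
            elif node.length < 0:
                raise ValidationError(f"negative branch length at node {node.name!r}")
        if n_missing:
            warnings.warn(f"{n_missing} branches had no length; treated as 0", stacklevel=2)

    def leaf_names(self) -> list[str]:
        return [tip.name for tip in self.root.tips()]

    def total_branch_length(self) -> float:
        return float(sum(node.length or 0.0 for node in self.root.traverse(include_self=False)))


# ---------------------------------------------------------------------------
# readers / writers


def _read_classic_tsv(path: Path) -> tuple[CountTable, TaxonomyMap | None]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        if line.startswith("#"):
            header_idx = i  # last comment line before data is the header
            continue
        if header_idx is None:
            header_idx = i
        break
    if header_idx is None:
        raise ParseError(f"{path}: no header line found")
    header = lines[header_idx].lstrip("#").rstrip("\n").split("\t")
    if len(header) < 2:
        raise ParseError(f"{path}: malformed header at line {header_idx + 1}: need id column plus samples")
    has_taxonomy = header[-1].strip().lower() in _TAXONOMY_COLUMN_NAMES
    sample_ids = header[1:-1] if has_taxonomy else header[1:]
    if not sample_ids:
        raise ParseError(f"{path}: header at line {header_idx + 1} has no sample columns")
    otu_ids: list[str] = []
    rows: list[list[int]] = []
    lineages: dict[str, list[tuple[str, str]]] = {}
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        expected = len(sample_ids) + 1 + int(has_taxonomy)
        if len(fields) != expected:
            raise ParseError(f"{path}: line {lineno} has {len(fields)} fields, expected {expected}")
        otu = fields[0]
        values = fields[1 : 1 + len(sample_ids)]
        row = []
        for sample, raw in zip(sample_ids, values):
            try:
                val = float(raw)
            except ValueError:
                raise ValidationError(
                    f"{path}: non-numeric count {raw!r} at OTU {otu!r}, sample {sample!r} (line {lineno})"
                ) from None
            if val < 0:
                raise ValidationError(
                    f"{path}: negative count at OTU {otu!r}, sample {sample!r} (line {lineno})"
                )
            if val != int(val):
                raise ValidationError(
                    f"{path}: fractional count {raw!r} at OTU {otu!r}, sample {sample!r} (line {lineno})"
                )
            row.append(int(val))
        otu_ids.append(otu)
        rows.append(row)
        if has_taxonomy:
            lineages[otu] = parse_lineage(fields[-1])
    if not rows:
        raise ParseError(f"{path}: no data rows")
    counts = np.asarray(rows, dtype=np.int64).T  # file is OTUs x samples
    table = CountTable(sample_ids, otu_ids, counts)
    taxonomy = TaxonomyMap(lineages) if has_taxonomy else None
    return table, taxonomy


def _read_biom_json(path: Path) -> tuple[CountTable, TaxonomyMap | None]:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from exc
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise ParseError(f"{path}: BIOM-JSON missing key {key!r}")
    otu_ids = [r["id"] for r in doc["rows"]]
    sample_ids = [c["id"] for c in doc["columns"]]
    n_obs, n_samp = doc["shape"]
    if (n_obs, n_samp) != (len(otu_ids), len(sample_ids)):
        raise ParseError(f"{path}: shape {doc['shape']} disagrees with rows/columns lists")
    dense = np.zeros((n_obs, n_samp), dtype=float)
    if doc["matrix_type"] == "dense":
        dense = np.asarray(doc["data"], dtype=float)
        if dense.shape != (n_obs, n_samp):
            raise ParseError(f"{path}: dense data shape {dense.shape} != declared {doc['shape']}")
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = v
    else:
        raise ParseError(f"{path}: unsupported matrix_type {doc['matrix_type']!r}")
    table = CountTable(sample_ids, otu_ids, dense.T)
    lineages: dict[str, list[tuple[str, str]]] = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax is not None:
            text = tax if isinstance(tax, str) else "; ".join(tax)
            lineages[row["id"]] = parse_lineage(text)
    taxonomy = TaxonomyMap(lineages) if lineages else None
    return table, taxonomy


def read_count_table(
    path: str | Path, format: str = "classic-tsv"
) -> tuple[CountTable, TaxonomyMap | None]:
    """Read a sample-by-OTU count table.

    Parameters
    ----------
    path : str or Path
    format : {"classic-tsv", "biom-json"}

    Returns
    -------
    (CountTable, TaxonomyMap or None)
        Orientation is normalized to samples x OTUs; a taxonomy column or
        row-metadata taxonomy, if present, is parsed into a TaxonomyMap.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "classic-tsv":
        return _read_classic_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(
    table: CountTable,
    path: str | Path,
    taxonomy: TaxonomyMap | None = None,
) -> None:
    """Write a classic tab-separated OTU table (OTU rows, sample columns)."""
    path = Path(path)
    with open(path, "w") as fh:
        header = ["#OTU ID", *table.sample_ids]
        if taxonomy is not None:
            header.append("taxonomy")
        fh.write("\t".join(header) + "\n")
        for j, otu in enumerate(table.otu_ids):
            row = [otu, *(str(int(v)) for v in table.counts[:, j])]
            if taxonomy is not None:
                row.append(format_lineage(taxonomy[otu]) if otu in taxonomy else "")
            fh.write("\t".join(row) + "\n")


def read_metadata(path: str | Path, sample_id_column: str = "sample_id") -> SampleMetadata:
    """Read per-sample metadata from a TSV/CSV file with a sample_id column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    candidates = [sample_id_column, "#SampleID", "SampleID", "sample-id", "sample"]
    id_col = next((c for c in candidates if c in df.columns), None)
    if id_col is None:
        raise ValidationError(f"{path}: no sample id column among {candidates}")
    ids = df[id_col].tolist()
    _check_unique(ids, "sample")
    records = {
        str(row[id_col]): {c: str(row[c]) for c in df.columns if c != id_col}
        for _, row in df.iterrows()
    }
    return SampleMetadata(records)


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    rows = [{"sample_id": s, **facts} for s, facts in meta.records.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path) -> Tree:
    """Read a rooted Newick tree; missing branch lengths become 0 (warned)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        root = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises its own parse errors
        raise ParseError(f"{path}: invalid Newick: {exc}") from exc
    return Tree(root)


def write_newick(tree: Tree, path: str | Path) -> None:
    tree.root.write(str(path), format="newick")
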