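"""Synthetic count-table generator with the statistical structure the
community-assembly analysis assumes.

The default generator draws, per sample and OTU, a latent relative abundance
from the stationary beta distribution Beta(N m p, N m (1 - p)) and then
binomial read counts at a per-sample depth. The discrete birth-death-
immigration chain (``simulate_hubbell_process``) is the slower, independent
cross-check of that shortcut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from neutralcomm.core_io import CountTable, SampleMetadata, TaxonomyMap, parse_lineage, ValidationError
from neutralcomm.neutral_model import predict_occurrence_neutral

_SHAPE_FLOOR = 1e-9


@dataclass
class SpikeSpec:
    """A deliberately non-neutral OTU: occurrence offset applied to one index."""

    otu_index: int
    direction: str  # "above" or "below"
    delta: float

    def __post_init__(self) -> None:
        if self.direction not in ("above", "below"):
            raise ValidationError(f"direction must be 'above' or 'below', got {self.direction!r}")
        if self.delta <= 0:
            raise ValidationError("occurrence offset delta must be positive")


@dataclass
class SimulationConfig:
    """All parameters and the seed for the synthetic community generator."""

    n_taxa: int = 300
    n_samples: int = 30
    metacommunity: str = "lognormal"  # or "logseries"
    # sigma = 3 gives the strongly skewed rank-abundance curve typical of
    # amplicon surveys and spreads OTUs across the whole occurrence range,
    # which keeps the migration rate well identified
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 3.0
    logseries_theta: float = 0.99
    m: float = 0.1
    N_local: float = 10000.0
    depth_low: int = 20000
    depth_high: int = 60000
    spiked: list[SpikeSpec] = field(default_factory=list)
    host_fraction: float = 0.0
    prey_fraction: float = 0.124
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_taxa < 1 or self.n_samples < 1:
            raise ValidationError("n_taxa and n_samples must be >= 1")
        if not 0 < self.m <= 1:
            raise ValidationError(f"m must be in (0, 1], got {self.m}")
        if self.N_local <= 0:
            raise ValidationError("N_local must be positive")
        if self.depth_low < 1 or self.depth_high < self.depth_low:
            raise ValidationError("need 1 <= depth_low <= depth_high")
        if not 0 <= self.host_fraction < 1:
            raise ValidationError("host_fraction must be in [0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def sample_metacommunity(config: SimulationConfig, seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Metacommunity relative-abundance vector from the configured family."""
    rng = _rng(config.seed if seed is None else seed)
    n = config.n_taxa
    if n == 1:
        return np.ones(1)
    if config.metacommunity == "lognormal":
        if config.lognormal_sigma < 0:
            raise ValidationError("lognormal sigma must be >= 0")
        if config.lognormal_sigma == 0:
            weights = np.ones(n)
        else:
            weights = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)
    elif config.metacommunity == "logseries":
        theta = config.logseries_theta
        if not 0 < theta < 1:
            raise ValidationError("logseries theta must be in (0, 1)")
        weights = rng.logseries(theta, size=n).astype(float)
    else:
        raise ValidationError(f"unknown metacommunity family {config.metacommunity!r}")
    if (weights <= 0).any() or weights.sum() <= 0:
        raise ValidationError("degenerate metacommunity draw")
    return weights / weights.sum()


def _otu_ids(n: int) -> list[str]:
    return [f"OTU_{i + 1:05d}" for i in range(n)]


def _sample_ids(n: int) -> list[str]:
    return [f"S{i + 1:04d}" for i in range(n)]


def draw_depths(config: SimulationConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(config.depth_low, config.depth_high + 1, size=n)


def simulate_neutral_table(
    p: np.ndarray,
    m: float,
    N_local: float,
    n_samples: int,
    depths: Sequence[int] | int,
    seed: int | np.random.Generator | None = None,
    sample_ids: list[str] | None = None,
    otu_ids: list[str] | None = None,
    detection: str = "threshold",
) -> CountTable:
    """Neutral local communities: beta-distributed latent abundances plus
    binomial read sampling.

    For sample j and OTU i, x_ij ~ Beta(N m p_i, N m (1 - p_i)) independently
    and counts c_ij ~ Binomial(depth_j, x_ij). Deterministic under a fixed
    seed.

    ``detection="threshold"`` (default) applies the model's own detection
    limit d = 1/N_local: an OTU is present in a sample iff x_ij >= d (counts
    below the limit are zeroed; detected OTUs carry at least one read). This
    keeps empirical occurrence frequencies exactly consistent with the
    occurrence predictor. ``detection="binomial"`` leaves raw binomial
    counts, whose presence/absence is smoother than the threshold rule for
    rare OTUs.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValidationError("metacommunity abundances must sum to 1")
    if not 0 < m <= 1:
        raise ValidationError(f"m must be in (0, 1], got {m}")
    rng = _rng(seed)
    if np.isscalar(depths):
        depths = np.full(n_samples, int(depths))
    else:
        depths = np.asarray(depths, dtype=np.int64)
        if len(depths) != n_samples:
            raise ValidationError("depths length must equal n_samples")
    alpha = N_local * m * p
    beta = N_local * m * (1.0 - p)
    if (alpha < _SHAPE_FLOOR).any() or (beta < _SHAPE_FLOOR).any():
        import warnings

        warnings.warn("beta shape parameter underflow; clamping", stacklevel=2)
        alpha = np.clip(alpha, _SHAPE_FLOOR, None)
        beta = np.clip(beta, _SHAPE_FLOOR, None)
    x = rng.beta(alpha[None, :], beta[None, :], size=(n_samples, len(p)))
    counts = rng.binomial(depths[:, None], x)
    if detection == "threshold":
        present = x >= 1.0 / N_local
        counts[~present] = 0
        counts[present] = np.maximum(counts[present], 1)
    elif detection != "binomial":
        raise ValidationError(f"unknown detection rule {detection!r}")
    return CountTable(
        sample_ids or _sample_ids(n_samples),
        otu_ids or _otu_ids(len(p)),
        counts,
    )


def simulate_binomial_table(
    p: np.ndarray,
    n_samples: int,
    depths: Sequence[int] | int,
    seed: int | np.random.Generator | None = None,
) -> CountTable:
    """Local communities as plain binomial subsamples of the metacommunity.

    No dispersal, no drift: c_ij ~ Binomial(depth_j, p_i). This is the
    ground-truth generator for the binomial null model.
    """
    p = np.asarray(p, dtype=float)
    if not np.isclose(p.sum(), 1.0):
        raise ValidationError("metacommunity abundances must sum to 1")
    rng = _rng(seed)
    if np.isscalar(depths):
        depths = np.full(n_samples, int(depths))
    else:
        depths = np.asarray(depths, dtype=np.int64)
    counts = rng.binomial(depths[:, None], p[None, :])
    return CountTable(_sample_ids(n_samples), _otu_ids(len(p)), counts)


def simulate_hubbell_process(
    p: np.ndarray,
    m: float,
    N_local: int,
    generations: int | None = None,
    seed: int | np.random.Generator | None = None,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Discrete zero-sum birth-death-immigration chain for one local community.

    Each event kills one individual uniformly at random; with probability m
    the replacement immigrates from the metacommunity ``p``, otherwise it is
    the offspring of a random survivor. Returns final per-OTU abundances
    (sums to ``N_local``). Default run length is 50 * N_local death events.
    """
    p = np.asarray(p, dtype=float)
    if not 0 <= m <= 1:
        raise ValidationError(f"m must be in [0, 1], got {m}")
    rng = _rng(seed)
    n_taxa = len(p)
    # individual-based representation: labels[i] is the taxon of individual i
    if init is None:
        counts = rng.multinomial(N_local, p)
    else:
        counts = np.asarray(init, dtype=np.int64)
        if counts.sum() != N_local:
            raise ValidationError("initial community must sum to N_local")
    labels = np.repeat(np.arange(n_taxa), counts)
    if generations is None:
        generations = 50 * N_local
    deaths = rng.integers(0, N_local, size=generations)
    immigration = rng.random(generations) < m
    immigrants = rng.choice(n_taxa, size=generations, p=p)
    parents = rng.integers(0, N_local - 1, size=generations)
    for step in range(generations):
        i = deaths[step]
        if immigration[step]:
            labels[i] = immigrants[step]
        else:
            j = parents[step]
            if j >= i:  # parent drawn uniformly among the survivors
                j += 1
            labels[i] = labels[j]
    return np.bincount(labels, minlength=n_taxa).astype(np.int64)


def spike_selected_otus(
    table: CountTable,
    p: np.ndarray,
    m: float,
    N_local: float,
    d: float,
    spiked: Sequence[SpikeSpec],
    seed: int | np.random.Generator | None = None,
) -> CountTable:
    """Inject known non-neutral OTUs by re-drawing their per-sample presence.

    For an "above" spike the OTU's presence probability is raised to
    min(1, f_pred + delta); for "below" it is thinned to max(0, f_pred -
    delta). Samples made present receive counts from the OTU's conditional
    abundance distribution; reads removed by a "below" spike are
    redistributed among the samples where the OTU remains present, so the
    OTU stays abundant in the metacommunity while occurring in few samples
    (the negative-selection signature). All other OTUs are untouched.
    """
    p = np.asarray(p, dtype=float)
    rng = _rng(seed)
    counts = table.counts.copy()
    depths = table.sample_totals()
    for spec in spiked:
        i = spec.otu_index
        if not 0 <= i < table.n_otus:
            raise ValidationError(f"spiked OTU index {i} out of range")
        f_pred = float(predict_occurrence_neutral(p[i], N_local, m, d))
        if spec.direction == "above":
            target = min(1.0, f_pred + spec.delta)
        else:
            target = max(0.0, f_pred - spec.delta)
        present = rng.random(table.n_samples) < target
        alpha = max(N_local * m * p[i], _SHAPE_FLOOR)
        beta = max(N_local * m * (1.0 - p[i]), _SHAPE_FLOOR)
        removed_reads = 0
        for j in range(table.n_samples):
            if present[j] and counts[j, i] == 0:
                x = rng.beta(alpha, beta)
                c = rng.binomial(max(int(depths[j]), 1), x)
                counts[j, i] = max(c, 1)
            elif not present[j]:
                removed_reads += int(counts[j, i])
                counts[j, i] = 0
        if spec.direction == "below" and removed_reads and present.any():
            # keep the OTU's metacommunity abundance: reallocate removed
            # reads among the samples where it remains present, producing
            # the abundant-but-restricted negative-selection signature
            weights = counts[present, i].astype(float) + 1.0
            extra = rng.multinomial(removed_reads, weights / weights.sum())
            counts[present, i] += extra
    return CountTable(list(table.sample_ids), list(table.otu_ids), counts)


def simulate_diet_table(
    config: SimulationConfig, seed: int | np.random.Generator | None = None
) -> tuple[CountTable, TaxonomyMap]:
    """Diet-style table: one host-order OTU dominating every sample.

    The host OTU receives ``host_fraction`` of each sample's reads; prey OTUs
    share the remainder via the neutral generator. With host_fraction = 0 no
    host OTU is emitted.
    """
    rng = _rng(config.seed if seed is None else seed)
    p = sample_metacommunity(config, rng)
    total_depths = draw_depths(config, config.n_samples, rng)
    host_reads = np.round(config.host_fraction * total_depths).astype(np.int64)
    prey_depths = total_depths - host_reads
    prey = simulate_neutral_table(
        p, config.m, config.N_local, config.n_samples, prey_depths, rng
    )
    lineages = {
        o: parse_lineage("k__Animalia; p__Arthropoda; c__Insecta; o__Diptera")
        for o in prey.otu_ids
    }
    if config.host_fraction == 0:
        return prey, TaxonomyMap(lineages)
    host_id = "OTU_HOST"
    counts = np.hstack([host_reads[:, None], prey.counts])
    table = CountTable(list(prey.sample_ids), [host_id, *prey.otu_ids], counts)
    lineages[host_id] = parse_lineage("k__Animalia; p__Arthropoda; c__Insecta; o__Odonata")
    return table, TaxonomyMap(lineages)


def simulate_dataset(
    config: SimulationConfig,
    groups: dict[str, dict] | None = None,
) -> tuple[CountTable, SampleMetadata, np.ndarray]:
    """Full synthetic dataset: metacommunity, neutral table, optional spikes,
    and per-sample metadata.

    ``groups`` maps a group label to parameter overrides (``m``, or
    ``metacommunity_seed`` for a disjoint metacommunity); samples are split
    evenly across groups. Returns (table, metadata, metacommunity p of the
    first/only group).
    """
    rng = _rng(config.seed)
    if not groups:
        p = sample_metacommunity(config, rng)
        depths = draw_depths(config, config.n_samples, rng)
        table = simulate_neutral_table(p, config.m, config.N_local, config.n_samples, depths, rng)
        if config.spiked:
            d = 1.0 / float(depths.mean())
            table = spike_selected_otus(table, p, config.m, config.N_local, d, config.spiked, rng)
        meta = SampleMetadata(
            {s: {"group": "all", "location": "sim", "species": "sim"} for s in table.sample_ids}
        )
        return table, meta, p

    labels = list(groups)
    per_group = config.n_samples // len(labels)
    tables = []
    records = {}
    first_p = None
    offset = 0
    for label in labels:
        override = groups[label]
        sub_rng = np.random.default_rng(rng.integers(0, 2**63 - 1))
        p = sample_metacommunity(config, sub_rng)
        if first_p is None:
            first_p = p
        m = float(override.get("m", config.m))
        depths = draw_depths(config, per_group, sub_rng)
        sample_ids = [f"S{offset + i + 1:04d}" for i in range(per_group)]
        tbl = simulate_neutral_table(
            p, m, config.N_local, per_group, depths, sub_rng, sample_ids=sample_ids
        )
        tables.append(tbl)
        for s in sample_ids:
            records[s] = {"group": label, "location": label, "species": label}
        offset += per_group
    counts = np.vstack([t.counts for t in tables])
    all_samples = [s for t in tables for s in t.sample_ids]
    table = CountTable(all_samples, list(tables[0].otu_ids), counts)
    return table, SampleMetadata(records), first_p
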