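"""Sloan neutral community model: occurrence-abundance fitting and OTU
classification.

The model predicts, for an OTU at metacommunity relative abundance ``p``,
the fraction of local communities in which it is detected:

    f_pred = 1 - BetaCDF(d; N*m*p, N*m*(1 - p))

with ``N`` the effective local community size (mean per-sample reads), ``d``
the detection limit (1/N) and ``m`` the migration rate. ``m`` is estimated by
bounded least squares against observed occurrence frequencies; OTUs are
classified neutral / above (positive selection) / below (negative selection)
against Wilson score intervals around the fitted curve. A binomial null
(local communities as plain subsamples of the metacommunity, no dispersal
or drift) is fitted for model comparison via R^2 and AIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from neutralcomm.core_io import CountTable, SampleMetadata, TaxonomyMap, RANKS, ValidationError

CLASS_NEUTRAL = "neutral"
CLASS_ABOVE = "above"
CLASS_BELOW = "below"


@dataclass
class MetacommunitySummary:
    """Occurrence-abundance summary of a set of local communities."""

    otu_ids: list[str]
    p: np.ndarray  # metacommunity relative abundance per OTU
    f_obs: np.ndarray  # observed occurrence frequency per OTU
    N: float  # effective local community size (mean per-sample reads)
    d: float  # detection limit, 1/N
    n_local: int  # number of local communities

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.f_obs = np.asarray(self.f_obs, dtype=float)
        if not math.isclose(float(self.p.sum()), 1.0, rel_tol=0, abs_tol=1e-8):
            raise ValidationError(f"metacommunity abundances must sum to 1, got {self.p.sum()}")
        if ((self.f_obs < 0) | (self.f_obs > 1)).any():
            raise ValidationError("occurrence frequencies must lie in [0, 1]")
        if self.N <= 0 or not 0 < self.d < 1:
            raise ValidationError("need N > 0 and d in (0, 1)")
        if self.n_local < 2:
            raise ValidationError("need at least 2 local communities")


@dataclass
class NeutralFitResult:
    """Fitted migration rate with predictions, CIs and per-OTU classes."""

    m: float
    m_se: float
    f_pred: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    ci_level: float
    classes: list[str]
    neutral_fraction: float
    above_fraction: float
    below_fraction: float
    r2_neutral: float
    r2_binomial: float
    aic_neutral: float
    aic_binomial: float
    converged: bool
    otu_ids: list[str] = field(default_factory=list)
    summary: "MetacommunitySummary | None" = None

    def class_fractions(self) -> dict[str, float]:
        return {
            CLASS_NEUTRAL: self.neutral_fraction,
            CLASS_ABOVE: self.above_fraction,
            CLASS_BELOW: self.below_fraction,
        }

    def to_frame(self, summary: MetacommunitySummary | None = None) -> pd.DataFrame:
        summary = summary if summary is not None else self.summary
        if summary is None:
            raise ValidationError("no metacommunity summary attached to this fit")
        return pd.DataFrame(
            {
                "otu_id": summary.otu_ids,
                "p": summary.p,
                "f_obs": summary.f_obs,
                "f_pred": self.f_pred,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "class": self.classes,
            }
        )


def prepare_metacommunity(table: CountTable, abundance: str = "reads") -> MetacommunitySummary:
    """Occurrence-abundance summary of a count table.

    ``abundance="reads"`` pools reads across samples (reads-weighted);
    ``"mean"`` averages per-sample proportions. N is the mean per-sample
    total and the detection limit is 1/N. OTUs with no reads anywhere are
    absent from the metacommunity and are dropped.
    """
    if table.n_samples < 2:
        raise ValidationError("occurrence frequency undefined for a single sample")
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValidationError(f"zero-total samples: {bad}")
    observed = table.otu_totals() > 0
    if not observed.all():
        table = table.subset_otus([o for o, keep in zip(table.otu_ids, observed) if keep])
    if abundance == "reads":
        p = table.otu_totals() / table.grand_total()
    elif abundance == "mean":
        p = (table.counts / totals[:, None]).mean(axis=0)
        p = p / p.sum()
    else:
        raise ValueError(f"unknown abundance basis {abundance!r}")
    f_obs = (table.counts > 0).mean(axis=0)
    n = float(totals.mean())
    return MetacommunitySummary(
        otu_ids=list(table.otu_ids), p=p, f_obs=f_obs, N=n, d=1.0 / n, n_local=table.n_samples
    )


def predict_occurrence_neutral(
    p: float | np.ndarray, N: float, m: float, d: float
) -> float | np.ndarray:
    """Neutral expected occurrence 1 - BetaCDF(d; N m p, N m (1 - p))."""
    p_arr = np.asarray(p, dtype=float)
    if N <= 0 or not 0 < d < 1:
        raise ValidationError("need N > 0 and d in (0, 1)")
    if not 0 < m <= 1:
        raise ValidationError(f"m must be in (0, 1], got {m}")
    if ((p_arr <= 0) | (p_arr >= 1)).any():
        raise ValidationError("abundances must lie strictly in (0, 1)")
    alpha = N * m * p_arr
    beta = N * m * (1.0 - p_arr)
    if (alpha <= 0).any() or (beta <= 0).any():
        raise ValidationError("beta shape parameters must be positive")
    out = stats.beta.sf(d, alpha, beta)
    return float(out) if np.isscalar(p) else out


def predict_occurrence_binomial(
    p: float | np.ndarray, N: float, d: float, detection: str = "abundance"
) -> float | np.ndarray:
    """Occurrence under plain binomial subsampling of the metacommunity.

    ``detection="abundance"`` (default) detects an OTU when its sampled
    relative abundance reaches d, i.e. P(X >= ceil(N*d)) = P(X > ceil(N*d) -
    1) with X ~ Bin(round(N), p); at d = 1/N this is the one-read rule
    P(X >= 1), consistent with the neutral model's threshold detection.
    ``detection="floor-cutoff"`` uses the stricter P(X > floor(N*d)).
    """
    p_arr = np.asarray(p, dtype=float)
    if N <= 0 or not 0 < d < 1:
        raise ValidationError("need N > 0 and d in (0, 1)")
    if ((p_arr < 0) | (p_arr > 1)).any():
        raise ValidationError("abundances must lie in [0, 1]")
    n_trials = int(round(N))
    if detection == "abundance":
        k = max(int(math.ceil(N * d)) - 1, 0)
    elif detection == "floor-cutoff":
        k = int(math.floor(N * d))
    else:
        raise ValueError(f"unknown detection rule {detection!r}")
    out = stats.binom.sf(k, n_trials, p_arr)
    return float(out) if np.isscalar(p) else out


def _sse_neutral(m: float, summary: MetacommunitySummary) -> float:
    pred = predict_occurrence_neutral(summary.p, summary.N, m, summary.d)
    return float(((summary.f_obs - pred) ** 2).sum())


def _gaussian_aic(sse: float, n: int, k: int) -> float:
    """AIC from a Gaussian residual likelihood: n ln(SSE/n) + 2k."""
    sse = max(sse, 1e-300)
    return n * math.log(sse / n) + 2 * k


_M_LOWER = 1e-6
_M_STARTS = (0.1, 0.01, 0.5)


def fit_neutral(
    summary: MetacommunitySummary,
    init_m: float = 0.1,
    ci_level: float = 99.0,
    binomial_detection: str = "abundance",
) -> NeutralFitResult:
    """Least-squares estimate of the migration rate plus OTU classification.

    Minimizes the occurrence-frequency SSE over m in (1e-6, 1], with
    multi-start if the first start fails. Non-convergence yields a flagged
    result rather than an exception. R^2 = 1 - SSE / SS_tot; AIC from the
    Gaussian residual likelihood with k = 2 (neutral: m + residual variance)
    and k = 1 (binomial).
    """
    n = len(summary.p)
    if n < 10:
        warnings.warn(f"only {n} OTUs; fit may be unstable", stacklevel=2)
    if np.allclose(summary.f_obs, summary.f_obs[0]):
        raise ValidationError("occurrence frequencies are all identical; nothing to fit")
    inside = (summary.p > 0) & (summary.p < 1)
    if not inside.all():
        raise ValidationError("metacommunity abundances must be strictly inside (0, 1)")

    converged = False
    best_m = float(init_m)
    best_sse = np.inf
    for start in (init_m, *_M_STARTS):
        res = optimize.minimize_scalar(
            _sse_neutral,
            bounds=(_M_LOWER, 1.0),
            args=(summary,),
            method="bounded",
            options={"xatol": 1e-10, "maxiter": 500},
        )
        if res.success and res.fun < best_sse:
            best_m = float(res.x)
            best_sse = float(res.fun)
            converged = True
        if converged:
            break
    if not converged:
        best_sse = _sse_neutral(best_m, summary)

    f_pred = np.asarray(predict_occurrence_neutral(summary.p, summary.N, best_m, summary.d))
    sse = float(((summary.f_obs - f_pred) ** 2).sum())
    ss_tot = float(((summary.f_obs - summary.f_obs.mean()) ** 2).sum())
    r2_neutral = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")

    # curvature-based standard error of m (Gaussian residuals)
    eps = max(1e-6, best_m * 1e-4)
    lo, hi = max(_M_LOWER, best_m - eps), min(1.0, best_m + eps)
    try:
        second = (
            _sse_neutral(hi, summary) - 2 * sse + _sse_neutral(lo, summary)
        ) / ((hi - best_m) * (best_m - lo))
        sigma2 = sse / max(n - 1, 1)
        m_se = math.sqrt(2 * sigma2 / second) if second > 0 else float("nan")
    except (ValueError, ZeroDivisionError):
        m_se = float("nan")

    f_binom = np.asarray(
        predict_occurrence_binomial(summary.p, summary.N, summary.d, binomial_detection)
    )
    sse_binom = float(((summary.f_obs - f_binom) ** 2).sum())
    r2_binom = 1.0 - sse_binom / ss_tot if ss_tot > 0 else float("nan")

    aic_neutral = _gaussian_aic(sse, n, k=2)
    aic_binom = _gaussian_aic(sse_binom, n, k=1)

    lower, upper = wilson_interval(f_pred, summary.n_local, ci_level)
    classes = _classify(summary.f_obs, lower, upper)
    fractions = _fractions(classes)

    return NeutralFitResult(
        m=best_m,
        m_se=m_se,
        f_pred=f_pred,
        ci_lower=lower,
        ci_upper=upper,
        ci_level=ci_level,
        classes=classes,
        neutral_fraction=fractions[CLASS_NEUTRAL],
        above_fraction=fractions[CLASS_ABOVE],
        below_fraction=fractions[CLASS_BELOW],
        r2_neutral=r2_neutral,
        r2_binomial=r2_binom,
        aic_neutral=aic_neutral,
        aic_binomial=aic_binom,
        converged=converged,
        otu_ids=list(summary.otu_ids),
        summary=summary,
    )


def wilson_interval(
    p_hat: np.ndarray | float, n: int, level: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson score interval for a proportion ``p_hat`` observed over ``n`` trials."""
    if not 0 < level < 100:
        raise ValidationError(f"confidence level must be in (0, 100), got {level}")
    p_arr = np.clip(np.asarray(p_hat, dtype=float), 0.0, 1.0)
    z = stats.norm.ppf(0.5 + level / 200.0)
    denom = 1.0 + z**2 / n
    center = (p_arr + z**2 / (2 * n)) / denom
    half = (z / denom) * np.sqrt(p_arr * (1 - p_arr) / n + z**2 / (4 * n**2))
    return np.clip(center - half, 0.0, 1.0), np.clip(center + half, 0.0, 1.0)


def jeffreys_interval(
    p_hat: np.ndarray | float, n: int, level: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Jeffreys (Beta(1/2, 1/2) posterior) interval, offered as an alternative."""
    p_arr = np.clip(np.asarray(p_hat, dtype=float), 0.0, 1.0)
    successes = p_arr * n
    alpha = 1.0 - level / 100.0
    lower = stats.beta.ppf(alpha / 2, successes + 0.5, n - successes + 0.5)
    upper = stats.beta.ppf(1 - alpha / 2, successes + 0.5, n - successes + 0.5)
    return np.nan_to_num(lower, nan=0.0), np.nan_to_num(upper, nan=1.0)


def prediction_band(
    p_hat: np.ndarray | float, n: int, level: float = 95.0
) -> tuple[np.ndarray, np.ndarray]:
    """Exact binomial prediction band for an observed occurrence frequency.

    Bounds are binomial quantiles of X/n at X ~ Bin(n, p_hat). Unlike the
    Wilson interval around the prediction, this band is calibrated as an
    acceptance region for observed frequencies: by construction the
    probability of an observation falling outside is at most 1 - level/100,
    including at the occupancy boundaries f = 0 and f = 1.
    """
    p_arr = np.clip(np.asarray(p_hat, dtype=float), 0.0, 1.0)
    alpha = 1.0 - level / 100.0
    lower = stats.binom.ppf(alpha / 2, n, p_arr) / n
    upper = stats.binom.ppf(1 - alpha / 2, n, p_arr) / n
    return lower, upper


def _classify(f_obs: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> list[str]:
    # boundary equality is conservative: exactly on a bound counts as neutral
    out = []
    for f, lo, hi in zip(f_obs, lower, upper):
        if f > hi:
            out.append(CLASS_ABOVE)
        elif f < lo:
            out.append(CLASS_BELOW)
        else:
            out.append(CLASS_NEUTRAL)
    return out


def _fractions(classes: Sequence[str]) -> dict[str, float]:
    n = len(classes)
    return {
        c: sum(1 for x in classes if x == c) / n
        for c in (CLASS_NEUTRAL, CLASS_ABOVE, CLASS_BELOW)
    }


def classify_otus(
    summary: MetacommunitySummary,
    fit: NeutralFitResult,
    level: float = 99.0,
    interval: str = "wilson",
    allow_any_level: bool = False,
) -> tuple[list[str], dict[str, float]]:
    """Re-classify OTUs at a stated confidence level against the fitted curve.

    ``interval`` selects the band: "wilson" (score interval around the
    predicted frequency; the convention of the published fitting script),
    "jeffreys", or "prediction" (exact binomial prediction band, calibrated
    at the occupancy boundaries).
    """
    if level not in (95.0, 99.0, 95, 99) and not allow_any_level:
        raise ValidationError(f"level must be 95 or 99 (got {level}); pass allow_any_level=True to override")
    if not fit.converged:
        raise ValidationError("fit did not converge; classification unavailable")
    ci_fn = {
        "wilson": wilson_interval,
        "jeffreys": jeffreys_interval,
        "prediction": prediction_band,
    }[interval]
    lower, upper = ci_fn(fit.f_pred, summary.n_local, float(level))
    classes = _classify(summary.f_obs, lower, upper)
    return classes, _fractions(classes)


def compare_models(summary: MetacommunitySummary, **fit_kwargs) -> pd.DataFrame:
    """R^2 / AIC comparison of the neutral fit against the binomial null."""
    fit = fit_neutral(summary, **fit_kwargs)
    rows = [
        {"model": "neutral", "R2": fit.r2_neutral, "AIC": fit.aic_neutral},
        {"model": "binomial", "R2": fit.r2_binomial, "AIC": fit.aic_binomial},
    ]
    out = pd.DataFrame(rows)
    out["dAIC"] = out["AIC"] - out["AIC"].min()
    out["preferred"] = out["AIC"] == out["AIC"].min()
    return out


def fit_per_group(
    table: CountTable,
    metadata: SampleMetadata,
    group_by: str | Sequence[str] = "location",
    level: float = 99.0,
    abundance: str = "reads",
    min_samples: int = 2,
    drop_absent_otus: bool = True,
    **fit_kwargs,
) -> tuple[dict[str, NeutralFitResult], dict[str, float]]:
    """Independent metacommunity fit per sample group.

    ``group_by`` may be one factor name or several (crossed groups, joined
    with "/"). Groups with fewer than ``min_samples`` samples are skipped
    with a warning. Returns per-group fits and a summary holding each
    group's neutral fraction plus their unweighted mean and sd.
    """
    factors = [group_by] if isinstance(group_by, str) else list(group_by)
    labels = []
    for s in table.sample_ids:
        if s not in metadata:
            raise ValidationError(f"sample {s!r} missing from metadata")
        labels.append("/".join(metadata[s][f] for f in factors))
    groups: dict[str, list[str]] = {}
    for s, lab in zip(table.sample_ids, labels):
        groups.setdefault(lab, []).append(s)

    fits: dict[str, NeutralFitResult] = {}
    fractions: dict[str, float] = {}
    for lab, samples in groups.items():
        if len(samples) < min_samples:
            warnings.warn(f"group {lab!r} has {len(samples)} samples; skipped", stacklevel=2)
            continue
        sub = table.subset_samples(samples)
        if drop_absent_otus:
            present = [o for o, t in zip(sub.otu_ids, sub.otu_totals()) if t > 0]
            sub = sub.subset_otus(present)
        summary = prepare_metacommunity(sub, abundance=abundance)
        fit = fit_neutral(summary, ci_level=float(level), **fit_kwargs)
        fits[lab] = fit
        fractions[lab] = fit.neutral_fraction
    if not fits:
        raise ValidationError("no group had enough samples to fit")
    values = np.array(list(fractions.values()))
    summary_stats = {
        **fractions,
        "mean_neutral_fraction": float(values.mean()),
        "sd_neutral_fraction": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
    }
    return fits, summary_stats


# ---------------------------------------------------------------------------
# taxonomic distinctness of selection classes


def _lineage_distance(lin_a: Sequence[tuple[str, str]], lin_b: Sequence[tuple[str, str]]) -> float:
    """Taxonomic path length in [0, 100]: 100 * (ranks - shared depth) / ranks."""
    shared = 0
    for (_, a), (_, b) in zip(lin_a, lin_b):
        if a and b and a == b:
            shared += 1
        else:
            break
    return 100.0 * (len(RANKS) - shared) / len(RANKS)


def taxonomic_distinctness(lineages: Sequence[Sequence[tuple[str, str]]]) -> float:
    """Mean pairwise taxonomic path length (Delta+) of a set of lineages."""
    if len(lineages) < 2:
        raise ValidationError("need at least 2 lineages")
    total = 0.0
    count = 0
    for i in range(len(lineages)):
        for j in range(i + 1, len(lineages)):
            total += _lineage_distance(lineages[i], lineages[j])
            count += 1
    return total / count


def compare_class_distinctness(
    class_lineages: Mapping[str, Sequence[Sequence[tuple[str, str]]]],
    n_bootstrap: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Observed Delta+ per class against a pooled-resampling null.

    For each class, the pooled lineages are resampled (without replacement)
    at the class's size ``n_bootstrap`` times; the table reports the observed
    statistic, the null mean, and the two-sided bootstrap p value.
    """
    pooled = [lin for lins in class_lineages.values() for lin in lins]
    rng = np.random.default_rng(seed)
    rows = []
    for label, lins in class_lineages.items():
        if len(lins) < 2:
            warnings.warn(f"class {label!r} has fewer than 2 lineages; skipped", stacklevel=2)
            continue
        observed = taxonomic_distinctness(lins)
        null = []
        for _ in range(n_bootstrap):
            idx = rng.choice(len(pooled), size=len(lins), replace=False)
            null.append(taxonomic_distinctness([pooled[i] for i in idx]))
        null_arr = np.asarray(null)
        tail = min(
            (null_arr <= observed).sum(),
            (null_arr >= observed).sum(),
        )
        p = min(1.0, 2 * (tail + 1) / (n_bootstrap + 1))
        rows.append(
            {
                "class": label,
                "n": len(lins),
                "delta_plus": observed,
                "null_mean": float(null_arr.mean()),
                "null_sd": float(null_arr.std(ddof=1)),
                "p": p,
            }
        )
    return pd.DataFrame(rows)
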