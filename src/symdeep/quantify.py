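"""Normalisation, detection limits, and validation statistics.

Mapped read counts are normalised to percentages of each sample's mapped
reads (controlling for variable read depth), aggregated to type level, and
validated against the known mixture design with:

* a false-positive detection limit from samples designed without a type
  (cutoff = mean FP percent + 2 standard errors, with extreme outliers
  excluded by a mean + k*sd rule);
* the Goodman-Kruskal gamma rank correlation, (Nc - Nd) / (Nc + Nd) over
  concordant/discordant pairs, in its robust form where pairs differing by
  at most a tolerance r count as ties, with permutation-based significance;
* percentile bootstrap confidence intervals for low-abundance groups;
* residual over/under-estimation summaries from the observed~expected
  least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mapping import MAPPED, ReadAssignment, TypeAnnotation


class UndefinedGamma(Exception):
    """No comparable pairs: gamma is undefined."""


@dataclass
class AbundanceTable:
    """Per-sample mapped counts and normalised percentages.

    ``counts`` is a samples x references integer table; reference and type
    percentages are derived per sample as 100 * count / mapped-in-sample.
    Samples with zero mapped reads keep NaN percentages and are listed in
    ``zero_mapped_samples``.
    """

    counts: pd.DataFrame
    reference_percents: pd.DataFrame
    type_percents: pd.DataFrame
    zero_mapped_samples: list[str] = field(default_factory=list)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)


def assignments_to_counts(
    assignments_by_sample: dict[str, list[ReadAssignment]],
) -> pd.DataFrame:
    """Samples x references table of unambiguously mapped read counts."""
    rows = {}
    for sample_id, assignments in assignments_by_sample.items():
        counts: dict[str, int] = {}
        for a in assignments:
            if a.status == MAPPED:
                counts[a.reference_id] = counts.get(a.reference_id, 0) + 1
        rows[sample_id] = counts
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return frame.sort_index(axis=0).sort_index(axis=1)


def normalize_and_aggregate(
    counts: pd.DataFrame, annotations: list[TypeAnnotation]
) -> AbundanceTable:
    """Reference percents per sample; type percents sum member references."""
    known = {a.reference_id for a in annotations}
    unknown = set(counts.columns) - known
    if unknown:
        raise KeyError(f"counts contain unannotated references: {sorted(unknown)}")
    totals = counts.sum(axis=1)
    zero = list(counts.index[totals == 0])
    ref_percents = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    type_of = {a.reference_id: a.type_name for a in annotations}
    type_percents = (
        ref_percents.T.groupby(
            lambda ref_id: type_of.get(ref_id) or "unannotated"
        ).sum(min_count=1).T
    )
    return AbundanceTable(
        counts=counts,
        reference_percents=ref_percents,
        type_percents=type_percents,
        zero_mapped_samples=zero,
    )


# ---------------------------------------------------------------------------
# detection limit


@dataclass
class DetectionLimit:
    """False-positive based detection limit: cutoff = mean FP + 2 SE."""

    fp_values: list[float]
    outliers: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.fp_values:
            raise ValueError("no false-positive observations")

    @property
    def mean_fp(self) -> float:
        return float(np.mean(self.fp_values))

    @property
    def se_fp(self) -> float:
        if len(self.fp_values) < 2:
            return 0.0
        return float(np.std(self.fp_values, ddof=1) / np.sqrt(len(self.fp_values)))

    @property
    def cutoff(self) -> float:
        return detection_cutoff(self.mean_fp, self.se_fp)


def detection_cutoff(mean_fp: float, se_fp: float) -> float:
    """Conservative detection-limit cutoff: mean + 2 standard errors."""
    return mean_fp + 2.0 * se_fp


def estimate_detection_limit(
    abundance: AbundanceTable,
    designs: dict[str, dict[str, float]],
    outlier_k: float = 5.0,
) -> DetectionLimit:
    """Detection limit from types designed absent (fraction 0) in samples.

    Observed percentages of absent types are the false-positive signal.
    A value is flagged as a (biological) outlier and excluded when it
    exceeds mean + ``outlier_k`` * sd of the *remaining* values
    (leave-one-out): with the handful of pure-sample observations
    available, a gross contaminant inflates the pooled sd so much that no
    value could ever exceed a pooled mean + k*sd threshold (the largest
    attainable z-score in a sample of n is (n-1)/sqrt(n)), so the
    comparison must exclude the value under test. Mean, SE and cutoff are
    recomputed on the retained values.
    """
    observations: list[float] = []
    for sample_id, fractions in designs.items():
        if sample_id not in abundance.type_percents.index:
            continue
        if sample_id in abundance.zero_mapped_samples:
            continue
        for type_name, fraction in fractions.items():
            if fraction == 0.0 and type_name in abundance.type_percents.columns:
                value = abundance.type_percents.loc[sample_id, type_name]
                observations.append(0.0 if pd.isna(value) else float(value))
    if not observations:
        raise ValueError("no absent-type observations; detection limit undefined")
    values = np.asarray(observations, dtype=float)
    outliers, kept = [], []
    if len(values) >= 3:
        for i, v in enumerate(values):
            rest = np.delete(values, i)
            sd = rest.std(ddof=1)
            if sd > 0 and v > rest.mean() + outlier_k * sd:
                outliers.append(float(v))
            else:
                kept.append(float(v))
    else:
        kept = [float(v) for v in values]
    if not kept:  # everything flagged: fall back to the full set
        kept, outliers = [float(v) for v in values], []
    return DetectionLimit(fp_values=kept, outliers=outliers)


# ---------------------------------------------------------------------------
# gamma rank correlation


@dataclass
class GammaResult:
    gamma: float
    n_concordant: int
    n_discordant: int
    tolerance_r: float = 0.0
    p_value: float | None = None
    n_permutations: int = 0


def gamma_correlation(x, y, tolerance_r: float = 0.0) -> GammaResult:
    """Goodman-Kruskal gamma with a robust tie tolerance.

    Over all index pairs i < j, a pair is concordant when the x- and
    y-differences share a sign and both exceed ``tolerance_r`` in
    magnitude, discordant when the signs are opposite (again both
    exceeding the tolerance); all other pairs are ties and excluded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 2")
    if tolerance_r < 0:
        raise ValueError("tolerance_r must be >= 0")
    dx = x[:, None] - x[None, :]
    dy = y[:, None] - y[None, :]
    upper = np.triu_indices(len(x), k=1)
    dx, dy = dx[upper], dy[upper]
    comparable = (np.abs(dx) > tolerance_r) & (np.abs(dy) > tolerance_r)
    product_sign = np.sign(dx) * np.sign(dy)
    n_concordant = int(np.sum(comparable & (product_sign > 0)))
    n_discordant = int(np.sum(comparable & (product_sign < 0)))
    denominator = n_concordant + n_discordant
    if denominator == 0:
        raise UndefinedGamma("no concordant or discordant pairs")
    return GammaResult(
        gamma=(n_concordant - n_discordant) / denominator,
        n_concordant=n_concordant,
        n_discordant=n_discordant,
        tolerance_r=tolerance_r,
    )


def gamma_permutation_p(
    x,
    y,
    tolerance_r: float = 0.0,
    n_iter: int = 1000,
    seed: int = 0,
    alternative: str = "greater",
) -> GammaResult:
    """Permutation significance for gamma (one-sided positive by default).

    y is permuted ``n_iter`` times; p = (1 + #{permuted gamma as extreme as
    observed}) / (n_iter + 1). The +1 pseudocount keeps p > 0. Permutations
    where gamma is undefined count as non-exceeding.
    """
    observed = gamma_correlation(x, y, tolerance_r)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    exceed = 0
    for _ in range(n_iter):
        permuted = rng.permutation(y)
        try:
            g = gamma_correlation(x, permuted, tolerance_r).gamma
        except UndefinedGamma:
            continue
        if alternative == "greater":
            exceed += g >= observed.gamma
        elif alternative == "less":
            exceed += g <= observed.gamma
        else:  # two-sided
            exceed += abs(g) >= abs(observed.gamma)
    observed.p_value = (1 + exceed) / (n_iter + 1)
    observed.n_permutations = n_iter
    return observed


# ---------------------------------------------------------------------------
# bootstrap


@dataclass
class BootstrapCI:
    mean: float
    lower: float
    upper: float
    n_resamples: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lower <= self.mean <= self.upper:
            raise ValueError("bootstrap CI must bracket the mean")


def bootstrap_ci(values, n_resamples: int = 1000, seed: int = 0) -> BootstrapCI:
    """Percentile (2.5/97.5) bootstrap CI for the mean."""
    values = np.asarray(values, dtype=float)
    if values.size < 1:
        raise ValueError("need at least one value")
    rng = np.random.default_rng(seed)
    resamples = rng.choice(values, size=(n_resamples, values.size), replace=True)
    means = resamples.mean(axis=1)
    lower, upper = np.percentile(means, [2.5, 97.5])
    point = float(values.mean())
    return BootstrapCI(
        mean=point,
        lower=float(min(lower, point)),
        upper=float(max(upper, point)),
        n_resamples=n_resamples,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# residual bias


@dataclass
class ResidualSummary:
    slope: float
    intercept: float
    residuals: np.ndarray
    per_level: pd.DataFrame  # expected level -> counts of over/under-estimates


def residual_bias(observed, expected) -> ResidualSummary:
    """Residuals of observed ~ expected and per-level over/under counts."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.ndim != 1 or len(observed) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(expected) == 0:
        raise ValueError("expected values are all equal; regression degenerate")
    fit = stats.linregress(expected, observed)
    residuals = observed - (fit.intercept + fit.slope * expected)
    frame = pd.DataFrame({"expected": expected, "residual": residuals})
    per_level = (
        frame.groupby("expected")["residual"]
        .agg(
            overestimated=lambda r: int((r > 0).sum()),
            underestimated=lambda r: int((r < 0).sum()),
        )
        .reset_index()
    )
    return ResidualSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        residuals=residuals,
        per_level=per_level,
    )


# ---------------------------------------------------------------------------
# plots


def plot_observed_vs_expected(
    observed, expected, path, ci_by_level: dict[float, BootstrapCI] | None = None
) -> None:
    """Scatter of observed vs expected background percents with CI bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(expected, observed, "o", color="grey", alpha=0.6, label="samples")
    if ci_by_level:
        levels = sorted(ci_by_level)
        means = [ci_by_level[l].mean for l in levels]
        err_low = [ci_by_level[l].mean - ci_by_level[l].lower for l in levels]
        err_high = [ci_by_level[l].upper - ci_by_level[l].mean for l in levels]
        ax.errorbar(levels, means, yerr=[err_low, err_high], fmt="ks", capsize=3,
                    label="mean (95% bootstrap CI)")
    lim = max(float(np.max(expected)), float(np.max(observed))) * 1.05
    ax.plot([0, lim], [0, lim], "k--", linewidth=0.8)
    ax.set_xlabel("expected abundance (%)")
    ax.set_ylabel("observed abundance (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
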