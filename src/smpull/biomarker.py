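"""Cohort-level statistics: ratios, morphology thresholds, tests, and ROC.

The discrimination machinery follows the assay's analysis chain:

* per-sample α-syn proportion R = α/(α+β) from mean spots per field;
* group-averaged cumulative histograms of perimeter and circularity, whose
  maximum control−PD difference fixes the morphology thresholds (P*, C*);
* the morphologically-distinct fraction f = P(perimeter > P* and
  circularity > C*) per sample, and the combined score S = R · f;
* a normality-gated two-sample test (Kolmogorov–Smirnov gate at α = 0.05,
  then Welch's two-tailed t-test or the Mann–Whitney U test);
* ROC analysis with the Mann–Whitney AUC estimator (ties count ½) and
  Wilson score intervals for sensitivity/specificity at the Youden point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.proportion import proportion_confint

from .errors import UndefinedFractionError, ValidationError

__all__ = [
    "CumulativeDiff",
    "ThresholdPick",
    "GroupComparison",
    "RocResult",
    "CohortResult",
    "alpha_syn_proportion",
    "group_cumulative_hist",
    "max_cumulative_difference",
    "discover_thresholds",
    "distinct_fraction",
    "combined_score",
    "compare_groups",
    "roc_auc",
    "run_cohort_analysis",
]

log = logging.getLogger(__name__)

POSITIVE_GROUP = "PD"
NEGATIVE_GROUP = "control"


def alpha_syn_proportion(count_asyn: float, count_abeta: float) -> float:
    """α-syn proportion R = α/(α+β) of the two per-sample mean counts."""
    if count_asyn < 0 or count_abeta < 0:
        raise ValidationError("counts must be non-negative")
    total = count_asyn + count_abeta
    if total == 0:
        raise UndefinedFractionError("ratio undefined when both counts are zero")
    return float(count_asyn / total)


@dataclass(frozen=True)
class CumulativeDiff:
    """Group-averaged cumulative histograms on a common threshold grid."""

    grid: np.ndarray
    cdf_control: np.ndarray
    cdf_pd: np.ndarray

    @property
    def diff(self) -> np.ndarray:
        return self.cdf_control - self.cdf_pd


class ThresholdPick(NamedTuple):
    threshold: float
    max_diff: float
    degenerate: bool


def group_cumulative_hist(
    per_sample_values: Mapping[str, np.ndarray],
    groups: Mapping[str, str],
    grid: np.ndarray,
) -> CumulativeDiff:
    """Average per-sample empirical CDFs within each group on a common grid.

    Averaging sample ECDFs (rather than pooling values) keeps each sample's
    weight equal regardless of how many aggregates it contributed.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing")
    acc = {POSITIVE_GROUP: [], NEGATIVE_GROUP: []}
    for sid, values in per_sample_values.items():
        values = np.asarray(values, dtype=float)
        if values.size == 0:
            log.warning("sample %s has no values; excluded from cumulative histogram", sid)
            continue
        ecdf = np.searchsorted(np.sort(values), grid, side="right") / values.size
        acc[groups[sid]].append(ecdf)
    for g, lst in acc.items():
        if not lst:
            raise ValidationError(f"no usable samples in group {g!r}")
    return CumulativeDiff(
        grid=grid,
        cdf_control=np.mean(acc[NEGATIVE_GROUP], axis=0),
        cdf_pd=np.mean(acc[POSITIVE_GROUP], axis=0),
    )


def max_cumulative_difference(cd: CumulativeDiff) -> ThresholdPick:
    """Grid point maximising (CDF_control − CDF_PD); ties go to the smallest."""
    diff = cd.diff
    idx = int(np.argmax(diff))  # argmax returns the first (smallest) maximiser
    degenerate = bool(np.allclose(diff, diff[0]))
    if degenerate:
        idx = 0
    return ThresholdPick(float(cd.grid[idx]), float(diff[idx]), degenerate)


def _default_grid(values: np.ndarray, n: int = 200) -> np.ndarray:
    lo, hi = float(np.min(values)), float(np.max(values))
    if lo == hi:
        hi = lo + 1e-9
    return np.linspace(lo, hi, n)


def discover_thresholds(
    morphology: pd.DataFrame,
    channel: str = "alpha_syn",
    grid_points: int = 200,
) -> dict:
    """Find (P*, C*) for one channel from a cohort morphology table.

    The perimeter threshold is the argmax of the group cumulative difference
    over all aggregates; the circularity threshold is then found among the
    "larger" aggregates (perimeter > P*) only.
    """
    sub = morphology[morphology["channel"] == channel]
    if sub.empty:
        raise ValidationError(f"no morphology rows for channel {channel!r}")
    groups = sub.groupby("sample_id")["group"].first().to_dict()

    per_sample_p = {sid: g["perimeter_um"].to_numpy() for sid, g in sub.groupby("sample_id")}
    cd_p = group_cumulative_hist(per_sample_p, groups, _default_grid(sub["perimeter_um"].to_numpy(), grid_points))
    pick_p = max_cumulative_difference(cd_p)

    larger = sub[sub["perimeter_um"] > pick_p.threshold]
    if larger.empty or set(larger["group"].unique()) != set(sub["group"].unique()):
        # the "larger" subset must still represent both groups
        log.warning("perimeter-thresholded subset too sparse; circularity uses all aggregates")
        larger = sub
    per_sample_c = {sid: g["circularity"].to_numpy() for sid, g in larger.groupby("sample_id")}
    groups_c = {sid: groups[sid] for sid in per_sample_c}
    cd_c = group_cumulative_hist(per_sample_c, groups_c, _default_grid(larger["circularity"].to_numpy(), grid_points))
    pick_c = max_cumulative_difference(cd_c)

    return {
        "channel": channel,
        "perimeter_um": pick_p.threshold,
        "perimeter_max_diff": pick_p.max_diff,
        "circularity": pick_c.threshold,
        "circularity_max_diff": pick_c.max_diff,
        "cumdiff_perimeter": cd_p,
        "cumdiff_circularity": cd_c,
    }


def distinct_fraction(
    perimeter_um: Sequence[float],
    circularity: Sequence[float],
    p_star: float,
    c_star: float,
) -> float:
    """Fraction of aggregates strictly exceeding both morphology thresholds.

    The denominator is every aggregate of the sample/channel.
    """
    p = np.asarray(perimeter_um, dtype=float)
    c = np.asarray(circularity, dtype=float)
    if p.size == 0:
        raise UndefinedFractionError("distinct fraction of an empty morphology list is undefined")
    if p_star <= 0 or c_star <= 0:
        raise ValidationError("thresholds must be positive")
    return float(np.mean((p > p_star) & (c > c_star)))


def combined_score(ratio: float, f_distinct: float) -> float:
    """Combined discriminator S = R · f_distinct."""
    for name, v in (("ratio", ratio), ("distinct fraction", f_distinct)):
        if not (0.0 <= v <= 1.0):
            raise ValidationError(f"{name} {v} outside [0, 1]")
    return float(ratio * f_distinct)


@dataclass(frozen=True)
class GroupComparison:
    test: str                  # "welch_t" or "mann_whitney"
    statistic: float
    p_value: float
    normal_pd: bool
    normal_control: bool
    alpha: float
    degenerate: bool = False


def _ks_normal(x: np.ndarray, alpha: float) -> bool:
    sd = np.std(x, ddof=1)
    if sd == 0:
        return False
    p = stats.kstest(x, "norm", args=(np.mean(x), sd)).pvalue
    return bool(p > alpha)


def compare_groups(values_pd, values_control, alpha: float = 0.05) -> GroupComparison:
    """Normality-gated two-sample comparison.

    Each group is checked against a normal with its sample moments using the
    Kolmogorov–Smirnov statistic at ``alpha``; if both pass, Welch's
    two-tailed t-test is used, otherwise the Mann–Whitney U test.
    """
    x = np.asarray(values_pd, dtype=float)
    y = np.asarray(values_control, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("each group needs at least 3 samples")
    degenerate = bool(np.std(x) == 0 or np.std(y) == 0)
    norm_x = _ks_normal(x, alpha) if not degenerate else False
    norm_y = _ks_normal(y, alpha) if not degenerate else False
    if norm_x and norm_y:
        res = stats.ttest_ind(x, y, equal_var=False)
        return GroupComparison("welch_t", float(res.statistic), float(res.pvalue), True, True, alpha)
    if np.ptp(np.concatenate([x, y])) == 0:
        return GroupComparison("mann_whitney", float("nan"), 1.0, False, False, alpha, True)
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(
        "mann_whitney", float(res.statistic), float(res.pvalue), norm_x, norm_y, alpha, degenerate
    )


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    youden_threshold: float
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, alpha: float = 0.05) -> RocResult:
    """ROC analysis of a per-sample score against binary group labels.

    AUC is the Mann–Whitney pairing estimator (tied pairs count ½), which
    equals the trapezoidal area under the full-threshold ROC curve. Wilson
    score intervals are attached to sensitivity and specificity at the
    Youden-optimal operating point; the AUC interval is the Hanley–McNeil
    normal approximation.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l in (1, True, POSITIVE_GROUP) else 0 for l in labels])
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")

    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (auc * (1 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)) / (
        n_pos * n_neg
    )
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    auc_ci = (max(auc - half, 0.0), min(auc + half, 1.0))

    fpr, tpr, thresholds = _sk_roc_curve(y, scores, drop_intermediate=False)
    j = int(np.argmax(tpr - fpr))
    sens, spec = float(tpr[j]), float(1.0 - fpr[j])
    sens_ci = proportion_confint(round(sens * n_pos), n_pos, alpha=alpha, method="wilson")
    spec_ci = proportion_confint(round(spec * n_neg), n_neg, alpha=alpha, method="wilson")

    return RocResult(
        auc=float(auc),
        auc_ci=auc_ci,
        fpr=fpr,
        tpr=tpr,
        thresholds=thresholds,
        youden_threshold=float(thresholds[j]),
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=(float(sens_ci[0]), float(sens_ci[1])),
        specificity_ci=(float(spec_ci[0]), float(spec_ci[1])),
        n_pos=n_pos,
        n_neg=n_neg,
    )


@dataclass
class CohortResult:
    samples: pd.DataFrame
    thresholds: dict
    comparisons: dict[str, GroupComparison]
    roc: dict[str, RocResult]
    counts_only: bool = False
    notes: list[str] = field(default_factory=list)

    def thresholds_frame(self) -> pd.DataFrame:
        rows = [
            {
                "channel": t["channel"],
                "perimeter_um": t["perimeter_um"],
                "perimeter_max_diff": t["perimeter_max_diff"],
                "circularity": t["circularity"],
                "circularity_max_diff": t["circularity_max_diff"],
            }
            for t in self.thresholds.values()
        ]
        return pd.DataFrame(rows)

    def roc_frame(self) -> pd.DataFrame:
        rows = []
        for metric, r in self.roc.items():
            for f, t, thr in zip(r.fpr, r.tpr, r.thresholds):
                rows.append({"metric": metric, "fpr": f, "tpr": t, "threshold": thr})
        return pd.DataFrame(rows)

    def summary_text(self) -> str:
        lines = ["Cohort analysis summary", "======================="]
        for metric, r in self.roc.items():
            c = self.comparisons[metric]
            test = f"{c.test} p={c.p_value:.4g}" if c is not None else "no test (tiny groups)"
            lines.append(
                f"{metric}: AUC={r.auc:.3f} [{r.auc_ci[0]:.3f}, {r.auc_ci[1]:.3f}]"
                f"  sens={r.sensitivity:.2f} ({r.sensitivity_ci[0]:.2f}-{r.sensitivity_ci[1]:.2f})"
                f"  spec={r.specificity:.2f} ({r.specificity_ci[0]:.2f}-{r.specificity_ci[1]:.2f})"
                f"  {test}"
            )
        for t in self.thresholds.values():
            lines.append(
                f"thresholds[{t['channel']}]: P*={t['perimeter_um']:.3f} um"
                f" (max diff {100 * t['perimeter_max_diff']:.1f}%),"
                f" C*={t['circularity']:.3f} (max diff {100 * t['circularity_max_diff']:.1f}%)"
            )
        lines.extend(self.notes)
        lines.append("No multiple-testing correction applied (prespecified discriminators).")
        return "\n".join(lines) + "\n"


def run_cohort_analysis(
    fov_metrics: pd.DataFrame,
    morphology: pd.DataFrame | None = None,
    grid_points: int = 200,
) -> CohortResult:
    """Full cohort analysis from per-field metrics and per-aggregate morphology.

    ``fov_metrics`` needs columns sample_id, group, channel, fov_id, n_spots
    and optionally high_intensity_fraction; ``morphology`` needs sample_id,
    group, channel, perimeter_um, circularity. Without morphology the
    analysis runs in counts-only mode (count, ratio and, when intensity
    fractions are present, an intensity-combined score).
    """
    required = {"sample_id", "group", "channel", "fov_id", "n_spots"}
    if not required.issubset(fov_metrics.columns):
        raise ValidationError(f"fov_metrics missing columns {sorted(required - set(fov_metrics.columns))}")

    counts_only = morphology is None or len(morphology) == 0
    rows = []
    for sid, g in fov_metrics.groupby("sample_id"):
        row = {"sample_id": sid, "group": g["group"].iloc[0]}
        for ch in ("alpha_syn", "abeta"):
            sub = g[g["channel"] == ch]
            if sub.empty:
                raise ValidationError(f"sample {sid} lacks channel {ch}")
            row[f"count_{ch}"] = float(sub["n_spots"].mean())
            if "high_intensity_fraction" in sub.columns:
                row[f"f_high_{ch}"] = float(sub["high_intensity_fraction"].mean())
        row["ratio"] = alpha_syn_proportion(row["count_alpha_syn"], row["count_abeta"])
        rows.append(row)
    samples = pd.DataFrame(rows)

    for grp in (POSITIVE_GROUP, NEGATIVE_GROUP):
        if (samples["group"] == grp).sum() < 2:
            raise ValidationError(f"need at least 2 samples in group {grp!r}")

    thresholds: dict = {}
    notes: list[str] = []
    if not counts_only:
        for ch in morphology["channel"].unique():
            thresholds[ch] = discover_thresholds(morphology, ch, grid_points)
        th = thresholds["alpha_syn"]
        fr = []
        for sid in samples["sample_id"]:
            sub = morphology[(morphology["sample_id"] == sid) & (morphology["channel"] == "alpha_syn")]
            if sub.empty:
                fr.append(np.nan)
                notes.append(f"sample {sid}: no alpha_syn morphology; distinct fraction undefined")
                continue
            fr.append(
                distinct_fraction(
                    sub["perimeter_um"], sub["circularity"], th["perimeter_um"], th["circularity"]
                )
            )
        samples["distinct_fraction"] = fr
        samples["combined_score"] = samples["ratio"] * samples["distinct_fraction"]
    elif "f_high_alpha_syn" in samples.columns:
        # validation-cohort mode: intensity fraction substitutes for morphology
        samples["combined_score"] = samples["ratio"] * samples["f_high_alpha_syn"]
        notes.append("counts-only mode: combined score uses the high-intensity fraction")

    metrics = ["count_alpha_syn", "count_abeta", "ratio"]
    if "combined_score" in samples.columns:
        metrics.append("combined_score")

    comparisons, roc = {}, {}
    is_pd = (samples["group"] == POSITIVE_GROUP).to_numpy()
    for metric in metrics:
        v = samples[metric].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if min((ok & is_pd).sum(), (ok & ~is_pd).sum()) >= 3:
            comparisons[metric] = compare_groups(v[ok & is_pd], v[ok & ~is_pd])
        else:
            comparisons[metric] = None
            notes.append(f"{metric}: groups too small for a hypothesis test")
        roc[metric] = roc_auc(v[ok], samples["group"].to_numpy()[ok])

    return CohortResult(
        samples=samples,
        thresholds=thresholds,
        comparisons=comparisons,
        roc=roc,
        counts_only=counts_only,
        notes=notes,
    )
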