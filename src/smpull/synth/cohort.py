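"""Two-group (PD vs control) serum cohort generator.

The generator reproduces the study conditions the assay reports: per-sample
mean spot counts per field of view drawn from a zero-truncated normal with
the printed group means and SDs (α-syn 200±100 PD vs 120±60 control;
Aβ 140±120 vs 150±100), Poisson counts per field around that mean, and
per-aggregate morphology from a hierarchical model — log-perimeter normal
and logit-circularity normal, each with a between-sample and a within-sample
spread — whose group parameters are placed so the cohort-averaged cumulative
histograms differ maximally near 0.24 µm (perimeter) and 0.64 (circularity)
for α-syn, and only weakly for Aβ (near 0.31 µm / 0.7).

Two fidelity levels are supported: ``metrics`` emits counts, per-spot
intensities and per-aggregate morphology directly from the generative model
(used for cohort-scale statistics), while ``images`` additionally renders
diffraction-limited stacks and dSTORM localization tables for every field so
the full detection chain can run on a small cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from ..errors import ValidationError
from ..seeding import stream
from .imaging import BlinkModel, OpticsModel, simulate_dlim_stack, simulate_localizations
from .shapes import aggregate_from_targets

log = logging.getLogger(__name__)

__all__ = [
    "MorphologyParams",
    "CohortSpec",
    "CohortBundle",
    "simulate_cohort",
    "PAPER_COUNT_PARAMS",
    "DEFAULT_MORPHOLOGY_PARAMS",
]

GROUPS = ("PD", "control")
CHANNELS = ("alpha_syn", "abeta")

# printed group means ± SDs of spots per field of view
PAPER_COUNT_PARAMS: dict[tuple[str, str], tuple[float, float]] = {
    ("PD", "alpha_syn"): (200.0, 100.0),
    ("control", "alpha_syn"): (120.0, 60.0),
    ("PD", "abeta"): (140.0, 120.0),
    ("control", "abeta"): (150.0, 100.0),
}


@dataclass(frozen=True)
class MorphologyParams:
    """Hierarchical morphology model for one group × channel.

    Per sample s: log-perimeter centre mu_s ~ N(log_perimeter_mu, between²),
    per aggregate log P ~ N(mu_s, within²); analogously for circularity on
    the logit scale.
    """

    log_perimeter_mu: float
    log_perimeter_within: float = 0.45
    log_perimeter_between: float = 0.06
    circ_logit_mu: float = 0.45
    circ_logit_within: float = 0.8
    circ_logit_between: float = 0.12


def _group_centres(argmax: float, max_diff: float, sigma_total: float, transform) -> tuple[float, float]:
    """(control, PD) distribution centres on the transformed scale.

    For two equal-width Gaussians the group-averaged CDF difference peaks
    midway between the centres with height 2Φ(δ/2)−1, so the printed
    (threshold, max difference) pair fixes both centres exactly.
    """
    delta = 2.0 * stats.norm.ppf((1.0 + max_diff) / 2.0) * sigma_total
    centre = transform(argmax)
    return centre - delta / 2.0, centre + delta / 2.0


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


_SIG_P = np.sqrt(0.45**2 + 0.06**2)   # total log-perimeter spread
_SIG_C = np.sqrt(0.8**2 + 0.12**2)    # total logit-circularity spread

# Group centres encode the printed group-level morphology contrasts: the
# cumulative control−PD difference peaks at 0.24 µm (3.6%) and circularity
# 0.64 (9.5%) for α-syn, and at 0.31 µm (3.0%) / 0.7 (5.0%) for Aβ.
_ASYN_P = _group_centres(0.24, 0.036, _SIG_P, np.log)
_ASYN_C = _group_centres(0.64, 0.095, _SIG_C, _logit)
_ABETA_P = _group_centres(0.31, 0.030, _SIG_P, np.log)
_ABETA_C = _group_centres(0.70, 0.050, _SIG_C, _logit)

DEFAULT_MORPHOLOGY_PARAMS: dict[tuple[str, str], MorphologyParams] = {
    ("PD", "alpha_syn"): MorphologyParams(log_perimeter_mu=_ASYN_P[1], circ_logit_mu=_ASYN_C[1]),
    ("control", "alpha_syn"): MorphologyParams(log_perimeter_mu=_ASYN_P[0], circ_logit_mu=_ASYN_C[0]),
    ("PD", "abeta"): MorphologyParams(log_perimeter_mu=_ABETA_P[1], circ_logit_mu=_ABETA_C[1]),
    ("control", "abeta"): MorphologyParams(log_perimeter_mu=_ABETA_P[0], circ_logit_mu=_ABETA_C[0]),
}

# per-spot intensity model (A.U.): lognormal whose 75th percentile sits near
# the 25,000 A.U. high-intensity cut; identical across groups, matching the
# antibody-imaging observation that intensity alone does not discriminate
INTENSITY_MEDIAN_AU = 18_000.0
INTENSITY_SIGMA = 0.5


@dataclass(frozen=True)
class CohortSpec:
    n_per_group: int = 20
    count_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(PAPER_COUNT_PARAMS)
    )
    morphology_params: Mapping[tuple[str, str], MorphologyParams] = field(
        default_factory=lambda: dict(DEFAULT_MORPHOLOGY_PARAMS)
    )
    fovs_per_sample_dlim: int = 28
    fovs_per_sample_storm: int = 6
    # squared CV of the shared per-sample capture efficiency. Both channels of
    # a sample are scaled by the same lognormal factor (mean 1); the printed
    # marginal count moments are preserved by shrinking the biological spread
    # accordingly. This nuisance variation is what the count ratio cancels.
    efficiency_cv2: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 samples per group")
        for key, (m, s) in self.count_params.items():
            if m < 0 or s < 0:
                raise ValidationError(f"negative count parameter for {key}")
        if self.fovs_per_sample_dlim < 1 or self.fovs_per_sample_storm < 1:
            raise ValidationError("each sample needs at least one field of view")
        if self.efficiency_cv2 < 0:
            raise ValidationError("efficiency_cv2 must be >= 0")


@dataclass
class CohortBundle:
    """Everything the downstream stages consume, plus the ground truth."""

    spec: CohortSpec
    samples: pd.DataFrame        # sample_id, group, per-channel latent parameters
    fov_counts: pd.DataFrame     # sample_id, group, channel, fov_id, n_spots, high_intensity_fraction
    morphology: pd.DataFrame     # sample_id, group, channel, label_id, perimeter_um, circularity
    stacks: dict = field(default_factory=dict)       # (sample_id, channel, fov) -> ImageStack
    loc_tables: dict = field(default_factory=dict)   # (sample_id, channel, fov) -> DataFrame
    truth_aggregates: dict = field(default_factory=dict)

    def ledger_bytes(self) -> bytes:
        """Canonical CSV serialisation of the ground-truth ledger (for hashing)."""
        parts = [
            self.samples.to_csv(index=False, float_format="%.9g"),
            self.fov_counts.to_csv(index=False, float_format="%.9g"),
            self.morphology.to_csv(index=False, float_format="%.9g"),
        ]
        return "\n".join(parts).encode()


_TRUNC_CACHE: dict[tuple[float, float], tuple[float, float]] = {}


def truncated_normal_parent(mean: float, sd: float) -> tuple[float, float]:
    """Parent (µ, σ) whose zero-truncated normal has the requested moments.

    The printed group values are means and SDs of non-negative counts, so the
    truncated distribution — not its parent — must carry them. For narrow
    distributions the correction is negligible; for the wide Aβ groups it is
    not.
    """
    key = (float(mean), float(sd))
    if key not in _TRUNC_CACHE:
        from scipy.optimize import root

        def moments(params):
            mu, sigma = params
            sigma = abs(sigma)
            a = -mu / sigma
            m, v = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
            return [m - mean, np.sqrt(v) - sd]

        sol = root(moments, [mean, sd])
        mu, sigma = float(sol.x[0]), float(abs(sol.x[1]))
        if not sol.success:  # extreme truncation: fall back to the printed values
            mu, sigma = mean, sd
        _TRUNC_CACHE[key] = (mu, sigma)
    return _TRUNC_CACHE[key]


def _truncated_normal(mean: float, sd: float, rng: np.random.Generator) -> float:
    if sd == 0:
        return max(mean, 0.0)
    mu, sigma = truncated_normal_parent(mean, sd)
    a = -mu / sigma
    return float(stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sigma, random_state=rng))


def simulate_cohort(spec: CohortSpec, level: str = "metrics",
                    optics: OpticsModel | None = None,
                    storm_optics: OpticsModel | None = None,
                    blink: BlinkModel | None = None,
                    storm_frames: int = 7000,
                    aggregates_per_storm_fov: int | None = None) -> CohortBundle:
    """Draw a full two-group cohort; deterministic for a fixed spec.

    ``metrics`` level stops at counts/intensities/morphology values;
    ``images`` level also renders stacks and localization tables (use small
    fields and counts — rendering a study-scale cohort is deliberately out of
    reach on a desk machine).
    """
    if level not in ("metrics", "images"):
        raise ValidationError("level must be 'metrics' or 'images'")
    rng = stream(spec.seed, "cohort")

    sample_rows, fov_rows, morph_rows = [], [], []
    stacks, loc_tables, truth_aggs = {}, {}, {}

    if level == "images":
        optics = optics or OpticsModel()
        storm_optics = storm_optics or OpticsModel.dstorm(fov_px=optics.fov_px)
        blink = blink or BlinkModel()

    for group in GROUPS:
        for i in range(spec.n_per_group):
            sid = f"{group}_{i:03d}"
            row: dict = {"sample_id": sid, "group": group}
            v_e = spec.efficiency_cv2
            if v_e > 0:
                s_ln = np.sqrt(np.log1p(v_e))
                eff = float(np.exp(s_ln * rng.standard_normal() - 0.5 * s_ln**2))
            else:
                eff = 1.0
            row["capture_efficiency"] = eff
            for ch in CHANNELS:
                mean, sd = spec.count_params[(group, ch)]
                # biological spread after removing the shared-efficiency share
                # of the printed marginal variance
                bio_var = (sd**2 - mean**2 * v_e) / (1.0 + v_e)
                if bio_var < 0:
                    log.warning(
                        "efficiency_cv2 exceeds the %s/%s count variance; "
                        "biological spread clamped to zero", group, ch,
                    )
                    bio_var = 0.0
                m = eff * _truncated_normal(mean, np.sqrt(bio_var), rng)
                row[f"count_mean_{ch}"] = m

                mp = spec.morphology_params[(group, ch)]
                mu_s = mp.log_perimeter_mu + mp.log_perimeter_between * rng.standard_normal()
                zeta_s = mp.circ_logit_mu + mp.circ_logit_between * rng.standard_normal()
                row[f"log_perimeter_mu_{ch}"] = mu_s
                row[f"circ_logit_mu_{ch}"] = zeta_s

                # diffraction-limited fields: counts + per-spot intensities
                counts = rng.poisson(m, size=spec.fovs_per_sample_dlim)
                for f, n in enumerate(counts):
                    n = int(n)
                    if n > 0:
                        inten = INTENSITY_MEDIAN_AU * np.exp(
                            INTENSITY_SIGMA * rng.standard_normal(n)
                        )
                        f_high = float(np.mean(inten > 25_000.0))
                    else:
                        inten = np.empty(0)
                        f_high = np.nan
                    fov_rows.append(
                        {
                            "sample_id": sid,
                            "group": group,
                            "channel": ch,
                            "fov_id": f"fov{f:03d}",
                            "n_spots": n,
                            "high_intensity_fraction": f_high,
                        }
                    )
                    if level == "images":
                        fov_nm = optics.fov_px * optics.pixel_size_nm
                        aggs = [
                            aggregate_from_targets(
                                0.2,
                                0.7,
                                rng.uniform(0.03 * fov_nm, 0.97 * fov_nm, size=2),
                                rng,
                                channel=ch,
                            )
                            for _ in range(n)
                        ]
                        stacks[(sid, ch, f)] = simulate_dlim_stack(
                            aggs, optics, seed=int(rng.integers(2**31)), brightness_au=inten
                        )

                # dSTORM fields: morphology of each segmented aggregate
                per_fov = aggregates_per_storm_fov
                for f in range(spec.fovs_per_sample_storm):
                    n_agg = int(rng.poisson(m)) if per_fov is None else int(per_fov)
                    perims = np.exp(mu_s + mp.log_perimeter_within * rng.standard_normal(n_agg))
                    circs = 1.0 / (
                        1.0 + np.exp(-(zeta_s + mp.circ_logit_within * rng.standard_normal(n_agg)))
                    )
                    morph_rows.append(
                        pd.DataFrame(
                            {
                                "sample_id": sid,
                                "group": group,
                                "channel": ch,
                                "fov_id": f"storm{f:03d}",
                                "label_id": np.arange(n_agg),
                                "perimeter_um": perims,
                                "circularity": circs,
                            }
                        )
                    )
                    if level == "images":
                        key = (sid, ch, f)
                        fov_nm = storm_optics.fov_px * storm_optics.pixel_size_nm
                        aggs = []
                        for j in range(n_agg):
                            centroid = rng.uniform(0.15 * fov_nm, 0.85 * fov_nm, size=2)
                            aggs.append(
                                aggregate_from_targets(
                                    float(perims[j]),
                                    float(np.clip(circs[j], 0.05, 1.0)),
                                    centroid,
                                    rng,
                                    channel=ch,
                                )
                            )
                        truth_aggs[key] = aggs
                        loc_tables[key] = simulate_localizations(
                            aggs, blink, storm_frames, seed=int(rng.integers(2**31))
                        )

            sample_rows.append(row)

    bundle = CohortBundle(
        spec=spec,
        samples=pd.DataFrame(sample_rows),
        fov_counts=pd.DataFrame(fov_rows),
        morphology=(
            pd.concat(morph_rows, ignore_index=True)
            if morph_rows
            else pd.DataFrame(
                columns=[
                    "sample_id", "group", "channel", "fov_id",
                    "label_id", "perimeter_um", "circularity",
                ]
            )
        ),
        stacks=stacks,
        loc_tables=loc_tables,
        truth_aggregates=truth_aggs,
    )
    return bundle
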