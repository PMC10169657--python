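"""Synthetic cohorts for exercising the full validation pipeline.

No individual-level data are distributed with this package, so every stage
is tested against generated cohorts. The generator emulates a
community-dwelling 75+ study population: anthropometry and questionnaire
responses, a latent "true" habitual protein intake per kg adjusted body
weight, 3-day dietary records observed with day-to-day noise, and a
screener score whose discrimination of low intake is tunable.

Mechanism
---------
1.  True intake ``T`` ~ Normal(protein_mean, protein_sd) truncated at 0
    (rejection sampling); the low-intake state is ``T < threshold``.
2.  Screener liability ``L = -a*z_T + sqrt(1-a^2)*eps`` with ``z_T`` the
    standardised intake and ``eps`` independent standard normal. The
    coupling ``a`` is calibrated numerically so that the theoretical AUC of
    ``L`` for discriminating ``T < threshold`` equals ``target_auc``
    (the classes are tail-truncated normals, so the calibration integrates
    over both truncated classes rather than using the two-normal shortcut).
3.  ``L`` maps monotonically to a probability score
    ``expit(score_mu + score_sigma * L)``; the defaults place the score
    median near 0.17 with interquartile range roughly 0.04-0.46, the
    scale observed for this instrument in older cohorts.
4.  Item responses are back-filled so that scoring them under the active
    model reproduces the target linear predictor: the covariate
    contribution is subtracted and the residual is matched greedily over
    the items in order of decreasing coefficient magnitude. With the
    bundled model's coefficient ladder the residual error is below ~0.05
    on the linear-predictor scale for targets inside the achievable range
    (targets outside are clipped). ``score_only=True`` skips back-filling
    when a test needs exact score control.
5.  Recorded days multiply ``T * aBW`` by lognormal day factors with the
    designed coefficient of variation; energy is linked to protein mass
    with a fixed slope plus residual noise, and fat/carbohydrate close the
    energy balance at a realistic fat energy share.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy import optimize, stats
from scipy.special import expit

from pro55.errors import InvalidInputError
from pro55.screener import (
    COVARIATE_KEYS,
    ITEM_KEYS,
    ScreenerModel,
    load_default_model,
)

#: fat energy share (percent) mean and SD used to close the macronutrient balance
FAT_EPCT_MEAN = 38.8
FAT_EPCT_SD = 6.8

#: kcal of additional daily energy per additional gram of daily protein
ENERGY_PROTEIN_SLOPE = 18.7


class CohortDesign(BaseModel):
    """Design parameters of a synthetic cohort.

    Defaults emulate a German community-dwelling 75+ validation cohort:
    age 81.6 +/- 3.9 y, 61.8 % female, BMI 28.0 +/- 5.1 kg/m², energy
    1770.1 +/- 440.4 kcal/d, true protein intake 1.0 +/- 0.3 g/kg aBW/d,
    and a screener-reference AUC of 0.62 at the 1.0 g/kg aBW/d threshold.
    """

    model_config = ConfigDict(frozen=True)

    n: int = Field(default=144, ge=2)
    seed: int = Field(ge=0)
    age_mean: float = 81.6
    age_sd: float = Field(default=3.9, gt=0)
    pct_female: float = Field(default=0.618, ge=0, le=1)
    bmi_mean: float = 28.0
    bmi_sd: float = Field(default=5.1, gt=0)
    protein_mean: float = 1.0
    protein_sd: float = Field(default=0.3, gt=0)
    energy_mean: float = 1770.1
    energy_sd: float = Field(default=440.4, gt=0)
    threshold: float = Field(default=1.0, gt=0)
    target_auc: float = Field(default=0.62, ge=0.5, lt=1.0)
    day_cv: float = Field(default=0.25, ge=0)
    n_days: int = Field(default=3, ge=1)
    score_mu: float = -1.5856  # logit(0.17)
    score_sigma: float = Field(default=2.24, gt=0)
    exclusion_rates: dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check_rates(self) -> "CohortDesign":
        known = {"low_mmse", "tube_feeding", "implausible_energy", "incomplete_data"}
        bad = set(self.exclusion_rates) - known
        if bad:
            raise ValueError(f"unknown exclusion reasons: {sorted(bad)}")
        if any(r < 0 for r in self.exclusion_rates.values()):
            raise ValueError("exclusion rates must be >= 0")
        if sum(self.exclusion_rates.values()) > 1:
            raise ValueError("exclusion rates sum to more than 1")
        return self


@dataclass
class Cohort:
    """Generated tables: one row per participant except ``dietary_days``."""

    participants: pd.DataFrame
    responses: Optional[pd.DataFrame]
    dietary_days: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# AUC calibration
# ---------------------------------------------------------------------------


def _theoretical_auc(a: float, z_thr: float, n_nodes: int = 64) -> float:
    """AUC of the liability for discriminating z < z_thr, given coupling a.

    Positives are the lower tail z < z_thr, negatives the upper tail; both
    classes are truncated normals, integrated by Gauss-Legendre quadrature
    in the probability domain.
    """
    if a <= 0:
        return 0.5
    if a >= 1:
        return 1.0
    p = stats.norm.cdf(z_thr)
    nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (nodes + 1)  # (0,1)
    w = 0.5 * weights
    z_pos = stats.norm.ppf(u * p)  # lower tail
    z_neg = stats.norm.ppf(p + u * (1 - p))  # upper tail
    scale = a / np.sqrt(2 * (1 - a**2))
    grid = stats.norm.cdf(scale * (z_neg[None, :] - z_pos[:, None]))
    return float(w @ grid @ w)


def coupling_for_auc(target_auc: float, z_thr: float) -> float:
    """Invert :func:`_theoretical_auc` for the coupling coefficient.

    ``target_auc = 0.5`` returns coupling 0 (score independent of intake).
    """
    if target_auc == 0.5:
        return 0.0
    if not 0.5 < target_auc < 1.0:
        raise InvalidInputError("target_auc must be in [0.5, 1)")
    f = lambda a: _theoretical_auc(a, z_thr) - target_auc
    return float(optimize.brentq(f, 1e-9, 1 - 1e-9, xtol=1e-10))


# ---------------------------------------------------------------------------
# item back-fill
# ---------------------------------------------------------------------------


def _backfill_items(
    model: ScreenerModel, target_lp: np.ndarray, covariate_contrib: np.ndarray
) -> tuple[pd.DataFrame, np.ndarray]:
    """Choose item categories whose coded sum approximates the target.

    Greedy over items in order of decreasing |coefficient|, always
    undershooting (item contributions are one-signed, so an overshoot could
    never be corrected by the remaining items); with the bundled model's
    coefficient ladder the final error is below the smallest item step.
    The achieved linear predictor is returned alongside the labels;
    residual targets outside the achievable item range are clipped.
    """
    residual = target_lp - model.intercept - covariate_contrib
    spans = []
    for key in ITEM_KEYS:
        coding = model.items[key]
        codes = np.asarray(sorted(set(coding.codes.values())), dtype=float)
        label_of = {v: k for k, v in coding.codes.items()}
        spans.append((key, coding.coefficient, codes, label_of))
    lo = sum(min(c * codes.min(), c * codes.max()) for _, c, codes, _ in spans)
    hi = sum(max(c * codes.min(), c * codes.max()) for _, c, codes, _ in spans)
    residual = np.clip(residual, lo, hi)

    achieved = np.zeros_like(residual)
    columns: dict[str, np.ndarray] = {}
    for key, coef, codes, label_of in sorted(spans, key=lambda s: -abs(s[1])):
        if coef == 0:
            pick = np.full(residual.shape, codes[0])
        else:
            ideal = residual / coef  # >= 0: residual and coef share sign
            # largest admissible code not exceeding the ideal (undershoot)
            idx = np.searchsorted(codes, ideal + 1e-9, side="right") - 1
            pick = codes[np.clip(idx, 0, codes.size - 1)]
        contrib = coef * pick
        residual = residual - contrib
        achieved = achieved + contrib
        columns[key] = pick

    labels = pd.DataFrame(
        {
            key: [dict_[v] for v in columns[key]]
            for key, _, _, dict_ in spans
        }
    )
    achieved_lp = model.intercept + covariate_contrib + achieved
    return labels, achieved_lp


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _truncated_normal_positive(
    rng: np.random.Generator, mean: float, sd: float, size: int
) -> np.ndarray:
    """Rejection-sample Normal(mean, sd) conditioned on > 0."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 16)
        draw = draw[draw > 0]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_cohort(
    design: CohortDesign,
    model: Optional[ScreenerModel] = None,
    score_only: bool = False,
) -> Cohort:
    """Generate a full synthetic cohort; deterministic given ``design.seed``.

    Returns participants, item responses (``None`` in score-only mode),
    per-day dietary records and a truth table holding the latent state
    (true intake, liability, target score, and in back-fill mode the
    achieved score after item quantisation).
    """
    if model is None:
        model = load_default_model()
    rng = np.random.default_rng(design.seed)
    n = design.n
    ids = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    # --- anthropometry -----------------------------------------------------
    female = rng.random(n) < design.pct_female
    age = rng.normal(design.age_mean, design.age_sd, n).clip(60.0, 105.0)
    height = np.where(
        female, rng.normal(1.60, 0.06, n), rng.normal(1.73, 0.07, n)
    ).clip(1.35, 2.05)
    bmi = rng.normal(design.bmi_mean, design.bmi_sd, n).clip(15.0, 55.0)
    weight = bmi * height**2
    abw = np.where(bmi > 27.0, 27.0 * height**2, np.where(bmi < 22.0, 22.0 * height**2, weight))
    mmse = np.round(rng.normal(28.0, 1.5, n)).clip(24, 30).astype(int)

    participants = pd.DataFrame(
        {
            "participant_id": ids,
            "age": np.round(age, 1),
            "sex": np.where(female, "female", "male"),
            "height_m": np.round(height, 3),
            "weight_kg": np.round(weight, 1),
            "mmse": mmse,
            "tube_feeding": np.zeros(n, dtype=bool),
        }
    )
    # recompute aBW from the rounded values actually shipped, so the truth
    # table matches what the pipeline will compute
    h = participants["height_m"].to_numpy()
    w = participants["weight_kg"].to_numpy()
    bmi_ship = w / h**2
    abw = np.where(bmi_ship > 27.0, 27.0 * h**2, np.where(bmi_ship < 22.0, 22.0 * h**2, w))

    # --- latent intake and screener liability ------------------------------
    true_intake = _truncated_normal_positive(rng, design.protein_mean, design.protein_sd, n)
    z = (true_intake - design.protein_mean) / design.protein_sd
    z_thr = (design.threshold - design.protein_mean) / design.protein_sd
    a = coupling_for_auc(design.target_auc, z_thr)
    liability = -a * z + np.sqrt(1 - a**2) * rng.standard_normal(n)
    target_lp = design.score_mu + design.score_sigma * liability
    target_score = expit(target_lp)

    truth = pd.DataFrame(
        {
            "participant_id": ids,
            "true_protein_per_kg_abw": true_intake,
            "abw": abw,
            "liability": liability,
            "target_score": target_score,
            "low_intake_true": true_intake < design.threshold,
            "coupling": a,
        }
    )

    # --- item back-fill -----------------------------------------------------
    responses: Optional[pd.DataFrame] = None
    if not score_only:
        cov_contrib = np.zeros(n)
        cov_values = {
            "age_years": participants["age"].to_numpy(float),
            "sex_female": female.astype(float),
            "weight_kg": abw if model.weight_term == "adjusted" else w,
            "height_cm": h * 100.0,
        }
        for cov in COVARIATE_KEYS:
            if cov in model.covariates:
                cov_contrib += model.covariates[cov] * cov_values[cov]
        labels, achieved_lp = _backfill_items(model, target_lp, cov_contrib)
        responses = pd.concat(
            [pd.DataFrame({"participant_id": ids}), labels[list(ITEM_KEYS)]], axis=1
        )
        truth["achieved_lp"] = achieved_lp
        truth["achieved_score"] = expit(achieved_lp)

    # --- dietary days --------------------------------------------------------
    protein_gd = true_intake * abw  # true mean grams/day
    resid_var = design.energy_sd**2 - ENERGY_PROTEIN_SLOPE**2 * np.var(protein_gd)
    resid_sd = np.sqrt(max(resid_var, (0.25 * design.energy_sd) ** 2))
    energy_subject = (
        design.energy_mean
        + ENERGY_PROTEIN_SLOPE * (protein_gd - protein_gd.mean())
        + rng.normal(0.0, resid_sd, n)
    ).clip(400.0, None)
    fat_pct = rng.normal(FAT_EPCT_MEAN, FAT_EPCT_SD, n).clip(15.0, 60.0)

    if design.day_cv > 0:
        sig = np.sqrt(np.log1p(design.day_cv**2))
        day_mult = np.exp(rng.normal(-0.5 * sig**2, sig, (n, design.n_days)))
        # Jensen correction: E[1 / mean(day factors)] = 1 + CV^2/n_days to
        # first order, which would bias the g/kg classification toward "low";
        # rescale so the recorded 3-day mean is unbiased for classification.
        day_mult *= 1.0 + design.day_cv**2 / design.n_days
    else:
        day_mult = np.ones((n, design.n_days))

    day_rows = []
    for d in range(design.n_days):
        m = day_mult[:, d]
        energy_d = energy_subject * m
        protein_d = protein_gd * m
        fat_d = fat_pct / 100.0 * energy_d / 9.0
        carb_d = np.maximum((energy_d - 4.0 * protein_d - 9.0 * fat_d) / 4.0, 0.0)
        day_rows.append(
            pd.DataFrame(
                {
                    "participant_id": ids,
                    "day": d + 1,
                    "energy_kcal": np.round(energy_d, 1),
                    "protein_g": np.round(protein_d, 1),
                    "fat_g": np.round(fat_d, 1),
                    "carb_g": np.round(carb_d, 1),
                }
            )
        )
    dietary_days = (
        pd.concat(day_rows, ignore_index=True)
        .sort_values(["participant_id", "day"], kind="stable")
        .reset_index(drop=True)
    )

    return Cohort(
        participants=participants,
        responses=responses,
        dietary_days=dietary_days,
        truth=truth,
    )


def plant_exclusions(
    cohort: Cohort,
    design: CohortDesign,
    counts: Optional[dict[str, int]] = None,
) -> Cohort:
    """Inject eligibility failures into a generated cohort.

    ``counts`` gives the number of participants per reason
    (``low_mmse, tube_feeding, implausible_energy, incomplete_data``);
    when omitted it is derived from ``design.exclusion_rates`` rounded to
    whole subjects. Affected participants are disjoint across reasons. The
    randomness is seeded from ``design.seed + 1`` so planting is
    deterministic and independent of generation order.
    """
    if counts is None:
        counts = {
            reason: int(round(rate * design.n))
            for reason, rate in design.exclusion_rates.items()
        }
    counts = {k: v for k, v in counts.items() if v > 0}
    known = {"low_mmse", "tube_feeding", "implausible_energy", "incomplete_data"}
    bad = set(counts) - known
    if bad:
        raise InvalidInputError(f"unknown exclusion reasons: {sorted(bad)}")
    total = sum(counts.values())
    if total > design.n:
        raise InvalidInputError("more planted exclusions than participants")
    if not counts:
        return cohort

    rng = np.random.default_rng(design.seed + 1)
    participants = cohort.participants.copy()
    dietary_days = cohort.dietary_days.copy()
    responses = cohort.responses.copy() if cohort.responses is not None else None
    truth = cohort.truth.copy()

    chosen = rng.choice(design.n, size=total, replace=False)
    idx_by_reason: dict[str, np.ndarray] = {}
    start = 0
    for reason in ("tube_feeding", "low_mmse", "implausible_energy", "incomplete_data"):
        c = counts.get(reason, 0)
        idx_by_reason[reason] = chosen[start : start + c]
        start += c

    ids = participants["participant_id"].to_numpy()

    if idx_by_reason["tube_feeding"].size:
        participants.loc[idx_by_reason["tube_feeding"], "tube_feeding"] = True
    if idx_by_reason["low_mmse"].size:
        participants.loc[idx_by_reason["low_mmse"], "mmse"] = rng.integers(
            15, 24, size=idx_by_reason["low_mmse"].size
        )
    if idx_by_reason["implausible_energy"].size:
        bad_ids = set(ids[idx_by_reason["implausible_energy"]])
        mask = dietary_days["participant_id"].isin(bad_ids)
        # 10x the sample mean is > 3 SD away for any energy CV below ~3
        dietary_days.loc[mask, "energy_kcal"] *= 10.0
    if idx_by_reason["incomplete_data"].size:
        if responses is None:
            raise InvalidInputError(
                "cannot plant incomplete questionnaires in score-only mode"
            )
        for i in idx_by_reason["incomplete_data"]:
            item = ITEM_KEYS[int(rng.integers(0, len(ITEM_KEYS)))]
            responses.loc[i, item] = np.nan

    planted = np.full(design.n, "", dtype=object)
    for reason in ("tube_feeding", "low_mmse", "implausible_energy", "incomplete_data"):
        planted[idx_by_reason[reason]] = reason
    truth["planted_exclusion"] = planted

    return Cohort(
        participants=participants,
        responses=responses,
        dietary_days=dietary_days,
        truth=truth,
    )
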