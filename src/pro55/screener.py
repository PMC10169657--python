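"""Scoring of the Protein Screener 55+ questionnaire.

The screener asks ten questions about habitual consumption of protein-rich
foods (bread, milk, meat, cheese amount and frequency, dairy, eggs, pasta,
fish, nuts) and additionally records age, sex, body height and weight. Each
item response is mapped to a numeric code; the codes and anthropometric
covariates enter a logistic prediction model whose inverse-logit output is
the predicted probability that protein intake is below 1.0 g per kg adjusted
body weight per day.

The coding maps and coefficients are *data*, not code: they live in a YAML
configuration (see :func:`load_model`) so that different equation versions
can be swapped without touching the scoring logic. The bundled default
configuration is a synthetic stand-in (see ``data/screener_model_synthetic.yaml``):
it has the published instrument's structure — ten items, age/sex/height/weight
covariates, a logistic link — but placeholder coefficient values.
"""

from __future__ import annotations

import math
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from pro55.errors import (
    CodingError,
    ConfigurationError,
    ContractError,
    IncompleteResponseError,
    InvalidInputError,
)

#: The ten questionnaire items, in instrument order.
ITEM_KEYS: tuple[str, ...] = (
    "bread_slices",
    "milk_glasses",
    "meat_portion",
    "cheese_amount",
    "cheese_frequency",
    "dairy_frequency",
    "egg_frequency",
    "pasta_frequency",
    "fish_frequency",
    "nuts_frequency",
)

#: Covariate names a model configuration may use, with their units.
COVARIATE_KEYS: tuple[str, ...] = ("age_years", "sex_female", "weight_kg", "height_cm")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


class Anthropometry(BaseModel):
    """Height (m), weight (kg), age (years) and sex for one subject.

    Height and weight bounds are hard errors; age below 55 is allowed (the
    instrument targets 55+, but scoring younger adults is not physically
    impossible) and merely outside the validated range.
    """

    model_config = ConfigDict(frozen=True)

    height: float = Field(gt=0.5, lt=2.5, description="standing height in meters")
    weight: float = Field(gt=20, lt=300, description="body weight in kilograms")
    age: float = Field(gt=0, description="age in years")
    sex: str = Field(description="'female' or 'male'")

    @field_validator("sex")
    @classmethod
    def _check_sex(cls, v: str) -> str:
        v = v.strip().lower()
        if v not in {"female", "male"}:
            raise ValueError(f"sex must be 'female' or 'male', got {v!r}")
        return v


class ScreenerResponse(BaseModel):
    """One participant's answers to the ten screener items.

    Each field holds the *category label* as it appears in the active
    model's coding map. ``None`` marks a missing item; a response with any
    missing item is incomplete and is excluded from scoring rather than
    imputed.
    """

    model_config = ConfigDict(frozen=True)

    participant_id: str
    bread_slices: Optional[str] = None
    milk_glasses: Optional[str] = None
    meat_portion: Optional[str] = None
    cheese_amount: Optional[str] = None
    cheese_frequency: Optional[str] = None
    dairy_frequency: Optional[str] = None
    egg_frequency: Optional[str] = None
    pasta_frequency: Optional[str] = None
    fish_frequency: Optional[str] = None
    nuts_frequency: Optional[str] = None

    def items_dict(self) -> dict[str, Optional[str]]:
        return {k: getattr(self, k) for k in ITEM_KEYS}

    @property
    def complete(self) -> bool:
        return all(getattr(self, k) is not None for k in ITEM_KEYS)


class ItemCoding(BaseModel):
    """Coding map and weight for one questionnaire item.

    ``codes`` maps each admissible category label to its numeric code;
    ``coefficient`` is the logistic-regression weight applied to the code.
    """

    model_config = ConfigDict(frozen=True)

    codes: dict[str, float]
    coefficient: float

    @field_validator("codes")
    @classmethod
    def _nonempty(cls, v: dict[str, float]) -> dict[str, float]:
        if not v:
            raise ValueError("coding map must declare at least one category")
        return v


class ScreenerModel(BaseModel):
    """A fully specified Pro55+ prediction equation.

    linear predictor = intercept
                       + sum_i  coefficient_i * code_i(label_i)
                       + sum_c  covariate_coefficient_c * covariate_c

    and predicted probability = expit(linear predictor). Covariates may be
    any subset of ``age_years``, ``sex_female`` (indicator, reference level
    in metadata), ``weight_kg`` and ``height_cm``; ``weight_term`` states
    explicitly whether the weight covariate uses raw or adjusted body weight.
    """

    model_config = ConfigDict(frozen=True)

    intercept: float
    items: dict[str, ItemCoding]
    covariates: dict[str, float] = Field(default_factory=dict)
    weight_term: str = "raw"  # 'raw' | 'adjusted'
    metadata: dict[str, str] = Field(default_factory=dict)

    @field_validator("weight_term")
    @classmethod
    def _check_weight_term(cls, v: str) -> str:
        if v not in {"raw", "adjusted"}:
            raise ValueError("weight_term must be 'raw' or 'adjusted'")
        return v

    @model_validator(mode="after")
    def _check_keys(self) -> "ScreenerModel":
        missing = set(ITEM_KEYS) - set(self.items)
        extra = set(self.items) - set(ITEM_KEYS)
        if missing:
            raise ValueError(f"model is missing item definitions: {sorted(missing)}")
        if extra:
            raise ValueError(f"model declares unknown items: {sorted(extra)}")
        bad_cov = set(self.covariates) - set(COVARIATE_KEYS)
        if bad_cov:
            raise ValueError(f"unknown covariates: {sorted(bad_cov)}")
        return self

    @property
    def term_names(self) -> list[str]:
        """Ordered names of the design-vector terms (items then covariates)."""
        return list(ITEM_KEYS) + [c for c in COVARIATE_KEYS if c in self.covariates]

    @property
    def coefficients(self) -> np.ndarray:
        """Coefficient vector aligned with :attr:`term_names`."""
        item_part = [self.items[k].coefficient for k in ITEM_KEYS]
        cov_part = [self.covariates[c] for c in COVARIATE_KEYS if c in self.covariates]
        return np.asarray(item_part + cov_part, dtype=float)


# ---------------------------------------------------------------------------
# anthropometric operations
# ---------------------------------------------------------------------------


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m², from weight (kg) and height (m)."""
    weight = float(weight)
    height = float(height)
    if not math.isfinite(weight) or weight <= 0:
        raise InvalidInputError(f"weight must be positive and finite, got {weight}")
    if not math.isfinite(height) or height <= 0:
        raise InvalidInputError(f"height must be positive and finite, got {height}")
    return weight / height**2


def adjusted_body_weight(weight: float, height: float) -> float:
    """Body weight capped/floored to the BMI 22-27 kg/m² band.

    For BMI above 27 the weight corresponding to BMI 27 is used, for BMI
    below 22 the weight corresponding to BMI 22; otherwise the measured
    weight is returned unchanged. The adjusted weight therefore always lies
    in [22 h², 27 h²]. It is the denominator for protein intake per kg,
    reflecting lower protein needs per measured kg in overweight and higher
    needs in underweight persons.
    """
    bmi = compute_bmi(weight, height)
    if bmi > 27.0:
        return 27.0 * float(height) ** 2
    if bmi < 22.0:
        return 22.0 * float(height) ** 2
    return float(weight)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def _covariate_value(name: str, anthro: Anthropometry, model: ScreenerModel) -> float:
    if name == "age_years":
        return anthro.age
    if name == "sex_female":
        return 1.0 if anthro.sex == "female" else 0.0
    if name == "weight_kg":
        if model.weight_term == "adjusted":
            return adjusted_body_weight(anthro.weight, anthro.height)
        return anthro.weight
    if name == "height_cm":
        return anthro.height * 100.0
    raise ContractError(f"unknown covariate {name!r}")


def code_response(
    model: ScreenerModel, response: ScreenerResponse, anthro: Anthropometry
) -> np.ndarray:
    """Code a complete response into the model's design vector.

    The vector is aligned with :attr:`ScreenerModel.term_names`: ten item
    codes followed by the covariate values the model uses. Deterministic:
    the same response always yields the identical vector.
    """
    if not response.complete:
        missing = [k for k, v in response.items_dict().items() if v is None]
        raise IncompleteResponseError(
            f"participant {response.participant_id!r} has missing items: {missing}"
        )
    values: list[float] = []
    for key in ITEM_KEYS:
        label = getattr(response, key)
        coding = model.items[key]
        if label not in coding.codes:
            raise CodingError(
                f"item {key!r}: unknown category label {label!r} "
                f"(expected one of {sorted(coding.codes)})"
            )
        values.append(coding.codes[label])
    for cov in COVARIATE_KEYS:
        if cov in model.covariates:
            values.append(_covariate_value(cov, anthro, model))
    return np.asarray(values, dtype=float)


def linear_predictor(model: ScreenerModel, design: np.ndarray) -> float:
    """Intercept plus coefficient-weighted design vector."""
    design = np.asarray(design, dtype=float)
    coef = model.coefficients
    if design.shape[-1] != coef.shape[0]:
        raise ContractError(
            f"design vector has {design.shape[-1]} terms, model expects {coef.shape[0]}"
        )
    return model.intercept + design @ coef


def predicted_probability(model: ScreenerModel, design: np.ndarray) -> float:
    """Predicted probability of low protein intake: expit of the linear predictor.

    Strictly inside (0, 1) and monotone increasing in the linear predictor.
    """
    from scipy.special import expit

    return expit(linear_predictor(model, design))


def score_participants(
    model: ScreenerModel,
    responses: pd.DataFrame,
    anthropometry: pd.DataFrame,
) -> pd.DataFrame:
    """Score a cohort of questionnaire responses.

    Parameters
    ----------
    responses
        One row per participant; columns ``participant_id`` plus the ten
        item keys holding category labels (NaN/empty = missing).
    anthropometry
        Columns ``participant_id, age, sex, height_m, weight_kg``.

    Returns
    -------
    DataFrame with columns ``participant_id, bmi, abw, complete,
    linear_predictor, predicted_probability``; incomplete responses keep
    NaN in the score columns and ``complete == False``. Scoring is pure and
    row-wise: batch output equals element-wise scoring.
    """
    required = {"participant_id", *ITEM_KEYS}
    missing_cols = required - set(responses.columns)
    if missing_cols:
        raise ContractError(f"responses missing columns: {sorted(missing_cols)}")
    anth_req = {"participant_id", "age", "sex", "height_m", "weight_kg"}
    missing_cols = anth_req - set(anthropometry.columns)
    if missing_cols:
        raise ContractError(f"anthropometry missing columns: {sorted(missing_cols)}")

    merged = responses.merge(
        anthropometry[list(anth_req)], on="participant_id", how="left", validate="1:1"
    )
    if merged["age"].isna().any():
        orphans = merged.loc[merged["age"].isna(), "participant_id"].tolist()
        raise ContractError(f"no anthropometry for participants: {orphans}")

    rows = []
    for rec in merged.to_dict("records"):
        anthro = Anthropometry(
            height=rec["height_m"], weight=rec["weight_kg"], age=rec["age"], sex=rec["sex"]
        )
        items = {
            k: (None if pd.isna(rec[k]) or rec[k] == "" else str(rec[k])) for k in ITEM_KEYS
        }
        resp = ScreenerResponse(participant_id=str(rec["participant_id"]), **items)
        bmi = compute_bmi(anthro.weight, anthro.height)
        abw = adjusted_body_weight(anthro.weight, anthro.height)
        if resp.complete:
            design = code_response(model, resp, anthro)
            lp = linear_predictor(model, design)
            prob = predicted_probability(model, design)
        else:
            lp = prob = float("nan")
        rows.append(
            {
                "participant_id": rec["participant_id"],
                "bmi": bmi,
                "abw": abw,
                "complete": resp.complete,
                "linear_predictor": lp,
                "predicted_probability": prob,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------


def _model_from_mapping(raw: Mapping) -> ScreenerModel:
    if not isinstance(raw, Mapping):
        raise ConfigurationError("model configuration must be a mapping")
    try:
        return ScreenerModel(**raw)
    except Exception as exc:  # pydantic ValidationError -> descriptive config error
        raise ConfigurationError(f"invalid screener model configuration: {exc}") from exc


def load_model(path: str | Path) -> ScreenerModel:
    """Load and validate a screener model from a YAML configuration file."""
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return _model_from_mapping(raw)


def save_model(model: ScreenerModel, path: str | Path) -> None:
    """Write a model back to YAML; round-trips through :func:`load_model`."""
    payload = model.model_dump()
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_default_model() -> ScreenerModel:
    """Load the bundled synthetic stand-in model configuration."""
    ref = resources.files("pro55.data").joinpath("screener_model_synthetic.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _model_from_mapping(raw)


def achievable_lp_range(
    model: ScreenerModel, anthro: Anthropometry
) -> tuple[float, float]:
    """Min and max linear predictor reachable by varying item answers only.

    Used by the synthetic generator to back-fill item responses for a
    target score.
    """
    base = model.intercept + sum(
        model.covariates[c] * _covariate_value(c, anthro, model)
        for c in model.covariates
    )
    lo = base
    hi = base
    for key in ITEM_KEYS:
        coding = model.items[key]
        contrib = [coding.coefficient * v for v in coding.codes.values()]
        lo += min(contrib)
        hi += max(contrib)
    return lo, hi
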