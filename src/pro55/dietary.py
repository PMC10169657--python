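"""Reference-standard protein intake from 3-day dietary records.

Per-day nutrient totals (energy kcal, protein/fat/carbohydrate g) are
averaged over the recorded days; protein intake is normalised to grams per
kg *adjusted* body weight per day and classified against a low-intake
threshold (1.0 or 0.8 g/kg aBW/d, strict "<"). The module also applies the
study-style eligibility filters: cognitive status (MMSE >= 24), a clinical
exclusion flag (tube feeding), plausible energy intake (within +/- 3 sample
standard deviations of the sample mean), and completeness of both the
questionnaire and the record.

Energy percentages use the Atwater factors 4 kcal/g for protein and
carbohydrate and 9 kcal/g for fat.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pro55.errors import ContractError, DegenerateDataError, InvalidInputError
from pro55.screener import Anthropometry, adjusted_body_weight

KCAL_PER_G_PROTEIN = 4.0
KCAL_PER_G_FAT = 9.0
KCAL_PER_G_CARB = 4.0

#: Exclusion reasons in precedence order (highest first). A participant
#: failing several criteria is logged once, under the first that applies.
EXCLUSION_PRECEDENCE: tuple[str, ...] = (
    "tube_feeding",
    "low_mmse",
    "implausible_energy",
    "incomplete_data",
)

MMSE_CUTOFF = 24


@dataclass(frozen=True)
class DietaryDay:
    """Nutrient totals for one recorded day."""

    participant_id: str
    day_index: int
    energy: float  # kcal
    protein: float  # g
    fat: float  # g
    carbohydrate: float  # g

    def __post_init__(self) -> None:
        if self.day_index < 1:
            raise InvalidInputError("day_index must be >= 1")
        if self.energy <= 0:
            raise InvalidInputError("a recorded day must have energy > 0")
        for field in ("protein", "fat", "carbohydrate"):
            if getattr(self, field) < 0:
                raise InvalidInputError(f"{field} must be >= 0")


@dataclass(frozen=True)
class DietarySummary:
    """Mean daily intake for one participant, normalised to adjusted body weight."""

    participant_id: str
    n_days: int
    mean_energy: float
    mean_protein: float
    mean_fat: float
    mean_carb: float
    protein_per_kg_abw: float
    energy_pct_protein: float
    energy_pct_fat: float
    energy_pct_carb: float


@dataclass(frozen=True)
class EligibilityFlags:
    """Component eligibility flags; ``included`` is their conjunction."""

    mmse_ok: bool
    not_tube_fed: bool
    energy_plausible: bool
    data_complete: bool

    @property
    def included(self) -> bool:
        return (
            self.mmse_ok
            and self.not_tube_fed
            and self.energy_plausible
            and self.data_complete
        )


def summarize_record(
    days: Sequence[DietaryDay], anthro: Anthropometry
) -> DietarySummary:
    """Average a participant's recorded days and normalise protein to aBW.

    Arithmetic means over however many days are present (three expected);
    permutation-invariant over days.
    """
    if not days:
        raise InvalidInputError("at least one recorded day is required")
    pids = {d.participant_id for d in days}
    if len(pids) != 1:
        raise ContractError(f"days span multiple participants: {sorted(pids)}")
    energy = float(np.mean([d.energy for d in days]))
    protein = float(np.mean([d.protein for d in days]))
    fat = float(np.mean([d.fat for d in days]))
    carb = float(np.mean([d.carbohydrate for d in days]))
    abw = adjusted_body_weight(anthro.weight, anthro.height)
    return DietarySummary(
        participant_id=days[0].participant_id,
        n_days=len(days),
        mean_energy=energy,
        mean_protein=protein,
        mean_fat=fat,
        mean_carb=carb,
        protein_per_kg_abw=protein / abw,
        energy_pct_protein=100.0 * KCAL_PER_G_PROTEIN * protein / energy,
        energy_pct_fat=100.0 * KCAL_PER_G_FAT * fat / energy,
        energy_pct_carb=100.0 * KCAL_PER_G_CARB * carb / energy,
    )


def summarize_records(
    days: pd.DataFrame, anthropometry: pd.DataFrame
) -> pd.DataFrame:
    """Batch version of :func:`summarize_record` over a long-format day table.

    ``days`` needs columns ``participant_id, day, energy_kcal, protein_g,
    fat_g, carb_g``; ``anthropometry`` needs ``participant_id, height_m,
    weight_kg``. Returns one row per participant with the
    :class:`DietarySummary` fields plus ``abw``.
    """
    req = {"participant_id", "day", "energy_kcal", "protein_g", "fat_g", "carb_g"}
    missing = req - set(days.columns)
    if missing:
        raise ContractError(f"dietary days missing columns: {sorted(missing)}")

    agg = (
        days.groupby("participant_id", sort=False)
        .agg(
            n_days=("day", "size"),
            mean_energy=("energy_kcal", "mean"),
            mean_protein=("protein_g", "mean"),
            mean_fat=("fat_g", "mean"),
            mean_carb=("carb_g", "mean"),
        )
        .reset_index()
    )
    anth = anthropometry[["participant_id", "height_m", "weight_kg"]]
    merged = agg.merge(anth, on="participant_id", how="left", validate="1:1")
    if merged["height_m"].isna().any():
        orphans = merged.loc[merged["height_m"].isna(), "participant_id"].tolist()
        raise ContractError(f"no anthropometry for participants: {orphans}")
    h = merged["height_m"].to_numpy(float)
    w = merged["weight_kg"].to_numpy(float)
    bmi = w / h**2
    abw = np.where(bmi > 27.0, 27.0 * h**2, np.where(bmi < 22.0, 22.0 * h**2, w))
    merged["abw"] = abw
    merged["protein_per_kg_abw"] = merged["mean_protein"] / abw
    merged["energy_pct_protein"] = (
        100.0 * KCAL_PER_G_PROTEIN * merged["mean_protein"] / merged["mean_energy"]
    )
    merged["energy_pct_fat"] = (
        100.0 * KCAL_PER_G_FAT * merged["mean_fat"] / merged["mean_energy"]
    )
    merged["energy_pct_carb"] = (
        100.0 * KCAL_PER_G_CARB * merged["mean_carb"] / merged["mean_energy"]
    )
    return merged.drop(columns=["height_m", "weight_kg"])


def classify_low_intake(
    summary: DietarySummary | float, threshold: float = 1.0
) -> bool:
    """True iff protein intake per kg aBW is strictly below ``threshold``.

    Strict inequality: a person at exactly the threshold has adequate
    intake. Monotone in the threshold.
    """
    if threshold <= 0:
        raise InvalidInputError("threshold must be positive")
    value = (
        summary.protein_per_kg_abw if isinstance(summary, DietarySummary) else float(summary)
    )
    return value < threshold


def energy_plausibility_filter(
    mean_energies: Iterable[float], k: float = 3.0
) -> np.ndarray:
    """Flag implausible mean energy intakes, a single pass over the sample.

    A value is plausible iff it lies inside [mean - k*SD, mean + k*SD]
    (inclusive bounds; sample SD with n-1 denominator), where mean and SD
    are computed on the submitted sample itself — the bounds are not
    re-estimated after exclusions. A zero-SD sample flags everything
    plausible (the bounds collapse onto the mean and equality passes).
    """
    values = np.asarray(list(mean_energies), dtype=float)
    if values.size < 2:
        raise DegenerateDataError(
            "energy plausibility needs at least 2 records to estimate the sample SD"
        )
    mean = values.mean()
    sd = values.std(ddof=1)
    return (values >= mean - k * sd) & (values <= mean + k * sd)


def apply_eligibility(
    participants: pd.DataFrame,
    summaries: pd.DataFrame,
    scored: pd.DataFrame,
    energy_sd_multiplier: float = 3.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the four eligibility filters and log exclusions.

    Parameters
    ----------
    participants
        Columns ``participant_id, mmse`` and optional ``tube_feeding``
        (boolean/0-1 clinical flag; tube feeding is an input, never
        inferred from intake).
    summaries
        Output of :func:`summarize_records` (needs ``mean_energy``).
        Participants without any dietary record count as incomplete data.
    scored
        Output of :func:`pro55.screener.score_participants` (needs
        ``complete``).

    Returns
    -------
    (included, exclusion_log)
        ``included``: the participant rows passing every filter.
        ``exclusion_log``: columns ``participant_id, reason, detail`` with
        one row per excluded participant, the reason chosen by the fixed
        precedence tube feeding > low MMSE > implausible energy >
        incomplete data. Included + excluded partition the input.
    """
    if "participant_id" not in participants.columns or "mmse" not in participants.columns:
        raise ContractError("participants needs columns participant_id and mmse")
    pid = participants["participant_id"]
    orphan_sum = set(summaries["participant_id"]) - set(pid)
    orphan_scr = set(scored["participant_id"]) - set(pid)
    if orphan_sum or orphan_scr:
        raise ContractError(
            f"records for unknown participants: {sorted(orphan_sum | orphan_scr)}"
        )

    df = participants.copy()
    if "tube_feeding" not in df.columns:
        df["tube_feeding"] = False
    df["tube_feeding"] = df["tube_feeding"].fillna(False).astype(bool)

    df = df.merge(
        summaries[["participant_id", "mean_energy"]], on="participant_id", how="left"
    )
    df = df.merge(
        scored[["participant_id", "complete"]].rename(
            columns={"complete": "screener_complete"}
        ),
        on="participant_id",
        how="left",
    )
    df["screener_complete"] = df["screener_complete"].fillna(False).astype(bool)

    has_record = df["mean_energy"].notna()
    plausible = np.ones(len(df), dtype=bool)
    if has_record.any():
        plausible_rec = energy_plausibility_filter(
            df.loc[has_record, "mean_energy"], k=energy_sd_multiplier
        )
        plausible[has_record.to_numpy()] = plausible_rec

    fail = {
        "tube_feeding": df["tube_feeding"].to_numpy(),
        "low_mmse": (df["mmse"] < MMSE_CUTOFF).to_numpy(),
        "implausible_energy": has_record.to_numpy() & ~plausible,
        "incomplete_data": (~df["screener_complete"] | ~has_record).to_numpy(),
    }
    detail = {
        "tube_feeding": "clinical exclusion flag set",
        "low_mmse": f"MMSE below {MMSE_CUTOFF}",
        "implausible_energy": (
            f"mean energy outside sample mean +/- {energy_sd_multiplier:g} SD"
        ),
        "incomplete_data": "missing screener items or dietary record",
    }

    reason = np.full(len(df), "", dtype=object)
    for r in EXCLUSION_PRECEDENCE:
        reason = np.where((reason == "") & fail[r], r, reason)

    log = pd.DataFrame(
        {
            "participant_id": df.loc[reason != "", "participant_id"].to_numpy(),
            "reason": reason[reason != ""],
        }
    )
    log["detail"] = log["reason"].map(detail)
    included = participants[np.asarray(reason == "", dtype=bool)].copy()
    return included, log
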