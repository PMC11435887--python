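"""Clinical scoring and trial-level outcomes.

Covers the canine chronic enteropathy clinical activity index (CCECAI: nine
items scored 0-3, total 0-27 with severity bands), the 9-point fecal
consistency score (FCS, 1-5 in half-point steps), fecal dry matter (FDM)
from duplicate wet/dry weighings, the remission/relapse classifiers built
on those scores, weight-banded capsule dosing, per-phase responder
arithmetic with an exact test for the group contrast, the FCS~FDM simple
linear regression, and baseline-adjusted change-from-baseline (ANCOVA).

A note on FDM: the conventional formula in the veterinary literature prints
as ((wet - dry) / wet) x 100, which is the moisture percentage, while
reported dry-matter medians are on the dry/wet scale. Both conventions are
implemented; the default is dry/wet x 100 (the two always sum to 100).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


class ClinicalError(ValueError):
    pass


CCECAI_ITEMS = (
    "attitude_activity",
    "appetite",
    "vomiting",
    "fecal_consistency",
    "defecation_frequency",
    "weight_loss",
    "albumin",
    "ascites_edema",
    "pruritus",
)

CCECAI_BANDS = (
    (0, 3, "insignificant"),
    (4, 5, "mild"),
    (6, 8, "moderate"),
    (9, 11, "severe"),
    (12, 27, "very_severe"),
)

FCS_GRID = tuple(x / 2 for x in range(2, 11))  # 1.0, 1.5, ..., 5.0


def round_half_up(value: float, decimals: int = 1) -> float:
    """Decimal half-up rounding (5 rounds away from zero), as printed in
    clinical reports; numpy/python banker's rounding would turn 0.25 -> 0.2."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def ccecai_total(items) -> int:
    """Sum of the nine 0-3 item scores."""
    items = list(items)
    if len(items) != len(CCECAI_ITEMS):
        raise ClinicalError(f"expected {len(CCECAI_ITEMS)} item scores, got {len(items)}")
    for name, value in zip(CCECAI_ITEMS, items):
        if value not in (0, 1, 2, 3):
            raise ClinicalError(f"item {name!r} must be an integer 0-3, got {value!r}")
    return int(sum(items))


def ccecai_band(total: int) -> str:
    """Severity band: 0-3 insignificant, 4-5 mild, 6-8 moderate, 9-11 severe,
    >=12 very severe."""
    if not isinstance(total, (int, np.integer)) or not 0 <= total <= 27:
        raise ClinicalError(f"total must be an integer in [0, 27], got {total!r}")
    for lo, hi, band in CCECAI_BANDS:
        if lo <= total <= hi:
            return band
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class CcecaiAssessment:
    dog_id: str
    visit: str
    items: tuple[int, ...]

    @property
    def total(self) -> int:
        return ccecai_total(self.items)

    @property
    def band(self) -> str:
        return ccecai_band(self.total)


@dataclass(frozen=True)
class FecalDiaryEntry:
    dog_id: str
    day: int
    fcs: float

    def __post_init__(self) -> None:
        if self.fcs not in FCS_GRID:
            raise ClinicalError(
                f"FCS must be on the half-point grid 1.0-5.0, got {self.fcs!r}"
            )


def mean_fcs(diary: list[FecalDiaryEntry], evaluation_day: int, window_days: int = 3) -> float:
    """Mean FCS over all defecation events in the `window_days`-day window
    ending at `evaluation_day` (inclusive)."""
    start = evaluation_day - window_days + 1
    values = [e.fcs for e in diary if start <= e.day <= evaluation_day]
    if not values:
        raise ClinicalError(
            f"no diary entries in days [{start}, {evaluation_day}]: evaluation impossible"
        )
    return float(np.mean(values))


def classify_remission(ccecai_total: int, mean_fcs: float) -> bool:
    """Remission: CCECAI total <= 3 AND mean FCS <= 3."""
    return ccecai_total <= 3 and mean_fcs <= 3


def classify_relapse(ccecai_total: int, ce_signs: bool, fcs: float) -> bool:
    """Relapse: CCECAI total > 3, OR clinical signs of CE together with
    FCS >= 4."""
    return (ccecai_total > 3) or (ce_signs and fcs >= 4)


# ---------------------------------------------------------------------------
# Fecal dry matter
# ---------------------------------------------------------------------------

def fdm_percent(wet_mass: float, dry_mass: float, convention: str = "dry_over_wet") -> float:
    """FDM% for one weighing: dry/wet x 100 (default) or the printed
    moisture-style formula (wet - dry)/wet x 100. The two sum to 100."""
    if wet_mass <= 0:
        raise ClinicalError("wet mass must be positive")
    if dry_mass < 0 or dry_mass > wet_mass:
        raise ClinicalError("dry mass must satisfy 0 <= dry <= wet")
    if convention == "dry_over_wet":
        return 100.0 * dry_mass / wet_mass
    if convention == "printed_formula":
        return 100.0 * (wet_mass - dry_mass) / wet_mass
    raise ClinicalError(f"unknown convention {convention!r}")


@dataclass(frozen=True)
class FdmMeasurement:
    """Duplicate wet/dry weighing pair for one fecal sample."""

    dog_id: str
    visit: str
    wet1: float
    dry1: float
    wet2: float
    dry2: float
    convention: str = "dry_over_wet"

    @property
    def replicate_percents(self) -> tuple[float, float]:
        return (
            fdm_percent(self.wet1, self.dry1, self.convention),
            fdm_percent(self.wet2, self.dry2, self.convention),
        )

    @property
    def fdm_percent(self) -> float:
        """Mean of the duplicate percentages."""
        a, b = self.replicate_percents
        return (a + b) / 2.0

    @property
    def cv_percent(self) -> float:
        reps = np.asarray(self.replicate_percents)
        m = reps.mean()
        return float(100.0 * reps.std(ddof=1) / m) if m > 0 else 0.0


# ---------------------------------------------------------------------------
# Dosing
# ---------------------------------------------------------------------------

def capsule_dose(body_weight_kg: float) -> int:
    """Daily capsule count by body-weight band: (5,10] 1, (10,20] 2,
    (20,30] 3, >30 4. Weights below the dosing table are an error."""
    if body_weight_kg < 5:
        raise ClinicalError(f"weight {body_weight_kg} kg below the dosing table (>= 5 kg)")
    if body_weight_kg <= 10:
        return 1
    if body_weight_kg <= 20:
        return 2
    if body_weight_kg <= 30:
        return 3
    return 4


# ---------------------------------------------------------------------------
# Trial outcomes
# ---------------------------------------------------------------------------

STATUSES = ("responder", "relapsed", "excluded")


@dataclass(frozen=True)
class DispositionRecord:
    """Terminal status of one dog in one phase."""

    dog_id: str
    group: str  # FMT | placebo
    phase: str  # treatment | post_treatment
    status: str  # responder | relapsed | excluded
    exclusion_reason: str = ""

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ClinicalError(f"unknown status {self.status!r}")
        if self.group not in ("FMT", "placebo"):
            raise ClinicalError(f"unknown group {self.group!r}")
        if self.phase not in ("treatment", "post_treatment"):
            raise ClinicalError(f"unknown phase {self.phase!r}")


@dataclass
class PhaseOutcome:
    group: str
    phase: str
    n_evaluable: int
    n_relapsed: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)

    @property
    def responder_percent(self) -> float:
        return round_half_up(
            100.0 * (self.n_evaluable - self.n_relapsed) / self.n_evaluable, 1
        )

    @property
    def relapse_percent(self) -> float:
        return round_half_up(100.0 * self.n_relapsed / self.n_evaluable, 1)


def phase_outcomes(
    records: list[DispositionRecord],
) -> tuple[list[PhaseOutcome], dict[str, float]]:
    """Per group x phase disposition arithmetic plus a two-sided exact-test p
    for the FMT-vs-placebo relapse contrast in each phase.

    A dog is evaluable in a phase if it has a record there and was not
    excluded; the exact test is Fisher's on the 2x2 relapse table.
    """
    outcomes = []
    p_values: dict[str, float] = {}
    frame = pd.DataFrame([r.__dict__ for r in records])
    if frame.empty:
        raise ClinicalError("no disposition records")
    dup = frame.duplicated(subset=["dog_id", "phase"])
    if dup.any():
        raise ClinicalError(
            f"duplicate disposition record(s): {frame.loc[dup, ['dog_id', 'phase']].values.tolist()}"
        )
    for phase in ("treatment", "post_treatment"):
        table = []
        for group in ("FMT", "placebo"):
            sub = frame[(frame["group"] == group) & (frame["phase"] == phase)]
            if sub.empty:
                continue
            excluded = sub[sub["status"] == "excluded"]
            evaluable = sub[sub["status"] != "excluded"]
            if evaluable.empty:
                raise ClinicalError(f"no evaluable dogs in group {group!r}, phase {phase!r}")
            n_rel = int((evaluable["status"] == "relapsed").sum())
            outcomes.append(
                PhaseOutcome(
                    group=group,
                    phase=phase,
                    n_evaluable=len(evaluable),
                    n_relapsed=n_rel,
                    exclusions=list(
                        zip(excluded["dog_id"], excluded["exclusion_reason"])
                    ),
                )
            )
            table.append([n_rel, len(evaluable) - n_rel])
        if len(table) == 2:
            _, p = stats.fisher_exact(table, alternative="two-sided")
            p_values[phase] = float(p)
    return outcomes, p_values


def cumulative_relapse(records: list[DispositionRecord], group: str) -> tuple[int, int, float]:
    """Relapses across both phases over dogs never excluded, as
    (n_relapsed, n_evaluable, relapse_percent)."""
    frame = pd.DataFrame([r.__dict__ for r in records])
    sub = frame[frame["group"] == group]
    if sub.empty:
        raise ClinicalError(f"no records for group {group!r}")
    excluded_dogs = set(sub.loc[sub["status"] == "excluded", "dog_id"])
    evaluable_dogs = sorted(set(sub["dog_id"]) - excluded_dogs)
    if not evaluable_dogs:
        raise ClinicalError(f"no evaluable dogs in group {group!r}")
    relapsed_dogs = set(sub.loc[sub["status"] == "relapsed", "dog_id"]) & set(evaluable_dogs)
    n_rel, n_eval = len(relapsed_dogs), len(evaluable_dogs)
    return n_rel, n_eval, round_half_up(100.0 * n_rel / n_eval, 1)


def fcs_fdm_regression(pairs) -> dict[str, float]:
    """OLS of FCS on FDM%: slope, intercept, Pearson r, r_squared."""
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ClinicalError("need at least 3 (FDM, FCS) pairs")
    fdm = np.asarray([p[0] for p in pairs], dtype=float)
    fcs = np.asarray([p[1] for p in pairs], dtype=float)
    if np.ptp(fdm) == 0:
        raise ClinicalError("FDM is constant: regression undefined")
    fit = stats.linregress(fdm, fcs)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "pearson_r": float(fit.rvalue),
        "r_squared": float(fit.rvalue**2),
        "p_value": float(fit.pvalue),
        "n": len(pairs),
    }


def baseline_adjusted_change(baseline, followup, group) -> tuple[float, float]:
    """ANCOVA: followup ~ group + baseline; returns (group effect, p)."""
    import statsmodels.api as sm

    baseline = np.asarray(baseline, dtype=float)
    followup = np.asarray(followup, dtype=float)
    group = np.asarray(list(group))
    if not (len(baseline) == len(followup) == len(group)):
        raise ClinicalError("baseline, followup, and group must have equal length")
    uniq = np.unique(group)
    if len(uniq) != 2:
        raise ClinicalError(f"need exactly two groups, got {list(uniq)}")
    counts = [int((group == g).sum()) for g in uniq]
    if min(counts) < 2:
        raise ClinicalError("need at least 2 subjects per group")
    indicator = (group == uniq[1]).astype(float)
    x = sm.add_constant(np.column_stack([indicator, baseline]))
    fit = sm.OLS(followup, x).fit()
    return float(fit.params[1]), float(fit.pvalues[1])


# ---------------------------------------------------------------------------
# Clinical CSV I/O
# ---------------------------------------------------------------------------

def read_ccecai(path) -> list[CcecaiAssessment]:
    frame = pd.read_csv(path)
    expected = ["dog_id", "visit", *CCECAI_ITEMS]
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ClinicalError(f"{path}: missing column(s) {missing}")
    return [
        CcecaiAssessment(
            dog_id=row["dog_id"],
            visit=row["visit"],
            items=tuple(int(row[c]) for c in CCECAI_ITEMS),
        )
        for _, row in frame.iterrows()
    ]


def read_fcs_diary(path) -> list[FecalDiaryEntry]:
    frame = pd.read_csv(path)
    return [
        FecalDiaryEntry(dog_id=row["dog_id"], day=int(row["day"]), fcs=float(row["fcs"]))
        for _, row in frame.iterrows()
    ]


def read_fdm(path, convention: str = "dry_over_wet") -> list[FdmMeasurement]:
    frame = pd.read_csv(path)
    return [
        FdmMeasurement(
            dog_id=row["dog_id"],
            visit=row["visit"],
            wet1=float(row["wet1"]),
            dry1=float(row["dry1"]),
            wet2=float(row["wet2"]),
            dry2=float(row["dry2"]),
            convention=convention,
        )
        for _, row in frame.iterrows()
    ]


def read_disposition(path) -> list[DispositionRecord]:
    frame = pd.read_csv(path, keep_default_na=False)
    return [
        DispositionRecord(
            dog_id=row["dog_id"],
            group=row["group"],
            phase=row["phase"],
            status=row["status"],
            exclusion_reason=str(row.get("exclusion_reason", "")),
        )
        for _, row in frame.iterrows()
    ]
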