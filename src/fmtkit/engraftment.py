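"""Donor-ASV engraftment in FMT recipients.

Engraftment is quantified by set exclusion: the candidate set for a
recipient is every ASV detected in the donor minus the ASVs the recipient
already carried pre-FMT (endoscopy visit, the last visit before the first
capsule). The engraftment rate is the percentage of that candidate set
detected in the recipient's post-FMT samples (treatment and post-treatment
visits pooled). Rates are only meaningful on a table that already had
dataset-wide singleton/doubleton ASVs removed — rare sequencing artifacts
shared by chance would otherwise inflate the rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median

import pandas as pd

from .feature_table import AsvTable, SampleMetadata


class EngraftmentError(ValueError):
    pass


CONTEXTS = ("pre_fmt", "post_fmt", "donor")


@dataclass(frozen=True)
class PresenceProfile:
    """Set of ASVs with count >= 1 in any contributing sample."""

    owner: str  # dog_id, or "donor"
    context: str  # pre_fmt | post_fmt | donor
    present_asvs: frozenset[str]

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise EngraftmentError(f"unknown context {self.context!r}")


@dataclass(frozen=True)
class EngraftmentResult:
    dog_id: str
    candidate_donor_asvs: frozenset[str]
    engrafted_asvs: frozenset[str]

    def __post_init__(self) -> None:
        if not self.engrafted_asvs <= self.candidate_donor_asvs:
            raise EngraftmentError("engrafted set must be a subset of the candidate set")

    @property
    def rate_percent(self) -> float:
        return 100.0 * len(self.engrafted_asvs) / len(self.candidate_donor_asvs)


@dataclass
class EngraftmentSummary:
    rates: dict[str, float]
    mean_percent: float
    median_percent: float
    min_percent: float
    max_percent: float
    asv_frequency: dict[str, int] = field(default_factory=dict)


_CONTEXT_VISITS = {
    "pre_fmt": ["endoscopy"],
    "post_fmt": ["treatment", "post_treatment"],
}


def build_presence(
    table: AsvTable,
    metadata: SampleMetadata,
    owner: str,
    context: str,
    baseline_visit: str | None = None,
) -> PresenceProfile:
    """Presence profile for one dog (or the donor) in one context.

    pre_fmt uses the dog's endoscopy sample(s) unless `baseline_visit`
    overrides it (for dogs that skipped endoscopy); post_fmt pools the dog's
    treatment and post-treatment samples; donor pools all donor samples.
    """
    if context == "donor":
        sample_ids = metadata.samples_where(group="donor")
    elif context in _CONTEXT_VISITS:
        visits = [baseline_visit] if (context == "pre_fmt" and baseline_visit) else _CONTEXT_VISITS[context]
        sample_ids = metadata.samples_where(dog_id=owner, visit=visits)
    else:
        raise EngraftmentError(f"unknown context {context!r}")
    sample_ids = [s for s in sample_ids if s in set(table.sample_ids)]
    if not sample_ids:
        raise EngraftmentError(
            f"no contributing sample for owner {owner!r} in context {context!r}"
        )
    sub = table.counts.loc[sample_ids]
    present = frozenset(sub.columns[(sub >= 1).any(axis=0)])
    return PresenceProfile(owner=owner, context=context, present_asvs=present)


def candidate_donor_set(donor: PresenceProfile, pre: PresenceProfile) -> frozenset[str]:
    """Donor ASVs not already present in the recipient pre-FMT."""
    if donor.context != "donor":
        raise EngraftmentError("first profile must have context 'donor'")
    if pre.context != "pre_fmt":
        raise EngraftmentError("second profile must have context 'pre_fmt'")
    return donor.present_asvs - pre.present_asvs


def engraftment_rate(
    donor: PresenceProfile, pre: PresenceProfile, post: PresenceProfile
) -> EngraftmentResult:
    """Rate = 100 x |candidates ∩ post| / |candidates|."""
    candidates = candidate_donor_set(donor, pre)
    if not candidates:
        raise EngraftmentError(
            f"dog {pre.owner!r}: empty candidate donor set (every donor ASV was "
            "already present pre-FMT); exclude this dog from engraftment analysis"
        )
    engrafted = candidates & post.present_asvs
    return EngraftmentResult(
        dog_id=post.owner,
        candidate_donor_asvs=candidates,
        engrafted_asvs=frozenset(engrafted),
    )


def summarize_engraftment(results: list[EngraftmentResult]) -> EngraftmentSummary:
    """Mean/median/min/max rate plus per-ASV engraftment frequency."""
    if not results:
        raise EngraftmentError("no engraftment results to summarize")
    rates = {r.dog_id: r.rate_percent for r in results}
    values = list(rates.values())
    freq: dict[str, int] = {}
    for r in results:
        for asv in r.engrafted_asvs:
            freq[asv] = freq.get(asv, 0) + 1
    return EngraftmentSummary(
        rates=rates,
        mean_percent=sum(values) / len(values),
        median_percent=float(median(values)),
        min_percent=min(values),
        max_percent=max(values),
        asv_frequency=freq,
    )


def engraftment_table(results: list[EngraftmentResult]) -> pd.DataFrame:
    """Per-dog TSV-ready frame: dog_id, n_candidates, n_engrafted, rate_percent."""
    rows = [
        {
            "dog_id": r.dog_id,
            "n_candidates": len(r.candidate_donor_asvs),
            "n_engrafted": len(r.engrafted_asvs),
            "rate_percent": round(r.rate_percent, 2),
        }
        for r in sorted(results, key=lambda r: r.dog_id)
    ]
    return pd.DataFrame(rows, columns=["dog_id", "n_candidates", "n_engrafted", "rate_percent"])
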