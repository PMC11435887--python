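"""Published disposition of the motivating oral-FMT trial, as example data.

A 14-dog double-blinded placebo-controlled trial of oral freeze-dried FMT
capsules in dogs with tylosin-responsive enteropathy: 7 dogs per arm, a
4-week treatment phase and a 4-week post-treatment follow-up, with outcomes
scored both by the CCECAI and by the fecal consistency score (FCS). These
event records let the outcome arithmetic be exercised (and checked) without
access to the underlying per-visit measurements.

Event narrative encoded below:

* One placebo dog was excluded during treatment (pyometra), leaving 6
  evaluable per the placebo arm.
* CCECAI scoring, treatment phase: 2/7 FMT dogs and 3/6 placebo dogs
  relapsed.
* Eight dogs (5 FMT, 3 placebo) entered post-treatment; one FMT dog was
  excluded there (corticosteroids for a skin condition); 2 more FMT dogs
  relapsed and no placebo dog did.
* FCS scoring, treatment phase: one FMT dog had no treatment-visit FCS data
  (it relapsed early by CCECAI with normal fecal consistency) and is
  excluded from the FCS analysis set, leaving 1/6 FMT and 3/6 placebo
  relapses.
* FCS scoring, post-treatment: two FMT dogs excluded (corticosteroids;
  missing post-treatment data), one more FMT relapse -> 2/4 FMT
  non-responders cumulatively; placebo stayed at 3/6.
* Recruitment funnel: 55 dogs offered, 14 enrolled into the treatment phase.
"""

from __future__ import annotations

from .clinical import DispositionRecord

RECRUITMENT = {"suspected_tre": 55, "entered_treatment": 14}

_FMT_DOGS = [f"F{i}" for i in range(1, 8)]
_PLACEBO_DOGS = [f"P{i}" for i in range(1, 8)]


def ccecai_disposition() -> list[DispositionRecord]:
    """Per-dog, per-phase terminal status under CCECAI-based scoring."""
    records = []
    # FMT treatment phase: F1, F2 relapsed; F3..F7 responded
    for dog in _FMT_DOGS:
        status = "relapsed" if dog in ("F1", "F2") else "responder"
        records.append(DispositionRecord(dog, "FMT", "treatment", status))
    # Placebo: P7 excluded (pyometra); P1..P3 relapsed; P4..P6 responded
    for dog in _PLACEBO_DOGS:
        if dog == "P7":
            records.append(
                DispositionRecord(dog, "placebo", "treatment", "excluded", "pyometra")
            )
        elif dog in ("P1", "P2", "P3"):
            records.append(DispositionRecord(dog, "placebo", "treatment", "relapsed"))
        else:
            records.append(DispositionRecord(dog, "placebo", "treatment", "responder"))
    # Post-treatment: the 5 FMT responders continue; F3 excluded
    # (corticosteroids), F4 and F5 relapse, F6 and F7 respond.
    records.append(
        DispositionRecord("F3", "FMT", "post_treatment", "excluded", "corticosteroids")
    )
    for dog, status in [("F4", "relapsed"), ("F5", "relapsed"), ("F6", "responder"), ("F7", "responder")]:
        records.append(DispositionRecord(dog, "FMT", "post_treatment", status))
    # The 3 placebo responders continue; none relapse.
    for dog in ("P4", "P5", "P6"):
        records.append(DispositionRecord(dog, "placebo", "post_treatment", "responder"))
    return records


def fcs_disposition() -> list[DispositionRecord]:
    """Per-dog, per-phase terminal status under FCS-based scoring."""
    records = []
    # FMT treatment phase: F1 excluded (no treatment-visit FCS data; early
    # CCECAI relapse with normal fecal consistency), F2 relapsed, rest responded.
    for dog in _FMT_DOGS:
        if dog == "F1":
            records.append(
                DispositionRecord(
                    dog, "FMT", "treatment", "excluded", "no treatment-visit FCS data"
                )
            )
        elif dog == "F2":
            records.append(DispositionRecord(dog, "FMT", "treatment", "relapsed"))
        else:
            records.append(DispositionRecord(dog, "FMT", "treatment", "responder"))
    # Placebo identical to the CCECAI accounting in the treatment phase.
    for dog in _PLACEBO_DOGS:
        if dog == "P7":
            records.append(
                DispositionRecord(dog, "placebo", "treatment", "excluded", "pyometra")
            )
        elif dog in ("P1", "P2", "P3"):
            records.append(DispositionRecord(dog, "placebo", "treatment", "relapsed"))
        else:
            records.append(DispositionRecord(dog, "placebo", "treatment", "responder"))
    # FMT post-treatment: F3 excluded (corticosteroids), F4 excluded (no
    # post-treatment data), F5 relapsed, F6/F7 responded.
    records.append(
        DispositionRecord("F3", "FMT", "post_treatment", "excluded", "corticosteroids")
    )
    records.append(
        DispositionRecord("F4", "FMT", "post_treatment", "excluded", "no post-treatment FCS data")
    )
    for dog, status in [("F5", "relapsed"), ("F6", "responder"), ("F7", "responder")]:
        records.append(DispositionRecord(dog, "FMT", "post_treatment", status))
    for dog in ("P4", "P5", "P6"):
        records.append(DispositionRecord(dog, "placebo", "post_treatment", "responder"))
    return records


def recruitment_percent(decimals: int = 0) -> float:
    """Fraction of suspected-TRE dogs that entered the treatment phase, as a
    percentage at the requested precision."""
    from .clinical import round_half_up

    return round_half_up(
        100.0 * RECRUITMENT["entered_treatment"] / RECRUITMENT["suspected_tre"], decimals
    )
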