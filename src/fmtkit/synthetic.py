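"""Synthetic FMT trials with known ground truth.

The generator emulates the study design end to end: one healthy stool
donor, FMT and placebo recipients sampled at five visits (screening,
inclusion, endoscopy, treatment, post-treatment), a healthy reference
cohort, and the clinical layer (CCECAI items, fecal-consistency diaries,
duplicate fecal dry-matter weighings with a linear FCS-FDM link).

Microbial communities are Dirichlet-multinomial: a community is a Dirichlet
draw over its taxon pool (power-law base weights give one dominant taxon
plus a long tail, as real donor communities show), and a sample is a
multinomial draw of `sequencing_depth` reads from it. Dysbiosis is modeled
by scaling the Dirichlet concentration down, which makes individual draws
more uneven and lowers expected Shannon diversity. Donor-specific ASVs are
disjoint from the recipients' background pool by construction, so
engraftment ground truth is unambiguous: each candidate donor ASV transfers
independently with probability `engraft_prob`, and transferred ASVs receive
a relative abundance floor of `transfer_floor_reads / sequencing_depth` so
detection is near-certain at the default depth.

All randomness flows from the single `seed` in the config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clinical as clin
from .feature_table import (
    RANKS,
    AsvTable,
    SampleMetadata,
    TaxonomyAssignment,
    write_asv_table,
    write_metadata,
    write_taxonomy,
)

TRIAL_VISITS = ("screening", "inclusion", "endoscopy", "treatment", "post_treatment")

_GENUS_POOL = [
    ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Blautia"),
    ("Bacteria", "Firmicutes", "Negativicutes", "Veillonellales", "Selenomonadaceae", "Megamonas"),
    ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales", "Streptococcaceae", "Streptococcus"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
    ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Clostridiaceae", "Clostridium"),
    ("Bacteria", "Fusobacteriota", "Fusobacteriia", "Fusobacteriales", "Fusobacteriaceae", "Fusobacterium"),
    ("Bacteria", "Firmicutes", "Clostridia", "Peptostreptococcales", "Peptostreptococcaceae", "Romboutsia"),
    ("Bacteria", "Actinobacteriota", "Coriobacteriia", "Coriobacteriales", "Coriobacteriaceae", "Collinsella"),
    ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", "Lachnoclostridium"),
    ("Bacteria", "Firmicutes", "Clostridia", "Oscillospirales", "Ruminococcaceae", "Faecalibacterium"),
    ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Enterobacterales", "Enterobacteriaceae", "Escherichia"),
    ("Bacteria", "Firmicutes", "Clostridia", "Peptostreptococcales", "Peptostreptococcaceae", "Peptoclostridium"),
    ("Bacteria", "Bacteroidota", "Bacteroidia", "Bacteroidales", "Bacteroidaceae", "Bacteroides"),
    ("Bacteria", "Firmicutes", "Bacilli", "Erysipelotrichales", "Turicibacteraceae", "Turicibacter"),
    ("Bacteria", "Firmicutes", "Clostridia", "Lachnospirales", "Lachnospiraceae", ""),  # genus-unassigned
]


@dataclass
class TrialSimConfig:
    """Study conditions for one simulated trial (defaults sized to the
    motivating study: 7 dogs per arm, 30 healthy references, one donor with
    ~60 transferable ASVs, ~30% per-ASV transfer probability)."""

    n_fmt: int = 7
    n_placebo: int = 7
    n_healthy: int = 30
    n_donor_asvs: int = 60
    n_background_asvs: int = 200
    donor_overlap_fraction: float = 0.0  # share of background taxa also in the donor
    engraft_prob: float = 0.30
    sequencing_depth: int = 20_000
    n_donor_samples: int = 2
    dysbiosis_severity: float = 2.0  # concentration divisor - 1 for pre-FMT dogs
    engrafted_mass: float = 0.20  # community share taken by transferred taxa
    transfer_floor_reads: float = 5.0  # detection floor, in expected reads
    relapse_prob: dict = field(
        default_factory=lambda: {
            "FMT": {"treatment": 2 / 7, "post_treatment": 0.5},
            "placebo": {"treatment": 0.5, "post_treatment": 0.0},
        }
    )
    fcs_fdm_slope: float = -0.09
    fcs_intercept: float = 5.0
    fcs_noise_sd: float = 0.397
    fdm_mean: float = 35.0
    fdm_sd: float = 5.0
    fdm_relapse_shift: float = -8.0  # relapsed-phase FDM mean offset (wetter stool)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.engraft_prob, self.donor_overlap_fraction):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        for g, phases in self.relapse_prob.items():
            for p in phases.values():
                if not 0 <= p <= 1:
                    raise ValueError("relapse probabilities must be in [0, 1]")
        if self.sequencing_depth < 1:
            raise ValueError("sequencing_depth must be >= 1")
        if self.dysbiosis_severity < 0:
            raise ValueError("dysbiosis_severity must be >= 0")


@dataclass
class CommunityProfile:
    taxon_ids: list[str]
    concentration: np.ndarray
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")


def _power_law_weights(n: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** exponent
    return w / w.sum()


def _dirichlet(rng: np.random.Generator, concentration: np.ndarray) -> np.ndarray:
    draw = rng.dirichlet(np.maximum(concentration, 1e-6))
    return draw / draw.sum()


def donor_taxon_ids(config: TrialSimConfig) -> list[str]:
    return [f"D{i:04d}" for i in range(1, config.n_donor_asvs + 1)]


def background_taxon_ids(config: TrialSimConfig) -> list[str]:
    return [f"B{i:04d}" for i in range(1, config.n_background_asvs + 1)]


def simulate_donor(config: TrialSimConfig, rng: np.random.Generator | None = None) -> CommunityProfile:
    """Donor community: Dirichlet over the donor pool with power-law base
    weights (one dominant taxon, long tail), plus an optional slice of the
    background pool shared with recipients."""
    if config.n_donor_asvs < 5:
        raise ValueError("need at least 5 donor ASVs")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    ids = donor_taxon_ids(config)
    weights = _power_law_weights(config.n_donor_asvs, exponent=1.2)
    n_shared = int(round(config.donor_overlap_fraction * config.n_background_asvs))
    if n_shared:
        shared = background_taxon_ids(config)[:n_shared]
        shared_w = _power_law_weights(n_shared, exponent=1.2)
        ids = ids + shared
        weights = np.concatenate([0.7 * weights, 0.3 * shared_w])
        weights /= weights.sum()
    # total concentration 100 keeps one dominant taxon (~30% expected) while
    # letting nearly the whole donor pool clear the sequencing detection
    # limit, so per-recipient candidate sets land near the pool size
    concentration = 100.0 * weights
    return CommunityProfile(ids, concentration, _dirichlet(rng, concentration))


def _background_concentration(config: TrialSimConfig, dysbiotic: bool) -> np.ndarray:
    if not dysbiotic:
        return 150.0 * _power_law_weights(config.n_background_asvs, exponent=1.0)
    # dysbiosis both sharpens the expected composition (a steeper power law:
    # a few blooming taxa dominate, shifting the community away from the
    # healthy centroid) and scales total concentration down (more uneven,
    # more variable individual draws)
    tilted = _power_law_weights(config.n_background_asvs, exponent=1.6)
    return 150.0 * tilted / (1.0 + config.dysbiosis_severity)


def simulate_healthy(config: TrialSimConfig, rng: np.random.Generator) -> CommunityProfile:
    conc = _background_concentration(config, dysbiotic=False)
    return CommunityProfile(background_taxon_ids(config), conc, _dirichlet(rng, conc))


def simulate_recipient_timeline(
    donor: CommunityProfile,
    config: TrialSimConfig,
    dog_index: int,
    group: str,
    rng: np.random.Generator,
) -> tuple[dict[str, CommunityProfile], list[str]]:
    """Per-visit community profiles for one recipient plus the ground-truth
    transferred donor-ASV list (empty for placebo dogs).

    Pre-FMT visits are independent draws from the dysbiotic background;
    post visits are drift redraws, with the FMT arm additionally receiving
    each donor-specific ASV independently with probability `engraft_prob`
    at an abundance floored for detection.
    """
    ids = background_taxon_ids(config)
    conc = _background_concentration(config, dysbiotic=True)
    profiles: dict[str, CommunityProfile] = {}
    for visit in ("screening", "inclusion", "endoscopy"):
        profiles[visit] = CommunityProfile(ids, conc, _dirichlet(rng, conc))

    donor_only = [t for t in donor.taxon_ids if t.startswith("D")]
    transferred: list[str] = []
    if group == "FMT":
        mask = rng.random(len(donor_only)) < config.engraft_prob
        transferred = [t for t, m in zip(donor_only, mask) if m]

    floor = config.transfer_floor_reads / config.sequencing_depth
    donor_prop = dict(zip(donor.taxon_ids, donor.proportions))
    for visit in ("treatment", "post_treatment"):
        base = _dirichlet(rng, conc)  # drift redraw of the dog's background
        if transferred:
            w = np.array([max(donor_prop[t], 1e-12) for t in transferred])
            w = w / w.sum() * config.engrafted_mass
            w = np.maximum(w, floor)
            full_ids = ids + transferred
            full = np.concatenate([(1.0 - w.sum()) * base, w])
            full /= full.sum()
            profiles[visit] = CommunityProfile(full_ids, np.zeros(len(full_ids)), full)
        else:
            profiles[visit] = CommunityProfile(ids, conc, base)
    return profiles, transferred


def simulate_counts(
    profile: CommunityProfile, depth: int, rng: np.random.Generator
) -> np.ndarray:
    """One multinomial sequencing draw; counts sum to `depth` exactly."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return rng.multinomial(depth, profile.proportions)


def _make_taxonomy(taxon_ids: list[str], rng: np.random.Generator) -> dict[str, TaxonomyAssignment]:
    out = {}
    for i, taxon in enumerate(sorted(taxon_ids)):
        lineage = _GENUS_POOL[i % len(_GENUS_POOL)]
        genus = lineage[5]
        species = f"{genus} sp{i // len(_GENUS_POOL) + 1}" if genus else ""
        ranks = ("Bacteria",) + lineage[1:] + (species,)
        assert len(ranks) == len(RANKS)
        out[taxon] = TaxonomyAssignment(ranks)
    return out


def simulate_da_dataset(
    n_taxa: int = 40,
    n_dogs: int = 10,
    depth: int = 20_000,
    spike_taxon: int | None = None,
    spike_fold: float = 1.0,
    dog_effect_sd: float = 0.3,
    seed: int = 0,
) -> tuple[AsvTable, SampleMetadata]:
    """Paired pre/post dataset for differential-abundance benchmarking.

    Each dog contributes one pre (endoscopy) and one post (treatment)
    sample. Log abundances are a power-law baseline plus a dog-level random
    intercept (sd `dog_effect_sd`, shared between the dog's two samples);
    `spike_taxon` (column index) is multiplied by `spike_fold` post-phase.
    With `spike_fold=1` the dataset is an exact null.
    """
    rng = np.random.default_rng(seed)
    base = np.log(_power_law_weights(n_taxa, exponent=1.0))
    taxa = [f"T{i:03d}" for i in range(1, n_taxa + 1)]
    rows, sample_ids, meta_rows = [], [], []
    for d in range(n_dogs):
        dog = f"d{d + 1:02d}"
        dog_logw = base + rng.normal(0.0, dog_effect_sd, size=n_taxa)
        for visit, phase in (("endoscopy", 0), ("treatment", 1)):
            logw = dog_logw.copy()
            if spike_taxon is not None and phase == 1:
                logw[spike_taxon] += np.log(spike_fold)
            p = np.exp(logw - logw.max())
            p /= p.sum()
            rows.append(rng.multinomial(depth, p))
            sample_id = f"{dog}_{visit}"
            sample_ids.append(sample_id)
            meta_rows.append(
                {"sample_id": sample_id, "dog_id": dog, "group": "FMT", "visit": visit}
            )
    counts = pd.DataFrame(
        np.vstack(rows), index=pd.Index(sample_ids), columns=pd.Index(taxa)
    )
    return AsvTable(counts), SampleMetadata(pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# Clinical layer
# ---------------------------------------------------------------------------

_PHASE_EVAL_DAY = {"treatment": 28, "post_treatment": 56}


def simulate_fcs_fdm_pairs(
    n: int, config: TrialSimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """(FDM%, FCS) pairs from the generator's linear link:
    FDM ~ Normal(fdm_mean, fdm_sd^2), FCS = intercept + slope*FDM + noise.
    Values are unclipped (the diary writes grid-clipped copies)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    fdm = rng.normal(config.fdm_mean, config.fdm_sd, size=n)
    fcs = (
        config.fcs_intercept
        + config.fcs_fdm_slope * fdm
        + rng.normal(0.0, config.fcs_noise_sd, size=n)
    )
    return pd.DataFrame({"fdm_percent": fdm, "fcs": fcs})


def _clip_to_fcs_grid(value: float) -> float:
    snapped = round(value * 2.0) / 2.0
    return float(min(5.0, max(1.0, snapped)))


def _draw_ccecai_items(total: int, rng: np.random.Generator) -> tuple[int, ...]:
    """Distribute `total` points over the nine items, each capped at 3."""
    items = [0] * len(clin.CCECAI_ITEMS)
    for _ in range(total):
        open_items = [i for i, v in enumerate(items) if v < 3]
        items[int(rng.choice(open_items))] += 1
    return tuple(items)


def simulate_clinical(
    config: TrialSimConfig, rng: np.random.Generator | None = None
) -> dict:
    """Clinical trajectories for every trial dog.

    Relapse is drawn per dog per phase with the configured probability (a
    treatment-phase relapse removes the dog from the post-treatment phase).
    CCECAI totals are <= 3 for dogs in remission and >= 4 at relapse; FDM is
    normal per visit (shifted down when relapsed) and daily diary FCS values
    follow the linear FDM link, clipped to the half-point grid.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    dogs = [(f"F{i + 1}", "FMT") for i in range(config.n_fmt)] + [
        (f"P{i + 1}", "placebo") for i in range(config.n_placebo)
    ]
    ccecai_rows, diary_rows, fdm_rows, disposition = [], [], [], []
    relapse_truth: dict[str, dict[str, bool]] = {}

    for dog, group in dogs:
        relapse_truth[dog] = {}
        # visit-level latent state: in remission unless the visit's phase relapsed
        relapsed_treatment = bool(rng.random() < config.relapse_prob[group]["treatment"])
        relapsed_post = (not relapsed_treatment) and bool(
            rng.random() < config.relapse_prob[group]["post_treatment"]
        )
        relapse_truth[dog]["treatment"] = relapsed_treatment
        relapse_truth[dog]["post_treatment"] = relapsed_post

        visit_state = {
            "screening": False,
            "inclusion": True,  # relapse after tylosin withdrawal is the entry criterion
            "endoscopy": False,
            "treatment": relapsed_treatment,
            "post_treatment": relapsed_post,
        }
        for visit in TRIAL_VISITS:
            if visit == "post_treatment" and relapsed_treatment:
                continue  # dog left the trial at the treatment-phase relapse
            sick = visit_state[visit]
            total = int(rng.integers(4, 10)) if sick else int(rng.integers(0, 4))
            ccecai_rows.append(
                {"dog_id": dog, "visit": visit, **dict(zip(clin.CCECAI_ITEMS, _draw_ccecai_items(total, rng)))}
            )
            fdm_mu = config.fdm_mean + (config.fdm_relapse_shift if sick else 0.0)
            fdm_value = float(np.clip(rng.normal(fdm_mu, config.fdm_sd), 5.0, 95.0))
            wet1, wet2 = rng.normal(0.5, 0.03, size=2)
            rep_noise = rng.normal(0.0, 0.4, size=2)
            dry1 = np.clip(wet1 * (fdm_value + rep_noise[0]) / 100.0, 0.0, wet1)
            dry2 = np.clip(wet2 * (fdm_value + rep_noise[1]) / 100.0, 0.0, wet2)
            fdm_rows.append(
                {
                    "dog_id": dog, "visit": visit,
                    "wet1": round(float(wet1), 4), "dry1": round(float(dry1), 4),
                    "wet2": round(float(wet2), 4), "dry2": round(float(dry2), 4),
                }
            )
            if visit in _PHASE_EVAL_DAY:
                eval_day = _PHASE_EVAL_DAY[visit]
                for day in range(eval_day - 2, eval_day + 1):
                    fcs = (
                        config.fcs_intercept
                        + config.fcs_fdm_slope * fdm_value
                        + rng.normal(0.0, config.fcs_noise_sd)
                    )
                    diary_rows.append(
                        {"dog_id": dog, "day": day, "fcs": _clip_to_fcs_grid(fcs)}
                    )

        disposition.append(
            {
                "dog_id": dog, "group": group, "phase": "treatment",
                "status": "relapsed" if relapsed_treatment else "responder",
                "exclusion_reason": "",
            }
        )
        if not relapsed_treatment:
            disposition.append(
                {
                    "dog_id": dog, "group": group, "phase": "post_treatment",
                    "status": "relapsed" if relapsed_post else "responder",
                    "exclusion_reason": "",
                }
            )

    return {
        "ccecai": pd.DataFrame(ccecai_rows),
        "fcs_diary": pd.DataFrame(diary_rows),
        "fdm": pd.DataFrame(fdm_rows),
        "disposition": pd.DataFrame(disposition),
        "relapse_truth": relapse_truth,
    }


# ---------------------------------------------------------------------------
# Full bundle
# ---------------------------------------------------------------------------

def simulate_trial(config: TrialSimConfig) -> dict:
    """Simulate the whole trial in memory; see `make_fixture_dataset` to
    write it to disk. Returns table, metadata, taxonomy, clinical frames,
    and ground truth."""
    rng = np.random.default_rng(config.seed)
    donor = simulate_donor(config, rng)

    all_taxa = sorted(set(background_taxon_ids(config)) | set(donor.taxon_ids))
    taxon_pos = {t: i for i, t in enumerate(all_taxa)}

    sample_ids: list[str] = []
    meta_rows: list[dict] = []
    count_rows: list[np.ndarray] = []

    def add_sample(sample_id: str, dog_id: str, group: str, visit: str, profile: CommunityProfile):
        counts = simulate_counts(profile, config.sequencing_depth, rng)
        row = np.zeros(len(all_taxa), dtype=np.int64)
        for taxon, c in zip(profile.taxon_ids, counts):
            row[taxon_pos[taxon]] += c
        sample_ids.append(sample_id)
        meta_rows.append({"sample_id": sample_id, "dog_id": dog_id, "group": group, "visit": visit})
        count_rows.append(row)

    for k in range(config.n_donor_samples):
        add_sample(f"donor_s{k + 1}", "donor", "donor", "donor", donor)

    transferred_truth: dict[str, list[str]] = {}
    for group, n, prefix in (("FMT", config.n_fmt, "F"), ("placebo", config.n_placebo, "P")):
        for i in range(n):
            dog = f"{prefix}{i + 1}"
            profiles, transferred = simulate_recipient_timeline(donor, config, i, group, rng)
            if group == "FMT":
                transferred_truth[dog] = sorted(transferred)
            for visit in TRIAL_VISITS:
                add_sample(f"{dog}_{visit}", dog, group, visit, profiles[visit])

    for i in range(config.n_healthy):
        dog = f"H{i + 1:02d}"
        add_sample(f"{dog}_healthy", dog, "healthy", "healthy", simulate_healthy(config, rng))

    counts = pd.DataFrame(
        np.vstack(count_rows), index=pd.Index(sample_ids), columns=pd.Index(all_taxa)
    )
    taxonomy = _make_taxonomy(all_taxa, rng)
    table = AsvTable(counts, taxonomy)
    metadata = SampleMetadata(pd.DataFrame(meta_rows))
    clinical = simulate_clinical(config, rng)

    ground_truth = {
        "engraft_prob": config.engraft_prob,
        "seed": config.seed,
        "transferred": transferred_truth,
        "relapse": clinical["relapse_truth"],
        "fcs_fdm": {
            "slope": config.fcs_fdm_slope,
            "intercept": config.fcs_intercept,
            "noise_sd": config.fcs_noise_sd,
        },
    }
    return {
        "table": table,
        "metadata": metadata,
        "clinical": clinical,
        "ground_truth": ground_truth,
        "donor": donor,
    }


def make_fixture_dataset(config: TrialSimConfig, out_dir) -> dict[str, Path]:
    """Write a complete, internally consistent input bundle; deterministic
    given the config seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = simulate_trial(config)
    paths = {
        "feature_table": out / "feature_table.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "metadata": out / "metadata.tsv",
        "ccecai": out / "ccecai.csv",
        "fcs_diary": out / "fcs_diary.csv",
        "fdm": out / "fdm.csv",
        "disposition": out / "disposition.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_asv_table(sim["table"], paths["feature_table"])
    write_taxonomy(sim["table"].taxonomy, paths["taxonomy"])
    write_metadata(sim["metadata"], paths["metadata"])
    for key in ("ccecai", "fcs_diary", "fdm", "disposition"):
        sim["clinical"][key].to_csv(paths[key], index=False, lineterminator="\n")
    with open(paths["ground_truth"], "w") as fh:
        json.dump(sim["ground_truth"], fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths
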