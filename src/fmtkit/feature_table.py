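"""ASV feature tables: data model, I/O, filtering, scaling, aggregation.

The pipeline starts at the denoised ASV level: a samples x ASVs integer
count matrix with optional seven-rank taxonomy. Everything downstream
(diversity, differential abundance, engraftment) consumes the structures
defined here.

On-disk conventions
-------------------
* Count table TSV: first column ``asv_id``, remaining columns samples
  (ASVs as rows), tab separated, header row present.
* Taxonomy TSV: ``asv_id`` + seven tab-separated rank labels
  (domain, phylum, class, order, family, genus, species); empty cells mean
  "unassigned at this rank".
* Metadata TSV: columns ``sample_id``, ``dog_id``, ``group``, ``visit``.
* BIOM (read-only): format 1.0 JSON and format 2.1 HDF5.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

TRIAL_VISITS = ("screening", "inclusion", "endoscopy", "treatment", "post_treatment")
GROUPS = ("FMT", "placebo", "donor", "healthy")


class FeatureTableError(ValueError):
    """Malformed input: bad header, duplicate ids, non-integer counts, ..."""


@dataclass(frozen=True)
class TaxonomyAssignment:
    """Seven-rank taxonomic assignment for one ASV.

    Unassigned ranks are stored as empty strings; :meth:`label` renders them
    as ``unclassified <nearest assigned parent>`` so that, e.g., an ASV with
    an empty genus but family Lachnospiraceae aggregates under
    "unclassified Lachnospiraceae".
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise FeatureTableError(
                f"taxonomy needs exactly {len(RANKS)} rank slots, got {len(self.ranks)}"
            )

    def label(self, rank: str) -> str:
        """Label at `rank`, falling back to 'unclassified <nearest parent>'."""
        idx = RANKS.index(rank)
        value = self.ranks[idx].strip()
        if value:
            return value
        for parent in range(idx - 1, -1, -1):
            if self.ranks[parent].strip():
                return f"unclassified {self.ranks[parent].strip()}"
        return "unclassified"


def _check_axis_ids(ids: pd.Index, what: str) -> None:
    dup = ids[ids.duplicated()]
    if len(dup):
        raise FeatureTableError(f"duplicate {what} id(s): {sorted(set(dup))}")


@dataclass
class AsvTable:
    """Samples x ASVs integer count matrix with optional taxonomy.

    `counts` is a pandas DataFrame indexed by sample id with ASV ids as
    columns; every cell is a non-negative integer.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, TaxonomyAssignment] | None = None

    def __post_init__(self) -> None:
        _check_axis_ids(self.counts.index, "sample")
        _check_axis_ids(self.counts.columns, "ASV")
        values = self.counts.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.integer):
                frac, _ = np.modf(values.astype(float))
                if np.any(frac != 0):
                    i, j = np.argwhere(frac != 0)[0]
                    raise FeatureTableError(
                        f"non-integer count at sample {self.counts.index[i]!r}, "
                        f"ASV {self.counts.columns[j]!r}"
                    )
            if np.any(values < 0):
                i, j = np.argwhere(values < 0)[0]
                raise FeatureTableError(
                    f"negative count at sample {self.counts.index[i]!r}, "
                    f"ASV {self.counts.columns[j]!r}"
                )
        self.counts = self.counts.astype(np.int64)
        if self.taxonomy is not None:
            unknown = set(self.taxonomy) - set(self.counts.columns)
            if unknown:
                # taxonomy may cover a subset of ASVs, never extra ones
                self.taxonomy = {
                    a: t for a, t in self.taxonomy.items() if a in set(self.counts.columns)
                }

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.counts.shape[1]

    def select_asvs(self, keep: list[str]) -> "AsvTable":
        tax = None
        if self.taxonomy is not None:
            tax = {a: t for a, t in self.taxonomy.items() if a in set(keep)}
        return AsvTable(self.counts.loc[:, keep].copy(), tax)

    def select_samples(self, keep: list[str]) -> "AsvTable":
        return AsvTable(self.counts.loc[keep, :].copy(), self.taxonomy)


@dataclass
class RelAbundTable:
    """Samples x taxa relative-abundance matrix; each row sums to 1."""

    proportions: pd.DataFrame

    def __post_init__(self) -> None:
        _check_axis_ids(self.proportions.index, "sample")
        _check_axis_ids(self.proportions.columns, "taxon")
        values = self.proportions.to_numpy(dtype=float)
        if np.any(values < 0):
            raise FeatureTableError("negative proportion")
        if values.size:
            sums = values.sum(axis=1)
            bad = np.where(np.abs(sums - 1.0) > 1e-9)[0]
            if len(bad):
                raise FeatureTableError(
                    f"sample {self.proportions.index[bad[0]]!r} proportions sum to "
                    f"{sums[bad[0]]!r}, expected 1"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.proportions.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.proportions.columns)


@dataclass
class SampleMetadata:
    """Maps each sample to its dog, treatment group, and visit."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("sample_id", "dog_id", "group", "visit")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FeatureTableError(f"metadata missing column(s): {missing}")
        _check_axis_ids(pd.Index(self.frame["sample_id"]), "metadata sample")
        bad_group = set(self.frame["group"]) - set(GROUPS)
        if bad_group:
            raise FeatureTableError(f"unknown group(s): {sorted(bad_group)}")
        trial = self.frame[self.frame["group"].isin(["FMT", "placebo"])]
        bad_visit = set(trial["visit"]) - set(TRIAL_VISITS)
        if bad_visit:
            raise FeatureTableError(f"unknown trial visit(s): {sorted(bad_visit)}")
        ref = self.frame[self.frame["group"].isin(["donor", "healthy"])]
        leaked = set(ref["visit"]) & set(TRIAL_VISITS)
        if leaked:
            raise FeatureTableError(
                f"donor/healthy samples may not carry trial visits: {sorted(leaked)}"
            )
        self.frame = self.frame.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_where(
        self,
        dog_id: str | None = None,
        group: str | None = None,
        visit: str | list[str] | None = None,
    ) -> list[str]:
        mask = pd.Series(True, index=self.frame.index)
        if dog_id is not None:
            mask &= self.frame["dog_id"] == dog_id
        if group is not None:
            mask &= self.frame["group"] == group
        if visit is not None:
            visits = [visit] if isinstance(visit, str) else list(visit)
            mask &= self.frame["visit"].isin(visits)
        return list(self.frame.loc[mask, "sample_id"])

    def dogs_in_group(self, group: str) -> list[str]:
        return sorted(set(self.frame.loc[self.frame["group"] == group, "dog_id"]))

    def require_covers(self, table: AsvTable) -> None:
        missing = set(table.sample_ids) - set(self.sample_ids)
        if missing:
            raise FeatureTableError(f"samples without metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_asv_table(path, format: str = "tsv", taxonomy_path=None) -> AsvTable:
    """Read a count table from TSV (canonical) or BIOM (read-only)."""
    if format == "tsv":
        table = _read_tsv(path)
    elif format == "biom":
        table = _read_biom(path)
    else:
        raise FeatureTableError(f"unknown format {format!r}")
    if taxonomy_path is not None:
        table.taxonomy = read_taxonomy(taxonomy_path, restrict_to=table.asv_ids)
    return table


def _read_tsv(path) -> AsvTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    if not header or header[0] != "asv_id":
        raise FeatureTableError(
            f"{path}: malformed header, first column must be 'asv_id' (got {header[:1]})"
        )
    sample_cols = header[1:]
    seen: set[str] = set()
    for col in sample_cols:
        if col in seen:
            raise FeatureTableError(f"{path}: duplicate sample column {col!r}")
        seen.add(col)
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    raw.columns = header  # undo pandas' dedup-renaming, lengths always match
    asv_ids = pd.Index(raw["asv_id"])
    _check_axis_ids(asv_ids, "ASV")
    values = np.empty((len(raw), len(sample_cols)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(raw[col]):
            try:
                v = int(cell)
            except ValueError:
                raise FeatureTableError(
                    f"{path}: non-integer count {cell!r} at ASV {asv_ids[i]!r}, "
                    f"sample {col!r}"
                ) from None
            if v < 0:
                raise FeatureTableError(
                    f"{path}: negative count at ASV {asv_ids[i]!r}, sample {col!r}"
                )
            values[i, j] = v
    counts = pd.DataFrame(values.T, index=pd.Index(sample_cols), columns=asv_ids)
    return AsvTable(counts)


def _read_biom(path) -> AsvTable:
    """Minimal BIOM reader: format 1.0 (JSON) and 2.1 (HDF5) layouts."""
    with open(path, "rb") as fh:
        magic = fh.read(8)
    if magic.startswith(b"\x89HDF"):
        return _read_biom_hdf5(path)
    with open(path) as fh:
        doc = json.load(fh)
    asv_ids = [row["id"] for row in doc["rows"]]
    sample_ids = [col["id"] for col in doc["columns"]]
    shape = tuple(doc["shape"])
    dense = np.zeros(shape, dtype=np.int64)
    if doc.get("matrix_type") == "dense":
        dense = np.asarray(doc["data"], dtype=np.int64)
    else:
        for i, j, v in doc["data"]:
            dense[int(i), int(j)] = int(v)
    taxonomy = {}
    for row in doc["rows"]:
        meta = row.get("metadata") or {}
        tax = meta.get("taxonomy")
        if tax:
            ranks = [_strip_rank_prefix(t) for t in tax][: len(RANKS)]
            ranks += [""] * (len(RANKS) - len(ranks))
            taxonomy[row["id"]] = TaxonomyAssignment(tuple(ranks))
    counts = pd.DataFrame(dense.T, index=pd.Index(sample_ids), columns=pd.Index(asv_ids))
    return AsvTable(counts, taxonomy or None)


def _read_biom_hdf5(path) -> AsvTable:
    import h5py
    from scipy import sparse

    with h5py.File(path, "r") as fh:
        asv_ids = [x.decode() if isinstance(x, bytes) else x for x in fh["observation/ids"][:]]
        sample_ids = [x.decode() if isinstance(x, bytes) else x for x in fh["sample/ids"][:]]
        grp = fh["observation/matrix"]
        mat = sparse.csr_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]),
            shape=(len(asv_ids), len(sample_ids)),
        )
    counts = pd.DataFrame(
        np.asarray(mat.todense(), dtype=np.int64).T,
        index=pd.Index(sample_ids),
        columns=pd.Index(asv_ids),
    )
    return AsvTable(counts)


def _strip_rank_prefix(label: str) -> str:
    label = label.strip()
    if len(label) >= 3 and label[1:3] == "__":  # greengenes-style k__/p__/...
        return label[3:]
    return label


def write_asv_table(table: AsvTable, path, format: str = "tsv") -> None:
    """Write ASVs-as-rows TSV; byte-stable for identical input."""
    if format != "tsv":
        raise FeatureTableError("only TSV write is supported")
    out = table.counts.T
    out.index.name = "asv_id"
    out.to_csv(path, sep="\t", lineterminator="\n")


def read_taxonomy(path, restrict_to=None) -> dict[str, TaxonomyAssignment]:
    raw = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    if raw.columns[0] != "asv_id" or raw.shape[1] != 1 + len(RANKS):
        raise FeatureTableError(
            f"{path}: taxonomy TSV needs columns asv_id + {len(RANKS)} ranks"
        )
    keep = set(restrict_to) if restrict_to is not None else None
    out = {}
    for _, row in raw.iterrows():
        asv = row["asv_id"]
        if keep is not None and asv not in keep:
            continue
        out[asv] = TaxonomyAssignment(tuple(row.iloc[1:]))
    return out


def write_taxonomy(taxonomy: dict[str, TaxonomyAssignment], path) -> None:
    rows = [{"asv_id": a, **dict(zip(RANKS, t.ranks))} for a, t in taxonomy.items()]
    pd.DataFrame(rows, columns=["asv_id", *RANKS]).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False))


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Filters and transforms
# ---------------------------------------------------------------------------

def remove_rare_asvs(table: AsvTable, max_total: int = 2) -> AsvTable:
    """Drop ASVs whose summed count across all samples is <= `max_total`.

    The default removes singletons and doubletons (dataset-wide total of 1 or
    2 reads), which would otherwise inflate engraftment rates.
    """
    if max_total < 0:
        raise FeatureTableError("max_total must be >= 0")
    totals = table.counts.sum(axis=0)
    keep = [a for a in table.asv_ids if totals[a] > max_total]
    return table.select_asvs(keep)


def low_count_filter(table: AsvTable, min_count: int = 4, min_prevalence: float = 0.20) -> AsvTable:
    """Keep features with >= `min_count` counts in >= `min_prevalence` of samples.

    Boundary inclusive on both thresholds.
    """
    if not 0 <= min_prevalence <= 1:
        raise FeatureTableError("min_prevalence must be in [0, 1]")
    n = table.n_samples
    if n == 0:
        return table.select_asvs([])
    prevalence = (table.counts >= min_count).sum(axis=0) / n
    keep = [a for a in table.asv_ids if prevalence[a] >= min_prevalence]
    return table.select_asvs(keep)


def low_variance_filter(table, drop_fraction: float = 0.10, spread: str = "iqr"):
    """Remove the lowest `drop_fraction` of features ranked by IQR.

    floor(drop_fraction x n_features) features are removed; ties on IQR are
    broken by feature id (lexicographically smaller ids removed first) so the
    filter is deterministic.
    """
    if spread != "iqr":
        raise FeatureTableError(f"unknown spread measure {spread!r}")
    if not 0 <= drop_fraction <= 1:
        raise FeatureTableError("drop_fraction must be in [0, 1]")
    if isinstance(table, AsvTable):
        values = table.counts
    else:
        values = table.proportions
    n_features = values.shape[1]
    if n_features < 1:
        raise FeatureTableError("need at least one feature")
    n_drop = int(np.floor(drop_fraction * n_features))
    if n_drop == 0:
        keep = list(values.columns)
    else:
        q75 = values.quantile(0.75, axis=0)
        q25 = values.quantile(0.25, axis=0)
        iqr = q75 - q25
        ranked = sorted(values.columns, key=lambda a: (iqr[a], a))
        dropped = set(ranked[:n_drop])
        keep = [a for a in values.columns if a not in dropped]
    if isinstance(table, AsvTable):
        return table.select_asvs(keep)
    return RelAbundTable(table.proportions.loc[:, keep].copy())


def total_sum_scaling(table: AsvTable) -> RelAbundTable:
    """Divide each cell by its sample total (relative abundances).

    Zero-total samples are excluded with a warning; an all-zero table is an
    error.
    """
    totals = table.counts.sum(axis=1)
    empty = list(totals.index[totals == 0])
    if len(empty) == table.n_samples:
        raise FeatureTableError("all samples have zero total count")
    if empty:
        msg = f"excluding zero-total sample(s) from scaling: {empty}"
        log.warning(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    kept = table.counts.loc[totals > 0]
    props = kept.div(kept.sum(axis=1), axis=0)
    return RelAbundTable(props)


def aggregate_taxa(table: AsvTable, rank: str) -> AsvTable:
    """Sum ASV counts sharing a rank label; unlabeled ASVs pool under
    'unclassified <nearest assigned parent>'. Per-sample totals are conserved.
    """
    if rank not in RANKS:
        raise FeatureTableError(f"unknown rank {rank!r}")
    if table.taxonomy is None:
        raise FeatureTableError("aggregate_taxa requires taxonomy")
    labels = {}
    for asv in table.asv_ids:
        tax = table.taxonomy.get(asv)
        labels[asv] = tax.label(rank) if tax is not None else "unclassified"
    grouped = table.counts.T.groupby(pd.Series(labels)).sum().T
    grouped = grouped.loc[:, sorted(grouped.columns)]
    return AsvTable(grouped)


def collapse_other(rel: RelAbundTable, min_mean_abundance: float) -> RelAbundTable:
    """Pool taxa with mean relative abundance below the threshold into "Other".

    Taxa at/above `min_mean_abundance` keep their own column; rows still sum
    to 1. When nothing falls below the threshold no "Other" column is added.
    """
    means = rel.proportions.mean(axis=0)
    minor = [t for t in rel.taxon_ids if means[t] < min_mean_abundance]
    if not minor:
        return RelAbundTable(rel.proportions.copy())
    major = [t for t in rel.taxon_ids if t not in set(minor)]
    out = rel.proportions.loc[:, major].copy()
    out["Other"] = rel.proportions.loc[:, minor].sum(axis=1)
    return RelAbundTable(out)
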