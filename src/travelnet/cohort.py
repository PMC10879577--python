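"""Multi-center cohorts: synthesis, train/test splitting and manifest I/O.

The package targets the regime where a disease classifier must be trained
across many real healthcare centers with wildly unequal contributions: a
couple of large multi-site studies, many single-site studies, and several
centers holding fewer than 5 scans.  This module represents such cohorts,
generates synthetic ones with that long-tailed structure, and performs the
per-center 80/20 train/test split with a deterministic greedy rule that
keeps small centers' records globally balanced by sex and age band.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import derive_seed

__all__ = [
    "ParticipantRecord",
    "Cohort",
    "SplitCohort",
    "CohortSpec",
    "CenterGroup",
    "Constant",
    "Uniform",
    "Beta",
    "TwoBandAge",
    "FixedTotalSizes",
    "ConstantSizes",
    "PoissonSizes",
    "build_cohort",
    "split_cohort",
    "load_manifest",
    "write_manifest",
    "summarize",
    "from_split_table",
    "paper_center_table",
    "ConfigurationError",
    "SchemaError",
    "ValidationError",
]

VENDORS = ("Siemens", "GE", "Philips")
FIELD_STRENGTHS = (1.5, 3.0)
AGE_BAND_CUTOFF = 60.0  # strict <60 vs 60+

MANIFEST_COLUMNS = [
    "participant_id",
    "center_id",
    "label",
    "sex",
    "age_years",
    "vendor",
    "field_strength_tesla",
    "split",
]


class ConfigurationError(ValueError):
    """Invalid cohort or generator configuration."""


class SchemaError(ValueError):
    """A manifest file does not have the expected columns."""


class ValidationError(ValueError):
    """A manifest file has the right schema but invalid content."""


# ---------------------------------------------------------------------------
# records and cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantRecord:
    """One subject: identity, center, label, demographics, scanner, split."""

    participant_id: str
    center_id: str
    label: int  # 1 = disease-positive, 0 = healthy
    sex: str  # "M" or "F"
    age_years: float
    vendor: str
    field_strength_tesla: float
    split: str = "unassigned"  # "train" | "test" | "unassigned"

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValidationError(f"label must be 0 or 1, got {self.label!r}")
        if self.sex not in ("M", "F"):
            raise ValidationError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age_years < 0:
            raise ValidationError(f"age_years must be >= 0, got {self.age_years}")
        if self.vendor not in VENDORS:
            raise ValidationError(f"unknown vendor {self.vendor!r}")
        if self.split not in ("train", "test", "unassigned"):
            raise ValidationError(f"bad split {self.split!r}")

    @property
    def age_band(self) -> str:
        return "<60" if self.age_years < AGE_BAND_CUTOFF else "60+"


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of participant records, grouped by center."""

    records: tuple[ParticipantRecord, ...]

    @property
    def centers(self) -> dict[str, list[ParticipantRecord]]:
        groups: dict[str, list[ParticipantRecord]] = {}
        for r in self.records:
            groups.setdefault(r.center_id, []).append(r)
        return groups

    @property
    def center_ids(self) -> list[str]:
        return sorted(self.centers.keys())

    def __len__(self) -> int:
        return len(self.records)

    def participant_ids(self) -> list[str]:
        return [r.participant_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=MANIFEST_COLUMNS)


@dataclass(frozen=True)
class SplitCohort:
    """Disjoint train/test partition of a cohort with a per-center report."""

    train: Cohort
    test: Cohort
    split_report: pd.DataFrame

    @property
    def full(self) -> Cohort:
        return Cohort(self.train.records + self.test.records)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

Sampler = Callable[[np.random.Generator], float]


@dataclass(frozen=True)
class Constant:
    value: float

    def __call__(self, rng: np.random.Generator) -> float:
        return self.value


@dataclass(frozen=True)
class Uniform:
    low: float
    high: float

    def __call__(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))


@dataclass(frozen=True)
class Beta:
    a: float
    b: float

    def __call__(self, rng: np.random.Generator) -> float:
        return float(rng.beta(self.a, self.b))


@dataclass(frozen=True)
class TwoBandAge:
    """Draw an age by first drawing the <60 / 60+ band, then uniform within it."""

    p_old: float = 0.6
    young: tuple[float, float] = (45.0, 60.0)
    old: tuple[float, float] = (60.0, 85.0)

    def __call__(self, rng: np.random.Generator) -> float:
        if rng.random() < self.p_old:
            return float(rng.uniform(*self.old))
        return float(rng.uniform(*self.young))


class SizeSampler:
    """Joint sampler for the sizes of the n centers in a group."""

    def sample_sizes(self, n: int, rng: np.random.Generator) -> list[int]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class ConstantSizes(SizeSampler):
    size: int

    def sample_sizes(self, n: int, rng: np.random.Generator) -> list[int]:
        return [int(self.size)] * n


@dataclass(frozen=True)
class PoissonSizes(SizeSampler):
    """IID shifted-Poisson sizes (minimum 1)."""

    mean: float

    def sample_sizes(self, n: int, rng: np.random.Generator) -> list[int]:
        return [int(max(1, s)) for s in rng.poisson(self.mean, size=n)]


@dataclass(frozen=True)
class FixedTotalSizes(SizeSampler):
    """Allocate an exact total across n centers with a heavy-tailed profile.

    Lognormal weights are normalised and rounded by largest remainder so the
    sizes sum exactly to ``total`` with every center getting at least
    ``min_size``.  With sigma around 1 a multi-site study ends up with a few
    dominant centers and a tail of centers holding only a handful of samples.
    """

    total: int
    min_size: int = 1
    sigma: float = 1.0

    def sample_sizes(self, n: int, rng: np.random.Generator) -> list[int]:
        if self.total < n * self.min_size:
            raise ConfigurationError(
                f"total {self.total} cannot give {n} centers at least {self.min_size} each"
            )
        w = rng.lognormal(mean=0.0, sigma=self.sigma, size=n)
        spare = self.total - n * self.min_size
        raw = spare * w / w.sum()
        base = np.floor(raw).astype(int)
        remainder = raw - base
        short = spare - int(base.sum())
        order = np.argsort(-remainder, kind="stable")
        base[order[:short]] += 1
        return [int(self.min_size + b) for b in base]


# ---------------------------------------------------------------------------
# cohort specification and generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CenterGroup:
    """A block of centers sharing one sampling profile (e.g. one study)."""

    name: str
    n_centers: int
    sizes: SizeSampler
    label_fraction: Sampler | None = None
    male_fraction: Sampler | None = None
    age: Sampler | None = None
    vendor_weights: Mapping[str, float] | None = None


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to synthesise a deterministic multi-center cohort."""

    center_size_profile: tuple[CenterGroup, ...]
    label_fraction_sampler: Sampler = field(default_factory=lambda: Constant(0.5))
    male_fraction_sampler: Sampler = field(default_factory=lambda: Constant(0.55))
    age_sampler: Sampler = field(default_factory=TwoBandAge)
    vendor_weights: Mapping[str, float] = field(
        default_factory=lambda: {"Siemens": 0.6, "GE": 0.25, "Philips": 0.15}
    )
    master_seed: int = 0

    @property
    def n_centers(self) -> int:
        return sum(g.n_centers for g in self.center_size_profile)

    def validate(self) -> None:
        if not self.center_size_profile:
            raise ConfigurationError("center_size_profile is empty")
        for g in self.center_size_profile:
            if g.n_centers < 1:
                raise ConfigurationError(f"group {g.name!r} has n_centers < 1")
            _check_simplex(g.vendor_weights or self.vendor_weights)
        _check_simplex(self.vendor_weights)

    @staticmethod
    def paper_default(master_seed: int = 0, scale: float = 1.0) -> "CohortSpec":
        """The 83-center Parkinson's-database profile.

        Fourteen studies: one 42-center and one 24-center multi-site study,
        one 6-center study and eleven single-center studies; per-study sample
        totals, label mix, sex mix, age-band mix and scanner vendors follow
        the published demographics, rescaled so the cohort totals 1,817
        participants.  ``scale`` < 1 shrinks every study proportionally
        (used by the scaled-down experiment presets).
        """
        groups = []
        for row in paper_center_table().itertuples():
            total = max(row.n_centers, int(round(row.scaled_total * scale)))
            groups.append(
                CenterGroup(
                    name=row.study,
                    n_centers=row.n_centers,
                    sizes=FixedTotalSizes(total=total, min_size=1, sigma=1.0),
                    label_fraction=Constant(row.label_fraction),
                    male_fraction=Constant(row.male_fraction),
                    age=TwoBandAge(p_old=row.old_fraction),
                    vendor_weights=row.vendor_weights,
                )
            )
        return CohortSpec(center_size_profile=tuple(groups), master_seed=master_seed)


def _check_simplex(weights: Mapping[str, float]) -> None:
    if not weights:
        raise ConfigurationError("vendor_weights is empty")
    vals = list(weights.values())
    if any(v < 0 for v in vals) or not np.isclose(sum(vals), 1.0, atol=1e-9):
        raise ConfigurationError(f"vendor weights must be a simplex, got {dict(weights)}")
    for v in weights:
        if v not in VENDORS:
            raise ConfigurationError(f"unknown vendor {v!r}")


# Published multi-center Parkinson's database: per-study center counts, sample
# totals and demographic cells.  Raw sample totals over-count the final cohort
# (they include scans excluded downstream), so the generator rescales them to
# the stated cohort size of 1,817.  Demographic cells are
# (PD male, PD female, PD <60, PD 60+, HC male, HC female, HC <60, HC 60+);
# None marks a class a study did not contribute.
_STUDY_TABLE: list[tuple] = [
    # study, n_centers, raw_total, pd cells, hc cells, vendors
    ("ADNI", 42, 564, None, (96, 177, 18, 255), ("Siemens", "GE", "Philips")),
    ("BIOCOG", 1, 94, (25, 20, 0, 45), (28, 21, 0, 49), ("Siemens",)),
    ("C-BIG", 1, 76, (36, 30, 16, 50), (1, 9, 3, 7), ("Siemens",)),
    ("HAMBURG", 1, 113, (52, 22, 23, 51), (24, 15, 13, 26), ("Siemens",)),
    ("CCNA", 6, 57, (37, 20, 8, 47), None, ("GE",)),
    ("JAPAN", 1, 45, (13, 17, 4, 26), (7, 8, 4, 11), ("Siemens",)),
    ("NEUROCON", 1, 42, (16, 10, 4, 22), (4, 12, 6, 10), ("Siemens",)),
    ("OASIS", 1, 27, None, (17, 10, 5, 22), ("Siemens",)),
    ("PD-MCI-CALGARY", 1, 121, (53, 26, 0, 79), (20, 22, 0, 42), ("GE",)),
    ("PD-MCI-PLS", 1, 62, (26, 15, 15, 26), (10, 11, 7, 14), ("Siemens",)),
    ("PPMI", 24, 530, (228, 136, 147, 237), (108, 58, 132, 217), ("Siemens", "GE", "Philips")),
    ("SALD", 1, 78, None, (78, 0, 34, 44), ("Siemens",)),
    ("TAOWU", 1, 37, (8, 9, 1, 16), (12, 8, 3, 17), ("Siemens",)),
    ("UKBB", 1, 245, (28, 20, 4, 44), (119, 78, 37, 160), ("Siemens",)),
]

COHORT_TOTAL = 1817  # stated size of the assembled cohort


def paper_center_table() -> pd.DataFrame:
    """Per-study profile of the 83-center database as a DataFrame.

    Columns: study, n_centers, raw_total, scaled_total (largest-remainder
    rescaling of raw totals to the 1,817-participant cohort), label_fraction,
    male_fraction, old_fraction and vendor_weights.
    """
    raw_totals = np.array([row[2] for row in _STUDY_TABLE], dtype=float)
    target = COHORT_TOTAL * raw_totals / raw_totals.sum()
    base = np.floor(target).astype(int)
    rem = target - base
    short = COHORT_TOTAL - int(base.sum())
    order = np.argsort(-rem, kind="stable")
    base[order[:short]] += 1

    rows = []
    for (study, n_centers, raw_total, pd_cells, hc_cells, vendors), scaled in zip(
        _STUDY_TABLE, base
    ):
        pd_n = sum(pd_cells[:2]) if pd_cells else 0
        hc_n = sum(hc_cells[:2]) if hc_cells else 0
        males = (pd_cells[0] if pd_cells else 0) + (hc_cells[0] if hc_cells else 0)
        old = (pd_cells[3] if pd_cells else 0) + (hc_cells[3] if hc_cells else 0)
        demo_n = pd_n + hc_n
        rows.append(
            {
                "study": study,
                "n_centers": n_centers,
                "raw_total": raw_total,
                "scaled_total": int(scaled),
                "label_fraction": pd_n / demo_n if demo_n else 0.5,
                "male_fraction": males / demo_n if demo_n else 0.5,
                "old_fraction": old / demo_n if demo_n else 0.6,
                "vendor_weights": {v: 1.0 / len(vendors) for v in vendors},
            }
        )
    return pd.DataFrame(rows)


def build_cohort(spec: CohortSpec) -> Cohort:
    """Synthesise a cohort from a spec; deterministic given ``master_seed``.

    Center ids are ``{group}-{k:02d}``.  Per-center attribute draws use a
    dedicated PRNG stream seeded by ``(master_seed, "center", center_id)``
    and consume draws in a fixed documented order (label fraction, male
    fraction, vendor, field strength, then per-participant label, sex, age),
    so tests can replay them independently.
    """
    spec.validate()
    records: list[ParticipantRecord] = []
    for group in spec.center_size_profile:
        size_rng = np.random.Generator(
            np.random.PCG64(derive_seed(spec.master_seed, "sizes", group.name))
        )
        sizes = group.sizes.sample_sizes(group.n_centers, size_rng)
        if any(s < 1 for s in sizes):
            raise ConfigurationError(
                f"group {group.name!r} drew a center of size < 1: {sizes}"
            )
        for k, size in enumerate(sizes):
            center_id = f"{group.name}-{k:02d}"
            records.extend(_draw_center(center_id, size, group, spec))
    return Cohort(tuple(records))


def _draw_center(
    center_id: str, size: int, group: CenterGroup, spec: CohortSpec
) -> list[ParticipantRecord]:
    rng = np.random.Generator(
        np.random.PCG64(derive_seed(spec.master_seed, "center", center_id))
    )
    label_p = (group.label_fraction or spec.label_fraction_sampler)(rng)
    male_p = (group.male_fraction or spec.male_fraction_sampler)(rng)
    weights = group.vendor_weights or spec.vendor_weights
    vendors = sorted(weights.keys())
    probs = np.array([weights[v] for v in vendors], dtype=float)
    vendor = vendors[int(rng.choice(len(vendors), p=probs / probs.sum()))]
    field_strength = FIELD_STRENGTHS[int(rng.integers(0, 2))]
    age_sampler = group.age or spec.age_sampler

    out = []
    for i in range(size):
        label = int(rng.random() < label_p)
        sex = "M" if rng.random() < male_p else "F"
        age = float(age_sampler(rng))
        out.append(
            ParticipantRecord(
                participant_id=f"{center_id}-{i:04d}",
                center_id=center_id,
                label=label,
                sex=sex,
                age_years=age,
                vendor=vendor,
                field_strength_tesla=field_strength,
            )
        )
    return out


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------


def split_cohort(
    cohort: Cohort,
    train_fraction: float = 0.8,
    small_center_threshold: int = 25,
    seed: int = 0,
) -> SplitCohort:
    """Per-center train/test split with small-center demographic balancing.

    Centers holding at least ``small_center_threshold`` records are split
    within-center: records are shuffled (stream seeded by the split seed and
    center id) and the first ``floor(train_fraction * n + 0.5)`` go to train
    (round half up), the remainder to test.

    Smaller centers are pooled and assigned one record at a time by a greedy
    rule that keeps the global train/test composition balanced over the four
    (sex, age-band) cells: small centers are processed in descending size
    (ties broken by center id), records within a center in seed-shuffled
    order, and each record goes to test only when the test side of its cell
    is further below its target share than the train side — capped so that at
    most ``1 - train_fraction`` of the small-center pool lands in test.
    """
    if len(cohort) == 0:
        raise ValueError("cannot split an empty cohort")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if small_center_threshold < 1:
        raise ValueError("small_center_threshold must be >= 1")

    assignment: dict[str, str] = {}
    centers = cohort.centers

    small_pool: list[tuple[str, list[ParticipantRecord]]] = []
    for center_id in sorted(centers):
        recs = centers[center_id]
        if len(recs) >= small_center_threshold:
            rng = np.random.Generator(
                np.random.PCG64(derive_seed(seed, "split", center_id))
            )
            order = rng.permutation(len(recs))
            n_train = int(np.floor(train_fraction * len(recs) + 0.5))
            for rank, idx in enumerate(order):
                assignment[recs[idx].participant_id] = (
                    "train" if rank < n_train else "test"
                )
        else:
            small_pool.append((center_id, recs))

    _assign_small_pool(small_pool, assignment, train_fraction, seed)

    train_records = []
    test_records = []
    for r in cohort.records:
        split = assignment[r.participant_id]
        r2 = replace(r, split=split)
        (train_records if split == "train" else test_records).append(r2)

    report = _split_report(train_records, test_records)
    return SplitCohort(
        train=Cohort(tuple(train_records)),
        test=Cohort(tuple(test_records)),
        split_report=report,
    )


def _assign_small_pool(
    small_pool: list[tuple[str, list[ParticipantRecord]]],
    assignment: dict[str, str],
    train_fraction: float,
    seed: int,
) -> None:
    pool_size = sum(len(recs) for _, recs in small_pool)
    if pool_size == 0:
        return
    test_cap = int(np.floor((1.0 - train_fraction) * pool_size))
    # running per-(sex, age-band) cell counts across the whole small pool
    cell_counts: dict[tuple[str, str], dict[str, int]] = {}
    n_test_assigned = 0

    ordered = sorted(small_pool, key=lambda item: (-len(item[1]), item[0]))
    for center_id, recs in ordered:
        rng = np.random.Generator(
            np.random.PCG64(derive_seed(seed, "split-small", center_id))
        )
        for idx in rng.permutation(len(recs)):
            r = recs[idx]
            cell = (r.sex, r.age_band)
            counts = cell_counts.setdefault(cell, {"train": 0, "test": 0})
            n_cell = counts["train"] + counts["test"] + 1
            test_deficit = (1.0 - train_fraction) * n_cell - counts["test"]
            train_deficit = train_fraction * n_cell - counts["train"]
            to_test = test_deficit > train_deficit and n_test_assigned < test_cap
            split = "test" if to_test else "train"
            counts[split] += 1
            n_test_assigned += split == "test"
            assignment[r.participant_id] = split


def _split_report(
    train: list[ParticipantRecord], test: list[ParticipantRecord]
) -> pd.DataFrame:
    rows = []
    per_center: dict[str, dict[str, int]] = {}
    for split_name, recs in (("train", train), ("test", test)):
        for r in recs:
            per_center.setdefault(r.center_id, {"train": 0, "test": 0})
            per_center[r.center_id][split_name] += 1
    for center_id in sorted(per_center):
        c = per_center[center_id]
        rows.append(
            {"center_id": center_id, "n_train": c["train"], "n_test": c["test"]}
        )
    report = pd.DataFrame(rows, columns=["center_id", "n_train", "n_test"])
    for split_name, recs in (("train", train), ("test", test)):
        n = max(len(recs), 1)
        report.attrs[f"{split_name}_male_fraction"] = (
            sum(r.sex == "M" for r in recs) / n
        )
        report.attrs[f"{split_name}_old_fraction"] = (
            sum(r.age_band == "60+" for r in recs) / n
        )
    return report


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------


def write_manifest(cohort: Cohort, path: str | Path | io.TextIOBase) -> None:
    """Write a cohort as a UTF-8 CSV manifest (one row per participant)."""
    df = cohort.to_frame()
    df.to_csv(path, index=False)


def load_manifest(path: str | Path | io.TextIOBase) -> Cohort:
    """Load a manifest CSV back into a Cohort, validating schema and content."""
    df = pd.read_csv(path, dtype={"participant_id": str, "center_id": str})
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"manifest is missing required column {col!r}")
    ids = df["participant_id"].tolist()
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicated participant_id values: {dupes[:5]}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ParticipantRecord(
                participant_id=str(row.participant_id),
                center_id=str(row.center_id),
                label=int(row.label),
                sex=str(row.sex),
                age_years=float(row.age_years),
                vendor=str(row.vendor),
                field_strength_tesla=float(row.field_strength_tesla),
                split=str(row.split),
            )
        )
    return Cohort(tuple(records))


# ---------------------------------------------------------------------------
# demographics
# ---------------------------------------------------------------------------


def summarize(cohort: Cohort) -> pd.DataFrame:
    """Per-center and global counts by label, sex and age band (<60 / 60+)."""
    if len(cohort) == 0:
        raise ValueError("cannot summarise an empty cohort")

    def _count(recs: Iterable[ParticipantRecord]) -> dict[str, int]:
        recs = list(recs)
        return {
            "n": len(recs),
            "n_positive": sum(r.label == 1 for r in recs),
            "n_negative": sum(r.label == 0 for r in recs),
            "n_male": sum(r.sex == "M" for r in recs),
            "n_female": sum(r.sex == "F" for r in recs),
            "n_under60": sum(r.age_band == "<60" for r in recs),
            "n_60plus": sum(r.age_band == "60+" for r in recs),
        }

    rows = []
    for center_id in cohort.center_ids:
        rows.append({"center_id": center_id, **_count(cohort.centers[center_id])})
    rows.append({"center_id": "__all__", **_count(cohort.records)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reconstruction from the published split table
# ---------------------------------------------------------------------------

# Published split distribution: (label, split, sex) -> count.
# PD 680 train / 187 test; healthy 730 train / 220 test; total 1,817.
SPLIT_TABLE: dict[tuple[int, str, str], int] = {
    (1, "train", "M"): 418,
    (1, "train", "F"): 262,
    (1, "test", "M"): 124,
    (1, "test", "F"): 63,
    (0, "train", "M"): 400,
    (0, "train", "F"): 330,
    (0, "test", "M"): 120,
    (0, "test", "F"): 100,
}


def from_split_table(table: Mapping[tuple[int, str, str], int] | None = None) -> Cohort:
    """Reconstruct a cohort directly from the published split cell counts.

    Each (label, split, sex) cell becomes that many records with already
    assigned splits.  Ages alternate across the band cutoff and scanner
    fields are fixed; only the counts carry information — the result is used
    for manifest arithmetic, not for training.
    """
    table = dict(SPLIT_TABLE if table is None else table)
    records = []
    for (label, split, sex), count in sorted(table.items()):
        for i in range(count):
            records.append(
                ParticipantRecord(
                    participant_id=f"T2-{label}{split[0]}{sex}-{i:04d}",
                    center_id="T2",
                    label=label,
                    sex=sex,
                    age_years=55.0 if i % 2 == 0 else 65.0,
                    vendor="Siemens",
                    field_strength_tesla=3.0,
                    split=split,
                )
            )
    return Cohort(tuple(records))
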