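"""Core data model for panel-sequenced tumor cohorts.

A :class:`Sample` bundles the four molecular/clinical layers the subtyping
pipeline consumes: somatic variant calls, microsatellite locus read-length
histograms, copy-number segments, and the clinical record.  A
:class:`Cohort` is an ordered collection of samples keyed by ``sample_id``.

Conventions
-----------
* Variant positions are 1-based (VCF convention).
* Copy-number segments are 0-based half-open intervals (BED convention).
* Survival times are in months.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import percentage

__all__ = [
    "Consequence",
    "Variant",
    "MicrosatelliteLocus",
    "CNSegment",
    "ClinicalRecord",
    "Sample",
    "Cohort",
    "CohortSummary",
    "ValidationError",
    "IntegrityError",
    "FormatError",
    "summarize_cohort",
]


class ValidationError(ValueError):
    """A field value violates a model invariant."""


class IntegrityError(ValueError):
    """Cross-record consistency violation (e.g. duplicate sample ids)."""


class FormatError(ValueError):
    """An on-disk file does not match its documented layout."""


class Consequence(str, enum.Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    SYNONYMOUS = "synonymous"
    INFRAME_INDEL = "inframe_indel"
    OTHER = "other"


#: consequences counted as protein-altering for TMB and gene-mutation calls
NONSYNONYMOUS = frozenset(
    {
        Consequence.MISSENSE,
        Consequence.NONSENSE,
        Consequence.FRAMESHIFT,
        Consequence.SPLICE,
        Consequence.INFRAME_INDEL,
    }
)


@dataclass(frozen=True)
class Variant:
    """One somatic small-variant call from the panel."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    hgvs_p: str
    consequence: Consequence
    vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(f"VAF {self.vaf} outside [0, 1] at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValidationError(f"position {self.pos} < 1 (positions are 1-based)")
        if self.ref == self.alt:
            raise ValidationError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")


@dataclass(frozen=True)
class MicrosatelliteLocus:
    """Paired baseline/observed repeat-length histograms for one panel locus.

    ``baseline_hist`` maps repeat length -> probability (normal-tissue
    reference distribution); ``observed_hist`` maps repeat length -> tumor
    read count.
    """

    locus_id: str
    repeat_unit: str
    baseline_hist: Mapping[int, float]
    observed_hist: Mapping[int, int]

    def __post_init__(self) -> None:
        total = sum(self.baseline_hist.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValidationError(
                f"baseline histogram of {self.locus_id} sums to {total}, expected 1"
            )
        if any(c < 0 for c in self.observed_hist.values()):
            raise ValidationError(f"negative observed read count at {self.locus_id}")

    @property
    def total_reads(self) -> int:
        return int(sum(self.observed_hist.values()))


@dataclass(frozen=True)
class CNSegment:
    """A copy-number segment with its mean log2 tumor/normal ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end} has start >= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


STAGES = ("I", "II", "III", "IV", "unknown")
GRADES = ("G1", "G2", "G3", "undifferentiated", "unknown")
HISTOLOGIES = ("endometrioid", "serous", "mucinous", "other", "unknown")
LVSI_LEVELS = ("yes", "no", "unknown")
VITAL_LEVELS = ("alive", "deceased", "unknown")


@dataclass
class ClinicalRecord:
    """Demographics, histopathology, and time-to-event endpoints (months)."""

    sample_id: str
    age: float | None = None
    stage: str = "unknown"
    grade: str = "unknown"
    histology: str = "unknown"
    lvsi: str = "unknown"
    os_months: float | None = None
    os_event: int | None = None
    dss_months: float | None = None
    dss_event: int | None = None
    vital_status: str = "unknown"

    def __post_init__(self) -> None:
        for name, value, levels in (
            ("stage", self.stage, STAGES),
            ("grade", self.grade, GRADES),
            ("histology", self.histology, HISTOLOGIES),
            ("lvsi", self.lvsi, LVSI_LEVELS),
            ("vital_status", self.vital_status, VITAL_LEVELS),
        ):
            if value not in levels:
                raise ValidationError(f"{self.sample_id}: {name}={value!r} not in {levels}")
        if self.os_event is not None and self.os_months is None:
            raise ValidationError(f"{self.sample_id}: os_event present but os_months missing")
        if self.dss_event is not None and self.dss_months is None:
            raise ValidationError(f"{self.sample_id}: dss_event present but dss_months missing")
        if self.dss_event == 1 and self.os_event != 1:
            raise ValidationError(
                f"{self.sample_id}: disease-specific death implies os_event=1"
            )
        for ev in (self.os_event, self.dss_event):
            if ev is not None and ev not in (0, 1):
                raise ValidationError(f"{self.sample_id}: event indicator {ev} not in {{0,1}}")
        for t in (self.os_months, self.dss_months):
            if t is not None and t < 0:
                raise ValidationError(f"{self.sample_id}: negative survival time {t}")


@dataclass
class Sample:
    """All molecular layers plus the clinical record for one tumor."""

    sample_id: str
    variants: list[Variant] = field(default_factory=list)
    msi_loci: list[MicrosatelliteLocus] = field(default_factory=list)
    segments: list[CNSegment] = field(default_factory=list)
    clinical: ClinicalRecord | None = None
    gene_mutations: dict[str, int] | None = None
    missing_layers: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        # CN segments on one chromosome must not overlap
        by_chrom: dict[str, list[CNSegment]] = {}
        for seg in self.segments:
            by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in by_chrom.items():
            segs = sorted(segs, key=lambda s: s.start)
            for a, b in zip(segs, segs[1:]):
                if b.start < a.end:
                    raise ValidationError(
                        f"{self.sample_id}: overlapping segments on {chrom} "
                        f"({a.start}-{a.end} and {b.start}-{b.end})"
                    )


@dataclass
class Cohort:
    """Ordered sample collection with unique ids.

    ``truth_labels`` is populated only by the synthetic generator and the
    packaged fixtures; it carries the planted/pre-assigned subtype of every
    sample, for label-recovery checks and for summaries that do not rerun
    the classifier.
    """

    samples: list[Sample]
    truth_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise IntegrityError(f"duplicate sample_id(s): {dup}")

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    def __getitem__(self, sample_id: str) -> Sample:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def clinical_frame(self) -> pd.DataFrame:
        """Clinical records as a DataFrame indexed by sample_id."""
        rows = []
        for s in self.samples:
            c = s.clinical or ClinicalRecord(sample_id=s.sample_id)
            rows.append(vars(c).copy())
        columns = [f.name for f in fields(ClinicalRecord)]
        return pd.DataFrame(rows, columns=columns).set_index("sample_id")


AGE_BANDS = ("<55", ">=55", "unknown")


def _age_band(age: float | None) -> str:
    if age is None or (isinstance(age, float) and math.isnan(age)):
        return "unknown"
    return "<55" if age < 55 else ">=55"


@dataclass
class CohortSummary:
    """Per-subtype counts/percentages and clinicopathological cross-tabs.

    Percentages always use the full cohort size as denominator and are
    rounded half-up to two decimals, matching how clinical characteristics
    tables report explicit "unknown" rows against the column total.
    """

    n_total: int
    counts: dict[str, int]
    percentages: dict[str, float]
    crosstabs: dict[str, pd.DataFrame]

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise IntegrityError("subtype counts do not sum to n_total")


def summarize_cohort(
    cohort: Cohort,
    subtype_labels: Mapping[str, str],
    subtype_order: Sequence[str] = ("POLE", "MSI-H", "CNH", "CNL"),
) -> CohortSummary:
    """Tabulate subtype composition against stage, grade, histology, LVSI
    and age band.

    ``subtype_labels`` must provide one label per sample.  Unknown clinical
    categories are reported as their own level rather than dropped.
    """
    missing = set(cohort.sample_ids) - set(subtype_labels)
    extra = set(subtype_labels) - set(cohort.sample_ids)
    if missing or extra:
        raise IntegrityError(
            f"label/sample mismatch: {len(missing)} unlabeled, {len(extra)} unmatched labels"
        )

    labels = [subtype_labels[sid] for sid in cohort.sample_ids]
    order = list(subtype_order) + sorted(set(labels) - set(subtype_order))

    n = len(cohort)
    counts = {s: labels.count(s) for s in order}
    percentages = {s: percentage(c, n) for s, c in counts.items()}

    clin = cohort.clinical_frame()
    clin["subtype"] = labels
    clin["age_band"] = [_age_band(a) for a in clin["age"]]

    axes = {
        "stage": STAGES,
        "grade": GRADES,
        "histology": HISTOLOGIES,
        "lvsi": LVSI_LEVELS,
        "age_band": AGE_BANDS,
    }
    crosstabs: dict[str, pd.DataFrame] = {}
    for axis, levels in axes.items():
        if n == 0:
            tab = pd.DataFrame(0, index=list(levels), columns=order)
        else:
            tab = pd.crosstab(clin[axis], clin["subtype"])
            tab = tab.reindex(index=list(levels), columns=order, fill_value=0)
        crosstabs[axis] = tab.astype(int)

    return CohortSummary(n_total=n, counts=counts, percentages=percentages, crosstabs=crosstabs)
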