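"""Synthetic panel-level cohorts with the structure the classifier assumes.

The generator emulates a retrospective endometrial-carcinoma cohort typed
by a one-step targeted NGS panel: four molecular subtypes drawn at their
observed study proportions (19/44/27/143 of 233); per-subtype mutational
burden (POLE ultramutated >> MSI-H hypermutated >> copy-number groups);
microsatellite locus read-length histograms whose unstable-locus fraction
separates MSI-H from the rest; TP53-driven copy-number-high samples with
elevated fraction of genome altered; subtype-dependent exponential
survival (CNH median ~35 months, POLE essentially event-free over ten
years) under a uniform administrative censoring window of 7-122 months;
and CNL/MSI-H biomarker mutations (ARID1A, ZFHX4) with planted hazard
ratios.

Every draw flows from a single seeded :class:`numpy.random.Generator`;
identical seeds give byte-identical cohorts.  The planted subtype of each
sample is recorded in ``Cohort.truth_labels`` for label-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markers import ConfigError
from .model import (
    ClinicalRecord,
    CNSegment,
    Cohort,
    Consequence,
    MicrosatelliteLocus,
    Sample,
    Variant,
)

__all__ = ["SimulationConfig", "generate_cohort"]

SUBTYPES = ("POLE", "MSI-H", "CNH", "CNL")

#: background panel genes for filler mutations (never POLE or TP53)
_BACKGROUND_GENES = (
    "PTEN", "PIK3CA", "PIK3R1", "CTNNB1", "CTCF", "KRAS", "ARID1B", "KMT2C",
    "KMT2D", "FBXW7", "PPP2R1A", "FGFR2", "SOX17", "ATM", "BRCA2", "RB1",
)

#: microsatellite baseline: repeat-length offsets and probabilities shared
#: by all panel loci; "novel" tumor lengths sit 2-3 units below the support
_BASELINE_OFFSETS = (0, 1, 2, 3, 4)
_BASELINE_PROBS = (0.1, 0.2, 0.4, 0.2, 0.1)


def _rate_from_survival(s_at: float, horizon: float) -> float:
    return -math.log(s_at) / horizon


def _rate_from_median(median: float) -> float:
    return math.log(2.0) / median


@dataclass
class SimulationConfig:
    """Study-level parameters of the synthetic cohort.

    Defaults encode the emulated study conditions: subtype mix 19/44/27/143
    of 233; log-normal TMB with medians 200 / 40 / 5 / 5 mut/Mb; MSI-H
    unstable-locus fractions in 0.4-0.8 vs at most one unstable locus
    elsewhere; TP53 certain in CNH and absent in CNL; exponential overall
    survival with CNH median 35 months and POLE 120-month survival 0.99;
    censoring uniform on 7-122 months (median follow-up ~66); ARID1A and
    ZFHX4 enriched in CNL/MSI-H with hazard ratios 2 and 3.
    """

    n_samples: int = 233
    subtype_proportions: tuple[float, float, float, float] = (
        19 / 233, 44 / 233, 27 / 233, 143 / 233,
    )
    tmb_median: dict[str, float] = field(
        default_factory=lambda: {"POLE": 200.0, "MSI-H": 40.0, "CNH": 5.0, "CNL": 5.0}
    )
    tmb_log_sigma: float = 0.35
    panel_size_mb: float = 1.0
    n_msi_loci: int = 25
    msi_reads_per_locus: int = 100
    msi_unstable_fraction_range: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "POLE": (0.0, 0.04), "MSI-H": (0.4, 0.8), "CNH": (0.0, 0.04), "CNL": (0.0, 0.04),
        }
    )
    tp53_probability: dict[str, float] = field(
        default_factory=lambda: {"POLE": 0.3, "MSI-H": 0.25, "CNH": 1.0, "CNL": 0.0}
    )
    n_segments: int = 10
    segment_length: int = 1_000_000
    fga_target: dict[str, float] = field(
        default_factory=lambda: {"POLE": 0.0, "MSI-H": 0.0, "CNH": 0.5, "CNL": 0.0}
    )
    os_rate_per_month: dict[str, float] = field(
        default_factory=lambda: {
            "POLE": _rate_from_survival(0.99, 120.0),
            "MSI-H": _rate_from_survival(0.80, 120.0),
            "CNH": _rate_from_median(35.0),
            "CNL": _rate_from_survival(0.85, 120.0),
        }
    )
    weibull_shape: float = 1.0
    censor_window_months: tuple[float, float] = (7.0, 122.0)
    age_mean_sd: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "POLE": (53.65, 10.21), "MSI-H": (56.32, 8.93),
            "CNH": (59.33, 10.88), "CNL": (53.63, 9.62),
        }
    )
    arid1a_prevalence: dict[str, float] = field(
        default_factory=lambda: {"POLE": 0.3, "MSI-H": 0.45, "CNH": 0.1, "CNL": 0.35}
    )
    zfhx4_prevalence: dict[str, float] = field(
        default_factory=lambda: {"POLE": 0.05, "MSI-H": 0.25, "CNH": 0.02, "CNL": 0.04}
    )
    arid1a_hr: float = 2.0
    zfhx4_hr: float = 3.0
    dss_given_os_event: float = 0.9

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.subtype_proportions), 1.0, abs_tol=1e-9):
            raise ConfigError("subtype proportions must sum to 1")
        if any(p < 0 for p in self.subtype_proportions):
            raise ConfigError("subtype proportions must be non-negative")
        if any(r <= 0 for r in self.os_rate_per_month.values()):
            raise ConfigError("survival rates must be > 0")
        if self.n_samples < 0:
            raise ConfigError("n_samples must be >= 0")


def _make_locus(
    locus_index: int, unstable: bool, reads: int, rng: np.random.Generator
) -> MicrosatelliteLocus:
    base_len = 10 + (locus_index % 7)
    baseline = {base_len + off: p for off, p in zip(_BASELINE_OFFSETS, _BASELINE_PROBS)}
    observed: dict[int, int] = {}
    if unstable:
        novel_reads = int(round(0.4 * reads))
        half = novel_reads // 2
        observed[base_len - 3] = half
        observed[base_len - 2] = novel_reads - half
        supported = reads - novel_reads
    else:
        supported = reads
    counts = rng.multinomial(supported, _BASELINE_PROBS)
    for off, c in zip(_BASELINE_OFFSETS, counts):
        observed[base_len + off] = int(c)
    return MicrosatelliteLocus(
        locus_id=f"MS{locus_index:02d}",
        repeat_unit="A" if locus_index % 2 == 0 else "CA",
        baseline_hist=baseline,
        observed_hist=observed,
    )


def _make_variant(
    gene: str, consequence: Consequence, hgvs_p: str, rng: np.random.Generator
) -> Variant:
    pos = int(rng.integers(1_000, 10_000_000))
    ref, alt = ("A", "G") if rng.random() < 0.5 else ("C", "T")
    vaf = float(rng.uniform(0.06, 0.6))
    return Variant(
        chrom=f"chr{int(rng.integers(1, 23))}", pos=pos, ref=ref, alt=alt,
        gene=gene, hgvs_p=hgvs_p, consequence=consequence, vaf=vaf,
    )


def _clinical_categoricals(rng: np.random.Generator) -> dict[str, str]:
    stage = rng.choice(
        ["I", "II", "III", "IV", "unknown"], p=[0.674, 0.073, 0.146, 0.013, 0.094]
    )
    grade = rng.choice(
        ["G1", "G2", "G3", "undifferentiated", "unknown"],
        p=[0.416, 0.236, 0.193, 0.013, 0.142],
    )
    histology = rng.choice(
        ["endometrioid", "serous", "mucinous", "other", "unknown"],
        p=[0.786, 0.047, 0.009, 0.030, 0.128],
    )
    lvsi = rng.choice(["no", "yes", "unknown"], p=[0.742, 0.056, 0.202])
    return {"stage": str(stage), "grade": str(grade), "histology": str(histology),
            "lvsi": str(lvsi)}


def generate_cohort(config: SimulationConfig | None = None, seed: int = 0) -> Cohort:
    """Draw a fully reproducible synthetic cohort.

    Markers are generated unambiguously for the planted subtype: POLE
    samples carry a hotspot POLE variant; MSI-H samples are hypermutated
    with >=40% unstable loci; CNH samples are TP53-mutant with high FGA;
    CNL samples are TP53-wild-type with a quiet genome.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    subtype_idx = rng.choice(len(SUBTYPES), size=config.n_samples, p=config.subtype_proportions)

    samples: list[Sample] = []
    truth: dict[str, str] = {}
    for i in range(config.n_samples):
        subtype = SUBTYPES[subtype_idx[i]]
        sid = f"S{i + 1:04d}"
        truth[sid] = subtype

        tmb = float(
            np.exp(np.log(config.tmb_median[subtype]) + config.tmb_log_sigma * rng.normal())
        )
        n_variants = max(1, int(round(tmb * config.panel_size_mb)))

        variants: list[Variant] = []
        if subtype == "POLE":
            variants.append(_make_variant("POLE", Consequence.MISSENSE, "p.P286R", rng))
        tp53 = rng.random() < config.tp53_probability[subtype]
        if tp53:
            variants.append(_make_variant("TP53", Consequence.MISSENSE, "p.R273H", rng))
        while len(variants) < n_variants:
            gene = str(rng.choice(_BACKGROUND_GENES))
            variants.append(_make_variant(gene, Consequence.MISSENSE, "p.X1X", rng))

        lo, hi = config.msi_unstable_fraction_range[subtype]
        frac = float(rng.uniform(lo, hi))
        n_unstable = int(round(frac * config.n_msi_loci))
        loci = [
            _make_locus(j, j < n_unstable, config.msi_reads_per_locus, rng)
            for j in range(config.n_msi_loci)
        ]

        altered = int(round(config.fga_target[subtype] * config.n_segments))
        segments = []
        for j in range(config.n_segments):
            if j < altered:
                log2 = float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.2))
            else:
                log2 = float(rng.uniform(-0.1, 0.1))
            start = j * config.segment_length
            segments.append(
                CNSegment(chrom="chr1", start=start, end=start + config.segment_length,
                          log2_ratio=log2)
            )

        arid1a = int(rng.random() < config.arid1a_prevalence[subtype])
        zfhx4 = int(rng.random() < config.zfhx4_prevalence[subtype])
        gene_mutations = {"ARID1A": arid1a, "ZFHX4": zfhx4}

        rate = config.os_rate_per_month[subtype]
        rate *= config.arid1a_hr ** arid1a * config.zfhx4_hr ** zfhx4
        shape = config.weibull_shape
        u = rng.random()
        # Weibull with exponential special case at shape 1; hazard scales by rate
        t_event = (-math.log(u)) ** (1.0 / shape) / rate if shape != 1.0 else -math.log(u) / rate
        c_lo, c_hi = config.censor_window_months
        t_censor = float(rng.uniform(c_lo, c_hi))
        os_event = int(t_event <= t_censor)
        os_months = round(min(t_event, t_censor), 2)
        dss_event = int(os_event and rng.random() < config.dss_given_os_event)

        cats = _clinical_categoricals(rng)
        mean, sd = config.age_mean_sd[subtype]
        age = float(np.clip(round(rng.normal(mean, sd)), 30, 84))
        clinical = ClinicalRecord(
            sample_id=sid,
            age=age,
            os_months=os_months,
            os_event=os_event,
            dss_months=os_months,
            dss_event=dss_event,
            vital_status="deceased" if os_event else "alive",
            **cats,
        )
        samples.append(
            Sample(
                sample_id=sid,
                variants=variants,
                msi_loci=loci,
                segments=segments,
                clinical=clinical,
                gene_mutations=gene_mutations,
            )
        )
    return Cohort(samples=samples, truth_labels=truth)
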