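"""Per-sample molecular markers feeding the hierarchical subtype call.

Five markers are derived from the panel layers:

* ``pole_positive`` — pathogenic POLE variant, either a known exonuclease-
  domain (EDM) hotspot or any nonsynonymous EDM variant in an ultramutated
  sample.
* ``tp53_mutated`` — any protein-altering TP53 variant.
* ``tmb`` — tumor mutational burden, nonsynonymous variants per megabase of
  panel territory, after the VAF sensitivity filter.
* ``msi_status`` — MSI-H / MSI-L / MSS from per-locus read-length histogram
  instability scores.
* ``fga`` — fraction of the covered genome altered, length-weighted share
  of segment bases with |log2 ratio| above threshold.

The per-locus MSI score is deliberately simple and fully reproducible: a
locus is unstable when too large a fraction of its tumor reads sits at
repeat lengths essentially unsupported by the baseline distribution.
Commercial panel pipelines use proprietary scoring; this surrogate keeps
the same decision structure (per-locus call, then unstable-locus fraction)
with documented, overridable thresholds.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .model import NONSYNONYMOUS, CNSegment, MicrosatelliteLocus, Variant

logger = logging.getLogger(__name__)

__all__ = [
    "CallerConfig",
    "MarkerProfile",
    "ConfigError",
    "NotEvaluableError",
    "POLE_PATHOGENIC_DEFAULT",
    "POLE_EDM_RANGE",
    "compute_tmb",
    "assess_pole",
    "assess_tp53",
    "score_locus_instability",
    "call_msi",
    "compute_fga",
    "classify_cn",
    "build_profile",
]


class ConfigError(ValueError):
    """Invalid caller configuration."""


class NotEvaluableError(ValueError):
    """A marker cannot be computed from the available layer (e.g. no
    scoreable MSI locus)."""


#: Recurrent pathogenic POLE exonuclease-domain hotspots.  This is the
#: widely used curated set of variants with proven ultramutator phenotype;
#: override via ``CallerConfig.pole_pathogenic_list`` to extend or replace.
POLE_PATHOGENIC_DEFAULT = frozenset(
    {
        "p.P286R",
        "p.V411L",
        "p.S297F",
        "p.S459F",
        "p.A456P",
        "p.F367S",
        "p.L424I",
        "p.M295R",
        "p.P436R",
        "p.M444K",
        "p.D368Y",
    }
)

#: POLE exonuclease-domain residue range (amino acids 268-471).
POLE_EDM_RANGE = (268, 471)


@dataclass(frozen=True)
class CallerConfig:
    """All thresholds of the marker callers, JSON-serializable.

    Defaults encode conventional cutoffs: 5% VAF sensitivity, 100 mut/Mb
    ultramutation, 10 mut/Mb hypermutation, 30%/10% unstable-locus
    fractions for MSI-H/MSI-L, |log2| > 0.3 for an altered copy-number
    segment and FGA >= 0.2 for the copy-number-high clause.
    """

    vaf_min: float = 0.05
    pole_pathogenic_list: frozenset[str] = POLE_PATHOGENIC_DEFAULT
    tmb_ultra_threshold: float = 100.0
    tmb_hyper_threshold: float = 10.0
    msi_novel_length_tau: float = 0.10
    baseline_support_floor: float = 0.01
    msi_h_locus_fraction: float = 0.30
    msi_l_locus_fraction: float = 0.10
    fga_log2_threshold: float = 0.3
    fga_cnh_threshold: float = 0.2
    cn_rule: str = "tp53_or_fga"
    panel_size_mb: float = 1.0
    per_gene_vaf_min: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.msi_l_locus_fraction < self.msi_h_locus_fraction <= 1:
            raise ConfigError(
                "require 0 < msi_l_locus_fraction < msi_h_locus_fraction <= 1"
            )
        for name in (
            "vaf_min", "tmb_ultra_threshold", "msi_novel_length_tau",
            "baseline_support_floor", "fga_log2_threshold", "fga_cnh_threshold",
            "panel_size_mb",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.tmb_hyper_threshold < 0:
            raise ConfigError("tmb_hyper_threshold must be >= 0")
        if self.cn_rule not in ("tp53_only", "tp53_or_fga"):
            raise ConfigError(f"unknown cn_rule {self.cn_rule!r}")
        object.__setattr__(self, "pole_pathogenic_list", frozenset(self.pole_pathogenic_list))

    def to_json(self) -> str:
        d = {k: (sorted(v) if isinstance(v, frozenset) else v) for k, v in vars(self).items()}
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CallerConfig":
        return cls(**json.loads(text))

    def with_overrides(self, **kwargs) -> "CallerConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class MarkerProfile:
    """Derived markers for one sample; ``msi_status`` is None when the MSI
    layer was not evaluable."""

    pole_positive: bool
    tp53_mutated: bool
    tmb: float
    msi_status: str | None
    fga: float

    def __post_init__(self) -> None:
        if self.tmb < 0:
            raise ValueError("tmb must be >= 0")
        if not 0.0 <= self.fga <= 1.0:
            raise ValueError("fga must be in [0, 1]")
        if self.msi_status not in (None, "MSI-H", "MSI-L", "MSS"):
            raise ValueError(f"bad msi_status {self.msi_status!r}")


def _passes_vaf(v: Variant, config: CallerConfig) -> bool:
    return v.vaf >= config.per_gene_vaf_min.get(v.gene, config.vaf_min)


def filter_variants(variants: Iterable[Variant], config: CallerConfig) -> list[Variant]:
    """Apply the panel's VAF sensitivity filter (per-gene overridable)."""
    return [v for v in variants if _passes_vaf(v, config)]


def compute_tmb(variants: Iterable[Variant], config: CallerConfig) -> float:
    """Nonsynonymous variants passing the VAF filter, per Mb of panel."""
    if config.panel_size_mb <= 0:
        raise ConfigError("panel_size_mb must be > 0")
    n = sum(
        1
        for v in variants
        if v.consequence in NONSYNONYMOUS and _passes_vaf(v, config)
    )
    return n / config.panel_size_mb


_RESIDUE_RE = re.compile(r"^p\.[A-Za-z*]{1,3}(\d+)")


def _protein_residue(hgvs_p: str) -> int | None:
    m = _RESIDUE_RE.match(hgvs_p)
    return int(m.group(1)) if m else None


def _in_edm(v: Variant) -> bool:
    residue = _protein_residue(v.hgvs_p)
    return residue is not None and POLE_EDM_RANGE[0] <= residue <= POLE_EDM_RANGE[1]


def assess_pole(variants: Iterable[Variant], tmb: float, config: CallerConfig) -> bool:
    """Pathogenic-POLE call.

    True when a POLE variant's protein change is on the pathogenic hotspot
    list, or when a nonsynonymous POLE exonuclease-domain variant co-occurs
    with ultramutation (tmb >= tmb_ultra_threshold).
    """
    for v in filter_variants(variants, config):
        if v.gene != "POLE":
            continue
        if v.hgvs_p in config.pole_pathogenic_list:
            return True
        if v.consequence in NONSYNONYMOUS and _in_edm(v) and tmb >= config.tmb_ultra_threshold:
            return True
    return False


def assess_tp53(variants: Iterable[Variant], config: CallerConfig) -> bool:
    """True iff a protein-altering TP53 variant passes the VAF filter."""
    return any(
        v.gene == "TP53" and v.consequence in NONSYNONYMOUS
        for v in filter_variants(variants, config)
    )


def score_locus_instability(locus: MicrosatelliteLocus, config: CallerConfig) -> bool:
    """Per-locus instability from the novel-length read fraction.

    ``novel_fraction`` is the share of tumor reads at repeat lengths whose
    baseline probability is below ``baseline_support_floor``; the locus is
    unstable when it strictly exceeds ``msi_novel_length_tau``.
    """
    total = locus.total_reads
    if total <= 0:
        raise NotEvaluableError(f"locus {locus.locus_id} has no observed reads")
    novel = sum(
        count
        for length, count in locus.observed_hist.items()
        if locus.baseline_hist.get(length, 0.0) < config.baseline_support_floor
    )
    return novel / total > config.msi_novel_length_tau


def call_msi(
    loci: Sequence[MicrosatelliteLocus], tmb: float, config: CallerConfig
) -> str:
    """Sample-level MSI status from per-locus calls.

    MSI-H requires both an unstable-locus fraction >= msi_h_locus_fraction
    and hypermutation (tmb >= tmb_hyper_threshold); MSI-L requires the
    fraction >= msi_l_locus_fraction; otherwise MSS.  Loci with zero reads
    are skipped (with a warning) and excluded from the denominator.
    """
    unstable = 0
    scoreable = 0
    for locus in loci:
        try:
            is_unstable = score_locus_instability(locus, config)
        except NotEvaluableError:
            logger.warning("skipping MSI locus %s: no observed reads", locus.locus_id)
            continue
        scoreable += 1
        unstable += is_unstable
    if scoreable == 0:
        raise NotEvaluableError("MSI not evaluable: no scoreable locus")
    fraction = unstable / scoreable
    if fraction >= config.msi_h_locus_fraction and tmb >= config.tmb_hyper_threshold:
        return "MSI-H"
    if fraction >= config.msi_l_locus_fraction:
        return "MSI-L"
    return "MSS"


def compute_fga(segments: Sequence[CNSegment], config: CallerConfig) -> float:
    """Length-weighted fraction of covered bases in altered segments.

    A segment is altered when |log2_ratio| > fga_log2_threshold (strict).
    Returns 0.0 when the sample has no segments.
    """
    covered = sum(seg.length for seg in segments)
    if covered == 0:
        return 0.0
    altered = sum(
        seg.length for seg in segments if abs(seg.log2_ratio) > config.fga_log2_threshold
    )
    return altered / covered


def classify_cn(tp53_mutated: bool, fga: float, config: CallerConfig) -> str:
    """Copy-number branch: CNH vs CNL.

    The published in-house copy-number algorithm behind the panel is not
    public; this surrogate is TP53-driven (CNH is the TP53-mutant,
    serous-like group) with an optional FGA clause under the default
    ``tp53_or_fga`` rule.
    """
    if config.cn_rule == "tp53_only":
        return "CNH" if tp53_mutated else "CNL"
    return "CNH" if (tp53_mutated or fga >= config.fga_cnh_threshold) else "CNL"


def build_profile(
    variants: Iterable[Variant],
    loci: Sequence[MicrosatelliteLocus],
    segments: Sequence[CNSegment],
    config: CallerConfig,
) -> MarkerProfile:
    """Derive the full marker profile for one sample.

    ``msi_status`` is left as None (rather than raising) when no locus is
    scoreable, so the caller can mark the sample unclassifiable.
    """
    variants = list(variants)
    tmb = compute_tmb(variants, config)
    pole = assess_pole(variants, tmb, config)
    tp53 = assess_tp53(variants, config)
    try:
        msi = call_msi(loci, tmb, config)
    except NotEvaluableError:
        msi = None
    fga = compute_fga(segments, config)
    return MarkerProfile(
        pole_positive=pole, tp53_mutated=tp53, tmb=tmb, msi_status=msi, fga=fga
    )
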