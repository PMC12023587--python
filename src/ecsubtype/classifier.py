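"""Hierarchical molecular subtype assignment.

The classifier applies a strict three-step precedence to each sample's
marker profile:

1. **POLE** — a pathogenic POLE variant (including ultramutated status)
   wins outright, regardless of MSI or TP53 status.
2. **MSI-H** — hypermutated microsatellite-unstable samples.
3. **CNH / CNL** — everything else (MSI-L and MSS are treated alike) is
   split by the copy-number rule.

A sample whose markers cannot all be evaluated (a missing molecular layer,
no scoreable MSI locus) is reported as UNCLASSIFIABLE instead of raising.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

from .markers import CallerConfig, MarkerProfile, build_profile, classify_cn
from .model import Cohort

logger = logging.getLogger(__name__)

__all__ = ["Subtype", "classify_sample", "classify_cohort", "classification_frame"]


class Subtype(str, enum.Enum):
    POLE = "POLE"
    MSI_H = "MSI-H"
    CNH = "CNH"
    CNL = "CNL"
    UNCLASSIFIABLE = "unclassifiable"


def classify_sample(profile: MarkerProfile, config: CallerConfig | None = None) -> Subtype:
    """Assign one subtype by strict precedence POLE > MSI-H > CN branch."""
    config = config or CallerConfig()
    if profile.pole_positive:
        return Subtype.POLE
    if profile.msi_status is None:
        return Subtype.UNCLASSIFIABLE
    if profile.msi_status == "MSI-H":
        return Subtype.MSI_H
    # MSI-L and MSS both proceed to the copy-number branch
    return Subtype(classify_cn(profile.tp53_mutated, profile.fga, config))


def classify_cohort(
    cohort: Cohort, config: CallerConfig | None = None
) -> dict[str, Subtype]:
    """Marker derivation plus hierarchical assignment for every sample.

    Deterministic given the cohort and config.  Per-sample evaluability
    problems surface as UNCLASSIFIABLE with a logged reason, never as an
    exception that aborts the cohort.
    """
    config = config or CallerConfig()
    out: dict[str, Subtype] = {}
    for sample in cohort:
        profile = build_profile(sample.variants, sample.msi_loci, sample.segments, config)
        # A pathogenic POLE variant classifies the sample even when a lower-
        # precedence layer is missing; otherwise missing layers block the call.
        if not profile.pole_positive and sample.missing_layers & {"msi", "segments"}:
            logger.info(
                "sample %s unclassifiable: missing layers %s",
                sample.sample_id, sorted(sample.missing_layers),
            )
            out[sample.sample_id] = Subtype.UNCLASSIFIABLE
            continue
        label = classify_sample(profile, config)
        if label is Subtype.UNCLASSIFIABLE:
            logger.info("sample %s unclassifiable: MSI not evaluable", sample.sample_id)
        out[sample.sample_id] = label
    return out


def classification_frame(cohort: Cohort, config: CallerConfig | None = None):
    """Per-sample classification table (for the TSV export).

    Columns: sample_id, subtype, pole_positive, msi_status, tp53_mutated,
    tmb, fga.
    """
    import pandas as pd

    config = config or CallerConfig()
    rows = []
    labels = classify_cohort(cohort, config)
    for sample in cohort:
        p = build_profile(sample.variants, sample.msi_loci, sample.segments, config)
        rows.append(
            {
                "sample_id": sample.sample_id,
                "subtype": labels[sample.sample_id].value,
                "pole_positive": p.pole_positive,
                "msi_status": p.msi_status if p.msi_status is not None else "",
                "tp53_mutated": p.tp53_mutated,
                "tmb": p.tmb,
                "fga": p.fga,
            }
        )
    return pd.DataFrame(rows)
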