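"""Exact reference cohorts rebuilt from the study's printed tables.

Two fixtures are constructed programmatically (no data files):

* ``table1`` — the 233-sample typing cohort.  Subtype labels and every
  clinicopathological cross-tab cell (stage, LVSI, histology, grade)
  match the printed characteristics table exactly; each sample also
  carries a minimal molecular layer set so that rerunning the classifier
  reproduces the pre-assigned labels (19 POLE / 44 MSI-H / 27 CNH /
  143 CNL).
* ``fig4`` — the 39 CNL/MSI-H samples sent for wide-panel sequencing.
  The deceased/surviving split (13/26) and per-group ARID1A and ZFHX4
  mutation counts (7/8 and 4/0) are the unique integer composition
  consistent with the printed one-decimal percentages (53.8% vs 30.8%;
  30.8% vs 0%) and with all four ZFHX4 mutations occurring in deceased
  cases.

Ages and survival times are not printed per patient; they are filled in
deterministically (fixed internal seed) with the reported group-level
structure and are synthetic in that sense.
"""

from __future__ import annotations

import math

import numpy as np

from .model import (
    ClinicalRecord,
    CNSegment,
    Cohort,
    Consequence,
    MicrosatelliteLocus,
    Sample,
    Variant,
)
from .simulate import _make_locus

__all__ = ["load_fixture", "TABLE1_COUNTS", "FIG4_COMPOSITION"]

#: per-subtype stratum counts from the printed characteristics table;
#: order of subtype columns: POLE, MSI-H, CNH, CNL
TABLE1_COUNTS = {
    "n": {"POLE": 19, "MSI-H": 44, "CNH": 27, "CNL": 143},
    "stage": {
        "I": (16, 26, 12, 103),
        "II": (0, 6, 3, 8),
        "III": (2, 6, 8, 18),
        "IV": (0, 0, 1, 2),
        "unknown": (1, 6, 3, 12),
    },
    "lvsi": {
        "no": (13, 33, 18, 109),
        "yes": (2, 1, 5, 5),
        "unknown": (4, 10, 4, 29),
    },
    "histology": {
        "endometrioid": (15, 34, 15, 119),
        "mucinous": (0, 2, 0, 0),
        "serous": (2, 0, 6, 3),
        "other": (0, 2, 4, 1),
        "unknown": (2, 6, 2, 20),
    },
    "grade": {
        "G1": (9, 12, 4, 72),
        "G2": (2, 13, 5, 35),
        "G3": (6, 11, 14, 14),
        "undifferentiated": (0, 1, 1, 1),
        "unknown": (2, 7, 3, 21),
    },
}

_SUBTYPE_ORDER = ("POLE", "MSI-H", "CNH", "CNL")

#: unique integer composition of the 39-sample wide-panel subset
FIG4_COMPOSITION = {
    "n": 39,
    "n_deceased": 13,
    "n_surviving": 26,
    "arid1a_deceased": 7,
    "arid1a_surviving": 8,
    "zfhx4_deceased": 4,
    "zfhx4_surviving": 0,
    # of the 4 ZFHX4 mutations, 3 in MSI-H and 1 in CNL tumors
    "subtype_counts": {"CNL": 27, "MSI-H": 12},
}

_AGE_RANGE = {
    "POLE": (53.65, 10.21, 30, 68),
    "MSI-H": (56.32, 8.93, 36, 75),
    "CNH": (59.33, 10.88, 39, 84),
    "CNL": (53.63, 9.62, 31, 76),
}


def _expand(level_counts: dict[str, tuple[int, int, int, int]], col: int) -> list[str]:
    out: list[str] = []
    for level, counts in level_counts.items():
        out.extend([level] * counts[col])
    return out


def _stable_loci(rng: np.random.Generator, n: int = 5) -> list[MicrosatelliteLocus]:
    return [_make_locus(j, False, 100, rng) for j in range(n)]


def _unstable_loci(rng: np.random.Generator, n_unstable: int = 2, n: int = 5):
    return [_make_locus(j, j < n_unstable, 100, rng) for j in range(n)]


def _neutral_segments() -> list[CNSegment]:
    return [CNSegment(chrom="chr1", start=0, end=2_000_000, log2_ratio=0.0)]


def _variant(gene: str, hgvs_p: str, vaf: float, pos: int) -> Variant:
    return Variant(
        chrom="chr17" if gene == "TP53" else "chr12",
        pos=pos, ref="C", alt="T", gene=gene, hgvs_p=hgvs_p,
        consequence=Consequence.MISSENSE, vaf=vaf,
    )


def _molecular_layers(subtype: str, rng: np.random.Generator):
    """Minimal marker-consistent layers for a pre-assigned subtype label."""
    if subtype == "POLE":
        variants = [_variant("POLE", "p.P286R", 0.3, 132_673_702)]
        loci = _stable_loci(rng)
    elif subtype == "MSI-H":
        # hypermutated (12 mut/Mb on a 1 Mb panel) with 2/5 unstable loci
        variants = [
            _variant("PTEN", f"p.X{k}X", 0.2, 89_000_000 + k) for k in range(12)
        ]
        loci = _unstable_loci(rng)
    elif subtype == "CNH":
        variants = [_variant("TP53", "p.R273H", 0.4, 7_577_120)]
        loci = _stable_loci(rng)
    else:  # CNL
        variants = [_variant("PTEN", "p.R130G", 0.25, 89_692_904)]
        loci = _stable_loci(rng)
    return variants, loci, _neutral_segments()


def _table1_cohort() -> Cohort:
    rng = np.random.default_rng(20170233)  # fixed: the fixture is a constant
    samples: list[Sample] = []
    truth: dict[str, str] = {}
    counter = 0

    # survival layer: OS known for 131 of 233 patients, DSS for 126 of the
    # 131; assigned deterministically below, CNH markedly worse
    os_rates = {"POLE": 8.4e-5, "MSI-H": 1.9e-3, "CNH": math.log(2) / 35, "CNL": 1.4e-3}
    os_idx = rng.choice(233, size=131, replace=False)
    has_os_mask = np.zeros(233, dtype=bool)
    has_os_mask[os_idx] = True
    dss_idx = rng.choice(os_idx, size=126, replace=False)
    has_dss_mask = np.zeros(233, dtype=bool)
    has_dss_mask[dss_idx] = True

    for col, subtype in enumerate(_SUBTYPE_ORDER):
        n_sub = TABLE1_COUNTS["n"][subtype]
        stages = _expand(TABLE1_COUNTS["stage"], col)
        lvsis = _expand(TABLE1_COUNTS["lvsi"], col)
        histologies = _expand(TABLE1_COUNTS["histology"], col)
        grades = _expand(TABLE1_COUNTS["grade"], col)
        assert len(stages) == len(lvsis) == len(histologies) == len(grades) == n_sub
        mean, sd, lo, hi = _AGE_RANGE[subtype]
        for j in range(n_sub):
            counter += 1
            sid = f"T{counter:03d}"
            truth[sid] = subtype
            variants, loci, segments = _molecular_layers(subtype, rng)
            age = float(np.clip(round(rng.normal(mean, sd)), lo, hi))

            os_months = os_event = dss_months = dss_event = None
            vital = "unknown"
            if has_os_mask[counter - 1]:
                t_event = float(rng.exponential(1.0 / os_rates[subtype]))
                t_censor = float(rng.uniform(7.0, 122.0))
                os_event = int(t_event <= t_censor)
                os_months = round(min(t_event, t_censor), 1)
                vital = "deceased" if os_event else "alive"
                if has_dss_mask[counter - 1]:
                    dss_months = os_months
                    dss_event = os_event
            clinical = ClinicalRecord(
                sample_id=sid, age=age, stage=stages[j], grade=grades[j],
                histology=histologies[j], lvsi=lvsis[j],
                os_months=os_months, os_event=os_event,
                dss_months=dss_months, dss_event=dss_event, vital_status=vital,
            )
            samples.append(
                Sample(sample_id=sid, variants=variants, msi_loci=loci,
                       segments=segments, clinical=clinical)
            )
    return Cohort(samples=samples, truth_labels=truth)


def _fig4_cohort() -> Cohort:
    rng = np.random.default_rng(4039)
    comp = FIG4_COMPOSITION
    samples: list[Sample] = []
    truth: dict[str, str] = {}

    # deceased block first (13), then surviving (26); within each block
    # MSI-H first.  ZFHX4: 3 of the deceased MSI-H, 1 deceased CNL.
    roster: list[tuple[str, str]] = (
        [("deceased", "MSI-H")] * 5 + [("deceased", "CNL")] * 8
        + [("surviving", "MSI-H")] * 7 + [("surviving", "CNL")] * 19
    )
    zfhx4_ids = {1, 2, 3, 6}  # 3 MSI-H + 1 CNL, all deceased
    # ARID1A spread over both subtypes: deceased 3 MSI-H + 4 CNL,
    # surviving 3 MSI-H + 5 CNL (marginals 7/13 and 8/26 as printed)
    arid1a_ids = {1, 2, 3, 6, 7, 8, 9, 14, 15, 16, 21, 22, 23, 24, 25}

    for k, (vital, subtype) in enumerate(roster, start=1):
        sid = f"F{k:03d}"
        truth[sid] = subtype
        deceased = vital == "deceased"
        arid1a = int(k in arid1a_ids)
        zfhx4 = int(k in zfhx4_ids)
        gene_mutations = {
            "ARID1A": arid1a, "ZFHX4": zfhx4,
            "PTEN": int(rng.random() < 0.6), "PIK3CA": int(rng.random() < 0.4),
            "PIK3R1": int(rng.random() < 0.25), "CTNNB1": int(rng.random() < 0.25),
            "CTCF": int(rng.random() < 0.2), "KRAS": int(rng.random() < 0.2),
            "KMT2C": int(rng.random() < 0.3), "KMT2D": int(rng.random() < 0.3),
        }
        if deceased:
            os_months = round(float(rng.uniform(7.0, 60.0)), 1)
            os_event = 1
        else:
            os_months = round(float(rng.uniform(60.0, 122.0)), 1)
            os_event = 0
        variants, loci, segments = _molecular_layers(subtype, rng)
        clinical = ClinicalRecord(
            sample_id=sid,
            age=float(np.clip(round(rng.normal(56.5, 8.9)), 31, 75)),
            stage="I", grade="G2", histology="endometrioid", lvsi="no",
            os_months=os_months, os_event=os_event,
            dss_months=os_months, dss_event=os_event,
            vital_status="deceased" if deceased else "alive",
        )
        samples.append(
            Sample(sample_id=sid, variants=variants, msi_loci=loci,
                   segments=segments, clinical=clinical,
                   gene_mutations=gene_mutations)
        )
    return Cohort(samples=samples, truth_labels=truth)


def load_fixture(name: str) -> Cohort:
    """Build one of the packaged reference cohorts: 'table1' or 'fig4'."""
    if name == "table1":
        return _table1_cohort()
    if name == "fig4":
        return _fig4_cohort()
    raise KeyError(f"unknown fixture {name!r}; available: table1, fig4")
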