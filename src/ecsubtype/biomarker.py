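"""Biomarker sub-stratification of the CNL and MSI-H groups.

The copy-number-low and microsatellite-unstable tumors are prognostically
heterogeneous; this module builds a binary sample x gene mutation matrix
from the wide-panel results, compares per-gene mutation frequencies
between deceased and surviving patients, and stratifies survival within a
chosen subset (e.g. CNL+MSI-H, or TP53-wild-type/CNL only) by the
mutation status of a single gene such as ARID1A or ZFHX4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .markers import CallerConfig, filter_variants
from .model import NONSYNONYMOUS, Cohort
from .survival import LogRankResult, SurvivalCurve, km_estimate, logrank_test

__all__ = [
    "MutationMatrix",
    "default_gene_sets",
    "build_mutation_matrix",
    "mutation_frequencies_by_outcome",
    "km_by_mutation",
    "waterfall_long_table",
]


def default_gene_sets() -> dict[str, list[str]]:
    """Shipped gene groups (mTOR pathway, SWI/SNF, H3K4 methyltransferase);
    editable JSON under ``ecsubtype/data/gene_sets.json``."""
    text = resources.files("ecsubtype").joinpath("data/gene_sets.json").read_text()
    return json.loads(text)


@dataclass
class MutationMatrix:
    """Binary samples x genes matrix with optional named gene groups."""

    matrix: pd.DataFrame
    gene_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        values = self.matrix.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("mutation matrix entries must be 0/1")
        for name, genes in self.gene_sets.items():
            missing = set(genes) - set(self.matrix.columns)
            if missing:
                raise ValueError(f"gene set {name!r} references absent genes {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.columns)


def build_mutation_matrix(
    cohort: Cohort,
    genes: Sequence[str] | None = None,
    config: CallerConfig | None = None,
    gene_sets: Mapping[str, Sequence[str]] | None = None,
) -> MutationMatrix:
    """Sample x gene 0/1 matrix from the cohort.

    A sample's explicit ``gene_mutations`` map (wide-panel results) takes
    precedence; otherwise a gene counts as mutated when any nonsynonymous
    variant passes the VAF filter (per-gene VAF overrides honor the
    panel's higher hotspot sensitivity).
    """
    config = config or CallerConfig()
    if genes is None:
        pool: set[str] = set()
        for s in cohort:
            if s.gene_mutations:
                pool.update(s.gene_mutations)
            pool.update(v.gene for v in s.variants if v.gene)
        genes = sorted(pool)
    genes = list(genes)

    rows = {}
    for s in cohort:
        row = dict.fromkeys(genes, 0)
        if s.gene_mutations is not None:
            for g, flag in s.gene_mutations.items():
                if g in row:
                    row[g] = int(bool(flag))
        else:
            for v in filter_variants(s.variants, config):
                if v.gene in row and v.consequence in NONSYNONYMOUS:
                    row[v.gene] = 1
        rows[s.sample_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")[genes]
    sets = {k: list(v) for k, v in (gene_sets or {}).items()}
    sets = {k: v for k, v in sets.items() if set(v) <= set(genes)}
    return MutationMatrix(matrix=matrix, gene_sets=sets)


def mutation_frequencies_by_outcome(
    mm: MutationMatrix, vital_status: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene mutated fraction among deceased and among surviving cases.

    Returns a DataFrame indexed by gene with columns ``freq_deceased`` and
    ``freq_surviving`` as one-decimal percentages, plus the raw counts.
    A stratum with no samples yields NaN frequencies.
    """
    status = pd.Series(dict(vital_status)).reindex(mm.matrix.index)
    if status.isna().any() or (status == "unknown").any():
        bad = list(status.index[status.isna() | (status == "unknown")])
        raise ValueError(f"vital status unknown for samples: {bad}")

    out = {}
    for stratum, name in (("deceased", "deceased"), ("alive", "surviving")):
        sub = mm.matrix.loc[status == stratum]
        n = len(sub)
        counts = sub.sum(axis=0)
        freqs = (
            counts.map(lambda c: round_half_up(100.0 * c / n, 1)) if n else np.nan
        )
        out[f"n_mutated_{name}"] = counts
        out[f"freq_{name}"] = freqs
        out[f"n_{name}"] = n
    return pd.DataFrame(out, index=mm.matrix.columns)


@dataclass
class MutationSurvivalResult:
    """KM curves and log-rank comparison for mutant vs wild-type, with an
    explicit accounting of which samples entered each arm."""

    curve_mutant: SurvivalCurve
    curve_wildtype: SurvivalCurve
    logrank: LogRankResult
    mutant_ids: list[str]
    wildtype_ids: list[str]


def km_by_mutation(
    cohort: Cohort,
    mm: MutationMatrix,
    gene: str,
    subset_ids: Sequence[str] | None = None,
    endpoint: str = "os",
) -> MutationSurvivalResult:
    """Survival split by mutation status of ``gene`` within ``subset_ids``.

    Only samples in the subset with observed time-to-event data are used;
    an empty mutant or wild-type arm is an error naming the arm.
    """
    if gene not in mm.matrix.columns:
        raise KeyError(f"gene {gene!r} not in mutation matrix")
    if endpoint not in ("os", "dss"):
        raise ValueError("endpoint must be 'os' or 'dss'")
    subset = list(subset_ids) if subset_ids is not None else list(mm.matrix.index)
    if not subset:
        raise ValueError("empty sample subset")

    times, events, flags, ids = [], [], [], []
    for sid in subset:
        sample = cohort[sid]
        c = sample.clinical
        t = getattr(c, f"{endpoint}_months", None) if c else None
        e = getattr(c, f"{endpoint}_event", None) if c else None
        if t is None or e is None:
            continue
        times.append(float(t))
        events.append(int(e))
        flags.append(int(mm.matrix.loc[sid, gene]))
        ids.append(sid)

    flags_arr = np.array(flags)
    times_arr = np.array(times)
    events_arr = np.array(events)
    mut_ids = [sid for sid, f in zip(ids, flags) if f == 1]
    wt_ids = [sid for sid, f in zip(ids, flags) if f == 0]
    if not mut_ids:
        raise ValueError(f"mutant arm for {gene} is empty within the subset")
    if not wt_ids:
        raise ValueError(f"wild-type arm for {gene} is empty within the subset")

    curve_mut = km_estimate(times_arr[flags_arr == 1], events_arr[flags_arr == 1])
    curve_wt = km_estimate(times_arr[flags_arr == 0], events_arr[flags_arr == 0])
    lr = logrank_test(times_arr, events_arr, flags_arr)
    return MutationSurvivalResult(
        curve_mutant=curve_mut,
        curve_wildtype=curve_wt,
        logrank=lr,
        mutant_ids=mut_ids,
        wildtype_ids=wt_ids,
    )


def waterfall_long_table(
    mm: MutationMatrix,
    vital_status: Mapping[str, str],
    subtype_labels: Mapping[str, str],
) -> pd.DataFrame:
    """Long-format export (sample_id, gene, mutated, vital_status, subtype)
    for external waterfall/oncoprint plotting."""
    rows = []
    for sid in mm.matrix.index:
        for gene in mm.matrix.columns:
            rows.append(
                {
                    "sample_id": sid,
                    "gene": gene,
                    "mutated": int(mm.matrix.loc[sid, gene]),
                    "vital_status": vital_status.get(sid, "unknown"),
                    "subtype": subtype_labels.get(sid, "unknown"),
                }
            )
    return pd.DataFrame(rows)
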