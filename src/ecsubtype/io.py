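"""Readers and writers for the on-disk cohort layers.

All tabular layers are plain TSV.  Variants may alternatively come from a
VCF v4.x file (read via :mod:`cyvcf2`), with the VAF taken from ``INFO/AF``
or derived from ``FORMAT/AD``; gene annotation is read from the optional
``INFO`` keys ``GENE``, ``HGVSP`` and ``CSQ``.

Documented headers (tab-separated, one header row):

=================  ==========================================================
layer              columns
=================  ==========================================================
variants           sample_id chrom pos ref alt gene hgvs_p consequence vaf
msi                sample_id locus_id repeat_unit length baseline_prob
                   observed_count  (long format, one row per repeat length)
segments           sample_id chrom start end log2_ratio
clinical           sample_id age stage grade histology lvsi os_months
                   os_event dss_months dss_event vital_status
gene_mutations     sample_id gene mutated
=================  ==========================================================
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Mapping

import pandas as pd

from .model import (
    ClinicalRecord,
    CNSegment,
    Cohort,
    Consequence,
    FormatError,
    IntegrityError,
    MicrosatelliteLocus,
    Sample,
    Variant,
)

VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "gene", "hgvs_p", "consequence", "vaf"]
MSI_COLUMNS = ["sample_id", "locus_id", "repeat_unit", "length", "baseline_prob", "observed_count"]
SEGMENT_COLUMNS = ["sample_id", "chrom", "start", "end", "log2_ratio"]
CLINICAL_COLUMNS = [
    "sample_id", "age", "stage", "grade", "histology", "lvsi",
    "os_months", "os_event", "dss_months", "dss_event", "vital_status",
]
GENE_MUTATION_COLUMNS = ["sample_id", "gene", "mutated"]


def _read_tsv(path: str | os.PathLike, expected: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}, line 1: header {list(df.columns)} does not match expected {expected}"
        )
    return df


def _opt_float(s: str) -> float | None:
    return None if s == "" else float(s)


def _opt_int(s: str) -> int | None:
    return None if s == "" else int(float(s))


def read_variants_tsv(path: str | os.PathLike) -> dict[str, list[Variant]]:
    df = _read_tsv(path, VARIANT_COLUMNS)
    out: dict[str, list[Variant]] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            v = Variant(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                gene=row.gene,
                hgvs_p=row.hgvs_p,
                consequence=Consequence(row.consequence),
                vaf=float(row.vaf),
            )
        except ValueError as exc:
            raise type(exc)(f"{path}, line {i}: {exc}") from None
        out.setdefault(row.sample_id, []).append(v)
    return out


def read_variants_vcf(path: str | os.PathLike) -> dict[str, list[Variant]]:
    """Read per-sample variants from a (possibly multi-sample) VCF.

    A variant is attributed to every sample whose genotype carries the
    alternate allele.  VAF comes from FORMAT/AD (alt / total) when present,
    otherwise from INFO/AF, shared across carrier samples.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_names = list(vcf.samples)
    out: dict[str, list[Variant]] = {sid: [] for sid in sample_names}
    for rec in vcf:
        gene = rec.INFO.get("GENE") or ""
        hgvs_p = rec.INFO.get("HGVSP") or ""
        csq = rec.INFO.get("CSQ") or "other"
        try:
            consequence = Consequence(csq)
        except ValueError:
            consequence = Consequence.OTHER
        info_af = rec.INFO.get("AF")
        ad = rec.format("AD")  # None if FORMAT/AD absent
        for si, sid in enumerate(sample_names):
            gt = rec.genotypes[si][:-1] if rec.genotypes else [1]
            if sample_names and not any(a == 1 for a in gt):
                continue
            if ad is not None:
                ref_n, alt_n = int(ad[si][0]), int(ad[si][1])
                total = ref_n + alt_n
                if total == 0:
                    continue
                vaf = alt_n / total
            elif info_af is not None:
                vaf = float(info_af)
            else:
                raise FormatError(f"{path}: record {rec.CHROM}:{rec.POS} has neither AF nor AD")
            out[sid].append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=rec.ALT[0],
                    gene=gene,
                    hgvs_p=hgvs_p,
                    consequence=consequence,
                    vaf=vaf,
                )
            )
    return out


def read_msi_tsv(path: str | os.PathLike) -> dict[str, list[MicrosatelliteLocus]]:
    df = _read_tsv(path, MSI_COLUMNS)
    out: dict[str, list[MicrosatelliteLocus]] = {}
    grouped = df.groupby(["sample_id", "locus_id"], sort=False)
    for (sid, locus_id), g in grouped:
        baseline = {}
        observed = {}
        unit = g["repeat_unit"].iloc[0]
        for row in g.itertuples(index=False):
            length = int(row.length)
            bp = float(row.baseline_prob)
            if bp > 0:
                baseline[length] = baseline.get(length, 0.0) + bp
            oc = int(float(row.observed_count))
            if oc != 0 or length in baseline:
                observed[length] = observed.get(length, 0) + oc
        locus = MicrosatelliteLocus(
            locus_id=locus_id, repeat_unit=unit, baseline_hist=baseline, observed_hist=observed
        )
        out.setdefault(sid, []).append(locus)
    return out


def read_segments_tsv(path: str | os.PathLike) -> dict[str, list[CNSegment]]:
    df = _read_tsv(path, SEGMENT_COLUMNS)
    out: dict[str, list[CNSegment]] = {}
    for row in df.itertuples(index=False):
        seg = CNSegment(
            chrom=row.chrom, start=int(row.start), end=int(row.end),
            log2_ratio=float(row.log2_ratio),
        )
        out.setdefault(row.sample_id, []).append(seg)
    return out


def read_clinical_tsv(path: str | os.PathLike) -> dict[str, ClinicalRecord]:
    df = _read_tsv(path, CLINICAL_COLUMNS)
    out: dict[str, ClinicalRecord] = {}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        if row.sample_id in out:
            raise IntegrityError(f"{path}, line {i}: duplicate sample_id {row.sample_id!r}")
        try:
            rec = ClinicalRecord(
                sample_id=row.sample_id,
                age=_opt_float(row.age),
                stage=row.stage or "unknown",
                grade=row.grade or "unknown",
                histology=row.histology or "unknown",
                lvsi=row.lvsi or "unknown",
                os_months=_opt_float(row.os_months),
                os_event=_opt_int(row.os_event),
                dss_months=_opt_float(row.dss_months),
                dss_event=_opt_int(row.dss_event),
                vital_status=row.vital_status or "unknown",
            )
        except ValueError as exc:
            raise type(exc)(f"{path}, line {i}: {exc}") from None
        out[row.sample_id] = rec
    return out


def read_gene_mutations_tsv(path: str | os.PathLike) -> dict[str, dict[str, int]]:
    df = _read_tsv(path, GENE_MUTATION_COLUMNS)
    out: dict[str, dict[str, int]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.sample_id, {})[row.gene] = int(row.mutated)
    return out


def load_cohort(
    variant_path: str | os.PathLike | None,
    msi_path: str | os.PathLike | None,
    segment_path: str | os.PathLike | None,
    clinical_path: str | os.PathLike,
    gene_mutation_path: str | os.PathLike | None = None,
) -> Cohort:
    """Join all layers on sample_id into a Cohort.

    The sample universe is the union of ids across the provided files.
    A sample missing a molecular layer keeps the layer empty and records
    it in ``Sample.missing_layers`` (downstream it becomes unclassifiable
    rather than being dropped).
    """
    if str(variant_path or "").endswith((".vcf", ".vcf.gz")):
        variants = read_variants_vcf(variant_path)
    elif variant_path is not None:
        variants = read_variants_tsv(variant_path)
    else:
        variants = {}
    msi = read_msi_tsv(msi_path) if msi_path is not None else {}
    segments = read_segments_tsv(segment_path) if segment_path is not None else {}
    clinical = read_clinical_tsv(clinical_path)
    gene_muts = read_gene_mutations_tsv(gene_mutation_path) if gene_mutation_path else {}

    ids: list[str] = []
    for source in (clinical, variants, msi, segments, gene_muts):
        for sid in source:
            if sid not in ids:
                ids.append(sid)

    samples = []
    for sid in ids:
        missing = {
            layer
            for layer, source in (
                ("variants", variants), ("msi", msi), ("segments", segments),
            )
            if sid not in source
        }
        samples.append(
            Sample(
                sample_id=sid,
                variants=variants.get(sid, []),
                msi_loci=msi.get(sid, []),
                segments=segments.get(sid, []),
                clinical=clinical.get(sid),
                gene_mutations=gene_muts.get(sid),
                missing_layers=frozenset(missing),
            )
        )
    return Cohort(samples=samples)


def _fmt(value) -> str:
    if value is None:
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write all TSV layers to ``out_dir``; returns layer -> path.

    Floats are serialized with ``repr`` so that a read back reproduces the
    in-memory values bit-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    var_rows = []
    msi_rows = []
    seg_rows = []
    clin_rows = []
    gm_rows = []
    for s in cohort:
        for v in s.variants:
            var_rows.append(
                [s.sample_id, v.chrom, v.pos, v.ref, v.alt, v.gene, v.hgvs_p,
                 v.consequence.value, _fmt(v.vaf)]
            )
        for loc in s.msi_loci:
            lengths = sorted(set(loc.baseline_hist) | set(loc.observed_hist))
            for length in lengths:
                msi_rows.append(
                    [s.sample_id, loc.locus_id, loc.repeat_unit, length,
                     _fmt(float(loc.baseline_hist.get(length, 0.0))),
                     int(loc.observed_hist.get(length, 0))]
                )
        for seg in s.segments:
            seg_rows.append([s.sample_id, seg.chrom, seg.start, seg.end, _fmt(seg.log2_ratio)])
        c = s.clinical or ClinicalRecord(sample_id=s.sample_id)
        clin_rows.append(
            [c.sample_id, _fmt(c.age), c.stage, c.grade, c.histology, c.lvsi,
             _fmt(c.os_months), _fmt(c.os_event), _fmt(c.dss_months), _fmt(c.dss_event),
             c.vital_status]
        )
        if s.gene_mutations is not None:
            for gene in sorted(s.gene_mutations):
                gm_rows.append([s.sample_id, gene, s.gene_mutations[gene]])

    def _dump(name: str, columns: list[str], rows: list[list]) -> Path:
        path = out / f"{name}.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    paths["variants"] = _dump("variants", VARIANT_COLUMNS, var_rows)
    paths["msi"] = _dump("msi", MSI_COLUMNS, msi_rows)
    paths["segments"] = _dump("segments", SEGMENT_COLUMNS, seg_rows)
    paths["clinical"] = _dump("clinical", CLINICAL_COLUMNS, clin_rows)
    if gm_rows:
        paths["gene_mutations"] = _dump("gene_mutations", GENE_MUTATION_COLUMNS, gm_rows)
    if cohort.truth_labels is not None:
        path = out / "truth_labels.tsv"
        pd.DataFrame(
            [[sid, cohort.truth_labels[sid]] for sid in cohort.sample_ids],
            columns=["sample_id", "subtype"],
        ).to_csv(path, sep="\t", index=False)
        paths["truth_labels"] = path
    return paths
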