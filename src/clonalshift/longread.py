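"""Targeted long-read JAK2 haplotype and V617F mutation calling.

Works on per-read allele observations over three germline SNPs tagging the
46/1 risk haplotype (rs3780367, rs10974944, rs12343867) plus the somatic
V617F site (GRCh38 chr9:5,073,770).  The calling procedure is:

1. tabulate 4-site haplotypes with exact counts and frequencies;
2. remove haplotypes with frequency strictly below 1% of the sample's reads
   (frequencies are *not* renormalised afterwards; counts are preserved);
3. QC: fail on total reads < 1000, more than two distinct germline
   (3-SNP) backgrounds after filtering, or mutant haplotypes on both
   backgrounds (biallelic mutation is flagged, not silently dropped);
4. call 46/1 carriership (any background == GGC), the mutation's background
   haplotype, its allelic fraction (mutant reads on that background divided
   by all reads on that background), and cis/trans phase for samples
   heterozygous 46/1 / non-46/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import RISK_HAPLOTYPE

QC_PASS = "pass"
QC_LOW_DEPTH = "fail_low_depth"
QC_MANY_HAPS = "fail_many_germline_haps"
QC_BIALLELIC = "fail_biallelic_mutation"


@dataclass
class HaplotypeTable:
    """Counts of distinct (germline background, somatic state) haplotypes.

    ``df`` columns: background (3-SNP string), somatic ('ref'/'mut'),
    count, frequency.  ``total_reads`` is the pre-filter read count; the <1%
    filter keeps frequencies on that denominator.
    """

    df: pd.DataFrame
    total_reads: int


@dataclass
class SampleCall:
    sample_id: str
    qc_status: str
    germline_haps: tuple[str, ...]
    carrier_46_1: bool
    v617f_present: bool
    v617f_background: str | None = None
    v617f_af: float | None = None
    phase: str | None = None  # cis | trans | uninformative
    notes: list[str] = field(default_factory=list)


def build_haplotype_table(reads: pd.DataFrame) -> HaplotypeTable:
    """Exact haplotype counts from a per-read allele table.

    ``reads`` needs columns a1, a2, a3 (germline alleles) and v617f
    ('ref'/'mut').  Row order never affects the result.
    """
    if len(reads) == 0:
        raise ValueError("no reads supplied")
    background = reads["a1"].astype(str) + reads["a2"].astype(str) + reads["a3"].astype(str)
    counts = (
        pd.DataFrame({"background": background, "somatic": reads["v617f"].astype(str)})
        .groupby(["background", "somatic"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["background", "somatic"], ignore_index=True)
    )
    total = int(counts["count"].sum())
    counts["frequency"] = counts["count"] / total
    return HaplotypeTable(df=counts, total_reads=total)


def filter_rare(table: HaplotypeTable, min_freq: float = 0.01) -> HaplotypeTable:
    """Drop haplotype rows with frequency strictly below ``min_freq``.

    A haplotype at exactly the threshold is retained.  Frequencies keep the
    original total-read denominator.
    """
    kept = table.df[table.df["frequency"] >= min_freq].reset_index(drop=True)
    if len(kept) == 0:
        raise ValueError("rare-haplotype filter removed every haplotype")
    return HaplotypeTable(df=kept, total_reads=table.total_reads)


def qc_sample(table: HaplotypeTable, min_reads: int = 1000) -> str:
    """QC status of a filtered haplotype table."""
    if table.total_reads < min_reads:
        return QC_LOW_DEPTH
    backgrounds = table.df["background"].unique()
    if len(backgrounds) > 2:
        return QC_MANY_HAPS
    mutant_backgrounds = table.df.loc[table.df["somatic"] == "mut", "background"].unique()
    if len(mutant_backgrounds) > 1:
        return QC_BIALLELIC
    return QC_PASS


def call_sample(
    table: HaplotypeTable,
    sample_id: str = "",
    min_reads: int = 1000,
    allow_qc_fail: bool = False,
) -> SampleCall:
    """Carriership, mutation background, allelic fraction, and phase.

    By default a QC-failing sample gets a call carrying only its status;
    ``allow_qc_fail`` forces a best-effort call with the failure recorded.
    """
    status = qc_sample(table, min_reads=min_reads)
    notes: list[str] = []
    if status != QC_PASS:
        if not allow_qc_fail:
            return SampleCall(
                sample_id=sample_id,
                qc_status=status,
                germline_haps=tuple(sorted(table.df["background"].unique())),
                carrier_46_1=False,
                v617f_present=False,
            )
        notes.append(f"called despite {status}")

    per_bg = table.df.groupby("background")["count"].sum().sort_values(ascending=False)
    backgrounds = tuple(per_bg.index[:2]) if len(per_bg) > 1 else (per_bg.index[0],)
    carrier = any(bg == RISK_HAPLOTYPE for bg in backgrounds)

    mut_rows = table.df[table.df["somatic"] == "mut"]
    present = len(mut_rows) > 0
    background = None
    af = None
    phase = None
    if present:
        mut_by_bg = mut_rows.groupby("background")["count"].sum().sort_values(ascending=False)
        background = str(mut_by_bg.index[0])
        bg_total = int(per_bg.get(background, 0))
        af = float(mut_by_bg.iloc[0] / bg_total) if bg_total else None
        if len(backgrounds) == 2 and backgrounds[0] != backgrounds[1]:
            other = backgrounds[0] if backgrounds[1] == background else backgrounds[1]
            risk_on_mut = background == RISK_HAPLOTYPE
            risk_on_other = other == RISK_HAPLOTYPE
            if risk_on_mut and not risk_on_other:
                phase = "cis"
            elif risk_on_other and not risk_on_mut:
                phase = "trans"
            else:
                phase = "uninformative"
        else:
            phase = "uninformative"

    return SampleCall(
        sample_id=sample_id,
        qc_status=status,
        germline_haps=tuple(sorted(backgrounds)),
        carrier_46_1=carrier,
        v617f_present=present,
        v617f_background=background,
        v617f_af=af,
        phase=phase,
        notes=notes,
    )


def replicate_concordance(call_a: SampleCall, call_b: SampleCall) -> bool:
    """Two sequencing runs agree when the germline background set, mutation
    presence, and phase all match."""
    return (
        set(call_a.germline_haps) == set(call_b.germline_haps)
        and call_a.v617f_present == call_b.v617f_present
        and call_a.phase == call_b.phase
    )


def call_cohort(
    reads: pd.DataFrame,
    min_freq: float = 0.01,
    min_reads: int = 1000,
) -> pd.DataFrame:
    """Run the full haplotype-calling procedure per sample.

    ``reads`` holds all samples (column sample_id).  Returns one row per
    sample with QC status, carriership, mutation call, AF, and phase.
    """
    rows = []
    for sample_id, sample_reads in reads.groupby("sample_id", sort=True):
        table = build_haplotype_table(sample_reads)
        try:
            table = filter_rare(table, min_freq=min_freq)
        except ValueError:
            rows.append(
                {
                    "sample_id": sample_id,
                    "qc_status": QC_MANY_HAPS,
                    "germline_haps": "",
                    "carrier_46_1": False,
                    "v617f_present": False,
                    "v617f_background": "",
                    "v617f_af": np.nan,
                    "phase": "",
                }
            )
            continue
        call = call_sample(table, sample_id=str(sample_id), min_reads=min_reads)
        rows.append(
            {
                "sample_id": call.sample_id,
                "qc_status": call.qc_status,
                "germline_haps": ",".join(call.germline_haps),
                "carrier_46_1": call.carrier_46_1,
                "v617f_present": call.v617f_present,
                "v617f_background": call.v617f_background or "",
                "v617f_af": call.v617f_af if call.v617f_af is not None else np.nan,
                "phase": call.phase or "",
            }
        )
    return pd.DataFrame(rows)
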