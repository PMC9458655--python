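"""End-to-end orchestration: simulate -> mCA calling -> haplotype calling ->
interaction statistics -> Mendelian randomization -> summary report.

`run_pipeline` produces, under an output directory: the cohort truth table,
array-signal and mCA call tables, per-sample haplotype calls, a
``summary.json`` with the headline cohort statistics (V617F and 46/1
frequencies, mCA frequency, per-state allelic shift, cis fraction, clonal
ordering, co-occurrence, locus enrichment, MR table, telomere association),
and a ``manifest.json`` recording the config hash, seed, package version
and file digests.  ``summary.json`` contains no timestamps, so identical
config + seed reproduce it byte-for-byte.
"""

from __future__ import annotations

import datetime
import hashlib
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import ConfigurationError, SimulationConfig
from .genome import V617F_POS
from .io import sha256_file, write_json, write_tsv
from .longread import QC_PASS, build_haplotype_table, call_sample, filter_rare
from .mca import McaParams, call_mcas, calls_to_frame
from .mr import mr_report
from .simulate import (
    CohortSample,
    cohort_truth_frame,
    default_site_grid,
    emit_array_signal,
    emit_instruments,
    emit_reads,
    simulate_cohort,
)
from .stats import (
    ShiftCount,
    allelic_shift_test,
    binom_two_sided,
    clonal_order_test,
    cooccurrence_test,
    locus_enrichment,
)

logger = logging.getLogger("clonalshift")

NOT_APPLICABLE = {"not_applicable": True}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def percentage(k: int, n: int) -> float | None:
    """100*k/n rounded to 2 decimals; None marks an empty denominator."""
    if n == 0:
        return None
    return round(100.0 * k / n, 2)


def summarize_cohort(
    truth: pd.DataFrame, hap_calls: pd.DataFrame, mca_calls: pd.DataFrame
) -> pd.DataFrame:
    """Headline cohort percentages with explicit numerators/denominators."""
    qc_pass = hap_calls[hap_calls["qc_status"] == QC_PASS]
    n_pass = len(qc_pass)
    mca_samples = set(mca_calls["sample_id"]) if len(mca_calls) else set()
    rows = [
        ("v617f_mutated", int(qc_pass["v617f_present"].sum()), n_pass),
        ("carrier_46_1", int(qc_pass["carrier_46_1"].sum()), n_pass),
        ("any_mca", sum(1 for s in truth["sample_id"] if s in mca_samples), len(truth)),
    ]
    mutated = qc_pass[qc_pass["v617f_present"]]
    # mutation on a risk-haplotype background (homozygous carriers count)
    from .genome import RISK_HAPLOTYPE

    rows.append(
        (
            "cis_among_mutated",
            int((mutated["v617f_background"] == RISK_HAPLOTYPE).sum()),
            len(mutated),
        )
    )
    out = pd.DataFrame(rows, columns=["metric", "k", "n"])
    out["percent"] = [percentage(k, n) for k, n in zip(out["k"], out["n"])]
    return out


def _json_safe(obj):
    """Recursively convert numpy scalars and NaN for strict JSON output."""
    if isinstance(obj, dict):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if not math.isfinite(v) else v
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _risk_hap_index(row: pd.Series) -> int | None:
    if bool(row["is_46_1_hap1"]) != bool(row["is_46_1_hap2"]):
        return 1 if bool(row["is_46_1_hap1"]) else 2
    return None


def run_pipeline(
    config: SimulationConfig | str | Path,
    out_dir: str | Path,
    *,
    n_sites: int = 500,
    write_signal: bool = True,
    write_reads: bool = False,
    mca_params: McaParams | None = None,
    reference_mca_rate: float = 0.03,
    mr_n_variants: int = 19,
    mr_true_effect: float = math.log(7.69),
    mr_pleiotropy: tuple[int, float] | None = (5, 0.6),
    mr_fdr: float = 0.2,
    median_boot: int = 2_000,
) -> dict:
    """Run every stage on a fresh synthetic cohort; returns the summary dict.

    Any stage failure aborts with a stage-tagged :class:`PipelineError`
    after removing the partial outputs written so far.
    """
    if not isinstance(config, SimulationConfig):
        config = SimulationConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    mca_params = mca_params or McaParams()

    try:
        # ---- stage: simulate -----------------------------------------
        stage = "simulate"
        samples = simulate_cohort(config)
        truth = cohort_truth_frame(samples)
        written.append(write_tsv(truth, out / "truth.tsv"))
        logger.info("simulate: %d samples", len(samples))

        # ---- stage: array signal + mCA calling -----------------------
        stage = "mca-call"
        grid = default_site_grid(n_sites)
        signal_frames = []
        call_frames = []
        for s in samples:
            sig = emit_array_signal(s, grid, baf_sd=config.baf_sd, lrr_sd=config.lrr_sd)
            if write_signal:
                signal_frames.append(sig)
            calls = call_mcas(sig, mca_params)
            if calls:
                call_frames.append(calls_to_frame(calls, sample_id=s.sample_id))
        if write_signal:
            written.append(write_tsv(pd.concat(signal_frames, ignore_index=True), out / "signal.tsv"))
        mca_calls = (
            pd.concat(call_frames, ignore_index=True)
            if call_frames
            else calls_to_frame([], sample_id=None)
        )
        written.append(write_tsv(mca_calls, out / "mca_calls.bed.tsv"))
        logger.info("mca-call: %d calls in %d samples", len(mca_calls), mca_calls["sample_id"].nunique() if len(mca_calls) else 0)

        # ---- stage: long-read haplotype calling ----------------------
        stage = "hap-call"
        hap_rows = []
        read_frames = []
        for s in samples:
            reads = emit_reads(s, n_reads=config.reads_per_sample, error_rate=config.read_error_rate)
            if write_reads:
                read_frames.append(reads)
            table = filter_rare(build_haplotype_table(reads))
            call = call_sample(table, sample_id=s.sample_id)
            hap_rows.append(
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
        hap_calls = pd.DataFrame(hap_rows)
        if write_reads:
            written.append(write_tsv(pd.concat(read_frames, ignore_index=True), out / "reads.tsv"))
        written.append(write_tsv(hap_calls, out / "hap_calls.tsv"))
        n_fail = int((hap_calls["qc_status"] != QC_PASS).sum())
        logger.info("hap-call: %d samples, %d QC failures", len(hap_calls), n_fail)

        # ---- stage: interaction statistics ---------------------------
        stage = "stats"
        summary: dict = {
            "config": {"n_samples": config.n_samples, "seed": config.seed},
            "version": __version__,
        }
        cohort_table = summarize_cohort(truth, hap_calls, mca_calls)
        written.append(write_tsv(cohort_table, out / "cohort_summary.tsv"))
        summary["cohort"] = {
            row["metric"]: {"k": int(row["k"]), "n": int(row["n"]), "percent": row["percent"]}
            for _, row in cohort_table.iterrows()
        }

        # calls spanning the V617F site, one (largest n_het) per sample
        if len(mca_calls):
            span = mca_calls[
                (mca_calls["start0"] < V617F_POS) & (mca_calls["end0"] >= V617F_POS)
            ]
            span = span.sort_values("n_het", ascending=False).drop_duplicates("sample_id")
        else:
            span = mca_calls
        truth_idx = truth.set_index("sample_id")

        shift: dict = {}
        for state in ("gain", "loss", "CNLOH"):
            k = n = 0
            for _, call in span[span["state"] == state].iterrows():
                risk = _risk_hap_index(truth_idx.loc[call["sample_id"]])
                if risk is None:
                    continue  # not an informative heterozygous carrier
                n += 1
                if int(call["retained_haplotype"]) == risk:
                    k += 1
            res = allelic_shift_test(ShiftCount(state, k, n))
            shift[state] = (
                {"k": res.k, "n": res.n, "p": res.p_value} if res.p_value is not None else NOT_APPLICABLE
            )
        summary["allelic_shift"] = shift

        qc_pass = hap_calls[hap_calls["qc_status"] == QC_PASS]
        mutated = qc_pass[qc_pass["v617f_present"]]
        if len(mutated):
            from .genome import RISK_HAPLOTYPE

            k_cis = int((mutated["phase"] == "cis").sum())
            k_trans = int((mutated["phase"] == "trans").sum())
            informative = k_cis + k_trans
            k_risk_bg = int((mutated["v617f_background"] == RISK_HAPLOTYPE).sum())
            summary["cis"] = {
                "k_cis": k_cis,
                "n_informative": informative,
                "cis_fraction_pct": percentage(k_risk_bg, len(mutated)),
                "p": binom_two_sided(k_cis, informative, 0.5) if informative else None,
            }
        else:
            summary["cis"] = NOT_APPLICABLE

        # co-occurrence of detected mCAs and V617F
        has_mca = qc_pass["sample_id"].isin(set(span["sample_id"]))
        has_mut = qc_pass["v617f_present"].astype(bool)
        table = [
            [int((has_mca & has_mut).sum()), int((has_mca & ~has_mut).sum())],
            [int((~has_mca & has_mut).sum()), int((~has_mca & ~has_mut).sum())],
        ]
        if min(table[0][0] + table[0][1], table[1][0] + table[1][1]) > 0:
            co = cooccurrence_test(table)
            summary["cooccurrence"] = {
                "table": table,
                "odds_ratio": co.odds_ratio,
                "p": co.p_value,
                "method": co.method,
            }
        else:
            summary["cooccurrence"] = NOT_APPLICABLE

        # clonal ordering: AF vs CF in samples carrying both events.  The
        # per-haplotype AF is only identifiable when the two germline
        # backgrounds are distinct, so homozygous-background samples are
        # excluded (their pooled-background AF is systematically halved).
        het_bg = mutated[mutated["germline_haps"].astype(str).str.contains(",")]
        merged = het_bg.merge(span[["sample_id", "cell_fraction"]], on="sample_id")
        merged = merged.dropna(subset=["v617f_af", "cell_fraction"])
        if len(merged):
            order = clonal_order_test(
                merged.rename(columns={"cell_fraction": "mca_cf"})[["v617f_af", "mca_cf"]]
            )
            summary["clonal_order"] = {"k_af_gt_cf": order.k_af_gt_cf, "n": order.n, "p": order.p_value}
        else:
            summary["clonal_order"] = NOT_APPLICABLE

        n_mca_samples = int(mca_calls["sample_id"].nunique()) if len(mca_calls) else 0
        summary["locus_enrichment"] = {
            "k": n_mca_samples,
            "n": len(truth),
            "reference_rate": reference_mca_rate,
            "p": locus_enrichment(n_mca_samples, len(truth), reference_mca_rate),
        }

        # ---- stage: Mendelian randomization --------------------------
        stage = "mr"
        instruments = emit_instruments(
            n_variants=mr_n_variants,
            true_effect=mr_true_effect,
            pleiotropy_spec=mr_pleiotropy,
            seed=config.seed,
        )
        written.append(write_tsv(instruments, out / "instruments.tsv"))
        report, removed = mr_report(instruments, fdr=mr_fdr, median_boot=median_boot)
        written.append(write_tsv(report, out / "mr_report.tsv"))
        summary["mr"] = {
            "true_effect_or": math.exp(mr_true_effect),
            "n_removed_pleiotropic": len(removed),
            "table": [
                {k: (round(v, 6) if isinstance(v, float) else v) for k, v in row.items()}
                for row in report.to_dict(orient="records")
            ],
        }

        # ---- stage: telomere association -----------------------------
        stage = "telomere"
        with_mca = truth.dropna(subset=["mca_cell_fraction"])
        if len(with_mca) >= 10:
            import statsmodels.api as sm

            fit = sm.OLS(
                with_mca["rtl"].to_numpy(), sm.add_constant(with_mca["mca_cell_fraction"].to_numpy())
            ).fit()
            ci = fit.conf_int()[1]
            summary["telomere"] = {
                "rtl_vs_cf_slope": float(fit.params[1]),
                "ci": [float(ci[0]), float(ci[1])],
                "p": float(fit.pvalues[1]),
                "n": int(len(with_mca)),
            }
        else:
            summary["telomere"] = NOT_APPLICABLE

        # ---- stage: report -------------------------------------------
        stage = "report"
        summary_path = write_json(_json_safe(summary), out / "summary.json")
        written.append(summary_path)

        config_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
        manifest = {
            "config_sha256": hashlib.sha256(config_yaml.encode()).hexdigest(),
            "seed": config.seed,
            "version": __version__,
            "timestamp_utc": datetime.datetime.now(datetime.timezone.utc).isoformat(),
            "files": {p.name: sha256_file(p) for p in written if p.exists()},
        }
        write_json(manifest, out / "manifest.json")
        return summary

    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage-tagged abort with cleanup
        for p in written:
            try:
                p.unlink(missing_ok=True)
            except OSError:
                pass
        raise PipelineError(stage, str(exc)) from exc
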