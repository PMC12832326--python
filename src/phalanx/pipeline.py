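"""High-level orchestration: the simulate → build-ref → screen → roc chain.

These functions are the library face of the CLI subcommands; the CLI adds
only argument parsing and file paths. Each stage is deterministic given
the configuration's single seed.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .config import GeneratorConfig, PipelineConfig
from .measurement import compute_ratios
from .reference import ReferenceTable, TrimReport, build_reference, trim_outliers
from .screening import cohort_prevalence, screen_cohort
from .stats import ROCResult, roc_analysis, sens_spec_at
from .synthetic import fit_ts_mixture, generate_reference_cohort, generate_ts_cohort


def simulate_cohorts(
    config: GeneratorConfig,
    *,
    calibrate_mixture: bool = True,
    trim_limit: float = 2.25,
) -> dict:
    """Generate both cohorts; TS uses the ratio-level backend.

    Unless a mixture is already set (or the reference cohort is too small
    to trim), the affected-subgroup 4:3 MC mixture is first fitted against
    a reference table built from this run's own reference cohort, so the
    TS cohort's flag prevalence is calibrated out of the box.

    Returns a dict with ``ref_metadata``, ``ref_lengths``, ``ts_metadata``,
    ``ts_ratios`` and the (possibly mixture-augmented) ``config`` used for
    the TS draw.
    """
    ref_meta, ref_lengths = generate_reference_cohort(config)
    ts_config = config
    if calibrate_mixture and config.ts_mixture is None and config.ref_n >= 50:
        table, _, _, _ = reference_from_lengths(ref_lengths, ref_meta, trim_limit)
        ts_config = calibrated_ts_config(config, table)
    ts_meta, ts_ratios = generate_ts_cohort(ts_config, backend="ratio_level")
    return {
        "ref_metadata": ref_meta,
        "ref_lengths": ref_lengths,
        "ts_metadata": ts_meta,
        "ts_ratios": ts_ratios,
        "config": ts_config,
    }


def reference_from_lengths(
    lengths: pd.DataFrame,
    metadata: pd.DataFrame,
    trim_limit: float = 2.25,
) -> tuple[ReferenceTable, TrimReport, pd.DataFrame, pd.DataFrame]:
    """Lengths → ratios → trim → normative table.

    Returns ``(table, trim_report, retained_ratios, ratio_rejects)``.
    """
    ratios, rejects = compute_ratios(lengths)
    retained, report = trim_outliers(ratios, trim_limit)
    table = build_reference(retained, metadata, trim_limit)
    return table, report, retained, rejects


def build_default_reference(
    config: Optional[GeneratorConfig] = None, trim_limit: float = 2.25
) -> tuple[ReferenceTable, TrimReport, pd.DataFrame, pd.DataFrame]:
    """Simulate the default reference cohort and build its table.

    Returns ``(table, trim_report, retained_ratios, metadata)``.
    """
    config = config or GeneratorConfig()
    metadata, lengths = generate_reference_cohort(config)
    table, report, retained, _ = reference_from_lengths(
        lengths, metadata, trim_limit
    )
    return table, report, retained, metadata


def calibrated_ts_config(
    config: GeneratorConfig,
    table: ReferenceTable,
    target_flag_prev: float = 0.272,
) -> GeneratorConfig:
    """Return a copy of ``config`` with the 4:3 MC mixture fitted against
    ``table`` (published pooled TS moments, published flag prevalence)."""
    mix = fit_ts_mixture(
        config.ts_ratio_means[0],
        config.ts_ratio_sds[0],
        target_flag_prev,
        table,
        age_range=config.ts_age_range,
    )
    return config.model_copy(
        update={
            "ts_mixture": mix,
            "ts_mixture_mu0": table.pooled["r43mc"].mean,
        }
    )


def screen_and_summarize(
    ratios: pd.DataFrame,
    metadata: pd.DataFrame,
    table: ReferenceTable,
    *,
    pipeline: Optional[PipelineConfig] = None,
    min_bone_age: Optional[float] = None,
    compare_to: Optional[tuple[pd.DataFrame, Optional[pd.DataFrame]]] = None,
) -> tuple[pd.DataFrame, dict]:
    """Screen a cohort and summarize flag prevalence."""
    cfg = pipeline or PipelineConfig()
    results = screen_cohort(
        ratios,
        metadata,
        table,
        bda3_threshold=cfg.bda3_threshold,
        mc_sds_threshold=cfg.mc_sds_threshold,
        min_bone_age=min_bone_age,
    )
    summary = cohort_prevalence(results, metadata, compare_to=compare_to)
    return results, summary


def roc_with_fixed_cutoff(
    reference_values,
    ts_values,
    fixed_cutoff: Optional[float] = 0.876,
) -> dict:
    """Empirical ROC summary plus operating point at a fixed cutoff."""
    roc: ROCResult = roc_analysis(reference_values, ts_values)
    out = roc.to_dict()
    if fixed_cutoff is not None:
        sens, spec = sens_spec_at(fixed_cutoff, reference_values, ts_values)
        out["fixed_cutoff"] = {
            "cutoff": fixed_cutoff,
            "sensitivity": sens,
            "specificity": spec,
        }
    return out
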