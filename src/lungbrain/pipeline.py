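"""End-to-end run: simulate -> trend processing -> mechanics -> statistics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as lio
from .config import RunConfig
from .mechanics import compute_mechanics_table
from .stats import run_statistics
from .synth import ground_truth_frame, iterate_study
from .trends import process_recording

log = logging.getLogger("lungbrain")

#: holds/mechanics columns merged into the study table
_MECH_COLUMNS = ("paw_ei", "peep_tot", "pes_ei", "pes_ee", "ppeak_rs",
                 "ppeak_cw", "paw_ee", "vt_ml", "rr", "e_rs", "e_cw", "e_l",
                 "tpp_ei", "tpp_ee", "tpp_elast", "ppeak_l", "mp_rs",
                 "mp_ldep", "mp_lnondep", "occlusion_ratio", "occlusion_pass",
                 "pao2", "paco2", "co", "pap", "evlw", "svv")


@dataclass
class PipelineResult:
    study_table: pd.DataFrame
    ground_truth: pd.DataFrame
    reports: dict
    manifest: dict


def build_study_table(summaries: pd.DataFrame,
                      mechanics: pd.DataFrame) -> pd.DataFrame:
    """Merge period summaries with mechanics/auxiliary columns on period_id."""
    cols = ["period_id"] + [c for c in _MECH_COLUMNS if c in mechanics.columns]
    return summaries.merge(mechanics[cols], on="period_id", how="left",
                           validate="one_to_one")


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute every stage and write the outputs under ``cfg.out_dir``.

    Deterministic given ``cfg.synth.seed``.  Stage failures are re-raised with
    the stage and animal named.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    summaries, truths, holds_all, designs = [], [], [], []
    for rec, truth, design, holds in iterate_study(cfg.synth):
        log.info("processing %s (%s)", truth.animal, truth.sequence)
        try:
            _, _, summary = process_recording(
                rec, design=design, cardiac_hz=cfg.synth.cardiac_hz,
                amp_method=cfg.amp_method, artifact_level=cfg.artifact_level,
                icp_limits=cfg.icp_limits, cpp_limits=cfg.cpp_limits,
                min_valid_pairs=cfg.min_valid_pairs,
                min_raw_fraction=cfg.min_raw_fraction,
            )
        except Exception as exc:
            raise RuntimeError(
                f"trend stage failed for {truth.animal}: {exc}") from exc
        if cfg.write_waveforms:
            lio.write_waveforms_csv(rec, out / f"{truth.animal}_waveforms.csv")
        summaries.append(summary)
        truths.append(truth)
        holds_all.append(holds)
        designs.append(design)

    design = pd.concat(designs, ignore_index=True)
    holds = pd.concat(holds_all, ignore_index=True)
    try:
        mech = compute_mechanics_table(holds)
    except Exception as exc:
        raise RuntimeError(f"mechanics stage failed: {exc}") from exc

    table = build_study_table(pd.concat(summaries, ignore_index=True), mech)
    truth_df = ground_truth_frame(truths)

    try:
        reports = run_statistics(table, covariates=cfg.covariates,
                                 alpha=cfg.alpha)
    except Exception as exc:
        raise RuntimeError(f"statistics stage failed: {exc}") from exc

    lio.write_design_csv(design, out / "design.csv")
    lio.write_table_csv(holds, out / "holds.csv")
    lio.write_table_csv(mech, out / "mechanics.csv")
    lio.write_table_csv(table, out / "study_table.csv")
    lio.write_table_csv(truth_df, out / "ground_truth.csv")
    lio.write_reports_json(reports, out / "stat_reports.json")
    manifest = lio.build_manifest(cfg)
    lio.write_manifest(cfg, out / "manifest.json")

    if cfg.make_plots:
        from .plots import screen_scatterplots
        screen_scatterplots(table, out / "plots")

    return PipelineResult(study_table=table, ground_truth=truth_df,
                          reports=reports, manifest=manifest)
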