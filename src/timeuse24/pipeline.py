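"""End-to-end study emulation: simulate -> score -> process -> agree.

Mirrors the design of a questionnaire validation study: every participant
answers the questionnaire on two occasions about a week apart
(test-retest reliability) and wears a thigh-mounted device for seven days
with a nightly sleep diary (convergent validity).  The reliability report
compares occasion 1 with occasion 2 per behaviour; the validity report
compares occasion-2 questionnaire estimates with device estimates from
participants holding at least the minimum number of valid wear days.

Reports are plain DataFrames keyed behaviour x statistic, plus the
per-pair (mean, difference) dataset needed for Bland-Altman plots.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activpal import ProcessingConfig, process_participant
from .agreement import (
    PairedMeasurements,
    agreement_battery,
    bland_altman,
)
from .composition import BEHAVIOURS
from .dabq import score_composition
from .synthetic import (
    CohortConfig,
    generate_cohort,
    generate_dabq_responses,
    generate_event_stream,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StudyConfig:
    """Everything a full study emulation needs, under one seed."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    n_boot: int = 2000
    alpha: float = 0.05
    occasion2_missing_rate: float = 12 / 126  # dropout between occasions
    #: distribution of days the device was actually worn
    days_worn: tuple[tuple[int, float], ...] = ((7, 0.86), (6, 0.06), (5, 0.02), (4, 0.06))
    n_days: int = 7
    seed: int = 0


def _composition_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["participant_id", "occasion", *BEHAVIOURS, "valid"])


def score_cohort(cohort, config: CohortConfig, occasion: int) -> pd.DataFrame:
    """Generate and score one occasion's responses for a whole cohort."""
    rows = []
    for truth in cohort:
        comp = score_composition(generate_dabq_responses(truth, occasion, config))
        rows.append(
            {
                "participant_id": truth.participant_id,
                "occasion": occasion,
                **comp.as_dict(),
                "valid": comp.valid,
            }
        )
    return _composition_table(rows)


def process_cohort_devices(
    cohort, config: CohortConfig, processing: ProcessingConfig, days_by_pid: dict[str, int]
) -> pd.DataFrame:
    """Simulate and process a device week per participant."""
    rows = []
    for truth in cohort:
        n_days = days_by_pid.get(truth.participant_id, 7)
        stream = generate_event_stream(truth, config, n_days=n_days)
        weekly, _ = process_participant(
            stream.events, stream.diaries, sorted(stream.day_truths), processing
        )
        rows.append(
            {
                "participant_id": truth.participant_id,
                "occasion": 0,
                **weekly.as_dict(),
                "valid": weekly.valid,
            }
        )
    return _composition_table(rows)


def _paired(
    t1: pd.DataFrame, t2: pd.DataFrame, behaviour: str
) -> PairedMeasurements:
    merged = t1.merge(t2, on="participant_id", suffixes=("_1", "_2"))
    merged = merged[merged["valid_1"] & merged["valid_2"]]
    return PairedMeasurements.from_arrays(
        merged[f"{behaviour}_1"].to_numpy(),
        merged[f"{behaviour}_2"].to_numpy(),
        ids=merged["participant_id"].tolist(),
    )


def _complete(t1: pd.DataFrame, t2: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Restrict both tables to valid rows sharing participant ids."""
    v1 = t1[t1["valid"]]
    v2 = t2[t2["valid"]]
    shared = set(v1["participant_id"]) & set(v2["participant_id"])
    dropped = len(set(t1["participant_id"]) | set(t2["participant_id"])) - len(shared)
    if dropped:
        logger.info("dropped %d participants without complete valid pairs", dropped)
    return (
        v1[v1["participant_id"].isin(shared)],
        v2[v2["participant_id"].isin(shared)],
        len(shared),
    )


def _agreement_rows(
    t1: pd.DataFrame,
    t2: pd.DataFrame,
    labels: tuple[str, str],
    n_boot: int,
    alpha: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-behaviour agreement table plus Bland-Altman pair dataset."""
    rows = []
    pair_rows = []
    for bi, behaviour in enumerate(BEHAVIOURS):
        p = _paired(t1, t2, behaviour)
        agr = agreement_battery(p, n_boot=n_boot, seed=np.random.default_rng([seed, bi]), alpha=alpha)
        ba = bland_altman(p, alpha=alpha)
        rows.append(
            {
                "behaviour": behaviour,
                f"{labels[0]}_mean": float(p.x.mean()),
                f"{labels[0]}_sd": float(p.x.std(ddof=1)),
                f"{labels[1]}_mean": float(p.y.mean()),
                f"{labels[1]}_sd": float(p.y.std(ddof=1)),
                "icc_a1": agr.icc_a1.estimate,
                "icc_a1_lo": agr.icc_a1.lower,
                "icc_a1_hi": agr.icc_a1.upper,
                "icc_c1": agr.icc_c1.estimate,
                "icc_c1_lo": agr.icc_c1.lower,
                "icc_c1_hi": agr.icc_c1.upper,
                "rho": agr.spearman_rho.estimate,
                "rho_lo": agr.spearman_rho.lower,
                "rho_hi": agr.spearman_rho.upper,
                "mean_diff": ba.mean_diff.estimate,
                "mean_diff_lo": ba.mean_diff.lower,
                "mean_diff_hi": ba.mean_diff.upper,
                "sd_diff": ba.sd_diff,
                "loa_lower": ba.loa_lower.estimate,
                "loa_lower_lo": ba.loa_lower.lower,
                "loa_lower_hi": ba.loa_lower.upper,
                "loa_upper": ba.loa_upper.estimate,
                "loa_upper_lo": ba.loa_upper.lower,
                "loa_upper_hi": ba.loa_upper.upper,
                "prop_bias_beta": ba.prop_bias_beta,
                "prop_bias_p": ba.prop_bias_p,
                "n": p.n,
            }
        )
        for pid, x, y in zip(p.ids, p.x, p.y):
            pair_rows.append(
                {
                    "participant_id": pid,
                    "behaviour": behaviour,
                    "mean": (x + y) / 2.0,
                    "diff": x - y,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(pair_rows)


def run_reliability(
    dabq1: pd.DataFrame, dabq2: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test-retest reliability report per behaviour (occasion 1 vs 2)."""
    t1, t2, n = _complete(dabq1, dabq2)
    if n < 2:
        raise ValueError("fewer than 2 complete questionnaire pairs")
    return _agreement_rows(
        t1, t2, ("dabq1", "dabq2"), config.n_boot, config.alpha, config.seed + 1
    )


def run_validity(
    dabq2: pd.DataFrame, device: pd.DataFrame, config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convergent validity report (questionnaire vs device) per behaviour.

    Differences are questionnaire minus device, so a device that records
    more SB than the questionnaire yields a negative SB mean difference.
    """
    t1, t2, n = _complete(dabq2, device)
    if n < 2:
        raise ValueError("fewer than 2 complete questionnaire/device pairs")
    return _agreement_rows(
        t1, t2, ("dabq2", "device"), config.n_boot, config.alpha, config.seed + 2
    )


@dataclass(frozen=True)
class StudyResult:
    dabq1: pd.DataFrame
    dabq2: pd.DataFrame
    device: pd.DataFrame
    reliability: pd.DataFrame
    reliability_pairs: pd.DataFrame
    validity: pd.DataFrame
    validity_pairs: pd.DataFrame
    counts: dict[str, int]


def run_all(config: StudyConfig) -> StudyResult:
    """Full study emulation under a single seed."""
    cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
    cohort = generate_cohort(cohort_cfg)
    rng = np.random.default_rng([config.seed, 999])

    # attrition: who misses occasion 2; how many days each wore the device
    missing2 = {
        t.participant_id for t in cohort if rng.random() < config.occasion2_missing_rate
    }
    days, probs = zip(*config.days_worn)
    days_by_pid = {
        t.participant_id: int(rng.choice(days, p=probs)) for t in cohort
    }

    dabq1 = score_cohort(cohort, cohort_cfg, occasion=1)
    dabq2_full = score_cohort(cohort, cohort_cfg, occasion=2)
    dabq2 = dabq2_full[~dabq2_full["participant_id"].isin(missing2)].reset_index(drop=True)
    device = process_cohort_devices(cohort, cohort_cfg, config.processing, days_by_pid)

    reliability, rel_pairs = run_reliability(dabq1, dabq2, config)
    validity, val_pairs = run_validity(dabq2, device, config)

    counts = {
        "cohort": len(cohort),
        "completed_both_occasions": len(dabq2),
        "reliability_n": int(reliability["n"].iloc[0]),
        "device_valid": int(device["valid"].sum()),
        "validity_n": int(validity["n"].iloc[0]),
    }
    logger.info("filter accounting: %s", counts)
    return StudyResult(
        dabq1, dabq2, device, reliability, rel_pairs, validity, val_pairs, counts
    )
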