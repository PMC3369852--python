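"""End-to-end orchestration: ingest, classify, enumerate, test, correct,
report.

A run is configured by a small mapping (usually loaded from YAML):

.. code-block:: yaml

    panel: panel.tsv            # amplicon definitions
    genotypes: genotypes.tsv    # patient x amplicon calls
    clinical: clinical.tsv      # visits with DAS28 or components
    contrasts: [good_vs_none, good_vs_modnone, goodmod_vs_none]
    n_marker: 202               # omit to count amplicons with N_test >= 1
    alpha_family: 0.05
    min_group_fraction: 0.10
    contrast_multiplier: 1      # extra Bonferroni factor for the contrast family
    calibrate: hits             # "hits", "none", or list of amplicon ids
    calibration_rounds: 600000
    seed: 0
    out_dir: results/

Per amplicon the report carries protocol, allele count and length range,
genotyping rate (flagged below 95%/90%), the HWE screen minimum p, and per
contrast N_test / minimum p / best test; the hit list contains every
result below its amplicon's threshold ``alpha / (n_marker * N_test *
contrast_multiplier)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .association import CONTRASTS, ContrastSummary, run_contrast
from .cohort import (Cohort, attach_clinical, genotyping_rate, read_clinical_table,
                     read_genotype_table, read_panel)
from .multiplicity import MultiplicityPlan, effective_test_count
from .qc import hwe_min_chisq
from .response import derive_labels

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "load_config"]

DEFAULT_CONTRASTS = ("good_vs_none", "good_vs_modnone", "goodmod_vs_none")


@dataclass
class PipelineConfig:
    panel: str
    genotypes: str
    clinical: str
    contrasts: tuple[str, ...] = DEFAULT_CONTRASTS
    n_marker: Optional[int] = None
    alpha_family: float = 0.05
    min_group_fraction: float = 0.10
    contrast_multiplier: int = 1
    dedupe: str = "within_kind"
    calibrate: object = "none"      # "none", "hits", or list of amplicon ids
    calibration_rounds: int = 600_000
    calibration_contrast: str = "good_vs_none"
    seed: int = 0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        for c in self.contrasts:
            if c not in CONTRASTS:
                raise ValueError(f"unknown contrast {c!r}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "contrasts" in raw:
        raw["contrasts"] = tuple(raw["contrasts"])
    return PipelineConfig(**raw)


@dataclass
class RunReport:
    """Per-amplicon summary table, per-contrast results, hits and the log."""

    table: pd.DataFrame
    contrast_results: dict[str, pd.DataFrame]
    hits: pd.DataFrame
    plans: dict[str, MultiplicityPlan]
    calibration: dict[str, object] = field(default_factory=dict)
    log: list[str] = field(default_factory=list)
    n_marker: int = 0


def _results_frame(summaries: list[ContrastSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        min_p = s.min_p
        for r in s.results:
            rows.append({
                "amplicon_id": r.amplicon_id,
                "contrast": r.contrast,
                "test": r.test.label,
                "kind": r.test.grouping.kind,
                "model": r.test.model,
                "positive_n": r.test.positive_count,
                "negative_n": r.test.negative_count,
                "a": r.table.a, "b": r.table.b,
                "c": r.table.c, "d": r.table.d,
                "p": r.p_two_sided,
                "odds_ratio": r.odds_ratio,
                "ci_low": r.ci95[0], "ci_high": r.ci95[1],
                "is_min_p": r.p_two_sided == min_p,
            })
    cols = ["amplicon_id", "contrast", "test", "kind", "model", "positive_n",
            "negative_n", "a", "b", "c", "d", "p", "odds_ratio", "ci_low",
            "ci_high", "is_min_p"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: PipelineConfig | Mapping | str) -> RunReport:
    """Execute all stages on the configured inputs.

    Deterministic given the config seed; writes per-contrast TSVs, the
    amplicon report and the run log when ``out_dir`` is set.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    elif isinstance(config, Mapping):
        config = PipelineConfig(**dict(config))

    log: list[str] = []

    # ingest
    panel = read_panel(config.panel)
    cohort = read_genotype_table(config.genotypes, panel)
    attach_clinical(cohort, read_clinical_table(config.clinical))
    log.append(f"ingest: {len(panel)} amplicons, "
               f"{len(cohort.patients)} patients")

    # classify
    labels = derive_labels(cohort, log)
    counts = {c: sum(1 for v in labels.values() if v == c)
              for c in ("good", "moderate", "none")}
    log.append(f"classify: {counts}")

    # per-amplicon QC + association
    amp_rows = []
    per_contrast: dict[str, list[ContrastSummary]] = {c: [] for c in config.contrasts}
    summaries: dict[tuple[str, str], ContrastSummary] = {}
    for amp in panel:
        aid = amp.amplicon_id
        rate = genotyping_rate(cohort, aid)
        if rate.below_90:
            log.append(f"{aid}: genotyping rate {rate.rate:.2f} < 0.90")
        elif rate.below_95:
            log.append(f"{aid}: genotyping rate {rate.rate:.2f} < 0.95")
        calls = cohort.calls(aid)
        hwe = hwe_min_chisq(calls, amp.alleles, aid) if calls else None
        row = {
            "amplicon_id": aid,
            "gene": amp.gene,
            "protocol": amp.protocol,
            "n_alleles": amp.n_alleles,
            "length_range": amp.length_range,
            "genotyping_rate": rate.rate,
            "hwe_min_p": hwe.min_p if hwe else np.nan,
        }
        for contrast in config.contrasts:
            try:
                s = run_contrast(cohort, aid, contrast,
                                 config.min_group_fraction, config.dedupe)
            except ValueError as exc:
                raise RuntimeError(f"association stage failed at {aid} "
                                   f"({contrast}): {exc}") from exc
            summaries[(aid, contrast)] = s
            per_contrast[contrast].append(s)
            row[f"n_test_{contrast}"] = s.n_test
            row[f"min_p_{contrast}"] = s.min_p if s.min_p is not None else np.nan
        amp_rows.append(row)
    table = pd.DataFrame(amp_rows)

    # correct: N_test from the primary (first) contrast defines markerhood
    primary = config.contrasts[0]
    n_test_col = f"n_test_{primary}"
    n_marker = config.n_marker
    if n_marker is None:
        n_marker = int((table[n_test_col] >= 1).sum()) if len(table) else 0
        log.append(f"n_marker derived from data: {n_marker}")
    plans: dict[str, MultiplicityPlan] = {}
    hit_rows = []
    for row in amp_rows:
        n_test = row[n_test_col]
        if n_test < 1:
            continue
        plan = MultiplicityPlan(n_marker,
                                n_test * config.contrast_multiplier,
                                config.alpha_family)
        plans[row["amplicon_id"]] = plan
        for contrast in config.contrasts:
            s = summaries[(row["amplicon_id"], contrast)]
            for r in s.results:
                if r.p_two_sided < plan.threshold:
                    hit_rows.append({
                        "amplicon_id": r.amplicon_id,
                        "contrast": contrast,
                        "test": r.test.label,
                        "p": r.p_two_sided,
                        "odds_ratio": r.odds_ratio,
                        "threshold": plan.threshold,
                    })
    hits = pd.DataFrame(
        hit_rows, columns=["amplicon_id", "contrast", "test", "p",
                           "odds_ratio", "threshold"])

    # calibrate (optional): permutation effective N_test at each amplicon
    calibration: dict[str, object] = {}
    if config.calibrate != "none":
        targets = (sorted(hits["amplicon_id"].unique())
                   if config.calibrate == "hits" else list(config.calibrate))
        for aid in targets:
            s = summaries.get((aid, config.calibration_contrast))
            if s is None or s.n_test == 0:
                continue
            feats = np.column_stack([r.test.feature for r in s.results])
            est = effective_test_count(
                feats, (s.n_responders, s.n_comparators),
                p_ref=s.min_p, n_rounds=config.calibration_rounds,
                seed=config.seed)
            calibration[aid] = est
            plans[aid] = MultiplicityPlan(
                n_marker, plans[aid].n_test, config.alpha_family,
                effective_n_test=est.effective_n)
            log.append(f"{aid}: effective N_test {est.effective_n:.2f} "
                       f"(tail {est.tail_count}/{est.n_rounds})")

    contrast_frames = {c: _results_frame(per_contrast[c])
                       for c in config.contrasts}
    report = RunReport(table, contrast_frames, hits, plans, calibration,
                       log, n_marker)

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "amplicon_report.tsv", sep="\t", index=False)
        for c, frame in contrast_frames.items():
            frame.to_csv(out / f"results_{c}.tsv", sep="\t", index=False)
        hits.to_csv(out / "hits.tsv", sep="\t", index=False)
        with open(out / "run_log.txt", "w") as fh:
            fh.write("\n".join(log) + "\n")
        with open(out / "multiplicity.txt", "w") as fh:
            for aid in sorted(plans):
                fh.write(f"[{aid}]\n{plans[aid].report_block()}\n\n")
    return report
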