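"""End-to-end orchestration: motifs -> features -> selection -> MCCV.

A single experiment seed fans out to stage-specific seeds by a fixed
derivation (`classify.child_seed`), so each stage is independently
reproducible and a rerun with the same configuration yields byte-identical
reports.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .classify import (
    PerformanceReport,
    SplitPlan,
    balance_classes,
    child_seed,
    mccv_run,
)
from .features import FeatureMatrix, build_feature_matrix
from .io import LabelledDataset
from .motifs import MotifProfile, discover_motifs_builtin, run_meme_external
from .select import FeatureRanking, select_top

logger = logging.getLogger("mirclade")

# stage codes for seed derivation
_S_DISCOVERY, _S_BALANCE, _S_MCCV, _S_SUBSET = 20, 30, 40, 50


@dataclass
class PipelineResult:
    profiles_positive: list[MotifProfile]
    profiles_negative: list[MotifProfile]
    matrix: FeatureMatrix
    ranking: FeatureRanking
    report: PerformanceReport


def _discover(
    dataset: LabelledDataset,
    n_motifs: int,
    minw: int,
    maxw: int,
    seed: int,
    meme_path: str | None = None,
) -> list[MotifProfile]:
    if meme_path is not None:
        return run_meme_external(dataset, meme_path, n_motifs, minw, maxw)
    return discover_motifs_builtin(dataset, n_motifs, minw, maxw, seed=seed)


def run_pipeline(
    positive: LabelledDataset,
    negative: LabelledDataset,
    n_motifs: int = 100,
    minw: int = 11,
    maxw: int = 50,
    kmax: int = 3,
    n_selected: int = 100,
    n_bins: int = 10,
    n_folds: int = 100,
    holdout_fraction: float = 0.1,
    train_fraction: float = 0.8,
    n_trees: int = 100,
    seed: int = 0,
    meme_path: str | None = None,
) -> PipelineResult:
    """Full workflow on two labelled datasets.

    Stages: per-class motif discovery, k-mer + motif feature matrix,
    information-gain selection of the top `n_selected` features, class
    balancing, stratified holdout, then `n_folds` Monte Carlo folds of
    random-forest training/testing.
    """
    t0 = time.perf_counter()
    prof_pos = _discover(positive, n_motifs, minw, maxw, child_seed(seed, _S_DISCOVERY, 0), meme_path)
    prof_neg = _discover(negative, n_motifs, minw, maxw, child_seed(seed, _S_DISCOVERY, 1), meme_path)
    logger.info(
        "motif discovery: %d + %d profiles (%.1fs)",
        len(prof_pos), len(prof_neg), time.perf_counter() - t0,
    )
    matrix = build_feature_matrix([positive, negative], prof_pos + prof_neg, kmax=kmax)
    logger.info("feature matrix: %d examples x %d features", matrix.n_examples, matrix.n_features)
    ranking, reduced = select_top(matrix, n=n_selected, n_bins=n_bins)
    balanced = balance_classes(reduced, seed=child_seed(seed, _S_BALANCE, 0))
    plan = SplitPlan(
        holdout_fraction=holdout_fraction,
        train_fraction=train_fraction,
        n_folds=n_folds,
        seed=child_seed(seed, _S_MCCV, 0),
    )
    report = mccv_run(balanced, plan, n_trees=n_trees)
    logger.info(
        "MCCV: %d folds, mean test ACC %.3f, mean holdout ACC %.3f (%.1fs total)",
        n_folds,
        report.mean_metrics("test").acc,
        report.mean_metrics("holdout").acc,
        time.perf_counter() - t0,
    )
    return PipelineResult(
        profiles_positive=prof_pos,
        profiles_negative=prof_neg,
        matrix=matrix,
        ranking=ranking,
        report=report,
    )


def _subset(dataset: LabelledDataset, fraction: float, seed: int) -> LabelledDataset:
    """Uniform subsample without replacement, input order preserved."""
    if fraction >= 1.0:
        return dataset
    n = len(dataset.records)
    size = max(2, math.ceil(fraction * n))
    rng = np.random.default_rng(seed)
    keep = np.sort(rng.choice(n, size=size, replace=False))
    return LabelledDataset(
        records=tuple(dataset.records[i] for i in keep),
        label=dataset.label,
        provenance=dataset.provenance,
    )


def run_motif_recreation_experiment(
    positive: LabelledDataset,
    negative: LabelledDataset,
    outer_folds: int = 10,
    inner_folds: int = 10,
    n_motifs: int = 100,
    minw: int = 11,
    maxw: int = 50,
    kmax: int = 3,
    n_selected: int = 100,
    n_bins: int = 10,
    holdout_fraction: float = 0.1,
    train_fraction: float = 0.8,
    n_trees: int = 100,
    subset_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[PerformanceReport, PerformanceReport]:
    """Control experiment: pre-created motifs vs per-fold motif re-creation.

    Mode A discovers motifs once on the full class datasets and runs
    `outer_folds * inner_folds` Monte Carlo folds.  Mode B, per outer fold,
    discovers motifs on a random `subset_fraction` of each class, rebuilds
    the feature matrix, and runs `inner_folds` Monte Carlo folds.  Both
    accuracy distributions are returned for comparison; with
    `outer_folds=1, subset_fraction=1.0` mode B reduces exactly to mode A.
    """

    def one_round(disc_pos, disc_neg, n_folds, round_idx):
        prof_pos = _discover(disc_pos, n_motifs, minw, maxw, child_seed(seed, _S_DISCOVERY, 0))
        prof_neg = _discover(disc_neg, n_motifs, minw, maxw, child_seed(seed, _S_DISCOVERY, 1))
        matrix = build_feature_matrix([positive, negative], prof_pos + prof_neg, kmax=kmax)
        _, reduced = select_top(matrix, n=n_selected, n_bins=n_bins)
        balanced = balance_classes(reduced, seed=child_seed(seed, _S_BALANCE, round_idx))
        plan = SplitPlan(
            holdout_fraction=holdout_fraction,
            train_fraction=train_fraction,
            n_folds=n_folds,
            seed=child_seed(seed, _S_MCCV, round_idx),
        )
        return mccv_run(balanced, plan, n_trees=n_trees)

    report_a = one_round(positive, negative, outer_folds * inner_folds, 0)

    folds_b = []
    for o in range(outer_folds):
        sub_pos = _subset(positive, subset_fraction, child_seed(seed, _S_SUBSET, o, 0))
        sub_neg = _subset(negative, subset_fraction, child_seed(seed, _S_SUBSET, o, 1))
        rep = one_round(sub_pos, sub_neg, inner_folds, o)
        folds_b.extend(rep.folds)
    report_b = PerformanceReport(folds=folds_b, positive_label=report_a.positive_label)
    return report_a, report_b
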