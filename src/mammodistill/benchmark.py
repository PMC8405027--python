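"""The desk-scale end-to-end benchmark on synthetic phantoms.

One benchmark run generates a seeded phantom dataset (200 weakly-annotated
tiles for teacher pretraining, 100 fully-annotated tiles split 80/10/10),
pretrains the auto-encoder teacher, trains the requested student arms to
early-stopped convergence, and evaluates each on the held-out test split.
Problem sizes (64-pixel tiles, 8 base channels, the epoch caps below) are
chosen so a full five-seed sweep runs on a single CPU core in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import DatasetManifest, split as split_manifest
from .networks import NetConfig
from .synthetic import PhantomSpec, generate_dataset
from .training import ARMS, StudentDistillation, TeacherPretraining, TrainConfig

BENCH_NET = NetConfig(in_size=64, base_channels=8, depth=4)
BENCH_N_WEAK = 200
BENCH_N_FULL = 100
TEACHER_EPOCHS = 14
STUDENT_EPOCHS = 25
PATIENCE = 5
MIN_DELTA = 1e-3


def bench_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(seed=seed)


def teacher_config(seed: int) -> TrainConfig:
    return TrainConfig(epochs_max=TEACHER_EPOCHS, batch_size=8, seed=seed,
                       early_stop_patience=PATIENCE, min_delta=MIN_DELTA)


def student_config(seed: int, arm: str) -> TrainConfig:
    return TrainConfig(epochs_max=STUDENT_EPOCHS, batch_size=8, seed=seed,
                       early_stop_patience=PATIENCE, min_delta=MIN_DELTA,
                       arm=arm)


@dataclass
class BenchmarkRun:
    """Everything one seeded benchmark run produced."""

    seed: int
    teacher_results: "object"
    teacher_frozen: bool
    arm_results: dict[str, "object"]
    arm_test_iou: dict[str, float]

    @property
    def teacher_val_loss_reduction(self) -> float:
        return self.teacher_results.val_loss_reduction


def run_benchmark(seed: int, arms: tuple[str, ...] = ("unet", "aaws"),
                  n_weak: int = BENCH_N_WEAK, n_full: int = BENCH_N_FULL) -> BenchmarkRun:
    """Run teacher pretraining plus the requested student arms for one seed."""
    records = generate_dataset(bench_spec(seed), n_weak=n_weak, n_full=n_full)
    weak = [r for r in records if r.mask is None]
    full = [r for r in records if r.mask is not None]
    manifest = split_manifest(DatasetManifest(records=full, seed=seed))
    train = manifest.subset("train")
    val = manifest.subset("val")
    test = manifest.subset("test")

    need_teacher = any(ARMS[a].uses_teacher for a in arms)
    teacher_res = TeacherPretraining(weak, BENCH_NET, teacher_config(seed)).fit()
    checksum_before = teacher_res.teacher.checksum() if need_teacher else None

    arm_results, arm_iou = {}, {}
    for arm in arms:
        res = StudentDistillation(
            train, BENCH_NET, student_config(seed, arm),
            teacher=teacher_res.teacher if ARMS[arm].uses_teacher else None,
            val_records=val).fit()
        arm_results[arm] = res
        arm_iou[arm] = res.evaluate(test).iou

    frozen = (checksum_before is None
              or teacher_res.teacher.checksum() == checksum_before)
    return BenchmarkRun(seed=seed, teacher_results=teacher_res,
                        teacher_frozen=frozen, arm_results=arm_results,
                        arm_test_iou=arm_iou)


def run_seed_sweep(seeds: list[int],
                   arms: tuple[str, ...] = ("unet", "aaws")) -> pd.DataFrame:
    """Benchmark every seed; rows carry per-arm test IoU and teacher stats."""
    rows = []
    for seed in seeds:
        run = run_benchmark(seed, arms=arms)
        row = {"seed": seed,
               "teacher_val_reduction": run.teacher_val_loss_reduction,
               "teacher_frozen": run.teacher_frozen}
        for arm, iou in run.arm_test_iou.items():
            row[f"iou_{arm}"] = iou
        rows.append(row)
    return pd.DataFrame(rows)
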