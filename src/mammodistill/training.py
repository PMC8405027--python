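"""Two-phase training: teacher pretraining, student distillation, ablations.

The workflow mirrors the weakly-supervised distillation protocol:

1. **Teacher pretraining** — an auto-encoder with a pathology head is
   trained on weakly-annotated tiles (label, no mask) to minimize
   ``L_T = L1 + CE``.
2. **Student distillation** — a U-Net is trained on the fully-annotated
   subset to minimize ``L_S = alpha*L_KD + (1-alpha)*L_GT + lam*L_KL``
   while the teacher stays frozen (its weights are never touched by the
   optimizer; byte-identity is checkable via ``Teacher.checksum``).

Both phases are exposed as model objects whose ``fit()`` returns a
results object carrying the trained network, the per-epoch loss history
as a DataFrame, and a ``summary()`` table; thin functional wrappers
(:func:`pretrain_teacher`, :func:`train_student`, :func:`run_ablation`)
cover script-style use.  The seven-arm ablation harness retrains the
student under every combination of architecture, reconstruction
pretraining and distillation losses on a shared split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import losses as L
from .data import DatasetManifest, SampleRecord, random_flip, split as split_manifest
from .metrics import binarize, evaluate_masks
from .networks import NetConfig, Student, Teacher, build_student, build_teacher
from .nn import Adam
from .nn.layers import sigmoid


class TrainConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings shared by both phases."""

    epochs_max: int = 50
    batch_size: int = 8
    learning_rate: float = 1e-3
    early_stop_patience: int = 10
    min_delta: float = 1e-4
    seed: int = 0
    distill: L.DistillConfig = field(default_factory=L.DistillConfig)
    arm: str = "aaws"
    augment: bool = True
    val_fraction: float = 0.1

    def __post_init__(self):
        if self.epochs_max < 1:
            raise TrainConfigError(f"epochs_max must be >= 1, got {self.epochs_max}")
        if self.early_stop_patience < 1:
            raise TrainConfigError(
                f"early_stop_patience must be >= 1, got {self.early_stop_patience}")
        if self.batch_size < 1:
            raise TrainConfigError(f"batch_size must be >= 1, got {self.batch_size}")


@dataclass(frozen=True)
class AblationArm:
    """One row of the ablation table and the flags that define it."""

    name: str
    architecture: str              # "unet" or "skipless"
    uses_pretrained_encoder: bool  # init from a reconstruction-pretrained copy
    uses_kd: bool                  # class-level distillation loss active
    uses_kl: bool                  # bottleneck KL loss active

    @property
    def uses_teacher(self) -> bool:
        return self.uses_kd or self.uses_kl


ARMS: dict[str, AblationArm] = {
    "unet": AblationArm("unet", "unet", False, False, False),
    "unet_pre": AblationArm("unet_pre", "unet", True, False, False),
    "ae": AblationArm("ae", "skipless", False, False, False),
    "ae_pre": AblationArm("ae_pre", "skipless", True, False, False),
    "without_kd": AblationArm("without_kd", "unet", False, False, True),
    "without_kl": AblationArm("without_kl", "unet", False, True, False),
    "aaws": AblationArm("aaws", "unet", False, True, True),
}

ARM_ORDER = ["unet", "unet_pre", "ae", "ae_pre", "without_kd", "without_kl", "aaws"]


def _stack_images(records: list[SampleRecord]) -> np.ndarray:
    return np.stack([r.image for r in records]).astype(np.float32)


def _train_val_partition(records: list[SampleRecord], seed: int,
                         val_fraction: float) -> tuple[list, list]:
    """Seeded shuffle-split used inside a phase when no explicit split exists."""
    n = len(records)
    n_val = max(1, int(np.floor(val_fraction * n))) if n > 1 else 0
    order = np.random.default_rng([seed, 91]).permutation(n)
    val_idx = set(order[:n_val].tolist())
    train = [records[i] for i in range(n) if i not in val_idx]
    val = [records[i] for i in range(n) if i in val_idx]
    return train, val


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


# ---------------------------------------------------------------------------
# Phase 1: teacher pretraining


class TeacherPretraining:
    """Reconstruction + classification pretraining on weakly-annotated data.

    ``architecture`` selects the skipless auto-encoder (the teacher
    proper) or the U-Net topology (used by the reconstruction-pretrained
    U-Net ablation arm).  Every record must carry a pathology label.
    """

    def __init__(self, records: list[SampleRecord], net_config: NetConfig,
                 train_config: TrainConfig, architecture: str = "skipless"):
        for r in records:
            if r.label is None:
                raise ValueError(
                    f"record {r.id} has no pathology label; the classification "
                    "term of the teacher loss is undefined")
        if architecture not in ("skipless", "unet"):
            raise ValueError(f"unknown architecture {architecture!r}")
        self.records = [r.materialize() for r in records]
        self.net_config = net_config
        self.train_config = train_config
        self.architecture = architecture

    def _epoch_losses(self, model, recs: list[SampleRecord]) -> tuple[float, float]:
        """Mean L1 and CE over records, no augmentation, no gradients."""
        cfg = self.train_config
        l1s, ces = [], []
        imgs = _stack_images(recs)
        labels = [r.label_index for r in recs]
        for start in range(0, len(recs), cfg.batch_size):
            xb = imgs[start:start + cfg.batch_size]
            zb = labels[start:start + cfg.batch_size]
            out = model.net.forward(xb)
            recon = sigmoid(out["dense_logits"])
            l1s.extend(L.l1_loss_per_sample(recon, xb.astype(np.float64)))
            probs = L.soft_targets(out["class_logits"], T=1.0)
            ces.extend(L.ce_loss(probs[i, 1], z) for i, z in enumerate(zb))
        return float(np.mean(l1s)), float(np.mean(ces))

    def fit(self) -> "TeacherResults":
        cfg = self.train_config
        train, val = _train_val_partition(self.records, cfg.seed, cfg.val_fraction)
        if self.architecture == "skipless":
            model = build_teacher(self.net_config, seed=cfg.seed)
        else:
            model = build_student(self.net_config, seed=cfg.seed, skips=True)
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng([cfg.seed, 17])

        rows = []
        v_l1, v_ce = self._epoch_losses(model, val)
        rows.append({"epoch": 0, "train_l1": np.nan, "train_ce": np.nan,
                     "train_lt": np.nan, "val_l1": v_l1, "val_ce": v_ce,
                     "val_lt": L.teacher_loss(v_l1, v_ce)})
        best_val = rows[0]["val_lt"]
        best_state = model.state_dict()
        best_epoch = 0
        since_best = 0

        imgs = _stack_images(train)
        labels = np.array([r.label_index for r in train])
        for epoch in range(1, cfg.epochs_max + 1):
            ep_l1, ep_ce, n_seen = 0.0, 0.0, 0
            for idx in _batches(len(train), cfg.batch_size, rng):
                xb = imgs[idx]
                if cfg.augment:
                    xb = np.stack([random_flip(x, None, rng)[0] for x in xb])
                zb = labels[idx]
                B = len(idx)
                out = model.net.forward(xb)

                g_dense = np.stack([
                    L.grad_l1_wrt_recon_logits(out["dense_logits"][i], xb[i])
                    for i in range(B)]) / B
                g_class = np.stack([
                    L.grad_ce_wrt_logits(out["class_logits"][i], int(zb[i]))
                    for i in range(B)]) / B
                opt.zero_grad()
                model.net.backward(g_dense=g_dense, g_class=g_class)
                opt.step()

                recon = sigmoid(out["dense_logits"])
                ep_l1 += float(np.sum(L.l1_loss_per_sample(recon, xb.astype(np.float64))))
                probs = L.soft_targets(out["class_logits"], T=1.0)
                ep_ce += float(sum(L.ce_loss(probs[i, 1], int(zb[i])) for i in range(B)))
                n_seen += B

            t_l1, t_ce = ep_l1 / n_seen, ep_ce / n_seen
            v_l1, v_ce = self._epoch_losses(model, val)
            v_lt = L.teacher_loss(v_l1, v_ce)
            rows.append({"epoch": epoch, "train_l1": t_l1, "train_ce": t_ce,
                         "train_lt": L.teacher_loss(t_l1, t_ce),
                         "val_l1": v_l1, "val_ce": v_ce, "val_lt": v_lt})
            if v_lt < best_val - cfg.min_delta:
                best_val, best_epoch, since_best = v_lt, epoch, 0
                best_state = model.state_dict()
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break

        model.load_state_dict(best_state)
        return TeacherResults(model=model, history=pd.DataFrame(rows),
                              best_epoch=best_epoch, best_val_loss=best_val,
                              net_config=self.net_config,
                              train_config=cfg, architecture=self.architecture)


@dataclass
class TeacherResults:
    model: Teacher | Student
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    net_config: NetConfig
    train_config: TrainConfig
    architecture: str

    @property
    def teacher(self) -> Teacher:
        if self.architecture != "skipless":
            raise ValueError("this pretraining used the U-Net topology; "
                             "it cannot serve as the distillation teacher")
        return self.model

    @property
    def initial_val_loss(self) -> float:
        return float(self.history.iloc[0]["val_lt"])

    @property
    def val_loss_reduction(self) -> float:
        """Fractional drop of validation L_T from the untrained network."""
        v0 = self.initial_val_loss
        return (v0 - self.best_val_loss) / v0 if v0 > 0 else 0.0

    def save(self, path: str) -> None:
        from .networks import save_checkpoint

        save_checkpoint(path, self.model)

    def summary(self) -> str:
        lines = [
            "Teacher pretraining results",
            "===========================",
            f"architecture        : {self.architecture}",
            f"epochs run          : {int(self.history['epoch'].max())}",
            f"best epoch          : {self.best_epoch}",
            f"initial val L_T     : {self.initial_val_loss:.4f}",
            f"best val L_T        : {self.best_val_loss:.4f}",
            f"val L_T reduction   : {100 * self.val_loss_reduction:.1f}%",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Phase 2: student distillation


class _TeacherCache:
    """Precomputed frozen-teacher outputs per record and flip orientation."""

    def __init__(self, teacher: Teacher, T: float):
        self.teacher = teacher
        self.T = T
        self._store: dict[tuple[str, bool], tuple] = {}

    def populate(self, records: list[SampleRecord], flipped: bool) -> None:
        todo = [r for r in records if (r.id, flipped) not in self._store]
        if not todo:
            return
        imgs = _stack_images(todo)
        if flipped:
            imgs = imgs[:, :, ::-1].copy()
        for start in range(0, len(todo), 16):
            chunk = todo[start:start + 16]
            out = self.teacher.net.forward(imgs[start:start + 16])
            rho = L.soft_targets(out["class_logits"], self.T)
            q = L.soft_targets(out["bottleneck_flat"], T=1.0)
            for i, r in enumerate(chunk):
                rho_star = np.zeros_like(rho[i])
                rho_star[np.argmax(rho[i])] = 1.0
                self._store[(r.id, flipped)] = (rho[i], rho_star, q[i])

    def get(self, rec_id: str, flipped: bool):
        return self._store[(rec_id, flipped)]


class StudentDistillation:
    """Segmentation training of the student under one ablation arm.

    ``records`` must be fully annotated (mask present); the frozen
    ``teacher`` is required whenever the arm uses a distillation loss.
    ``init_state`` optionally seeds the weights from a
    reconstruction-pretrained copy of the same architecture.
    """

    def __init__(self, records: list[SampleRecord], net_config: NetConfig,
                 train_config: TrainConfig, teacher: Teacher | None = None,
                 init_state: dict | None = None,
                 val_records: list[SampleRecord] | None = None):
        cfg = train_config
        if cfg.arm not in ARMS:
            raise TrainConfigError(
                f"unknown ablation arm {cfg.arm!r}; expected one of {ARM_ORDER}")
        self.arm = ARMS[cfg.arm]
        for r in records:
            if r.mask is None and r.mask_path is None:
                raise ValueError(f"record {r.id} has no mask; the ground-truth "
                                 "segmentation loss is undefined")
        if self.arm.uses_teacher:
            if teacher is None:
                raise ValueError(f"arm {self.arm.name!r} requires a pretrained teacher")
            if teacher.cfg.bottleneck_len != net_config.bottleneck_len:
                raise ValueError(
                    f"teacher bottleneck length {teacher.cfg.bottleneck_len} does not "
                    f"match student {net_config.bottleneck_len}")
            if self.arm.uses_kd:
                for r in records:
                    if r.label is None:
                        raise ValueError(
                            f"record {r.id} has no label; the distillation "
                            "loss needs teacher soft targets per pathology class")
        self.records = [r.materialize() for r in records]
        self.val_records = [r.materialize() for r in val_records] if val_records else None
        self.net_config = net_config
        self.train_config = cfg
        self.teacher = teacher if self.arm.uses_teacher else None
        self.init_state = init_state

    @property
    def effective_distill(self) -> L.DistillConfig:
        """Arm-adjusted weights: excluded losses get exactly zero weight."""
        d = self.train_config.distill
        alpha = d.alpha if self.arm.uses_kd else 0.0
        lam = d.lam if self.arm.uses_kl else 0.0
        return L.DistillConfig(T=d.T, alpha=alpha, lam=lam)

    def _eval_losses(self, model: Student, recs, cache) -> dict:
        dc = self.effective_distill
        imgs = _stack_images(recs)
        gts, kds, kls = [], [], []
        for start in range(0, len(recs), self.train_config.batch_size):
            chunk = recs[start:start + self.train_config.batch_size]
            xb = imgs[start:start + len(chunk)]
            out = model.net.forward(xb)
            probs = sigmoid(out["dense_logits"])
            for i, r in enumerate(chunk):
                gts.append(L.gt_loss(r.mask, probs[i]))
                if self.teacher is not None:
                    rho, rho_star, q = cache.get(r.id, False)
                    if self.arm.uses_kd:
                        s_class = sigmoid(out["class_logits"][i])
                        kds.append(L.kd_loss(rho, rho_star, s_class))
                    if self.arm.uses_kl:
                        p = L.soft_targets(out["bottleneck_flat"][i], T=1.0)
                        kls.append(L.kl_loss(p, q))
        gt = float(np.mean(gts))
        kd = float(np.mean(kds)) if kds else np.nan
        kl = float(np.mean(kls)) if kls else np.nan
        ls = L.student_loss(0.0 if np.isnan(kd) else kd, gt,
                            0.0 if np.isnan(kl) else kl, dc)
        return {"l_gt": gt, "l_kd": kd, "l_kl": kl, "l_s": ls}

    def fit(self) -> "StudentResults":
        cfg = self.train_config
        dc = self.effective_distill
        if self.val_records is not None:
            train, val = self.records, self.val_records
        else:
            train, val = _train_val_partition(self.records, cfg.seed, cfg.val_fraction)

        model = build_student(self.net_config, seed=cfg.seed,
                              skips=self.arm.architecture == "unet")
        if self.arm.uses_pretrained_encoder:
            if self.init_state is None:
                raise ValueError(f"arm {self.arm.name!r} needs init_state from a "
                                 "reconstruction-pretrained network")
            model.load_state_dict(self.init_state)
        opt = Adam(model.parameters(), lr=cfg.learning_rate)
        rng = np.random.default_rng([cfg.seed, 23])

        teacher_checksum_before = self.teacher.checksum() if self.teacher else None
        cache = None
        if self.teacher is not None:
            cache = _TeacherCache(self.teacher, dc.T)
            cache.populate(train, False)
            if cfg.augment:
                cache.populate(train, True)
            cache.populate(val, False)

        imgs = _stack_images(train)
        masks = np.stack([r.mask for r in train]).astype(np.float64)
        rows = []
        best_val = np.inf
        best_state = model.state_dict()
        best_epoch = 0
        since_best = 0

        for epoch in range(1, cfg.epochs_max + 1):
            ep = {"l_gt": 0.0, "l_kd": 0.0, "l_kl": 0.0}
            n_seen = 0
            for idx in _batches(len(train), cfg.batch_size, rng):
                B = len(idx)
                xb, mb, flips = [], [], []
                for i in idx:
                    x, m = imgs[i], masks[i]
                    flipped = False
                    if cfg.augment and rng.random() < 0.5:
                        x, m = x[:, ::-1].copy(), m[:, ::-1].copy()
                        flipped = True
                    xb.append(x)
                    mb.append(m)
                    flips.append(flipped)
                xb = np.stack(xb)
                out = model.net.forward(xb)

                g_dense = np.zeros_like(out["dense_logits"], dtype=np.float64)
                g_class = None
                g_bott = None
                probs = sigmoid(out["dense_logits"])
                for i in range(B):
                    ep["l_gt"] += L.gt_loss(mb[i], probs[i])
                    g_dense[i] = L.grad_gt_wrt_seg_logits(mb[i], out["dense_logits"][i])
                g_dense *= (1.0 - dc.alpha) / B

                if self.arm.uses_kd:
                    g_class = np.zeros_like(out["class_logits"], dtype=np.float64)
                    for i, j in enumerate(idx):
                        rho, rho_star, _ = cache.get(train[j].id, flips[i])
                        s_class = sigmoid(out["class_logits"][i])
                        ep["l_kd"] += L.kd_loss(rho, rho_star, s_class)
                        g_class[i] = L.grad_kd_wrt_class_logits(
                            rho, rho_star, out["class_logits"][i])
                    g_class *= dc.alpha / B

                if self.arm.uses_kl:
                    g_bott = np.zeros_like(out["bottleneck_flat"], dtype=np.float64)
                    for i, j in enumerate(idx):
                        _, _, q = cache.get(train[j].id, flips[i])
                        p = L.soft_targets(out["bottleneck_flat"][i], T=1.0)
                        ep["l_kl"] += L.kl_loss(p, q)
                        g_bott[i] = p - q
                    g_bott *= dc.lam / B

                opt.zero_grad()
                model.net.backward(g_dense=g_dense, g_class=g_class,
                                   g_bottleneck_flat=g_bott)
                opt.step()
                n_seen += B

            t_gt = ep["l_gt"] / n_seen
            t_kd = ep["l_kd"] / n_seen if self.arm.uses_kd else np.nan
            t_kl = ep["l_kl"] / n_seen if self.arm.uses_kl else np.nan
            t_ls = L.student_loss(0.0 if np.isnan(t_kd) else t_kd, t_gt,
                                  0.0 if np.isnan(t_kl) else t_kl, dc)
            v = self._eval_losses(model, val, cache)
            rows.append({"epoch": epoch,
                         "train_l_gt": t_gt, "train_l_kd": t_kd,
                         "train_l_kl": t_kl, "train_l_s": t_ls,
                         "val_l_gt": v["l_gt"], "val_l_kd": v["l_kd"],
                         "val_l_kl": v["l_kl"], "val_l_s": v["l_s"]})
            if v["l_s"] < best_val - cfg.min_delta:
                best_val, best_epoch, since_best = v["l_s"], epoch, 0
                best_state = model.state_dict()
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break

        model.load_state_dict(best_state)
        if self.teacher is not None:
            assert self.teacher.checksum() == teacher_checksum_before, \
                "frozen teacher was modified during student training"
        return StudentResults(model=model, history=pd.DataFrame(rows),
                              best_epoch=best_epoch, best_val_loss=best_val,
                              arm=self.arm, net_config=self.net_config,
                              train_config=cfg,
                              distill=dc,
                              teacher_checksum=teacher_checksum_before)


@dataclass
class StudentResults:
    model: Student
    history: pd.DataFrame
    best_epoch: int
    best_val_loss: float
    arm: AblationArm
    net_config: NetConfig
    train_config: TrainConfig
    distill: L.DistillConfig
    teacher_checksum: int | None = None

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Segmentation probability maps for a batch (or single) image."""
        single = np.asarray(images).ndim == 2
        x = np.asarray(images, dtype=np.float32)
        if single:
            x = x[None]
        out = []
        for start in range(0, len(x), 16):
            res = self.model.forward(x[start:start + 16])
            out.append(sigmoid(res.seg_logits))
        probs = np.concatenate(out, axis=0)
        return probs[0] if single else probs

    def evaluate(self, records: list[SampleRecord],
                 aggregation: str = "per_image_mean"):
        if not records:
            raise ValueError("no records to evaluate")
        recs = [r.materialize() for r in records]
        probs = self.predict(_stack_images(recs))
        preds = [binarize(p) for p in probs]
        gts = [r.mask for r in recs]
        return evaluate_masks(preds, gts, aggregation=aggregation)

    def save(self, path: str) -> None:
        from .networks import save_checkpoint

        save_checkpoint(path, self.model)

    def summary(self) -> str:
        lines = [
            "Student distillation results",
            "============================",
            f"arm                 : {self.arm.name}",
            f"architecture        : {self.arm.architecture}",
            f"alpha / lambda / T  : {self.distill.alpha} / {self.distill.lam} / {self.distill.T}",
            f"epochs run          : {len(self.history)}",
            f"best epoch          : {self.best_epoch}",
            f"best val L_S        : {self.best_val_loss:.4f}",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Ablation harness


class AblationStudy:
    """Train all seven ablation arms on one shared split and seed.

    ``records`` mixes weakly-annotated tiles (label only — teacher
    pretraining material) and fully-annotated tiles (mask + label —
    student material).  Every arm sees identical train/val/test splits of
    the fully-annotated subset, so the comparison isolates architecture
    and loss choices.
    """

    def __init__(self, records: list[SampleRecord], net_config: NetConfig,
                 base_config: TrainConfig, arms: list[str] | None = None):
        self.weak = [r for r in records if r.mask is None and r.mask_path is None]
        self.full = [r for r in records if not (r.mask is None and r.mask_path is None)]
        if not self.full:
            raise ValueError("ablation needs a fully-annotated subset")
        self.net_config = net_config
        self.base_config = base_config
        self.arm_names = list(arms) if arms is not None else list(ARM_ORDER)
        unknown = set(self.arm_names) - set(ARMS)
        if unknown:
            raise TrainConfigError(f"unknown arms: {sorted(unknown)}")

    def run(self, aggregation: str = "per_image_mean") -> "AblationResults":
        cfg = self.base_config
        manifest = split_manifest(DatasetManifest(
            records=self.full, split_fractions=(0.8, 0.1, 0.1), seed=cfg.seed))
        train = manifest.subset("train")
        val = manifest.subset("val")
        test = manifest.subset("test")

        need_teacher = any(ARMS[a].uses_teacher or
                           (ARMS[a].uses_pretrained_encoder and
                            ARMS[a].architecture == "skipless")
                           for a in self.arm_names)
        need_unet_pre = any(ARMS[a].uses_pretrained_encoder and
                            ARMS[a].architecture == "unet" for a in self.arm_names)
        teacher_res = None
        unet_pre_res = None
        if need_teacher:
            if not self.weak:
                raise ValueError("arms using the teacher need weakly-annotated records")
            teacher_res = TeacherPretraining(
                self.weak, self.net_config, cfg, architecture="skipless").fit()
        if need_unet_pre:
            if not self.weak:
                raise ValueError("pretrained arms need weakly-annotated records")
            unet_pre_res = TeacherPretraining(
                self.weak, self.net_config, cfg, architecture="unet").fit()

        rows = []
        per_arm: dict[str, StudentResults] = {}
        for name in self.arm_names:
            arm = ARMS[name]
            init_state = None
            if arm.uses_pretrained_encoder:
                src = teacher_res if arm.architecture == "skipless" else unet_pre_res
                init_state = src.model.state_dict()
            trainer = StudentDistillation(
                train, self.net_config, replace(cfg, arm=name),
                teacher=teacher_res.teacher if arm.uses_teacher else None,
                init_state=init_state, val_records=val)
            res = trainer.fit()
            per_arm[name] = res
            rep = res.evaluate(test, aggregation=aggregation)
            rows.append({"arm": name, "iou": rep.iou, "re": rep.re, "f1": rep.f1,
                         "ac": rep.ac, "sp": rep.sp})
        table = pd.DataFrame(rows).set_index("arm")
        return AblationResults(table=table, per_arm=per_arm,
                               teacher=teacher_res,
                               test_ids=[r.id for r in test])


@dataclass
class AblationResults:
    table: pd.DataFrame
    per_arm: dict[str, StudentResults]
    teacher: TeacherResults | None
    test_ids: list[str]

    def summary(self) -> str:
        lines = ["Ablation study (test-split segmentation metrics)",
                 "================================================",
                 self.table[["iou", "re", "f1"]].round(4).to_string()]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# Functional wrappers


def pretrain_teacher(records: list[SampleRecord], net_config: NetConfig,
                     train_config: TrainConfig) -> TeacherResults:
    """Phase-1 wrapper: pretrain the auto-encoder teacher on weak data."""
    return TeacherPretraining(records, net_config, train_config,
                              architecture="skipless").fit()


def train_student(teacher: Teacher | None, records: list[SampleRecord],
                  net_config: NetConfig, train_config: TrainConfig,
                  **kwargs) -> StudentResults:
    """Phase-2 wrapper: distill (or plainly train) the student."""
    return StudentDistillation(records, net_config, train_config,
                               teacher=teacher, **kwargs).fit()


def run_ablation(records: list[SampleRecord], net_config: NetConfig,
                 base_config: TrainConfig, arms: list[str] | None = None,
                 aggregation: str = "per_image_mean") -> AblationResults:
    """Train and evaluate every ablation arm on a shared split."""
    return AblationStudy(records, net_config, base_config, arms=arms).run(
        aggregation=aggregation)
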