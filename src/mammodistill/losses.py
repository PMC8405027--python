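"""Loss terms of the teacher-student distillation framework.

The teacher (an auto-encoder with a pathology-classification head) is
trained with ``L_T = L1(reconstruction) + CE(classification)``.  The
student (a U-Net) is trained with an affine combination of three terms::

    L_S = alpha * L_KD + (1 - alpha) * L_GT + lam * L_KL

where ``L_GT`` is a Dice+BCE segmentation loss against the ground-truth
mask, ``L_KD`` is a Dice+BCE distillation loss between the teacher's
temperature-softened class probabilities and the student's auxiliary class
probabilities, and ``L_KL`` is a KL divergence pulling the student's
softmax-normalized bottleneck toward the teacher's.

All functions are pure numpy, use natural logarithms, clip probabilities
at ``CLIP_EPS`` before any log, and smooth the Dice ratio with
``DICE_EPS``.  Each also has a ``*_per_sample`` variant where a batched,
unreduced view is useful for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CLIP_EPS = 1e-7
DICE_EPS = 1e-6


@dataclass(frozen=True)
class DistillConfig:
    """Distillation hyper-parameters.

    T : softmax temperature for the teacher's soft targets (>0).
    alpha : weight of the distillation term in [0, 1]; 1-alpha weights the
        ground-truth segmentation term.
    lam : nonnegative weight of the bottleneck KL term.
    """

    T: float = 2.0
    alpha: float = 0.5
    lam: float = 0.1

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.lam < 0:
            raise ValueError(f"lam must be >= 0, got {self.lam}")


@dataclass
class LossBreakdown:
    """Per-step record of every loss component."""

    l1: float = np.nan
    ce: float = np.nan
    kl: float = np.nan
    kd: float = np.nan
    gt: float = np.nan
    total_teacher: float = np.nan
    total_student: float = np.nan


def soft_targets(logits: np.ndarray, T: float) -> np.ndarray:
    """Temperature softmax ``exp(tau_i/T) / sum_j exp(tau_j/T)``.

    With T=1 this is the ordinary softmax; large T flattens the
    distribution toward uniform.  Works on a vector or a batch of vectors
    (softmax over the last axis).
    """
    if not T > 0:
        raise ValueError(f"temperature must be > 0, got {T}")
    z = np.asarray(logits, dtype=np.float64) / T
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def l1_loss(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean absolute reconstruction error over all pixels."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    return float(np.mean(np.abs(y - y_hat)))


def ce_loss(z_hat: float, z: int) -> float:
    """Binary cross-entropy ``-z log(z_hat) - (1-z) log(1-z_hat)``.

    ``z_hat`` is the predicted probability of the positive (malignant)
    class; ``z`` the binary label.  The probability is clipped to
    ``[CLIP_EPS, 1-CLIP_EPS]`` so endpoint predictions stay finite.
    """
    if z not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {z}")
    p = float(np.clip(z_hat, CLIP_EPS, 1.0 - CLIP_EPS))
    return float(-(z * np.log(p) + (1 - z) * np.log(1.0 - p)))


def teacher_loss(l1: float, ce: float) -> float:
    """Teacher total: unweighted sum of reconstruction L1 and classification CE."""
    return float(l1) + float(ce)


def kl_loss(p: np.ndarray, q: np.ndarray) -> float:
    """KL divergence ``sum_j q_j log(q_j / p_j)`` (teacher q as reference).

    Both arguments must be probability vectors of equal length; the student
    distribution ``p`` is the one being pulled toward ``q``.
    """
    p = np.asarray(p, dtype=np.float64)
    q = np.asarray(q, dtype=np.float64)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    pc = np.clip(p, CLIP_EPS, None)
    qc = np.clip(q, CLIP_EPS, None)
    return float(np.sum(np.where(q > 0, q * (np.log(qc) - np.log(pc)), 0.0)))


def soft_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Smoothed Dice overlap ``(2*sum(a*b)+eps) / (sum(a)+sum(b)+eps)``.

    Accepts probability maps or vectors with entries in [0, 1]; equals 1
    for identical binary masks and ~0 for disjoint ones.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    num = 2.0 * np.sum(a * b) + DICE_EPS
    den = np.sum(a) + np.sum(b) + DICE_EPS
    return float(num / den)


def _bce_mean(target: np.ndarray, prob: np.ndarray) -> float:
    t = np.asarray(target, dtype=np.float64)
    p = np.clip(np.asarray(prob, dtype=np.float64), CLIP_EPS, 1.0 - CLIP_EPS)
    return float(np.mean(-(t * np.log(p) + (1.0 - t) * np.log(1.0 - p))))


def kd_loss(rho: np.ndarray, rho_star: np.ndarray, student_class_probs: np.ndarray) -> float:
    """Knowledge-distillation loss at the class-vector level.

    ``(1 - Dice(rho, sigma(tau_s))) + BCE(rho*, sigma(tau_s))`` where
    ``rho`` is the teacher's temperature-softened class distribution,
    ``rho_star`` its one-hot binarization (BCE cannot consume soft labels),
    and ``student_class_probs`` the elementwise-logistic activation of the
    student's auxiliary class logits.
    """
    rho = np.asarray(rho, dtype=np.float64)
    rho_star = np.asarray(rho_star, dtype=np.float64)
    s = np.asarray(student_class_probs, dtype=np.float64)
    if not (rho.shape == rho_star.shape == s.shape):
        raise ValueError("rho, rho_star and student probabilities must share a shape")
    if not (np.all(np.isin(rho_star, (0.0, 1.0))) and rho_star.sum() == 1.0):
        raise ValueError("rho_star must be one-hot")
    return (1.0 - soft_dice(rho, s)) + _bce_mean(rho_star, s)


def gt_loss(gt_mask: np.ndarray, student_seg_probs: np.ndarray) -> float:
    """Ground-truth segmentation loss: ``(1 - Dice) + pixel-mean BCE``."""
    m = np.asarray(gt_mask, dtype=np.float64)
    p = np.asarray(student_seg_probs, dtype=np.float64)
    if m.shape != p.shape:
        raise ValueError(f"shape mismatch: {m.shape} vs {p.shape}")
    return (1.0 - soft_dice(m, p)) + _bce_mean(m, p)


def student_loss(kd: float, gt: float, kl: float, cfg: DistillConfig) -> float:
    """Student total ``alpha*kd + (1-alpha)*gt + lam*kl``."""
    return cfg.alpha * kd + (1.0 - cfg.alpha) * gt + cfg.lam * kl


# ---------------------------------------------------------------------------
# Unreduced / per-sample variants


def l1_loss_per_sample(y_hat: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample mean absolute error for batched maps (batch first)."""
    y_hat = np.asarray(y_hat, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    return np.abs(y - y_hat).reshape(y.shape[0], -1).mean(axis=1)


def gt_loss_per_sample(gt_masks: np.ndarray, probs: np.ndarray) -> np.ndarray:
    """Dice+BCE per sample for batched masks/probability maps."""
    return np.array([gt_loss(m, p) for m, p in zip(gt_masks, probs)])


def kd_loss_per_sample(rhos: np.ndarray, rho_stars: np.ndarray, probs: np.ndarray) -> np.ndarray:
    return np.array([kd_loss(r, rs, p) for r, rs, p in zip(rhos, rho_stars, probs)])


def ce_loss_per_sample(z_hats: np.ndarray, zs: np.ndarray) -> np.ndarray:
    return np.array([ce_loss(float(zh), int(z)) for zh, z in zip(z_hats, zs)])


def kl_loss_per_sample(ps: np.ndarray, qs: np.ndarray) -> np.ndarray:
    return np.array([kl_loss(p, q) for p, q in zip(ps, qs)])


# ---------------------------------------------------------------------------
# Analytic gradients used by the training loops.  Each returns the gradient
# of the scalar loss with respect to the *logits* feeding it (chain rules
# through sigmoid/softmax are folded in).


def grad_ce_wrt_logits(class_logits: np.ndarray, z: int) -> np.ndarray:
    """d CE / d logits for a softmax classifier whose positive-class
    probability is fed to :func:`ce_loss`."""
    p = soft_targets(class_logits, T=1.0)
    onehot = np.zeros_like(p)
    onehot[..., z] = 1.0
    return p - onehot


def grad_l1_wrt_recon_logits(recon_logits: np.ndarray, y: np.ndarray) -> np.ndarray:
    """d L1 / d logits when the reconstruction is sigmoid(logits)."""
    from .nn.layers import sigmoid

    s = sigmoid(np.asarray(recon_logits, dtype=np.float64))
    n = s.size
    return np.sign(s - y) * s * (1.0 - s) / n


def _grad_dice_term(target: np.ndarray, prob: np.ndarray) -> np.ndarray:
    """d(1 - Dice(target, prob)) / d prob."""
    t = np.asarray(target, dtype=np.float64)
    p = np.asarray(prob, dtype=np.float64)
    num = 2.0 * np.sum(t * p) + DICE_EPS
    den = np.sum(t) + np.sum(p) + DICE_EPS
    return -(2.0 * t * den - num) / (den * den)


def grad_gt_wrt_seg_logits(gt_mask: np.ndarray, seg_logits: np.ndarray) -> np.ndarray:
    """Gradient of :func:`gt_loss` with respect to the segmentation logits."""
    from .nn.layers import sigmoid

    m = np.asarray(gt_mask, dtype=np.float64)
    p = sigmoid(np.asarray(seg_logits, dtype=np.float64))
    g_dice = _grad_dice_term(m, p) * p * (1.0 - p)
    g_bce = (p - m) / m.size
    return g_dice + g_bce


def grad_kd_wrt_class_logits(rho: np.ndarray, rho_star: np.ndarray,
                             class_logits: np.ndarray) -> np.ndarray:
    """Gradient of :func:`kd_loss` with respect to the student class logits."""
    from .nn.layers import sigmoid

    s = sigmoid(np.asarray(class_logits, dtype=np.float64))
    g_dice = _grad_dice_term(np.asarray(rho, dtype=np.float64), s)
    g_bce_prob = (s - np.asarray(rho_star, dtype=np.float64)) / (s * (1.0 - s) + CLIP_EPS) / s.size
    return (g_dice + g_bce_prob) * s * (1.0 - s)


def grad_kl_wrt_student_bottleneck(student_flat: np.ndarray,
                                   teacher_flat: np.ndarray) -> np.ndarray:
    """Gradient of KL(q || softmax(student)) with respect to the raw student
    bottleneck activations; equals softmax(student) - softmax(teacher)."""
    p = soft_targets(student_flat, T=1.0)
    q = soft_targets(teacher_flat, T=1.0)
    return p - q
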