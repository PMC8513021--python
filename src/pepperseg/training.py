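"""End-to-end optimization of the transmittance curve and the segmentation net.

Each step runs the full differentiable chain
``apply_filter -> sense_rgb -> normalize_and_clip -> ratio maps -> U-Net``,
forms ``L_total = L_bce + eta * L_smooth`` and takes one Adam step on all
parameters (filter + network), followed by the non-negativity projection of
the filter weights (projected gradient).  Per epoch the validation mIoU is
recorded and the checkpoint with the best validation mIoU is returned.

The three experiment arms are config flags, not code paths:
(use_filter, use_ratio_maps) = (True, True) for filter + color-ratio maps,
(True, False) for filter only, (False, False) for the raw-camera baseline.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .constraints import second_difference_matrix, smoothness_penalty, project_nonnegative
from .features import feature_stack_t
from .metrics import confusion_counts, f1_score, mean_iou
from .network import GroundTruthMask, UNet, bce_loss, build_network, total_loss
from .nn import Adam, Parameter
from .optics import (CameraResponse, SpectralCube, TransmittanceCurve,
                     estimate_normalization_bounds, gaussian_csr, initial_filter,
                     normalize_and_clip_t, sense_batch_t)

__all__ = ["TrainingConfig", "make_patches", "train", "reduce_lr_on_plateau",
           "predict_probability", "evaluate_scenes", "save_checkpoint",
           "load_checkpoint"]


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults follow the full-scale protocol (Adam at 1e-3 with betas
    (0.5, 0.999), batch 32, 50 epochs, 256-px crops, 70 crops per image,
    horizontal flips at p = 0.5).  ``demo()`` gives the desk-scale variant.
    ``norm_min``/``norm_max`` default to None, meaning: estimate them from the
    training set as 0.1/99.9 percentiles of raw sensed values under the
    initial filter.
    """

    eta: float = 0.001
    norm_min: float | None = None
    norm_max: float | None = None
    epsilon: float = 0.01
    learning_rate: float = 0.001
    adam_betas: tuple = (0.5, 0.999)
    batch_size: int = 32
    epochs: int = 50
    crop_size: int = 256
    crops_per_image: int = 70
    hflip_prob: float = 0.5
    seed: int = 0
    use_ratio_maps: bool = True
    use_filter: bool = True
    base_width: int = 64
    plateau_patience: int = 5
    plateau_factor: float = 0.5
    lr_floor: float = 1e-5
    bound_pcts: tuple = (0.1, 99.9)
    filter_init_level: float = 0.5
    filter_init_jitter: float = 0.05
    per_channel_norm: bool = False

    def __post_init__(self):
        if self.eta < 0:
            raise ValueError("eta must be non-negative")
        if self.crop_size % 16:
            raise ValueError("crop_size must be divisible by 16")
        if min(self.batch_size, self.epochs, self.crops_per_image) < 1:
            raise ValueError("counts must be positive")
        if self.norm_min is not None and self.norm_max is not None \
                and self.norm_max <= self.norm_min:
            raise ValueError("norm_max must exceed norm_min")

    @classmethod
    def demo(cls, **overrides) -> "TrainingConfig":
        """Desk-scale conditions: 64-px frames, width-8 net, 10 epochs.

        The learning rate is 5e-3 rather than 1e-3: the demo takes ~240
        optimizer steps versus ~11000 at full scale, and Adam's step
        displacement is proportional to the rate, so the rate is scaled to
        keep the filter able to traverse its feasible range.
        """
        base = dict(epochs=10, base_width=8, crop_size=64, batch_size=4,
                    crops_per_image=16, learning_rate=5e-3)
        base.update(overrides)
        return cls(**base)

    @property
    def in_channels(self) -> int:
        return 12 if self.use_ratio_maps else 3

    @classmethod
    def from_yaml(cls, path) -> "TrainingConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("adam_betas", "bound_pcts"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        from .io import atomic_write_text

        d = asdict(self)
        d["adam_betas"] = list(self.adam_betas)
        d["bound_pcts"] = list(self.bound_pcts)
        atomic_write_text(path, yaml.safe_dump(d, sort_keys=True))


def make_patches(cube: SpectralCube, mask: GroundTruthMask, cfg: TrainingConfig,
                 rng: np.random.Generator) -> list[tuple[np.ndarray, np.ndarray]]:
    """Aligned random crops with random horizontal flips.

    Returns ``cfg.crops_per_image`` pairs of (cube crop (H, W, N), mask crop);
    a flip is applied identically to cube and mask.
    """
    cs = cfg.crop_size
    if cube.height < cs or cube.width < cs:
        raise ValueError(f"scene {cube.height}x{cube.width} smaller than crop {cs}")
    out = []
    for _ in range(cfg.crops_per_image):
        y0 = int(rng.integers(0, cube.height - cs + 1))
        x0 = int(rng.integers(0, cube.width - cs + 1))
        crop = cube.values[y0:y0 + cs, x0:x0 + cs, :]
        mcrop = mask.values[y0:y0 + cs, x0:x0 + cs]
        if rng.random() < cfg.hflip_prob:
            crop = crop[:, ::-1, :]
            mcrop = mcrop[:, ::-1]
        out.append((np.ascontiguousarray(crop), np.ascontiguousarray(mcrop)))
    return out


def reduce_lr_on_plateau(val_history, rate: float, patience: int = 5,
                         factor: float = 0.5, floor: float = 1e-5) -> float:
    """Replay a plateau schedule over a validation-metric history.

    The rate is multiplied by ``factor`` (not below ``floor``) whenever the
    metric fails to improve for ``patience`` consecutive epochs; the counter
    resets after each reduction.
    """
    if not (0 < factor < 1) or patience < 1:
        raise ValueError("factor must be in (0, 1) and patience >= 1")
    best = -np.inf
    bad = 0
    for v in val_history:
        if v > best:
            best = v
            bad = 0
        else:
            bad += 1
            if bad >= patience:
                rate = max(rate * factor, floor)
                bad = 0
    return rate


class _PlateauScheduler:
    def __init__(self, opt: Adam, patience: int, factor: float, floor: float):
        self.opt = opt
        self.patience, self.factor, self.floor = patience, factor, floor
        self.best = -np.inf
        self.bad = 0

    def step(self, metric: float) -> None:
        if metric > self.best:
            self.best = metric
            self.bad = 0
        else:
            self.bad += 1
            if self.bad >= self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.floor)
                self.bad = 0


def _forward(batch: np.ndarray, weights, csr: CameraResponse, norm: tuple,
             cfg: TrainingConfig, net: UNet) -> Tensor:
    x = Tensor(batch)  # (B, N, H, W)
    raw = sense_batch_t(x, weights, csr)
    sensor = normalize_and_clip_t(raw, norm[0], norm[1], cfg.epsilon)
    feats = feature_stack_t(sensor, cfg.epsilon, cfg.use_ratio_maps)
    return net(feats)


def predict_probability(cube: SpectralCube, weights: np.ndarray,
                        csr: CameraResponse, norm: tuple, cfg: TrainingConfig,
                        net: UNet) -> np.ndarray:
    """Per-pixel pepper probability for one scene (eval-mode network)."""
    was_training = net.training
    net.eval()
    batch = cube.values.transpose(2, 0, 1)[None]
    prob = _forward(batch, Tensor(weights), csr, norm, cfg, net).data[0, 0]
    net.train(was_training)
    return prob


def evaluate_scenes(scenes, weights, csr, norm, cfg, net,
                    threshold: float = 0.5) -> dict:
    """Aggregate mIoU/F1 over scenes plus a per-image breakdown."""
    agg = None
    per_image = []
    for cube, mask in scenes:
        prob = predict_probability(cube, weights, csr, norm, cfg, net)
        pred = (prob >= threshold).astype(np.uint8)
        counts = confusion_counts(pred, mask.values)
        agg = counts if agg is None else agg + counts
        per_image.append({"miou": mean_iou(counts), "f1": f1_score(counts)})
    return {"miou": mean_iou(agg), "f1": f1_score(agg), "per_image": per_image}


def train(train_set, val_set, cfg: TrainingConfig,
          csr: CameraResponse | None = None) -> tuple[dict, dict]:
    """Optimize filter + network; return (best checkpoint, history).

    ``train_set``/``val_set`` are lists of (SpectralCube, GroundTruthMask).
    The checkpoint holds the network state, the filter curve, the CSR, the
    normalization constants and the config; ``history`` records per-epoch
    train loss, validation mIoU, learning rate and filter snapshot, plus the
    post-projection minimum filter weight after every optimizer step.
    """
    if not train_set or not val_set:
        raise ValueError("train and validation sets must be non-empty")
    wavelengths = train_set[0][0].wavelengths
    for cube, _ in list(train_set) + list(val_set):
        if cube.wavelengths.size != wavelengths.size or \
                not np.allclose(cube.wavelengths, wavelengths):
            raise ValueError("all cubes must share one band grid")

    ss = np.random.SeedSequence(cfg.seed)
    init_rng, net_seed_src, data_rng = (np.random.default_rng(s) for s in ss.spawn(3))

    if csr is None:
        csr = gaussian_csr(wavelengths)
    if cfg.use_filter:
        start = initial_filter(wavelengths, init_rng, cfg.filter_init_level,
                               cfg.filter_init_jitter)
        weights = Parameter(start.weights)
    else:
        weights = Tensor(np.ones(wavelengths.size))  # frozen all-pass

    if cfg.norm_min is None or cfg.norm_max is None:
        curve = TransmittanceCurve(weights.data.copy(), wavelengths)
        norm = estimate_normalization_bounds((c for c, _ in train_set), csr, curve,
                                             *cfg.bound_pcts,
                                             per_channel=cfg.per_channel_norm)
    else:
        norm = (cfg.norm_min, cfg.norm_max)

    net_seed = int(net_seed_src.integers(2 ** 31))
    net = build_network(cfg.in_channels, cfg.base_width, seed=net_seed)
    g_matrix = second_difference_matrix(wavelengths.size)

    params = net.parameters() + ([weights] if cfg.use_filter else [])
    opt = Adam(params, lr=cfg.learning_rate, betas=cfg.adam_betas)
    sched = _PlateauScheduler(opt, cfg.plateau_patience, cfg.plateau_factor,
                              cfg.lr_floor)

    history = {"epoch": [], "train_loss": [], "val_miou": [], "lr": [],
               "filter_curves": [], "step_min_weight": [],
               "initial_filter": weights.data.copy()}
    best_miou = -np.inf
    best_state = None
    step_index = 0

    for epoch in range(cfg.epochs):
        patches = []
        for cube, mask in train_set:
            patches.extend(make_patches(cube, mask, cfg, data_rng))
        order = data_rng.permutation(len(patches))

        net.train(True)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            cubes = np.stack([patches[i][0].transpose(2, 0, 1) for i in idx])
            masks = np.stack([patches[i][1] for i in idx])[:, None]
            prob = _forward(cubes, weights, csr, norm, cfg, net)
            bce = bce_loss(prob, masks)
            if cfg.use_filter:
                loss = total_loss(bce, smoothness_penalty(weights, g_matrix), cfg.eta)
            else:
                loss = bce
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite loss at step {step_index}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if cfg.use_filter:
                project_nonnegative(weights)
            history["step_min_weight"].append(float(weights.data.min()))
            losses.append(float(bce.data))
            step_index += 1

        val = evaluate_scenes(val_set, weights.data, csr, norm, cfg, net)
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["val_miou"].append(val["miou"])
        history["lr"].append(opt.lr)
        history["filter_curves"].append(weights.data.copy())
        if val["miou"] > best_miou:
            best_miou = val["miou"]
            best_state = (net.state_dict(), weights.data.copy())
        sched.step(val["miou"])

    net.load_state_dict(best_state[0])
    checkpoint = {
        "net_state": best_state[0],
        "filter": best_state[1],
        "wavelengths": wavelengths.copy(),
        "csr": csr.sensitivities.copy(),
        "norm_min": norm[0],
        "norm_max": norm[1],
        "best_val_miou": best_miou,
        "config": asdict(cfg),
    }
    return checkpoint, history


# -------------------------------------------------------- checkpoint files

_CKPT_VERSION = 1


def save_checkpoint(checkpoint: dict, path) -> None:
    """Serialize a checkpoint to ``.npz`` (versioned, config embedded as JSON)."""
    arrays = {f"net.{k}": v for k, v in checkpoint["net_state"].items()}
    arrays["filter"] = checkpoint["filter"]
    arrays["wavelengths"] = checkpoint["wavelengths"]
    arrays["csr"] = checkpoint["csr"]
    def _jsonable(v):
        return np.asarray(v).tolist() if isinstance(v, np.ndarray) else v

    meta = {
        "version": _CKPT_VERSION,
        "norm_min": _jsonable(checkpoint["norm_min"]),
        "norm_max": _jsonable(checkpoint["norm_max"]),
        "best_val_miou": checkpoint.get("best_val_miou"),
        "config": checkpoint["config"],
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    path = Path(path)
    tmp = path.with_name(path.name + ".tmp.npz")
    np.savez(tmp, **arrays)
    tmp.replace(path)


def load_checkpoint(path) -> tuple[dict, TrainingConfig, UNet]:
    """Load a checkpoint; returns (checkpoint dict, config, ready network)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"]).decode())
        if meta["version"] != _CKPT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta['version']}")
        net_state = {k[4:]: data[k] for k in data.files if k.startswith("net.")}
        checkpoint = {
            "net_state": net_state,
            "filter": data["filter"],
            "wavelengths": data["wavelengths"],
            "csr": data["csr"],
            "norm_min": (np.array(meta["norm_min"]) if isinstance(meta["norm_min"], list)
                         else meta["norm_min"]),
            "norm_max": (np.array(meta["norm_max"]) if isinstance(meta["norm_max"], list)
                         else meta["norm_max"]),
            "best_val_miou": meta["best_val_miou"],
            "config": meta["config"],
        }
    raw = dict(meta["config"])
    for key in ("adam_betas", "bound_pcts"):
        raw[key] = tuple(raw[key])
    cfg = TrainingConfig(**raw)
    net = build_network(cfg.in_channels, cfg.base_width, seed=0)
    net.load_state_dict(net_state)
    net.eval()
    return checkpoint, cfg, net
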