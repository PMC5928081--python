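"""Dataset construction and training for the artifact network.

A training pair is (f, x): the sparse-view FBP reconstruction and the
full-view (720-projection) FBP reconstruction of the same object — the
gold-standard reference.  Both come from the same analytic sinogram, with
views subsampled for f, so the only difference between them is the streak
field the network must learn.  Reconstructions are mapped to stored 12-bit
intensity units (attenuation ``ATTENUATION_FULL_SCALE`` maps to 4095) so
that metrics use the 12-bit peak while the optimizer sees inputs normalized
to roughly [0, 1].
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import metrics as _metrics
from ._nn import Adam
from .artifact_net import NetworkConfig, TrainedModel, correct_image, predict_artifact, residual_loss
from .fbp import fbp_fanbeam
from .phantoms import Image2D, INTENSITY_SCALE_12BIT, sample_random_phantom
from .projector import FanBeamGeometry, forward_project_analytic, subsample_views

__all__ = [
    "PairedDataset",
    "TrainConfig",
    "default_geometry_for",
    "make_dataset",
    "save_dataset",
    "load_dataset",
    "train",
    "evaluate",
    "ATTENUATION_FULL_SCALE",
]

#: Attenuation value mapped to the 12-bit full scale (4095).  Random phantoms
#: peak around 2 (background 1.0 plus overlapping inserts), so typical
#: reconstructions occupy the upper half of the 12-bit range without clipping.
ATTENUATION_FULL_SCALE = 2.5

VIEWS_FULL = 720


@dataclass
class PairedDataset:
    """Sparse/full FBP reconstruction pairs plus the provenance to rebuild them."""

    entries: list
    views_sparse: int
    views_full: int = VIEWS_FULL
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # views_sparse == views_full is allowed as a degenerate test case
        if self.views_full < self.views_sparse:
            raise ValueError("views_full must be >= views_sparse")
        shapes = {(f.size, x.size) for f, x in self.entries}
        if len(shapes) > 1:
            raise ValueError("all pairs must share one image size")

    def __len__(self) -> int:
        return len(self.entries)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stacked (f, x) pixel arrays, stored-intensity units, float64."""
        f = np.stack([e[0].pixels for e in self.entries])
        x = np.stack([e[1].pixels for e in self.entries])
        return f, x


@dataclass
class TrainConfig:
    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    seed: int = 0
    patch_size: int | None = None
    validation_fraction: float = 0.1
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")


def geometry_hash(geometry: FanBeamGeometry) -> str:
    return hashlib.sha256(
        json.dumps(asdict(geometry), sort_keys=True).encode()
    ).hexdigest()[:16]


def default_geometry_for(image_size: int, fov_diameter: float) -> FanBeamGeometry:
    """Scanner geometry with the detector bin count adapted to the grid.

    The bin pitch on the virtual (isocenter) detector is set to about half a
    pixel so detector sampling never limits the reconstruction.
    """
    base = FanBeamGeometry()
    pixel = fov_diameter / image_size
    width_iso = base.detector_width / base.magnification
    n_bins = max(64, int(np.ceil(width_iso / (pixel / 2.0))))
    return FanBeamGeometry(n_detector_bins=n_bins, n_views=VIEWS_FULL)


def make_dataset(
    n_phantoms: int,
    image_size: int,
    views_sparse: int,
    geometry: FanBeamGeometry | None = None,
    seed: int = 0,
    fov_diameter: float = 170.0,
) -> PairedDataset:
    """Simulate (f, x) pairs from seeded random phantoms.

    Per phantom: exact analytic 720-view sinogram -> x = full-view FBP;
    subsample the same sinogram to ``views_sparse`` -> f = sparse FBP.
    Deterministic given ``seed`` (child phantom seeds come from a
    SeedSequence and are recorded in the provenance).
    """
    if n_phantoms < 1:
        raise ValueError("n_phantoms must be >= 1")
    if geometry is None:
        geometry = default_geometry_for(image_size, fov_diameter)
    if geometry.n_views % views_sparse != 0:
        raise ValueError(
            f"views_sparse must divide {geometry.n_views}; got {views_sparse}"
        )
    pixel_size = fov_diameter / image_size
    gain = INTENSITY_SCALE_12BIT / ATTENUATION_FULL_SCALE
    phantom_seeds = [int(s) for s in np.random.SeedSequence(seed).generate_state(n_phantoms)]
    entries = []
    for ps in phantom_seeds:
        phantom = sample_random_phantom(ps, fov_diameter=fov_diameter)
        sino = forward_project_analytic(phantom, geometry)
        x = fbp_fanbeam(sino, image_size, pixel_size)
        f = fbp_fanbeam(subsample_views(sino, views_sparse), image_size, pixel_size)
        for img in (f, x):
            img.pixels = img.pixels * gain
            img.intensity_scale = INTENSITY_SCALE_12BIT
        entries.append((f, x))
    return PairedDataset(
        entries,
        views_sparse=views_sparse,
        views_full=geometry.n_views,
        provenance={
            "seed": seed,
            "phantom_seeds": phantom_seeds,
            "geometry_hash": geometry_hash(geometry),
            "geometry": asdict(geometry),
            "fov_diameter": fov_diameter,
            "image_size": image_size,
        },
    )


def save_dataset(data: PairedDataset, directory) -> None:
    """Write pairs as lossless float containers plus a JSON manifest."""
    from pathlib import Path
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_pairs": len(data),
        "views_sparse": data.views_sparse,
        "views_full": data.views_full,
        "provenance": data.provenance,
        "pixel_size": data.entries[0][0].pixel_size,
        "intensity_scale": data.entries[0][0].intensity_scale,
    }
    (d / "manifest.json").write_text(json.dumps(manifest, indent=2))
    # plain .npy (no zip timestamps): reruns are byte-identical
    for i, (f, x) in enumerate(data.entries):
        np.save(d / f"pair_{i:05d}_f.npy", f.pixels)
        np.save(d / f"pair_{i:05d}_x.npy", x.pixels)


def load_dataset(directory) -> PairedDataset:
    from pathlib import Path
    d = Path(directory)
    manifest = json.loads((d / "manifest.json").read_text())
    entries = []
    kw = dict(
        pixel_size=manifest["pixel_size"],
        intensity_scale=manifest["intensity_scale"],
    )
    for i in range(manifest["n_pairs"]):
        f = np.load(d / f"pair_{i:05d}_f.npy")
        x = np.load(d / f"pair_{i:05d}_x.npy")
        entries.append((Image2D(f, **kw), Image2D(x, **kw)))
    return PairedDataset(
        entries,
        views_sparse=manifest["views_sparse"],
        views_full=manifest["views_full"],
        provenance=manifest["provenance"],
    )


def _split(n: int, fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, seed-stable train/validation index split."""
    perm = np.random.default_rng(seed).permutation(n)
    n_val = int(round(fraction * n))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def train(
    model: TrainedModel, data: PairedDataset, cfg: TrainConfig
) -> tuple[TrainedModel, pd.DataFrame]:
    """Minimize the averaged squared residual loss by seeded mini-batch Adam.

    Returns the trained model (modified in place) and a per-epoch history
    with train and validation loss, both in normalized intensity units.
    Aborts with a diagnostic if the loss goes non-finite.
    """
    if len(data) == 0:
        raise ValueError("dataset is empty")
    f_all, x_all = data.arrays()
    scale = data.entries[0][0].intensity_scale
    dtype = next(iter(model.net.iter_layers())).params["W"].dtype
    f_n = (f_all / scale).astype(dtype)[..., None]
    target = ((f_all - x_all) / scale).astype(dtype)[..., None]

    tr_idx, va_idx = _split(len(data), cfg.validation_fraction, cfg.seed)
    if len(tr_idx) == 0:
        raise ValueError("no training samples after validation split")
    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.net, lr=cfg.learning_rate)
    history = []
    best_val = np.inf
    since_best = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        epoch_loss = 0.0
        n_seen = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            fb, tb = f_n[idx], target[idx]
            if cfg.patch_size is not None:
                fb, tb = _random_patches(fb, tb, cfg.patch_size, rng)
            pred = model.net.forward(fb, training=True)
            # float64 difference: exact for float32 operands, so the reported
            # loss agrees bit-for-bit with the standalone residual_loss
            diff64 = pred.astype(np.float64) - tb.astype(np.float64)
            loss = float(np.sum(diff64 ** 2) / (2 * len(idx)))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss is non-finite"
                )
            model.net.backward((diff64 / len(idx)).astype(dtype))
            opt.step()
            epoch_loss += loss * len(idx)
            n_seen += len(idx)
        val_loss = _eval_loss(model, f_n, target, va_idx, cfg.batch_size)
        history.append({
            "epoch": epoch,
            "train_loss": epoch_loss / n_seen,
            "val_loss": val_loss,
        })
        if cfg.early_stop_patience is not None and len(va_idx) > 0:
            if val_loss < best_val - 1e-12:
                best_val = val_loss
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stop_patience:
                    break
    model.training_meta.update(
        {
            "epochs_run": len(history),
            "final_train_loss": history[-1]["train_loss"],
            "final_val_loss": history[-1]["val_loss"],
            "train_seed": cfg.seed,
            "views_sparse": data.views_sparse,
        }
    )
    return model, pd.DataFrame(history)


def _random_patches(fb, tb, patch, rng):
    n, h, w, _ = fb.shape
    if patch >= h:
        return fb, tb
    fo = np.empty((n, patch, patch, 1), dtype=fb.dtype)
    to = np.empty_like(fo)
    for i in range(n):
        r = int(rng.integers(0, h - patch + 1))
        c = int(rng.integers(0, w - patch + 1))
        fo[i] = fb[i, r:r + patch, c:c + patch]
        to[i] = tb[i, r:r + patch, c:c + patch]
    return fo, to


def _eval_loss(model, f_n, target, idx, batch_size) -> float:
    if len(idx) == 0:
        return float("nan")
    total = 0.0
    for start in range(0, len(idx), batch_size):
        sel = idx[start:start + batch_size]
        pred = model.net.forward(f_n[sel], training=False)
        diff64 = pred.astype(np.float64) - target[sel].astype(np.float64)
        total += float(np.sum(diff64 ** 2)) / 2.0
    return total / len(idx)


def evaluate(model: TrainedModel, data: PairedDataset) -> pd.DataFrame:
    """Per-image and mean PSNR/SSIM before and after correction.

    The full-view FBP reconstruction x is the reference.  "Before" compares
    the raw sparse FBP f against x; "after" compares f - mu(f) against x.
    The last row holds the column means (image_id "mean").
    """
    rows = []
    for i, (f, x) in enumerate(data.entries):
        corrected = correct_image(f, predict_artifact(model, f))
        rows.append({
            "image_id": str(i),
            "psnr_before": _metrics.psnr(f, x, peak=f.intensity_scale),
            "psnr_after": _metrics.psnr(corrected, x, peak=f.intensity_scale),
            "ssim_before": _metrics.ssim(f, x, peak=f.intensity_scale),
            "ssim_after": _metrics.ssim(corrected, x, peak=f.intensity_scale),
        })
    df = pd.DataFrame(rows)
    mean_row = {"image_id": "mean"}
    for col in ("psnr_before", "psnr_after", "ssim_before", "ssim_after"):
        mean_row[col] = float(df[col].mean())
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
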