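"""Batch augmentation workflow: warp, refine, write, report.

Ties the stages together the way they are meant to be used on a
dataset: for every (image, mask) input pair, draw ``n_outputs_per_input``
strain values uniformly from ``s_range``, run the warp (with automated
rejection of folded or region-losing draws), refine the warped mask with
watershed, and write the augmented pair plus a sidecar JSON carrying
everything needed to replay that exact output (derived seed, s, d_min,
keypoints, deltas, retries).  A run report counts successes, retries and
rejections and states the achieved augmentation multiplier.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .fixtures import LabeledPair, MosaicSpec, generate_mosaic, read_pair, write_pair
from .geometry import border_lattice, combine_keypoints, extract_centroids, delaunay
from .refine import RefineConfig, refine_mask
from .rng import derive_seed, rng_from
from .warp_engine import DEFAULT_RETRY_BUDGET, WarpRejectedError, warp_pair

log = logging.getLogger(__name__)

__all__ = ["AugmentConfig", "augment_dataset", "demo", "replay_sidecar"]


@dataclass(frozen=True)
class AugmentConfig:
    """Batch augmentation parameters.

    ``s_range`` is the interval the strain parameter is drawn from;
    the default [2, 3] spans mild (s=3) to strong (s=2) deformation,
    within the useful regime s in [1, 3].
    """

    s_range: tuple[float, float] = (2.0, 3.0)
    n_outputs_per_input: int = 1
    seed: int = 0
    retry_budget: int = DEFAULT_RETRY_BUDGET
    refine_enabled: bool = True
    refine: RefineConfig = field(default_factory=RefineConfig)
    connectivity_side: str = "target"
    mask_warp: str = "labels"

    def __post_init__(self) -> None:
        lo, hi = self.s_range
        if not (0 < lo <= hi):
            raise ValueError(f"s_range must satisfy 0 < lo <= hi, got {self.s_range}")
        if self.n_outputs_per_input < 1:
            raise ValueError("n_outputs_per_input must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AugmentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "s" in raw:  # single fixed strain value
            raw["s_range"] = (raw.pop("s"),) * 2
        if "s_range" in raw:
            raw["s_range"] = tuple(float(v) for v in raw["s_range"])
        refine_keys = raw.pop("refine", None)
        cfg = {}
        if isinstance(refine_keys, dict):
            enabled = refine_keys.pop("enabled", True)
            cfg["refine_enabled"] = bool(enabled)
            cfg["refine"] = RefineConfig(**refine_keys)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw, **cfg)


def _read_manifest(path: str | Path) -> list[tuple[Path, Path]]:
    """CSV manifest of image,mask path pairs (header optional)."""
    base = Path(path).parent
    pairs = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("image", "image_path"):
                continue
            img, msk = row[0].strip(), row[1].strip()
            pairs.append((base / img if not Path(img).is_absolute() else Path(img),
                          base / msk if not Path(msk).is_absolute() else Path(msk)))
    return pairs


def _write_sidecar(path: Path, *, image_src, mask_src, s, seed, shifts, n_retries, refined) -> None:
    payload = {
        "image": str(image_src),
        "mask": str(mask_src),
        "s": s,
        "seed": seed,
        "d_min_used": shifts.d_min_used,
        "n_retries": n_retries,
        "refined": refined,
        "deltas": [[round(float(dx), 10), round(float(dy), 10)] for dx, dy in shifts.deltas],
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def augment_dataset(manifest: str | Path | list, out_dir: str | Path, cfg: AugmentConfig | None = None) -> dict:
    """Augment every pair in a manifest; returns (and writes) a run report.

    ``manifest`` is a CSV path of image,mask rows or an in-memory list of
    (image_path, mask_path) tuples.  Outputs per input i, draw j:
    ``<stem>_aug<j>.tif/.png`` image, ``<stem>_aug<j>_mask.png`` label
    mask, and a sidecar JSON.  Unreadable inputs are skipped with a
    logged error; the run fails only if every pair fails.
    """
    cfg = cfg or AugmentConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = _read_manifest(manifest) if isinstance(manifest, (str, Path)) else [
        (Path(a), Path(b)) for a, b in manifest
    ]
    report = {
        "n_inputs": len(pairs),
        "n_outputs": 0,
        "n_rejected": 0,
        "n_input_errors": 0,
        "total_retries": 0,
        "outputs": [],
    }
    for i, (img_path, msk_path) in enumerate(pairs):
        try:
            pair = read_pair(img_path, msk_path)
        except Exception as exc:  # unreadable input: skip, keep going
            log.error("skipping pair %s / %s: %s", img_path, msk_path, exc)
            report["n_input_errors"] += 1
            continue
        for j in range(cfg.n_outputs_per_input):
            s = float(rng_from(cfg.seed, i, j, 0).uniform(*cfg.s_range))
            child_seed = derive_seed(cfg.seed, i, j, 1)
            try:
                warped, shifts = warp_pair(
                    pair, s, child_seed,
                    retry_budget=cfg.retry_budget,
                    connectivity_side=cfg.connectivity_side,
                    mask_warp=cfg.mask_warp,
                )
            except WarpRejectedError as exc:
                log.warning("rejected: %s (input %s, draw %d)", exc, img_path.name, j)
                report["n_rejected"] += 1
                continue
            report["total_retries"] += shifts.stream
            mask_out = warped.label_mask
            if cfg.refine_enabled:
                mask_out = refine_mask(warped.image, mask_out, cfg.refine)
            out_pair = LabeledPair(image=warped.image, label_mask=mask_out)
            stem = f"{img_path.stem}_aug{j:02d}"
            img_out = out_dir / f"{stem}{img_path.suffix}"
            msk_out = out_dir / f"{stem}_mask.png"
            write_pair(out_pair, img_out, msk_out)
            _write_sidecar(
                out_dir / f"{stem}.json",
                image_src=img_path.name, mask_src=msk_path.name,
                s=s, seed=child_seed, shifts=shifts,
                n_retries=shifts.stream, refined=cfg.refine_enabled,
            )
            report["n_outputs"] += 1
            report["outputs"].append(stem)
    n_ok_inputs = report["n_inputs"] - report["n_input_errors"]
    if n_ok_inputs > 0:
        # multiplier counts originals + accepted augmentations
        report["multiplier"] = (n_ok_inputs + report["n_outputs"]) / n_ok_inputs
    if report["n_outputs"] == 0:
        raise RuntimeError("augmentation produced no outputs (all pairs failed or were rejected)")
    (out_dir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def replay_sidecar(pair: LabeledPair, sidecar: str | Path | dict, cfg: AugmentConfig | None = None) -> LabeledPair:
    """Reproduce one augmented output from its sidecar record."""
    cfg = cfg or AugmentConfig()
    meta = sidecar if isinstance(sidecar, dict) else json.loads(Path(sidecar).read_text())
    warped, _ = warp_pair(
        pair, meta["s"], meta["seed"],
        retry_budget=cfg.retry_budget,
        connectivity_side=cfg.connectivity_side,
        mask_warp=cfg.mask_warp,
    )
    mask_out = warped.label_mask
    if meta.get("refined", True):
        mask_out = refine_mask(warped.image, mask_out, cfg.refine)
    return LabeledPair(image=warped.image, label_mask=mask_out)


def demo(out_dir: str | Path, seed: int = 0) -> Path:
    """Generate a mosaic and show mild vs strong warping side by side.

    Writes the original pair, warped pairs at s=3 (mild) and s=2
    (strong), and a panel image with the keypoint meshes overlaid.
    Returns the panel path.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pair = generate_mosaic(MosaicSpec(n_cells=20, guttae_fraction=0.1, blur_sigma=0.6,
                                      noise_sd=0.01, illumination_amplitude=0.15, seed=seed))
    write_pair(pair, out_dir / "original.tif", out_dir / "original_mask.png")

    K = combine_keypoints(extract_centroids(pair), border_lattice(pair.shape[1], pair.shape[0]))
    panels = [("original", pair, K)]
    for name, s in (("mild_s3", 3.0), ("strong_s2", 2.0)):
        warped, shifts = warp_pair(pair, s, derive_seed(seed, int(s)))
        refined = refine_mask(warped.image, warped.label_mask)
        out = LabeledPair(image=warped.image, label_mask=refined)
        write_pair(out, out_dir / f"{name}.tif", out_dir / f"{name}_mask.png")
        Kp = combine_keypoints(extract_centroids(out), border_lattice(out.shape[1], out.shape[0]))
        panels.append((f"{name} (s={s:g})", out, Kp))

    fig, axes = plt.subplots(2, len(panels), figsize=(4 * len(panels), 8))
    for col, (title, p, kp) in enumerate(panels):
        mesh = delaunay(kp)
        for ax, raster, cmap in ((axes[0, col], p.image, "gray"),
                                 (axes[1, col], p.boundary_mask, "gray")):
            ax.imshow(raster, cmap=cmap, interpolation="nearest")
            ax.triplot(kp.points[:, 0], kp.points[:, 1], mesh.triangles, lw=0.4, color="tab:orange")
            ax.plot(kp.points[:, 0], kp.points[:, 1], ".", ms=2, color="tab:red")
            ax.set_axis_off()
        axes[0, col].set_title(title)
    panel_path = out_dir / "panel.png"
    fig.tight_layout()
    fig.savefig(panel_path, dpi=120)
    plt.close(fig)
    return panel_path
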