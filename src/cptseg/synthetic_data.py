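"""Seeded phantom abdominal-style volumes for pipeline testing.

Every stage of the package — training, slice-to-volume inference,
per-organ metrics — is exercisable without any download via phantom
cases: eight ellipsoidal "organs" on a background, stacked into small
volumes whose structure mirrors the multi-organ CT protocol (cases of
S slices, integer labels 0..8, anisotropic spacing).  The geometry is
deliberately schematic: fixed plausible priors in fractional
coordinates, jittered per case, with piecewise-constant intensities
plus optional noise.  The generator aims for structural realism
(per-case class inventories, organs varying smoothly across slices,
anisotropic voxels for the distance metrics), not anatomical realism.

Painting order is class 1 to 8; a voxel keeps the first label painted
into it, so organs are non-overlapping by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .networks import SegVolume, CLASS_NAMES

# fractional (z, y, x) center, fractional (z, y, x) semi-axes, intensity.
# Layout loosely follows an abdominal cross-section: large liver on the
# image left, spleen right, paired kidneys low, a small central aorta
# running the full stack, gallbladder near the liver, elongated pancreas,
# stomach mid-right.
ORGAN_PRIORS: dict[int, dict] = {
    1: {"name": "aorta",        "center": (0.50, 0.52, 0.50),
        "axes": (0.48, 0.045, 0.045), "intensity": 0.85},
    2: {"name": "gallbladder",  "center": (0.38, 0.40, 0.30),
        "axes": (0.16, 0.07, 0.06),  "intensity": 0.35},
    3: {"name": "left_kidney",  "center": (0.62, 0.68, 0.72),
        "axes": (0.26, 0.10, 0.08),  "intensity": 0.55},
    4: {"name": "right_kidney", "center": (0.62, 0.68, 0.26),
        "axes": (0.26, 0.10, 0.08),  "intensity": 0.55},
    5: {"name": "liver",        "center": (0.45, 0.38, 0.28),
        "axes": (0.42, 0.22, 0.20),  "intensity": 0.65},
    6: {"name": "pancreas",     "center": (0.52, 0.55, 0.55),
        "axes": (0.18, 0.05, 0.16),  "intensity": 0.45},
    7: {"name": "spleen",       "center": (0.42, 0.45, 0.78),
        "axes": (0.30, 0.12, 0.09),  "intensity": 0.60},
    8: {"name": "stomach",      "center": (0.40, 0.58, 0.42),
        "axes": (0.30, 0.13, 0.11),  "intensity": 0.25},
}

BACKGROUND_INTENSITY = 0.12
MIN_CLASSES_PRESENT = 6


@dataclass
class PhantomSpec:
    """Generator parameters; fully determines the dataset given a seed."""

    n_cases: int = 6
    slices_per_case: int = 10
    image_size: int = 64
    n_classes: int = 9
    noise_std: float = 0.03
    jitter: float = 0.04          # per-case fractional center jitter
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    train_fraction: float = 0.6   # mirrors the 18/12 case split ratio
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64 "
                             "(geometry priors unrepresentable below)")
        if self.n_classes != 9:
            raise ValueError("the phantom protocol is 9-class "
                             "(background + 8 organs)")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "spacing" in d:
            d["spacing"] = tuple(d["spacing"])
        return cls(**d)


def _case_rng(spec: PhantomSpec, case_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([spec.seed, int(case_index)]))


def ellipsoid_mask(shape: tuple[int, int, int], center, axes) -> np.ndarray:
    """Boolean mask of the ellipsoid with fractional center/semi-axes."""
    s, h, w = shape
    zc, yc, xc = (c * n for c, n in zip(center, (s, h, w)))
    za, ya, xa = (max(a * n, 0.5) for a, n in zip(axes, (s, h, w)))
    z, y, x = np.ogrid[:s, :h, :w]
    return (((z - zc) / za) ** 2 + ((y - yc) / ya) ** 2
            + ((x - xc) / xa) ** 2) <= 1.0


def generate_phantom_volume(spec: PhantomSpec, case_index: int) -> SegVolume:
    """One deterministic phantom case (same (seed, case_index) => identical)."""
    rng = _case_rng(spec, case_index)
    shape = (spec.slices_per_case, spec.image_size, spec.image_size)
    labels = np.zeros(shape, dtype=np.int16)
    intensity = np.full(shape, BACKGROUND_INTENSITY, dtype=np.float64)
    for cls in range(1, 9):
        prior = ORGAN_PRIORS[cls]
        center = np.asarray(prior["center"]) + rng.uniform(
            -spec.jitter, spec.jitter, size=3)
        axes = np.asarray(prior["axes"]) * rng.uniform(0.9, 1.1, size=3)
        mask = ellipsoid_mask(shape, center, axes) & (labels == 0)
        labels[mask] = cls
        intensity[mask] = prior["intensity"]
    if spec.noise_std > 0:
        intensity = intensity + rng.normal(0.0, spec.noise_std, size=shape)
    intensity = np.clip(intensity, 0.0, 1.0)
    present = np.unique(labels)
    n_fg = int((present > 0).sum())
    if n_fg < MIN_CLASSES_PRESENT:
        raise RuntimeError(
            f"phantom case {case_index} contains only {n_fg} organ classes; "
            "geometry priors violated")
    return SegVolume(case_id=f"phantom_{spec.seed:04d}_{case_index:03d}",
                     slices=intensity, labels=labels, spacing=spec.spacing)


def generate_dataset(spec: PhantomSpec
                     ) -> tuple[list[SegVolume], list[SegVolume], dict]:
    """Case-disjoint train/test split plus a regeneration manifest."""
    if spec.n_cases < 2:
        raise ValueError("need at least 2 cases to split")
    volumes = [generate_phantom_volume(spec, i) for i in range(spec.n_cases)]
    n_train = max(1, min(spec.n_cases - 1,
                         round(spec.train_fraction * spec.n_cases)))
    train, test = volumes[:n_train], volumes[n_train:]
    manifest = {
        "spec": spec.to_dict(),
        "cases": [{
            "case_id": v.case_id,
            "case_index": i,
            "split": "train" if i < n_train else "test",
            "classes_present": [int(c) for c in np.unique(v.labels) if c > 0],
        } for i, v in enumerate(volumes)],
    }
    return train, test, manifest


def regenerate_from_manifest(manifest: dict) -> list[SegVolume]:
    spec = PhantomSpec.from_dict(manifest["spec"])
    return [generate_phantom_volume(spec, c["case_index"])
            for c in manifest["cases"]]


# ---------------------------------------------------------------------------
# Fixture I/O
# ---------------------------------------------------------------------------

FORMATS = ("npz", "nii.gz", "png-pairs")


def write_fixture(volumes: list[SegVolume], out_dir, format: str = "npz",
                  manifest: dict | None = None) -> list[Path]:
    """Write volumes to disk; labels round-trip losslessly in all formats.

    ``png-pairs`` stores intensities as 8-bit PNGs (quantized to 1/255)
    and labels as separate 8-bit PNGs, one pair per slice.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if format == "npz":
        for v in volumes:
            p = out_dir / f"{v.case_id}.npz"
            np.savez_compressed(p, slices=v.slices, labels=v.labels,
                                spacing=np.asarray(v.spacing))
            written.append(p)
    elif format == "nii.gz":
        import nibabel as nib
        for v in volumes:
            # (S,H,W) -> nibabel's (x,y,z) with z the slice axis
            affine = np.diag([v.spacing[2], v.spacing[1], v.spacing[0], 1.0])
            img = nib.Nifti1Image(v.slices.transpose(2, 1, 0), affine)
            lab = nib.Nifti1Image(
                v.labels.transpose(2, 1, 0).astype(np.int16), affine)
            pi = out_dir / f"{v.case_id}_img.nii.gz"
            pl = out_dir / f"{v.case_id}_lab.nii.gz"
            nib.save(img, pi)
            nib.save(lab, pl)
            written += [pi, pl]
    elif format == "png-pairs":
        from PIL import Image
        for v in volumes:
            case_dir = out_dir / v.case_id
            case_dir.mkdir(exist_ok=True)
            spacing_file = case_dir / "spacing.json"
            spacing_file.write_text(json.dumps(list(v.spacing)))
            for i, (sl, lb) in enumerate(zip(v.slices, v.labels)):
                im = Image.fromarray(
                    np.round(sl * 255).astype(np.uint8), mode="L")
                la = Image.fromarray(lb.astype(np.uint8), mode="L")
                pi = case_dir / f"slice_{i:03d}_img.png"
                pl = case_dir / f"slice_{i:03d}_lab.png"
                im.save(pi)
                la.save(pl)
                written += [pi, pl]
    else:
        raise ValueError(f"unsupported format {format!r}; use one of {FORMATS}")
    if manifest is not None:
        mp = out_dir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=2))
        written.append(mp)
    return written


def read_fixture(out_dir, format: str = "npz") -> list[SegVolume]:
    """Read back volumes written by :func:`write_fixture`."""
    out_dir = Path(out_dir)
    volumes: list[SegVolume] = []
    if format == "npz":
        for p in sorted(out_dir.glob("*.npz")):
            data = np.load(p)
            volumes.append(SegVolume(
                case_id=p.stem, slices=data["slices"],
                labels=data["labels"].astype(np.int16),
                spacing=tuple(data["spacing"])))
    elif format == "nii.gz":
        import nibabel as nib
        for pi in sorted(out_dir.glob("*_img.nii.gz")):
            pl = Path(str(pi).replace("_img.nii.gz", "_lab.nii.gz"))
            img = nib.load(pi)
            lab = nib.load(pl)
            zooms = img.header.get_zooms()
            volumes.append(SegVolume(
                case_id=pi.name[:-len("_img.nii.gz")],
                slices=np.asarray(img.dataobj).transpose(2, 1, 0),
                labels=np.asarray(lab.dataobj).transpose(2, 1, 0).astype(np.int16),
                spacing=(float(zooms[2]), float(zooms[1]), float(zooms[0]))))
    elif format == "png-pairs":
        from PIL import Image
        for case_dir in sorted(d for d in out_dir.iterdir() if d.is_dir()):
            spacing = tuple(json.loads((case_dir / "spacing.json").read_text()))
            imgs = sorted(case_dir.glob("slice_*_img.png"))
            labs = sorted(case_dir.glob("slice_*_lab.png"))
            slices = np.stack([np.asarray(Image.open(p), dtype=np.float64) / 255
                               for p in imgs])
            labels = np.stack([np.asarray(Image.open(p)).astype(np.int16)
                               for p in labs])
            volumes.append(SegVolume(case_id=case_dir.name, slices=slices,
                                     labels=labels, spacing=spacing))
    else:
        raise ValueError(f"unsupported format {format!r}; use one of {FORMATS}")
    if not volumes:
        raise FileNotFoundError(f"no {format} volumes under {out_dir}")
    return volumes
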