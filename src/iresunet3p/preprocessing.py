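"""Case preprocessing: standardization, label-to-region mapping, padding,
cropping, 2D patch extraction and 3D block methods A/B with exact inverses.

A BraTS-style case is four co-registered modality volumes (T1, T2, FLAIR,
T1C) plus an integer label volume with tissue codes NET, ED, ET.  The three
nested evaluation regions are derived as WT = NET u ED u ET, TC = NET u ET,
ET = ET, so ET <= TC <= WT voxelwise by construction.

The 3D path pads the depth axis to a fixed target (155 -> 160 adds 3 black
slices in front and 2 behind), center-crops H/W, then slices depth-32
blocks: method A steps by 32 (disjoint cover), method B by 8 (overlapping).
Every geometric step records enough information (pad record, crop offsets,
block offsets) for a bit-exact inverse, so predictions map back to native
case geometry.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

# BraTS label codes (the conventional integers; configurable)
DEFAULT_LABEL_CODES = {"NET": 1, "ED": 2, "ET": 4}

MODALITY_NAMES = ("t1", "t2", "flair", "t1ce")


class PreprocessingError(ValueError):
    pass


@dataclass
class CaseRecord:
    """One subject: four modality volumes + label volume + id."""

    modalities: np.ndarray  # (4, D, H, W)
    labels: np.ndarray      # (D, H, W) integer codes
    case_id: str
    label_codes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self):
        self.modalities = np.asarray(self.modalities)
        self.labels = np.asarray(self.labels)
        if self.modalities.ndim != 4 or self.modalities.shape[0] != 4:
            raise PreprocessingError(
                f"modalities must be (4, D, H, W), got {self.modalities.shape}")
        if self.labels.shape != self.modalities.shape[1:]:
            raise PreprocessingError(
                f"label shape {self.labels.shape} != volume shape "
                f"{self.modalities.shape[1:]}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class RegionMask:
    """Binary nested region masks, et <= tc <= wt voxelwise."""

    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    def __post_init__(self):
        for name in ("wt", "tc", "et"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        if not (self.wt.shape == self.tc.shape == self.et.shape):
            raise PreprocessingError("region masks must share one shape")

    def stack(self) -> np.ndarray:
        """(3, D, H, W) float array ordered (wt, tc, et)."""
        return np.stack([self.wt, self.tc, self.et]).astype(np.float32)

    @classmethod
    def from_stack(cls, arr: np.ndarray) -> "RegionMask":
        return cls(arr[0] > 0.5, arr[1] > 0.5, arr[2] > 0.5)

    def nested(self) -> bool:
        return bool(np.all(self.et <= self.tc) and np.all(self.tc <= self.wt))


@dataclass
class BlockSpec:
    """Depth-axis blocking parameters (3D path).

    Defaults are the published configuration: depth-32 blocks from a volume
    padded to 160 slices and cropped to (160,160,160); method A steps by 32
    (5 disjoint blocks), method B by 8 (17 overlapping blocks).
    """

    block_depth: int = 32
    z_step: int = 32
    crop_shape: tuple[int, int, int] = (160, 160, 160)
    pad_target_depth: int = 160

    @classmethod
    def method_a(cls, **kw) -> "BlockSpec":
        return cls(z_step=kw.pop("z_step", 32), **kw)

    @classmethod
    def method_b(cls, **kw) -> "BlockSpec":
        return cls(z_step=kw.pop("z_step", 8), **kw)

    def validate_for_depth(self, depth: int):
        if self.block_depth > depth:
            raise PreprocessingError(
                f"block depth {self.block_depth} exceeds volume depth {depth}")
        if (depth - self.block_depth) % self.z_step:
            raise PreprocessingError(
                f"depth {depth} minus block depth {self.block_depth} is not "
                f"divisible by step {self.z_step}")


# ---------------------------------------------------------------------------
# intensity / label operations
# ---------------------------------------------------------------------------

def standardize(volume: np.ndarray) -> np.ndarray:
    """Zero-mean unit-SD (population convention) over the nonzero support;
    background zeros stay zero.  A constant nonzero region yields zeros with
    a warning (division guard)."""
    volume = np.asarray(volume, dtype=np.float64)
    support = volume != 0
    out = np.zeros_like(volume, dtype=np.float32)
    n = int(support.sum())
    if n == 0:
        warnings.warn("standardize: all-zero volume", stacklevel=2)
        return out
    vals = volume[support]
    mean = vals.mean()
    sd = vals.std()  # ddof=0
    if sd == 0:
        warnings.warn("standardize: constant nonzero region", stacklevel=2)
        return out
    out[support] = ((vals - mean) / sd).astype(np.float32)
    return out


def labels_to_regions(labels: np.ndarray,
                      codes: dict[str, int] | None = None) -> RegionMask:
    """Map tissue codes to the nested regions WT/TC/ET."""
    codes = codes or DEFAULT_LABEL_CODES
    labels = np.asarray(labels)
    known = {0, codes["NET"], codes["ED"], codes["ET"]}
    present = set(np.unique(labels).tolist())
    bad = sorted(present - known)
    if bad:
        raise PreprocessingError(f"unknown label codes: {bad}")
    net = labels == codes["NET"]
    ed = labels == codes["ED"]
    et = labels == codes["ET"]
    return RegionMask(wt=net | ed | et, tc=net | et, et=et)


# ---------------------------------------------------------------------------
# geometry: pad / crop / blocks
# ---------------------------------------------------------------------------

def pad_depth(volume: np.ndarray, target: int = 160
              ) -> tuple[np.ndarray, tuple[int, int]]:
    """Pad the depth (first) axis with zero slices to `target`; the deficit
    splits front-heavy, e.g. 155 -> 160 adds (3, 2).  Returns the padded
    volume and the (front, back) pad record."""
    volume = np.asarray(volume)
    depth = volume.shape[0]
    if depth > target:
        raise PreprocessingError(f"depth {depth} exceeds pad target {target}")
    deficit = target - depth
    front = -(-deficit // 2)  # ceil
    back = deficit // 2
    pads = [(front, back)] + [(0, 0)] * (volume.ndim - 1)
    return np.pad(volume, pads), (front, back)


def unpad_depth(volume: np.ndarray, pad_record: tuple[int, int]) -> np.ndarray:
    front, back = pad_record
    stop = volume.shape[0] - back
    return volume[front:stop]


def center_crop(volume: np.ndarray, crop_shape: tuple[int, ...]
                ) -> tuple[np.ndarray, tuple[int, ...]]:
    """Centered window (odd remainders put the extra voxel at the far end);
    returns the crop and the per-axis start offsets for inverse placement."""
    volume = np.asarray(volume)
    if len(crop_shape) != volume.ndim:
        raise PreprocessingError("crop_shape rank must match volume rank")
    offsets = []
    slices = []
    for size, want in zip(volume.shape, crop_shape):
        if want > size:
            raise PreprocessingError(
                f"crop size {want} exceeds volume size {size}")
        off = (size - want) // 2
        offsets.append(off)
        slices.append(slice(off, off + want))
    return volume[tuple(slices)], tuple(offsets)


def uncrop(cropped: np.ndarray, offsets: tuple[int, ...],
           full_shape: tuple[int, ...], fill=0) -> np.ndarray:
    out = np.full(full_shape, fill, dtype=cropped.dtype)
    slices = tuple(slice(o, o + s) for o, s in zip(offsets, cropped.shape))
    out[slices] = cropped
    return out


def blockify(volume: np.ndarray, spec: BlockSpec
             ) -> tuple[list[np.ndarray], list[int]]:
    """Slice depth-`block_depth` blocks every `z_step` slices.  The volume's
    depth axis is the first axis (a leading channel axis is allowed if the
    caller blockifies per channel).  Returns blocks and their z offsets."""
    volume = np.asarray(volume)
    depth = volume.shape[0]
    spec.validate_for_depth(depth)
    offsets = list(range(0, depth - spec.block_depth + 1, spec.z_step))
    blocks = [volume[z:z + spec.block_depth] for z in offsets]
    return blocks, offsets


def deblockify(blocks: list[np.ndarray], offsets: list[int],
               depth: int) -> np.ndarray:
    """Reassemble a volume from depth blocks, averaging overlapping voxels
    with equal weights.  Exact inverse of blockify for any input."""
    if not blocks:
        raise PreprocessingError("no blocks to assemble")
    rest = blocks[0].shape[1:]
    acc = np.zeros((depth,) + rest, dtype=np.float64)
    cnt = np.zeros(depth, dtype=np.int64)
    for b, z in zip(blocks, offsets):
        bd = b.shape[0]
        if z < 0 or z + bd > depth:
            raise PreprocessingError(f"block at z={z} outside depth {depth}")
        acc[z:z + bd] += b
        cnt[z:z + bd] += 1
    if np.any(cnt == 0):
        missing = np.flatnonzero(cnt == 0)
        raise PreprocessingError(
            f"coverage gap: slices {missing[:5].tolist()}... uncovered")
    acc /= cnt.reshape((-1,) + (1,) * len(rest))
    return acc.astype(blocks[0].dtype if blocks[0].dtype.kind == "f"
                      else np.float32)


# ---------------------------------------------------------------------------
# 2D patches
# ---------------------------------------------------------------------------

def make_2d_patches(case: CaseRecord, patch_hw: int = 160,
                    filter_empty: bool = False
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice channel-stacked patches for the 2D network.

    Standardizes each modality, maps labels to regions, center-crops H/W to
    `patch_hw`, and emits one (4, patch, patch) image stack plus one
    (3, patch, patch) region stack per axial slice.  With `filter_empty`,
    slices with no brain support (all modalities zero) are dropped.
    """
    imgs = np.stack([standardize(m) for m in case.modalities])
    regions = labels_to_regions(case.labels, case.label_codes).stack()
    d, h, w = case.shape
    crop = (4, d, patch_hw, patch_hw)
    imgs, _ = center_crop(imgs, crop)
    regions, _ = center_crop(regions, (3, d, patch_hw, patch_hw))
    # (D, 4, patch, patch) / (D, 3, patch, patch)
    img_patches = np.moveaxis(imgs, 1, 0)
    reg_patches = np.moveaxis(regions, 1, 0)
    if filter_empty:
        keep = np.any(img_patches != 0, axis=(1, 2, 3))
        img_patches = img_patches[keep]
        reg_patches = reg_patches[keep]
    return np.ascontiguousarray(img_patches), np.ascontiguousarray(reg_patches)


# ---------------------------------------------------------------------------
# I/O: NIfTI cases, .npy intermediates, geometry sidecars
# ---------------------------------------------------------------------------

def read_case(case_dir: str | Path, label_codes=None) -> CaseRecord:
    """Read a BraTS-style case directory case_id/{case_id}_{mod}.nii.gz."""
    import nibabel as nib

    case_dir = Path(case_dir)
    case_id = case_dir.name
    vols = []
    missing = []
    for mod in MODALITY_NAMES + ("seg",):
        hits = sorted(case_dir.glob(f"*_{mod}.nii*"))
        if not hits:
            missing.append(mod)
            continue
        vols.append(np.asanyarray(nib.load(hits[0]).dataobj))
    if missing:
        raise PreprocessingError(
            f"case {case_id}: missing modality file(s): {missing}")
    shapes = {v.shape for v in vols}
    if len(shapes) != 1:
        raise PreprocessingError(
            f"case {case_id}: inconsistent volume shapes {sorted(shapes)}")
    return CaseRecord(
        modalities=np.stack(vols[:4]).astype(np.float32),
        labels=np.rint(vols[4]).astype(np.int16),
        case_id=case_id,
        label_codes=dict(label_codes or DEFAULT_LABEL_CODES),
    )


def write_case(case: CaseRecord, root: str | Path) -> Path:
    """Write a CaseRecord as a BraTS-style NIfTI directory."""
    import nibabel as nib

    out = Path(root) / case.case_id
    out.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    for name, vol in zip(MODALITY_NAMES, case.modalities):
        nib.save(nib.Nifti1Image(vol.astype(np.float32), affine),
                 out / f"{case.case_id}_{name}.nii.gz")
    nib.save(nib.Nifti1Image(case.labels.astype(np.int16), affine),
             out / f"{case.case_id}_seg.nii.gz")
    return out


def write_arrays(arrays: dict[str, np.ndarray], out_dir: str | Path,
                 sidecar: dict | None = None) -> Path:
    """Save named arrays as .npy plus an optional JSON geometry sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, arr in arrays.items():
        np.save(out_dir / f"{name}.npy", arr)
    if sidecar is not None:
        (out_dir / "geometry.json").write_text(json.dumps(sidecar, indent=2))
    return out_dir


def read_arrays(in_dir: str | Path) -> tuple[dict[str, np.ndarray], dict | None]:
    in_dir = Path(in_dir)
    arrays = {p.stem: np.load(p) for p in sorted(in_dir.glob("*.npy"))}
    side_path = in_dir / "geometry.json"
    sidecar = json.loads(side_path.read_text()) if side_path.exists() else None
    return arrays, sidecar


# ---------------------------------------------------------------------------
# full 3D pipeline for one case
# ---------------------------------------------------------------------------

def preprocess_case_3d(case: CaseRecord, spec: BlockSpec
                       ) -> tuple[list[np.ndarray], list[np.ndarray], dict]:
    """standardize -> regions -> pad depth -> center crop -> blockify.

    Returns image blocks (each (4, bd, ch, cw)), region blocks (each
    (3, bd, ch, cw)) and the geometry sidecar needed to invert.
    """
    imgs = np.stack([standardize(m) for m in case.modalities])
    regions = labels_to_regions(case.labels, case.label_codes).stack()
    orig_shape = case.shape

    padded_imgs, pad_rec = zip(*[pad_depth(m, spec.pad_target_depth)
                                 for m in imgs])
    pad_rec = pad_rec[0]
    padded_regs = [pad_depth(r, spec.pad_target_depth)[0] for r in regions]

    cropped_imgs, offs = zip(*[center_crop(v, spec.crop_shape)
                               for v in padded_imgs])
    offsets = offs[0]
    cropped_regs = [center_crop(r, spec.crop_shape)[0] for r in padded_regs]

    img_blocks_per_mod = [blockify(v, spec) for v in cropped_imgs]
    z_offsets = img_blocks_per_mod[0][1]
    reg_blocks_per_ch = [blockify(r, spec)[0] for r in cropped_regs]

    n_blocks = len(z_offsets)
    image_blocks = [np.stack([img_blocks_per_mod[m][0][i] for m in range(4)])
                    for i in range(n_blocks)]
    region_blocks = [np.stack([reg_blocks_per_ch[c][i] for c in range(3)])
                     for i in range(n_blocks)]
    sidecar = {
        "case_id": case.case_id,
        "orig_shape": list(orig_shape),
        "pad_record": list(pad_rec),
        "crop_offsets": list(offsets),
        "z_offsets": list(z_offsets),
        "block_spec": {
            "block_depth": spec.block_depth,
            "z_step": spec.z_step,
            "crop_shape": list(spec.crop_shape),
            "pad_target_depth": spec.pad_target_depth,
        },
    }
    return image_blocks, region_blocks, sidecar


def reassemble_case_3d(prob_blocks: list[np.ndarray], sidecar: dict
                       ) -> np.ndarray:
    """Inverse of preprocess_case_3d geometry for predicted probability
    blocks (each (3, bd, ch, cw)): deblockify (average overlaps), place back
    at the crop offsets, strip depth padding.  Returns (3, D, H, W)."""
    spec = sidecar["block_spec"]
    depth = spec["crop_shape"][0]
    channels = prob_blocks[0].shape[0]
    full_padded_shape = (spec["pad_target_depth"],) + tuple(
        sidecar["orig_shape"][1:])
    out = []
    for c in range(channels):
        vol = deblockify([b[c] for b in prob_blocks],
                         sidecar["z_offsets"], depth)
        placed = uncrop(vol, tuple(sidecar["crop_offsets"]),
                        full_padded_shape)
        out.append(unpad_depth(placed, tuple(sidecar["pad_record"])))
    return np.stack(out)
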