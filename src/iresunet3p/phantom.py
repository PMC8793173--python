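"""Synthetic multimodal phantom cases shaped like BraTS subjects.

Each phantom is four co-registered modality volumes plus an integer label
volume.  Geometry: an ellipsoidal "brain" centered in the field of view,
zero outside; inside it a concentric three-shell tumor — enhancing core
(ET), non-enhancing shell (NET), edema rim (ED) — so the derived regions
nest by construction (ET <= TC <= WT).  Intensities are piecewise-constant
per tissue class with per-modality profiles (roughly mimicking the relative
contrasts of T1/T2/FLAIR/T1C, e.g. edema bright on FLAIR/T2, core enhancing
on T1C) plus additive Gaussian noise.  Generation is a pure function of
(config, seed).  An optional lumpy radial perturbation breaks the perfect
ellipsoids for less idealized shapes.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocessing import DEFAULT_LABEL_CODES, CaseRecord

# per-modality mean intensity for each tissue class
DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    "t1":    {"brain": 1.00, "ED": 0.80, "NET": 0.60, "ET": 0.70},
    "t2":    {"brain": 0.60, "ED": 1.20, "NET": 0.90, "ET": 0.80},
    "flair": {"brain": 0.50, "ED": 1.40, "NET": 1.00, "ET": 0.90},
    "t1ce":  {"brain": 0.90, "ED": 0.85, "NET": 0.70, "ET": 1.60},
}


class PhantomError(ValueError):
    pass


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of one synthetic case.

    Radii are fractions of the half-extent per axis; tumor radii must nest
    strictly (ET < TC < WT on every axis) and the whole tumor must sit
    inside the brain ellipsoid.
    """

    shape: tuple[int, int, int] = (155, 240, 240)
    brain_radii: tuple[float, float, float] = (0.90, 0.80, 0.80)
    tumor_center: tuple[float, float, float] = (0.0, 0.1, -0.1)  # fractional
    wt_radii: tuple[float, float, float] = (0.45, 0.35, 0.35)
    tc_radii: tuple[float, float, float] = (0.30, 0.22, 0.22)
    et_radii: tuple[float, float, float] = (0.15, 0.11, 0.11)
    modality_profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(v)
                                 for m, v in DEFAULT_PROFILES.items()})
    noise_sd: float = 0.05
    lumpiness: float = 0.0  # relative radial perturbation amplitude
    label_codes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_CODES))
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise PhantomError("noise_sd must be >= 0")
        for a, b, names in ((self.et_radii, self.tc_radii, "ET < TC"),
                            (self.tc_radii, self.wt_radii, "TC < WT")):
            if not all(x < y for x, y in zip(a, b)):
                raise PhantomError(f"tumor radii must nest: {names}")


def _ellipsoid(shape, center_frac, radii_frac, rng=None, lumpiness=0.0):
    """Boolean ellipsoid mask; optional smooth radial perturbation."""
    grids = []
    for n, c, r in zip(shape, center_frac, radii_frac):
        half = (n - 1) / 2.0
        coords = (np.arange(n) - half - c * half) / (r * half)
        grids.append(coords)
    zz, yy, xx = np.meshgrid(*grids, indexing="ij", sparse=True)
    rho2 = zz ** 2 + yy ** 2 + xx ** 2
    if lumpiness and rng is not None:
        # low-frequency multiplicative field perturbs the effective radius
        coarse = rng.normal(0.0, 1.0, size=(4, 4, 4))
        from scipy.ndimage import zoom

        f = zoom(coarse, [s / 4 for s in shape], order=1)
        rho2 = rho2 * (1.0 + lumpiness * f) ** 2
    return rho2 <= 1.0


def generate_case(config: PhantomConfig, case_id: str | None = None
                  ) -> CaseRecord:
    """Generate one phantom case deterministically from (config, seed)."""
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.shape)
    brain = _ellipsoid(shape, (0.0, 0.0, 0.0), config.brain_radii)
    geom_rng = np.random.default_rng(config.seed + 1)
    wt = _ellipsoid(shape, config.tumor_center, config.wt_radii,
                    rng=geom_rng, lumpiness=config.lumpiness)
    tc = _ellipsoid(shape, config.tumor_center, config.tc_radii,
                    rng=geom_rng, lumpiness=config.lumpiness)
    et = _ellipsoid(shape, config.tumor_center, config.et_radii,
                    rng=geom_rng, lumpiness=config.lumpiness)
    # lumpy perturbations could break nesting; restore it by intersection
    tc &= wt
    et &= tc
    if not (wt & ~brain).sum() == 0:
        raise PhantomError("tumor extends outside the brain ellipsoid")
    if not et.any():
        raise PhantomError("ET region empty at this shape; enlarge radii")

    codes = config.label_codes
    labels = np.zeros(shape, dtype=np.int16)
    labels[wt] = codes["ED"]
    labels[tc] = codes["NET"]
    labels[et] = codes["ET"]

    tissue = {"brain": brain & ~wt, "ED": wt & ~tc, "NET": tc & ~et, "ET": et}
    modalities = np.zeros((4,) + shape, dtype=np.float32)
    for i, (mod, profile) in enumerate(config.modality_profiles.items()):
        vol = np.zeros(shape, dtype=np.float32)
        for cls, mask in tissue.items():
            vol[mask] = profile[cls]
        if config.noise_sd:
            noise = rng.normal(0.0, config.noise_sd, size=shape)
            vol[brain] += noise[brain].astype(np.float32)
            # keep the background exactly zero and the support positive
            np.clip(vol, 1e-4, None, out=vol)
            vol[~brain] = 0.0
        modalities[i] = vol
    return CaseRecord(modalities=modalities, labels=labels,
                      case_id=case_id or f"phantom_{config.seed:05d}",
                      label_codes=dict(codes))


def generate_dataset(n: int, base_seed: int = 0,
                     config: PhantomConfig | None = None,
                     train_fraction: float = 285 / 351
                     ) -> tuple[list[CaseRecord], list[CaseRecord]]:
    """Generate n phantoms with per-case seeds base_seed+i and split them.

    The default split fraction mirrors the 285:66 train:validation case
    split of the BraTS2018 release.
    """
    if n < 2:
        raise PhantomError("need at least 2 cases for a train/val split")
    config = config or PhantomConfig()
    cases = [generate_case(replace(config, seed=base_seed + i),
                           case_id=f"phantom_{base_seed + i:05d}")
             for i in range(n)]
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    return cases[:n_train], cases[n_train:]
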