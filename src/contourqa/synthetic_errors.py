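"""Seeded synthetic contour pairs with realistic contouring-error structure.

No clinical CT contours ship with the package; instead this module generates
organ-scale phantom structures and pairs of contours around them that mirror
how a contour-QA training set is assembled in practice:

* four source sets — reference-vs-verification autocontours on "internal"
  scans (verification contours nearly perfect, emulating prediction on the
  verification system's own training data), the same on "external" scans
  (noisier verification), manually drawn acceptable contours, and manually
  drawn unacceptable contours;
* an error taxonomy for unacceptable contours — superior/inferior
  truncation, rigid shift, sector over-expansion, dropped component, gross
  misplacement;
* acceptable contours differ from the underlying anatomy by smooth boundary
  noise of bounded amplitude, occasionally carrying a small-area,
  high-amplitude "finger" artefact (a thin protrusion a clinician would not
  consider a major error but which dominates the Hausdorff distance).

Default set sizes are 49 / 38 / 49 / 49, i.e. 185 pairs per structure.
Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage

from .mask_io import ContourPair, LabelMask, write_mask

__all__ = [
    "ARCHETYPES",
    "ERROR_TYPES",
    "SyntheticConfig",
    "generate_structure",
    "perturb_acceptable",
    "add_local_bump",
    "add_surface_artifact",
    "inject_error",
    "generate_dataset",
]

ARCHETYPES = ("ellipsoid", "bent_tube", "bean_pair", "branched_slab")
ERROR_TYPES = ("superior_inferior_truncation", "rigid_shift", "over_expansion",
               "component_drop", "gross_misplacement")

DEFAULT_GRID_SHAPE = (48, 64, 64)          # (z, y, x) voxels
DEFAULT_SPACING_MM = (2.5, 1.5, 1.5)       # CT-like anisotropy

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)


def _world_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _check_not_touching_border(voxels: np.ndarray, archetype: str) -> None:
    if (voxels[0].any() or voxels[-1].any() or voxels[:, 0].any()
            or voxels[:, -1].any() or voxels[:, :, 0].any()
            or voxels[:, :, -1].any()):
        raise ValueError(
            f"grid too small for archetype {archetype!r}: structure touches "
            "the grid border"
        )


def generate_structure(archetype: str, grid_shape=DEFAULT_GRID_SHAPE,
                       spacing=DEFAULT_SPACING_MM, seed: int = 0) -> LabelMask:
    """Generate one organ-scale phantom structure.

    Archetypes (sizes in mm, jittered per seed):

    * ``ellipsoid`` — bladder/uterus-like blob, semi-axes ~18–32 mm;
    * ``bent_tube`` — rectum-like curved tube, radius ~10–14 mm;
    * ``bean_pair`` — kidneys-like pair of ellipsoids (exactly 2 components);
    * ``branched_slab`` — nodal-CTV-like Y of merged tubes (1 component).

    The structure never touches the grid border (truncation errors are
    injected later, not baked in); too small a grid raises ``ValueError``.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; valid: {ARCHETYPES}")
    rng = np.random.default_rng(seed)
    Z, Y, X = _world_grids(grid_shape, spacing)
    extent = np.array([(n - 1) * s for n, s in zip(grid_shape, spacing)])
    cz, cy, cx = extent / 2.0 + rng.uniform(-4.0, 4.0, size=3)

    if archetype == "ellipsoid":
        rz = rng.uniform(22.0, 32.0)
        ry = rng.uniform(18.0, 28.0)
        rx = rng.uniform(18.0, 28.0)
        vox = (((Z - cz) / rz) ** 2 + ((Y - cy) / ry) ** 2
               + ((X - cx) / rx) ** 2) <= 1.0
    elif archetype == "bent_tube":
        r = rng.uniform(10.0, 14.0)
        half_len = rng.uniform(35.0, 45.0)
        amp = rng.uniform(8.0, 14.0)
        phase = rng.uniform(0.0, 2 * np.pi)
        curve = amp * np.sin(2 * np.pi * (Z - cz) / (2 * half_len) + phase)
        vox = (((Y - cy - curve) ** 2 + (X - cx) ** 2) <= r ** 2) \
            & (np.abs(Z - cz) <= half_len)
    elif archetype == "bean_pair":
        sep = rng.uniform(24.0, 28.0)
        vox = np.zeros(grid_shape, dtype=bool)
        for side in (-1.0, 1.0):
            rz = rng.uniform(22.0, 28.0)
            ry = rng.uniform(10.0, 13.0)
            rx = rng.uniform(10.0, 13.0)
            vox |= (((Z - cz) / rz) ** 2 + ((Y - cy) / ry) ** 2
                    + ((X - (cx + side * sep)) / rx) ** 2) <= 1.0
    else:  # branched_slab
        r_main = rng.uniform(9.0, 12.0)
        r_branch = rng.uniform(8.0, 10.0)
        slope = rng.uniform(0.45, 0.65)
        trunk = (((Y - cy) ** 2 + (X - cx) ** 2) <= r_main ** 2) \
            & (Z >= cz - 40.0) & (Z <= cz + 8.0)
        vox = trunk
        for side in (-1.0, 1.0):
            yb = cy + side * slope * (Z - cz)
            branch = (((Y - yb) ** 2 + (X - cx) ** 2) <= r_branch ** 2) \
                & (Z >= cz) & (Z <= cz + 38.0)
            vox |= branch

    _check_not_touching_border(vox, archetype)
    if not vox.any():
        raise ValueError(f"archetype {archetype!r} produced an empty mask")
    return LabelMask(vox, tuple(spacing), (0.0, 0.0, 0.0),
                     structure_name=archetype)


def _signed_distance(mask: LabelMask) -> np.ndarray:
    """Signed Euclidean distance (mm) to the mask boundary; negative inside."""
    vox = mask.voxels
    d_out = ndimage.distance_transform_edt(~vox, sampling=mask.spacing)
    d_in = ndimage.distance_transform_edt(vox, sampling=mask.spacing)
    return d_out - d_in


def perturb_acceptable(mask: LabelMask, amplitude_mm: float,
                       seed: int = 0, smoothness_mm: float = 10.0) -> LabelMask:
    """Displace the boundary by a smooth random field of bounded amplitude.

    The new mask is ``{signed_distance <= amplitude * g}`` with ``g`` a
    seeded, Gaussian-smoothed noise field normalised to max |g| = 1, so the
    boundary moves by at most ``amplitude_mm`` (plus voxel discretisation).
    Amplitude 0 returns an identical mask.
    """
    if amplitude_mm < 0:
        raise ValueError("amplitude must be >= 0 mm")
    if amplitude_mm == 0.0:
        return mask.copy()
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(mask.shape)
    sigma_vox = [smoothness_mm / s for s in mask.spacing]
    g = ndimage.gaussian_filter(noise, sigma=sigma_vox)
    g /= max(np.abs(g).max(), 1e-12)
    sdist = _signed_distance(mask)
    out = sdist <= amplitude_mm * g
    return LabelMask(out, mask.spacing, mask.origin, mask.structure_name)


def add_local_bump(mask: LabelMask, height_mm: float, radius_mm: float = 8.0,
                   seed: int = 0, inward: bool | None = None) -> LabelMask:
    """Displace one smooth surface patch by up to ``height_mm``.

    Emulates the regional few-millimetre deviations of a contour scored as
    "needing minor edits": a Gaussian-weighted dome (outward) or dent
    (inward) centred on a random surface point, with lateral scale
    ``radius_mm``. Unlike :func:`perturb_acceptable` the displacement may
    exceed the global noise amplitude, but only over a small surface patch,
    so the contour remains clinically acceptable.
    """
    if height_mm <= 0:
        raise ValueError("bump height must be > 0 mm")
    rng = np.random.default_rng(seed)
    border = mask.voxels & ~ndimage.binary_erosion(mask.voxels,
                                                   structure=_FACE_STRUCT,
                                                   border_value=0)
    idx = np.argwhere(border)
    p = mask.world_coordinates(idx[rng.integers(len(idx))])[0]
    if inward is None:
        inward = bool(rng.random() < 0.5)
    Z, Y, X = _world_grids(mask.shape, mask.spacing)
    sq = (Z - p[0]) ** 2 + (Y - p[1]) ** 2 + (X - p[2]) ** 2
    w = np.exp(-sq / (2.0 * radius_mm ** 2))
    s = -1.0 if inward else 1.0
    out = _signed_distance(mask) <= s * height_mm * w
    if not out.any():
        return mask.copy()
    return LabelMask(out, mask.spacing, mask.origin, mask.structure_name)


def add_surface_artifact(mask: LabelMask, height_mm: float,
                         radius_mm: float = 1.5, seed: int = 0) -> LabelMask:
    """Attach a thin outward "finger" to the surface.

    Emulates the small blobs/tails real autocontours occasionally grow: the
    protrusion raises the Hausdorff distance by roughly ``height_mm`` while
    occupying a tiny fraction of the surface, so surface-Dice and MSD are
    nearly unaffected — the mechanism that makes maximum-distance metrics
    unreliable for acceptability classification.
    """
    if height_mm <= 0:
        raise ValueError("artifact height must be > 0 mm")
    rng = np.random.default_rng(seed)
    border = mask.voxels & ~ndimage.binary_erosion(mask.voxels,
                                                   structure=_FACE_STRUCT,
                                                   border_value=0)
    idx = np.argwhere(border)
    p = mask.world_coordinates(idx[rng.integers(len(idx))])[0]
    centroid = mask.world_coordinates(np.argwhere(mask.voxels)).mean(axis=0)
    u = p - centroid
    norm = np.linalg.norm(u)
    if norm < 1e-9:
        u = np.array([0.0, 0.0, 1.0])
    else:
        u = u / norm
    Z, Y, X = _world_grids(mask.shape, mask.spacing)
    pts = np.stack([Z - p[0], Y - p[1], X - p[2]], axis=-1)
    t = np.clip(pts @ u, 0.0, height_mm)
    closest = t[..., None] * u
    dist = np.linalg.norm(pts - closest, axis=-1)
    finger = dist <= radius_mm
    out = mask.voxels | finger
    return LabelMask(out, mask.spacing, mask.origin, mask.structure_name)


def _integer_shift(vox: np.ndarray, axis: int, n: int) -> np.ndarray:
    out = np.zeros_like(vox)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if n >= 0:
        src[axis] = slice(0, vox.shape[axis] - n)
        dst[axis] = slice(n, None)
    else:
        src[axis] = slice(-n, None)
        dst[axis] = slice(0, vox.shape[axis] + n)
    out[tuple(dst)] = vox[tuple(src)]
    return out


def inject_error(mask: LabelMask, error_type: str, magnitude_mm: float,
                 seed: int = 0) -> LabelMask:
    """Turn a contour into a clinically-unacceptable one.

    Each error has a geometric signature of at least ``magnitude_mm``:

    * ``superior_inferior_truncation`` — removes >= magnitude of cranio-
      caudal (z) extent from a randomly chosen end;
    * ``rigid_shift`` — translates by >= magnitude along a random axis
      (rounded up to whole voxels);
    * ``over_expansion`` — dilates the part of the structure inside a random
      half-space by magnitude;
    * ``component_drop`` — deletes one connected component (error if the
      structure has only one);
    * ``gross_misplacement`` — translates by >= 3 x magnitude (clipped at
      the grid border, as a grossly misplaced contour would be).
    """
    if error_type not in ERROR_TYPES:
        raise ValueError(f"unknown error type {error_type!r}; valid: {ERROR_TYPES}")
    if magnitude_mm <= 0:
        raise ValueError("error magnitude must be > 0 mm")
    rng = np.random.default_rng(seed)
    vox = mask.voxels

    if error_type == "superior_inferior_truncation":
        occupied = np.flatnonzero(vox.any(axis=(1, 2)))
        n_slices = int(np.ceil(magnitude_mm / mask.spacing[0]))
        if n_slices >= len(occupied):
            raise ValueError("truncation magnitude exceeds the structure's "
                             "cranio-caudal extent")
        out = vox.copy()
        if rng.random() < 0.5:  # superior end (largest z)
            out[occupied[-n_slices]:] = False
        else:
            out[:occupied[n_slices - 1] + 1] = False
    elif error_type == "rigid_shift":
        axis = int(rng.integers(3))
        n = max(1, int(np.ceil(magnitude_mm / mask.spacing[axis] - 1e-9)))
        sign = 1 if rng.random() < 0.5 else -1
        out = _integer_shift(vox, axis, sign * n)
        if out.sum() != vox.sum():  # fell off the grid; shift the other way
            out = _integer_shift(vox, axis, -sign * n)
        if not out.any():
            raise ValueError("shift moved the structure entirely off the grid")
    elif error_type == "over_expansion":
        axis = int(rng.integers(3))
        side = rng.random() < 0.5
        centroid_idx = np.argwhere(vox).mean(axis=0)
        coords = np.arange(vox.shape[axis])
        half = coords >= centroid_idx[axis] if side else coords <= centroid_idx[axis]
        shape_sel = [None, None, None]
        shape_sel[axis] = slice(None)
        half = half[tuple(shape_sel)]
        grown = ndimage.distance_transform_edt(~vox, sampling=mask.spacing) \
            <= magnitude_mm
        out = vox | (grown & half)
    elif error_type == "component_drop":
        labels, n_comp = ndimage.label(vox, structure=_FACE_STRUCT)
        if n_comp < 2:
            raise ValueError("component_drop requires >= 2 connected components")
        drop = int(rng.integers(1, n_comp + 1))
        out = vox & (labels != drop)
    else:  # gross_misplacement
        axis = int(rng.integers(3))
        n = int(np.ceil(3.0 * magnitude_mm / mask.spacing[axis]))
        sign = 1 if rng.random() < 0.5 else -1
        out = _integer_shift(vox, axis, sign * n)
        if out.sum() < vox.sum() * 0.25:  # mostly off-grid; try the other way
            out = _integer_shift(vox, axis, -sign * n)
        if not out.any():
            raise ValueError("misplacement moved the structure entirely off "
                             "the grid")
    return LabelMask(out, mask.spacing, mask.origin, mask.structure_name)


# ---------------------------------------------------------------------------
# dataset generation


@dataclass
class SyntheticConfig:
    """Configuration of a synthetic QA study.

    Defaults reproduce the population structure of a per-structure training
    set: 49 internal + 38 external reference-vs-verification pairs, 49
    acceptable and 49 unacceptable manual contours (185 pairs total), with
    smooth acceptable-contour noise of 1.5 mm and error magnitudes of at
    least 5 mm so that acceptable and unacceptable populations are genuinely
    separated.
    """

    n_pairs_per_set: dict = field(default_factory=lambda: {
        "ref_vs_verif_internal": 49,
        "ref_vs_verif_external": 38,
        "acceptable_manual": 49,
        "unacceptable_manual": 49,
    })
    structure_archetype: str = "ellipsoid"
    grid_shape: tuple = DEFAULT_GRID_SHAPE
    spacing: tuple = DEFAULT_SPACING_MM
    acceptable_perturbation_mm: float = 1.5
    verification_noise_internal_mm: float = 0.5
    verification_noise_external_mm: float = 1.5
    error_menu: tuple = ("superior_inferior_truncation", "rigid_shift",
                         "over_expansion", "gross_misplacement")
    error_magnitude_mm: dict = field(default_factory=lambda: {
        "superior_inferior_truncation": (25.0, 35.0),
        "rigid_shift": (5.0, 15.0),
        "over_expansion": (5.0, 12.0),
        "component_drop": (5.0, 5.0),
        "gross_misplacement": (8.0, 12.0),
    })
    unacceptable_rate_internal: float = 0.08
    unacceptable_rate_external: float = 0.13
    artifact_prob: float = 0.35
    artifact_height_mm: tuple = (4.0, 9.0)
    artifact_radius_mm: float = 1.5
    bump_prob: float = 0.6
    bump_count_max: int = 3
    bump_height_mm: tuple = (2.5, 4.5)
    bump_radius_mm: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.structure_archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.structure_archetype!r}")
        unknown = set(self.n_pairs_per_set) - {
            "ref_vs_verif_internal", "ref_vs_verif_external",
            "acceptable_manual", "unacceptable_manual"}
        if unknown:
            raise ValueError(f"unknown source sets {sorted(unknown)}")
        if sum(self.n_pairs_per_set.values()) <= 0:
            raise ValueError("zero pairs requested")
        bad = [e for e in self.error_menu if e not in ERROR_TYPES]
        if bad:
            raise ValueError(f"unknown error types {bad}")
        menu_min = min(self.error_magnitude_mm[e][0] for e in self.error_menu)
        if self.acceptable_perturbation_mm >= menu_min:
            raise ValueError(
                "acceptable perturbation amplitude must be smaller than the "
                "smallest error magnitude (the two populations must separate)"
            )

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("grid_shape", "spacing", "artifact_height_mm",
                    "bump_height_mm", "error_menu"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        if "error_magnitude_mm" in raw:
            raw["error_magnitude_mm"] = {
                k: tuple(v) for k, v in raw["error_magnitude_mm"].items()}
        return cls(**raw)

    def to_yaml(self, path: str | os.PathLike) -> None:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["spacing"] = list(self.spacing)
        d["error_menu"] = list(self.error_menu)
        d["artifact_height_mm"] = list(self.artifact_height_mm)
        d["bump_height_mm"] = list(self.bump_height_mm)
        d["error_magnitude_mm"] = {k: list(v)
                                   for k, v in self.error_magnitude_mm.items()}
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def _applicable_errors(config: SyntheticConfig) -> tuple[str, ...]:
    menu = tuple(config.error_menu)
    if config.structure_archetype != "bean_pair":
        menu = tuple(e for e in menu if e != "component_drop")
    if not menu:
        raise ValueError("error menu is empty for this archetype")
    return menu


def _make_unacceptable(base_ref: LabelMask, config: SyntheticConfig,
                       rng: np.random.Generator) -> tuple[LabelMask, str]:
    menu = _applicable_errors(config)
    error_type = menu[int(rng.integers(len(menu)))]
    lo, hi = config.error_magnitude_mm[error_type]
    magnitude = float(rng.uniform(lo, hi))
    err_seed = int(rng.integers(2 ** 31))
    return inject_error(base_ref, error_type, magnitude, seed=err_seed), error_type


def _make_acceptable(base: LabelMask, config: SyntheticConfig,
                     rng: np.random.Generator) -> LabelMask:
    ref = perturb_acceptable(base, config.acceptable_perturbation_mm,
                             seed=int(rng.integers(2 ** 31)))
    if rng.random() < config.bump_prob:
        lo, hi = config.bump_height_mm
        for _ in range(int(rng.integers(1, config.bump_count_max + 1))):
            ref = add_local_bump(ref, float(rng.uniform(lo, hi)),
                                 radius_mm=config.bump_radius_mm,
                                 seed=int(rng.integers(2 ** 31)))
    if rng.random() < config.artifact_prob:
        lo, hi = config.artifact_height_mm
        ref = add_surface_artifact(ref, float(rng.uniform(lo, hi)),
                                   radius_mm=config.artifact_radius_mm,
                                   seed=int(rng.integers(2 ** 31)))
    return ref


def generate_dataset(config: SyntheticConfig,
                     out_dir: str | os.PathLike | None = None
                     ) -> tuple[list[ContourPair], pd.DataFrame]:
    """Generate the full labelled pair collection plus its manifest.

    Each pair gets its own phantom anatomy; the verification contour is a
    low-noise (internal sets) or moderately noisy (external set) rendition
    of it, and the reference contour is either an acceptable rendition
    (smooth noise, optional finger artifact) or carries one injected error.
    If ``out_dir`` is given, NIfTI masks and ``manifest.csv`` are written
    there in a layout :mod:`contourqa.mask_io` can reload.
    """
    master = np.random.default_rng(config.seed)
    pairs: list[ContourPair] = []
    rows = []
    set_order = ["ref_vs_verif_internal", "ref_vs_verif_external",
                 "acceptable_manual", "unacceptable_manual"]
    counter = 0
    for source_set in set_order:
        n = int(config.n_pairs_per_set.get(source_set, 0))
        for _ in range(n):
            rng = np.random.default_rng(master.integers(2 ** 31))
            base = generate_structure(config.structure_archetype,
                                      config.grid_shape, config.spacing,
                                      seed=int(rng.integers(2 ** 31)))
            verif_noise = (config.verification_noise_external_mm
                           if source_set == "ref_vs_verif_external"
                           else config.verification_noise_internal_mm)
            verification = perturb_acceptable(base, verif_noise,
                                              seed=int(rng.integers(2 ** 31)))
            error_type = ""
            if source_set == "unacceptable_manual":
                label = "unacceptable"
            elif source_set == "acceptable_manual":
                label = "acceptable"
            else:
                rate = (config.unacceptable_rate_internal
                        if source_set == "ref_vs_verif_internal"
                        else config.unacceptable_rate_external)
                label = "unacceptable" if rng.random() < rate else "acceptable"
            if label == "unacceptable":
                seed_ref = perturb_acceptable(
                    base, config.acceptable_perturbation_mm,
                    seed=int(rng.integers(2 ** 31)))
                reference, error_type = _make_unacceptable(seed_ref, config, rng)
            else:
                reference = _make_acceptable(base, config, rng)

            pair_id = f"{config.structure_archetype}_{counter:04d}"
            counter += 1
            pair = ContourPair(reference, verification,
                               structure_name=config.structure_archetype,
                               label=label, source_set="synthetic",
                               pair_id=pair_id)
            pair.source_set = source_set  # set after grid validation
            pairs.append(pair)
            rows.append({
                "pair_id": pair_id,
                "structure": config.structure_archetype,
                "reference_path": f"{pair_id}_ref.nii.gz",
                "verification_path": f"{pair_id}_ver.nii.gz",
                "label": label,
                "source_set": source_set,
                "error_type": error_type,
            })
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for pair, row in zip(pairs, rows):
            write_mask(pair.reference, os.path.join(out_dir, row["reference_path"]))
            write_mask(pair.verification,
                       os.path.join(out_dir, row["verification_path"]))
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return pairs, manifest
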