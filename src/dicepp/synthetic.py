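"""Synthetic class-imbalanced segmentation data and simulated predictors.

The generator emulates the structure of the imaging tasks the losses are
meant for, at desk scale: thin curvilinear "vessel" foregrounds (retinal
vessels), compact "blob" lesions (tumours, polyps, nuclei) and a multi-class
"organ with lesion" layout (organ plus enclosed tumour), all with a small,
controllable foreground fraction, intensity contrast and additive Gaussian
noise.

``simulate_predictor`` produces a probability map from the signed distance to
the true boundary through a logistic with scale ``tau`` — graded uncertainty
near boundaries, confidence deep inside regions.  Label errors ("flips") are
placed preferentially where that base confidence is low, so at ``k = 1`` the
predictor is approximately calibrated: its confidence tracks its actual error
rate, as real segmentation networks err on the structures they are unsure of.
The sharpening exponent ``k`` then emulates the overconfident failure mode:
``k > 1`` pushes probabilities toward {0, 1} without changing the argmax, so
overlap metrics are untouched while proper scores (NLL, Brier) degrade.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .data import ParameterError, as_label_mask

KINDS = ("blob", "vessel", "multiclass-organ")


@dataclass
class SyntheticDatasetConfig:
    """Study conditions for one synthetic dataset.

    Defaults give 200 imbalanced 64x64 binary images with a 5% foreground
    target and additive Gaussian noise of sd 0.3 on an intensity contrast of
    about 0.6 between foreground and background.
    """

    n_images: int = 200
    shape: tuple = (64, 64)
    kind: str = "blob"
    foreground_fraction: float = 0.05
    noise_level: float = 0.3
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return 3 if self.kind == "multiclass-organ" else 2

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ParameterError(f"unknown kind {self.kind!r}; one of {KINDS}")
        if not (0 < self.foreground_fraction < 0.5):
            raise ParameterError("foreground_fraction must lie in (0, 0.5)")
        if len(self.shape) not in (2, 3):
            raise ParameterError("shape must be 2D or 3D")
        if min(self.shape) < 16:
            raise ParameterError("spatial dims must be >= 16")


def _smooth_field(shape, rng, sigma):
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _blob_mask(shape, fraction, rng):
    # threshold a smoothed Gaussian random field at the matching quantile:
    # compact blobs whose total area tracks the requested fraction
    field = _smooth_field(shape, rng, sigma=min(shape) / 10)
    thr = np.quantile(field, 1.0 - fraction)
    return (field > thr).astype(np.int64)


def _vessel_mask(shape, fraction, rng):
    """Connected curvilinear foreground: a random-walk trunk plus branches
    rooted on already-drawn pixels, dilated to width 1-3 px."""
    ndim = len(shape)
    size = int(np.prod(shape))
    target = fraction * size
    path = np.zeros(shape, dtype=bool)
    visited: list[tuple] = []
    width_iter = int(rng.integers(0, 2))  # dilation iterations -> width 1..3
    struct = ndimage.generate_binary_structure(ndim, ndim)  # 8/26-connected

    def realised() -> int:
        if width_iter:
            return int(ndimage.binary_dilation(path, structure=struct,
                                               iterations=width_iter).sum())
        return int(path.sum())

    max_branches = 64
    done = False
    for branch in range(max_branches):
        if done or (branch and realised() >= target):
            break
        if branch == 0 or not visited:
            pos = np.array([rng.uniform(2, s - 2) for s in shape])
        else:
            pos = np.array(visited[rng.integers(len(visited))], dtype=float)
        direction = rng.standard_normal(ndim)
        direction /= np.linalg.norm(direction) + 1e-12
        steps = int(rng.integers(min(shape) // 2, 2 * min(shape)))
        new_px = 0
        for _ in range(steps):
            ij = tuple(int(round(v)) for v in np.clip(pos, 0, np.array(shape) - 1))
            if not path[ij]:
                path[ij] = True
                visited.append(ij)
                new_px += 1
            # exact fraction check every few painted pixels keeps the
            # overshoot past the target small
            if new_px and new_px % 4 == 0 and realised() >= target:
                done = True
                break
            direction += 0.4 * rng.standard_normal(ndim)
            direction /= np.linalg.norm(direction) + 1e-12
            nxt = pos + direction
            # reflect off the borders
            for d, s in enumerate(shape):
                if nxt[d] < 1 or nxt[d] > s - 2:
                    direction[d] *= -1
                    nxt[d] = pos[d] + direction[d]
            pos = nxt
    if width_iter:
        path = ndimage.binary_dilation(path, structure=struct,
                                       iterations=width_iter)
    return path.astype(np.int64)


def _organ_mask(shape, fraction, rng):
    """Class 1: smooth organ blob; class 2: smaller lesion inside it."""
    coords = np.indices(shape).astype(float)
    centre = np.array([rng.uniform(0.35 * s, 0.65 * s) for s in shape])
    # radii sized so the organ covers ~fraction of the image; the overall
    # area scale and the aspect ratio are jittered independently so the
    # realised fraction stays close to the target
    organ_area = fraction * np.prod(shape)
    ndim = len(shape)
    base_r = (organ_area / (np.pi if ndim == 2 else 4 / 3 * np.pi)) ** (1 / ndim)
    area_scale = rng.uniform(0.9, 1.1) ** (1 / ndim)
    aspect = rng.uniform(0.75, 1.3) ** (1 / ndim)
    radii = base_r * area_scale * np.array(
        [aspect if d % 2 else 1.0 / aspect for d in range(ndim)])
    dist = sum(((coords[d] - centre[d]) / radii[d]) ** 2 for d in range(ndim))
    wobble = 0.12 * _smooth_field(shape, rng, sigma=min(shape) / 8)
    organ = dist + wobble < 1.0
    mask = np.where(organ, 1, 0)
    # lesion: smaller ellipse centred inside the organ
    if organ.any():
        pts = np.argwhere(organ)
        c2 = pts[rng.integers(len(pts))].astype(float)
        r2 = radii * rng.uniform(0.3, 0.45)
        d2 = sum(((coords[d] - c2[d]) / max(r2[d], 1.0)) ** 2 for d in range(ndim))
        mask[(d2 < 1.0) & organ] = 2
    return mask.astype(np.int64)


_MASK_FNS = {"blob": _blob_mask, "vessel": _vessel_mask,
             "multiclass-organ": _organ_mask}

#: per-class mean intensities of the rendered image
_CLASS_INTENSITY = (0.2, 0.8, 1.0)


def render_image(mask, rng, noise_level: float = 0.3):
    """Render an intensity image for a mask: class contrast, a smooth bias
    field and additive Gaussian noise."""
    mask = as_label_mask(mask)
    img = np.take(_CLASS_INTENSITY, np.minimum(mask, len(_CLASS_INTENSITY) - 1))
    img = img + 0.1 * _smooth_field(mask.shape, rng, sigma=min(mask.shape) / 4)
    img = img + noise_level * rng.standard_normal(mask.shape)
    return img.astype(np.float64)


def generate_dataset(cfg: SyntheticDatasetConfig):
    """Generate ``cfg.n_images`` (image, mask) pairs, deterministic in seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    mask_fn = _MASK_FNS[cfg.kind]
    out = []
    for _ in range(cfg.n_images):
        # jitter the per-image fraction so the dataset has realistic spread,
        # clipped so every image stays within +/-50% of the configured target
        frac = cfg.foreground_fraction * float(
            np.clip(np.exp(rng.normal(0, 0.15)), 0.8, 1.2))
        frac = min(frac, 0.49)
        mask = mask_fn(cfg.shape, frac, rng)
        img = render_image(mask, rng, cfg.noise_level)
        out.append((img, mask))
    return out


def _signed_distances(mask: np.ndarray, n_classes: int) -> np.ndarray:
    """Per-class signed Euclidean distance: positive inside the class."""
    s = np.empty(mask.shape + (n_classes,))
    for c in range(n_classes):
        inside = mask == c
        s[..., c] = ndimage.distance_transform_edt(inside) - \
            ndimage.distance_transform_edt(~inside)
    return s


def simulate_predictor(truth, tau: float = 2.0, k: float = 1.0,
                       flip_fraction: float = 0.0, seed: int = 0,
                       n_classes: int | None = None) -> np.ndarray:
    """Simulate a segmentation model's probability map for a ground truth.

    Base probabilities are a softmax over per-class signed boundary distances
    scaled by ``tau`` (larger tau = less confident).  ``flip_fraction`` is the
    overall label-error rate; errors are sampled only inside the uncertain
    boundary band, with per-pixel rate proportional to the base uncertainty,
    and the reported confidence there is reset to one minus the local error
    rate — so the k=1 map is calibrated by construction (its confidence
    equals its correctness probability).  ``k >= 1`` sharpens probabilities
    (p**k, renormalised) without changing any argmax, modelling the
    overconfident failure mode; on a calibrated map this strictly degrades
    the proper scores while leaving overlap metrics untouched.
    """
    if tau <= 0:
        raise ParameterError(f"tau must be > 0, got {tau}")
    if k < 1:
        raise ParameterError(f"sharpening k must be >= 1, got {k}")
    if not (0 <= flip_fraction < 0.5):
        raise ParameterError(f"flip_fraction must lie in [0, 0.5), got {flip_fraction}")
    mask = as_label_mask(truth)
    C = int(n_classes or max(int(mask.max()) + 1, 2))
    s = _signed_distances(mask, C)
    z = s / tau
    z -= z.max(axis=-1, keepdims=True)
    p = np.exp(z)
    p /= p.sum(axis=-1, keepdims=True)

    if flip_fraction > 0:
        rng = np.random.default_rng(seed)
        conf = p.max(axis=-1)
        u = 1.0 - conf
        band = u > 0.05  # errors live where the model is genuinely uncertain
        if band.any():
            e = np.zeros_like(u)
            e[band] = flip_fraction * u[band] * u.size / u[band].sum()
            e = np.clip(e, 0.0, 0.45)
            flip = rng.random(mask.shape) < e
            pred = np.where(flip, (mask + 1) % C, mask)
            conf_rep = np.where(band, 1.0 - e, conf)
            # rebuild the map: predicted class gets the calibrated
            # confidence, the remainder is shared in base proportion
            hot = np.zeros_like(p)
            np.put_along_axis(hot, pred[..., None], 1.0, axis=-1)
            rest = p * (1.0 - hot) + 1e-12
            rest /= rest.sum(axis=-1, keepdims=True)
            p = hot * conf_rep[..., None] + rest * (1.0 - conf_rep[..., None])

    if k != 1.0:
        p = p**k
        p /= p.sum(axis=-1, keepdims=True)
    return p


# --- augmentation -----------------------------------------------------------

def mirror_pair(image, mask, axis: int):
    return np.flip(image, axis=axis).copy(), np.flip(mask, axis=axis).copy()


def rotate_pair(image, mask, angle: float):
    """In-plane rotation; nearest-neighbour on the mask keeps labels integral."""
    axes = (-2, -1)
    img = ndimage.rotate(image, angle, axes=axes, reshape=False, order=1,
                         mode="reflect")
    msk = ndimage.rotate(mask, angle, axes=axes, reshape=False, order=0,
                         mode="reflect")
    return img, msk.astype(mask.dtype)


def scale_pair(image, mask, factor: float):
    """Zoom about the centre, then crop/pad back to the original shape."""
    img = ndimage.zoom(image, factor, order=1, mode="reflect")
    msk = ndimage.zoom(mask, factor, order=0, mode="reflect")

    def fit(arr, shape, pad_value):
        slices = []
        pads = []
        for s_out, s_in in zip(shape, arr.shape):
            if s_in >= s_out:
                start = (s_in - s_out) // 2
                slices.append(slice(start, start + s_out))
                pads.append((0, 0))
            else:
                slices.append(slice(None))
                lo = (s_out - s_in) // 2
                pads.append((lo, s_out - s_in - lo))
        arr = arr[tuple(slices)]
        return np.pad(arr, pads, mode="edge")

    return fit(img, image.shape, 0.0), fit(msk, mask.shape, 0).astype(mask.dtype)


def elastic_pair(image, mask, alpha: float, sigma: float, rng):
    """Elastic deformation: Gaussian-smoothed random displacement fields of
    magnitude alpha and smoothness sigma applied to both arrays."""
    shape = mask.shape
    coords = np.indices(shape).astype(np.float64)
    warped = [c + alpha * ndimage.gaussian_filter(
        rng.uniform(-1, 1, shape), sigma, mode="reflect") for c in coords]
    img = ndimage.map_coordinates(image, warped, order=1, mode="reflect")
    msk = ndimage.map_coordinates(mask, warped, order=0, mode="reflect")
    return img, msk.astype(mask.dtype)


def brightness_pair(image, mask, factor: float):
    return image * factor, mask


_AUG_NAMES = ("scale", "rotate", "mirror_v", "mirror_h", "elastic", "brightness")


def augment(image, mask, rng, probability: float = 0.15):
    """With the given probability apply one randomly chosen transform:
    scaling 0.85-1.25x, rotation +/-15 deg, vertical/horizontal mirroring,
    elastic deformation (alpha in [0, 900], sigma in [9, 13]) or brightness
    0.5-2x (image only).  Otherwise returns the pair unchanged."""
    if rng.random() >= probability:
        return image, mask
    name = _AUG_NAMES[rng.integers(len(_AUG_NAMES))]
    if name == "scale":
        return scale_pair(image, mask, rng.uniform(0.85, 1.25))
    if name == "rotate":
        return rotate_pair(image, mask, rng.uniform(-15.0, 15.0))
    if name == "mirror_v":
        return mirror_pair(image, mask, -2)
    if name == "mirror_h":
        return mirror_pair(image, mask, -1)
    if name == "elastic":
        return elastic_pair(image, mask, rng.uniform(0, 900), rng.uniform(9.0, 13.0), rng)
    return brightness_pair(image, mask, rng.uniform(0.5, 2.0))


def sample_patches(volume, mask, patch_shape, overlap, rng, n_patches=None):
    """Random patches whose origins lie on the stride grid implied by the
    overlap (stride = patch - overlap), with end-aligned origins added so the
    grid covers the whole volume.

    Returns a list of (patch, mask_patch) pairs, all exactly ``patch_shape``.
    With ``n_patches=None`` every grid origin is returned once, in random
    order.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    patch_shape = tuple(int(s) for s in patch_shape)
    overlap = tuple(int(o) for o in overlap)
    if any(ps > vs for ps, vs in zip(patch_shape, volume.shape)):
        raise ParameterError(
            f"patch {patch_shape} larger than volume {volume.shape}")
    if any(o >= ps for o, ps in zip(overlap, patch_shape)):
        raise ParameterError("overlap must be smaller than the patch elementwise")
    axes_starts = []
    for vs, ps, ov in zip(volume.shape, patch_shape, overlap):
        stride = ps - ov
        starts = list(range(0, vs - ps + 1, stride))
        if starts[-1] != vs - ps:
            starts.append(vs - ps)
        axes_starts.append(starts)
    origins = np.array(np.meshgrid(*axes_starts, indexing="ij")).reshape(
        len(patch_shape), -1).T
    if n_patches is None:
        idx = rng.permutation(len(origins))
    else:
        idx = rng.choice(len(origins), size=n_patches,
                         replace=n_patches > len(origins))
    out = []
    for i in idx:
        sl = tuple(slice(o, o + ps) for o, ps in zip(origins[i], patch_shape))
        out.append((volume[sl], mask[sl]))
    return out


def zscore_normalize(image) -> np.ndarray:
    """Per-image z-score: output has mean 0 and sd 1; a constant image maps
    to zeros with a warning."""
    img = np.asarray(image, dtype=np.float64)
    if img.size < 2:
        raise ParameterError("z-score needs at least 2 pixels")
    sd = img.std()
    if sd == 0:
        warnings.warn("constant image: z-score undefined, returning zeros")
        return np.zeros_like(img)
    return (img - img.mean()) / sd
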