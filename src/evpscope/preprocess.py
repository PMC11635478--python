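"""Illumination flattening and diffuse-background removal.

The pipeline order is fixed: flat-field correction first (division by the
normalized Gaussian-blurred image, removing multiplicative illumination
inhomogeneity while preserving relative spot intensities), then rolling-ball
background subtraction (removing additive diffuse background such as the
camera offset and out-of-focus haze).  Defaults correspond to a 7.5 µm blur
and a 12.5 µm ball at the 0.25 µm/px scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import block_reduce
from skimage.restoration import ellipsoid_kernel, rolling_ball
from skimage.transform import resize

from .fields import FieldImage

log = logging.getLogger(__name__)

__all__ = ["PreprocessParams", "flat_field_correct", "rolling_ball_subtract", "preprocess_field"]


@dataclass(frozen=True)
class PreprocessParams:
    blur_radius_px: float = 30.0
    ball_radius_px: float = 50.0

    def __post_init__(self) -> None:
        if self.blur_radius_px < 1 or self.ball_radius_px < 1:
            raise ValueError("blur and ball radii must be >= 1 px")


def flat_field_correct(image: np.ndarray, blur_radius_px: float = 30.0) -> np.ndarray:
    """Divide out the low-frequency illumination profile.

    The profile is estimated as the Gaussian blur of the image (sigma =
    ``blur_radius_px``) normalized by its own mean, so a spot of fixed true
    intensity measures the same regardless of where it sits on the gain
    ramp.  The overall image mean is preserved exactly.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if blur_radius_px < 1:
        raise ValueError("blur_radius_px must be >= 1")
    # odd reflection extrapolates linear trends across the border, so a
    # linear illumination ramp is estimated without edge flattening
    pad = min(int(np.ceil(4 * blur_radius_px)), min(img.shape) - 1)
    padded = np.pad(img, pad, mode="reflect", reflect_type="odd")
    blurred = gaussian_filter(padded, sigma=blur_radius_px, mode="nearest")
    blurred = blurred[pad:-pad, pad:-pad]
    mean = blurred.mean()
    if mean <= 0:
        raise ValueError("image mean must be positive for flat-field correction")
    gain = blurred / mean
    floor = 1e-6
    bad = gain <= floor
    if bad.any():
        log.warning("flat-field: clamped %d near-zero gain pixels", int(bad.sum()))
        gain = np.where(bad, floor, gain)
    out = img / gain
    out = np.clip(out, 0.0, None)
    out_mean = out.mean()
    if out_mean > 0:
        out *= img.mean() / out_mean
    return out


def rolling_ball_subtract(
    image: np.ndarray, ball_radius_px: float = 50.0, downscale: int | None = None
) -> np.ndarray:
    """Subtract the morphological rolling-ball background estimate.

    The background is the surface traced by a ball of the given radius
    rolled under the intensity landscape; features narrower than the ball
    (diffraction-limited spots) ride on top and are preserved.  For speed
    the background is estimated on a down-scaled copy with a proportionally
    smaller radius, then bilinearly upsampled — background variation at the
    ball scale survives this unchanged.  Output is clipped at zero.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("empty image")
    if (img < 0).any():
        raise ValueError("rolling-ball input must be non-negative")
    if ball_radius_px >= min(img.shape):
        raise ValueError("ball radius must be smaller than the image")
    if downscale is None:
        downscale = max(1, int(ball_radius_px // 12))
    downscale = max(1, int(downscale))
    if downscale > 1 and min(img.shape) // downscale >= 8:
        # shrink by block minimum (keeps the background a lower envelope of
        # the noise, so subtraction does not rectify it), roll the ball at
        # the reduced radius, then upsample
        d = downscale
        pad = ((0, -img.shape[0] % d), (0, -img.shape[1] % d))
        padded = np.pad(img, pad, mode="edge")
        small = block_reduce(padded, (d, d), np.min)
        # spatial axes shrink by d but intensities do not: the ball becomes
        # an ellipsoid with spatial semi-axis r/d and intensity semi-axis r,
        # which preserves its curvature on the original grid
        a = max(ball_radius_px / d, 1.0)
        kernel = ellipsoid_kernel((2 * a, 2 * a), 2 * ball_radius_px)
        bg_small = rolling_ball(small, kernel=kernel)
        bg = resize(bg_small, padded.shape, order=1, mode="edge")[
            : img.shape[0], : img.shape[1]
        ]
    else:
        bg = rolling_ball(img, radius=ball_radius_px)
    return np.clip(img - bg, 0.0, None)


def preprocess_field(field: FieldImage, params: PreprocessParams | None = None) -> FieldImage:
    """Flat-field then rolling-ball, each channel independently."""
    params = params or PreprocessParams()
    channels = {
        c: rolling_ball_subtract(
            flat_field_correct(img, params.blur_radius_px), params.ball_radius_px
        )
        for c, img in field.channels.items()
    }
    return FieldImage(channels=channels, pixel_size_um=field.pixel_size_um,
                      field_id=field.field_id)
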