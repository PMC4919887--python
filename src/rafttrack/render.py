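"""Rendering of synthetic diffraction-limited image stacks (16-bit TIFF)."""

from __future__ import annotations

import logging
from typing import List, Sequence

import numpy as np
import tifffile

from .params import ImageParams
from .trajectory import Trajectory

log = logging.getLogger(__name__)


def render_frames(tracks: Sequence[Trajectory], image_params: ImageParams,
                  seed: int = 0) -> np.ndarray:
    """Render one 16-bit frame per time point with Gaussian spots.

    Each molecule contributes a 2D Gaussian of integrated intensity
    ``photons`` and sigma ``psf_sigma`` (µm); Poisson noise is applied to
    the summed expectation including the uniform ``background``.
    Molecules outside the field are clipped with a logged warning.
    Returns an (n_frames, H, W) uint16 array.
    """
    ip = image_params
    h, w = ip.shape
    if tracks:
        n_frames = int(max(t.frames.max() for t in tracks)) + 1
    else:
        n_frames = 1
    yy, xx = np.mgrid[0:h, 0:w]
    px = ip.pixel_size
    sig_px = ip.psf_sigma / px
    expect = np.full((n_frames, h, w), float(ip.background))
    clipped = 0
    for t in tracks:
        cx = t.x / px
        cy = t.y / px
        for k, f in enumerate(t.frames):
            if not (0 <= cx[k] < w and 0 <= cy[k] < h):
                clipped += 1
                continue
            g = np.exp(-((xx - cx[k]) ** 2 + (yy - cy[k]) ** 2) / (2 * sig_px**2))
            expect[f] += ip.photons * g / (2 * np.pi * sig_px**2)
    if clipped:
        log.warning("%d localizations fell outside the field and were clipped", clipped)
    rng = np.random.default_rng(seed)
    stack = rng.poisson(expect).astype(np.uint16)
    return stack


def write_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, stack.astype(np.uint16))


def read_tiff(path) -> np.ndarray:
    return tifffile.imread(path)
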