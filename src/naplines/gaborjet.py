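"""GaborJet V1-like features and cosine similarity.

The model samples the magnitudes of complex (quadrature-pair) Gabor filter
responses at a fixed spatial grid of "jets", concatenates them into one
feature vector per image, and compares images by the cosine of the angle
between their vectors.  It is the standard low-level audit used to check
that metric and nonaccidental stimulus variants are equally distant from
their base stimulus in early-visual terms: if the nonaccidental variant
were systematically *less* similar to the base, a behavioral advantage
could be a mere contrast artifact.

Phase is discarded; only magnitudes enter the feature vector.  Feature
ordering is row-major over (grid_y, grid_x, scale, orientation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .geometry import Triplet
from .render import RenderConfig, rasterize

__all__ = [
    "JetGridConfig",
    "JetFeatures",
    "TripletAudit",
    "make_filter_bank",
    "extract_jets",
    "cosine_similarity",
    "cosine_dissimilarity",
    "audit_triplets",
    "summarize_audit",
    "mirror_permutation",
]


@dataclass(frozen=True)
class JetGridConfig:
    grid_size: int = 12
    n_scales: int = 5
    n_orientations: int = 8
    freq_min: float = 2.0  # cycles per image
    freq_max: float = 16.0
    sigma: float = 2.0 * math.pi  # Gaussian envelope width in carrier units

    def __post_init__(self) -> None:
        if min(self.grid_size, self.n_scales, self.n_orientations) < 1:
            raise ValueError("grid_size, n_scales, n_orientations must be >= 1")
        if not 0 < self.freq_min < self.freq_max:
            raise ValueError("need 0 < freq_min < freq_max")

    def frequencies(self, image_side: int) -> np.ndarray:
        """Log-spaced spatial frequencies, decreasing across scales (c/img)."""
        return np.geomspace(self.freq_max, self.freq_min, self.n_scales)

    def orientations(self) -> np.ndarray:
        """Orientation angles in radians, [0, pi)."""
        return np.arange(self.n_orientations) * math.pi / self.n_orientations

    @property
    def n_features(self) -> int:
        return self.grid_size**2 * self.n_scales * self.n_orientations


@dataclass(frozen=True)
class JetFeatures:
    magnitudes: np.ndarray
    config: JetGridConfig

    def __post_init__(self) -> None:
        if self.magnitudes.shape != (self.config.n_features,):
            raise ValueError(
                f"feature vector length {self.magnitudes.shape} inconsistent "
                f"with config ({self.config.n_features},)"
            )


@dataclass(frozen=True)
class TripletAudit:
    triplet_id: str
    condition: str
    sim_nap_base: float
    sim_mp_base: float
    matched: bool


def _gabor_kernel(image_side: int, freq: float, theta: float,
                  sigma: float) -> np.ndarray:
    """Zero-DC complex Gabor kernel (Lades-style parametrization).

    ``freq`` in cycles/image is converted to the carrier wavenumber
    k = 2*pi*freq/side (radians/pixel); the Gaussian envelope has standard
    deviation sigma/k pixels.  The kernel is truncated at 2.5 envelope
    standard deviations, capped at the image side, and DC-corrected after
    truncation so a uniform field elicits zero response.
    """
    k = 2.0 * math.pi * freq / image_side
    std = sigma / k
    half = min(int(math.ceil(2.5 * std)), (image_side - 1) // 2)
    ax = np.arange(-half, half + 1)
    xx, yy = np.meshgrid(ax, ax)
    kx, ky = k * math.cos(theta), k * math.sin(theta)
    envelope = np.exp(-(xx**2 + yy**2) * (k * k) / (2.0 * sigma * sigma))
    carrier = np.exp(1j * (kx * xx + ky * yy))
    kern = envelope * carrier
    # remove the DC component of the (truncated) kernel
    kern -= envelope * (kern.sum() / envelope.sum())
    return kern * (k * k / (sigma * sigma))


def make_filter_bank(image_side: int, cfg: JetGridConfig | None = None
                     ) -> list[list[np.ndarray]]:
    """Complex kernels indexed [scale][orientation].

    Raises if the image is too small to host even the smallest kernel.
    """
    cfg = cfg or JetGridConfig()
    if image_side < 3:
        raise ValueError(f"image side {image_side} smaller than any kernel")
    bank = []
    for freq in cfg.frequencies(image_side):
        k = 2.0 * math.pi * freq / image_side
        min_half = int(math.ceil(2.5 * cfg.sigma / k))
        if 2 * min(min_half, (image_side - 1) // 2) + 1 > image_side:
            raise ValueError(
                f"kernel for frequency {freq:.2f} c/img larger than the image"
            )
        bank.append(
            [_gabor_kernel(image_side, freq, th, cfg.sigma)
             for th in cfg.orientations()]
        )
    return bank


def _grid_indices(image_side: int, grid_size: int) -> np.ndarray:
    """Pixel indices of the uniformly spaced jet grid."""
    return np.round((np.arange(grid_size) + 0.5) * image_side / grid_size - 0.5
                    ).astype(int)


_BANK_CACHE: dict[tuple, list[list[np.ndarray]]] = {}


def extract_jets(image: np.ndarray, cfg: JetGridConfig | None = None) -> JetFeatures:
    """Sample complex filter magnitudes on the jet grid.

    The image mean is removed before filtering (the kernels are zero-DC, so
    this only suppresses boundary-padding artifacts of the convolution).
    """
    cfg = cfg or JetGridConfig()
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError(f"image must be square, got shape {image.shape}")
    side = image.shape[0]
    if side < cfg.grid_size:
        raise ValueError("image side smaller than the jet grid")
    key = (side, cfg)
    bank = _BANK_CACHE.get(key)
    if bank is None:
        bank = make_filter_bank(side, cfg)
        _BANK_CACHE[key] = bank
    img = image.astype(np.float64) - float(image.mean())
    idx = _grid_indices(side, cfg.grid_size)
    mags = np.empty((cfg.grid_size, cfg.grid_size, cfg.n_scales,
                     cfg.n_orientations))
    for si, row in enumerate(bank):
        for oi, kern in enumerate(row):
            resp = fftconvolve(img, kern, mode="same")
            mags[:, :, si, oi] = np.abs(resp)[np.ix_(idx, idx)]
    return JetFeatures(mags.ravel(), cfg)


def cosine_similarity(a: JetFeatures | np.ndarray,
                      b: JetFeatures | np.ndarray) -> float:
    """dot(a,b)/(|a||b|); in [0, 1] for nonnegative magnitude vectors."""
    va = a.magnitudes if isinstance(a, JetFeatures) else np.asarray(a, float)
    vb = b.magnitudes if isinstance(b, JetFeatures) else np.asarray(b, float)
    if va.shape != vb.shape:
        raise ValueError(f"length mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(va, vb) / (na * nb))


def cosine_dissimilarity(a, b) -> float:
    return 1.0 - cosine_similarity(a, b)


def mirror_permutation(cfg: JetGridConfig, axis: str) -> np.ndarray:
    """Feature-index permutation matching an image mirror.

    Mirroring an image left-right maps the jet at grid column j to column
    G-1-j and orientation theta to pi-theta; up-down flips grid rows and
    negates theta.  Returns indices P with features(mirror(img)) ==
    features(img)[P] (up to filter discretization error).
    """
    G, S, O = cfg.grid_size, cfg.n_scales, cfg.n_orientations
    gy, gx, sc, ori = np.meshgrid(np.arange(G), np.arange(G), np.arange(S),
                                  np.arange(O), indexing="ij")
    if axis == "left_right":
        gx = G - 1 - gx
    elif axis == "up_down":
        gy = G - 1 - gy
    else:
        raise ValueError(f"unknown mirror axis: {axis!r}")
    ori = (O - ori) % O  # theta -> pi - theta for either single-axis flip
    return (((gy * G + gx) * S + sc) * O + ori).ravel()


def audit_triplets(
    triplets: list[Triplet],
    render_cfg: RenderConfig | None = None,
    jet_cfg: JetGridConfig | None = None,
    matched_tol: float = 0.01,
) -> list[TripletAudit]:
    """Low-level matchedness audit of base/metric/nonaccidental triplets.

    Renders each variant in its canonical pose (no jitter), extracts jets,
    and compares each variant with the base by cosine similarity.  A
    triplet is "properly matched" when the nonaccidental variant is at
    least as similar to the base as the metric variant is, within
    ``matched_tol`` (i.e. equal within tolerance, or NAP-closer).
    """
    render_cfg = render_cfg or RenderConfig()
    jet_cfg = jet_cfg or JetGridConfig()
    audits = []
    for t in triplets:
        jets = {
            v.variant: extract_jets(rasterize(v, render_cfg), jet_cfg)
            for v in t.stimuli
        }
        sim_nap = cosine_similarity(jets["nonaccidental"], jets["base"])
        sim_mp = cosine_similarity(jets["metric"], jets["base"])
        audits.append(
            TripletAudit(
                triplet_id=t.triplet_id,
                condition=t.condition,
                sim_nap_base=sim_nap,
                sim_mp_base=sim_mp,
                matched=bool(sim_nap >= sim_mp - matched_tol),
            )
        )
    return audits


def audit_frame(audits: list[TripletAudit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "triplet_id": [a.triplet_id for a in audits],
            "condition": [a.condition for a in audits],
            "sim_nap_base": [a.sim_nap_base for a in audits],
            "sim_mp_base": [a.sim_mp_base for a in audits],
            "matched": [a.matched for a in audits],
        }
    )


def summarize_audit(audits: list[TripletAudit]) -> tuple[float, pd.DataFrame]:
    """Fraction matched plus per-condition mean similarities with standard
    errors over the triplets of each condition."""
    df = audit_frame(audits)
    frac = float(df["matched"].mean())
    g = df.groupby("condition")
    summary = g.agg(
        sim_nap_mean=("sim_nap_base", "mean"),
        sim_nap_sem=("sim_nap_base", "sem"),
        sim_mp_mean=("sim_mp_base", "mean"),
        sim_mp_sem=("sim_mp_base", "sem"),
        n_triplets=("triplet_id", "count"),
        frac_matched=("matched", "mean"),
    ).reset_index()
    return frac, summary
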