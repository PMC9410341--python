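"""Synthetic planar fluorescence-reflectance images of heart slices.

The slice is a disc of tissue on a dark off-tissue background.  A smaller
disc inside the tissue is the infarct/target region whose expected mean
intensity is ``ratio`` times the remote-tissue mean; the remote mask is
the tissue away from the infarct (with a safety margin).  Gaussian noise
of a given SD is added everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from stormquant.fri import FRISlice

__all__ = ["SliceSimSpec", "SliceGroundTruth", "simulate_fri_slice"]


@dataclass
class SliceSimSpec:
    """Parameters of one synthetic slice image."""

    shape: tuple[int, int] = (128, 128)
    infarct_center_frac: tuple[float, float] = (0.38, 0.38)  # (row, col) of image
    infarct_radius_frac: float = 0.12
    tissue_radius_frac: float = 0.40
    intensity_ratio: float = 3.0          # infarct mean / remote mean
    remote_mean: float = 100.0
    off_tissue_mean: float = 5.0
    noise_sd: float = 0.0                 # absolute intensity units
    assay: str = "annexin"
    seed: int = 0

    def validate(self) -> None:
        if self.intensity_ratio <= 0:
            raise ValueError("intensity_ratio must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.infarct_radius_frac >= self.tissue_radius_frac:
            raise ValueError("infarct must fit inside the tissue disc")


@dataclass
class SliceGroundTruth:
    """Planted truth for one synthetic slice (JSON-serializable)."""

    intensity_ratio: float
    remote_mean: float
    infarct_mask: np.ndarray
    remote_mask: np.ndarray

    def to_dict(self) -> dict:
        return {
            "intensity_ratio": self.intensity_ratio,
            "remote_mean": self.remote_mean,
            "infarct_mask": self.infarct_mask.astype(int).tolist(),
            "remote_mask": self.remote_mask.astype(int).tolist(),
        }


def simulate_fri_slice(spec: SliceSimSpec) -> tuple[FRISlice, SliceGroundTruth]:
    """Generate one slice image with remote / target / off-tissue masks.

    The expected pixel mean over the infarct mask equals
    ``intensity_ratio`` times the expected mean over the remote mask.
    Rejects geometries where the masks would overlap.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    scale = min(h, w)
    rr, cc = np.mgrid[0:h, 0:w]

    tc = (h / 2.0, w / 2.0)
    tissue = (rr - tc[0]) ** 2 + (cc - tc[1]) ** 2 <= (spec.tissue_radius_frac * scale) ** 2
    ic = (spec.infarct_center_frac[0] * h, spec.infarct_center_frac[1] * w)
    d2 = (rr - ic[0]) ** 2 + (cc - ic[1]) ** 2
    infarct = tissue & (d2 <= (spec.infarct_radius_frac * scale) ** 2)
    margin = 1.5 * spec.infarct_radius_frac * scale
    remote = tissue & (d2 > margin ** 2)
    off_tissue = ~tissue
    if np.any(infarct & remote):
        raise ValueError("infarct and remote masks overlap")
    if not remote.any() or not infarct.any():
        raise ValueError("degenerate geometry: empty remote or infarct mask")

    img = np.full((h, w), spec.off_tissue_mean, dtype=float)
    img[tissue] = spec.remote_mean
    img[infarct] = spec.intensity_ratio * spec.remote_mean
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, img.shape)

    sl = FRISlice(
        image=img,
        remote_mask=remote,
        target_mask=infarct,
        background_mask=off_tissue,
        slice_id=f"sim-{spec.seed}",
        assay=spec.assay,
    )
    truth = SliceGroundTruth(
        intensity_ratio=spec.intensity_ratio,
        remote_mean=spec.remote_mean,
        infarct_mask=infarct,
        remote_mask=remote,
    )
    return sl, truth
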