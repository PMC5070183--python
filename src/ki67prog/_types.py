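"""Shared dataclasses used by both the synthetic generator and the scorer.

Kept in a private module to avoid an import cycle: the generator renders
images with the stain basis, and the scorer inverts the same basis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class StainVectors:
    """Optical-density stain basis for H-DAB colour deconvolution.

    Each vector holds the optical density contributed per unit stain
    concentration in the R, G, B channels.  Defaults are the widely used
    published H-DAB pair; the residual vector completes an invertible
    basis as the normalised cross product of the first two.
    """

    hematoxylin_od: tuple[float, float, float] = (0.65, 0.70, 0.29)
    dab_od: tuple[float, float, float] = (0.27, 0.57, 0.78)
    residual_od: tuple[float, float, float] | None = None

    def matrix(self) -> np.ndarray:
        """3x3 matrix whose *columns* are the unit-norm stain vectors."""
        hem = np.asarray(self.hematoxylin_od, dtype=float)
        dab = np.asarray(self.dab_od, dtype=float)
        for name, v in (("hematoxylin", hem), ("dab", dab)):
            if np.linalg.norm(v) <= 0:
                raise ValueError(f"{name} OD vector must have positive norm")
        hem = hem / np.linalg.norm(hem)
        dab = dab / np.linalg.norm(dab)
        if self.residual_od is None:
            res = np.cross(hem, dab)
        else:
            res = np.asarray(self.residual_od, dtype=float)
        if np.linalg.norm(res) <= 0:
            raise ValueError("residual OD vector must have positive norm")
        res = res / np.linalg.norm(res)
        return np.column_stack([hem, dab, res])

    def inverse(self) -> np.ndarray:
        m = self.matrix()
        cond = np.linalg.cond(m)
        if not np.isfinite(cond) or cond > 1e8:
            raise ValueError(
                f"stain matrix is singular or near-singular (condition number {cond:.3g})"
            )
        return np.linalg.inv(m)


@dataclass
class CoreImage:
    """One digitised TMA core: an 8-bit RGB photograph plus its scale.

    ``mpp`` is microns per pixel; core sizes in the emulated studies run
    0.6-1.0 mm so a whole core spans roughly 600-2000 px depending on
    magnification.
    """

    pixels: np.ndarray
    mpp: float
    core_id: str = ""
    patient_id: str = ""
    study_id: str = ""
    tma_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("CoreImage.pixels must be an HxWx3 RGB array")
        if self.pixels.shape[0] <= 0 or self.pixels.shape[1] <= 0:
            raise ValueError("CoreImage must have positive height and width")
        if self.mpp <= 0:
            raise ValueError("mpp (microns per pixel) must be positive")


@dataclass
class CoreScore:
    """Nuclei counts and % positive malignant nuclei for one core."""

    core_id: str
    patient_id: str
    n_total_malignant: int
    n_positive: int
    study_id: str = ""
    qc_pass: bool | None = None
    qc_reason: str = ""

    def __post_init__(self) -> None:
        if not 0 <= self.n_positive <= max(self.n_total_malignant, 0):
            raise ValueError("need 0 <= n_positive <= n_total_malignant")

    @property
    def ki67_pct(self) -> float:
        """Percent positive malignant nuclei; NaN when no malignant nuclei."""
        if self.n_total_malignant == 0:
            return float("nan")
        return 100.0 * self.n_positive / self.n_total_malignant
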