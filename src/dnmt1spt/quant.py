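"""Supporting quantifications outside the tracking stack.

Three small computations: the size-scaling regression of diffusion
coefficients against MW^(-1/3) (a Stokes-Einstein relation, since the
hydrodynamic radius of a roughly globular protein scales with the cube
root of its molecular weight), molecule counting against a fluorescence
standard of known copy number, and chromatin/nucleoplasm fractionation
ratios from loading-normalized gel intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ScalingFit", "stokes_einstein_fit", "molecule_count",
           "fractionation_ratio", "ratio_summary"]


@dataclass
class ScalingFit:
    """OLS fit of D against MW^(-1/3)."""

    slope: float
    intercept: float
    residuals: np.ndarray
    predictor: np.ndarray     # MW^(-1/3) values
    fitted: np.ndarray


def stokes_einstein_fit(molecular_weights, diffusion_coeffs) -> ScalingFit:
    """Ordinary least squares of D (µm²/s) on MW^(-1/3) (MW in kDa)."""
    mw = np.asarray(molecular_weights, float)
    D = np.asarray(diffusion_coeffs, float)
    if mw.shape != D.shape or mw.size < 2:
        raise ValueError("need >= 2 paired (MW, D) points")
    if np.any(mw <= 0) or np.any(D <= 0):
        raise ValueError("molecular weights and diffusion coefficients must be > 0")
    x = mw ** (-1.0 / 3.0)
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all molecular weights equal")
    A = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(A, D, rcond=None)
    fitted = slope * x + intercept
    return ScalingFit(float(slope), float(intercept), D - fitted, x, fitted)


def molecule_count(sample_signal: float, background_signal: float,
                   standard_signal: float, standard_count: float) -> float:
    """Molecules per cell by linear interpolation against a copy-number standard.

    count = (sample - background) / (standard - background) * standard_count.
    The standard's absolute copy number is a required input (it comes from
    independent calibration, never from this package).
    """
    if standard_signal <= background_signal:
        raise ValueError("standard signal must exceed background")
    num = sample_signal - background_signal
    if num < 0:
        warnings.warn("sample signal below background; clipping count to 0",
                      stacklevel=2)
        return 0.0
    return num / (standard_signal - background_signal) * standard_count


def fractionation_ratio(chromatin_target: float, chromatin_loading: float,
                        nucleoplasm_target: float, nucleoplasm_loading: float) -> float:
    """Chromatin/nucleoplasm ratio of loading-normalized target intensities."""
    if chromatin_loading <= 0 or nucleoplasm_loading <= 0:
        raise ValueError("loading normalizer intensities must be > 0")
    nuc = nucleoplasm_target / nucleoplasm_loading
    if nuc == 0:
        raise ValueError("nucleoplasmic normalized intensity is 0")
    return (chromatin_target / chromatin_loading) / nuc


def ratio_summary(ratios) -> tuple[float, float]:
    """Mean and standard error of replicate ratios."""
    r = np.asarray(ratios, float)
    if r.size < 2:
        raise ValueError("need >= 2 replicates for a standard error")
    return float(r.mean()), float(r.std(ddof=1) / np.sqrt(r.size))
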