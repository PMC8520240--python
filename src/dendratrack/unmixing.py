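"""Linear spectral unmixing of rD2 against autofluorescence by NNLS.

Observed 561-nm-excited emission spectra are decomposed into a
non-negative combination of the filter-corrected rD2 reference and a
broad autofluorescence reference.  The rD2 coefficient is reported
normalized to the autofluorescence coefficient, which cancels
multiplicative gain (laser power, optical alignment) between sessions —
the quantity tracked across days to follow converted-protein decay.

An optional third gD2 column supports 488-nm-excited data; the default
two-component set reflects that the 561-nm long-pass detection path
suppresses green emission.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from dendratrack import photophysics as pp
from dendratrack.photophysics import FilterSpec, WavelengthGrid


@dataclass
class ReferenceMatrix:
    """Stacked component spectra on a common wavelength grid."""

    components: list[str]
    matrix: np.ndarray  # (n_wavelengths, n_components)
    grid: WavelengthGrid
    filter_applied: FilterSpec | None = None

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.components):
            raise ValueError("matrix must be (n_wavelengths, n_components)")
        if np.any(self.matrix < 0):
            raise ValueError("reference columns must be non-negative")
        if np.any(np.all(self.matrix == 0, axis=0)):
            raise ValueError("reference matrix contains an all-zero column")


@dataclass
class UnmixResult:
    coefficients: dict[str, float]
    residual_norm: float
    normalized_rd2: float | None  # rD2 ÷ autofluorescence; None if AF = 0

    def __post_init__(self) -> None:
        if any(c < -1e-12 for c in self.coefficients.values()):
            raise ValueError("unmixed coefficients must be non-negative")


def build_reference_matrix(grid: WavelengthGrid | None = None,
                           include_gd2: bool = False,
                           filt: FilterSpec | None = None,
                           ) -> ReferenceMatrix:
    """rD2 + autofluorescence references through the 561 LP detection filter.

    With ``include_gd2`` a filtered gD2 column is added (for 488-excited
    spectra use a 503 LP filter instead).
    """
    grid = grid or WavelengthGrid()
    filt = filt or pp.DEFAULT_FILTERS[pp.RED_EX_NM]
    spectra = {s.name: s for s in pp.build_reference_spectra(grid)}
    names = ["rD2", "autofluorescence"] + (["gD2"] if include_gd2 else [])
    cols = [pp.apply_filter(spectra[n].emission_curve, filt, grid)
            for n in names]
    return ReferenceMatrix(components=names,
                           matrix=np.column_stack(cols), grid=grid,
                           filter_applied=filt)


def average_replicates(spectra: list[np.ndarray]) -> np.ndarray:
    """Pointwise mean of replicate spectra (e.g. 20 × 1000-ms acquisitions)."""
    if len(spectra) == 0:
        raise ValueError("need at least one spectrum to average")
    lengths = {len(s) for s in spectra}
    if len(lengths) != 1:
        raise ValueError("replicate spectra must share one wavelength grid")
    arr = np.asarray(spectra, dtype=float)
    if np.any(arr < 0):
        raise ValueError("spectra must be non-negative")
    return arr.mean(axis=0)


def _detection_band(refs: ReferenceMatrix) -> np.ndarray:
    """Wavelength mask over which the residual is meaningful: where the
    detection filter passes (or everywhere, if no filter was applied)."""
    if refs.filter_applied is None:
        return np.ones(len(refs.grid), dtype=bool)
    return refs.filter_applied.transmission(refs.grid) > 0.5


def nnls_unmix(observed: np.ndarray, refs: ReferenceMatrix) -> UnmixResult:
    """Non-negative least-squares decomposition of one observed spectrum.

    Residual is the RMS misfit over the filtered detection band only.
    An all-zero observation yields all-zero coefficients and zero residual.
    """
    observed = np.asarray(observed, dtype=float)
    if len(observed) != len(refs.grid):
        raise ValueError("observed spectrum length does not match the "
                         "reference wavelength grid")
    if np.all(observed == 0):
        coeffs = {name: 0.0 for name in refs.components}
        return UnmixResult(coefficients=coeffs, residual_norm=0.0,
                           normalized_rd2=None)
    coef, _ = scipy.optimize.nnls(refs.matrix, observed)
    band = _detection_band(refs)
    misfit = (refs.matrix @ coef - observed)[band]
    residual = float(np.sqrt(np.mean(misfit ** 2))) if band.any() else 0.0
    coeffs = dict(zip(refs.components, map(float, coef)))
    af = coeffs.get("autofluorescence", 0.0)
    normalized = coeffs.get("rD2", 0.0) / af if af > 0 else None
    return UnmixResult(coefficients=coeffs, residual_norm=residual,
                       normalized_rd2=normalized)


def quantify_rd2_timecourse(daily_spectra: list[np.ndarray],
                            refs: ReferenceMatrix,
                            days: list[float] | None = None,
                            ) -> list[tuple[float, float]]:
    """Normalized rD2 per day from a series of observed spectra.

    Days with a zero autofluorescence coefficient are flagged as missing
    (NaN), never as zero signal.
    """
    if len(daily_spectra) < 2:
        raise ValueError("need at least two timepoints")
    days = list(days) if days is not None else list(range(len(daily_spectra)))
    if len(days) != len(daily_spectra):
        raise ValueError("days and spectra must pair up")
    out = []
    for day, spec in zip(days, daily_spectra):
        result = nnls_unmix(spec, refs)
        value = (result.normalized_rd2
                 if result.normalized_rd2 is not None else math.nan)
        out.append((day, value))
    return out
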