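"""Theoretical singly charged b/y fragment ions and observed-intensity tables.

For a peptide of length ``n`` the b series covers prefixes 1..n-1 and the y
series suffixes 1..n-1, all at charge 1 (the series the intensity models are
trained for). Observed intensities are extracted by nearest-peak matching
within a ppm or Da tolerance and normalized to the spectrum's total ion
current before a log2 transform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np

from .constants import PROTON_MASS, RESIDUE_MASS, WATER_MASS
from .io import Peptidoform, Spectrum

__all__ = [
    "FragmentTable",
    "theoretical_fragment_mz",
    "annotate_spectrum",
    "normalize_log_intensities",
    "DEFAULT_PSEUDOCOUNT",
]

DEFAULT_PSEUDOCOUNT = 0.001


@dataclass
class FragmentTable:
    peptidoform: Peptidoform
    b_mz: np.ndarray
    y_mz: np.ndarray
    b_obs: np.ndarray
    y_obs: np.ndarray
    normalized: bool = False
    tic: float = 0.0

    @property
    def n_sites(self) -> int:
        return len(self.b_mz)

    def concatenated(self) -> np.ndarray:
        """b then y intensities as one vector (the per-PSM correlation target)."""
        return np.concatenate([self.b_obs, self.y_obs])

    @property
    def n_matched(self) -> int:
        if self.normalized:
            raise ValueError("matched-ion count is defined on raw intensities")
        return int((self.b_obs > 0).sum() + (self.y_obs > 0).sum())


@lru_cache(maxsize=65536)
def _fragment_mz_cached(peptidoform: Peptidoform):
    seq = peptidoform.sequence
    n = len(seq)
    residue = np.array([RESIDUE_MASS[a] for a in seq])
    residue = residue + peptidoform.residue_mod_mass()
    if n < 2:
        b_mz, y_mz = np.empty(0), np.empty(0)
    else:
        b_mz = np.cumsum(residue)[:-1] + PROTON_MASS
        y_mz = np.cumsum(residue[::-1])[:-1] + WATER_MASS + PROTON_MASS
    b_mz.setflags(write=False)
    y_mz.setflags(write=False)
    return b_mz, y_mz


def theoretical_fragment_mz(peptidoform: Peptidoform) -> tuple[np.ndarray, np.ndarray]:
    """Singly charged b and y ion m/z arrays, each of length ``n - 1``.

    ``b_i`` is the first-``i``-residues prefix plus a proton; ``y_i`` is the
    last-``i``-residues suffix plus water and a proton. Modifications
    (terminal ones folded into the first/last residue) travel with their
    residue. Results are memoized per peptidoform and returned read-only.
    """
    return _fragment_mz_cached(peptidoform)


def _match_peaks(
    theo: np.ndarray, spectrum: Spectrum, tolerance: float, unit: str
) -> np.ndarray:
    """Nearest observed peak within tolerance per theoretical ion (0 if none).

    One observed peak may serve several theoretical ions; each theoretical ion
    takes at most one peak, the closest in m/z.
    """
    obs = np.zeros(len(theo))
    if len(spectrum.mz) == 0 or len(theo) == 0:
        return obs
    idx = np.searchsorted(spectrum.mz, theo)
    left = np.clip(idx - 1, 0, len(spectrum.mz) - 1)
    right = np.clip(idx, 0, len(spectrum.mz) - 1)
    d_left = np.abs(spectrum.mz[left] - theo)
    d_right = np.abs(spectrum.mz[right] - theo)
    nearest = np.where(d_left <= d_right, left, right)
    dist = np.minimum(d_left, d_right)
    if unit == "ppm":
        limit = theo * tolerance * 1e-6
    elif unit == "da":
        limit = np.full_like(theo, tolerance)
    else:
        raise ValueError(f"unknown tolerance unit {unit!r}")
    hit = dist <= limit
    obs[hit] = spectrum.intensity[nearest[hit]]
    return obs


def annotate_spectrum(
    spectrum: Spectrum,
    peptidoform: Peptidoform,
    tolerance: float = 10.0,
    unit: str = "ppm",
) -> FragmentTable:
    """Extract observed b/y intensities from a spectrum (unmatched ions -> 0)."""
    b_mz, y_mz = theoretical_fragment_mz(peptidoform)
    return FragmentTable(
        peptidoform=peptidoform,
        b_mz=b_mz,
        y_mz=y_mz,
        b_obs=_match_peaks(b_mz, spectrum, tolerance, unit),
        y_obs=_match_peaks(y_mz, spectrum, tolerance, unit),
        normalized=False,
        tic=spectrum.tic,
    )


def normalize_log_intensities(
    table: FragmentTable,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    tic: float | None = None,
) -> FragmentTable:
    """TIC-normalize then log2-transform observed intensities.

    The denominator is the full spectrum's total ion current (all peaks, not
    only annotated ones); pass ``tic`` to override, e.g. for annotated-only
    normalization. A zero TIC maps every value to ``log2(pseudocount)``.
    """
    if table.normalized:
        raise ValueError("table is already normalized")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be positive")
    denom = table.tic if tic is None else tic
    if denom <= 0:
        b = np.full_like(table.b_obs, np.log2(pseudocount))
        y = np.full_like(table.y_obs, np.log2(pseudocount))
    else:
        b = np.log2(table.b_obs / denom + pseudocount)
        y = np.log2(table.y_obs / denom + pseudocount)
    return replace(table, b_obs=b, y_obs=y, normalized=True)
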