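"""Heavy-fraction identification from density-gradient qPCR profiles.

Per-fraction qPCR signal for a target taxon is normalized to its maximum
across the gradient, 13C/12C ratios are formed on a common density grid
(replicates averaged per condition first), and fractions are selected for
pooling where the ratio exceeds a threshold inside a buoyant-density window.
The selection is scale-free: absolute gene copy numbers never matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "QPCRProfile",
    "normalize_to_max",
    "enrichment_ratio",
    "select_heavy_fractions",
    "DEFAULT_RATIO_THRESHOLD",
    "DEFAULT_DENSITY_WINDOW",
]

#: Ratio cutoff mirroring the observed 2.0-2.2x enrichment in selected fractions.
DEFAULT_RATIO_THRESHOLD = 2.0

#: Buoyant-density window (g/mL) used for pooling heavy DNA.
DEFAULT_DENSITY_WINDOW = (1.700, 1.705)


class DegenerateProfileError(ValueError):
    """All-zero qPCR profile cannot be normalized."""


@dataclass(frozen=True)
class QPCRProfile:
    """qPCR signal across gradient fractions for one gradient.

    ``densities`` (g/mL) must be strictly monotone; ``signals`` >= 0.
    """

    densities: tuple[float, ...]
    signals: tuple[float, ...]
    condition: str = "13C"
    replicate: str = "1"

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        s = np.asarray(self.signals, dtype=float)
        if d.size != s.size or d.size == 0:
            raise ValueError("densities and signals must be equal-length, non-empty")
        diffs = np.diff(d)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("densities must be strictly monotone")
        if np.any(s < 0):
            raise ValueError("signals must be non-negative")
        object.__setattr__(self, "densities", tuple(d))
        object.__setattr__(self, "signals", tuple(s))

    def ascending(self) -> "QPCRProfile":
        if self.densities[0] < self.densities[-1]:
            return self
        return replace(
            self, densities=self.densities[::-1], signals=self.signals[::-1]
        )


def normalize_to_max(profile: QPCRProfile) -> QPCRProfile:
    """Divide every signal by the profile maximum; output maximum is 1."""
    peak = max(profile.signals)
    if peak <= 0:
        raise DegenerateProfileError("all-zero qPCR profile")
    return replace(profile, signals=tuple(s / peak for s in profile.signals))


def _average_normalized(
    profiles: QPCRProfile | Sequence[QPCRProfile], grid: np.ndarray
) -> np.ndarray:
    if isinstance(profiles, QPCRProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("need at least one profile")
    interped = []
    for p in profiles:
        p = p.ascending()
        interped.append(np.interp(grid, p.densities, p.signals))
    return np.mean(interped, axis=0)


def enrichment_ratio(
    profiles_13c: QPCRProfile | Sequence[QPCRProfile],
    profiles_12c: QPCRProfile | Sequence[QPCRProfile],
    density_grid: Sequence[float],
) -> list[tuple[float, float]]:
    """13C/12C normalized-signal ratio at each grid density.

    Both inputs must already be normalized to their maxima; replicate profiles
    are averaged per condition after linear interpolation onto the grid. Where
    the 12C signal interpolates to zero the ratio is reported as +inf with a
    warning.
    """
    grid = np.asarray(density_grid, dtype=float)
    s13 = _average_normalized(profiles_13c, grid)
    s12 = _average_normalized(profiles_12c, grid)
    if np.any(s12 == 0):
        warnings.warn(
            "12C signal is zero at some grid densities; ratio reported as +inf",
            RuntimeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(s12 > 0, s13 / s12, np.where(s13 > 0, np.inf, np.nan))
    return list(zip(grid.tolist(), ratio.tolist()))


def select_heavy_fractions(
    ratios: Sequence[tuple[float, float]],
    ratio_threshold: float = DEFAULT_RATIO_THRESHOLD,
    density_window: tuple[float, float] | None = DEFAULT_DENSITY_WINDOW,
    window_width: float = 0.005,
) -> list[float]:
    """Grid densities where ratio >= threshold and density lies in the window.

    With ``density_window=None`` the window is chosen post hoc: a band of
    ``window_width`` g/mL centered on the density of the maximum finite ratio
    (argmax mode). An empty selection triggers a warning, not an error.
    """
    if ratio_threshold <= 1:
        raise ValueError("ratio_threshold must exceed 1")
    dens = np.array([d for d, _ in ratios], dtype=float)
    vals = np.array([r for _, r in ratios], dtype=float)
    if density_window is None:
        finite = np.where(np.isfinite(vals), vals, -np.inf)
        center = dens[int(np.argmax(finite))]
        density_window = (center - window_width / 2, center + window_width / 2)
    lo, hi = min(density_window), max(density_window)
    with np.errstate(invalid="ignore"):
        keep = (vals >= ratio_threshold) & (dens >= lo) & (dens <= hi)
    selected = dens[keep].tolist()
    if not selected:
        warnings.warn(
            f"no fraction passed ratio >= {ratio_threshold} within "
            f"[{lo:.3f}, {hi:.3f}] g/mL",
            RuntimeWarning,
            stacklevel=2,
        )
    return selected
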