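"""Grating stimulus ensemble: direction x spatial frequency x temporal frequency grid."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["StimulusEnsemble", "default_ensemble"]


def _octave_grid(lo: float, n: int) -> np.ndarray:
    return lo * 2.0 ** np.arange(n)


@dataclass(frozen=True)
class StimulusEnsemble:
    """Full-field grating ensemble with a stationary and a moving phase.

    Stimulus types enumerate the Cartesian product direction x SF x TF, with
    direction varying slowest and temporal frequency fastest.  Frequencies are
    expressed both in physical units and in octaves relative to the lowest
    probed value (log2 units).

    Parameters
    ----------
    directions : array of float
        Drift directions in degrees.
    spatial_freqs : array of float
        Spatial frequencies in cycles/deg, log-spaced.
    temporal_freqs : array of float
        Temporal frequencies in Hz, log-spaced.
    n_stationary_frames, n_moving_frames : int
        Imaging frames acquired during each phase of one stimulus.
    moving_window : (int, int)
        First and last frame index (0-based, inclusive) used when averaging
        the moving-phase response.
    volume_rate : float
        Imaging volume rate in Hz.
    """

    directions: np.ndarray = field(
        default_factory=lambda: np.arange(8) * 45.0
    )
    spatial_freqs: np.ndarray = field(
        default_factory=lambda: _octave_grid(0.01, 6)
    )
    temporal_freqs: np.ndarray = field(
        default_factory=lambda: _octave_grid(0.5, 6)
    )
    n_stationary_frames: int = 8
    n_moving_frames: int = 8
    moving_window: tuple[int, int] | None = None
    volume_rate: float = 3.7

    def __post_init__(self):
        object.__setattr__(self, "directions", np.asarray(self.directions, float))
        object.__setattr__(self, "spatial_freqs", np.asarray(self.spatial_freqs, float))
        object.__setattr__(self, "temporal_freqs", np.asarray(self.temporal_freqs, float))
        if self.moving_window is None:
            a = self.n_stationary_frames
            b = self.n_stationary_frames + self.n_moving_frames - 1
            object.__setattr__(self, "moving_window", (a, b))
        a, b = self.moving_window
        if not (0 <= a <= b <= self.n_frames - 1):
            raise ValueError(
                f"moving_window {self.moving_window} outside frame range "
                f"[0, {self.n_frames - 1}]"
            )

    @property
    def n_stim(self) -> int:
        """Number of distinct stimulus types (|dir| * |SF| * |TF|)."""
        return len(self.directions) * len(self.spatial_freqs) * len(self.temporal_freqs)

    @property
    def n_frames(self) -> int:
        return self.n_stationary_frames + self.n_moving_frames

    @property
    def sf_octaves(self) -> np.ndarray:
        """Probed spatial frequencies in octaves relative to the lowest."""
        return np.log2(self.spatial_freqs / self.spatial_freqs[0])

    @property
    def tf_octaves(self) -> np.ndarray:
        return np.log2(self.temporal_freqs / self.temporal_freqs[0])

    def grid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-stimulus (direction_deg, sf_octaves, tf_octaves) arrays, length n_stim."""
        d, s, t = np.meshgrid(
            self.directions, self.sf_octaves, self.tf_octaves, indexing="ij"
        )
        return d.ravel(), s.ravel(), t.ravel()

    def table(self) -> pd.DataFrame:
        d, s, t = self.grid()
        return pd.DataFrame(
            {
                "stimulus": np.arange(self.n_stim),
                "direction_deg": d,
                "sf_cpd": self.spatial_freqs[0] * 2.0 ** s,
                "tf_hz": self.temporal_freqs[0] * 2.0 ** t,
                "sf_oct": s,
                "tf_oct": t,
            }
        )

    @property
    def moving_mask(self) -> np.ndarray:
        m = np.zeros(self.n_frames, bool)
        m[self.n_stationary_frames:] = True
        return m


def default_ensemble() -> StimulusEnsemble:
    """The 6 SF x 6 TF x 8 direction ensemble used throughout."""
    return StimulusEnsemble()
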