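"""Flashed square-wave grating ensembles.

The stimulus set is a grid of square-wave gratings: a few spatial
frequencies (parameterised by bar width in microns on the retina) crossed
with equally spaced spatial phases.  Each grating is flashed for a fixed
duration and followed by a uniform gray mask; a "trial" is one flash.

Stimuli are indexed sorted by spatial frequency (ascending) then phase, so
with four bar widths and eight phases, stimuli 0-7 are the lowest
frequency, 8-15 the next, and so on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["StimulusEnsemble", "Stimulus", "make_grating_ensemble", "grating_profile"]


@dataclass(frozen=True)
class Stimulus:
    """A single grating: spatial frequency + phase.

    ``bar_width`` is half the spatial period (one bright or dark bar), in
    microns on the retina.  ``phase_deg`` in degrees; a 45 degree step
    corresponds to a spatial shift of 1/4 bar width.
    """

    index: int
    bar_width: float
    frequency: float  # cycles per degree
    phase_deg: float

    @property
    def period(self) -> float:
        """Spatial period in microns (two bars)."""
        return 2.0 * self.bar_width

    @property
    def phase_offset_um(self) -> float:
        """Spatial offset of the grating in microns for this phase."""
        return self.phase_deg / 360.0 * self.period


@dataclass(frozen=True)
class StimulusEnsemble:
    """Grating geometry and trial timing for one experiment.

    frequency = microns_per_degree / (2 * bar_width) for each bar width.
    """

    bar_widths: tuple[float, ...]
    microns_per_degree: float
    phases_deg: tuple[float, ...]
    flash_duration: float
    gray_duration: float
    n_trials: int
    stimuli: tuple[Stimulus, ...] = field(repr=False)

    @property
    def frequencies(self) -> tuple[float, ...]:
        """Spatial frequencies in cycles/degree, ascending."""
        return tuple(self.microns_per_degree / (2.0 * bw) for bw in self.bar_widths)

    @property
    def printed_frequencies(self) -> tuple[float, ...]:
        """Frequencies truncated (toward zero) to 3 decimals, the convention
        used when quoting them in cpd."""
        return tuple(math.floor(f * 1000) / 1000 for f in self.frequencies)

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def n_phases(self) -> int:
        return len(self.phases_deg)

    @property
    def trial_duration(self) -> float:
        """Full trial window: flash + gray mask, seconds."""
        return self.flash_duration + self.gray_duration

    def stimulus(self, index: int) -> Stimulus:
        return self.stimuli[index]

    def stimuli_for_frequency(self, freq_index: int) -> list[int]:
        """Stimulus indices (sorted by phase) for one spatial frequency."""
        p = self.n_phases
        return list(range(freq_index * p, (freq_index + 1) * p))

    def to_dict(self) -> dict:
        return {
            "bar_widths": list(self.bar_widths),
            "microns_per_degree": self.microns_per_degree,
            "n_phases": self.n_phases,
            "flash_duration": self.flash_duration,
            "gray_duration": self.gray_duration,
            "n_trials": self.n_trials,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusEnsemble":
        return make_grating_ensemble(
            bar_widths=d["bar_widths"],
            microns_per_degree=d["microns_per_degree"],
            n_phases=d["n_phases"],
            flash_duration=d["flash_duration"],
            gray_duration=d["gray_duration"],
            n_trials=d["n_trials"],
        )


def make_grating_ensemble(
    bar_widths,
    microns_per_degree: float = 30.0,
    n_phases: int = 8,
    flash_duration: float = 0.5,
    gray_duration: float = 1.0,
    n_trials: int = 105,
) -> StimulusEnsemble:
    """Build a grating ensemble from bar widths (µm) and a phase count.

    Phases are equally spaced over 360°; phase step k corresponds to a
    spatial offset of k/4 × bar width when ``n_phases`` is 8.  Stimuli are
    ordered by ascending frequency, then ascending phase.
    """
    bar_widths = [float(b) for b in bar_widths]
    if not bar_widths or any(b <= 0 for b in bar_widths):
        raise ValueError("bar widths must be positive")
    if microns_per_degree <= 0:
        raise ValueError("microns_per_degree must be positive")
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    if flash_duration <= 0 or gray_duration < 0:
        raise ValueError("flash_duration must be > 0 and gray_duration >= 0")

    phases = tuple(360.0 * k / n_phases for k in range(n_phases))
    # sort bar widths descending so frequencies come out ascending
    widths_sorted = tuple(sorted(bar_widths, reverse=True))
    stimuli = []
    idx = 0
    for bw in widths_sorted:
        freq = microns_per_degree / (2.0 * bw)
        for ph in phases:
            stimuli.append(Stimulus(index=idx, bar_width=bw, frequency=freq, phase_deg=ph))
            idx += 1
    return StimulusEnsemble(
        bar_widths=widths_sorted,
        microns_per_degree=float(microns_per_degree),
        phases_deg=phases,
        flash_duration=float(flash_duration),
        gray_duration=float(gray_duration),
        n_trials=int(n_trials),
        stimuli=tuple(stimuli),
    )


def grating_profile(x, stimulus: Stimulus):
    """Square-wave luminance (+1 bright / -1 dark) at retinal position x (µm).

    Position 0 with phase 0 sits at the start of a bright bar; increasing
    phase shifts the grating toward positive x.
    """
    x = np.asarray(x, dtype=float)
    rel = np.mod(x - stimulus.phase_offset_um, stimulus.period)
    return np.where(rel < stimulus.bar_width, 1.0, -1.0)
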