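"""Stimulation paradigm timing and BOLD-domain regressors.

The experimental design modeled here is a block paradigm repeated over
several short fMRI runs: a pre-stimulation baseline, a brief stimulation
epoch, and a post-stimulation baseline.  Participants are informed of the
upcoming stimulus type partway through the pre-stimulation period, which
matters for windowed analyses (anticipation vs. stimulation).

Stimulus-locked regressors are formed by convolving the stimulation boxcar
with a canonical double-gamma hemodynamic response function (HRF) and
sampling the result at the repetition time (TR).  No hemodynamic
deconvolution is performed anywhere in this package: all modeled signals
live in the BOLD domain, so stimulus timing must enter through this
convolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Paradigm", "canonical_hrf", "make_paradigm_regressor"]


@dataclass(frozen=True)
class Paradigm:
    """Timing of one block-design run, repeated ``n_runs`` times.

    Defaults describe a 270 s run sampled at TR 6.75 s (40 volumes/run,
    200 volumes over 5 runs): 120 s baseline, 30 s stimulation, 120 s
    post-stimulation, with the stimulus type announced at the 60 s mark.
    """

    pre_s: float = 120.0
    stim_s: float = 30.0
    post_s: float = 120.0
    tr: float = 6.75
    n_runs: int = 5
    informed_at_s: float = 60.0

    def __post_init__(self) -> None:
        for name in ("pre_s", "stim_s", "post_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Paradigm.{name} must be positive")
        if self.tr <= 0:
            raise ValueError("Paradigm.tr must be positive")
        if self.n_runs < 1:
            raise ValueError("Paradigm.n_runs must be >= 1")
        if self.tr >= self.run_duration_s:
            raise ValueError("Paradigm.tr must be shorter than one run")
        if not 0 <= self.informed_at_s <= self.pre_s:
            raise ValueError("informed_at_s must fall within the pre-stimulation period")

    @property
    def run_duration_s(self) -> float:
        return self.pre_s + self.stim_s + self.post_s

    @property
    def volumes_per_run(self) -> int:
        return int(self.run_duration_s // self.tr)

    @property
    def total_volumes(self) -> int:
        return self.volumes_per_run * self.n_runs

    @property
    def runs(self) -> list[tuple[int, int]]:
        """Run boundaries as (start, length) over the concatenated axis."""
        v = self.volumes_per_run
        return [(r * v, v) for r in range(self.n_runs)]

    def stimulation_mask(self) -> np.ndarray:
        """Boolean mask of volumes acquired during stimulation (all runs)."""
        t = np.arange(self.volumes_per_run) * self.tr
        one = (t >= self.pre_s) & (t < self.pre_s + self.stim_s)
        return np.tile(one, self.n_runs)

    def prestimulation_mask(self) -> np.ndarray:
        """Volumes before stimulation onset, in every run."""
        t = np.arange(self.volumes_per_run) * self.tr
        return np.tile(t < self.pre_s, self.n_runs)

    def stimulation_inclusive_mask(self) -> np.ndarray:
        """Volumes from stimulation onset to the end of each run."""
        return ~self.prestimulation_mask()


def canonical_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    ratio: float = 1.0 / 6.0,
    dispersion: float = 1.0,
) -> np.ndarray:
    """Canonical double-gamma HRF evaluated at times ``t`` (seconds).

    The response is a gamma density peaking near ``peak_delay - dispersion``
    seconds minus a scaled gamma density modeling the post-stimulus
    undershoot.  With the defaults the mode sits at ~5 s, the standard
    shape used to project stimulus timing into the BOLD domain.
    """
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    peak = gamma.pdf(t, peak_delay / dispersion, scale=dispersion)
    under = gamma.pdf(t, undershoot_delay / dispersion, scale=dispersion)
    return peak - ratio * under


def make_paradigm_regressor(
    p: Paradigm,
    dt: float = 0.1,
    hrf_length_s: float = 32.0,
    normalize: bool = True,
) -> np.ndarray:
    """Paradigm-locked regressor over the concatenated time axis.

    A unit boxcar spanning the stimulation epoch is convolved with the
    canonical HRF on a fine grid (``dt`` seconds), sampled at volume
    acquisition times, truncated to the run length, and tiled across runs.
    With ``normalize`` the template is scaled to unit peak so that a fixed
    latent's fitted amplitude is expressed in percent-signal-change units.
    """
    run_s = p.run_duration_s
    t_hi = np.arange(0.0, run_s, dt)
    box = ((t_hi >= p.pre_s) & (t_hi < p.pre_s + p.stim_s)).astype(float)
    h = canonical_hrf(np.arange(0.0, hrf_length_s + dt, dt))
    conv = np.convolve(box, h)[: t_hi.size] * dt
    vol_times = np.arange(p.volumes_per_run) * p.tr
    idx = np.clip(np.round(vol_times / dt).astype(int), 0, t_hi.size - 1)
    one_run = conv[idx]
    if normalize:
        peak = np.max(np.abs(one_run))
        if peak > 0:
            one_run = one_run / peak
    return np.tile(one_run, p.n_runs)
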