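"""Synthetic replica of the behavioral study design.

The experiment crossed three hydrodynamic treatments (freestream flow,
a high-periodicity Karman-vortex-street array, and a low-periodicity
parallel-vortex-street array) with three flow speeds (22, 48 and
74 cm/s) for five fish, collecting sixteen tail beats per combination,
grouped into four four-beat sequences.

Two levels of synthesis are offered:

* :func:`trial_specs` maps every fish x treatment x speed cell to a
  :class:`~wakekin.synthetic.swimmer.SwimmerSpec`, for exercising the
  full landmark -> midline -> kinematics chain;
* :func:`synthesize_study_kinematics` draws the per-sequence kinematic
  responses directly (cell mean + fish intercept + sequence noise,
  amplitudes varied multiplicatively so they are log-normal), producing
  the tidy table the statistics stage consumes.

The cell means emulate the qualitative pattern of station-holding
trout: tail-beat frequency rises with flow speed but less steeply
behind cylinders; snout and COM amplitudes rise with speed and behind
cylinders; the tail amplitude is largest behind the high-periodicity
array; wavelength is nearly flat.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .swimmer import SwimmerSpec

TREATMENTS = ("freestream", "KVS", "PVS")
SPEEDS_CM_S = (22, 48, 74)
RESPONSES = ("f_Hz", "wavelength_L", "amp_snout_L", "amp_com_L", "amp_tail_L")


def _default_cell_means() -> dict:
    f_free = {22: 3.2, 48: 4.6, 74: 5.8}
    f_cyl = {22: 3.0, 48: 3.7, 74: 4.3}      # lower rise behind cylinders
    snout = {22: 0.015, 48: 0.022, 74: 0.025}
    com = {22: 0.020, 48: 0.028, 74: 0.032}
    tail = {22: 0.110, 48: 0.120, 74: 0.130}
    means: dict = {}
    for sp in SPEEDS_CM_S:
        for tr in TREATMENTS:
            cyl = tr != "freestream"
            means[(tr, sp)] = {
                "f_Hz": f_cyl[sp] if cyl else f_free[sp],
                "wavelength_L": 1.05 + (0.03 if cyl else 0.0),
                "amp_snout_L": snout[sp] + (0.006 if cyl else 0.0),
                "amp_com_L": com[sp]
                + (0.006 if tr == "PVS" else 0.003 if tr == "KVS" else 0.0),
                "amp_tail_L": tail[sp] + (0.030 if tr == "KVS" else 0.0),
            }
    return means


@dataclass
class StudyDesign:
    """Factor levels, replication and variability of the synthetic study."""

    treatments: tuple[str, ...] = TREATMENTS
    speeds_cm_s: tuple[int, ...] = SPEEDS_CM_S
    n_fish: int = 5
    sequences_per_trial: int = 4
    beats_per_sequence: int = 4
    body_length: float = 0.074            # m (mean of the study animals)
    frame_rate: float = 100.0             # Hz
    fish_sd_frac: float = 0.04            # per-fish random intercept, x mean
    resid_sd_frac: float = 0.07           # per-sequence noise, x mean
    cell_means: dict = field(default_factory=_default_cell_means)

    @property
    def beats_per_trial(self) -> int:
        return self.sequences_per_trial * self.beats_per_sequence


def trial_specs(
    design: StudyDesign, seed: int = 0, landmark_noise_sd: float = 0.002
) -> list[dict]:
    """One swimmer spec per fish x treatment x speed cell.

    Per-fish variation enters as a multiplicative intercept shared
    across that fish's cells.  Returns dicts with keys ``fish_id``,
    ``treatment``, ``speed``, ``spec`` and ``duration`` (sized to cover
    the design's beat count plus margin).
    """
    rng = np.random.default_rng(seed)
    fish_effect = rng.normal(1.0, design.fish_sd_frac, design.n_fish)
    trials = []
    for i_fish in range(design.n_fish):
        for tr in design.treatments:
            for sp in design.speeds_cm_s:
                m = design.cell_means[(tr, sp)]
                fe = fish_effect[i_fish]
                spec = SwimmerSpec(
                    body_length=design.body_length,
                    tailbeat_frequency=m["f_Hz"] * fe,
                    body_wavelength=m["wavelength_L"],
                    amplitude_snout=m["amp_snout_L"] * fe,
                    amplitude_tail=m["amp_tail_L"] * fe,
                    frame_rate=design.frame_rate,
                    landmark_noise_sd=landmark_noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                duration = (design.beats_per_trial + 1.5) / spec.tailbeat_frequency
                trials.append(
                    {
                        "fish_id": f"fish_{i_fish + 1}",
                        "treatment": tr,
                        "speed": sp,
                        "spec": spec,
                        "duration": duration,
                    }
                )
    return trials


def synthesize_study_kinematics(
    design: StudyDesign | None = None, seed: int = 0
) -> pd.DataFrame:
    """Draw the per-sequence kinematics table directly.

    Returns the tidy layout consumed by the statistics stage:
    ``fish_id, treatment, speed, sequence, f_Hz, wavelength_L,
    amp_snout_L, amp_com_L, amp_tail_L, qc_flag``.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    fish_effect = rng.normal(1.0, design.fish_sd_frac, design.n_fish)
    rows = []
    for i_fish in range(design.n_fish):
        for tr in design.treatments:
            for sp in design.speeds_cm_s:
                m = design.cell_means[(tr, sp)]
                for seq in range(1, design.sequences_per_trial + 1):
                    row = {
                        "fish_id": f"fish_{i_fish + 1}",
                        "treatment": tr,
                        "speed": sp,
                        "sequence": seq,
                        "qc_flag": "ok",
                    }
                    for resp in RESPONSES:
                        noise = rng.normal(0.0, design.resid_sd_frac)
                        base = m[resp] * fish_effect[i_fish]
                        if resp.startswith("amp"):
                            # multiplicative noise: log-amplitudes are normal
                            row[resp] = base * np.exp(noise)
                        else:
                            row[resp] = base * (1.0 + noise)
                    rows.append(row)
    return pd.DataFrame(rows)
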