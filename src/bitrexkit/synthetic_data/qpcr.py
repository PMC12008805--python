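"""Population-average copy-number measurement series.

Emulates the qPCR time course used to track array copy number: the
measurement at each time point is the population mean copy number plus
Gaussian noise, with replicate structure preserved.  Generations are mapped
to days through ``g_per_day`` (divisions per day, as counted from optical-
density fold change under a serial-dilution culture regime).
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .population import PopulationTrajectory

SERIES_COLUMNS = ("day", "replicate", "copy_number")


def simulate_qpcr_series(
    trajectories: Sequence[PopulationTrajectory],
    noise_sd: float,
    seed: int = 0,
    *,
    g_per_day: float = 6.0,
    sample_every: int = 1,
) -> pd.DataFrame:
    """Measurement series (day, replicate, copy_number) from replicate runs.

    One replicate per trajectory; every ``sample_every``-th generation is
    measured.  ``noise_sd = 0`` returns the population means exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if g_per_day <= 0:
        raise ValueError("g_per_day must be > 0")
    if sample_every < 1:
        raise ValueError("sample_every must be >= 1")
    rng = np.random.default_rng(seed)
    rows: list[tuple[float, int, float]] = []
    for rep, traj in enumerate(trajectories):
        for j in range(0, len(traj.generations), sample_every):
            day = float(traj.generations[j]) / g_per_day
            value = float(traj.mean_copy[j])
            if noise_sd > 0:
                value += rng.normal(0.0, noise_sd)
            rows.append((day, rep, value))
    return pd.DataFrame(rows, columns=list(SERIES_COLUMNS))
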