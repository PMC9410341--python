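import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from stormquant import (
    EcgSimSpec,
    MovieSimSpec,
    classify_beat_origin,
    detect_r_peaks,
    simulate_calcium_movie,
    simulate_ecg,
)
from stormquant.simulate import PlantedEpisode, sample_separated_cells


@pytest.fixture(scope="session")
def sinus_trace():
    """20 s of clean 550 bpm sinus rhythm plus its ground truth."""
    return simulate_ecg(EcgSimSpec(duration_s=20.0, seed=11))


@pytest.fixture(scope="session")
def storm_trace():
    """60 s recording with one VT run, one Vfib segment and one
    extrasystole, at 5% noise — the full arrhythmia phenotype."""
    spec = EcgSimSpec(
        duration_s=60.0,
        planted_episodes=[
            PlantedEpisode("VT", 10.0, 3.0, 1100.0),
            PlantedEpisode("extrasystole", 25.0, 0.05),
            PlantedEpisode("Vfib", 40.0, 4.0),
        ],
        noise_sd_mv=0.05,
        seed=5,
    )
    return simulate_ecg(spec)


@pytest.fixture(scope="session")
def storm_beats(storm_trace):
    trace, _ = storm_trace
    return classify_beat_origin(detect_r_peaks(trace))


def study_movie_spec(seed: int, mode: str = "uniform", n_neutrophils: int = 15,
                     cluster_radius_um: float = 25.0) -> MovieSimSpec:
    """One field of view under the study conditions: 10x10 myocyte grid at
    2 µm/px, 8 Hz pacing, 30 cycles, three well-separated dyssynchronous
    cells with 8–12% cycle jitter, noise at 1/5 of the transient
    amplitude (SNR 5)."""
    rng = np.random.default_rng(seed)
    cells = sample_separated_cells(rng, (10, 10), 3)
    jitter = rng.uniform(0.08, 0.12, 3)
    return MovieSimSpec(
        grid=(10, 10),
        dyssync_cells={c: float(j) for c, j in zip(cells, jitter)},
        neutrophil_mode=mode,
        n_neutrophils=n_neutrophils,
        cluster_radius_um=cluster_radius_um,
        noise_sd=0.2,
        seed=int(rng.integers(2**31)),
    )


@pytest.fixture(scope="session")
def study_movie():
    return simulate_calcium_movie(study_movie_spec(21))
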