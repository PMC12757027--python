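"""Serial-dilution spot-plate simulator for conjugation efficiency assays.

Emulates the standard titration readout: a cell resuspension is 10-fold
serially diluted, a fixed volume of each dilution is spotted in technical
replicate drops, and colonies are counted after growth.  Colony counts per
spot are Poisson around ``true_cfu_per_ml x spot_volume / dilution``;
spots too dense to resolve single colonies are flagged as lawns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..dna import rng_for

POPULATIONS = ("transconjugant", "total")


@dataclass(frozen=True)
class SimPlateTruth:
    """Ground truth for one sample (one mating spot) on one day."""

    true_total_cfu_per_ml: float
    true_transconjugant_cfu_per_ml: float
    day_label: str
    sample_id: str = "sample"
    role: str = "treatment"            # "treatment" or "control"
    dilution_factors: tuple = tuple(10 ** d for d in range(8))
    spot_volume_ul: float = 10.0

    def __post_init__(self):
        if self.true_transconjugant_cfu_per_ml > self.true_total_cfu_per_ml:
            raise ValueError("transconjugant titer exceeds total titer")
        if self.spot_volume_ul <= 0:
            raise ValueError("spot_volume_ul must be positive")
        for f in self.dilution_factors:
            d = np.log10(f)
            if abs(d - round(d)) > 1e-9:
                raise ValueError("dilution factors must be powers of 10")

    @property
    def true_efficiency(self) -> float:
        return self.true_transconjugant_cfu_per_ml / self.true_total_cfu_per_ml


def simulate_spot_plates(truth: SimPlateTruth, seed: int = 0,
                         n_spots: int = 3,
                         lawn_threshold: int = 300) -> pd.DataFrame:
    """Simulate colony counts for one sample's dilution series.

    Returns a tidy table with one row per (population, dilution, spot):
    columns sample, day, role, population, dilution_factor,
    spot_volume_ul, spot, count, lawn.  Counts above ``lawn_threshold``
    are flagged as confluent lawns (uncountable).
    """
    rng = rng_for("plates", seed)
    rows = []
    for population, cfu in [("transconjugant", truth.true_transconjugant_cfu_per_ml),
                            ("total", truth.true_total_cfu_per_ml)]:
        for factor in truth.dilution_factors:
            mean = cfu * (truth.spot_volume_ul / 1000.0) / factor
            counts = rng.poisson(mean, n_spots)
            for spot, c in enumerate(counts, start=1):
                rows.append({
                    "sample": truth.sample_id, "day": truth.day_label,
                    "role": truth.role, "population": population,
                    "dilution_factor": factor,
                    "spot_volume_ul": truth.spot_volume_ul,
                    "spot": spot, "count": int(c),
                    "lawn": bool(c > lawn_threshold),
                })
    return pd.DataFrame(rows)


def simulate_experiment(day_truths: list[SimPlateTruth], seed: int = 0,
                        n_spots: int = 3,
                        lawn_threshold: int = 300) -> pd.DataFrame:
    """Simulate several samples/days into one tidy plate table."""
    frames = []
    for i, truth in enumerate(day_truths):
        frames.append(simulate_spot_plates(truth, seed=seed + i,
                                           n_spots=n_spots,
                                           lawn_threshold=lawn_threshold))
    return pd.concat(frames, ignore_index=True)
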