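"""Planted CAST insertion outcomes and the delivery-vector model.

The simulated vector follows the canonical CAST delivery layout: the
mobilised transposon unit (left end, cargo, right end) carried on a
plasmid backbone.  A *simple insertion* integrates only the unit; a
*cointegrate* integrates the unit, the entire backbone and a duplicated
copy of the unit, which is the structure produced when replicative
transposition resolves the whole donor plasmid into the target.

Orientation is encoded relative to the target: ``RL`` means the transposon
right end is the PAM-proximal end, ``LR`` the opposite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..dna import random_dna, revcomp, rng_for
from .genome import SimGenome, Target

ORIENTATIONS = ("RL", "LR")


@dataclass(frozen=True)
class VectorRecord:
    """Delivery plasmid: ``[left end][cargo][right end][backbone]``."""

    seq: str
    left_end: tuple[int, int]
    right_end: tuple[int, int]
    cargo: tuple[int, int]

    @property
    def unit(self) -> str:
        """The mobilised transposon unit (left end through right end)."""
        return self.seq[self.left_end[0]:self.right_end[1]]

    @property
    def backbone(self) -> str:
        return self.seq[self.right_end[1]:]


@dataclass(frozen=True)
class TransposonRecord:
    """Transposon unit sequence with annotated end intervals, the reference
    the profiler maps reads against."""

    seq: str
    left_end: tuple[int, int]
    right_end: tuple[int, int]

    def to_fasta(self, path, name: str = "transposon") -> None:
        with open(path, "w") as fh:
            fh.write(f">{name}\n{self.seq}\n")

    def ends_to_bed(self, path, name: str = "transposon") -> None:
        with open(path, "w") as fh:
            fh.write(f"{name}\t{self.left_end[0]}\t{self.left_end[1]}\tleft_end\n")
            fh.write(f"{name}\t{self.right_end[0]}\t{self.right_end[1]}\tright_end\n")


def make_vector(seed: int = 0, cargo_len: int = 2000, backbone_len: int = 4500,
                left_end_len: int = 150, right_end_len: int = 100) -> VectorRecord:
    """Random delivery vector with annotated transposon ends and cargo."""
    rng = rng_for("vector", seed)
    seq = random_dna(rng, left_end_len + cargo_len + right_end_len + backbone_len)
    le = (0, left_end_len)
    cargo = (left_end_len, left_end_len + cargo_len)
    re = (cargo[1], cargo[1] + right_end_len)
    return VectorRecord(seq, le, re, cargo)


def transposon_record(vector: VectorRecord) -> TransposonRecord:
    unit_start = vector.left_end[0]
    return TransposonRecord(
        vector.unit,
        (vector.left_end[0] - unit_start, vector.left_end[1] - unit_start),
        (vector.right_end[0] - unit_start, vector.right_end[1] - unit_start),
    )


@dataclass(frozen=True)
class InsertionEvent:
    event_id: int
    position: int          # genomic junction (0-based insertion point)
    orientation: str       # "RL" or "LR"
    offset_bp: int         # downstream distance from the protospacer 3' end
    cointegrate: bool
    on_target: bool


@dataclass
class SimTruth:
    events: list[InsertionEvent]
    target: Target
    on_target_window: int = 100

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([{
            "event_id": e.event_id, "position": e.position,
            "orientation": e.orientation, "offset_bp": e.offset_bp,
            "cointegrate": e.cointegrate, "on_target": e.on_target,
        } for e in self.events])


def inserted_sequence(vector: VectorRecord, orientation: str,
                      target_strand: str, cointegrate: bool) -> str:
    """Sequence placed into the genome at the junction for a given outcome.

    For a '+' target the PAM-proximal side of the insertion is its lower-
    coordinate side, so an RL event (right end proximal) carries the
    reverse-complemented cassette; for a '-' target this is mirrored.
    """
    cassette = vector.unit if not cointegrate else (
        vector.unit + vector.backbone + vector.unit)
    forward_in_genome = (orientation == "LR") if target_strand == "+" \
        else (orientation == "RL")
    return cassette if forward_in_genome else revcomp(cassette)


def simulate_insertions(genome: SimGenome, target: Target,
                        vector: VectorRecord, n_events: int,
                        offset_mean: int = 49, offset_sd: float = 0.0,
                        orientation_probs: dict[str, float] | None = None,
                        cointegrate_rate: float = 0.0,
                        off_target_rate: float = 0.0,
                        on_target_window: int = 100,
                        exact_counts: bool = False,
                        seed: int = 0) -> SimTruth:
    """Draw independent insertion events around (and away from) the target.

    On-target events land ``offset_mean`` bp downstream of the protospacer
    3' end (optionally jittered with a truncated normal of sd
    ``offset_sd``); off-target events are placed uniformly over the genome
    outside the on-target window.  Orientation, cointegrate and on-target
    status are independent Bernoulli draws at the configured rates, or,
    with ``exact_counts``, assigned to a random permutation of the events
    in exact proportion - use this when the planted *frequency* (not just
    its expectation) must equal the configured rate, e.g. for
    rate-recovery experiments where generator shot noise is not part of
    the question.
    """
    probs = orientation_probs or {"RL": 0.9, "LR": 0.1}
    if abs(sum(probs.values()) - 1.0) > 1e-9:
        raise ValueError("orientation probabilities must sum to 1")
    for r, name in [(cointegrate_rate, "cointegrate_rate"),
                    (off_target_rate, "off_target_rate")]:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = rng_for("insertions", seed)
    p_rl = probs.get("RL", 0.0)
    L = len(genome)
    margin = 2000
    window_lo = min(target.junction_at(0), target.junction_at(on_target_window))
    window_hi = max(target.junction_at(0), target.junction_at(on_target_window))
    if exact_counts:
        def flags(rate):
            k = int(round(rate * n_events))
            arr = np.zeros(n_events, dtype=bool)
            arr[:k] = True
            rng.shuffle(arr)
            return arr

        off_flags = flags(off_target_rate)
        rl_flags = flags(p_rl)
        coint_flags = flags(cointegrate_rate)
    events = []
    for i in range(n_events):
        if exact_counts:
            on_target = not off_flags[i]
            orientation = "RL" if rl_flags[i] else "LR"
            cointegrate = bool(coint_flags[i])
        else:
            on_target = rng.random() >= off_target_rate
            orientation = "RL" if rng.random() < p_rl else "LR"
            cointegrate = rng.random() < cointegrate_rate
        if on_target:
            offset = offset_mean if offset_sd == 0 else \
                max(0, int(round(rng.normal(offset_mean, offset_sd))))
            position = target.junction_at(offset)
        else:
            offset = -1
            while True:
                position = int(rng.integers(margin, L - margin))
                if not (window_lo - 500 <= position <= window_hi + 500):
                    break
            offset = target.offset_of(position)
        events.append(InsertionEvent(i, position, orientation, offset,
                                     cointegrate, on_target))
    return SimTruth(events, target, on_target_window)
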