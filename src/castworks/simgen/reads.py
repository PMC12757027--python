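"""Long-read simulation over planted insertion alleles.

Each simulated read spans one insertion event: the genomic context, the
integrated cassette and the opposite flank, copied from the per-event
allele and corrupted with substitution/indel errors at a configurable
per-base rate.  Per-read truth (source event, genome strand) is returned
alongside the FASTQ records so downstream calls can be scored exactly.

The error model is deliberately simple - independent per-base
substitutions, single-base duplications and deletions - and is not a
calibrated Nanopore error profile (no homopolymer or quality-correlated
structure).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..dna import ALPHABET, encode, rng_for
from .genome import SimGenome
from .insertions import SimTruth, VectorRecord, inserted_sequence

_REV = str.maketrans("ACGT", "TGCA")


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: np.ndarray  # phred scores, len == len(sequence)

    @property
    def mean_quality(self) -> float:
        return float(self.quality.mean()) if len(self.quality) else 0.0

    def fastq_block(self) -> str:
        qual = "".join(chr(q + 33) for q in self.quality)
        return f"@{self.id}\n{self.sequence}\n+\n{qual}\n"


def _corrupt(seq: str, per_base_error: float, rng: np.random.Generator) -> str:
    """Apply substitutions (60% of errors), single-base duplications (20%)
    and deletions (20%) independently per base."""
    if per_base_error <= 0:
        return seq
    codes = encode(seq).astype(np.int8).copy()
    n = len(codes)
    u = rng.random(n)
    p_sub = 0.6 * per_base_error
    p_del = 0.2 * per_base_error
    p_ins = 0.2 * per_base_error
    sub = u < p_sub
    dele = (u >= p_sub) & (u < p_sub + p_del)
    ins = (u >= p_sub + p_del) & (u < p_sub + p_del + p_ins)
    n_sub = int(sub.sum())
    if n_sub:
        codes[sub] = (codes[sub] + rng.integers(1, 4, n_sub)) % 4
    counts = np.ones(n, dtype=np.int64)
    counts[dele] = 0
    counts[ins] = 2
    out = np.repeat(codes, counts)
    return "".join(ALPHABET[c] for c in out)


def simulate_long_reads(genome: SimGenome, truth: SimTruth,
                        vector: VectorRecord, n_reads: int,
                        length_dist: tuple = ("normal", 15_000, 1_500),
                        per_base_error: float = 0.05,
                        mean_quality: float = 30.0,
                        quality_sd: float = 3.0,
                        min_margin: int = 300,
                        seed: int = 0) -> tuple[list[SimRead], pd.DataFrame]:
    """Simulate reads spanning the planted insertions.

    ``length_dist`` is ``("point", L)`` or ``("normal", mean, sd)``.  A
    drawn length shorter than the cassette plus twice ``min_margin`` is
    extended to that floor so every read fully spans its insertion with
    mappable genomic flanks on both sides.  Events are cycled round-robin
    so each receives ``~n_reads / n_events`` reads.

    Returns the read records and a truth table with one row per read.
    """
    if not truth.events:
        raise ValueError("truth contains no events")
    rng = rng_for("reads", seed)
    seq = genome.sequence
    L = len(seq)
    reads: list[SimRead] = []
    rows = []
    for i in range(n_reads):
        ev = truth.events[i % len(truth.events)]
        ins = inserted_sequence(vector, ev.orientation, truth.target.strand,
                                ev.cointegrate)
        if length_dist[0] == "point":
            read_len = int(length_dist[1])
        elif length_dist[0] == "normal":
            read_len = int(round(rng.normal(length_dist[1], length_dist[2])))
        else:
            raise ValueError(f"unknown length_dist {length_dist[0]!r}")
        read_len = max(read_len, len(ins) + 2 * min_margin)
        left_max = min(read_len - len(ins) - min_margin, ev.position)
        right_avail = L - ev.position
        left_genomic = int(rng.integers(min_margin, max(min_margin, left_max) + 1))
        right_genomic = min(read_len - len(ins) - left_genomic, right_avail)
        clean = seq[ev.position - left_genomic:ev.position] + ins + \
            seq[ev.position:ev.position + right_genomic]
        noisy = _corrupt(clean, per_base_error, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            noisy = noisy.translate(_REV)[::-1]
        qual = np.clip(np.rint(rng.normal(mean_quality, quality_sd, len(noisy))),
                       2, 41).astype(np.int64)
        rid = f"read{i:05d}"
        reads.append(SimRead(rid, noisy, qual))
        rows.append({
            "read_id": rid, "event_id": ev.event_id, "length": len(noisy),
            "read_strand": strand, "position": ev.position,
            "orientation": ev.orientation, "offset_bp": ev.offset_bp,
            "cointegrate": ev.cointegrate, "on_target": ev.on_target,
        })
    return reads, pd.DataFrame(rows)


def write_fastq(reads: list[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(r.fastq_block())
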