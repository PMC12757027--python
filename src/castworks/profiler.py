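"""Classify long sequencing reads into CAST insertion outcomes.

Pipeline (mirroring the standard long-read insertion-validation workflow):

1. quality/length filtering (mean Phred > Q20, length >= 150 bp), then an
   analysis subset of reads exceeding 10 kb so that complete cargo plus
   genomic flanks fit inside a single read;
2. cargo location: local alignment of each read against the annotated
   transposon unit; reads covering less than 80% of the transposon right
   end are discarded;
3. flank classification: the read sequence on either side of the cargo is
   aligned to the reference genome and to the delivery plasmid and
   labelled genomic / plasmid / both / unmapped by a >100 bp mapped-length
   rule;
4. insertion call: the transposon-genome junction is projected onto
   reference coordinates, orientation (RL = right end PAM-proximal) is
   derived from the strand geometry, the downstream offset from the
   protospacer 3' end is computed, and the call is categorised on-target
   when the junction falls within a 100-bp window downstream of the
   target 3' end.  Reads with plasmid-involved flanks contiguous with the
   cargo are cointegrates (whole-backbone integrations);
5. summary: on-target percentage, orientation mix, cointegrate rate
   (read-level, plus clone-level majority vote when clone identifiers are
   available), offset histogram and genome-wide junction histogram.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .align import Alignment, KmerIndex, LocalAligner
from .simgen.genome import Target
from .simgen.insertions import TransposonRecord


@dataclass
class ReadRecord:
    id: str
    sequence: str
    mean_quality: float

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_fastq(path) -> tuple[list[ReadRecord], list[tuple[str, str]]]:
    """Tolerant FASTQ reader: malformed records are rejected individually
    (with a reason) instead of aborting the file."""
    reads: list[ReadRecord] = []
    rejected: list[tuple[str, str]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    for i in range(0, len(lines) - 3, 4):
        head, seq, plus, qual = lines[i:i + 4]
        name = head[1:].split()[0] if head.startswith("@") and len(head) > 1 \
            else f"record_{i // 4}"
        if not head.startswith("@"):
            rejected.append((name, "missing @ header"))
            continue
        if not plus.startswith("+"):
            rejected.append((name, "missing + separator"))
            continue
        if len(seq) != len(qual):
            rejected.append((name, "sequence/quality length mismatch"))
            continue
        q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(float) - 33
        reads.append(ReadRecord(name, seq.upper(), float(q.mean()) if len(q) else 0.0))
    return reads, rejected


def _as_read_records(reads) -> tuple[list[ReadRecord], list[tuple[str, str]]]:
    if isinstance(reads, (str, Path)):
        return parse_fastq(reads)
    out = []
    for r in reads:
        if isinstance(r, ReadRecord):
            out.append(r)
        else:  # simgen.SimRead or anything with id/sequence/mean_quality
            out.append(ReadRecord(r.id, r.sequence, r.mean_quality))
    return out, []


@dataclass
class FilterResult:
    qc_set: list[ReadRecord]
    analysis_set: list[ReadRecord]
    rejected: list[tuple[str, str]]
    n_input: int


def filter_reads(reads, min_quality: float = 20.0, min_length: int = 150,
                 analysis_min_length: int = 10_000) -> FilterResult:
    """Quality/length filter plus the long-read analysis subset.

    ``qc_set``: mean quality strictly above ``min_quality`` and length at
    least ``min_length``.  ``analysis_set``: qc reads strictly longer than
    ``analysis_min_length``.
    """
    if min_quality <= 0 or min_length <= 0 or analysis_min_length <= 0:
        raise ValueError("filter thresholds must be positive")
    records, rejected = _as_read_records(reads)
    qc, rej = [], list(rejected)
    for r in records:
        if r.length < min_length:
            rej.append((r.id, "short"))
        elif r.mean_quality <= min_quality:
            rej.append((r.id, "low_quality"))
        else:
            qc.append(r)
    analysis = [r for r in qc if r.length > analysis_min_length]
    return FilterResult(qc, analysis, rej, len(records))


@dataclass
class CargoHit:
    read_id: str
    q_start: int            # cargo span on the read (forward read coords)
    q_end: int
    t_start: int            # aligned span on the transposon unit
    t_end: int
    strand: str             # '+': read carries the unit in forward sense
    score: int
    right_end_coverage: float
    left_end_found: bool


def _interval_cov(span: tuple[int, int], interval: tuple[int, int]) -> float:
    s = max(span[0], interval[0])
    e = min(span[1], interval[1])
    width = interval[1] - interval[0]
    return max(0, e - s) / width if width else 0.0


def locate_cargo(read: ReadRecord, transposon: TransposonRecord,
                 aligner: LocalAligner | None = None,
                 index: KmerIndex | None = None,
                 min_right_end_cov: float = 0.80,
                 min_left_end_cov: float = 0.50):
    """Find the transposon unit on a read.

    Returns a :class:`CargoHit`, or a rejection-reason string
    (``"no_cargo"`` / ``"right_end_below_threshold"``).  The right-end
    coverage is the aligned fraction of the annotated right-end interval;
    reads covering less than ``min_right_end_cov`` of it are rejected.
    """
    aligner = aligner or LocalAligner()
    if index is None:
        index = KmerIndex(transposon.seq, aligner.word_size)
    aln = aligner.align(read.sequence, index=index)
    if aln is None:
        return "no_cargo"
    cov = _interval_cov((aln.t_start, aln.t_end), transposon.right_end)
    left_found = _interval_cov((aln.t_start, aln.t_end),
                               transposon.left_end) >= min_left_end_cov
    if cov < min_right_end_cov:
        return "right_end_below_threshold"
    return CargoHit(read.id, aln.q_start, aln.q_end, aln.t_start, aln.t_end,
                    aln.strand, aln.score, cov, left_found)


@dataclass
class FlankClassification:
    read_id: str
    left_flank: str                 # genomic / plasmid / both / unmapped
    right_flank: str
    left_genome_aln: Alignment | None = None
    right_genome_aln: Alignment | None = None
    left_mapped: dict = field(default_factory=dict)
    right_mapped: dict = field(default_factory=dict)


def classify_flanks(read: ReadRecord, hit: CargoHit,
                    genome_index: KmerIndex, plasmid_index: KmerIndex,
                    aligner: LocalAligner | None = None,
                    min_flank_bp: int = 100,
                    max_flank_bp: int = 2500) -> FlankClassification:
    """Label the read sequence either side of the cargo by where it maps.

    A flank is *genomic* / *plasmid* when more than ``min_flank_bp`` of it
    aligns to the respective reference, *both* when both qualify,
    *unmapped* otherwise.  Only the ``max_flank_bp`` of flank adjacent to
    the cargo are examined: the junction and the classification are
    determined there, and capping the window keeps alignment cost bounded
    on very long reads.
    """
    aligner = aligner or LocalAligner()
    flanks = {"left": read.sequence[max(0, hit.q_start - max_flank_bp):hit.q_start],
              "right": read.sequence[hit.q_end:hit.q_end + max_flank_bp]}
    labels, alns, mapped = {}, {}, {}
    for side, seq in flanks.items():
        g_aln = aligner.align(seq, index=genome_index) if len(seq) >= aligner.word_size else None
        p_aln = aligner.align(seq, index=plasmid_index) if len(seq) >= aligner.word_size else None
        g_bp = g_aln.q_span if g_aln else 0
        p_bp = p_aln.q_span if p_aln else 0
        g_ok = g_bp > min_flank_bp
        p_ok = p_bp > min_flank_bp
        if g_ok and p_ok:
            labels[side] = "both"
        elif g_ok:
            labels[side] = "genomic"
        elif p_ok:
            labels[side] = "plasmid"
        else:
            labels[side] = "unmapped"
        alns[side] = g_aln if g_ok else None
        mapped[side] = {"genome": g_bp, "plasmid": p_bp}
    return FlankClassification(read.id, labels["left"], labels["right"],
                               alns["left"], alns["right"],
                               mapped["left"], mapped["right"])


@dataclass
class InsertionCall:
    read_id: str
    junction: int           # reference insertion point (0-based)
    orientation: str        # RL / LR / ambiguous
    offset_bp: int          # downstream of the protospacer 3' end
    on_target: bool
    cointegrate: bool


def call_insertion(read: ReadRecord, hit: CargoHit,
                   flanks: FlankClassification, target: Target,
                   on_target_window: int = 100,
                   symmetric_window: bool = False):
    """Project the insertion onto the reference and categorise it.

    Returns an :class:`InsertionCall` or the rejection string
    ``"unplaceable"`` when neither flank maps to the genome.  Orientation
    is RL when the transposon right end is the PAM-proximal end; it is
    reported ``ambiguous`` when the left end was not observed on the read.
    The junction is the first genomic base after the transposon on the
    reference; both flanks share that coordinate, so whichever genomic
    flank is available determines it (left preferred).
    """
    left, right = flanks.left_genome_aln, flanks.right_genome_aln
    if left is None and right is None:
        return "unplaceable"
    # prefer a purely genomic flank: a "both" flank (plasmid-involved, as
    # in cointegrates) can overshoot the junction by a base or two when
    # the transposon terminus coincides with the adjacent genomic bases
    candidates = []
    if left is not None:
        j = left.t_end if left.strand == "+" else left.t_start
        candidates.append((flanks.left_flank == "genomic", j, left.strand))
    if right is not None:
        j = right.t_start if right.strand == "+" else right.t_end
        candidates.append((flanks.right_flank == "genomic", j, right.strand))
    candidates.sort(key=lambda c: c[0], reverse=True)
    _, junction, read_strand = candidates[0]
    forward_in_genome = (read_strand == hit.strand)
    if not hit.left_end_found:
        orientation = "ambiguous"
    elif target.strand == "+":
        orientation = "LR" if forward_in_genome else "RL"
    else:
        orientation = "RL" if forward_in_genome else "LR"
    offset = target.offset_of(junction)
    if symmetric_window:
        on_target = abs(offset) <= on_target_window
    else:
        on_target = 0 <= offset <= on_target_window
    cointegrate = ("plasmid" in (flanks.left_flank, flanks.right_flank)
                   or "both" in (flanks.left_flank, flanks.right_flank))
    return InsertionCall(read.id, junction, orientation, offset,
                         on_target, cointegrate)


@dataclass
class ProfileSummary:
    n_input: int
    n_pass_qc: int
    n_ge_10kb: int
    n_cargo: int
    n_called: int
    on_target_pct: float
    orientation_fractions: dict
    cointegrate_pct: float
    cointegrate_pct_clone: float | None
    offset_hist: dict               # offset bp -> percent of called reads
    genome_hist: dict               # bin start -> junction count
    empty: bool = False

    def to_json(self, path=None) -> str:
        payload = {k: (None if isinstance(v, float) and math.isnan(v) else v)
                   for k, v in self.__dict__.items()}
        payload["offset_hist"] = {str(k): v for k, v in self.offset_hist.items()}
        payload["genome_hist"] = {str(k): v for k, v in self.genome_hist.items()}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def empty_summary(cls, n_input=0, n_pass_qc=0, n_ge_10kb=0, n_cargo=0):
        return cls(n_input, n_pass_qc, n_ge_10kb, n_cargo, 0,
                   float("nan"), {}, float("nan"), None, {}, {}, empty=True)


def summarize(calls: list[InsertionCall], genome_length: int,
              bin_size: int = 1000, counts: dict | None = None,
              clone_ids: dict | None = None) -> ProfileSummary:
    """Aggregate insertion calls into the outcome summary.

    ``counts`` carries the filter-chain tallies (n_input, n_pass_qc,
    n_ge_10kb, n_cargo).  ``clone_ids`` optionally maps read id -> clone
    id; when present a clone-level cointegrate rate (majority vote over
    each clone's reads) is reported alongside the read-level rate.
    """
    counts = counts or {}
    base = dict(n_input=counts.get("n_input", len(calls)),
                n_pass_qc=counts.get("n_pass_qc", len(calls)),
                n_ge_10kb=counts.get("n_ge_10kb", len(calls)),
                n_cargo=counts.get("n_cargo", len(calls)))
    if not calls:
        return ProfileSummary.empty_summary(**base)
    n = len(calls)
    on_target_pct = 100.0 * sum(c.on_target for c in calls) / n
    orient: dict[str, float] = {}
    for key in ("RL", "LR", "ambiguous"):
        k = sum(c.orientation == key for c in calls)
        if k:
            orient[key] = k / n
    cointegrate_pct = 100.0 * sum(c.cointegrate for c in calls) / n
    clone_pct = None
    if clone_ids:
        votes: dict = {}
        for c in calls:
            cid = clone_ids.get(c.read_id)
            if cid is None:
                continue
            votes.setdefault(cid, []).append(c.cointegrate)
        if votes:
            clone_pct = 100.0 * sum(
                sum(v) * 2 > len(v) for v in votes.values()) / len(votes)
    offsets = pd.Series([c.offset_bp for c in calls])
    offset_hist = {int(k): 100.0 * v / n
                   for k, v in offsets.value_counts().sort_index().items()}
    bins = {}
    for c in calls:
        b = (c.junction // bin_size) * bin_size
        bins[b] = bins.get(b, 0) + 1
    return ProfileSummary(**base, n_called=n, on_target_pct=on_target_pct,
                          orientation_fractions=orient,
                          cointegrate_pct=cointegrate_pct,
                          cointegrate_pct_clone=clone_pct,
                          offset_hist=offset_hist,
                          genome_hist=dict(sorted(bins.items())))


def profile_reads(reads, genome_seq: str, plasmid_seq: str,
                  transposon: TransposonRecord, target: Target,
                  min_quality: float = 20.0, min_length: int = 150,
                  analysis_min_length: int = 10_000,
                  min_right_end_cov: float = 0.80,
                  min_flank_bp: int = 100,
                  on_target_window: int = 100,
                  symmetric_window: bool = False,
                  bin_size: int = 1000,
                  clone_ids: dict | None = None,
                  aligner: LocalAligner | None = None):
    """Run the full read-to-outcome pipeline.

    ``reads`` may be a FASTQ path or an iterable of read records.  Returns
    ``(calls_df, summary, rejections)``; the calls table reports junctions
    both 0-based (internal convention) and 1-based (reporting convention).
    """
    aligner = aligner or LocalAligner()
    flt = filter_reads(reads, min_quality=min_quality, min_length=min_length,
                       analysis_min_length=analysis_min_length)
    tn_index = KmerIndex(transposon.seq, aligner.word_size)
    genome_index = KmerIndex(genome_seq, aligner.word_size)
    plasmid_index = KmerIndex(plasmid_seq, aligner.word_size)
    calls: list[InsertionCall] = []
    rejections: list[tuple[str, str]] = list(flt.rejected)
    n_cargo = 0
    rows = []
    for read in flt.analysis_set:
        hit = locate_cargo(read, transposon, aligner, index=tn_index,
                           min_right_end_cov=min_right_end_cov)
        if isinstance(hit, str):
            rejections.append((read.id, hit))
            continue
        n_cargo += 1
        flanks = classify_flanks(read, hit, genome_index, plasmid_index,
                                 aligner, min_flank_bp=min_flank_bp)
        call = call_insertion(read, hit, flanks, target,
                              on_target_window=on_target_window,
                              symmetric_window=symmetric_window)
        if isinstance(call, str):
            rejections.append((read.id, call))
            continue
        calls.append(call)
        rows.append({
            "read_id": read.id, "junction": call.junction,
            "junction_1based": call.junction + 1,
            "orientation": call.orientation, "offset_bp": call.offset_bp,
            "on_target": call.on_target, "cointegrate": call.cointegrate,
            "left_flank": flanks.left_flank, "right_flank": flanks.right_flank,
            "right_end_coverage": hit.right_end_coverage,
        })
    counts = dict(n_input=flt.n_input, n_pass_qc=len(flt.qc_set),
                  n_ge_10kb=len(flt.analysis_set), n_cargo=n_cargo)
    # the filter chain can only shrink
    chain = [counts["n_input"], counts["n_pass_qc"], counts["n_ge_10kb"],
             counts["n_cargo"], len(calls)]
    assert all(a >= b for a, b in zip(chain, chain[1:])), chain
    summary = summarize(calls, len(genome_seq), bin_size=bin_size,
                        counts=counts, clone_ids=clone_ids)
    calls_df = pd.DataFrame(rows)
    return calls_df, summary, rejections
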