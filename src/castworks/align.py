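"""Local sequence alignment used by the read profiler and the guide designer.

The package performs all alignment internally with a seed-and-extend local
aligner (exact-word seeding, banded affine-gap Smith-Waterman extension) so
that no external aligner binary is required.  The decision logic built on
top of it consumes only alignment spans and scores, so any local aligner
with equivalent optima is interchangeable; the test suite enforces
agreement with an independent full-matrix Smith-Waterman oracle.

Two entry points:

* :class:`LocalAligner` - seed-and-extend search of a long query against a
  long target (reads vs. transposon / genome / plasmid).  Targets that are
  reused across many queries can be pre-indexed with :class:`KmerIndex`.
* :func:`scan_short_query` - exhaustive full-matrix scan of a short query
  (a 32-nt protospacer) against a genome, with traceback, used for
  off-target assessment.

Scoring defaults follow the common nucleotide local-alignment convention
(match +2, mismatch -3, gap open -5, gap extend -2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .dna import encode, revcomp

NEG = -(10 ** 7)


@dataclass(frozen=True)
class Scoring:
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2


@dataclass
class Alignment:
    """A local alignment of ``query`` against ``target``.

    ``q_start``/``q_end`` are half-open coordinates on the query as
    supplied (forward orientation) even when ``strand`` is '-', in which
    case the reverse complement of the query was aligned.  ``t_start`` /
    ``t_end`` are half-open coordinates on the target.
    """

    score: int
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    strand: str = "+"
    # aligned (query_index, target_index, is_match) triples, query indices on
    # the aligned orientation; only populated by the full-matrix scan
    pairs: list = field(default_factory=list)

    @property
    def q_span(self) -> int:
        return self.q_end - self.q_start

    @property
    def t_span(self) -> int:
        return self.t_end - self.t_start

    def n_matches(self) -> int:
        return sum(1 for _, _, m in self.pairs if m)

    def identity(self) -> float:
        return self.n_matches() / len(self.pairs) if self.pairs else float("nan")


@njit(cache=True)
def _banded_sw(q, t, dlo, dhi, match, mismatch, gap_open, gap_extend):
    """Banded affine local alignment restricted to diagonals j - i in
    [dlo, dhi].  Returns (best_score, q_end_exclusive, t_end_exclusive)."""
    m = q.shape[0]
    n = t.shape[0]
    W = dhi - dlo + 1
    neg = -(10 ** 7)
    h_prev = np.zeros(W, dtype=np.int32)
    f_prev = np.full(W, neg, dtype=np.int32)
    h_cur = np.zeros(W, dtype=np.int32)
    f_cur = np.full(W, neg, dtype=np.int32)
    e_cur = np.full(W, neg, dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    # only rows whose band intersects the target can contribute
    i_lo = max(0, -dhi)
    i_hi = min(m, n - dlo)
    # row -1 (no query consumed): H = 0 on valid columns, gaps closed
    for i in range(i_lo, i_hi):
        for k in range(W):
            h_cur[k] = 0
            f_cur[k] = neg
            e_cur[k] = neg
        qi = q[i]
        for k in range(W):
            j = i + dlo + k
            if j < 0 or j >= n:
                h_cur[k] = 0
                continue
            # E: gap in query (from same row, previous column)
            e = neg
            if k > 0:
                a = h_cur[k - 1] + gap_open
                b = e_cur[k - 1] + gap_extend
                e = a if a > b else b
            # F: gap in target (from previous row, same column)
            f = neg
            if k + 1 < W:
                a = h_prev[k + 1] + gap_open
                b = f_prev[k + 1] + gap_extend
                f = a if a > b else b
            # diagonal
            if qi == t[j] and qi < 4:
                s = match
            else:
                s = mismatch
            diag = h_prev[k] + s if (j - 1 >= -1) else neg
            if i == 0 or j == 0:
                diag = s  # previous H is 0 on the matrix border
            h = 0
            if diag > h:
                h = diag
            if e > h:
                h = e
            if f > h:
                h = f
            h_cur[k] = h
            e_cur[k] = e
            f_cur[k] = f
            if h > best:
                best = h
                bi = i
                bj = j
        # roll rows
        tmp = h_prev
        h_prev = h_cur
        h_cur = tmp
        tmp = f_prev
        f_prev = f_cur
        f_cur = tmp
    return best, bi + 1, bj + 1


@njit(cache=True)
def _full_sw_fill(q, t, match, mismatch, gap_open, gap_extend):
    """Full affine Smith-Waterman matrices for a short query.

    Returns (H, E, F) of shape (m+1, n+1); intended for m << n.
    """
    m = q.shape[0]
    n = t.shape[0]
    neg = -(10 ** 7)
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), neg, dtype=np.int32)
    F = np.full((m + 1, n + 1), neg, dtype=np.int32)
    for i in range(1, m + 1):
        qi = q[i - 1]
        for j in range(1, n + 1):
            a = H[i, j - 1] + gap_open
            b = E[i, j - 1] + gap_extend
            E[i, j] = a if a > b else b
            a = H[i - 1, j] + gap_open
            b = F[i - 1, j] + gap_extend
            F[i, j] = a if a > b else b
            if qi == t[j - 1] and qi < 4:
                s = match
            else:
                s = mismatch
            h = H[i - 1, j - 1] + s
            if h < 0:
                h = 0
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            H[i, j] = h
    return H, E, F


def _traceback(H, E, F, q, t, i, j, scoring: Scoring):
    """Trace one optimal local path back from H[i, j]; returns
    (q_start, t_start, pairs) with pairs as (qi, tj, is_match)."""
    pairs = []
    state = "H"
    while i > 0 and j > 0:
        if state == "H":
            h = H[i, j]
            if h == 0:
                break
            s = scoring.match if (q[i - 1] == t[j - 1] and q[i - 1] < 4) else scoring.mismatch
            if h == H[i - 1, j - 1] + s:
                pairs.append((i - 1, j - 1, bool(q[i - 1] == t[j - 1] and q[i - 1] < 4)))
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = "E"
            elif h == F[i, j]:
                state = "F"
            else:  # pragma: no cover - defensive
                break
        elif state == "E":
            if E[i, j] == H[i, j - 1] + scoring.gap_open:
                j -= 1
                state = "H"
            else:
                j -= 1
        else:  # F
            if F[i, j] == H[i - 1, j] + scoring.gap_open:
                i -= 1
                state = "H"
            else:
                i -= 1
    pairs.reverse()
    return i, j, pairs


def _kmer_hashes(codes: np.ndarray, k: int):
    """Vectorised 2-bit rolling hashes: (positions, hashes) for every
    k-mer window free of ambiguity codes."""
    n = len(codes)
    if n < k:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    c = codes.astype(np.int64)
    h = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        h = (h << 2) | c[j:n - k + 1 + j]
    bad = (codes >= 4).astype(np.int64)
    cb = np.concatenate([[0], np.cumsum(bad)])
    window_bad = cb[k:] - cb[:-k]
    pos = np.nonzero(window_bad == 0)[0]
    return pos, h[pos]


class KmerIndex:
    """Exact k-mer position index over a reference string (forward strand)."""

    def __init__(self, seq: str, word_size: int):
        self.seq = seq
        self.word_size = word_size
        self.codes = encode(seq)
        self._index: dict[int, list[int]] = {}
        pos, hashes = _kmer_hashes(self.codes, word_size)
        for p, h in zip(pos.tolist(), hashes.tolist()):
            self._index.setdefault(h, []).append(p)

    def lookup(self, kmer_hash: int) -> list[int]:
        return self._index.get(kmer_hash, [])


class LocalAligner:
    """Seed-and-extend local aligner.

    Parameters
    ----------
    word_size:
        Exact-match seed length (default 11).
    band:
        Half-width of the diagonal band explored around each seed cluster.
        Must exceed the expected net indel drift of the alignments; 100 is
        ample for reads with a few percent indel error.
    scoring:
        Affine-gap scores.
    min_score:
        Alignments scoring below this are reported as ``None``.
    """

    def __init__(self, word_size: int = 11, band: int = 100,
                 scoring: Scoring | None = None, min_score: int = 40,
                 max_clusters: int = 4, min_cluster_seeds: int = 3,
                 early_stop_score: int = 300):
        self.word_size = word_size
        self.band = band
        self.scoring = scoring or Scoring()
        self.min_score = min_score
        self.max_clusters = max_clusters
        # clusters with fewer seeds are spurious word matches; any genuine
        # local alignment long enough to matter carries many exact words
        self.min_cluster_seeds = min_cluster_seeds
        # a cluster scoring this high is decisive; lower-seeded clusters of
        # the same strand cannot overtake it and are skipped
        self.early_stop_score = early_stop_score

    # -- seeding -----------------------------------------------------------
    def _clusters(self, q_codes: np.ndarray, index: KmerIndex):
        diags = []
        positions, hashes = _kmer_hashes(q_codes, self.word_size)
        lookup = index._index.get
        for qpos, h in zip(positions.tolist(), hashes.tolist()):
            for tpos in lookup(h, ()):
                diags.append((tpos - qpos, tpos))
        if not diags:
            return []
        diags.sort()
        clusters = []  # (n_seeds, dmin, dmax, tmin, tmax)
        dmin = dmax = diags[0][0]
        tmin = tmax = diags[0][1]
        n = 1
        for d, tpos in diags[1:]:
            if d - dmax <= self.band:
                dmax = d
                n += 1
                tmin = min(tmin, tpos)
                tmax = max(tmax, tpos)
            else:
                clusters.append((n, dmin, dmax, tmin, tmax))
                dmin = dmax = d
                tmin = tmax = tpos
                n = 1
        clusters.append((n, dmin, dmax, tmin, tmax))
        clusters = [c for c in clusters if c[0] >= self.min_cluster_seeds]
        clusters.sort(reverse=True)
        return clusters[: self.max_clusters]

    # -- extension ---------------------------------------------------------
    def _extend(self, q_codes: np.ndarray, t_codes: np.ndarray,
                dlo: int, dhi: int):
        sc = self.scoring
        best, qe, te = _banded_sw(q_codes, t_codes, dlo, dhi,
                                  sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
        if best <= 0:
            return None
        # locate the start with a reverse pass ending at (qe, te)
        qr = q_codes[:qe][::-1].copy()
        tr = t_codes[:te][::-1].copy()
        D = te - qe
        rb, rqe, rte = _banded_sw(qr, tr, D - dhi, D - dlo,
                                  sc.match, sc.mismatch, sc.gap_open, sc.gap_extend)
        qs = qe - rqe
        ts = te - rte
        return best, qs, qe, ts, te

    def align(self, query: str, target: str | None = None,
              index: KmerIndex | None = None, strands: str = "+-"):
        """Best local alignment of *query* (either strand) against *target*.

        Returns an :class:`Alignment` or ``None`` if no alignment reaches
        ``min_score``.  Ties are broken toward the '+' strand, then the
        leftmost target coordinate.
        """
        if index is None:
            if target is None:
                raise ValueError("either target or index is required")
            index = KmerIndex(target, self.word_size)
        t_codes = index.codes
        best: Alignment | None = None
        n_q = len(query)
        for strand in strands:
            q = query if strand == "+" else revcomp(query)
            q_codes = encode(q)
            for _, dmin, dmax, _, _ in self._clusters(q_codes, index):
                res = self._extend(q_codes, t_codes, dmin - self.band, dmax + self.band)
                if res is None:
                    continue
                score, qs, qe, ts, te = res
                if strand == "-":
                    qs, qe = n_q - qe, n_q - qs
                cand = Alignment(score, qs, qe, ts, te, strand)
                if (best is None or cand.score > best.score
                        or (cand.score == best.score and cand.t_start < best.t_start)):
                    best = cand
                if score >= self.early_stop_score:
                    break
        if best is None or best.score < self.min_score:
            return None
        return best


def scan_short_query(query: str, target: str, scoring: Scoring | None = None,
                     exclude: tuple[int, int] | None = None,
                     score_floor: int = 32, max_tied: int = 5000):
    """Exhaustive local-alignment scan of a short query against a target.

    Both strands of the query are scanned against the full dynamic-
    programming matrix (no seeding, no complexity masking), mirroring an
    ungapped-word-seeded nucleotide search at word size <= 4 where seeds
    exist at essentially every position.  ``exclude`` masks a target
    interval (the on-target locus) from the scan.

    Returns ``(best_hits, n_hits)``: *best_hits* lists every alignment
    (with traceback pairs) achieving the maximum score, both strands, up
    to ``max_tied`` entries ordered by target coordinate (empty if
    nothing scores > 0); *n_hits* counts distinct target regions whose
    best local score reaches ``score_floor`` (contiguous runs of
    qualifying end-columns merged, both strands pooled).
    """
    sc = scoring or Scoring()
    if exclude is not None:
        s, e = exclude
        target = target[:s] + "N" * (e - s) + target[e:]
    t_codes = encode(target)
    hit_cols = np.zeros(len(target) + 1, dtype=bool)
    mats = {}
    best_score = 0
    for strand in "+-":
        q = query if strand == "+" else revcomp(query)
        q_codes = encode(q)
        H, E, F = _full_sw_fill(q_codes, t_codes, sc.match, sc.mismatch,
                                sc.gap_open, sc.gap_extend)
        hit_cols |= H.max(axis=0) >= score_floor
        mats[strand] = (q_codes, H, E, F)
        best_score = max(best_score, int(H.max()))
    best_hits: list[Alignment] = []
    if best_score > 0:
        for strand in "+-":
            q_codes, H, E, F = mats[strand]
            for i, j in zip(*np.nonzero(H == best_score)):
                qs, ts, pairs = _traceback(H, E, F, q_codes, t_codes,
                                           int(i), int(j), sc)
                best_hits.append(Alignment(best_score, qs, int(i), ts, int(j),
                                           strand, pairs))
                if len(best_hits) >= max_tied:
                    break
            if len(best_hits) >= max_tied:
                break
        best_hits.sort(key=lambda a: (a.t_start, a.t_end, a.strand))
    # merge contiguous qualifying columns into distinct hit regions
    n_hits = int(np.diff(np.concatenate([[0], hit_cols.view(np.int8)])).clip(min=0).sum())
    return best_hits, n_hits
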