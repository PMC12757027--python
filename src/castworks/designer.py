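"""Safe-site selection and guide design for CAST integration.

A *safe site* is an intergenic region between converging genes (-> <-)
where a cargo insertion is expected to be phenotypically neutral.  The
designer:

1. finds converging-gene gaps of 300-600 nt, discarding those that
   overlap mobile-element or noncoding-RNA masks or are flanked by
   essential genes (rejected sites are kept with audit flags);
2. enumerates 5'-CN-3' PAMs on both strands within each accepted site and
   takes the 32 nt immediately 3' of each PAM as a candidate protospacer;
3. keeps candidates with GC content 40-60% whose predicted insertion
   locus - a window ~49 bp downstream of the protospacer 3' end - stays
   inside the intergenic region and clear of terminator masks;
4. scores off-target potential by exhaustive local alignment of the
   protospacer against the genome (its own locus masked out), recording
   the best hit and its complementarity in the PAM-proximal seed region
   (first ~10 nt), where mismatches are most protective;
5. ranks candidates (fewest seed matches, then lowest best-hit score,
   ties to the leftmost coordinate) and returns the top *k* per site.

Ranking uses raw alignment score rather than BLAST e-values; on a single
genome the two orderings are monotone in one another.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .align import Scoring, scan_short_query
from .dna import gc_content, revcomp
from .simgen.genome import Gene, SimGenome, Target

GUIDE_LEN = 32
DEFAULT_GC_RANGE = (40.0, 60.0)
DEFAULT_OFFSET_WINDOW = (45, 55)
DEFAULT_SEED_LEN = 10
DEFAULT_SCORE_FLOOR = 32      # raw score of 16 matched bases at +2/match


@dataclass
class SafeSite:
    index: int
    start: int
    end: int
    left_gene: str
    right_gene: str
    exclusion_flags: set = field(default_factory=set)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def accepted(self) -> bool:
        return not self.exclusion_flags


def _overlaps(start: int, end: int, intervals) -> bool:
    return any(s < end and start < e for s, e in intervals or [])


def find_safe_sites(genes: list[Gene], genome_length: int,
                    min_len: int = 300, max_len: int = 600,
                    masks: dict | None = None,
                    essential_genes: set | None = None) -> list[SafeSite]:
    """Converging-gene intergenic regions with exclusion audit flags.

    ``masks`` may contain ``mobile_element`` / ``ncRNA`` interval lists;
    ``essential_genes`` is a set of gene ids whose flanking sites are
    excluded.  Unsorted or overlapping gene models are normalised with a
    warning.  All converging gaps are returned; callers normally keep
    ``site.accepted`` ones.
    """
    masks = masks or {}
    essential = essential_genes or set()
    ordered = sorted(genes, key=lambda g: (g.start, g.end))
    if [g.id for g in ordered] != [g.id for g in genes]:
        warnings.warn("gene models were unsorted; normalised by coordinate")
    sites = []
    idx = 0
    for a, b in zip(ordered, ordered[1:]):
        if a.strand != "+" or b.strand != "-":
            continue
        start, end = a.end, b.start
        if end <= start:
            warnings.warn(f"overlapping converging genes {a.id}/{b.id}; skipped")
            continue
        site = SafeSite(idx, start, end, a.id, b.id)
        idx += 1
        if site.length < min_len:
            site.exclusion_flags.add("too_short")
        if site.length > max_len:
            site.exclusion_flags.add("too_long")
        if _overlaps(start, end, masks.get("mobile_element")):
            site.exclusion_flags.add("mobile_element")
        if _overlaps(start, end, masks.get("ncRNA")):
            site.exclusion_flags.add("ncRNA")
        if a.id in essential or b.id in essential:
            site.exclusion_flags.add("essential_flank")
        sites.append(site)
    return sites


@dataclass(frozen=True)
class PamSite:
    """A 5'-CN-3' PAM occurrence; ``start`` is the forward-strand start of
    the 2-nt PAM interval regardless of strand."""

    start: int
    strand: str


def scan_pams(seq: str, offset: int = 0) -> list[PamSite]:
    """Every 5'-CN-3' PAM on both strands of *seq*.

    On '+' a PAM is any C followed by one more base; on '-' it is any
    position whose reverse-complement reading starts with C (a G on the
    forward strand at the PAM interval's second base).  Ambiguity codes
    are skipped with a warning.  ``offset`` shifts reported coordinates
    (e.g. the genomic start of the scanned window).
    """
    seq = seq.upper()
    pams = []
    for i in range(len(seq) - 1):
        b0, b1 = seq[i], seq[i + 1]
        if b0 not in "ACGT" or b1 not in "ACGT":
            if b0 not in "ACGT":
                warnings.warn(f"ambiguity code at position {offset + i}; skipped")
            continue
        if b0 == "C":
            pams.append(PamSite(offset + i, "+"))
        if b1 == "G":
            pams.append(PamSite(offset + i, "-"))
    return pams


@dataclass
class OffTargetReport:
    best_hit_length: int
    best_hit_identity: float
    best_hit_score: int
    seed_matches: int
    n_hits_above_floor: int


@dataclass
class GuideCandidate:
    protospacer: str
    pam: str
    strand: str
    proto_start: int
    proto_end: int
    gc_pct: float
    predicted_locus: tuple[int, int]
    site_index: int | None = None
    passes: dict = field(default_factory=dict)
    offtarget: OffTargetReport | None = None
    rank: int | None = None

    @property
    def accepted(self) -> bool:
        return bool(self.passes) and all(self.passes.values())

    def as_target(self) -> Target:
        return Target(self.protospacer, self.pam, self.strand,
                      self.proto_start, self.proto_end)


def extract_guide(genome_seq: str, pam: PamSite, guide_len: int = GUIDE_LEN,
                  offset_window: tuple[int, int] = DEFAULT_OFFSET_WINDOW,
                  site_index: int | None = None) -> GuideCandidate | None:
    """The ``guide_len`` nt immediately 3' of a PAM on the PAM's strand,
    or ``None`` when the window runs off the contig."""
    n = len(genome_seq)
    if pam.strand == "+":
        proto_start = pam.start + 2
        proto_end = proto_start + guide_len
        if proto_end > n:
            return None
        proto = genome_seq[proto_start:proto_end]
        pam_seq = genome_seq[pam.start:pam.start + 2]
        locus = (proto_end + offset_window[0], proto_end + offset_window[1])
    else:
        proto_end = pam.start
        proto_start = proto_end - guide_len
        if proto_start < 0:
            return None
        proto = revcomp(genome_seq[proto_start:proto_end])
        pam_seq = revcomp(genome_seq[pam.start:pam.start + 2])
        locus = (proto_start - offset_window[1], proto_start - offset_window[0])
    return GuideCandidate(proto, pam_seq, pam.strand, proto_start, proto_end,
                          gc_content(proto), locus, site_index)


def filter_guides(candidates: list[GuideCandidate], site: SafeSite,
                  gc_range: tuple[float, float] = DEFAULT_GC_RANGE,
                  terminator_mask=None) -> list[GuideCandidate]:
    """Apply the GC, insertion-locus-containment and terminator rules.

    Every candidate's ``passes`` dict records each rule's outcome; the
    returned list contains only candidates passing all rules.
    """
    accepted = []
    for c in candidates:
        lo, hi = c.predicted_locus
        c.passes = {
            "gc": gc_range[0] <= c.gc_pct <= gc_range[1],
            "locus_inside": site.start <= lo and hi <= site.end,
            "terminator": not _overlaps(lo, hi, terminator_mask),
        }
        if c.accepted:
            accepted.append(c)
    return accepted


def offtarget_scan(candidate: GuideCandidate | str, genome_seq: str,
                   word_size: int = 4, seed_len: int = DEFAULT_SEED_LEN,
                   exclude_interval: tuple[int, int] | None = None,
                   score_floor: int = DEFAULT_SCORE_FLOOR,
                   scoring: Scoring | None = None) -> OffTargetReport:
    """Off-target assessment of one protospacer against the genome.

    The scan is an exhaustive both-strand local alignment without
    complexity masking (equivalent to word seeding at ``word_size`` <= 4,
    where seeds occur at essentially every position), with the on-target
    locus excluded.  ``seed_matches`` counts matching bases within the
    PAM-proximal ``seed_len`` nucleotides of the *worst offender* among
    the top-scoring hits: when several loci tie at the best score, the
    one with the highest seed complementarity determines the risk.  Tied
    hits are collected from the genome and its reverse complement so the
    report is independent of the reference orientation (co-optimal
    alignments can otherwise surface asymmetrically).
    """
    proto = candidate if isinstance(candidate, str) else candidate.protospacer
    hits, n_hits = scan_short_query(proto, genome_seq, scoring=scoring,
                                    exclude=exclude_interval,
                                    score_floor=score_floor)
    L = len(genome_seq)
    ex_rc = None if exclude_interval is None else \
        (L - exclude_interval[1], L - exclude_interval[0])
    hits_rc, _ = scan_short_query(proto, revcomp(genome_seq), scoring=scoring,
                                  exclude=ex_rc, score_floor=score_floor)
    hits = hits + hits_rc
    if not hits:
        return OffTargetReport(0, 0.0, 0, 0, n_hits)
    n = len(proto)

    def seed_of(aln):
        seed = 0
        for qi, _, is_match in aln.pairs:
            proto_idx = qi if aln.strand == "+" else n - 1 - qi
            if proto_idx < seed_len and is_match:
                seed += 1
        return seed

    worst = max(hits, key=seed_of)
    return OffTargetReport(worst.q_span, worst.identity(), worst.score,
                           seed_of(worst), n_hits)


def select_guides(site: SafeSite, accepted: list[GuideCandidate],
                  k: int = 3) -> list[GuideCandidate]:
    """Rank accepted guides and return the top *k* for a site.

    Sort key: fewest seed-region matches of the best off-target hit, then
    lowest best-hit score, ties broken by leftmost genomic coordinate.
    Fewer than *k* accepted guides returns them all with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not accepted:
        warnings.warn(f"site {site.index}: no accepted guides")
        return []
    ranked = sorted(accepted, key=lambda c: (
        c.offtarget.seed_matches if c.offtarget else 0,
        c.offtarget.best_hit_score if c.offtarget else 0,
        c.proto_start))
    if len(ranked) < k:
        warnings.warn(f"site {site.index}: only {len(ranked)} of {k} "
                      "requested guides available")
    chosen = ranked[:k]
    for i, c in enumerate(chosen, start=1):
        c.rank = i
    return chosen


def audit_guides(guides: list[GuideCandidate], sites: dict[int, SafeSite],
                 gc_range=DEFAULT_GC_RANGE) -> bool:
    """Post-pipeline re-check of every emitted guide's invariants."""
    for g in guides:
        assert len(g.protospacer) == GUIDE_LEN, g
        assert g.pam[0] == "C", g
        assert gc_range[0] <= g.gc_pct <= gc_range[1], g
        site = sites[g.site_index]
        lo, hi = g.predicted_locus
        assert site.start <= lo and hi <= site.end, g
    return True


def design_guides(genome: SimGenome, k: int = 3,
                  min_len: int = 300, max_len: int = 600,
                  gc_range=DEFAULT_GC_RANGE,
                  offset_window: tuple[int, int] = DEFAULT_OFFSET_WINDOW,
                  seed_len: int = DEFAULT_SEED_LEN,
                  score_floor: int = DEFAULT_SCORE_FLOOR,
                  essential_genes: set | None = None):
    """Full design pipeline over a genome with annotations and masks.

    Returns ``(sites, guides)``: all converging sites with their audit
    flags, and up to *k* ranked guides per accepted site.
    """
    seq = genome.sequence
    sites = find_safe_sites(genome.genes, len(seq), min_len=min_len,
                            max_len=max_len, masks=genome.masks,
                            essential_genes=essential_genes)
    guides: list[GuideCandidate] = []
    for site in sites:
        if not site.accepted:
            continue
        pams = scan_pams(seq[site.start:site.end], offset=site.start)
        cands = []
        for pam in pams:
            c = extract_guide(seq, pam, offset_window=offset_window,
                              site_index=site.index)
            if c is not None:
                cands.append(c)
        accepted = filter_guides(cands, site, gc_range=gc_range,
                                 terminator_mask=genome.masks.get("terminator"))
        for c in accepted:
            # mask the protospacer plus its PAM (2 nt on either strand side)
            exclude = (max(0, c.proto_start - 7),
                       min(len(seq), c.proto_end + 7))
            c.offtarget = offtarget_scan(c, seq, seed_len=seed_len,
                                         exclude_interval=exclude,
                                         score_floor=score_floor)
        guides.extend(select_guides(site, accepted, k=k))
    audit_guides(guides, {s.index: s for s in sites}, gc_range=gc_range)
    return sites, guides
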