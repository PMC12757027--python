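"""Synthetic genomes with converging-gene safe sites and planted targets.

The generator builds a random bacterial-like reference in which pairs of
converging protein-coding genes (-> <-) enclose intergenic gaps of a
configurable length range.  These gaps are the "safe sites" the guide
designer is expected to find, and one of them can host a planted
protospacer + PAM that directs simulated CAST insertions.

Coordinates are 0-based half-open throughout; FASTA/GFF3 emission converts
to the 1-based conventions of those formats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ..dna import (gc_content, random_dna, random_dna_gc_bounded,
                    revcomp, rng_for)

PROTOSPACER_LEN = 32
PAM_LEN = 2


class InfeasibleConfig(ValueError):
    """Requested gene/site layout cannot fit in the genome."""


@dataclass(frozen=True)
class Gene:
    id: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class SafeSiteTruth:
    """A planted converging-gene intergenic region."""

    index: int
    start: int
    end: int
    left_gene: str
    right_gene: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Target:
    """A planted (or designed) protospacer with its 5'-CN-3' PAM.

    ``proto_start``/``proto_end`` delimit the protospacer on the forward
    strand of the genome.  On the '+' strand the PAM occupies the two bases
    immediately 5' (lower coordinates) of the protospacer and integration
    occurs downstream of ``proto_end``; on the '-' strand everything is
    mirrored and integration occurs at coordinates below ``proto_start``.
    """

    protospacer: str
    pam: str
    strand: str
    proto_start: int
    proto_end: int

    @property
    def three_prime(self) -> int:
        """Genomic coordinate of the insertion-side (3') protospacer edge,
        expressed as the junction coordinate at offset zero."""
        return self.proto_end if self.strand == "+" else self.proto_start

    def offset_of(self, junction: int) -> int:
        """Signed distance of a genomic junction downstream of the
        protospacer 3' end (positive = downstream on the target strand)."""
        if self.strand == "+":
            return junction - self.three_prime
        return self.three_prime - junction

    def junction_at(self, offset: int) -> int:
        """Genomic junction coordinate for a given downstream offset."""
        if self.strand == "+":
            return self.three_prime + offset
        return self.three_prime - offset


@dataclass
class SimGenome:
    sequence: str
    genes: list[Gene]
    masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    planted_sites: list[SafeSiteTruth] = field(default_factory=list)
    name: str = "simchr1"

    def __len__(self) -> int:
        return len(self.sequence)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), width):
                fh.write(self.sequence[i:i + width] + "\n")

    def genes_to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for g in self.genes:
                fh.write("\t".join([
                    self.name, "castworks_sim", "gene",
                    str(g.start + 1), str(g.end), ".", g.strand, ".",
                    f"ID={g.id}",
                ]) + "\n")

    def masks_to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for label, ivals in sorted(self.masks.items()):
                for s, e in ivals:
                    fh.write(f"{self.name}\t{s}\t{e}\t{label}\n")


def make_genome(length: int = 50_000, n_converging_pairs: int = 4,
                intergenic_length_range: tuple[int, int] = (300, 600),
                mask_spec: dict[str, list[tuple[int, int]]] | None = None,
                seed: int = 0, gene_length: int = 900,
                pair_spacing: tuple[int, int] = (300, 800),
                margin: int = 1500) -> SimGenome:
    """Generate a random genome containing converging-gene safe sites.

    Each of the ``n_converging_pairs`` blocks is laid out as a forward
    gene, an intergenic gap drawn uniformly from
    ``intergenic_length_range``, and a reverse gene, so the gap sits
    between converging genes by construction.  Blocks are separated by
    diverging spacers so no spurious converging gaps arise.

    Raises :class:`InfeasibleConfig` when the requested layout cannot fit.
    """
    lo, hi = intergenic_length_range
    if length < 10_000:
        raise InfeasibleConfig("genome length must be at least 10 kb")
    if not (50 <= lo <= hi <= 5000):
        raise ValueError("intergenic_length_range must lie within [50, 5000]")
    rng = rng_for("genome", seed)
    worst = 2 * margin + n_converging_pairs * (2 * gene_length + hi) + \
        max(0, n_converging_pairs - 1) * pair_spacing[1]
    best_case = 2 * margin + n_converging_pairs * (2 * gene_length + lo) + \
        max(0, n_converging_pairs - 1) * pair_spacing[0]
    if best_case > length:
        raise InfeasibleConfig(
            f"{n_converging_pairs} converging pairs need >= {best_case} bp, "
            f"genome is {length} bp")
    # leave headroom for the random draws; shrink spacing if tight
    seq = list(random_dna(rng, length))
    genes: list[Gene] = []
    sites: list[SafeSiteTruth] = []
    pos = margin
    for i in range(n_converging_pairs):
        gap = int(rng.integers(lo, hi + 1))
        spacing = int(rng.integers(pair_spacing[0], pair_spacing[1] + 1))
        g1 = Gene(f"gene{2 * i + 1:04d}", pos, pos + gene_length, "+")
        site_start = g1.end
        site_end = site_start + gap
        g2 = Gene(f"gene{2 * i + 2:04d}", site_end, site_end + gene_length, "-")
        if g2.end + margin > length:
            raise InfeasibleConfig("converging pairs do not fit at drawn sizes")
        genes.append(g1)
        genes.append(g2)
        sites.append(SafeSiteTruth(i, site_start, site_end, g1.id, g2.id))
        pos = g2.end + spacing
    masks = {k: sorted(tuple(iv) for iv in v) for k, v in (mask_spec or {}).items()}
    for label, ivals in masks.items():
        for s, e in ivals:
            if not (0 <= s < e <= length):
                raise ValueError(f"mask interval {label}:{(s, e)} out of bounds")
    return SimGenome("".join(seq), genes, masks, sites)


def plant_target(genome: SimGenome, site_index: int, seed: int = 0,
                 strand: str = "+", clearance: int = 110,
                 pad: int = 10) -> tuple[SimGenome, Target]:
    """Write a 5'-CN-3' PAM and a 32-nt protospacer (GC 40-60%) into a
    planted safe site and return the edited genome plus target record.

    ``clearance`` bases are kept free between the protospacer 3' end and
    the far edge of the site so that the default integration offset plus
    the on-target window remain inside the intergenic region.
    """
    sites = {s.index: s for s in genome.planted_sites}
    if site_index not in sites:
        raise KeyError(f"no planted site with index {site_index}")
    site = sites[site_index]
    need = PAM_LEN + PROTOSPACER_LEN + clearance + pad
    if site.length < need:
        raise InfeasibleConfig(
            f"site {site_index} ({site.length} bp) cannot host PAM + "
            f"protospacer + {clearance} bp clearance")
    rng = rng_for("target", seed)
    proto = random_dna_gc_bounded(rng, PROTOSPACER_LEN, 40.0, 60.0)
    pam = "C" + "ACGT"[rng.integers(4)]
    seq = list(genome.sequence)
    if strand == "+":
        pam_start = site.start + pad
        proto_start = pam_start + PAM_LEN
        proto_end = proto_start + PROTOSPACER_LEN
        seq[pam_start:pam_start + PAM_LEN] = pam
        seq[proto_start:proto_end] = proto
    elif strand == "-":
        # mirrored: PAM at the high-coordinate side, integration toward
        # lower coordinates
        pam_start = site.end - pad - PAM_LEN
        proto_end = pam_start
        proto_start = proto_end - PROTOSPACER_LEN
        seq[pam_start:pam_start + PAM_LEN] = revcomp(pam)
        seq[proto_start:proto_end] = revcomp(proto)
    else:
        raise ValueError("strand must be '+' or '-'")
    target = Target(proto, pam, strand, proto_start, proto_end)
    edited = replace(genome, sequence="".join(seq))
    assert 40.0 <= gc_content(target.protospacer) <= 60.0
    return edited, target
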