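"""Small sequence utilities shared across the package.

All coordinates in this package are 0-based, half-open on the forward
strand of the reference unless a function documents otherwise.  File
formats that are 1-based (GFF3, summary TSVs of genomic positions) are
converted at the I/O boundary only.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# numeric encoding used by the alignment kernels
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def rng_for(domain: str, seed: int) -> np.random.Generator:
    """Seeded generator with per-domain stream separation.

    Different generators (genome, vector, reads, ...) called with the
    same integer seed must not replay the same random stream - otherwise
    e.g. a vector sequence could duplicate the genome prefix.  The domain
    name is folded into the seed material as a spawn key.
    """
    key = tuple(domain.encode("ascii"))
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=key))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_content(seq: str) -> float:
    """GC fraction of *seq* in percent (0..100); 0 for empty input."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA of the given length with expected GC fraction *gc*."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return "".join(ALPHABET[i] for i in idx)


def random_dna_gc_bounded(
    rng: np.random.Generator, length: int, gc_min: float, gc_max: float,
    max_tries: int = 1000,
) -> str:
    """Random DNA whose realised GC percent lies within [gc_min, gc_max]."""
    target = (gc_min + gc_max) / 200.0
    for _ in range(max_tries):
        s = random_dna(rng, length, gc=target)
        if gc_min <= gc_content(s) <= gc_max:
            return s
    raise RuntimeError("could not sample sequence within GC bounds")
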