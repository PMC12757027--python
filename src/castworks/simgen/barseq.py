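"""Barcoded transposon-mutant screen simulator (RB-TnSeq / BarSeq).

Emulates a pooled library of uniquely barcoded single-gene insertion
mutants screened twice (two independent selections) under a CAST
condition and a matched unrelated-transposase (mariner) control.

The generative model per screen:

* every gene carries a *general* fitness effect drawn N(0, null_effect_sd)
  that applies equally to the CAST and the control condition - ordinary
  growth effects of losing the gene, which the control arm exists to
  cancel;
* genes that modulate CAST integration additionally carry a CAST-specific
  differential effect (negative for activators: the mutant acquires fewer
  insertions and is depleted after selection; positive for inhibitors);
* a strain's expected post-selection share is its time-zero share times
  2**(total effect), renormalised; counts are negative-binomial around
  ``depth`` total reads per sample;
* per-screen dropout genes have zero abundance at time zero, emulating
  library bottlenecks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..dna import rng_for

SCREENS = (1, 2)
CONDITIONS = ("cast", "mariner")


def default_hit_set() -> dict[str, float]:
    """CAST-specific differential effects for the 15-gene hit panel used in
    recovery experiments: 11 activators (negative) and 4 inhibitors
    (positive), every magnitude above the |delta| > 1 calling threshold.

    The named genes are the E. coli host factors recurrently implicated in
    type I-F CAST integration (IHF subunit beta, cold-shock protein CspC,
    the RecBCD helicase subunit RecD, the nucleoid factor Hha, ...); the
    remaining entries are synthetic placeholders for screen-only hits.
    """
    activators = {
        "ihfB": -3.2, "cspC": -2.4, "ynbE": -2.0, "umuD": -1.9,
        "chaB": -1.8, "nudG": -1.6, "yneK": -1.5,
        "actH08": -2.2, "actH09": -1.9, "actH10": -1.7, "actH11": -1.5,
    }
    inhibitors = {"recD": 2.8, "hha": 1.8, "inhH03": 1.6, "inhH04": 1.5}
    return {**activators, **inhibitors}


@dataclass
class SimScreenDesign:
    """Library design plus planted truth for a two-screen experiment."""

    genes: list[str]
    strains: pd.DataFrame      # barcode, gene, fractional_position, t0_weight
    effects: pd.DataFrame      # index gene, columns (screen, condition)
    hit_effects: dict[str, float] = field(default_factory=dict)
    dropouts: dict[int, set] = field(default_factory=dict)

    def meta(self) -> pd.DataFrame:
        """Strain metadata table (barcode, gene, fractional_position)."""
        return self.strains[["barcode", "gene", "fractional_position"]].copy()


def make_screen_design(n_genes: int = 3744, strains_per_gene: int = 10,
                       hit_effects: dict[str, float] | None = None,
                       null_effect_sd: float = 0.3,
                       dropout: dict[int, int] | dict[int, list] | None = None,
                       seed: int = 0) -> SimScreenDesign:
    """Build a library design with planted CAST-specific hits.

    ``hit_effects`` maps gene id -> differential effect (added to the CAST
    condition only, identically in both screens).  ``dropout`` maps screen
    number to either a count of random null genes or an explicit gene
    list absent from that screen's starting library.
    """
    rng = rng_for("screen_design", seed)
    hits = dict(hit_effects or {})
    n_null = n_genes - len(hits)
    if n_null < 0:
        raise ValueError("more hit genes than n_genes")
    genes = list(hits) + [f"gene{i:05d}" for i in range(n_null)]
    barcodes, gene_col, pos = [], [], []
    for g in genes:
        for s in range(strains_per_gene):
            barcodes.append(f"bc_{g}_{s}")
            gene_col.append(g)
    pos = rng.uniform(0.0, 1.0, len(barcodes))
    weights = rng.lognormal(0.0, 0.7, len(barcodes))
    strains = pd.DataFrame({
        "barcode": barcodes, "gene": gene_col,
        "fractional_position": pos, "t0_weight": weights,
    })
    cols = pd.MultiIndex.from_product([SCREENS, CONDITIONS],
                                      names=["screen", "condition"])
    eff = pd.DataFrame(0.0, index=pd.Index(genes, name="gene"), columns=cols)
    for screen in SCREENS:
        base = rng.normal(0.0, null_effect_sd, n_genes)
        for cond in CONDITIONS:
            eff[(screen, cond)] = base
        for g, d in hits.items():
            eff.loc[g, (screen, "cast")] += d
    dropouts: dict[int, set] = {s: set() for s in SCREENS}
    null_genes = [g for g in genes if g not in hits]
    for screen, spec in (dropout or {}).items():
        if isinstance(spec, int):
            dropouts[screen] = set(rng.choice(null_genes, spec, replace=False))
        else:
            dropouts[screen] = set(spec)
    return SimScreenDesign(genes, strains, eff, hits, dropouts)


def simulate_barseq(design: SimScreenDesign, depth: int = 1_000_000,
                    n_replicates: int = 3, nb_size: float = 50.0,
                    seed: int = 0) -> pd.DataFrame:
    """Draw BarSeq count tables for every screen, condition and replicate.

    Returns a DataFrame indexed by barcode with one column per sample,
    named ``s{screen}_{t0|cast|mariner}_r{replicate}``.  Counts are
    negative-binomial with dispersion ``nb_size`` (larger = closer to
    Poisson) around ``depth`` expected reads per sample.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = rng_for("barseq", seed)
    strains = design.strains
    out = pd.DataFrame(index=pd.Index(strains["barcode"], name="barcode"))

    def draw(mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, dtype=float)
        p = nb_size / (nb_size + mean)
        counts = np.zeros(len(mean), dtype=np.int64)
        pos = mean > 0
        counts[pos] = rng.negative_binomial(nb_size, p[pos])
        return counts

    for screen in SCREENS:
        w0 = strains["t0_weight"].to_numpy().copy()
        absent = strains["gene"].isin(design.dropouts.get(screen, set())).to_numpy()
        w0[absent] = 0.0
        t0_share = w0 / w0.sum()
        for rep in range(1, n_replicates + 1):
            out[f"s{screen}_t0_r{rep}"] = draw(depth * t0_share)
        for cond in CONDITIONS:
            eff = design.effects[(screen, cond)]
            mult = np.power(2.0, strains["gene"].map(eff).to_numpy())
            w = w0 * mult
            share = w / w.sum()
            for rep in range(1, n_replicates + 1):
                out[f"s{screen}_{cond}_r{rep}"] = draw(depth * share)
    return out
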