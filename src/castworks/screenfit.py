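"""Gene fitness and candidate calling for the pooled CAST host-factor screen.

The analysis is a deliberately compact re-implementation of the standard
RB-TnSeq gene-fitness workflow, reduced to the parts the downstream
decision rule consumes:

1. per-strain fitness: median-centred log2 of (post-selection + pseudo) /
   (time-zero + pseudo) barcode counts;
2. per-gene fitness: unweighted mean over *usable* strains - those with
   adequate time-zero counts and an insertion in the central portion of
   the gene (insertions near either gene end often leave function intact
   and are excluded);
3. differential fitness: replicate-averaged CAST fitness minus
   replicate-averaged control (mariner) fitness, per screen;
4. candidate call: a gene is an *inhibitor* when its differential exceeds
   +threshold in both screens (losing it helps CAST), an *activator* when
   below -threshold in both, ``nd`` when either screen lacks usable
   time-zero abundance, ``none`` otherwise.

The full published RB-TnSeq pipeline applies additional weighted-variance
normalisations; those are intentionally not reproduced here (see the
methods note), since candidate calling only consumes gene-level scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simgen.barseq import CONDITIONS, SCREENS

DEFAULT_CENTRAL_WINDOW = (0.1, 0.9)
DEFAULT_MIN_T0 = 3
DEFAULT_MIN_STRAINS = 1
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_THRESHOLD = 1.0


def strain_fitness(t0_counts: pd.Series, post_counts: pd.Series,
                   meta: pd.DataFrame,
                   pseudocount: float = DEFAULT_PSEUDOCOUNT,
                   central_window: tuple[float, float] = DEFAULT_CENTRAL_WINDOW,
                   min_t0: int = DEFAULT_MIN_T0) -> pd.DataFrame:
    """Per-strain log2 fitness for one post-selection sample.

    ``t0_counts`` and ``post_counts`` are Series keyed by barcode;
    ``meta`` holds barcode, gene and fractional_position columns.  The
    log-ratios are centred on their median over strains with adequate
    time-zero counts, pinning the typical (null) strain at fitness 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    barcodes = t0_counts.index.intersection(post_counts.index)
    if barcodes.empty:
        raise ValueError("no shared barcodes between t0 and post tables")
    meta = meta.set_index("barcode").loc[barcodes]
    t0 = t0_counts.loc[barcodes].astype(float)
    post = post_counts.loc[barcodes].astype(float)
    ratio = np.log2((post + pseudocount) / (t0 + pseudocount))
    has_t0 = t0 >= min_t0
    ratio = ratio - ratio[has_t0].median()
    lo, hi = central_window
    central = (meta["fractional_position"] >= lo) & (meta["fractional_position"] <= hi)
    return pd.DataFrame({
        "barcode": barcodes,
        "gene": meta["gene"].to_numpy(),
        "fractional_position": meta["fractional_position"].to_numpy(),
        "t0_count": t0.to_numpy(),
        "log2_ratio": ratio.to_numpy(),
        "usable": (has_t0 & central).to_numpy(),
    }).reset_index(drop=True)


def gene_fitness(strain_table: pd.DataFrame,
                 min_strains: int = DEFAULT_MIN_STRAINS) -> pd.DataFrame:
    """Aggregate strain fitness to genes by unweighted central-region mean.

    Genes with fewer than ``min_strains`` usable strains are flagged
    ``sufficient_t0 = False`` and carry NaN fitness (reported "nd").
    """
    usable = strain_table[strain_table["usable"]]
    agg = usable.groupby("gene")["log2_ratio"].agg(["mean", "size"])
    genes = strain_table["gene"].unique()
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    out["fitness"] = agg["mean"]
    out["n_usable_strains"] = agg["size"].reindex(genes).fillna(0).astype(int)
    out["sufficient_t0"] = out["n_usable_strains"] >= min_strains
    out.loc[~out["sufficient_t0"], "fitness"] = np.nan
    return out.reset_index()


def differential_fitness(cast_fits: list[pd.DataFrame],
                         mariner_fits: list[pd.DataFrame]) -> pd.DataFrame:
    """Replicate-averaged CAST-minus-control differential per gene.

    Each input is a list of :func:`gene_fitness` tables (one per
    replicate).  A gene insufficient at time zero in any replicate of
    either condition is reported NaN with ``sufficient_t0 = False``.
    """
    if not cast_fits or not mariner_fits:
        raise ValueError("at least one replicate per condition is required")

    def stack(tables):
        fit = pd.concat([t.set_index("gene")["fitness"] for t in tables], axis=1)
        ok = pd.concat([t.set_index("gene")["sufficient_t0"] for t in tables], axis=1)
        return fit.mean(axis=1), ok.all(axis=1)

    cast_mean, cast_ok = stack(cast_fits)
    mar_mean, mar_ok = stack(mariner_fits)
    genes = cast_mean.index.union(mar_mean.index)
    delta = cast_mean.reindex(genes) - mar_mean.reindex(genes)
    ok = cast_ok.reindex(genes, fill_value=False) & \
        mar_ok.reindex(genes, fill_value=False)
    delta[~ok] = np.nan
    return pd.DataFrame({"gene": genes, "delta": delta.to_numpy(),
                         "sufficient_t0": ok.to_numpy()})


def call_candidates(delta1: pd.DataFrame, delta2: pd.DataFrame,
                    threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Two-screen consistency rule on differential fitness.

    inhibitor: delta > +threshold in both screens; activator: delta <
    -threshold in both; nd: insufficient time-zero abundance in either
    screen; none otherwise.  Output is sorted by |mean delta| descending.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    d1 = delta1.set_index("gene")
    d2 = delta2.set_index("gene")
    genes = d1.index.union(d2.index)
    t = pd.DataFrame(index=genes)
    t["delta_screen1"] = d1["delta"].reindex(genes)
    t["delta_screen2"] = d2["delta"].reindex(genes)
    nd = ~(d1["sufficient_t0"].reindex(genes, fill_value=False)
           & d2["sufficient_t0"].reindex(genes, fill_value=False))
    inhib = (t["delta_screen1"] > threshold) & (t["delta_screen2"] > threshold)
    activ = (t["delta_screen1"] < -threshold) & (t["delta_screen2"] < -threshold)
    call = np.where(nd, "nd",
                    np.where(inhib, "inhibitor",
                             np.where(activ, "activator", "none")))
    t["call"] = call
    t["mean_abs_delta"] = t[["delta_screen1", "delta_screen2"]].mean(axis=1).abs()
    t = t.sort_values("mean_abs_delta", ascending=False)
    return t.drop(columns="mean_abs_delta").reset_index().rename(
        columns={"index": "gene"})


def t0_qc(t0_counts: pd.Series, meta: pd.DataFrame,
          min_t0: int = DEFAULT_MIN_T0) -> dict:
    """Report genes missing from the starting library.

    A gene is *missing* when its total time-zero count over all its
    strains falls below ``min_t0``.  Returns the missing gene list, the
    gene-universe size and the missing fraction (percent, 1 d.p.).
    """
    meta = meta.set_index("barcode")
    totals = t0_counts.groupby(meta["gene"].reindex(t0_counts.index)).sum()
    totals = totals.reindex(meta["gene"].unique(), fill_value=0)
    missing = sorted(totals.index[totals < min_t0])
    n_genes = len(totals)
    fraction = len(missing) / n_genes if n_genes else 0.0
    return {
        "missing_genes": missing,
        "n_missing": len(missing),
        "n_genes": n_genes,
        "fraction": fraction,
        "percent": round(100.0 * fraction, 1),
    }


@dataclass
class ScreenResult:
    strain_tables: dict
    gene_tables: dict
    deltas: dict            # screen -> differential table
    calls: pd.DataFrame
    qc: dict                # screen -> t0 QC report


def analyze_screens(counts: pd.DataFrame, meta: pd.DataFrame,
                    threshold: float = DEFAULT_THRESHOLD,
                    pseudocount: float = DEFAULT_PSEUDOCOUNT,
                    central_window: tuple[float, float] = DEFAULT_CENTRAL_WINDOW,
                    min_t0: int = DEFAULT_MIN_T0,
                    min_strains: int = DEFAULT_MIN_STRAINS) -> ScreenResult:
    """End-to-end analysis of a two-screen count table.

    ``counts`` is indexed by barcode with sample columns named
    ``s{screen}_{t0|cast|mariner}_r{rep}`` (the layout emitted by
    :func:`castworks.simgen.simulate_barseq` and accepted from TSV input).
    Time-zero replicates are summed per screen before ratio formation.
    """
    strain_tables: dict = {}
    gene_tables: dict = {}
    deltas: dict = {}
    qc: dict = {}
    for screen in SCREENS:
        t0_cols = [c for c in counts.columns if c.startswith(f"s{screen}_t0_")]
        if not t0_cols:
            raise ValueError(f"no time-zero columns for screen {screen}")
        t0 = counts[t0_cols].sum(axis=1)
        qc[screen] = t0_qc(t0, meta, min_t0=min_t0)
        per_condition: dict[str, list[pd.DataFrame]] = {c: [] for c in CONDITIONS}
        for cond in CONDITIONS:
            reps = sorted(c for c in counts.columns
                          if c.startswith(f"s{screen}_{cond}_"))
            for col in reps:
                st = strain_fitness(t0, counts[col], meta,
                                    pseudocount=pseudocount,
                                    central_window=central_window,
                                    min_t0=min_t0)
                strain_tables[(screen, cond, col)] = st
                gf = gene_fitness(st, min_strains=min_strains)
                gene_tables[(screen, cond, col)] = gf
                per_condition[cond].append(gf)
        deltas[screen] = differential_fitness(per_condition["cast"],
                                              per_condition["mariner"])
    calls = call_candidates(deltas[1], deltas[2], threshold=threshold)
    return ScreenResult(strain_tables, gene_tables, deltas, calls, qc)
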