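"""Transcription-priority ranking: absolute CPM change at phloem arrest.

Because transcription and translation (especially of membrane proteins)
are energetically expensive, the genes whose transcription the berry
shuts down *fastest and hardest* at the stop of phloem unloading are
ranked by their absolute change in expression — the signed stage-mean CPM
difference S - G, deliberately uncorrected for transcript length — after
merging the time-course and pairwise DEG lists.  Percent variation
(100 x (S - G) / G, rounded half away from zero) is reported alongside.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._table1 import GOLDEN8, TABLE1

__all__ = [
    "percent_variation",
    "absolute_difference",
    "merge_and_rank",
    "render_table",
    "reference_table",
    "GOLDEN8",
]

TABLE_COLUMNS = ["gene_id_a", "gene_id_b", "annotation", "cpm_G", "cpm_P",
                 "cpm_S", "variation_pct", "difference", "rank"]


def _round_half_away(x):
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def percent_variation(cpm_g, cpm_s):
    """Integer percent change from G to S: round-half-away-from-zero of
    100 x (S - G) / G.  Undefined (NaN) where the G mean is 0."""
    g = np.asarray(cpm_g, dtype=float)
    s = np.asarray(cpm_s, dtype=float)
    if np.ndim(g) == 0 and g == 0:
        raise ValueError("percent variation undefined for cpm_G = 0")
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * (s - g) / g
    out = np.where(g > 0, _round_half_away(pct), np.nan)
    if np.ndim(out) == 0:
        return int(out)
    if np.isnan(out).any():
        warnings.warn("percent variation undefined for genes with cpm_G = 0")
    return out


def absolute_difference(cpm_g, cpm_s):
    """Signed stage-mean CPM difference S - G (the ranking statistic)."""
    out = np.asarray(cpm_s, dtype=float) - np.asarray(cpm_g, dtype=float)
    return float(out) if np.ndim(out) == 0 else out


def merge_and_rank(
    timecourse_genes,
    pairwise_genes,
    cpm_means: pd.DataFrame,
    annotations: pd.Series | None = None,
    id_map: pd.Series | None = None,
) -> pd.DataFrame:
    """Union of the two DEG lists, ranked by descending |S - G| CPM.

    ``cpm_means`` must carry columns cpm_G, cpm_P, cpm_S indexed by gene.
    Ties in |difference| break lexicographically by gene id, so the rank
    column is a permutation of 1..N independent of input order.
    """
    genes = sorted(set(timecourse_genes) | set(pairwise_genes))
    if not genes:
        warnings.warn("merge_and_rank: empty union of DEG lists")
        return pd.DataFrame(columns=TABLE_COLUMNS)
    missing = [g for g in genes if g not in cpm_means.index]
    if missing:
        raise KeyError(f"no CPM stage means for genes: {missing[:5]}")
    sub = cpm_means.loc[genes, ["cpm_G", "cpm_P", "cpm_S"]].copy()
    sub["difference"] = absolute_difference(sub["cpm_G"], sub["cpm_S"])
    sub["variation_pct"] = percent_variation(sub["cpm_G"].to_numpy(),
                                             sub["cpm_S"].to_numpy())
    sub["abs_difference"] = sub["difference"].abs()
    sub = (
        sub.rename_axis("gene_id_a")
        .reset_index()
        .sort_values(["abs_difference", "gene_id_a"], ascending=[False, True],
                     kind="mergesort")
        .reset_index(drop=True)
    )
    sub["rank"] = np.arange(1, len(sub) + 1)
    sub["gene_id_b"] = sub["gene_id_a"].map(id_map) if id_map is not None else ""
    sub["annotation"] = sub["gene_id_a"].map(annotations) if annotations is not None else ""
    sub["annotation"] = sub["annotation"].fillna("")
    return sub[TABLE_COLUMNS + ["abs_difference"]]


def render_table(ranked: pd.DataFrame, path=None, top: int | None = None) -> pd.DataFrame:
    """Emit the ranked table with the canonical column set (TSV if ``path``).

    A re-render of a rendered table round-trips losslessly.
    """
    out = ranked.copy()
    for col in TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = ""
    out = out[TABLE_COLUMNS]
    if top is not None:
        out = out.head(top)
    if path is not None:
        out.to_csv(path, sep="\t", index=False)
    return out


def reference_table() -> pd.DataFrame:
    """The bundled 35-gene reference table as a DataFrame."""
    return pd.DataFrame(TABLE1, columns=TABLE1[0]._fields)
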