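"""Enhancer-presence vs AS-shift association testing.

For every gene-mediated pairing of a refined enhancer with an AS event, the
samples carrying an inclusive or exclusive shift are cross-tabulated against
the enhancer's tissue-level presence (broadcast to all replicates of a
tissue):

                inclusive   exclusive
    present         a           b
    absent          c           d

Samples whose shift is "none" or missing do not enter the table.  The
concordant cells are a and d (presence tracks inclusion), the discordant
cells b and c.  Pairs are prefiltered for association strength before
testing: the odds ratio a*d / (b*c) must be > 2 or < 0.5, and the effective
size |(a+d) - (b+c)| must be > 10 (all strict).  Zero-cell convention: the
odds ratio is +inf when b*c = 0 with a*d > 0, 0 when a*d = 0 with b*c > 0,
and undefined (prefilter fails) when both products vanish.

Every pair receives a two-sided Fisher exact p-value.  By default the
Benjamini-Hochberg adjustment runs over all pairs jointly (across AS
types), and a pair is significant iff it passes the prefilter AND q < 0.05.
Restricting the adjustment to prefilter-passing pairs only
(``bh_scope="tested"``) is available but anti-conservative: the prefilter
selects on the same evidence the test measures, so the selected p-values
are small by construction and a small-m adjustment over them alone rejects
nearly everything (see the methods documentation).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .psi import AS_TYPES, SHIFT_EXCLUSIVE, SHIFT_INCLUSIVE

logger = logging.getLogger(__name__)

DEFAULT_OR_HI = 2.0
DEFAULT_OR_LO = 0.5
DEFAULT_MIN_EFFECT = 10
DEFAULT_FDR = 0.05

RECORD_COLUMNS = [
    "refined_id",
    "event_id",
    "gene_id",
    "as_type",
    "a",
    "b",
    "c",
    "d",
    "odds_ratio",
    "effective_size",
    "prefilter_pass",
    "p_value",
    "q_value",
    "significant",
]


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Cross-product ratio with the zero-cell convention (inf / 0 / NaN)."""
    ad, bc = a * d, b * c
    if bc == 0:
        return float("inf") if ad > 0 else float("nan")
    return ad / bc


def effective_size(a: int, b: int, c: int, d: int) -> int:
    """|concordant - discordant| = |(a+d) - (b+c)|."""
    return abs((a + d) - (b + c))


def prefilter(
    a: int,
    b: int,
    c: int,
    d: int,
    or_hi: float = DEFAULT_OR_HI,
    or_lo: float = DEFAULT_OR_LO,
    min_effect: float = DEFAULT_MIN_EFFECT,
) -> bool:
    """Association-strength gate: (OR > or_hi or OR < or_lo) and effect > min_effect.

    All inequalities strict.  An undefined odds ratio (both cross-products
    zero) fails; OR = +inf passes the high side and OR = 0 the low side.
    """
    or_ = odds_ratio(a, b, c, d)
    if np.isnan(or_):
        return False
    return (or_ > or_hi or or_ < or_lo) and effective_size(a, b, c, d) > min_effect


def fisher_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p (probability-mass definition of extremeness)."""
    if min(a, b, c, d) < 0:
        raise ValueError("contingency cells must be non-negative")
    if a + b + c + d == 0:
        return 1.0
    p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1]
    return min(1.0, float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j >= i} ( p_(j) * m / j ), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1, dtype=float)
    q_sorted = (p[order] * m) / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def build_contingency(presence: np.ndarray, shifts: np.ndarray) -> tuple[int, int, int, int]:
    """Count (a, b, c, d) from per-sample presence booleans and shift labels.

    Samples labelled "none" (or missing) are excluded.
    """
    pres = np.asarray(presence, dtype=bool)
    sh = np.asarray(shifts, dtype=object)
    inc = sh == SHIFT_INCLUSIVE
    exc = sh == SHIFT_EXCLUSIVE
    a = int(np.sum(pres & inc))
    b = int(np.sum(pres & exc))
    c = int(np.sum(~pres & inc))
    d = int(np.sum(~pres & exc))
    return a, b, c, d


def run_association(
    presence: pd.DataFrame,
    psi_table: pd.DataFrame,
    pairings: pd.DataFrame,
    or_hi: float = DEFAULT_OR_HI,
    or_lo: float = DEFAULT_OR_LO,
    min_effect: float = DEFAULT_MIN_EFFECT,
    fdr: float = DEFAULT_FDR,
    joint_bh: bool = True,
    bh_scope: str = "all",
) -> pd.DataFrame:
    """Score every paired (refined enhancer, AS event) combination.

    Parameters
    ----------
    presence
        Boolean refined_id x tissue matrix from ``call_presence``.
    psi_table
        Output of ``psi.quantify`` (needs event_id, gene_id, as_type,
        sample_id, tissue, shift).
    pairings
        Gene-mediated pairs, columns gene_id and refined_id (many-to-many).
    joint_bh
        Adjust p-values jointly across AS types (default) or within each
        AS type separately.
    bh_scope
        "all" (default): adjust the p-values of every pair; "tested":
        adjust only prefilter-passing pairs (anti-conservative, see module
        docstring); other pairs then carry no q-value.

    Returns one record per (refined enhancer, event of the paired gene),
    sorted by (refined_id, event_id).  ``significant`` means prefilter_pass
    and q < ``fdr`` (strict).  Pairings that reference an unknown gene or
    enhancer are skipped with a warning; the skip count is stored in
    ``result.attrs["n_skipped_pairings"]``.
    """
    if bh_scope not in ("all", "tested"):
        raise ValueError(f"bh_scope must be 'all' or 'tested', got {bh_scope!r}")
    known_tissues = set(presence.columns)
    psi_tissues = set(psi_table["tissue"].unique()) if len(psi_table) else set()
    stray = psi_tissues - known_tissues
    if stray:
        raise ValueError(f"sample tissue(s) {sorted(stray)} absent from the presence matrix")

    # Per event: tissue / shift arrays of shift-labelled samples only.
    labelled = psi_table[psi_table["shift"].isin([SHIFT_INCLUSIVE, SHIFT_EXCLUSIVE])]
    per_event: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    meta: dict[str, tuple[str, str]] = {}
    for eid, sub in psi_table.groupby("event_id"):
        meta[eid] = (sub["gene_id"].iloc[0], sub["as_type"].iloc[0])
    for eid, sub in labelled.groupby("event_id"):
        per_event[eid] = (sub["tissue"].to_numpy(), sub["shift"].to_numpy())

    events_of_gene: dict[str, list[str]] = {}
    for eid, (gid, _) in meta.items():
        events_of_gene.setdefault(gid, []).append(eid)

    known_enh = set(presence.index)
    rows: list[dict] = []
    n_skipped = 0
    for gene_id, refined_id in pairings[["gene_id", "refined_id"]].itertuples(index=False):
        if refined_id not in known_enh or gene_id not in events_of_gene:
            logger.warning("skipping pairing (%s, %s): unknown gene or enhancer", gene_id, refined_id)
            n_skipped += 1
            continue
        pres_row = presence.loc[refined_id]
        for event_id in events_of_gene[gene_id]:
            if event_id in per_event:
                tissues, shifts = per_event[event_id]
                pres = pres_row.reindex(tissues).to_numpy(dtype=bool)
                a, b, c, d = build_contingency(pres, shifts)
            else:  # every sample unshifted
                a = b = c = d = 0
            rows.append(
                {
                    "refined_id": refined_id,
                    "event_id": event_id,
                    "gene_id": gene_id,
                    "as_type": meta[event_id][1],
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": odds_ratio(a, b, c, d),
                    "effective_size": effective_size(a, b, c, d),
                    "prefilter_pass": prefilter(a, b, c, d, or_hi, or_lo, min_effect),
                }
            )

    records = pd.DataFrame(rows, columns=RECORD_COLUMNS[:11])
    if records.empty:
        records = pd.DataFrame(columns=RECORD_COLUMNS)
        records.attrs["n_skipped_pairings"] = n_skipped
        return records
    records = (
        records.drop_duplicates(subset=["refined_id", "event_id"])
        .sort_values(["refined_id", "event_id"], kind="stable")
        .reset_index(drop=True)
    )

    records["p_value"] = np.array(
        [
            fisher_exact(int(a), int(b), int(c), int(d))
            for a, b, c, d in records[["a", "b", "c", "d"]].itertuples(index=False)
        ],
        dtype=float,
    )
    records["q_value"] = np.nan
    scope = records.index if bh_scope == "all" else records.index[records["prefilter_pass"]]
    if len(scope):
        if joint_bh:
            records.loc[scope, "q_value"] = bh_adjust(records.loc[scope, "p_value"].to_numpy())
        else:
            for _, idx in records.loc[scope].groupby("as_type").groups.items():
                records.loc[idx, "q_value"] = bh_adjust(records.loc[idx, "p_value"].to_numpy())
    records["significant"] = records["prefilter_pass"] & (records["q_value"] < fdr)
    records.attrs["n_skipped_pairings"] = n_skipped
    return records


def summarize_counts(records: pd.DataFrame) -> pd.DataFrame:
    """Per-AS-type (and overall) counts of associated genes and enhancers.

    "Input" counts are the distinct genes/enhancers with at least one
    tested (prefilter-passing) record; "significant" counts require at
    least one significant record.  A gene or enhancer significant in
    several AS types counts once per type and once in the "All" row.
    """
    out_rows = []
    tested = records[records["prefilter_pass"]] if len(records) else records
    sig = records[records["significant"]] if len(records) else records
    for as_type in list(AS_TYPES) + ["All"]:
        t = tested if as_type == "All" else tested[tested["as_type"] == as_type]
        s = sig if as_type == "All" else sig[sig["as_type"] == as_type]
        n_in_g = t["gene_id"].nunique() if len(t) else 0
        n_in_e = t["refined_id"].nunique() if len(t) else 0
        n_sig_g = s["gene_id"].nunique() if len(s) else 0
        n_sig_e = s["refined_id"].nunique() if len(s) else 0
        out_rows.append(
            {
                "as_type": as_type,
                "n_significant_genes": n_sig_g,
                "n_input_genes": n_in_g,
                "pct_genes": 100.0 * n_sig_g / n_in_g if n_in_g else 0.0,
                "n_significant_enhancers": n_sig_e,
                "n_input_enhancers": n_in_e,
                "pct_enhancers": 100.0 * n_sig_e / n_in_e if n_in_e else 0.0,
            }
        )
    return pd.DataFrame(out_rows)


def enhancers_per_gene(records: pd.DataFrame, pairings: pd.DataFrame) -> dict[str, float]:
    """Association-degree summary: significant partners per gene/enhancer.

    Means are taken over the genes (resp. enhancers) appearing in the
    pairing table, so entities with no significant partner contribute zeros;
    the pairing-table degrees are reported as baselines.
    """
    genes = pairings["gene_id"].unique()
    enhancers = pairings["refined_id"].unique()
    sig = records[records["significant"]] if len(records) else records
    sig_e_per_g = sig.groupby("gene_id")["refined_id"].nunique() if len(sig) else pd.Series(dtype=int)
    sig_g_per_e = sig.groupby("refined_id")["gene_id"].nunique() if len(sig) else pd.Series(dtype=int)
    paired_e_per_g = pairings.groupby("gene_id")["refined_id"].nunique()
    paired_g_per_e = pairings.groupby("refined_id")["gene_id"].nunique()
    return {
        "mean_significant_enhancers_per_gene": float(
            sig_e_per_g.reindex(genes).fillna(0).mean() if len(genes) else 0.0
        ),
        "mean_significant_genes_per_enhancer": float(
            sig_g_per_e.reindex(enhancers).fillna(0).mean() if len(enhancers) else 0.0
        ),
        "mean_paired_enhancers_per_gene": float(paired_e_per_g.mean() if len(genes) else 0.0),
        "mean_paired_genes_per_enhancer": float(paired_g_per_e.mean() if len(enhancers) else 0.0),
    }
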