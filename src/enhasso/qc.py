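"""Sample-similarity QC and cross-species co-existence summaries.

Two diagnostics accompany the association pipeline:

* A pairwise sample-similarity index over enhancer-AS events.  For each
  paired (refined enhancer, AS event) combination, a sample's call is the
  pair (enhancer presence in the sample's tissue, AS shift label of the
  sample).  The similarity of two samples is the number of combinations
  with identical calls divided by the total number of combinations.  (This
  follows the field's usage of "Jaccard coefficient index" for this
  quantity; as defined it is a simple matching coefficient.)  Replicates of
  one tissue should score higher with each other than with other tissues.

* A homology co-existence summary: given externally supplied gene-homolog
  and enhancer-liftover maps between two species, the fraction of
  enhancer-AS pairs whose gene has a homolog AND whose enhancer has a
  lifted counterpart is tabulated per AS type, separately for significant
  and insignificant pairs, and the two groups of per-type percentages are
  compared with a Welch two-sample t-test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .psi import AS_TYPES, SHIFT_EXCLUSIVE, SHIFT_INCLUSIVE

_SHIFT_CODE = {SHIFT_INCLUSIVE: 1, SHIFT_EXCLUSIVE: 2, "none": 3}


def sample_call_matrix(
    presence: pd.DataFrame, psi_table: pd.DataFrame, pairings: pd.DataFrame
) -> pd.DataFrame:
    """Encode per-sample (presence, shift) calls over all paired events.

    Rows: (refined_id, event_id) combinations from the pairing table (via
    the event's gene); columns: samples.  Each cell is a small integer
    encoding the (present/absent, inclusive/exclusive/none/missing) pair.
    """
    samples = sorted(psi_table["sample_id"].unique())
    sample_tissue = (
        psi_table.drop_duplicates("sample_id").set_index("sample_id")["tissue"].to_dict()
    )
    events_of_gene: dict[str, list[str]] = {}
    for eid, sub in psi_table.groupby("event_id"):
        events_of_gene.setdefault(sub["gene_id"].iloc[0], []).append(eid)

    shift_codes = (
        psi_table.assign(code=psi_table["shift"].map(_SHIFT_CODE).fillna(0).astype(int))
        .pivot_table(index="event_id", columns="sample_id", values="code", aggfunc="first")
        .reindex(columns=samples)
        .fillna(0)
        .astype(int)
    )

    rows, index = [], []
    tissue_arr = np.array([sample_tissue[s] for s in samples])
    for gene_id, refined_id in pairings[["gene_id", "refined_id"]].itertuples(index=False):
        if refined_id not in presence.index or gene_id not in events_of_gene:
            continue
        pres = presence.loc[refined_id].reindex(tissue_arr).to_numpy(dtype=bool)
        for event_id in events_of_gene[gene_id]:
            codes = shift_codes.loc[event_id].to_numpy()
            rows.append(pres.astype(int) * 4 + codes)
            index.append((refined_id, event_id))
    if not rows:
        raise ValueError("no enhancer-AS event combinations: empty call universe")
    return pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index, names=["refined_id", "event_id"]), columns=samples
    )


def jaccard_similarity(calls_s1, calls_s2) -> float:
    """Fraction of enhancer-AS events with identical (presence, shift) calls."""
    u = np.asarray(calls_s1)
    v = np.asarray(calls_s2)
    if u.shape != v.shape:
        raise ValueError("call vectors must share the enhancer-AS event universe")
    if u.size == 0:
        raise ValueError("empty enhancer-AS event universe")
    return float(np.mean(u == v))


def jaccard_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """All pairwise sample similarities from a call matrix (symmetric)."""
    samples = list(calls.columns)
    mat = calls.to_numpy()
    n = len(samples)
    out = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = float(np.mean(mat[:, i] == mat[:, j]))
    return pd.DataFrame(out, index=samples, columns=samples)


def within_between_similarity(
    jaccard: pd.DataFrame, sample_map: pd.DataFrame
) -> tuple[float, float]:
    """Mean similarity among replicates of one tissue vs across tissues."""
    tissue_of = dict(zip(sample_map["sample_id"], sample_map["tissue"]))
    samples = list(jaccard.columns)
    within, between = [], []
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1 :]:
            (within if tissue_of[s1] == tissue_of[s2] else between).append(jaccard.loc[s1, s2])
    return float(np.mean(within)), float(np.mean(between))


def homology_coexistence(
    records: pd.DataFrame,
    gene_homologs: pd.DataFrame,
    enhancer_liftover: pd.DataFrame,
    gene_col: str = "gene_a",
    enh_col: str = "refined_a",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Per-AS-type co-existence of homologous genes and lifted enhancers.

    A pair counts as "with homologous genes and enhancers" iff its gene
    appears in the homolog map and its enhancer has a lifted counterpart
    with overlap >= ``min_overlap`` bp (a liftover map without an
    overlap_bp column is taken at face value).  Percentages are computed
    separately for significant and insignificant pairs.
    """
    homolog_genes = set(gene_homologs[gene_col])
    lift = enhancer_liftover
    if "overlap_bp" in lift.columns:
        lift = lift[lift["overlap_bp"] >= min_overlap]
    lifted = set(lift[enh_col])

    rec = records.copy()
    rec["homologous"] = rec["gene_id"].isin(homolog_genes) & rec["refined_id"].isin(lifted)
    rows = []
    for as_type in AS_TYPES:
        sub = rec[rec["as_type"] == as_type]
        sig = sub[sub["significant"]]
        insig = sub[~sub["significant"]]
        rows.append(
            {
                "as_type": as_type,
                "n_significant": len(sig),
                "n_significant_homologous": int(sig["homologous"].sum()),
                "pct_significant": 100.0 * sig["homologous"].mean() if len(sig) else 0.0,
                "n_insignificant": len(insig),
                "n_insignificant_homologous": int(insig["homologous"].sum()),
                "pct_insignificant": 100.0 * insig["homologous"].mean() if len(insig) else 0.0,
            }
        )
    return pd.DataFrame(rows)


def welch_t_test(sig_percentages, insig_percentages) -> tuple[float, float]:
    """Two-sided Welch (unequal-variance) t-test; returns (t, p).

    Degrees of freedom follow Welch-Satterthwaite.  Groups need >= 2 values.
    """
    x = np.asarray(sig_percentages, dtype=float)
    y = np.asarray(insig_percentages, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.var(x) == 0 and np.var(y) == 0:  # degenerate: t undefined, decide by means
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return float(t), float(p)
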