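"""Percent-spliced-in (PSI) quantification and shift calling.

PSI of an alternative-splicing (AS) event in one sample is the fraction of
junction reads supporting the inclusive isoform:

    PSI = inc_reads / (inc_reads + exc_reads)

A sample with no junction reads for an event has no PSI estimate (missing),
not PSI = 0.  Events whose PSI varies too little across samples carry no
usable signal and are removed: an event is kept only if it has >= 2
non-missing samples and max(PSI) - min(PSI) >= ``min_range`` (0.1 by
default; removal is strict, an event with range exactly 0.1 is retained).

Retained events are Z-transformed per event across all non-missing samples
(sample standard deviation, n-1 denominator).  A sample with Z-PSI > 1 is
labelled an "inclusive shift", Z-PSI < -1 an "exclusive shift", anything in
[-1, 1] "none"; the inequalities are strict, so Z exactly +/-1 is "none".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

AS_TYPES = ("A5SS", "A3SS", "SE", "RI", "MSE", "MXE", "AFE", "ALE", "ATSS", "ATTS")
"""The ten recognised AS event types (splice sites, exon/intron choice, ends)."""

DEFAULT_MIN_RANGE = 0.1
DEFAULT_Z_CUT = 1.0

SHIFT_INCLUSIVE = "inclusive"
SHIFT_EXCLUSIVE = "exclusive"
SHIFT_NONE = "none"


def compute_psi(inc_reads, exc_reads):
    """PSI from junction-read counts; NaN where both counts are zero.

    Accepts scalars or array-likes; negative counts are rejected.
    """
    inc = np.asarray(inc_reads, dtype=float)
    exc = np.asarray(exc_reads, dtype=float)
    if np.any(inc < 0) or np.any(exc < 0):
        raise ValueError("junction read counts must be non-negative")
    total = inc + exc
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(total > 0, inc / np.where(total > 0, total, 1.0), np.nan)
    if np.ndim(inc_reads) == 0 and np.ndim(exc_reads) == 0:
        return float(psi) if total > 0 else float("nan")
    return psi


def classify_shift(z, z_cut: float = DEFAULT_Z_CUT):
    """Label Z-PSI values: > z_cut inclusive, < -z_cut exclusive, else none.

    Boundaries are strict; NaN input yields a missing (NaN) label.
    """
    zarr = np.asarray(z, dtype=float)
    out = np.full(zarr.shape, SHIFT_NONE, dtype=object)
    out[zarr > z_cut] = SHIFT_INCLUSIVE
    out[zarr < -z_cut] = SHIFT_EXCLUSIVE
    out[np.isnan(zarr)] = np.nan
    if np.ndim(z) == 0:
        return out[()]
    return out


def filter_psi_range(table: pd.DataFrame, min_range: float = DEFAULT_MIN_RANGE) -> pd.DataFrame:
    """Drop events whose non-missing PSI range is below ``min_range``.

    Events with fewer than 2 non-missing samples are dropped as well.  The
    removal rule is strict-less-than, so an event whose range equals
    ``min_range`` is retained.
    """
    grouped = table.groupby("event_id")["psi"]
    n_obs = grouped.count()
    rng = grouped.max() - grouped.min()
    keep = n_obs.index[(n_obs >= 2) & (rng >= min_range)]
    return table[table["event_id"].isin(set(keep))].copy()


def z_transform(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-event ``z_psi`` = (psi - mean) / sd over non-missing samples.

    Uses the sample standard deviation (n-1).  Assumes the range filter ran
    first, so no retained event has zero variance.
    """
    out = table.copy()
    grp = out.groupby("event_id")["psi"]
    mean = grp.transform("mean")
    sd = grp.transform("std")  # ddof=1
    out["z_psi"] = (out["psi"] - mean) / sd
    return out


def quantify(
    junctions: pd.DataFrame,
    sample_map: pd.DataFrame,
    min_range: float = DEFAULT_MIN_RANGE,
    z_cut: float = DEFAULT_Z_CUT,
    tissue_level: bool = False,
) -> pd.DataFrame:
    """Full PSI table from junction counts: PSI, range filter, Z, shift.

    Parameters
    ----------
    junctions
        Long-format counts with columns event_id, gene_id, as_type,
        sample_id, inc_reads, exc_reads.
    sample_map
        Columns sample_id, tissue.
    tissue_level
        If True, replicates are first collapsed to tissue-mean PSI, the
        Z-transform runs over tissue means, and the resulting tissue shift
        label is broadcast back to every replicate of the tissue.  The
        default (False) Z-transforms and labels each sample individually.

    Returns the long-format table with added columns tissue, psi, z_psi,
    shift, restricted to events surviving the range filter.
    """
    required = {"event_id", "gene_id", "as_type", "sample_id", "inc_reads", "exc_reads"}
    missing = required - set(junctions.columns)
    if missing:
        raise ValueError(f"junction table is missing columns {sorted(missing)}")
    bad_types = set(junctions["as_type"].unique()) - set(AS_TYPES)
    if bad_types:
        raise ValueError(f"unrecognised AS type(s) {sorted(bad_types)}; expected one of {AS_TYPES}")

    tissue_of = dict(zip(sample_map["sample_id"], sample_map["tissue"]))
    unknown = set(junctions["sample_id"].unique()) - set(tissue_of)
    if unknown:
        raise ValueError(f"sample(s) {sorted(unknown)} missing from the sample->tissue map")

    table = junctions.copy()
    table["tissue"] = table["sample_id"].map(tissue_of)
    table["psi"] = compute_psi(table["inc_reads"].to_numpy(), table["exc_reads"].to_numpy())
    table = filter_psi_range(table, min_range=min_range)
    if table.empty:
        table["z_psi"] = pd.Series(dtype=float)
        table["shift"] = pd.Series(dtype=object)
        return table.reset_index(drop=True)

    if tissue_level:
        tmeans = (
            table.dropna(subset=["psi"])
            .groupby(["event_id", "tissue"], as_index=False)["psi"]
            .mean()
            .rename(columns={"psi": "tissue_psi"})
        )
        grp = tmeans.groupby("event_id")["tissue_psi"]
        tmeans["z_psi"] = (tmeans["tissue_psi"] - grp.transform("mean")) / grp.transform("std")
        tmeans["shift"] = classify_shift(tmeans["z_psi"].to_numpy(), z_cut=z_cut)
        table = table.merge(
            tmeans[["event_id", "tissue", "z_psi", "shift"]], on=["event_id", "tissue"], how="left"
        )
        table.loc[table["psi"].isna(), ["z_psi", "shift"]] = np.nan
    else:
        table = z_transform(table)
        table["shift"] = classify_shift(table["z_psi"].to_numpy(), z_cut=z_cut)

    return table.sort_values(["event_id", "sample_id"], kind="stable").reset_index(drop=True)
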