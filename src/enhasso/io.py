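"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV with headers; enhancer calls are BED3+1 (chrom, start,
end, tissue), 0-based half-open.  Output writing is deterministic: fixed
column order, ``\\n`` line endings, pandas' default float repr.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .refine import EnhancerInterval, RefinedEnhancer, refined_to_frame


def read_enhancer_bed(path: str | Path, tissue: str | None = None) -> list[EnhancerInterval]:
    """Read one BED3+1 enhancer file.

    The fourth column carries the tissue label; if absent, ``tissue`` must
    be given (it also overrides the column when supplied).
    """
    path = Path(path)
    intervals: list[EnhancerInterval] = []
    with path.open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 BED columns, got {len(fields)}")
            t = tissue if tissue is not None else (fields[3] if len(fields) > 3 else None)
            if t is None:
                raise ValueError(f"{path}:{ln}: no tissue column and no tissue label supplied")
            intervals.append(
                EnhancerInterval(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    tissue=t,
                    source_id=f"{path.name}:{ln}",
                )
            )
    return intervals


def read_enhancer_beds(paths, tissues=None) -> list[EnhancerInterval]:
    """Read several per-tissue BED files into one interval list."""
    tissues = tissues or [None] * len(paths)
    out: list[EnhancerInterval] = []
    for path, tissue in zip(paths, tissues):
        out.extend(read_enhancer_bed(path, tissue=tissue))
    return out


def read_junction_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"event_id": str, "gene_id": str, "sample_id": str})
    required = {"event_id", "gene_id", "as_type", "sample_id", "inc_reads", "exc_reads"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: junction table missing columns {sorted(missing)}")
    return df


def read_sample_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "tissue"} <= set(df.columns):
        raise ValueError(f"{path}: sample map needs columns sample_id, tissue")
    return df


def read_pairings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "refined_id"} <= set(df.columns):
        raise ValueError(f"{path}: pairing table needs columns gene_id, refined_id")
    return df


def read_homolog_map(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str)


def read_liftover_map(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "overlap_bp" in df.columns:
        df["overlap_bp"] = df["overlap_bp"].astype(int)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path


def write_refined_bed(refined: list[RefinedEnhancer], path: str | Path) -> Path:
    return write_table(refined_to_frame(refined), path)


def write_presence_matrix(presence: pd.DataFrame, path: str | Path) -> Path:
    out = presence.astype(int).reset_index()
    return write_table(out, path)
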