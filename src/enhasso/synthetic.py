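"""Synthetic multi-tissue enhancer calls and junction counts with planted signal.

The generator emulates the statistical structure the association pipeline
assumes, at the study's scale by default (24 tissues x 3 replicates):

* Latent enhancer loci are placed along one synthetic chromosome with
  pairwise midpoint separation greater than twice the refinement cut
  height, so ground-truth cluster membership is unambiguous (a ``stress``
  mode lifts this guarantee for clustering robustness experiments).  Each
  latent locus is independently active in each tissue with probability
  ``presence_prob``; where active, one interval is emitted whose midpoint
  is the locus midpoint plus Normal(0, boundary_jitter_sd) noise and whose
  length is drawn around ``enhancer_length_mean`` (rounded to an even
  number of bases so the emitted midpoint is exact).

* AS events receive binomially sampled junction reads: per event and
  sample, depth ~ Poisson(read_depth), inclusion reads ~ Binomial(depth,
  inclusion fraction); depth 0 yields a missing PSI.  Unplanted events sit
  at ``baseline_psi`` everywhere.  A planted (enhancer, event) pair shifts
  the event's inclusion fraction by ``effect_size`` in tissues where the
  enhancer is present: inclusive-direction events go from baseline_psi up
  to baseline_psi + effect_size; exclusive-direction events mirror the
  baseline (unshifted inclusion 1 - baseline_psi) and go down by
  effect_size, so the planted shift has the stated magnitude in both
  directions without clamping at the PSI boundaries.

* The gene <-> enhancer pairing table contains every planted pair plus
  random decoy pairings, so multiple-testing behaves realistically, and
  synthetic homolog / liftover maps are emitted with planted entities
  enriched for mapped counterparts.

Latent loci are named ``<chrom>_<k>`` by genomic order — the ids the
refinement step itself will assign when every locus is called in at least
one tissue — so truth joins directly onto pipeline output.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .psi import AS_TYPES
from .refine import EnhancerInterval

_CALLS_STREAM = 17
_COUNTS_STREAM = 29
_BUNDLE_STREAM = 43


def _default_events_per_type() -> dict[str, int]:
    return {t: 20 for t in AS_TYPES}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic generator.

    Defaults mirror the study design the pipeline targets: 24 tissues with
    3 RNA-seq replicates each, ~3 kb enhancers, and planted enhancer-AS
    associations of PSI magnitude 0.5 at tissue presence probability 0.5.
    """

    n_tissues: int = 24
    n_replicates_per_tissue: int = 3
    n_latent_enhancers: int = 50
    n_events_per_type: dict[str, int] = field(default_factory=_default_events_per_type)
    boundary_jitter_sd: float = 150.0
    enhancer_length_mean: float = 3000.0
    enhancer_length_sd: float = 300.0
    presence_prob: float = 0.5
    read_depth: float = 100.0
    baseline_psi: float = 0.3
    effect_size: float = 0.5
    n_planted: int = 30
    n_decoy_pairs: int = 300
    seed: int = 0
    chrom: str = "chr1"
    chrom_length: int = 2_000_000
    cut_height: float = 3000.0
    stress: bool = False
    homology_frac_planted: float = 0.9
    homology_frac_background: float = 0.35

    def __post_init__(self) -> None:
        for name in ("presence_prob", "baseline_psi", "effect_size",
                     "homology_frac_planted", "homology_frac_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("n_tissues", "n_latent_enhancers", "n_planted", "n_decoy_pairs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates_per_tissue < 1:
            raise ValueError("n_replicates_per_tissue must be >= 1")
        if self.boundary_jitter_sd < 0 or self.enhancer_length_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.read_depth < 0:
            raise ValueError("read_depth must be >= 0")
        unknown = set(self.n_events_per_type) - set(AS_TYPES)
        if unknown:
            raise ValueError(f"unknown AS type(s) in n_events_per_type: {sorted(unknown)}")
        if any(n < 0 for n in self.n_events_per_type.values()):
            raise ValueError("event counts must be >= 0")
        n_events = sum(self.n_events_per_type.values())
        if self.n_planted > n_events:
            raise ValueError(f"n_planted ({self.n_planted}) exceeds total events ({n_events})")
        if not self.stress:
            min_gap = 2 * self.cut_height + 1
            margin = self.enhancer_length_mean
            needed = (self.n_latent_enhancers - 1) * min_gap + 2 * margin
            if self.n_latent_enhancers and needed >= self.chrom_length:
                raise ValueError(
                    f"cannot place {self.n_latent_enhancers} latent loci with pairwise "
                    f"separation > {2 * self.cut_height:.0f} bp on a {self.chrom_length} bp "
                    "chromosome; increase chrom_length or enable stress mode"
                )

    @property
    def tissues(self) -> list[str]:
        return [f"T{i + 1:02d}" for i in range(self.n_tissues)]

    @property
    def samples(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{t}_r{j + 1}", "tissue": t}
            for t in self.tissues
            for j in range(self.n_replicates_per_tissue)
        ]
        return pd.DataFrame(rows, columns=["sample_id", "tissue"])


@dataclass
class SyntheticTruth:
    """Ground truth of one simulation: planted pairs and latent structure."""

    config: GeneratorConfig
    latent: pd.DataFrame  # latent_id, chrom, midpoint
    presence: pd.DataFrame  # latent_id x tissue, bool
    events: pd.DataFrame  # event_id, gene_id, as_type
    planted_pairs: list[tuple[str, str, str]]  # (latent_id, event_id, direction)
    tissue_fractions: pd.DataFrame  # event_id x tissue, true inclusion fraction

    @property
    def sample_fractions(self) -> pd.DataFrame:
        """True inclusion fraction per (event, sample): tissue fraction broadcast."""
        samples = self.config.samples
        cols = {
            row.sample_id: self.tissue_fractions[row.tissue]
            for row in samples.itertuples(index=False)
        }
        return pd.DataFrame(cols, index=self.tissue_fractions.index)


def _place_loci(config: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_latent_enhancers
    if n == 0:
        return np.array([], dtype=int)
    margin = config.enhancer_length_mean
    if config.stress:
        mids = np.sort(rng.uniform(margin, config.chrom_length - margin, size=n))
        return np.round(mids).astype(int)
    min_gap = 2 * config.cut_height + 1
    free = config.chrom_length - 2 * margin - (n - 1) * min_gap
    offsets = np.sort(rng.uniform(0.0, free, size=n))
    mids = margin + offsets + np.arange(n) * min_gap
    return np.round(mids).astype(int)


def simulate_enhancer_calls(
    config: GeneratorConfig,
) -> tuple[dict[str, list[EnhancerInterval]], SyntheticTruth]:
    """Draw latent loci, per-tissue presence, jittered interval calls, and truth.

    Returns a mapping tissue -> interval calls plus the full ground truth
    (latent presence matrix, planted pairs, true inclusion fractions).
    Reproducible for a fixed config (seeded independently of the
    junction-count stream).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _CALLS_STREAM]))
    tissues = config.tissues
    mids = _place_loci(config, rng)
    latent_ids = [f"{config.chrom}_{k + 1}" for k in range(len(mids))]
    latent = pd.DataFrame({"latent_id": latent_ids, "chrom": config.chrom, "midpoint": mids})

    presence = pd.DataFrame(
        rng.random((len(mids), len(tissues))) < config.presence_prob,
        index=pd.Index(latent_ids, name="latent_id"),
        columns=tissues,
    )

    calls: dict[str, list[EnhancerInterval]] = {t: [] for t in tissues}
    for i, lid in enumerate(latent_ids):
        for t in tissues:
            if not presence.loc[lid, t]:
                continue
            mid = mids[i] + (
                int(round(rng.normal(0.0, config.boundary_jitter_sd)))
                if config.boundary_jitter_sd > 0
                else 0
            )
            length = rng.normal(config.enhancer_length_mean, config.enhancer_length_sd)
            length = 2 * max(1, int(round(length / 2)))  # even => emitted midpoint is exact
            start = max(0, mid - length // 2)
            calls[t].append(
                EnhancerInterval(
                    chrom=config.chrom,
                    start=start,
                    end=start + length,
                    tissue=t,
                    source_id=f"{lid}:{t}",
                )
            )

    # Event universe and planted associations.
    events = pd.DataFrame(
        [
            {"event_id": f"{as_type}_{i + 1:04d}", "gene_id": f"g_{as_type}_{i + 1:04d}", "as_type": as_type}
            for as_type in AS_TYPES
            for i in range(config.n_events_per_type.get(as_type, 0))
        ],
        columns=["event_id", "gene_id", "as_type"],
    )
    planted_pairs: list[tuple[str, str, str]] = []
    if config.n_planted:
        if not len(latent_ids):
            raise ValueError("cannot plant associations without latent enhancers")
        event_pick = rng.choice(len(events), size=config.n_planted, replace=False)
        if config.n_planted <= len(latent_ids):
            enh_pick = rng.choice(len(latent_ids), size=config.n_planted, replace=False)
        else:
            enh_pick = rng.choice(len(latent_ids), size=config.n_planted, replace=True)
        directions = rng.random(config.n_planted) < 0.5
        for e_i, l_i, inclusive in zip(event_pick, enh_pick, directions):
            planted_pairs.append(
                (latent_ids[l_i], events.iloc[e_i]["event_id"], "inclusive" if inclusive else "exclusive")
            )

    # True inclusion fractions, per event x tissue.
    frac = np.full((len(events), len(tissues)), config.baseline_psi)
    event_row = {eid: i for i, eid in enumerate(events["event_id"])}
    for lid, eid, direction in planted_pairs:
        pres = presence.loc[lid].to_numpy()
        if direction == "inclusive":
            base, shifted = config.baseline_psi, config.baseline_psi + config.effect_size
        else:  # mirrored baseline keeps the planted magnitude without clamping
            base, shifted = 1.0 - config.baseline_psi, 1.0 - config.baseline_psi - config.effect_size
        row = np.where(pres, shifted, base)
        frac[event_row[eid]] = row
    frac = np.clip(frac, 0.0, 1.0)
    tissue_fractions = pd.DataFrame(
        frac, index=pd.Index(events["event_id"], name="event_id"), columns=tissues
    )

    truth = SyntheticTruth(
        config=config,
        latent=latent,
        presence=presence,
        events=events,
        planted_pairs=planted_pairs,
        tissue_fractions=tissue_fractions,
    )
    return calls, truth


def simulate_junction_counts(config: GeneratorConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Binomial junction reads per (event, sample) from the truth fractions.

    depth ~ Poisson(read_depth); inc ~ Binomial(depth, inclusion fraction);
    exc = depth - inc.  Uses its own seed stream, so it is reproducible
    independently of when the enhancer calls were drawn.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _COUNTS_STREAM]))
    samples = config.samples
    frac = truth.sample_fractions.to_numpy()  # events x samples
    n_events, n_samples = frac.shape
    depth = rng.poisson(config.read_depth, size=(n_events, n_samples))
    inc = rng.binomial(depth, frac)
    exc = depth - inc

    ev = truth.events
    rows = pd.DataFrame(
        {
            "event_id": np.repeat(ev["event_id"].to_numpy(), n_samples),
            "gene_id": np.repeat(ev["gene_id"].to_numpy(), n_samples),
            "as_type": np.repeat(ev["as_type"].to_numpy(), n_samples),
            "sample_id": np.tile(samples["sample_id"].to_numpy(), n_events),
            "inc_reads": inc.ravel(),
            "exc_reads": exc.ravel(),
        }
    )
    return rows


def make_pairings(config: GeneratorConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """Gene <-> enhancer pairing table: planted pairs plus random decoys."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _BUNDLE_STREAM]))
    gene_of = dict(zip(truth.events["event_id"], truth.events["gene_id"]))
    pairs = {(gene_of[eid], lid) for lid, eid, _ in truth.planted_pairs}
    genes = truth.events["gene_id"].to_numpy()
    lids = truth.latent["latent_id"].to_numpy()
    if len(genes) and len(lids):
        attempts = 0
        while len(pairs) < len(truth.planted_pairs) + config.n_decoy_pairs and attempts < 50:
            need = len(truth.planted_pairs) + config.n_decoy_pairs - len(pairs)
            g = rng.choice(genes, size=need)
            e = rng.choice(lids, size=need)
            pairs.update(zip(g, e))
            attempts += 1
    out = pd.DataFrame(sorted(pairs), columns=["gene_id", "refined_id"])
    out["provenance"] = "synthetic"
    return out


def make_homology_maps(
    config: GeneratorConfig, truth: SyntheticTruth
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic gene-homolog and enhancer-liftover maps to a mirror species.

    Genes/enhancers participating in planted pairs are mapped with
    probability ``homology_frac_planted``, the rest with
    ``homology_frac_background`` — significant associations should then be
    enriched for co-existing homologs, as in real comparative data.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _BUNDLE_STREAM, 1]))
    gene_of = dict(zip(truth.events["event_id"], truth.events["gene_id"]))
    planted_genes = {gene_of[eid] for _, eid, _ in truth.planted_pairs}
    planted_enh = {lid for lid, _, _ in truth.planted_pairs}

    gene_rows = []
    for g in truth.events["gene_id"]:
        p = config.homology_frac_planted if g in planted_genes else config.homology_frac_background
        if rng.random() < p:
            gene_rows.append({"gene_a": g, "gene_b": f"B_{g}"})
    enh_rows = []
    for lid in truth.latent["latent_id"]:
        p = config.homology_frac_planted if lid in planted_enh else config.homology_frac_background
        if rng.random() < p:
            enh_rows.append(
                {"refined_a": lid, "refined_b": f"B_{lid}", "overlap_bp": int(rng.integers(1, 3001))}
            )
    return (
        pd.DataFrame(gene_rows, columns=["gene_a", "gene_b"]),
        pd.DataFrame(enh_rows, columns=["refined_a", "refined_b", "overlap_bp"]),
    )


def emit_fixture_bundle(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete, pipeline-loadable input bundle to ``out_dir``.

    Files: ``enhancers/<tissue>.bed`` (BED3+1), ``junctions.tsv``,
    ``samples.tsv``, ``pairs.tsv``, ``gene_homologs.tsv``,
    ``enhancer_liftover.tsv``, and ``truth.json``.
    """
    out = Path(out_dir)
    calls, truth = simulate_enhancer_calls(config)
    junctions = simulate_junction_counts(config, truth)
    pairings = make_pairings(config, truth)
    gene_map, enh_map = make_homology_maps(config, truth)

    enh_dir = out / "enhancers"
    try:
        enh_dir.mkdir(parents=True, exist_ok=True)
    except OSError as err:
        raise OSError(f"cannot create bundle directory {enh_dir}: {err}") from err

    paths: dict[str, Path] = {}
    for tissue, intervals in calls.items():
        path = enh_dir / f"{tissue}.bed"
        with path.open("w") as fh:
            for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{tissue}\n")
        paths[f"enhancers/{tissue}"] = path

    def _write(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")
        paths[name] = path

    _write(junctions, "junctions.tsv")
    _write(config.samples, "samples.tsv")
    _write(pairings, "pairs.tsv")
    _write(gene_map, "gene_homologs.tsv")
    _write(enh_map, "enhancer_liftover.tsv")

    truth_json = {
        "config": dataclasses.asdict(config),
        "latent": truth.latent.to_dict(orient="list"),
        "presence": {
            lid: {t: bool(v) for t, v in row.items()}
            for lid, row in truth.presence.iterrows()
        },
        "planted_pairs": [list(p) for p in truth.planted_pairs],
    }
    path = out / "truth.json"
    with path.open("w") as fh:
        json.dump(truth_json, fh, indent=1, sort_keys=True)
        fh.write("\n")
    paths["truth.json"] = path
    return paths


def load_truth_json(path: str | Path) -> dict:
    """Read back a bundle's ``truth.json`` (planted pairs, presence, config)."""
    with Path(path).open() as fh:
        return json.load(fh)


def score_against_truth(records: pd.DataFrame, planted_pairs) -> dict[str, float]:
    """Recovery metrics of association records against planted truth.

    ``planted_pairs`` is an iterable of (latent/refined id, event_id[, ...]).
    Returns recall over planted pairs, empirical FDR among significant
    records, and the raw counts.
    """
    planted = {(p[0], p[1]) for p in planted_pairs}
    if len(records):
        sig = {
            (r, e)
            for r, e in records.loc[records["significant"], ["refined_id", "event_id"]].itertuples(
                index=False
            )
        }
    else:
        sig = set()
    tp = len(sig & planted)
    return {
        "recall": tp / len(planted) if planted else float("nan"),
        "empirical_fdr": (len(sig) - tp) / len(sig) if sig else 0.0,
        "n_significant": len(sig),
        "n_planted": len(planted),
        "n_true_positive": tp,
    }
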