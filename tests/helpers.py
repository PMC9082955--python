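"""Shared simulation-and-run helpers for the test suite."""

from __future__ import annotations

import enhasso as E


def simulate_inputs(seed: int, **overrides):
    """One synthetic dataset: (intervals, junctions, sample_map, pairings, truth)."""
    cfg = E.GeneratorConfig(seed=seed, **overrides)
    calls, truth = E.simulate_enhancer_calls(cfg)
    junctions = E.simulate_junction_counts(cfg, truth)
    pairings = E.make_pairings(cfg, truth)
    intervals = [iv for tissue in calls for iv in calls[tissue]]
    return intervals, junctions, cfg.samples, pairings, truth


def simulate_and_run(seed: int, config_overrides=None, **pipeline_params):
    """Generate a dataset under the study conditions and run the pipeline."""
    intervals, junctions, samples, pairings, truth = simulate_inputs(
        seed, **(config_overrides or {})
    )
    result = E.run_pipeline(intervals, junctions, samples, pairings, **pipeline_params)
    return result, truth, pairings
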