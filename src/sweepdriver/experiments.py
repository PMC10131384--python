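"""Reproducible study-condition experiments built on the simulator.

These functions define the canonical synthetic study conditions — a
three-deme cohort at reduced scale (N = 500 diploids per deme,
L = 2x10^5 bp, scaled rates) with a hard sweep (s = 0.05) planted in the
most recently founded deme — and run the full scan pipeline on them. They
back both the test suite and the acceptance script, so every reported
number is recomputed from scratch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import haplostats, pipeline, synthpop

#: canonical sweep for the recovery experiment
SWEEP_DEME = 2
FOCAL_POSITION = 100_000
SELECTION_COEFFICIENT = 0.05
SWEEP_ONSET = 200
CALL_RADIUS_BP = 10_000


def _derive_seed(seed: int, i: int) -> int:
    return int((seed * 100_003 + 7919 * i) % (2**31 - 1))


def study_sim_config(seed: int, sweep: bool = True) -> synthpop.SimConfig:
    """The canonical reduced-scale simulation, with or without the sweep."""
    sw = (
        synthpop.SweepSpec(
            deme=SWEEP_DEME,
            position=FOCAL_POSITION,
            s=SELECTION_COEFFICIENT,
            onset=SWEEP_ONSET,
        )
        if sweep
        else None
    )
    return synthpop.SimConfig(seed=seed, sweep=sw)


def study_scan_config() -> pipeline.ScanConfig:
    """Default thresholds, outgroup = the ancestral deme, scans focused on
    the sweep deme."""
    return pipeline.ScanConfig(
        populations=("pop0", "pop1", "pop2"),
        outgroup="pop0",
        focal_only=f"pop{SWEEP_DEME}",
    )


@dataclass
class ReplicateOutcome:
    seed: int
    called: bool
    focal_freq: float | None
    n_candidates: int
    n_sweep_restarts: int


def run_replicate(seed: int, sweep: bool = True) -> ReplicateOutcome:
    """Simulate one replicate and ask whether a final call lands within
    CALL_RADIUS_BP of the (planted or virtual) focal position in the sweep
    deme."""
    sim_cfg = study_sim_config(seed, sweep)
    matrices, truth = synthpop.simulate(sim_cfg)
    result = pipeline.run_pipeline(matrices, study_scan_config())
    c = result.candidates
    called = False
    if len(c):
        near = (
            c["final_call"]
            & (c["population"] == f"pop{SWEEP_DEME}")
            & ((c["pos"] - FOCAL_POSITION).abs() <= CALL_RADIUS_BP)
        )
        called = bool(near.any())
    return ReplicateOutcome(
        seed=seed,
        called=called,
        focal_freq=truth.focal_final_freqs.get(f"pop{SWEEP_DEME}"),
        n_candidates=int(c["final_call"].sum()) if len(c) else 0,
        n_sweep_restarts=truth.n_sweep_restarts,
    )


@dataclass
class SweepRecoveryResult:
    sweep_outcomes: list[ReplicateOutcome] = field(default_factory=list)
    neutral_outcomes: list[ReplicateOutcome] = field(default_factory=list)

    @property
    def recovery_rate(self) -> float:
        return float(np.mean([o.called for o in self.sweep_outcomes]))

    @property
    def false_call_rate(self) -> float:
        return float(np.mean([o.called for o in self.neutral_outcomes]))


def sweep_recovery(
    n_sweep: int = 50, n_neutral: int = 50, seed: int = 1
) -> SweepRecoveryResult:
    """Sweep-recovery power and matched-neutral false-call rate."""
    result = SweepRecoveryResult()
    for i in range(n_sweep):
        result.sweep_outcomes.append(run_replicate(_derive_seed(seed, i), True))
    for i in range(n_neutral):
        result.neutral_outcomes.append(
            run_replicate(_derive_seed(seed, n_sweep + i), False)
        )
    return result


def neutral_tail_fraction(
    seed: int = 1, n_scores: int = 10_000, n_bins: int = 100
) -> float:
    """Fraction of |standardized score| > 2 after frequency-bin
    standardization of Monte-Carlo null scores.

    Null raw scores are standard-normal draws with uniform derived-allele
    frequencies; after per-bin standardization the two-sided tail mass
    should approximate 2*Phi(-2) ~ 0.0455.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, n_scores + 1),
            "derived_freq": rng.uniform(0, 1, n_scores),
            "raw": rng.normal(size=n_scores),
            "standardized": np.nan,
            "reason": "ok",
        }
    )
    track = haplostats.ScoreTrack("iHS", df)
    out = haplostats.standardize(track, n_bins=n_bins)
    std = out.data["standardized"]
    return float((std.abs() > 2).mean())
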