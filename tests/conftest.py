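"""Shared fixtures: small deterministic assemblies and full simulator runs.

The expensive end-to-end simulator replicates are session-scoped and
shared by the conservation, convergence and truth-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from uidscaffold.merging import MergeParameters, ScaffoldResult, run_cycles
from uidscaffold.simulate import (
    FragmentedGenome,
    SimParams,
    evaluate_reconstruction,
    fragment_genome,
    simulate_genome,
)

N_REPLICATE_SEEDS = 20


@dataclass
class SimRun:
    params: SimParams
    genome_seq: str
    frag: FragmentedGenome
    result: ScaffoldResult
    precision: float
    recall: float


def _run_replicate(seed: int, divergence: float) -> SimRun:
    params = SimParams(seed=seed, divergence=divergence)
    genome, annotations = simulate_genome(params)
    frag = fragment_genome(genome, annotations, params)
    result = run_cycles(frag.contigs, frag.annotations, MergeParameters())
    layouts = {c.id: c.agp_components() for c in result.contigs}
    report = evaluate_reconstruction(layouts, frag.adjacencies,
                                     [c.id for c in frag.contigs])
    return SimRun(
        params=params,
        genome_seq=genome.seq,
        frag=frag,
        result=result,
        precision=report.precision,
        recall=report.recall,
    )


@pytest.fixture(scope="session")
def default_sim_runs() -> list[SimRun]:
    """Simulator defaults (2% repeat-copy divergence), 20 fixed seeds."""
    return [_run_replicate(seed, 0.02) for seed in range(1, N_REPLICATE_SEEDS + 1)]


@pytest.fixture(scope="session")
def zero_divergence_runs() -> list[SimRun]:
    """Identical repeat copies (the easy setting), 20 fixed seeds."""
    return [_run_replicate(seed, 0.0) for seed in range(1, N_REPLICATE_SEEDS + 1)]
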