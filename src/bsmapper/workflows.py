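"""High-level workflows combining simulation, mapping and evaluation."""
from __future__ import annotations

import numpy as np

from .pipeline import MapParams, MappingResult, run_mapping
from .readprep import BSRead
from .refprep import Genome
from .simulator import SimConfig, SimMetrics, evaluate, simulate_methylome, simulate_reads


def simulate_and_map(
    genome: Genome,
    n_reads: int,
    protocol: str = "lister",
    p_CG: float = 0.72,
    p_CHG: float = 0.0,
    p_CHH: float = 0.0,
    read_len: int = 36,
    error_profile: np.ndarray | None = None,
    seed: int = 0,
    params: MapParams | None = None,
):
    """Simulate a bisulfite library, map it, and score against truth.

    Returns ``(result, truth, metrics)``. The methylome and read seeds
    are derived from ``seed`` so a single integer reproduces the whole
    experiment.
    """
    if params is None:
        params = MapParams(protocol=protocol)
    elif params.protocol != protocol:
        raise ValueError("params.protocol disagrees with the protocol argument")
    methylome = simulate_methylome(genome, p_CG, p_CHG, p_CHH, seed=seed)
    cfg = SimConfig(
        n_reads=n_reads,
        read_len=read_len,
        protocol=protocol,
        p_CG=p_CG,
        p_CHG=p_CHG,
        p_CHH=p_CHH,
        error_profile=error_profile,
        rng_seed=seed + 1,
        tag_config=params.tag_config,
    )
    records, truth = simulate_reads(genome, methylome, cfg)
    reads = [BSRead(read_id=r, seq=s, qual=q) for r, s, q in records]
    result = run_mapping(genome, reads, params)
    metrics = evaluate(result, truth)
    return result, truth, metrics
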