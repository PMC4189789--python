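"""Default study cohorts: simulated genotype groups for behavior and imaging.

The behavioral cohort mirrors the published design — 6 wild-type and 9 Fmr1
KO mice, 12 sessions each — with a generative learning structure in which
both genotypes learn at nose distances but only wild types learn at
whisker-only distances.  The imaging cohort generates per-animal phantoms in
which the knockout group's responsive region is larger and stronger, the
qualitative pattern seen with intrinsic-signal imaging of single whiskers.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agent import AgentConfig, BehavioralAgent
from .engine import ExperimentRecord, GapCrossConfig, run_experiment
from .io import records_to_frame
from .phantom import OISPhantomConfig, Phantom, generate_ois_stack

#: whisker-class learning is absent in the knockout model
DEFAULT_AGENTS = {
    "WT": AgentConfig(genotype="WT", nose_learning_rate=0.2, whisker_learning_rate=0.2),
    "KO": AgentConfig(genotype="KO", nose_learning_rate=0.2, whisker_learning_rate=0.0),
}


def default_agent_config(genotype: str, **overrides) -> AgentConfig:
    """Study-condition agent parameters for a genotype ("WT" or "KO")."""
    if genotype not in DEFAULT_AGENTS:
        raise ValueError(f"unknown genotype {genotype!r}")
    base = DEFAULT_AGENTS[genotype]
    return replace(base, **overrides) if overrides else base


def simulate_cohort(
    n_wt: int = 6,
    n_ko: int = 9,
    config: Optional[GapCrossConfig] = None,
    seed: int = 0,
    wt_agent: Optional[AgentConfig] = None,
    ko_agent: Optional[AgentConfig] = None,
) -> list[ExperimentRecord]:
    """Simulate a full two-genotype behavioral cohort.

    Each mouse gets an independent random stream spawned from ``seed``; the
    default group sizes are the published design (6 WT, 9 KO).
    """
    config = config or GapCrossConfig()
    wt_agent = wt_agent or default_agent_config("WT")
    ko_agent = ko_agent or default_agent_config("KO")
    streams = np.random.SeedSequence(seed).spawn(n_wt + n_ko)
    records = []
    idx = 0
    for genotype, n, agent_cfg in (("WT", n_wt, wt_agent), ("KO", n_ko, ko_agent)):
        agent = BehavioralAgent(agent_cfg)
        for i in range(n):
            rng = np.random.default_rng(streams[idx])
            idx += 1
            records.append(
                run_experiment(agent, config, rng, mouse_id=f"{genotype}{i + 1:02d}")
            )
    return records


def simulate_cohort_frame(
    n_wt: int = 6, n_ko: int = 9, config: Optional[GapCrossConfig] = None, seed: int = 0, **kw
) -> pd.DataFrame:
    """Convenience: :func:`simulate_cohort` flattened to a tidy trial log."""
    return records_to_frame(simulate_cohort(n_wt=n_wt, n_ko=n_ko, config=config, seed=seed, **kw))


#: imaging phantom base shared by both genotypes (desk-scale: 48 px, 12 cycles)
IMAGING_BASE = OISPhantomConfig(
    n_frames=240,
    frame_rate=1.0,
    stim_frequency=0.05,
    image_shape=(48, 48),
    blob_center=(24.0, 24.0),
    blob_sigma=3.5,
    peak_drr=8e-4,
    baseline_reflectance=1000.0,
    white_noise_sd=2.0,
    drift_amplitude=5.0,
    confound_frequencies=(0.35, 0.45),
)

#: knockout phantoms: larger and stronger responsive region
KO_IMAGING_SCALE = {"blob_sigma": 1.35, "peak_drr": 1.3}


def imaging_cohort_configs(
    n_wt: int = 10,
    n_ko: int = 10,
    seed: int = 0,
    base: Optional[OISPhantomConfig] = None,
) -> list[tuple[str, OISPhantomConfig]]:
    """Per-animal phantom configs for a two-genotype imaging comparison.

    Animal-to-animal variability enters as +/-10% lognormal-ish jitter on the
    blob size and peak amplitude and a small jitter of the blob centre.
    """
    base = base or IMAGING_BASE
    rng = np.random.default_rng(seed)
    configs = []
    for genotype, n in (("WT", n_wt), ("KO", n_ko)):
        s_sigma = KO_IMAGING_SCALE["blob_sigma"] if genotype == "KO" else 1.0
        s_peak = KO_IMAGING_SCALE["peak_drr"] if genotype == "KO" else 1.0
        for i in range(n):
            jitter = np.exp(rng.normal(0.0, 0.1, size=2))
            center = (
                base.blob_center[0] + rng.uniform(-1.5, 1.5),
                base.blob_center[1] + rng.uniform(-1.5, 1.5),
            )
            configs.append(
                (
                    genotype,
                    replace(
                        base,
                        blob_sigma=base.blob_sigma * s_sigma * jitter[0],
                        peak_drr=base.peak_drr * s_peak * jitter[1],
                        blob_center=center,
                        seed=int(rng.integers(2**31 - 1)),
                    ),
                )
            )
    return configs


def generate_imaging_cohort(
    n_wt: int = 10, n_ko: int = 10, seed: int = 0, base: Optional[OISPhantomConfig] = None
) -> list[tuple[str, Phantom]]:
    """Generate the phantoms of :func:`imaging_cohort_configs`."""
    return [
        (genotype, generate_ois_stack(cfg))
        for genotype, cfg in imaging_cohort_configs(n_wt, n_ko, seed, base)
    ]
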