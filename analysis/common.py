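"""Shared study configuration for the numbered analysis drivers.

Three populations (Cold, Warm, Temp) on three 12.8-Mb chromosome arms at
25-kb bins: large enough for six dyadic scales (50 kb - 1.6 Mb) with
reasonable coefficient counts, small enough that every driver runs in
seconds.  Twelve warm spots (four per arm, 15-fold over background) are
injected, partitioned across the populations, with divergent regions
covering 80% of them.
"""

from pathlib import Path

from rhoscape.pipeline import RunConfig
from rhoscape.synthetic import SyntheticConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "analysis"
ARMS = {"2L": 12_800_000, "2R": 12_800_000, "3L": 12_800_000}
SEED = 1


def injected_spots():
    spots = []
    for arm in ARMS:
        for k in range(4):
            start = 800_000 + 1_000_000 * k
            spots.append((arm, start, start + 1_000 + 450 * k, 15.0))
    return tuple(spots)


def study_config() -> RunConfig:
    return RunConfig(
        outdir=str(RESULTS),
        seed=SEED,
        synthetic_config=SyntheticConfig(
            arm_lengths=dict(ARMS),
            warm_spots=injected_spots(),
            divergent_overlap_fraction=0.8,
            seed=SEED,
        ),
    )
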