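"""Shared study conditions for the numbered analysis scripts.

One mid-sized synthetic coastal region serves as the study area for the
whole narrative: two tiers of counties (coastal/inland), ~80 block
groups, three tide gauges, and the default site mix (~150 raw records
across eleven hazard categories, 8% injected near-duplicates).
"""

from pathlib import Path

from coastrisk.synth import RegionConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
BUNDLE = RESULTS / "region_bundle"

STUDY_CONFIG = RegionConfig(
    seed=7,
    extent_m=(24000.0, 16000.0),
    cell_m=60.0,
    n_counties=6,
    n_blockgroups=80,
    n_gauges=3,
    slr_samples=1000,
)
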