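"""Shared study configuration and result paths for the analysis scripts.

The study design: two synthetic cohorts over the same 300-gene genome
(5 chromosomes x 2 cytobands of 30 genes), 50 samples each. The cancer-like
cohort carries a planted 30-gene co-expression block (rho = 0.8) filling
cytoband 1p11; the normal-like cohort is driven by 5 global trans factors
(loading 0.6). Networks keep the top 10,000 edges.
"""

from pathlib import Path

import ssgcn

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"        # small summary tables (kept)
SCRATCH = ROOT / "scratch"        # bulky intermediates (regenerated on demand)
DATA = SCRATCH / "data"

SEED = 20_260_927 % (2**31)
N_SAMPLES = 50
K_TOP = 10_000
COHORTS = {"normal": "normal_like", "cancer": "cancer_like"}
PLANTED_REGION = "1:1p11"


def study_config() -> ssgcn.SimulationConfig:
    return ssgcn.default_config(seed=SEED, n_samples=N_SAMPLES)


def path(*parts) -> Path:
    """A path under results/ (small summary tables)."""
    p = RESULTS.joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p


def spath(*parts) -> Path:
    """A path under scratch/ (bulky intermediates: matrices, edge lists)."""
    p = SCRATCH.joinpath(*parts)
    p.parent.mkdir(parents=True, exist_ok=True)
    return p
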