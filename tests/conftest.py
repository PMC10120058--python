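import numpy as np
import pandas as pd
import pytest

from tsrsweep import DFEConfig, SimulationConfig, build_template
from tsrsweep.simulate import PopulationState


@pytest.fixture(scope="session")
def template():
    """Default ACCase-like locus: 12,250 bp, 10 exons, 7 TSR sites."""
    return build_template()


@pytest.fixture(scope="session")
def template7():
    """Minimal locus of just the 7 TSR target nucleotides (no background)."""
    return build_template(length_bp=7, n_exons=1, coding_fraction=1.0,
                          tsr_sites=[0, 1, 2, 3, 4, 5, 6])


@pytest.fixture(scope="session")
def dfe():
    return DFEConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(20220914)


def make_tsr_state(config: SimulationConfig, template, dfe, count: int,
                   s: float = 0.0, h: float = 0.5, origin_generation: int = -5) -> PopulationState:
    """Generation-0 state with a single TSR mutation at `count` copies
    (carried by the first `count` haplotype slots)."""
    two_n = 2 * config.N
    if not 0 <= count <= two_n:
        raise ValueError("count out of range")
    off = np.zeros(two_n + 1, np.int64)
    off[1 : count + 1] = np.arange(1, count + 1)
    off[count + 1 :] = count
    reg = pd.DataFrame(
        {"origin_id": [0], "site": [min(template.tsr_sites)],
         "origin_generation": [origin_generation]}
    ).set_index("origin_id")
    reg["origin_phase"] = "selection" if origin_generation >= 1 else "burnin"
    return PopulationState(
        generation=0,
        N=config.N,
        mut_site=np.array([min(template.tsr_sites)], np.int32),
        mut_s=np.array([s]),
        mut_h=np.array([h]),
        mut_is_tsr=np.array([1], np.uint8),
        mut_origin_gen=np.array([origin_generation], np.int32),
        mut_origin_id=np.array([0], np.int64),
        next_origin_id=1,
        tsr_registry=reg,
        config=config,
        template=template,
        dfe=dfe,
        pop_offsets=off,
        pop_muts=np.zeros(count, np.int32),
    )
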