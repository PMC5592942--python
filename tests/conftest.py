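import numpy as np
import pandas as pd
import pytest

from aneuscreen import synthetic_data as sd
from aneuscreen.variants import (
    CallerParams,
    call_mutations,
    classify_effects,
    refine_reference,
)


@pytest.fixture(scope="session")
def small_genome():
    spec = sd.GenomeSpec(("chrA", "chrB"), (20000, 15000), 0.38, seed=1)
    return sd.simulate_genome(spec)


@pytest.fixture(scope="session")
def cohort42():
    """The packaged point-mutation cohort, refined and called once per
    session (noiseless 100x throughout)."""
    fx = sd.make_point_mutation_cohort(seed=42)

    def provider(genome):
        return sd.simulate_pileup(fx.progenitor_model, genome, 100, 0.0, "none", 7)

    refined = refine_reference(fx.base_reference, provider)
    frames = []
    for i, (mutant_id, model) in enumerate(fx.mutants):
        plp = sd.simulate_pileup(model, refined.genome, 100, 0.0, "none", 100 + i)
        calls = call_mutations(plp, refined.genome, CallerParams(), mutant_id)
        frames.append(classify_effects(calls, fx.annotation, refined.genome))
    cohort_calls = pd.concat(frames, ignore_index=True)
    return fx, refined, cohort_calls
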