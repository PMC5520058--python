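import numpy as np
import pytest

from paleodog import damagefit, simdata


@pytest.fixture(scope="session")
def std_damage_model() -> damagefit.DamageModel:
    """The canonical simulated-damage model: a=0.3, b=0.3, c=1 at both ends."""
    return damagefit.DamageModel.flat(0.3, 0.3, 1.0)


@pytest.fixture(scope="session")
def single_pop_config() -> simdata.DemographyConfig:
    return simdata.DemographyConfig(
        populations=["POP"], pop_sizes={"POP": 0.01}, samples={"POP": 1}
    )


@pytest.fixture(scope="session")
def small_truth_panel(single_pop_config) -> simdata.GenotypePanel:
    return simdata.simulate_genotypes(single_pop_config, 400, seed=11)


def make_stack(bases, quals=30, mapq=37, orient=1, pos5=1, length=70):
    """Hand-build a one-site read stack for caller tests."""
    bases = np.array(list(bases))
    n = len(bases)

    def arr(x):
        return np.full(n, x, dtype=np.int64) if np.isscalar(x) else np.asarray(x)

    p5 = arr(pos5)
    return dict(
        bases=bases,
        quals=arr(quals),
        mapqs=arr(mapq),
        orients=arr(orient),
        pos5=p5,
        pos3=arr(length) - p5 + 1,
    )
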