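import pytest
from hypothesis import HealthCheck, settings

import mornaseq as m

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cfg():
    return m.PipelineConfig()


@pytest.fixture(scope="session")
def std_sim():
    """The standard simulation scenario: 20 hairpins, 12 planted moRNAs
    (>=20 reads each), 0.1%/base errors, 50k reads, fixed seed."""
    cfg = m.SimConfig(seed=1)
    ref = m.simulate_reference(cfg)
    reads, truth = m.simulate_library(ref, cfg)
    return cfg, ref, reads, truth


@pytest.fixture(scope="session")
def std_result(std_sim, default_cfg):
    """Full pipeline run over the standard scenario."""
    cfg, ref, reads, truth = std_sim
    bundle = m.ReferenceBundle(ref.genome, ref.hairpins, ref.class_refs,
                               ref.conservation)
    pipe = m.MoRNAPipeline(bundle, default_cfg)
    res = pipe.run({"sim": reads}, cfg.adapter)
    return pipe, res


@pytest.fixture(scope="session")
def small_sim():
    """A lighter library for tests that rerun the pipeline repeatedly."""
    cfg = m.SimConfig(seed=7, library_size=4000, n_hairpins=8,
                      n_planted_mornas=5, n_single_mature=1)
    ref = m.simulate_reference(cfg)
    reads, truth = m.simulate_library(ref, cfg)
    return cfg, ref, reads, truth


def run_pipeline(ref, reads, pcfg, adapter, library="sim"):
    bundle = m.ReferenceBundle(ref.genome, ref.hairpins, ref.class_refs,
                               ref.conservation)
    pipe = m.MoRNAPipeline(bundle, pcfg)
    return pipe.run({library: reads}, adapter)
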