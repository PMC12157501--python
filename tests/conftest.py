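import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True, max_examples=50)
settings.load_profile("default")

from srnaclass.pipeline import demo_config, make_demo, run_all


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """Default synthetic study bundle (seed 42, 10 loci/class, 6 classes)."""
    out = tmp_path_factory.mktemp("demo") / "bundle"
    paths, manifest = make_demo(seed=42, outdir=str(out))
    return paths, manifest


@pytest.fixture(scope="session")
def demo_run(demo_bundle, tmp_path_factory):
    """Full pipeline result on the default bundle."""
    paths, manifest = demo_bundle
    out = tmp_path_factory.mktemp("run")
    res = run_all(demo_config(paths, str(out), seed=42))
    return res, manifest
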