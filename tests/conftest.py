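import numpy as np
import pytest

from wsimil import SynthSlideConfig, make_toy_slide, open_slide


@pytest.fixture(scope="session")
def toy_slide(tmp_path_factory):
    """One rendered toy slide (class B texture) + ROI + ground truth."""
    out = tmp_path_factory.mktemp("slide")
    cfg = SynthSlideConfig(seed=4, tumor_class="B")
    tiff, roi, truth = make_toy_slide(cfg, out)
    return {"config": cfg, "tiff": tiff, "roi": roi, "truth": truth,
            "slide": open_slide(tiff)}


@pytest.fixture(scope="session")
def toy_qc(toy_slide):
    """QC table for the toy slide (computed once; several tests share it)."""
    from wsimil.pipeline import qc_slide, qc_table
    qc = qc_slide(toy_slide["slide"])
    return {"qc": qc, "table": qc_table(qc)}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_params():
    """Small random model (d=6, C=2) for forward-pass property tests."""
    from wsimil.model import init_params
    return init_params(6, 2, hidden_trunk=8, hidden_gate=5,
                       rng=np.random.default_rng(0))
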