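import numpy as np
import pandas as pd
import pytest

from pathprofiler import synthetic
from pathprofiler.pmf import SearchConfig


@pytest.fixture(scope="session")
def toy_db():
    """Three hand-made proteins; P1 shares two tryptic peptides (all
    with [M+H]+ inside 800-3000) with P2 and uniquely owns a third."""
    pep1 = "ELVISLIVESK"        # ~1229.7
    pep2 = "GENTLYWINGSR"       # ~1409.7
    pep3 = "DAVIDWASHAPPYK"     # ~1569.7, unique to P1
    return {
        "P1": pep1 + pep2 + pep3,
        "P2": pep1 + pep2,
        "P3": "WHISPERINGWINDMILLSYK",
    }


@pytest.fixture(scope="session")
def small_db():
    return synthetic.make_protein_db(20, (80, 200), seed=1)


@pytest.fixture(scope="session")
def config():
    return SearchConfig()


@pytest.fixture(scope="session")
def balanced_truth(small_db):
    """Planted truth with folds in both directions so that gel-total
    normalization preserves the planted ratios exactly."""
    return synthetic.make_truth(sorted(small_db), n_de=4, fold=2.0, seed=1)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    from pathprofiler.pipeline import demo
    outdir = tmp_path_factory.mktemp("demo")
    report = demo(outdir, seed=0)
    return outdir, report
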