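import numpy as np
import pytest

import tendos as td


@pytest.fixture(scope="session")
def clean_synth():
    """120 s clean synthetic ECG at 60 bpm with ground-truth fiducials."""
    rec, r_idx, tend_idx = td.gen_synth_ecg(td.SynthEcgSpec(duration_s=120.0, seed=11))
    return rec, r_idx, tend_idx


@pytest.fixture(scope="session")
def prepared(clean_synth):
    """Preprocessed clean record with its (known) R-peak series and truth."""
    rec, r_idx, tend_idx = clean_synth
    prep = td.preprocess(rec)
    rp = td.load_rpeaks(td.AnnotationSeries("rpeak", r_idx, rec.fs, "truth"), prep)
    truth = td.TendAnnotation(tend_idx, "truth", rec.fs, r_idx)
    return prep, rp, truth


@pytest.fixture(scope="session")
def library(prepared):
    prep, rp, _ = prepared
    return td.build_library(prep, rp)
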