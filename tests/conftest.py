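import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from calnc.simulate import SimulationConfig, simulate_all
from calnc.types import ExpressionMatrix, TranscriptRecord, full_design

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_record(tid="t1", chrom="Chr1", exons=((1, 100),), strand="+",
                class_code="u", **kw):
    exons = [tuple(e) for e in exons]
    return TranscriptRecord(
        transcript_id=tid,
        locus_id=kw.pop("locus_id", f"loc_{tid}"),
        chrom=chrom,
        start=min(a for a, _ in exons),
        end=max(b for _, b in exons),
        strand=strand,
        exons=exons,
        class_code=class_code,
        **kw,
    )


def make_matrix(rows: dict) -> ExpressionMatrix:
    """ExpressionMatrix over the full 54-sample design from per-transcript
    value vectors (length 54) or scalars."""
    samples = full_design(3)
    cols = [s.sample_id for s in samples]
    data = {}
    for tid, v in rows.items():
        v = np.asarray(v, dtype=float)
        data[tid] = np.full(54, float(v)) if v.ndim == 0 else v
    return ExpressionMatrix(pd.DataFrame(data, index=cols).T, samples)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        seed=7,
        n_pcg=120,
        n_known_lnc=12,
        n_known_lnc_low=3,
        n_novel_lnc={"j": 10, "u": 4, "o": 3, "x": 3, "i": 2},
        n_coding_decoys=4,
        n_short_decoys=3,
        n_homology_decoys=3,
        n_low_expression_decoys=3,
        calcium_scheme={"none": 8, "cyt_only": 6, "nuc_only": 6, "both": 6},
        n_cis_pairs=4,
        module_sizes=(35, 30),
    )


@pytest.fixture(scope="session")
def bundle(small_config):
    """Default-noise synthetic world (desk scale)."""
    return simulate_all(small_config)


@pytest.fixture(scope="session")
def noiseless_bundle(small_config):
    import dataclasses

    cfg = dataclasses.replace(small_config, noise_sd=0.0, seed=5)
    return simulate_all(cfg)
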