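import pandas as pd
import pytest

from csmfinder.pipeline import PipelineConfig, run_pipeline
from csmfinder.simulate import MethylomeSpec, make_synthetic_methylome


@pytest.fixture(scope="session")
def planted_methylome(tmp_path_factory):
    """Full-size synthetic methylome with planted CSM/ASM/AM/null loci."""
    outdir = tmp_path_factory.mktemp("methylome")
    return make_synthetic_methylome(outdir, MethylomeSpec(), seed=7)


@pytest.fixture(scope="session")
def planted_pipeline_result(planted_methylome):
    """Pipeline run over the planted methylome (shared across tests)."""
    return run_pipeline(
        planted_methylome["reads"],
        PipelineConfig(seed=1),
        hairpin_path=planted_methylome["hairpin"],
        asm_bed=planted_methylome["truth_asm"],
    )


@pytest.fixture(scope="session")
def small_methylome(tmp_path_factory):
    """Reduced methylome for fast pipeline/CLI behaviour tests."""
    outdir = tmp_path_factory.mktemp("small_methylome")
    spec = MethylomeSpec(n_csm=6, n_asm=3, n_am=3, n_null=20, reads_per_locus=10)
    return make_synthetic_methylome(outdir, spec, seed=11)


def called_intervals(calls: pd.DataFrame) -> pd.DataFrame:
    """region_id strings -> chrom/start/end frame for overlap checks."""
    called = calls[calls["is_csm"]]
    parts = called["region_id"].str.extract(r"(\w+):(\d+)-(\d+)")
    return pd.DataFrame(
        {
            "chrom": parts[0],
            "start": parts[1].astype(int),
            "end": parts[2].astype(int),
        }
    )


def overlap_counts(called: pd.DataFrame, truth: pd.DataFrame) -> tuple[int, int]:
    """(#called overlapping truth, #truth overlapped by a call)."""
    hits_called = 0
    for r in called.itertuples():
        if (
            (truth["chrom"] == r.chrom)
            & (truth["start"] < r.end)
            & (r.start < truth["end"])
        ).any():
            hits_called += 1
    hits_truth = 0
    for t in truth.itertuples():
        if (
            (called["chrom"] == t.chrom)
            & (called["start"] < t.end)
            & (t.start < called["end"])
        ).any():
            hits_truth += 1
    return hits_called, hits_truth
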