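import pytest

import phagesv


@pytest.fixture(scope="session")
def cohort():
    """The default synthetic cohort at a fixed seed, shared read-only."""
    return phagesv.generate_cohort(seed=1)


@pytest.fixture(scope="session")
def pipeline_summary(cohort, tmp_path_factory):
    """Full pipeline run on the default cohort, with outputs on disk."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    summary = phagesv.run_pipeline(cohort, outdir=outdir)
    summary["_outdir"] = outdir
    return summary
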