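"""Shared fixtures: session-scoped synthetic-panel pipeline runs.

Two panels are simulated once per session and shared by all tests that
verify pipeline-level properties against truth:

* ``study_run`` — boundary homeolog divergence (0.02): an ~87-bp prepared
  read at similarity 0.98 tolerates one mismatch, so cross-subgenome
  mapping is partial, the regime in which homeo-SNP artifacts arise.
* ``homeo_run`` — divergence well below the threshold (0.002): nearly all
  homeologous reads cross-map, the regime that stresses the homeo-SNP
  mask hardest.

Both use error-free 20x reads so caller and genotyping properties are not
confounded by sequencing error, 6 intraspecific lines (line 1 the
reference genotype), one moderately diverged tetraploid, and one strongly
diverged diploid.
"""

from __future__ import annotations

import pytest

from bessnp.pipeline import PipelineConfig, run_pipeline
from bessnp.simdata import SimConfig

PANEL = dict(
    seed=11,
    ancestral_length=20_000,
    n_fragments=32,
    fragment_length_range=(300, 600),
    coverage=20.0,
    base_error_rate=0.0,
    line_snp_rate=0.002,
    n_lines=6,
)


@pytest.fixture(scope="session")
def study_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    return run_pipeline(PipelineConfig(outdir=out, sim=SimConfig(**PANEL)))


@pytest.fixture(scope="session")
def homeo_run(tmp_path_factory):
    out = tmp_path_factory.mktemp("homeo")
    return run_pipeline(
        PipelineConfig(
            outdir=out, sim=SimConfig(**PANEL, homeolog_divergence=0.002)
        )
    )
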