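"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import pytest

from intronmap import RunConfig, run_pipeline
from intronmap.similarity import ScoringScheme
from intronmap.synthetic import SimConfig, survey_scale_config, simulate_dataset, small_config


def bruteforce_local_score(a: str, b: str, s: ScoringScheme) -> int:
    """Exhaustive local-alignment maximization by memoized recursion over moves.

    Independent of the DP kernel: explores every gapped alignment extension
    from every start cell, charging gap_open on the first gapped position of
    a run and gap_extend afterwards, with the option to stop anywhere.
    """
    n, m = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, state: str) -> int:
        best = 0  # stop the alignment here
        if i < n and j < m:
            sub = s.match if (a[i] == b[j] and a[i] != "N") else s.mismatch
            best = max(best, sub + ext(i + 1, j + 1, "M"))
        if j < m:
            cost = s.gap_extend if state == "E" else s.gap_open
            best = max(best, cost + ext(i, j + 1, "E"))
        if i < n:
            cost = s.gap_extend if state == "F" else s.gap_open
            best = max(best, cost + ext(i + 1, j, "F"))
        return best

    best = 0
    for i in range(n):
        for j in range(m):
            best = max(best, ext(i, j, "M"))
    return best


@pytest.fixture(scope="session")
def small_truth(tmp_path_factory):
    """A miniature simulated dataset with its written files."""
    outdir = tmp_path_factory.mktemp("sim_small")
    truth, paths = simulate_dataset(small_config(seed=3), outdir)
    return truth, paths


@pytest.fixture(scope="session")
def survey_run(tmp_path_factory):
    """One full pipeline run at the default (survey-shaped) scale, seed 1."""
    outdir = tmp_path_factory.mktemp("run_survey")
    cfg = RunConfig(outdir=outdir, simulate=survey_scale_config(seed=1), seed=1)
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def mid_sim_config():
    """A reduced 4-clade configuration for fast full-pipeline checks."""
    return SimConfig(species_per_clade=2, paralogs_per_species_family=(1, 2),
                     seed=11)
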