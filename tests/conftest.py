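"""Shared fixtures: a toy hand-checkable genome and one full synthetic study.

The session-scoped study (seed 7, desk-scale preset) is reused by the
annotation, target and dynamics tests; its peak sets are called once with the
replicate-calibrated threshold.
"""

from __future__ import annotations

import numpy as np
import pytest

import damidkit as dk


@pytest.fixture
def toy_genome() -> dict[str, str]:
    # chr_toy: GATC at 2 and 8 -> fragments [0,2) [2,8) [8,14)
    return {"chr_toy": "AAGATCTTGATCAA", "chr_plain": "ACGTACGTACGT"}


@pytest.fixture
def toy_fmap(toy_genome):
    with pytest.warns(UserWarning):
        return dk.build_fragment_map(toy_genome)


@pytest.fixture(scope="session")
def study() -> dk.SimulatedStudy:
    return dk.simulate_study(dk.SimConfig(seed=7))


def build_tracks(study, factor, genotype):
    chans = study.counts[(factor, genotype)]
    sig = dk.build_signal_track(
        [chans[("dam_fusion", 1)], chans[("dam_fusion", 2)]],
        [chans[("dam_alone", 1)], chans[("dam_alone", 2)]],
        factor=factor,
        genotype=genotype,
    )
    noise = dk.noise_track(chans[("dam_fusion", 1)], chans[("dam_fusion", 2)])
    return sig, noise


@pytest.fixture(scope="session")
def study_peaks(study) -> dict:
    """FDR-calibrated peak sets for every profiled factor/genotype."""
    import warnings

    out = {}
    for factor, genotype in study.counts:
        sig, noise = build_tracks(study, factor, genotype)
        with warnings.catch_warnings():
            # the desk-scale comr track sits marginally above FDR 0.05 on
            # the default grid; the tightest-threshold fallback is intended
            warnings.simplefilter("ignore", UserWarning)
            curve = dk.calibrate_fdr(sig, noise, study.fmap)
        out[(factor, genotype)] = dk.call_peaks(
            sig, study.fmap, t_star=curve.t_star
        )
    return out


@pytest.fixture(scope="session")
def study_index(study):
    lengths = {c: len(s) for c, s in study.genome.items()}
    return dk.GeneIndex(study.genes, lengths)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260923)
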