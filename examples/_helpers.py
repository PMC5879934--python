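"""Shared plumbing for the example scripts."""

import warnings

import damidkit as dk


def study_with_peaks(seed: int, factor: str, genotype: str = "wt"):
    study = dk.simulate_study(dk.SimConfig(seed=seed))
    return study, peaks_for(study, factor, genotype)


def peaks_for(study, factor: str, genotype: str = "wt"):
    chans = study.counts[(factor, genotype)]
    signal = dk.build_signal_track(
        [chans[("dam_fusion", 1)], chans[("dam_fusion", 2)]],
        [chans[("dam_alone", 1)], chans[("dam_alone", 2)]],
        factor=factor, genotype=genotype,
    )
    noise = dk.noise_track(chans[("dam_fusion", 1)],
                           chans[("dam_fusion", 2)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        curve = dk.calibrate_fdr(signal, noise, study.fmap)
    return dk.call_peaks(signal, study.fmap, t_star=curve.t_star)
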