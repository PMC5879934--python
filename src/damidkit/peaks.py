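"""FDR-calibrated peak calling on GATC-fragment signal tracks.

Peak calling uses three compound criteria at the fragment level: positive
enrichment sign, Fisher P below a significance threshold, and
log2(Dam-X/Dam) > 1.  The significance threshold is not fixed a priori:
an empirical false-discovery rate is estimated by running the identical
peak-calling procedure on a *noise track* built by comparing two biological
replicates of the same library against each other.  At a candidate threshold
t, FDR(t) = peaks called on the noise track / peaks called on the signal
track, and the loosest threshold with FDR <= 0.05 is adopted.  Defaults:
P < 1e-3 as the loosest admissible threshold and log2 ratio > 1.

Peaks are maximal runs of adjacent eligible fragments (no gap tolerance:
the fragment is the resolution unit); the summit is the fragment with the
largest -log10 P, leftmost on ties.  Depleted regions are called
symmetrically with sign -1 and log2 ratio < -1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fragments import FragmentCounts, FragmentMap
from .signal import SignalTrack, build_signal_track

DEFAULT_FDR_CUTOFF = 0.05
DEFAULT_P_CUTOFF = 1e-3
DEFAULT_RATIO_CUTOFF = 1.0


def default_threshold_grid(
    loosest: float = DEFAULT_P_CUTOFF, tightest: float = 1e-12, n: int = 50
) -> np.ndarray:
    """Decreasing grid of candidate P-value cutoffs (log-spaced)."""
    return np.logspace(np.log10(loosest), np.log10(tightest), n)


@dataclass
class PeakSet:
    """Called peaks for one factor/genotype plus the calling parameters.

    ``peaks`` columns: chrom, start, end, first_fragment, last_fragment,
    summit_fragment, summit_pos (summit-fragment midpoint, the position used
    for all distance computations), max_neglog10_p, max_log2_ratio.
    """

    factor: str
    genotype: str
    peaks: pd.DataFrame
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def summits(self) -> pd.DataFrame:
        return self.peaks[["chrom", "summit_pos"]]

    def to_bed(self, path: str | Path) -> None:
        """BED6+ output: name, score = max -log10 P, strand '.', extra ratio."""
        with open(path, "w") as fh:
            for key, val in sorted(self.params.items()):
                fh.write(f"# {key}={val}\n")
            for i, row in self.peaks.reset_index(drop=True).iterrows():
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t"
                    f"{self.factor}_{self.genotype}_peak{i}\t"
                    f"{row.max_neglog10_p:.6g}\t.\t{row.max_log2_ratio:.6g}\t"
                    f"{row.summit_pos}\n"
                )

    @classmethod
    def from_bed(cls, path: str | Path,
                 factor: str = "damX", genotype: str = "custom") -> "PeakSet":
        params = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line.lstrip("# ").rstrip("\n").partition("=")
                    params[key] = val
                    continue
                f = line.rstrip("\n").split("\t")
                rows.append(
                    {
                        "chrom": f[0], "start": int(f[1]), "end": int(f[2]),
                        "max_neglog10_p": float(f[4]),
                        "max_log2_ratio": float(f[6]) if len(f) > 6 else np.nan,
                        "summit_pos": int(f[7]) if len(f) > 7
                        else (int(f[1]) + int(f[2])) // 2,
                    }
                )
        cols = ["chrom", "start", "end", "summit_pos",
                "max_neglog10_p", "max_log2_ratio"]
        df = pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)
        return cls(factor=factor, genotype=genotype, peaks=df, params=params)


def _merge_eligible(
    eligible: np.ndarray, fmap: FragmentMap, signal: SignalTrack
) -> pd.DataFrame:
    """Merge runs of adjacent eligible fragments (within chromosomes)."""
    records = []
    for chrom in fmap.chroms:
        off = fmap.chrom_offset(chrom)
        n = fmap.n_fragments_chrom(chrom)
        b = fmap.boundaries[chrom]
        mask = eligible[off : off + n]
        if not mask.any():
            continue
        # run boundaries within this chromosome
        d = np.diff(np.concatenate([[0], mask.view(np.int8), [0]]))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for s, e in zip(starts, ends):
            frag_ids = np.arange(s, e) + off
            stats = signal.neglog10_p[frag_ids]
            summit_local = int(np.argmax(stats))  # argmax is leftmost on ties
            summit = int(frag_ids[summit_local])
            records.append(
                {
                    "chrom": chrom,
                    "start": int(b[s]),
                    "end": int(b[e]),
                    "first_fragment": int(frag_ids[0]),
                    "last_fragment": int(frag_ids[-1]),
                    "summit_fragment": summit,
                    "summit_pos": int((b[s + summit_local]
                                       + b[s + summit_local + 1]) // 2),
                    "max_neglog10_p": float(stats[summit_local]),
                    "max_log2_ratio": float(
                        np.max(signal.log2_ratio[frag_ids])
                    ),
                }
            )
    cols = ["chrom", "start", "end", "first_fragment", "last_fragment",
            "summit_fragment", "summit_pos", "max_neglog10_p",
            "max_log2_ratio"]
    return pd.DataFrame(records, columns=cols)


def call_peaks(
    signal: SignalTrack,
    fmap: FragmentMap,
    t_star: float | None = None,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
) -> PeakSet:
    """Call enriched peaks with the compound criteria.

    A fragment is eligible iff sign = +1, P <= min(t_star, p_cutoff) and
    log2 ratio > ratio_cutoff; adjacent eligible fragments merge into one
    peak.  ``t_star`` is typically the replicate-calibrated FDR threshold
    (see :func:`calibrate_fdr`); when None only ``p_cutoff`` applies.
    """
    effective = p_cutoff if t_star is None else min(t_star, p_cutoff)
    neglog_cut = -np.log10(effective)
    eligible = (
        (signal.sign == 1)
        & (signal.neglog10_p >= neglog_cut)
        & (signal.log2_ratio > ratio_cutoff)
    )
    peaks = _merge_eligible(eligible, fmap, signal)
    return PeakSet(
        factor=signal.factor,
        genotype=signal.genotype,
        peaks=peaks,
        params={
            "p_cutoff": effective,
            "ratio_cutoff": ratio_cutoff,
            "direction": "enriched",
        },
    )


def depleted_regions(
    signal: SignalTrack,
    fmap: FragmentMap,
    t_star: float | None = None,
    p_cutoff: float = DEFAULT_P_CUTOFF,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
) -> PeakSet:
    """Mirror of :func:`call_peaks`: sign -1 and log2 ratio < -ratio_cutoff."""
    effective = p_cutoff if t_star is None else min(t_star, p_cutoff)
    neglog_cut = -np.log10(effective)
    eligible = (
        (signal.sign == -1)
        & (signal.neglog10_p >= neglog_cut)
        & (signal.log2_ratio < -ratio_cutoff)
    )
    peaks = _merge_eligible(eligible, fmap, signal)
    return PeakSet(
        factor=signal.factor,
        genotype=signal.genotype,
        peaks=peaks,
        params={
            "p_cutoff": effective,
            "ratio_cutoff": ratio_cutoff,
            "direction": "depleted",
        },
    )


def noise_track(
    rep1: FragmentCounts,
    rep2: FragmentCounts,
    pseudocount: float = 0.5,
) -> SignalTrack:
    """Replicate-vs-replicate Fisher track: the empirical noise floor.

    Treats rep1 as "treatment" and rep2 as "control"; with two well-behaved
    biological replicates every significant call on this track is a false
    discovery by construction, which is what calibrates the FDR.
    """
    if rep1.construct != rep2.construct or rep1.genotype != rep2.genotype:
        raise ValueError("noise track requires replicates of the same library")
    if rep1.replicate == rep2.replicate and rep1.sample_id == rep2.sample_id:
        raise ValueError("noise track requires two distinct replicates")
    return build_signal_track(
        [rep1], [rep2],
        factor=f"noise_{rep1.sample_id}",
        genotype=rep1.genotype,
        pseudocount=pseudocount,
    )


@dataclass
class FdrCurve:
    """Replicate-noise FDR as a function of the P-value threshold."""

    thresholds: np.ndarray  # decreasing P-value cutoffs
    n_signal: np.ndarray
    n_noise: np.ndarray
    fdr: np.ndarray  # n_noise / max(n_signal, 1)
    t_star: float
    fdr_cutoff: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "p_threshold": self.thresholds,
                "n_signal_peaks": self.n_signal,
                "n_noise_peaks": self.n_noise,
                "fdr": self.fdr,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# t_star={self.t_star:.8g}\tfdr_cutoff={self.fdr_cutoff}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False,
                                   float_format="%.8g")


def calibrate_fdr(
    signal: SignalTrack,
    noise: SignalTrack,
    fmap: FragmentMap,
    grid: np.ndarray | None = None,
    fdr_cutoff: float = DEFAULT_FDR_CUTOFF,
    ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
) -> FdrCurve:
    """Sweep P thresholds, counting merged peaks on signal and noise tracks.

    Both tracks are subjected to the identical compound peak criteria at each
    threshold; FDR(t) = noise peaks / max(signal peaks, 1).  Returns the curve
    and the loosest threshold t* with FDR <= ``fdr_cutoff`` (the tightest grid
    point, with a warning, if no threshold qualifies).
    """
    if grid is None:
        grid = default_threshold_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("threshold grid is empty")
    grid = np.sort(grid)[::-1]
    if signal.n_fragments != noise.n_fragments:
        raise ValueError("signal and noise tracks are on different maps")

    n_signal = np.empty(grid.size, dtype=np.int64)
    n_noise = np.empty(grid.size, dtype=np.int64)
    for i, t in enumerate(grid):
        n_signal[i] = len(call_peaks(signal, fmap, p_cutoff=t,
                                     ratio_cutoff=ratio_cutoff))
        n_noise[i] = len(call_peaks(noise, fmap, p_cutoff=t,
                                    ratio_cutoff=ratio_cutoff))
    fdr = n_noise / np.maximum(n_signal, 1)

    passing = np.flatnonzero(fdr <= fdr_cutoff)
    if passing.size:
        t_star = float(grid[passing[0]])  # loosest passing threshold
    else:
        t_star = float(grid[-1])
        warnings.warn(
            f"no threshold on the grid reaches FDR <= {fdr_cutoff}; "
            "falling back to the tightest grid point",
            stacklevel=2,
        )
    return FdrCurve(
        thresholds=grid,
        n_signal=n_signal,
        n_noise=n_noise,
        fdr=fdr,
        t_star=t_star,
        fdr_cutoff=fdr_cutoff,
    )
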