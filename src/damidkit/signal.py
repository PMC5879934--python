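"""Fragment-level DamID signal: signed -log10 Fisher P and normalised ratios.

The core DamID statistic compares, for each GATC fragment, the read count in
the Dam-fusion library against the Dam-alone control with a two-sided Fisher
exact test on the 2x2 table

    [ count_x ,  total_x  - count_x  ]
    [ count_dam, total_dam - count_dam ]

The signal is presented as -log10(P) with a separate sign: +1 where the
fusion channel is proportionally enriched over the control, -1 where it is
depleted, 0 where the rates are identical.  A depth-normalised log2 ratio
(fusion rate over control rate, with a pseudocount) accompanies the P-values
and is used as an effect-size filter during peak calling.

The Fisher computation is vectorised over fragments: conditional on the
margins, the first cell follows a hypergeometric distribution whose support is
at most count_x + count_dam + 1 wide, so the two-sided P (sum of outcome
probabilities not exceeding the observed table's) is an explicit sum over a
short support, evaluated for all fragments in one pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .fragments import FragmentCounts, FragmentMap

# Relative tolerance when comparing outcome probabilities to the observed
# table's probability; matches the convention used by standard two-sided
# Fisher implementations to absorb floating-point ties.
_TIE_RTOL = 1e-7

DEFAULT_PSEUDOCOUNT = 0.5
DEFAULT_CEILING = 300.0


def fisher_two_sided(
    count_x: np.ndarray,
    total_x: np.ndarray,
    count_dam: np.ndarray,
    total_dam: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided Fisher exact test for many 2x2 tables.

    Parameters are broadcastable arrays of non-negative integers with
    ``count <= total`` per channel and positive totals.  Returns
    ``(p_value, sign)`` where sign compares the per-channel rates.
    """
    cx, tx, cd, td = np.broadcast_arrays(
        np.asarray(count_x, dtype=np.int64),
        np.asarray(total_x, dtype=np.int64),
        np.asarray(count_dam, dtype=np.int64),
        np.asarray(total_dam, dtype=np.int64),
    )
    shape = cx.shape
    cx, tx, cd, td = (a.ravel() for a in (cx, tx, cd, td))
    if (tx <= 0).any() or (td <= 0).any():
        raise ValueError("channel totals must be positive")
    if (cx < 0).any() or (cd < 0).any() or (cx > tx).any() or (cd > td).any():
        raise ValueError("counts must satisfy 0 <= count <= total")

    N = tx + td
    K = cx + cd  # column margin of the tested cell
    n = tx
    lo = np.maximum(0, K - td)
    hi = np.minimum(K, tx)
    width = hi - lo + 1

    # Flatten the per-table supports into one array of candidate cell values.
    idx = np.repeat(np.arange(cx.size), width)
    group_starts = np.concatenate([[0], np.cumsum(width)[:-1]])
    k = lo[idx] + (np.arange(int(width.sum())) - np.repeat(group_starts, width))
    logpmf = hypergeom.logpmf(k, N[idx], K[idx], n[idx])
    log_obs = hypergeom.logpmf(cx, N, K, n)

    include = logpmf <= log_obs[idx] + np.log1p(_TIE_RTOL)
    contrib = np.where(include, np.exp(logpmf), 0.0)
    p = np.bincount(idx, weights=contrib, minlength=cx.size)
    p = np.clip(p, 0.0, 1.0)
    # Summation noise can leave a full-support sum marginally below 1.
    p[p > 1.0 - 1e-11] = 1.0

    sign = np.sign(cx * td - cd * tx).astype(np.int8)
    return p.reshape(shape), sign.reshape(shape)


def fisher_fragment_test(
    count_x: int, total_x: int, count_dam: int, total_dam: int
) -> tuple[float, int]:
    """Two-sided Fisher exact P and enrichment sign for a single fragment.

    Sign is +1 if the fusion-channel rate exceeds the control rate, -1 if it
    is lower, and 0 if the rates are exactly equal.
    """
    p, sign = fisher_two_sided(
        np.array([count_x]), np.array([total_x]),
        np.array([count_dam]), np.array([total_dam]),
    )
    return float(p[0]), int(sign[0])


@dataclass
class SignalTrack:
    """Per-fragment DamID signal for one factor in one genotype."""

    factor: str
    genotype: str
    neglog10_p: np.ndarray
    sign: np.ndarray
    log2_ratio: np.ndarray
    counts_x: np.ndarray
    counts_dam: np.ndarray
    total_x: int
    total_dam: int

    @property
    def n_fragments(self) -> int:
        return len(self.neglog10_p)

    @property
    def signed_neglog10_p(self) -> np.ndarray:
        return self.sign * self.neglog10_p

    def to_bedgraph(self, fmap: FragmentMap, path: str | Path) -> None:
        """Signed -log10 P as a bedGraph-style TSV (chrom, start, end, value)."""
        mids = fmap.fragment_midpoints()
        out = mids[["chrom", "start", "end"]].copy()
        out["signed_neglog10_p"] = self.signed_neglog10_p
        out.to_csv(path, sep="\t", index=False, header=False,
                   float_format="%.6g")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "neglog10_p": self.neglog10_p,
                "sign": self.sign,
                "log2_ratio": self.log2_ratio,
                "count_x": self.counts_x,
                "count_dam": self.counts_dam,
            }
        )
        df.index.name = "fragment_id"
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        with open(path, "w") as fh:
            fh.write(f"# factor={self.factor}\tgenotype={self.genotype}"
                     f"\ttotal_x={self.total_x}\ttotal_dam={self.total_dam}\n")
            df.to_csv(fh, sep="\t", float_format="%.8g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignalTrack":
        with open(path) as fh:
            header = fh.readline()
            meta = dict(
                item.split("=", 1) for item in header.lstrip("# ").split("\t")
            )
            df = pd.read_csv(fh, sep="\t", index_col="fragment_id")
        return cls(
            factor=meta["factor"].strip(),
            genotype=meta["genotype"].strip(),
            neglog10_p=df["neglog10_p"].to_numpy(),
            sign=df["sign"].to_numpy(np.int8),
            log2_ratio=df["log2_ratio"].to_numpy(),
            counts_x=df["count_x"].to_numpy(np.int64),
            counts_dam=df["count_dam"].to_numpy(np.int64),
            total_x=int(meta["total_x"]),
            total_dam=int(meta["total_dam"]),
        )


def _sum_replicates(reps: Sequence[FragmentCounts]) -> np.ndarray:
    if len(reps) == 0:
        raise ValueError("at least one replicate per channel is required")
    n = len(reps[0].counts)
    for r in reps:
        if len(r.counts) != n:
            raise ValueError("replicates are on different fragment maps")
    return np.sum([r.counts for r in reps], axis=0)


def build_signal_track(
    x_reps: Sequence[FragmentCounts],
    dam_reps: Sequence[FragmentCounts],
    factor: str = "damX",
    genotype: str = "custom",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    ceiling: float = DEFAULT_CEILING,
) -> SignalTrack:
    """Build the signed -log10 Fisher track from replicate count tables.

    Replicates are summed per channel before testing (replicate-to-replicate
    variation is instead exploited for FDR calibration during peak calling).
    The log2 ratio compares depth-normalised rates, with the pseudocount
    converted to a rate using the mean channel depth so that its sign always
    agrees with the raw rate comparison.  -log10 P is capped at ``ceiling``.
    """
    cx = _sum_replicates(x_reps)
    cd = _sum_replicates(dam_reps)
    if len(cx) != len(cd):
        raise ValueError("channels are on different fragment maps")
    tx = int(cx.sum())
    td = int(cd.sum())
    if tx == 0 or td == 0:
        raise ValueError("each channel needs at least one read")

    p, sign = fisher_two_sided(cx, tx, cd, td)
    with np.errstate(divide="ignore"):
        neglog = -np.log10(p)
    neglog = np.minimum(neglog, ceiling)
    neglog[p >= 1.0] = 0.0

    pseudorate = pseudocount / ((tx + td) / 2.0)
    log2_ratio = np.log2(
        (cx / tx + pseudorate) / (cd / td + pseudorate)
    )
    return SignalTrack(
        factor=factor,
        genotype=genotype,
        neglog10_p=neglog,
        sign=sign,
        log2_ratio=log2_ratio,
        counts_x=cx,
        counts_dam=cd,
        total_x=tx,
        total_dam=td,
    )
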