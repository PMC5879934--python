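"""Direct vs indirect target classification and co-binding statistics.

A transcript is a *direct* target of a factor when its expression drops at
least eightfold in the corresponding mutant AND the factor has an enrichment
peak within 1 kb of (any of) its TSSs; transcripts meeting the fold criterion
without a nearby peak are *indirect* targets; everything else is unaffected.
Fold changes are computed on FPKM with a pseudocount of 1 ("eightfold down"
means (FPKM_wt + 1) / (FPKM_mut + 1) >= 8), and by default a transcript must
also carry the differential-expression significance flag.

The module also provides the fourfold up/down TSS-distance comparison with a
chi-square test on the within-1-kb bin, co-binding enrichment between one
factor's target set and another factor's peaks, and the per-transcript signal
category coding (no binding / nonsignificant / medium / high) of the raw
DamID statistic around the TSS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import nearest_peak_distances, tss_distance_bins
from .fragments import FragmentMap
from .peaks import PeakSet
from .signal import SignalTrack

DEFAULT_FOLD_CUTOFF = 8.0
DEFAULT_DIST_CUTOFF = 1_000
DEFAULT_PSEUDOCOUNT = 1.0

SIGNAL_CATEGORIES = ("no_binding", "nonsignificant", "medium", "high")


def down_fold(expr: pd.DataFrame, mutant: str,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Down-regulation fold: (FPKM_wt + pc) / (FPKM_mutant + pc)."""
    return (expr["fpkm_wt"] + pseudocount) / (expr[f"fpkm_{mutant}"] + pseudocount)


def up_fold(expr: pd.DataFrame, mutant: str,
            pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    return (expr[f"fpkm_{mutant}"] + pseudocount) / (expr["fpkm_wt"] + pseudocount)


def _sig_mask(expr: pd.DataFrame, mutant: str, require_sig: bool) -> pd.Series:
    col = f"sig_{mutant}"
    if require_sig and col in expr.columns:
        return expr[col].astype(bool)
    return pd.Series(True, index=expr.index)


def _transcript_peak_distance(
    expr_index: pd.Index, tss: pd.DataFrame, peaks: PeakSet
) -> pd.Series:
    """Min distance from any of a transcript's TSSs to the nearest summit."""
    per_tss = nearest_peak_distances(tss, peaks, signed=False)
    per_tss = per_tss.groupby(level=0).min()
    return per_tss.reindex(expr_index)


def classify_targets(
    expr: pd.DataFrame,
    peaks: PeakSet,
    tss: pd.DataFrame,
    mutant: str,
    fold_cutoff: float = DEFAULT_FOLD_CUTOFF,
    dist_cutoff: int = DEFAULT_DIST_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    require_sig: bool = True,
) -> pd.DataFrame:
    """Label every transcript direct / indirect / unaffected for one factor.

    Transcripts present in the expression table but absent from the TSS
    annotation are skipped with a warning (their count is recorded in the
    returned frame's ``attrs['n_unmatched']``).  A transcript is peak-proximal
    if *any* of its annotated TSSs lies within ``dist_cutoff`` of a summit.
    Up-regulated transcripts are never direct targets: the definition is
    down-regulation only.
    """
    matched = expr.index.intersection(tss["transcript_id"])
    n_unmatched = len(expr.index) - len(matched)
    if n_unmatched:
        warnings.warn(
            f"{n_unmatched} transcripts in the expression table have no "
            "TSS annotation and were skipped",
            stacklevel=2,
        )
    e = expr.loc[matched]
    dist = _transcript_peak_distance(
        e.index, tss[tss["transcript_id"].isin(matched)], peaks
    )
    dfold = down_fold(e, mutant, pseudocount)
    ufold = up_fold(e, mutant, pseudocount)
    sig = _sig_mask(e, mutant, require_sig)

    is_down = (dfold >= fold_cutoff) & sig
    near = dist <= dist_cutoff

    label = pd.Series("unaffected", index=e.index, name="label")
    label[is_down & near.fillna(False)] = "direct"
    label[is_down & ~near.fillna(False)] = "indirect"

    fc_class = pd.Series("none", index=e.index, name="fold_change_class")
    fc_class[(ufold >= 4) & sig] = "up4"
    fc_class[(dfold >= 4) & sig] = "down4"
    fc_class[(dfold >= 8) & sig] = "down8"

    out = pd.DataFrame(
        {
            "nearest_peak_distance": dist,
            "down_fold": dfold,
            "up_fold": ufold,
            "label": label,
            "fold_change_class": fc_class,
        }
    )
    out.attrs["n_unmatched"] = n_unmatched
    out.attrs["mutant"] = mutant
    return out


@dataclass
class FoldChangeDistanceResult:
    down_hist: pd.DataFrame
    up_hist: pd.DataFrame | None
    down_within: int
    down_total: int
    up_within: int
    up_total: int
    chi2_p: float | None
    test: str | None


def fold_change_distance_analysis(
    expr: pd.DataFrame,
    peaks: PeakSet,
    tss: pd.DataFrame,
    mutant: str,
    fold: float = 4.0,
    window: int = 10_000,
    bin_size: int = 1_000,
    dist_cutoff: int = DEFAULT_DIST_CUTOFF,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    require_sig: bool = True,
) -> FoldChangeDistanceResult:
    """Compare peak-to-TSS distances for up- vs down-regulated transcripts.

    Builds the binned nearest-peak histogram for transcripts >= ``fold``
    down and >= ``fold`` up in the mutant, and tests the 2x2 table of
    (direction) x (peak within ``dist_cutoff``) with a chi-square (Fisher
    exact when any expected cell < 5).  With one direction empty, the report
    is one-sided and no test is run.
    """
    sig = _sig_mask(expr, mutant, require_sig)
    dn_ids = expr.index[(down_fold(expr, mutant, pseudocount) >= fold) & sig]
    up_ids = expr.index[(up_fold(expr, mutant, pseudocount) >= fold) & sig]

    def side(ids) -> tuple[pd.DataFrame | None, int, int]:
        sub = tss[tss["transcript_id"].isin(ids)]
        if len(sub) == 0:
            return None, 0, 0
        dist = _transcript_peak_distance(pd.Index(ids), sub, peaks)
        _, hist = tss_distance_bins(sub, peaks, window=window,
                                    bin_size=bin_size)
        within = int((dist <= dist_cutoff).sum())
        return hist, within, int(dist.notna().count())

    down_hist, down_within, down_total = side(dn_ids)
    up_hist, up_within, up_total = side(up_ids)

    chi2_p = None
    test = None
    if down_total > 0 and up_total > 0:
        table = np.array(
            [[down_within, down_total - down_within],
             [up_within, up_total - up_within]]
        )
        chi2_p, test = _chi2_or_exact(table)
    return FoldChangeDistanceResult(
        down_hist=down_hist if down_hist is not None else pd.DataFrame(),
        up_hist=up_hist,
        down_within=down_within,
        down_total=down_total,
        up_within=up_within,
        up_total=up_total,
        chi2_p=chi2_p,
        test=test,
    )


def _chi2_or_exact(table: np.ndarray) -> tuple[float, str]:
    """Chi-square without Yates correction; Fisher exact if any expected < 5."""
    if table.sum() == 0:
        return 1.0, "none"
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).any():
        return float(stats.fisher_exact(table)[1]), "fisher_exact"
    chi2 = stats.chi2_contingency(table, correction=False)
    return float(chi2.pvalue), "chi2"


@dataclass
class CobindingResult:
    n_targets: int
    n_bound: int
    observed_pct: float
    expected_pct: float
    fold: float
    p_value: float
    test: str


def cobinding_enrichment(
    target_ids: Sequence[str],
    peaks_b: PeakSet,
    tss: pd.DataFrame,
    universe: Sequence[str] | None = None,
    dist_cutoff: int = DEFAULT_DIST_CUTOFF,
) -> CobindingResult:
    """How often factor B binds near the TSSs of factor A's targets.

    Observed % = fraction of target transcripts with a B summit within
    ``dist_cutoff`` of a TSS; expected % = the same fraction over the
    universe (all annotated transcripts by default); fold = observed /
    expected, with a chi-square on the 2x2 (in target set) x (B-bound).
    Empty target set gives NaN fold.
    """
    if universe is None:
        universe = tss["transcript_id"].unique()
    universe = pd.Index(pd.unique(pd.Series(universe)))
    target_ids = pd.Index(pd.unique(pd.Series(list(target_ids))))
    if not target_ids.isin(universe).all():
        raise ValueError("target set must be contained in the universe")
    if len(universe) < len(target_ids):
        raise ValueError("universe smaller than the target set")

    sub = tss[tss["transcript_id"].isin(universe)]
    dist = _transcript_peak_distance(universe, sub, peaks_b)
    bound = dist <= dist_cutoff

    n_t = len(target_ids)
    if n_t == 0:
        return CobindingResult(0, 0, np.nan, float(bound.mean()) * 100,
                               np.nan, np.nan, "none")
    n_bound = int(bound.loc[target_ids].sum())
    obs_pct = 100.0 * n_bound / n_t
    exp_pct = 100.0 * float(bound.mean())
    rest = universe.difference(target_ids)
    table = np.array(
        [[n_bound, n_t - n_bound],
         [int(bound.loc[rest].sum()), len(rest) - int(bound.loc[rest].sum())]]
    )
    p, test = _chi2_or_exact(table)
    fold = obs_pct / exp_pct if exp_pct > 0 else np.nan
    return CobindingResult(
        n_targets=n_t, n_bound=n_bound, observed_pct=obs_pct,
        expected_pct=exp_pct, fold=fold, p_value=p, test=test,
    )


def signal_category_at_tss(
    signal: SignalTrack,
    fmap: FragmentMap,
    tss: pd.DataFrame,
    window: int = 1_000,
    boundaries: tuple[float, float] = (1.0, 3.0),
) -> pd.Series:
    """Code the DamID statistic around each TSS into four categories.

    Looks at the maximum signed -log10 P over fragments overlapping
    [TSS - window, TSS + window] per transcript: ``no_binding`` when the best
    fragment is depleted (sign <= 0, i.e. fusion/control ratio < 1),
    ``nonsignificant`` for -log10 P in (0, lower], ``medium`` in
    (lower, upper], ``high`` above upper.  The upper boundary is typically
    the -log10 of the FDR-calibrated threshold (default 3).
    """
    lower, upper = boundaries
    if not lower < upper:
        raise ValueError("category boundaries must be strictly increasing")
    out = {}
    for _, row in tss.iterrows():
        frags = fmap.fragments_in_window(
            row.chrom, row.tss - window, row.tss + window + 1
        )
        if len(frags) == 0:
            out[row.transcript_id] = "no_binding"
            continue
        signed = signal.signed_neglog10_p[frags]
        best = float(signed.max())
        if best <= 0:
            cat = "no_binding"
        elif best <= lower:
            cat = "nonsignificant"
        elif best <= upper:
            cat = "medium"
        else:
            cat = "high"
        prev = out.get(row.transcript_id)
        if prev is None or SIGNAL_CATEGORIES.index(cat) > SIGNAL_CATEGORIES.index(prev):
            out[row.transcript_id] = cat
    return pd.Series(out, name="signal_category")
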