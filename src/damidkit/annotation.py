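"""Relating peaks to gene models.

Covers the annotation layer of the pipeline: classifying peak summits into
gene-feature categories (promoter, 5'UTR, CDS, intron, 3'UTR, intergenic)
with a binomial enrichment test against genome coverage, nearest-peak TSS
distance binning, averaged peak profiles around TSSs, intergenic peak
selection, pairwise colocalization curves against a random-GATC baseline and
exact Euler-style peak-set intersections.

The promoter is defined as the 400 bp immediately upstream of the TSS,
strand-aware.  All distances are measured from the peak summit (the midpoint
of the summit fragment); windows are exact: a summit at 400 bp upstream is
still in the promoter, at 401 bp it is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fragments import FragmentMap
from .peaks import PeakSet

PROMOTER_LENGTH = 400
CATEGORIES = ("promoter", "utr5", "cds", "intron", "utr3")
DEFAULT_PRECEDENCE = ("promoter", "utr5", "cds", "intron", "utr3")


@dataclass
class GeneModel:
    """One transcript: extent, strand, TSS and feature blocks.

    Blocks are lists of (start, end) half-open intervals.  Introns are the
    parts of the transcript extent not covered by any exon block.  The
    promoter is the 400 bp upstream of the TSS (strand-aware), truncated at
    chromosome edges.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    utr5: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def exons(self) -> list[tuple[int, int]]:
        return sorted(self.utr5 + self.cds + self.utr3)

    @property
    def introns(self) -> list[tuple[int, int]]:
        out = []
        prev = self.start
        for s, e in _merge_intervals(self.exons):
            if s > prev:
                out.append((prev, s))
            prev = max(prev, e)
        if prev < self.end:
            out.append((prev, self.end))
        return out

    def promoter(self, length: int = PROMOTER_LENGTH,
                 chrom_length: int | None = None) -> tuple[int, int]:
        if self.strand == "+":
            s, e = self.start - length, self.start
        else:
            s, e = self.end, self.end + length
        s = max(0, s)
        if chrom_length is not None:
            e = min(e, chrom_length)
        return (s, max(s, e))


def _merge_intervals(ivals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if e <= s:
            continue
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def tss_table(genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Per-transcript TSS table (transcript_id, gene_id, chrom, strand, tss).

    Alternative TSSs are represented simply as separate transcripts.
    """
    return pd.DataFrame(
        {
            "transcript_id": [g.transcript_id for g in genes],
            "gene_id": [g.gene_id for g in genes],
            "chrom": [g.chrom for g in genes],
            "strand": [g.strand for g in genes],
            "tss": [g.tss for g in genes],
        }
    )


class GeneIndex:
    """Merged per-category interval index over a set of gene models."""

    def __init__(self, genes: Sequence[GeneModel],
                 chrom_lengths: Mapping[str, int] | None = None,
                 promoter_length: int = PROMOTER_LENGTH):
        self.genes = list(genes)
        self.promoter_length = promoter_length
        self.chrom_lengths = dict(chrom_lengths or {})
        per_cat: dict[str, dict[str, list[tuple[int, int]]]] = {
            c: {} for c in CATEGORIES
        }
        self._extents: dict[str, list[tuple[int, int]]] = {}
        for g in self.genes:
            cl = self.chrom_lengths.get(g.chrom)
            per_cat["promoter"].setdefault(g.chrom, []).append(
                g.promoter(promoter_length, cl)
            )
            per_cat["utr5"].setdefault(g.chrom, []).extend(g.utr5)
            per_cat["cds"].setdefault(g.chrom, []).extend(g.cds)
            per_cat["utr3"].setdefault(g.chrom, []).extend(g.utr3)
            per_cat["intron"].setdefault(g.chrom, []).extend(g.introns)
            self._extents.setdefault(g.chrom, []).append((g.start, g.end))
        self._merged = {
            cat: {c: _to_arrays(_merge_intervals(iv))
                  for c, iv in by_chrom.items()}
            for cat, by_chrom in per_cat.items()
        }
        self._extents_merged = {
            c: _to_arrays(_merge_intervals(iv))
            for c, iv in self._extents.items()
        }

    def overlaps(self, category: str, chrom: str, pos: int) -> bool:
        arr = self._merged[category].get(chrom)
        return _point_in(arr, pos)

    def in_transcript(self, chrom: str, pos: int) -> bool:
        return _point_in(self._extents_merged.get(chrom), pos)

    def coverage_bp(self, category: str) -> int:
        """Base pairs assigned to ``category`` under the precedence order.

        Each base is attributed to the highest-precedence overlapping
        category, so category coverages are disjoint and comparable with the
        summit classification.
        """
        total = 0
        higher: dict[str, np.ndarray | None] = {}
        rank = DEFAULT_PRECEDENCE.index(category)
        for chrom, arr in self._merged[category].items():
            if arr is None:
                continue
            ivals = list(zip(arr[0], arr[1]))
            for above in DEFAULT_PRECEDENCE[:rank]:
                ab = self._merged[above].get(chrom)
                if ab is not None:
                    ivals = _subtract(ivals, list(zip(ab[0], ab[1])))
            total += sum(e - s for s, e in ivals)
        return total


def _to_arrays(ivals: list[tuple[int, int]]):
    if not ivals:
        return None
    a = np.asarray(ivals, dtype=np.int64)
    return a[:, 0], a[:, 1]


def _point_in(arr, pos: int) -> bool:
    if arr is None:
        return False
    starts, ends = arr
    i = int(np.searchsorted(starts, pos, side="right")) - 1
    return i >= 0 and pos < ends[i]


def _subtract(a: list[tuple[int, int]],
              b: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Interval-set difference a \\ b (both merged & sorted)."""
    out = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def classify_peak_feature(
    chrom: str,
    summit_pos: int,
    index: GeneIndex,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> str:
    """Assign a summit to the highest-precedence overlapping category.

    Returns "intergenic" when the summit touches no annotated feature.
    """
    for cat in precedence:
        if index.overlaps(cat, chrom, summit_pos):
            return cat
    return "intergenic"


def feature_enrichment(
    peaks: PeakSet,
    index: GeneIndex,
    genome_bp: int,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
) -> pd.DataFrame:
    """Observed vs expected peak occurrence per gene-feature category.

    Expected probabilities come from the base-pair coverage of each category
    (under the precedence order, within the gene universe the index was built
    on) relative to the total genome size; significance is a one-sided
    binomial test of observed >= expected.  An empty peak set yields zero
    counts and P = 1 everywhere.
    """
    n = len(peaks)
    obs = {cat: 0 for cat in precedence}
    obs["intergenic"] = 0
    for _, row in peaks.peaks.iterrows():
        obs[classify_peak_feature(row.chrom, row.summit_pos,
                                  index, precedence)] += 1
    rows = []
    cum_p = 0.0
    for cat in precedence:
        p_exp = index.coverage_bp(cat) / genome_bp
        cum_p += p_exp
        o = obs[cat]
        pval = 1.0 if n == 0 else float(stats.binom.sf(o - 1, n, p_exp))
        rows.append({"category": cat, "observed": o, "expected_prob": p_exp,
                     "expected": n * p_exp, "binomial_p": pval})
    p_other = max(0.0, 1.0 - cum_p)
    o = obs["intergenic"]
    rows.append({
        "category": "other", "observed": o, "expected_prob": p_other,
        "expected": n * p_other,
        "binomial_p": 1.0 if n == 0 else float(stats.binom.sf(o - 1, n, p_other)),
    })
    return pd.DataFrame(rows)


def nearest_peak_distances(
    tss: pd.DataFrame, peaks: PeakSet, signed: bool = False
) -> pd.Series:
    """Distance from each TSS to the nearest peak summit.

    Unsigned by default; when signed, upstream distances are negative
    (strand-oriented).  TSSs on chromosomes without peaks get NaN.
    """
    tss = tss.reset_index(drop=True)
    out = np.full(len(tss), np.nan)
    for chrom, sub in tss.groupby("chrom", sort=False):
        s = peaks.peaks[peaks.peaks["chrom"] == chrom]
        if len(s) == 0:
            continue
        summits = np.sort(s["summit_pos"].to_numpy())
        pos = sub["tss"].to_numpy()
        idx = np.searchsorted(summits, pos)
        best = np.full(len(pos), np.iinfo(np.int64).max, dtype=np.int64)
        for cand in (idx - 1, idx):
            ok = (cand >= 0) & (cand < len(summits))
            d = np.where(ok, summits[np.clip(cand, 0, len(summits) - 1)] - pos,
                         np.iinfo(np.int64).max)
            better = np.abs(d) < np.abs(best)
            best[better] = d[better]
        dist = best.astype(float)
        if signed:
            minus = (sub["strand"] == "-").to_numpy()
            dist[minus] *= -1  # orient: negative = upstream of the TSS
        else:
            dist = np.abs(dist)
        out[sub.index.to_numpy()] = dist
    return pd.Series(out, index=tss["transcript_id"].to_numpy(),
                     name="nearest_peak_distance")


def tss_distance_bins(
    tss: pd.DataFrame,
    peaks: PeakSet,
    window: int = 10_000,
    bin_size: int = 1_000,
    signed: bool = False,
) -> tuple[pd.Series, pd.DataFrame]:
    """Nearest-peak distance per transcript plus a binned histogram.

    Distances beyond ``window`` are reported in the per-transcript series but
    excluded from the histogram.  Unsigned mode gives window/bin_size bins
    ([0, 1 kb), [1, 2 kb) ...); signed mode gives twice as many, spanning
    -window..window oriented by strand.
    """
    dist = nearest_peak_distances(tss, peaks, signed=signed)
    vals = dist.dropna()
    vals = vals[np.abs(vals) <= window]
    if signed:
        edges = np.arange(-window, window + bin_size, bin_size)
    else:
        edges = np.arange(0, window + bin_size, bin_size)
    # a distance exactly at the window edge belongs to the outermost bin
    clipped = np.clip(vals.to_numpy(), edges[0], edges[-1] - 1e-9)
    counts, _ = np.histogram(clipped, bins=edges)
    hist = pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
    return dist, hist


def averaged_tss_profile(
    tss: pd.DataFrame,
    peaks: PeakSet,
    chrom_lengths: Mapping[str, int],
    window: int = 1_000,
    n_random: int = 20,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Strand-oriented, peak-coverage profile around TSSs, unit-max scaled.

    Restricted to transcripts with a summit within ``window`` of the TSS.
    For every offset in [-window, window] the number of peak intervals
    covering that coordinate is accumulated over the selected TSSs, then the
    profile is normalised to unit maximum.  A baseline from ``n_random``
    placements of the same peaks at uniform random positions (widths
    preserved) is computed with the identical procedure.
    """
    rng = np.random.default_rng() if rng is None else rng
    profile = _coverage_profile(tss, peaks.peaks, window)
    baseline = np.zeros(2 * window + 1)
    for _ in range(n_random):
        shuffled = _randomize_peaks(peaks.peaks, chrom_lengths, rng)
        baseline += _coverage_profile(tss, shuffled, window)
    baseline /= max(n_random, 1)
    return pd.DataFrame(
        {
            "offset": np.arange(-window, window + 1),
            "profile": profile / profile.max() if profile.max() > 0 else profile,
            "baseline": baseline / baseline.max() if baseline.max() > 0 else baseline,
        }
    )


def _coverage_profile(tss: pd.DataFrame, peaks_df: pd.DataFrame,
                      window: int) -> np.ndarray:
    acc = np.zeros(2 * window + 2)
    for chrom, sub in tss.groupby("chrom", sort=False):
        p = peaks_df[peaks_df["chrom"] == chrom]
        if len(p) == 0:
            continue
        summits = np.sort(p["summit_pos"].to_numpy())
        starts = p["start"].to_numpy()
        ends = p["end"].to_numpy()
        for _, t in sub.iterrows():
            d = summits - t.tss
            if not (np.abs(d) <= window).any():
                continue  # gene has no peak within the window
            lo = np.maximum(starts - t.tss, -window)
            hi = np.minimum(ends - t.tss, window + 1)
            if t.strand == "-":
                lo, hi = -hi + 1, -lo + 1
            keep = hi > lo
            np.add.at(acc, lo[keep] + window, 1)
            np.add.at(acc, hi[keep] + window, -1)
    return np.cumsum(acc)[:-1]


def _randomize_peaks(peaks_df: pd.DataFrame,
                     chrom_lengths: Mapping[str, int],
                     rng: np.random.Generator) -> pd.DataFrame:
    out = peaks_df.copy()
    widths = (out["end"] - out["start"]).to_numpy()
    new_starts = np.empty(len(out), dtype=np.int64)
    for chrom, sub in out.groupby("chrom", sort=False):
        L = chrom_lengths[chrom]
        w = (sub["end"] - sub["start"]).to_numpy()
        new_starts[out.index.get_indexer(sub.index)] = rng.integers(
            0, np.maximum(1, L - w))
    out["start"] = new_starts
    out["end"] = new_starts + widths
    out["summit_pos"] = (out["start"] + out["end"]) // 2
    return out


def intergenic_peaks(
    peaks: PeakSet,
    tss: pd.DataFrame,
    index: GeneIndex,
    min_dist: int = 1_000,
) -> PeakSet:
    """Peaks whose summit is >= min_dist from every TSS and outside genes."""
    keep = []
    by_chrom = {c: np.sort(s["tss"].to_numpy())
                for c, s in tss.groupby("chrom", sort=False)}
    for i, row in peaks.peaks.iterrows():
        t = by_chrom.get(row.chrom)
        if t is not None and len(t):
            j = np.searchsorted(t, row.summit_pos)
            near = min(
                abs(int(t[k]) - row.summit_pos)
                for k in (j - 1, j) if 0 <= k < len(t)
            )
            if near < min_dist:
                continue
        if index.in_transcript(row.chrom, row.summit_pos):
            continue
        keep.append(i)
    return PeakSet(
        factor=peaks.factor,
        genotype=peaks.genotype,
        peaks=peaks.peaks.loc[keep].reset_index(drop=True),
        params={**peaks.params, "intergenic_min_dist": min_dist},
    )


def colocalization_curve(
    anchor: PeakSet,
    query: PeakSet,
    fmap: FragmentMap,
    max_offset: int = 5_000,
    bin_size: int = 500,
    n_permutations: int = 100,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observed/expected query-summit frequency around anchor summits.

    Offsets are signed query - anchor summit distances, binned.  The expected
    frequency places the same number of query summits on uniformly sampled
    GATC-fragment midpoints (``n_permutations`` draws, averaged), which
    preserves the fragment-level granularity of the data.  A one-sided
    binomial P per bin tests observed >= expected.
    """
    if len(anchor) == 0 or len(query) == 0:
        raise ValueError("anchor and query peak sets must be non-empty")
    rng = np.random.default_rng() if rng is None else rng
    edges = np.arange(-max_offset, max_offset + bin_size, bin_size)

    def offsets_hist(query_df: pd.DataFrame) -> np.ndarray:
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
        for chrom, a in anchor.peaks.groupby("chrom", sort=False):
            q = query_df[query_df["chrom"] == chrom]
            if len(q) == 0:
                continue
            qa = np.sort(q["summit_pos"].to_numpy())
            for apos in a["summit_pos"].to_numpy():
                lo = np.searchsorted(qa, apos - max_offset)
                hi = np.searchsorted(qa, apos + max_offset, side="right")
                d = qa[lo:hi] - apos
                c, _ = np.histogram(np.clip(d, edges[0], edges[-1] - 1e-9),
                                    bins=edges)
                counts += c
        return counts

    observed = offsets_hist(query.peaks)

    mids = fmap.fragment_midpoints()
    expected = np.zeros(len(edges) - 1)
    n_query = len(query)
    for _ in range(n_permutations):
        pick = mids.iloc[rng.integers(0, len(mids), n_query)]
        rand = pd.DataFrame(
            {"chrom": pick["chrom"].to_numpy(),
             "summit_pos": pick["midpoint"].to_numpy()}
        )
        expected += offsets_hist(rand)
    expected /= max(n_permutations, 1)

    n_pairs = len(anchor) * n_query
    p_exp = np.clip(expected / n_pairs, 1e-12, 1.0)
    pvals = stats.binom.sf(observed - 1, n_pairs, p_exp)
    with np.errstate(divide="ignore", invalid="ignore"):
        enrich = np.where(expected > 0, observed / expected, np.nan)
    return pd.DataFrame(
        {
            "offset_start": edges[:-1],
            "offset_end": edges[1:],
            "observed": observed,
            "expected": expected,
            "enrichment": enrich,
            "binomial_p": pvals,
        }
    )


def intersect_peak_sets(sets: Mapping[str, PeakSet]) -> pd.DataFrame:
    """Exact membership partition of 2-3 peak sets (Euler-diagram counts).

    Each peak is assigned the subset of set names whose peaks it overlaps by
    at least 1 bp (always including its own set); a peak overlapping several
    peaks of another set still counts once.  Returns per (origin, pattern)
    counts.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("provide 2 or 3 peak sets")
    merged = {
        name: {
            c: _to_arrays(_merge_intervals(
                list(zip(s["start"], s["end"]))))
            for c, s in ps.peaks.groupby("chrom", sort=False)
        }
        for name, ps in sets.items()
    }

    def hits(name: str, chrom: str, s: int, e: int) -> bool:
        arr = merged[name].get(chrom)
        if arr is None:
            return False
        starts, ends = arr
        i = int(np.searchsorted(starts, e, side="left"))
        return i > 0 and ends[i - 1] > s

    counts: dict[tuple[str, str], int] = {}
    for origin, ps in sets.items():
        for _, row in ps.peaks.iterrows():
            pattern = "&".join(
                n for n in names
                if n == origin or hits(n, row.chrom, row.start, row.end)
            )
            counts[(origin, pattern)] = counts.get((origin, pattern), 0) + 1
    return pd.DataFrame(
        [{"set": o, "pattern": p, "count": c}
         for (o, p), c in sorted(counts.items())]
    )
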