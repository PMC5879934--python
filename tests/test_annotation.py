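"""Feature classification, TSS distances, profiles, colocalization and
peak-set intersections."""

import numpy as np
import pandas as pd
import pytest

import damidkit as dk
from damidkit.annotation import GeneIndex, GeneModel
from damidkit.peaks import PeakSet


def make_peaks(rows, factor="f", genotype="wt"):
    """rows: (chrom, start, end, summit_pos)"""
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "summit_pos"]
    )
    df["first_fragment"] = 0
    df["last_fragment"] = 0
    df["summit_fragment"] = 0
    df["max_neglog10_p"] = 5.0
    df["max_log2_ratio"] = 2.0
    return PeakSet(factor=factor, genotype=genotype, peaks=df)


@pytest.fixture
def plus_gene():
    # + strand: 5'UTR [1000,1200), CDS [1200,1600)+[1700,2100),
    # intron [1600,1700), 3'UTR [2100,2300); TSS 1000, promoter [600,1000)
    return GeneModel(
        transcript_id="t1", gene_id="g1", chrom="c", strand="+",
        start=1000, end=2300,
        utr5=[(1000, 1200)], cds=[(1200, 1600), (1700, 2100)],
        utr3=[(2100, 2300)],
    )


@pytest.fixture
def minus_gene():
    # - strand: TSS at end-1=5299, promoter [5300,5700)
    return GeneModel(
        transcript_id="t2", gene_id="g2", chrom="c", strand="-",
        start=4000, end=5300,
        utr3=[(4000, 4200)], cds=[(4200, 4800)], utr5=[(4800, 5300)],
    )


class TestGeneModel:
    def test_tss_and_promoter_strand_aware(self, plus_gene, minus_gene):
        assert plus_gene.tss == 1000
        assert plus_gene.promoter() == (600, 1000)
        assert minus_gene.tss == 5299
        assert minus_gene.promoter() == (5300, 5700)

    def test_promoter_truncated_at_edges(self):
        g = GeneModel("t", "g", "c", "+", 100, 500)
        assert g.promoter() == (0, 100)
        gm = GeneModel("t", "g", "c", "-", 100, 500)
        assert gm.promoter(chrom_length=520) == (500, 520)

    def test_introns_derived_from_exons(self, plus_gene):
        assert plus_gene.introns == [(1600, 1700)]


class TestClassifyPeakFeature:
    def test_category_boundaries(self, plus_gene):
        index = GeneIndex([plus_gene])
        classify = lambda pos: dk.classify_peak_feature("c", pos, index)
        assert classify(800) == "promoter"    # 200 bp upstream
        assert classify(600) == "promoter"    # exactly 400 bp upstream
        assert classify(599) == "intergenic"  # 401 bp upstream
        assert classify(1100) == "utr5"
        assert classify(1300) == "cds"
        assert classify(1650) == "intron"
        assert classify(2200) == "utr3"
        assert classify(5000) == "intergenic"

    def test_precedence_order(self):
        # promoter of one gene overlapping the CDS of another: promoter wins
        g1 = GeneModel("a", "a", "c", "+", 1000, 2000, cds=[(1000, 2000)])
        g2 = GeneModel("b", "b", "c", "+", 1500, 3000, utr5=[(1500, 3000)])
        index = GeneIndex([g1, g2])
        assert dk.classify_peak_feature("c", 1200, index) == "promoter"

    def test_random_summits_match_coverage(self, study, study_index, rng):
        """Uniformly placed summits land in each category at its genome-
        coverage rate (binomial CI)."""
        genome_bp = sum(len(s) for s in study.genome.values())
        n = 3000
        chrom = study.fmap.chroms[0]
        pos = rng.integers(0, len(study.genome[chrom]), n)
        counts = {}
        for p in pos:
            cat = dk.classify_peak_feature(chrom, int(p), study_index)
            counts[cat] = counts.get(cat, 0) + 1
        for cat in ("promoter", "cds", "intron"):
            p_exp = study_index.coverage_bp(cat) / genome_bp
            obs = counts.get(cat, 0)
            se = np.sqrt(n * p_exp * (1 - p_exp))
            assert abs(obs - n * p_exp) < 4 * se + 3


class TestFeatureEnrichment:
    def test_all_promoter_peaks_highly_significant(self, plus_gene):
        index = GeneIndex([plus_gene])
        peaks = make_peaks([("c", 700, 900, 800)] * 100)
        dist = dk.feature_enrichment(peaks, index, genome_bp=100_000)
        row = dist.set_index("category").loc["promoter"]
        assert row.observed == 100
        assert row.binomial_p < 1e-6
        assert dist["observed"].sum() == 100

    def test_empty_peaks_p_one(self, plus_gene):
        index = GeneIndex([plus_gene])
        dist = dk.feature_enrichment(
            make_peaks([]), index, genome_bp=100_000
        )
        assert (dist["observed"] == 0).all()
        assert (dist["binomial_p"] == 1).all()

    def test_uniform_peaks_not_significant(self, study, study_index, rng):
        """Random peaks clear no category at P < 1e-3 in the vast majority
        of draws."""
        genome_bp = sum(len(s) for s in study.genome.values())
        chrom = study.fmap.chroms[0]
        hits = 0
        for _ in range(10):
            pos = rng.integers(500, genome_bp - 500, 150)
            peaks = make_peaks([(chrom, p - 50, p + 50, p) for p in pos])
            dist = dk.feature_enrichment(peaks, study_index, genome_bp)
            if (dist["binomial_p"] < 1e-3).any():
                hits += 1
        assert hits <= 1


class TestTssDistanceBins:
    def tss_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["transcript_id", "gene_id", "chrom", "strand", "tss"]
        )

    def test_nearest_rule_and_first_bin(self):
        tss = self.tss_frame([("t", "g", "c", "+", 10_000)])
        peaks = make_peaks([("c", 10_850, 10_950, 10_900),
                            ("c", 12_450, 12_550, 12_500)])
        dist, hist = dk.tss_distance_bins(tss, peaks)
        assert dist["t"] == 900  # nearest only
        assert hist.iloc[0]["count"] == 1
        assert hist["count"].sum() == 1

    def test_beyond_window_reported_not_binned(self):
        tss = self.tss_frame([("t", "g", "c", "+", 10_000)])
        peaks = make_peaks([("c", 30_000, 30_100, 30_050)])
        dist, hist = dk.tss_distance_bins(tss, peaks, window=10_000)
        assert dist["t"] == 20_050
        assert hist["count"].sum() == 0

    def test_signed_orientation(self):
        tss = self.tss_frame([("t", "g", "c", "-", 10_000)])
        peaks = make_peaks([("c", 10_850, 10_950, 10_900)])
        dist, _ = dk.tss_distance_bins(tss, peaks, signed=True)
        # downstream of a minus-strand TSS lies at smaller coordinates;
        # +900 in genome space is upstream -> negative offset
        assert dist["t"] == -900

    def test_nearest_matches_brute_force(self, rng):
        tss = self.tss_frame(
            [(f"t{i}", f"g{i}", "c", "+", int(p))
             for i, p in enumerate(rng.integers(0, 100_000, 60))]
        )
        summits = rng.integers(0, 100_000, 40)
        peaks = make_peaks([("c", s - 10, s + 10, int(s)) for s in summits])
        dist = dk.nearest_peak_distances(tss, peaks)
        for _, row in tss.iterrows():
            expected = min(abs(int(s) - row.tss) for s in summits)
            assert dist[row.transcript_id] == expected

    def test_uniform_peaks_match_poisson_oracle(self, rng):
        """With summits from a uniform (Poisson) process, the nearest-summit
        distance is exponential with rate 2*density; binned occupancy matches
        that closed form by chi-square goodness of fit."""
        from scipy import stats

        n_tss, n_peaks, span = 2_000, 150, 1_000_000
        tss = self.tss_frame(
            [(f"t{i}", f"g{i}", "c", "+", int(p))
             for i, p in enumerate(rng.integers(100_000, 900_000, n_tss))]
        )
        summits = rng.integers(0, span, n_peaks)
        peaks = make_peaks([("c", s, s + 1, int(s)) for s in summits])
        window, bin_size = 10_000, 1_000
        _, hist = dk.tss_distance_bins(tss, peaks, window=window,
                                       bin_size=bin_size)
        counts = hist["count"].to_numpy()
        lam = 2 * n_peaks / span
        edges = np.arange(0, window + bin_size, bin_size)
        probs = np.exp(-lam * edges[:-1]) - np.exp(-lam * edges[1:])
        probs /= probs.sum()
        p = stats.chisquare(counts, counts.sum() * probs).pvalue
        assert p > 1e-3


class TestAveragedTssProfile:
    def tss_frame(self, rows):
        return pd.DataFrame(
            rows, columns=["transcript_id", "gene_id", "chrom", "strand", "tss"]
        )

    def test_peaks_at_tss_peak_profile_at_zero(self, rng):
        tss = self.tss_frame(
            [(f"t{i}", f"g{i}", "c", "+", 10_000 * (i + 1))
             for i in range(20)]
        )
        peaks = make_peaks(
            [("c", t - 50, t + 50, t) for t in tss["tss"]]
        )
        prof = dk.averaged_tss_profile(
            tss, peaks, {"c": 400_000}, rng=rng
        )
        centre = prof.set_index("offset")["profile"]
        assert centre.loc[0] == 1.0
        assert centre.loc[-500] < 0.2

    def test_upstream_mass_preserved_under_strand(self, rng):
        """Peaks planted strictly upstream show up at negative offsets for
        both strands."""
        rows, peak_rows = [], []
        for i in range(10):
            t = 20_000 * (i + 1)
            rows.append((f"p{i}", f"p{i}", "c", "+", t))
            peak_rows.append(("c", t - 900, t - 500, t - 700))
        for i in range(10):
            t = 20_000 * (i + 11)
            rows.append((f"m{i}", f"m{i}", "c", "-", t))
            peak_rows.append(("c", t + 500, t + 900, t + 700))
        prof = dk.averaged_tss_profile(
            self.tss_frame(rows), make_peaks(peak_rows),
            {"c": 600_000}, rng=rng,
        )
        p = prof.set_index("offset")["profile"]
        assert p.loc[-700] == 1.0
        assert p.loc[700] == 0.0

    def test_randomized_baseline_roughly_flat(self, rng):
        tss = self.tss_frame(
            [(f"t{i}", f"g{i}", "c", "+", 5_000 * (i + 1))
             for i in range(50)]
        )
        peaks = make_peaks(
            [("c", t - 50, t + 50, t) for t in tss["tss"]]
        )
        prof = dk.averaged_tss_profile(
            tss, peaks, {"c": 300_000}, n_random=50, rng=rng
        )
        base = prof["baseline"].to_numpy()
        inner = base[200:-200]
        assert inner.max() <= 1.0
        # flat within a factor ~3 between central plateau values
        assert inner.min() > 0.15


class TestIntergenicPeaks:
    def test_distance_boundary(self, plus_gene):
        index = GeneIndex([plus_gene])
        tss = pd.DataFrame(
            {"transcript_id": ["t1"], "gene_id": ["g1"], "chrom": ["c"],
             "strand": ["+"], "tss": [1000]}
        )
        peaks = make_peaks([
            ("c", 0, 10, 1),          # 999 bp from TSS -> excluded
            ("c", 6_000, 6_100, 6_050),  # far from gene -> included
            ("c", 1_950, 2_050, 2_000),  # 1000 bp but inside transcript
        ])
        out = dk.intergenic_peaks(peaks, tss, index)
        assert list(out.peaks["summit_pos"]) == [6_050]

    def test_empty_gene_set_keeps_all(self):
        index = GeneIndex([])
        tss = pd.DataFrame(
            columns=["transcript_id", "gene_id", "chrom", "strand", "tss"]
        )
        peaks = make_peaks([("c", 10, 20, 15), ("c", 100, 120, 110)])
        assert len(dk.intergenic_peaks(peaks, tss, index)) == 2


class TestColocalization:
    def test_self_colocalization_peaks_at_zero(self, study, study_peaks, rng):
        ps = study_peaks[("can", "wt")]
        curve = dk.colocalization_curve(
            ps, ps, study.fmap, n_permutations=20, rng=rng
        )
        centre = curve.iloc[(curve["offset_start"] == 0).idxmax()]
        others = curve[curve["offset_start"].abs() > 1_000]
        assert centre["enrichment"] > others["enrichment"].max()
        assert centre["binomial_p"] < 1e-10

    def test_independent_query_flat(self, study, rng):
        anchors = make_peaks(
            [("chr1", p - 50, p + 50, int(p))
             for p in rng.integers(1_000, 999_000, 80)]
        )
        queries = make_peaks(
            [("chr1", p - 50, p + 50, int(p))
             for p in rng.integers(1_000, 999_000, 80)]
        )
        curve = dk.colocalization_curve(
            anchors, queries, study.fmap, n_permutations=40, rng=rng
        )
        # no bin should be overwhelmingly enriched
        assert (curve["binomial_p"] < 1e-6).sum() == 0

    def test_planted_cobinding_decays_with_offset(self, study, study_peaks, rng):
        """can and comr were planted on shared promoter fragments: strong
        central enrichment decaying toward 1 at large offsets."""
        curve = dk.colocalization_curve(
            study_peaks[("can", "wt")], study_peaks[("comr", "wt")],
            study.fmap, n_permutations=20, rng=rng,
        )
        centre = curve.iloc[(curve["offset_start"] == 0).idxmax()]
        edge = curve[curve["offset_start"].abs() >= 4_000]["enrichment"]
        assert centre["enrichment"] > 3
        assert edge.mean() < centre["enrichment"] / 2

    def test_empty_sets_rejected(self, study):
        empty = make_peaks([])
        full = make_peaks([("chr1", 0, 10, 5)])
        with pytest.raises(ValueError, match="non-empty"):
            dk.colocalization_curve(empty, full, study.fmap)


class TestIntersectPeakSets:
    def brute_force(self, sets):
        names = list(sets)
        out = {}
        for origin, ps in sets.items():
            for _, row in ps.peaks.iterrows():
                pattern = []
                for n in names:
                    other = sets[n].peaks
                    hit = (
                        (other["chrom"] == row.chrom)
                        & (other["start"] < row.end)
                        & (other["end"] > row.start)
                    ).any()
                    if n == origin or hit:
                        pattern.append(n)
                key = (origin, "&".join(pattern))
                out[key] = out.get(key, 0) + 1
        return out

    def test_disjoint_sets(self):
        a = make_peaks([("c", 0, 10, 5), ("c", 100, 110, 105)])
        b = make_peaks([("c", 50, 60, 55)])
        res = dk.intersect_peak_sets({"a": a, "b": b})
        assert set(res["pattern"]) == {"a", "b"}
        assert res["count"].sum() == 3

    def test_identical_sets(self):
        rows = [("c", i * 100, i * 100 + 10, i * 100 + 5) for i in range(5)]
        res = dk.intersect_peak_sets(
            {"a": make_peaks(rows), "b": make_peaks(rows)}
        )
        assert set(res["pattern"]) == {"a&b"}
        assert res["count"].sum() == 10

    @pytest.mark.parametrize("n_sets", [2, 3])
    def test_random_sets_match_quadratic_oracle(self, rng, n_sets):
        sets = {}
        for name in "abc"[:n_sets]:
            starts = np.sort(rng.choice(5_000, 120, replace=False)) * 10
            sets[name] = make_peaks(
                [("c", int(s), int(s + rng.integers(5, 200)), int(s))
                 for s in starts]
            )
        res = dk.intersect_peak_sets(sets)
        got = {
            (r["set"], r["pattern"]): r["count"]
            for _, r in res.iterrows()
        }
        assert got == self.brute_force(sets)
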