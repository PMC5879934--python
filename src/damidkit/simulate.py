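"""Synthetic DamID studies with planted, fully recorded truth.

The generator emulates the complete input side of a germline DamID study:

* a random genome in which GATC occurs at a configurable density, with a pair
  of GATC sites planted around every TSS so that each promoter owns a
  well-defined ~120 bp TSS fragment (DamID has fragment-level resolution;
  fixing the promoter fragment makes planted binding unambiguous);
* non-overlapping gene models (promoter, 5'UTR, CDS with an intron, 3'UTR);
* per-gene binding truth: a cross-genotype presence pattern for the shared
  factor (dynamics groups I-VI), wild-type binding for the other factors with
  planted co-binding, and intergenic bound fragments;
* fragment count tables per channel/replicate/genotype: Dam-alone rates are
  fragment-length x lognormal-accessibility, the fusion channel multiplies
  planted fragments by the effect size (default 8), and counts are drawn
  negative-binomially (replicates share rates, so replicate-based FDR
  calibration is non-trivial);
* expression tables coupled to the binding truth (direct targets at least
  eightfold down in the cognate mutant, factor-repressed genes at least
  fourfold up) and a FlyAtlas-style tissue log-ratio matrix with planted
  testis- and ovary-specific transcripts.

Everything is deterministic under the seed, and every planted fact is
recorded in the :class:`TruthSet`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel, tss_table
from .dynamics import DEFAULT_GROUP_PATTERNS, GENOTYPE_ORDER
from .fragments import FragmentCounts, FragmentMap, Read, build_fragment_map

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of a synthetic study; defaults are the desk-scale preset

    (1 chromosome x 1 Mb, ~4000 GATC fragments, 300 genes, 2x10^5 reads per
    channel) on which the full pipeline runs in well under two minutes.
    """

    seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 1_000_000
    gatc_density: float = 1.0 / 256.0
    n_genes: int = 300
    # binding truth
    group_fractions: dict = field(default_factory=lambda: {
        "I": 0.12, "II": 0.08, "III": 0.12, "IV": 0.12, "V": 0.08, "VI": 0.08,
    })
    comr_extra_fraction: float = 0.10   # comr binds III/IV plus this many others
    can_cobind_fraction: float = 0.5    # fraction of comr-bound genes can co-binds
    can_extra_fraction: float = 0.05
    n_intergenic_bound: int = 30
    effect_size: float = 8.0
    # sequencing
    depth: int = 200_000
    replicates: int = 2
    nb_dispersion: float = 0.05
    accessibility_sigma: float = 0.5
    # expression coupling
    p_couple: float = 1.0
    direct_fraction: float = 0.6        # of bound genes become direct targets
    indirect_fraction: float = 0.08     # of genes, down without binding
    repressed_fraction: float = 0.5     # of MMB-pattern genes up in mip40
    expression_noise_sigma: float = 0.15
    # tissue matrix
    n_tissues: int = 10
    testis_fraction: float = 0.3
    ovary_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.effect_size < 1:
            raise ValueError("effect size must be >= 1")
        fracs = list(self.group_fractions.values()) + [
            self.p_couple, self.direct_fraction, self.indirect_fraction,
            self.repressed_fraction, self.testis_fraction, self.ovary_fraction,
        ]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class TruthSet:
    """Everything the generator planted, keyed the way the pipeline reports."""

    bound_fragments: dict = field(default_factory=dict)  # (factor, genotype) -> list[int]
    bound_genes: dict = field(default_factory=dict)      # (factor, genotype) -> list[str]
    direct_targets: dict = field(default_factory=dict)   # factor -> list[str]
    indirect_targets: dict = field(default_factory=dict)
    pattern: dict = field(default_factory=dict)          # transcript -> (b,a,c,w)
    group: dict = field(default_factory=dict)            # transcript -> group
    repressed_by_mip40: list = field(default_factory=list)
    testis_specific: list = field(default_factory=list)
    ovary_specific: list = field(default_factory=list)
    accessibility: np.ndarray | None = None              # per-fragment lognormal

    def fragments_for(self, factor: str, genotype: str) -> np.ndarray:
        return np.asarray(
            self.bound_fragments.get((factor, genotype), []), dtype=np.int64
        )

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bound_fragments": {
                f"{f}|{g}": [int(x) for x in v]
                for (f, g), v in self.bound_fragments.items()
            },
            "bound_genes": {
                f"{f}|{g}": list(v) for (f, g), v in self.bound_genes.items()
            },
            "direct_targets": {k: list(v) for k, v in self.direct_targets.items()},
            "indirect_targets": {k: list(v) for k, v in self.indirect_targets.items()},
            "pattern": {k: list(v) for k, v in self.pattern.items()},
            "group": dict(self.group),
            "repressed_by_mip40": list(self.repressed_by_mip40),
            "testis_specific": list(self.testis_specific),
            "ovary_specific": list(self.ovary_specific),
            "accessibility": None if self.accessibility is None
            else [float(x) for x in self.accessibility],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        with open(path) as fh:
            d = json.load(fh)
        t = cls()
        t.bound_fragments = {
            tuple(k.split("|")): v for k, v in d["bound_fragments"].items()
        }
        t.bound_genes = {
            tuple(k.split("|")): v for k, v in d["bound_genes"].items()
        }
        t.direct_targets = d["direct_targets"]
        t.indirect_targets = d["indirect_targets"]
        t.pattern = {k: tuple(v) for k, v in d["pattern"].items()}
        t.group = d["group"]
        t.repressed_by_mip40 = d["repressed_by_mip40"]
        t.testis_specific = d["testis_specific"]
        t.ovary_specific = d["ovary_specific"]
        t.accessibility = (
            None if d["accessibility"] is None
            else np.asarray(d["accessibility"])
        )
        return t


# ---------------------------------------------------------------------------
# genome & gene models

def _random_sequence(length: int, density: float,
                     rng: np.random.Generator) -> str:
    """Random sequence with GATC at approximately the requested density.

    Uniform iid bases give GATC at 4^-4 = 1/256; densities above that are
    reached by overwriting extra motifs at random positions.
    """
    seq = rng.choice(BASES, size=length)
    natural = 1.0 / 256.0
    extra = int(round(max(0.0, density - natural) * length))
    if extra:
        pos = rng.integers(0, length - 4, size=extra)
        for p in pos:
            seq[p : p + 4] = list("GATC")
    return "".join(seq)


def _plant_motif(seq: list, pos: int) -> None:
    if 0 <= pos and pos + 4 <= len(seq):
        seq[pos : pos + 4] = list("GATC")


#: offsets of the GATC pair planted around every TSS; they bound the
#: "promoter fragment" the binding truth is planted on.  150 bp keeps every
#: planted summit well inside the +/-300 bp presence window while giving the
#: fragment enough background reads to clear tight FDR thresholds even when
#: natural motifs split it.
TSS_MOTIF_UP = 150
TSS_MOTIF_DOWN = 150


def simulate_genome_and_genes(
    cfg: SimConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome plus non-overlapping gene models, deterministic in seed.

    Genes are laid out on a regular grid of slots (alternating strands,
    jittered TSSs) with promoters and 1 kb flanks kept clear of neighbours.
    A GATC pair is planted just up- and downstream of every TSS.  Raises if
    the requested genes do not fit the genome.
    """
    rng = np.random.default_rng(cfg.seed)
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    per_chrom = int(np.ceil(cfg.n_genes / cfg.n_chroms))
    gid = 0
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = list(_random_sequence(cfg.chrom_length, cfg.gatc_density, rng))
        n_here = min(per_chrom, cfg.n_genes - gid)
        if n_here > 0:
            slot = cfg.chrom_length // n_here
            if slot < 3_000:
                raise ValueError(
                    f"{n_here} genes do not fit a {cfg.chrom_length} bp "
                    "chromosome (need >= 3 kb per gene)"
                )
            for k in range(n_here):
                strand = "+" if rng.random() < 0.5 else "-"
                utr5_len = int(rng.integers(100, 300))
                utr3_len = int(rng.integers(100, 300))
                cds1 = int(rng.integers(200, 500))
                intron = int(rng.integers(80, 300))
                cds2 = int(rng.integers(200, 500))
                span = utr5_len + cds1 + intron + cds2 + utr3_len
                # keep the promoter and a ~1 kb flank inside the slot
                margin = 700
                lo = k * slot + margin
                hi = (k + 1) * slot - margin - span
                if hi <= lo:
                    raise ValueError("gene span does not fit its slot")
                start = int(rng.integers(lo, hi))
                end = start + span
                if strand == "+":
                    tss = start
                    utr5 = [(start, start + utr5_len)]
                    c1 = (start + utr5_len, start + utr5_len + cds1)
                    c2 = (c1[1] + intron, c1[1] + intron + cds2)
                    utr3 = [(c2[1], end)]
                else:
                    tss = end - 1
                    utr3 = [(start, start + utr3_len)]
                    c2 = (start + utr3_len, start + utr3_len + cds2)
                    c1 = (c2[1] + intron, c2[1] + intron + cds1)
                    utr5 = [(c1[1], end)]
                tid = f"T{gid:04d}"
                genes.append(GeneModel(
                    transcript_id=tid, gene_id=f"G{gid:04d}", chrom=chrom,
                    strand=strand, start=start, end=end,
                    utr5=utr5, cds=[c1, c2], utr3=utr3,
                ))
                _plant_motif(seq, tss - TSS_MOTIF_UP - 4)
                _plant_motif(seq, tss + TSS_MOTIF_DOWN)
                gid += 1
        genome[chrom] = "".join(seq)
    return genome, genes


# ---------------------------------------------------------------------------
# binding truth

def _tss_fragments(fmap: FragmentMap, gene: GeneModel) -> np.ndarray:
    """Fragments fully covering the planted promoter-fragment window."""
    lo = gene.tss - TSS_MOTIF_UP
    hi = gene.tss + TSS_MOTIF_DOWN
    return fmap.fragments_in_window(gene.chrom, lo, hi)


def build_truth(
    cfg: SimConfig,
    fmap: FragmentMap,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Assign dynamics patterns, factor binding and target labels."""
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    truth = TruthSet()
    ids = [g.transcript_id for g in genes]
    by_id = {g.transcript_id: g for g in genes}
    n = len(ids)

    # dynamics groups for the shared factor
    pattern_of_group = {v: k for k, v in DEFAULT_GROUP_PATTERNS.items()}
    perm = rng.permutation(n)
    cursor = 0
    for grp, frac in cfg.group_fractions.items():
        take = int(round(frac * n))
        for i in perm[cursor : cursor + take]:
            truth.group[ids[i]] = grp
            truth.pattern[ids[i]] = pattern_of_group[grp]
        cursor += take
    for i in perm[cursor:]:
        truth.pattern[ids[i]] = (0, 0, 0, 0)

    # mip40 binding per genotype follows the pattern bit
    for gi, geno in enumerate(GENOTYPE_ORDER):
        bound = [t for t in ids if truth.pattern[t][gi] == 1]
        truth.bound_genes[("mip40", geno)] = bound

    # wild-type binding of the two activator-complex factors: comr covers the
    # spermatocyte-acquired groups (III/IV) plus extras; can co-binds a
    # planted fraction of comr genes plus its own extras.
    iii_iv = [t for t in ids if truth.group.get(t) in ("III", "IV")]
    others = [t for t in ids if truth.group.get(t) not in ("III", "IV")]
    comr = set(iii_iv) | set(
        rng.choice(others, int(cfg.comr_extra_fraction * n), replace=False)
    )
    comr_list = sorted(comr)
    can = set(
        rng.choice(comr_list, int(cfg.can_cobind_fraction * len(comr_list)),
                   replace=False)
    )
    not_comr = sorted(set(ids) - comr)
    can |= set(rng.choice(not_comr, int(cfg.can_extra_fraction * n),
                          replace=False))
    truth.bound_genes[("comr", "wt")] = sorted(comr)
    truth.bound_genes[("can", "wt")] = sorted(can)

    # genes -> fragments, plus intergenic bound fragments
    tss_pos = {g.transcript_id: (g.chrom, g.tss) for g in genes}
    mids = fmap.fragment_midpoints()
    intergenic_pool = []
    for chrom, sub in mids.groupby("chrom", sort=False):
        tss_here = np.sort([p for c, p in tss_pos.values() if c == chrom])
        m = sub["midpoint"].to_numpy()
        if len(tss_here):
            j = np.searchsorted(tss_here, m)
            dist = np.full(len(m), np.inf)
            for cand in (j - 1, j):
                ok = (cand >= 0) & (cand < len(tss_here))
                d = np.where(ok, np.abs(
                    tss_here[np.clip(cand, 0, len(tss_here) - 1)] - m),
                    np.inf)
                dist = np.minimum(dist, d)
        else:
            dist = np.full(len(m), np.inf)
        intergenic_pool.extend(sub.index.to_numpy()[dist > 1_500])
    intergenic_pool = np.asarray(intergenic_pool)

    for (factor, geno), bound in truth.bound_genes.items():
        frags: list[int] = []
        for t in bound:
            frags.extend(int(f) for f in _tss_fragments(fmap, by_id[t]))
        n_inter = min(cfg.n_intergenic_bound, len(intergenic_pool))
        if n_inter:
            frags.extend(
                int(f) for f in rng.choice(intergenic_pool, n_inter,
                                           replace=False)
            )
        truth.bound_fragments[(factor, geno)] = sorted(set(frags))

    # expression coupling
    for factor in ("can", "comr", "mip40"):
        if factor == "mip40":
            candidates = [
                t for t in truth.bound_genes[("mip40", "wt")]
                if truth.group.get(t) in ("III", "IV")
            ]
        else:
            candidates = list(truth.bound_genes[(factor, "wt")])
        n_direct = int(round(cfg.direct_fraction * len(candidates)))
        chosen = rng.choice(candidates, n_direct, replace=False)
        coupled = [t for t in chosen if rng.random() < cfg.p_couple]
        truth.direct_targets[factor] = sorted(coupled)
        unbound = sorted(set(ids) - set(truth.bound_genes[(factor, "wt")]))
        n_ind = int(round(cfg.indirect_fraction * n))
        truth.indirect_targets[factor] = sorted(
            rng.choice(unbound, min(n_ind, len(unbound)), replace=False)
        )

    mmb = [t for t in ids if truth.group.get(t) in ("I", "II", "V", "VI")]
    direct_mip40 = set(truth.direct_targets["mip40"]) | set(
        truth.indirect_targets["mip40"])
    mmb = [t for t in mmb if t not in direct_mip40]
    truth.repressed_by_mip40 = sorted(
        rng.choice(mmb, int(round(cfg.repressed_fraction * len(mmb))),
                   replace=False)
    )

    # tissue specificity: testis-specific genes preferentially in the
    # spermatocyte-acquired groups (weight 5), ovary-specific in the rest
    w = np.array([5.0 if truth.group.get(t) in ("III", "IV") else 1.0
                  for t in ids])
    n_testis = int(round(cfg.testis_fraction * n))
    testis = rng.choice(ids, n_testis, replace=False, p=w / w.sum())
    remaining = sorted(set(ids) - set(testis))
    w2 = np.array([5.0 if truth.group.get(t) in ("I", "II", "V", "VI")
                   else 1.0 for t in remaining])
    n_ovary = min(int(round(cfg.ovary_fraction * n)), len(remaining))
    ovary = rng.choice(remaining, n_ovary, replace=False, p=w2 / w2.sum())
    truth.testis_specific = sorted(testis)
    truth.ovary_specific = sorted(ovary)

    # per-fragment accessibility, shared by every library on this genome
    truth.accessibility = rng.lognormal(
        0.0, cfg.accessibility_sigma, fmap.n_fragments
    )
    return truth


def plant_random_fragments(
    cfg: SimConfig,
    fmap: FragmentMap,
    fraction: float,
    factor: str = "damX",
    genotype: str = "wt",
    rng: np.random.Generator | None = None,
) -> TruthSet:
    """Fragment-level truth without genes: a random ``fraction`` of fragments

    is bound (used for null / FDR-honesty simulations).
    """
    rng = np.random.default_rng(cfg.seed + 1) if rng is None else rng
    truth = TruthSet()
    n = fmap.n_fragments
    k = int(round(fraction * n))
    truth.bound_fragments[(factor, genotype)] = sorted(
        int(x) for x in rng.choice(n, k, replace=False)
    )
    truth.accessibility = rng.lognormal(0.0, cfg.accessibility_sigma, n)
    return truth


# ---------------------------------------------------------------------------
# counts

def simulate_counts(
    cfg: SimConfig,
    truth: TruthSet,
    fmap: FragmentMap,
    factor: str,
    genotype: str = "wt",
    rng: np.random.Generator | None = None,
) -> dict[tuple[str, int], FragmentCounts]:
    """Draw count tables for one factor/genotype: both channels, all reps.

    Dam-alone rates are fragment length x accessibility; the fusion channel
    multiplies planted fragments by the effect size.  Counts are negative
    binomial (dispersion ``nb_dispersion``); replicates share rates and
    differ only by sampling noise.  Returns a dict keyed by
    (construct, replicate).
    """
    rng = np.random.default_rng(cfg.seed + 2) if rng is None else rng
    if truth.accessibility is None or len(truth.accessibility) != fmap.n_fragments:
        raise ValueError("truth lacks accessibility for this fragment map")
    planted = truth.fragments_for(factor, genotype)
    if len(planted) and (planted >= fmap.n_fragments).any():
        raise ValueError("planted fragments fall outside the fragment map")

    background = fmap.fragment_lengths() * truth.accessibility
    fusion = background.copy()
    if len(planted):
        fusion[planted] *= cfg.effect_size

    out: dict[tuple[str, int], FragmentCounts] = {}
    for rep in range(1, cfg.replicates + 1):
        # Per-fragment biological state of this replicate (Gamma, mean 1,
        # variance = dispersion): shared by the fusion and control libraries
        # collected together, so marginal counts are negative binomial with
        # the configured dispersion while the fusion-vs-control comparison
        # stays calibrated and replicate-vs-replicate noise exceeds it.
        if cfg.nb_dispersion > 0:
            jitter = rng.gamma(1.0 / cfg.nb_dispersion,
                               cfg.nb_dispersion, fmap.n_fragments)
        else:
            jitter = np.ones(fmap.n_fragments)
        for construct, rates in (("dam_fusion", fusion),
                                 ("dam_alone", background)):
            r = rates * jitter
            mean = cfg.depth * r / r.sum()
            out[(construct, rep)] = FragmentCounts(
                sample_id=f"{factor}_{genotype}_{construct}_rep{rep}",
                genotype=genotype if genotype in
                ("wt", "bam", "aly", "can", "comr", "mip40") else "custom",
                construct=construct,
                replicate=rep,
                counts=rng.poisson(mean),
            )
    return out


# ---------------------------------------------------------------------------
# expression & tissues

def simulate_expression_and_tissues(
    cfg: SimConfig,
    truth: TruthSet,
    genes: Sequence[GeneModel],
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """FPKM table per genotype plus the tissue log-ratio matrix.

    Direct and indirect targets drop >= 8-fold in the cognate mutant,
    factor-repressed genes rise >= 4-fold in the *mip40* mutant, everything
    else fluctuates by lognormal noise.  Raises if the coupling rules would
    push the same transcript both ways in one mutant.
    """
    rng = np.random.default_rng(cfg.seed + 3) if rng is None else rng
    ids = [g.transcript_id for g in genes]
    n = len(ids)
    idx = pd.Index(ids, name="transcript_id")
    genotypes = ("wt", "bam", "aly", "can", "comr", "mip40")

    base = rng.lognormal(np.log(30.0), 0.8, n)
    changed_down = {t for v in truth.direct_targets.values() for t in v} | {
        t for v in truth.indirect_targets.values() for t in v
    }
    base = np.where(pd.Index(ids).isin(sorted(changed_down)),
                    rng.uniform(60, 300, n), base)

    expr = pd.DataFrame(index=idx)
    expr["fpkm_wt"] = base
    for geno in genotypes[1:]:
        noise = rng.lognormal(0.0, cfg.expression_noise_sigma, n)
        expr[f"fpkm_{geno}"] = base * noise
        expr[f"sig_{geno}"] = False

    for factor in ("can", "comr", "mip40"):
        mutant = factor
        down = set(truth.direct_targets[factor]) | set(
            truth.indirect_targets[factor])
        up = set(truth.repressed_by_mip40) if factor == "mip40" else set()
        both = down & up
        if both:
            raise ValueError(
                f"contradictory coupling in {mutant}: {sorted(both)[:5]}"
            )
        for t in sorted(down):
            fold = rng.uniform(12, 50)
            expr.loc[t, f"fpkm_{mutant}"] = expr.loc[t, "fpkm_wt"] / fold
            expr.loc[t, f"sig_{mutant}"] = True
        for t in sorted(up):
            fold = rng.uniform(8, 30)
            expr.loc[t, f"fpkm_{mutant}"] = (
                expr.loc[t, "fpkm_wt"] * fold + 10.0
            )
            expr.loc[t, f"sig_{mutant}"] = True
        expr[f"log2fc_{mutant}"] = np.log2(
            (expr[f"fpkm_{mutant}"] + 1) / (expr["fpkm_wt"] + 1)
        )

    tissues = ["testis", "ovary"] + [f"tissue{i}" for i in range(1, cfg.n_tissues - 1)]
    mat = pd.DataFrame(
        rng.normal(0.0, 1.0, (n, len(tissues))), index=idx, columns=tissues
    )
    testis = set(truth.testis_specific)
    ovary = set(truth.ovary_specific)
    others = [t for t in ids if t not in testis and t not in ovary]
    for rows, target in ((truth.testis_specific, "testis"),
                         (truth.ovary_specific, "ovary")):
        for t in rows:
            mat.loc[t, :] = -rng.uniform(0.2, 3.0, len(tissues))
            null_mask = rng.random(len(tissues)) < 0.3
            mat.loc[t, null_mask] = np.nan
            mat.loc[t, target] = rng.uniform(0.5, 3.0)
    # every non-specific transcript violates both rules in >= 1 tissue that
    # is neither testis nor ovary
    for t in others:
        mat.loc[t, rng.choice(tissues[2:])] = rng.uniform(0.1, 2.0)
    return expr, mat


# ---------------------------------------------------------------------------
# toy reads (for the GATC read-filter path only)

def reads_for_counts(
    fmap: FragmentMap,
    counts: np.ndarray,
    genome: Mapping[str, str],
    read_length: int = 36,
    rng: np.random.Generator | None = None,
) -> list[Read]:
    """Emit GATC-anchored reads reproducing ``counts`` exactly.

    Each fragment's reads alternate between plus-strand reads at its left
    boundary and minus-strand reads anchored at its right boundary (skipping
    boundaries that are chromosome ends rather than motifs).
    """
    rng = np.random.default_rng() if rng is None else rng
    reads: list[Read] = []
    for fid, chrom, start, end in fmap.iter_fragments():
        c = int(counts[fid])
        if c == 0:
            continue
        seq = genome[chrom]
        left_ok = seq[start : start + 4].upper() == "GATC"
        right_ok = seq[end : end + 4].upper() == "GATC"
        if not left_ok and not right_ok:
            raise ValueError(
                f"fragment {fid} has no motif boundary to anchor reads"
            )
        for i in range(c):
            use_left = left_ok and (i % 2 == 0 or not right_ok)
            if use_left:
                reads.append(Read(
                    sequence=seq[start : start + read_length],
                    chrom=chrom, position=start, strand="+",
                ))
            else:
                p = end + 3
                s = seq[max(0, p + 1 - read_length) : p + 1]
                reads.append(Read(
                    sequence=_revcomp(s), chrom=chrom, position=p,
                    strand="-",
                ))
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# one-call convenience bundle

@dataclass
class SimulatedStudy:
    cfg: SimConfig
    genome: dict
    genes: list
    fmap: FragmentMap
    truth: TruthSet
    counts: dict  # (factor, genotype) -> {(construct, rep): FragmentCounts}
    expression: pd.DataFrame
    tissue_matrix: pd.DataFrame

    @property
    def tss(self) -> pd.DataFrame:
        return tss_table(self.genes)


def simulate_study(cfg: SimConfig | None = None) -> SimulatedStudy:
    """Generate a complete study: genome, truth, counts for every profiled

    factor/genotype combination, expression and tissue matrix.
    """
    cfg = SimConfig() if cfg is None else cfg
    genome, genes = simulate_genome_and_genes(cfg)
    fmap = build_fragment_map(genome)
    truth = build_truth(cfg, fmap, genes)
    rng = np.random.default_rng(cfg.seed + 4)
    counts = {}
    for factor, geno in [("can", "wt"), ("comr", "wt")] + [
        ("mip40", g) for g in GENOTYPE_ORDER
    ]:
        counts[(factor, geno)] = simulate_counts(
            cfg, truth, fmap, factor, geno, rng
        )
    expr, tissue = simulate_expression_and_tissues(cfg, truth, genes, rng)
    return SimulatedStudy(
        cfg=cfg, genome=genome, genes=genes, fmap=fmap, truth=truth,
        counts=counts, expression=expr, tissue_matrix=tissue,
    )
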