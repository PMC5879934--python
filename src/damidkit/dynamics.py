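"""Cross-genotype binding dynamics of a shared factor (Mip40-style).

Profiling the same factor in a developmental genotype series — *bam*
(spermatogonia only), *aly* (tMAC-deficient spermatocytes), *can*
(tTAF-deficient spermatocytes) and wild type — gives each transcript a
boolean *presence pattern*: does a peak summit fall within +/- 300 bp of its
TSS in each genotype?  Transcripts with at least one presence are assigned to
six canonical dynamics groups; the two anchored patterns are group I
(bound in all four genotypes) and group II (bound only in spermatogonia,
pattern 1,0,0,0).  Patterns for groups III-VI are conventions shipped as a
configurable table: spermatocyte-acquired binding (III = wt only,
IV = can + wt) carries bam = 0 and wt = 1, spermatogonial binding
(V = bam + aly, VI = bam + can + wt) carries bam = 1.  Unmapped patterns are
"minor" (optionally merged to the nearest canonical pattern by Hamming
distance, ties staying minor).

The module also computes group-wise gene-set enrichment (e.g. testis- or
ovary-specific transcripts), the per-group repressed:activated ratio in a
mutant, and the tissue-specificity rule over a FlyAtlas-style log-ratio
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import PeakSet
from .targets import _chi2_or_exact, _sig_mask, down_fold, up_fold

GENOTYPE_ORDER = ("bam", "aly", "can", "wt")
DEFAULT_PRESENCE_WINDOW = 300

GROUPS = ("I", "II", "III", "IV", "V", "VI")

#: pattern (bam, aly, can, wt) -> group.  I and II are fixed by definition;
#: III-VI are shipped conventions consistent with the constraints that III/IV
#: acquire binding in spermatocytes (bam=0, wt=1) and V/VI bind already in
#: spermatogonia (bam=1).
DEFAULT_GROUP_PATTERNS: dict[tuple[int, int, int, int], str] = {
    (1, 1, 1, 1): "I",
    (1, 0, 0, 0): "II",
    (0, 0, 0, 1): "III",
    (0, 0, 1, 1): "IV",
    (1, 1, 0, 0): "V",
    (1, 0, 1, 1): "VI",
}


def _validate_mapping(mapping: Mapping[tuple[int, ...], str]) -> None:
    inv: dict[str, list[tuple[int, ...]]] = {}
    for pat, grp in mapping.items():
        inv.setdefault(grp, []).append(tuple(pat))
    if inv.get("I") != [(1, 1, 1, 1)]:
        raise ValueError("group I must be exactly the all-genotype pattern")
    if inv.get("II") != [(1, 0, 0, 0)]:
        raise ValueError("group II must be exactly the bam-only pattern")
    for grp in ("I", "II", "V", "VI"):
        for pat in inv.get(grp, []):
            if pat[0] != 1:
                raise ValueError(
                    f"group {grp} pattern {pat} violates spermatogonial "
                    "binding (bam bit must be 1)"
                )
    for grp in ("III", "IV"):
        for pat in inv.get(grp, []):
            if pat[0] != 0 or pat[3] != 1:
                raise ValueError(
                    f"group {grp} pattern {pat} violates spermatocyte-"
                    "acquired binding (bam=0, wt=1 required)"
                )


def presence_matrix(
    peaksets: Mapping[str, PeakSet],
    tss: pd.DataFrame,
    window: int = DEFAULT_PRESENCE_WINDOW,
    genotypes: Sequence[str] = GENOTYPE_ORDER,
) -> pd.DataFrame:
    """Transcripts x genotypes boolean matrix of TSS-proximal binding.

    A transcript is "present" in a genotype when a peak summit lies within
    +/- ``window`` bp of any of its TSSs (boundary inclusive).  All requested
    genotypes must be provided.  The full matrix is returned; grouping later
    drops all-zero rows.
    """
    missing = [g for g in genotypes if g not in peaksets]
    if missing:
        raise ValueError(f"missing peak sets for genotypes: {missing}")
    ids = pd.Index(tss["transcript_id"].unique())
    data = {}
    for g in genotypes:
        ps = peaksets[g]
        present = np.zeros(len(ids), dtype=bool)
        lookup = {t: i for i, t in enumerate(ids)}
        for chrom, sub in tss.groupby("chrom", sort=False):
            s = ps.peaks[ps.peaks["chrom"] == chrom]
            if len(s) == 0:
                continue
            summits = np.sort(s["summit_pos"].to_numpy())
            pos = sub["tss"].to_numpy()
            lo = np.searchsorted(summits, pos - window)
            hi = np.searchsorted(summits, pos + window, side="right")
            hit = hi > lo
            for t in sub["transcript_id"].to_numpy()[hit]:
                present[lookup[t]] = True
        data[g] = present
    return pd.DataFrame(data, index=ids, columns=list(genotypes))


@dataclass
class DynamicsAssignment:
    """Group label per retained transcript, plus the mapping used."""

    labels: pd.Series  # transcript -> group ("I".."VI" or "minor")
    patterns: pd.DataFrame  # retained presence rows
    mapping: dict

    def group_sizes(self) -> pd.Series:
        order = list(GROUPS) + ["minor"]
        return self.labels.value_counts().reindex(order, fill_value=0)

    def members(self, group: str) -> pd.Index:
        return self.labels.index[self.labels == group]


def assign_groups(
    pm: pd.DataFrame,
    mapping: Mapping[tuple[int, int, int, int], str] | None = None,
    merge_minor: bool = False,
) -> DynamicsAssignment:
    """Map presence patterns to dynamics groups.

    All-zero rows are dropped before grouping.  Patterns absent from the
    mapping become "minor"; with ``merge_minor`` they are reassigned to the
    canonical pattern at minimal Hamming distance (staying minor on ties).
    Assignment is a pure function of the pattern.
    """
    mapping = dict(DEFAULT_GROUP_PATTERNS if mapping is None else mapping)
    _validate_mapping(mapping)
    retained = pm[pm.any(axis=1)]
    pats = [tuple(int(v) for v in row) for row in retained.to_numpy()]
    labels = []
    canon = list(mapping.items())
    for pat in pats:
        grp = mapping.get(pat)
        if grp is None and merge_minor:
            dists = [sum(a != b for a, b in zip(pat, cp)) for cp, _ in canon]
            best = min(dists)
            winners = {canon[i][1] for i, d in enumerate(dists) if d == best}
            grp = winners.pop() if len(winners) == 1 else None
        labels.append(grp if grp is not None else "minor")
    return DynamicsAssignment(
        labels=pd.Series(labels, index=retained.index, name="group"),
        patterns=retained,
        mapping=mapping,
    )


def group_geneset_enrichment(
    assign: DynamicsAssignment,
    geneset: Sequence[str],
    universe: Sequence[str],
) -> pd.DataFrame:
    """Per-group over/under-representation of a gene set.

    Expected membership = |group| * |geneset| / |universe|; significance from
    a two-sided chi-square on (in group) x (in geneset) over the universe
    (Fisher exact for small expected cells).  Empty groups yield NA rows.
    """
    universe = pd.Index(pd.unique(pd.Series(list(universe))))
    geneset = pd.Index(pd.unique(pd.Series(list(geneset))))
    if not geneset.isin(universe).all():
        raise ValueError("geneset must be a subset of the universe")
    rows = []
    for grp in GROUPS:
        members = assign.members(grp).intersection(universe)
        n_g = len(members)
        if n_g == 0:
            rows.append({"group": grp, "n_group": 0, "observed": np.nan,
                         "expected": np.nan, "fold": np.nan, "p_value": np.nan})
            continue
        obs = int(members.isin(geneset).sum())
        exp = n_g * len(geneset) / len(universe)
        rest = universe.difference(members)
        table = np.array(
            [[obs, n_g - obs],
             [int(rest.isin(geneset).sum()),
              len(rest) - int(rest.isin(geneset).sum())]]
        )
        p, _ = _chi2_or_exact(table)
        rows.append({
            "group": grp, "n_group": n_g, "observed": obs, "expected": exp,
            "fold": obs / exp if exp > 0 else np.nan, "p_value": p,
        })
    return pd.DataFrame(rows)


def repression_activation_ratio(
    assign: DynamicsAssignment,
    expr: pd.DataFrame,
    mutant: str,
    fold: float = 4.0,
    pseudocount: float = 1.0,
    require_sig: bool = True,
) -> pd.DataFrame:
    """Repressed:activated transcript ratio per dynamics group.

    "Repressed by the factor" = up-regulated in the mutant (>= ``fold``),
    "activated" = down-regulated; only transcripts changing at least
    ``fold`` either way are retained.  The expected ratio is the global
    up:down ratio over all retained transcripts; each group is tested with a
    chi-square on the 2x2 of (group vs rest) x (up vs down).  Groups with no
    retained transcripts give NA.
    """
    sig = _sig_mask(expr, mutant, require_sig)
    up = (up_fold(expr, mutant, pseudocount) >= fold) & sig
    dn = (down_fold(expr, mutant, pseudocount) >= fold) & sig
    retained = expr.index[up | dn]
    up_ids = set(expr.index[up])
    global_up = int(up.sum())
    global_dn = int(dn.sum())
    expected_ratio = global_up / global_dn if global_dn else np.nan
    rows = []
    for grp in GROUPS:
        members = assign.members(grp)
        changed = members.intersection(retained)
        if len(changed) == 0:
            rows.append({"group": grp, "n_up": 0, "n_down": 0,
                         "ratio": np.nan, "expected_ratio": expected_ratio,
                         "p_value": np.nan})
            continue
        n_up = int(sum(t in up_ids for t in changed))
        n_dn = len(changed) - n_up
        table = np.array(
            [[n_up, n_dn],
             [global_up - n_up, global_dn - n_dn]]
        )
        p, _ = _chi2_or_exact(table)
        rows.append({
            "group": grp, "n_up": n_up, "n_down": n_dn,
            "ratio": n_up / n_dn if n_dn else np.inf,
            "expected_ratio": expected_ratio,
            "p_value": p,
        })
    return pd.DataFrame(rows)


def tissue_specific_transcripts(
    matrix: pd.DataFrame, target_tissue: str
) -> pd.Index:
    """Transcripts specific to ``target_tissue`` under the log-ratio rule.

    ``matrix`` is transcripts x tissues of log2(tissue / whole-organism
    mean), NA meaning null expression.  A transcript qualifies iff its
    target-tissue ratio is > 0 and every other tissue is either < 0 or
    null/missing.
    """
    if target_tissue not in matrix.columns:
        raise ValueError(f"tissue {target_tissue!r} absent from the matrix")
    others = matrix.drop(columns=[target_tissue])
    if others.shape[1] == 0:
        raise ValueError("matrix needs at least one non-target tissue")
    up_in_target = matrix[target_tissue] > 0
    down_elsewhere = ((others < 0) | others.isna()).all(axis=1)
    return matrix.index[up_in_target & down_elsewhere]
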