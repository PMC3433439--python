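"""Positional candidates by eQTL-pQTL collocation, and correlation matrices.

A transcript is a positional candidate for a trait when a large fraction
of its eQTLs fall into 10 cM map bins that also contain the trait's pQTLs,
and that fraction beats a randomization null in which the same number of
eQTLs is scattered uniformly over the map bins.  Composite candidates are
significant for every trait of a group (growth or resistance).  Trait x
trait matrices of Pearson correlations are computed both for phenotypes
and for per-transcript collocation profiles ("QTL correlations").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth import TRAIT_GROUPS


@dataclass
class BinIndex:
    """Half-open ``[k*w, (k+1)*w)`` bins from each linkage group's origin."""

    marker_bins: pd.DataFrame  # index marker; columns lg, bin
    n_bins: int  # bins spanned by the map, summed over linkage groups
    width_cm: float

    @property
    def mean_markers_per_bin(self) -> float:
        occupied = self.marker_bins.groupby(["lg", "bin"]).size()
        return float(len(self.marker_bins) / len(occupied))

    def bins_of(self, qtl: pd.DataFrame) -> pd.Series:
        """Map QTL records to (lg, bin) tuples via their marker."""
        mb = self.marker_bins
        return pd.Series(
            list(zip(mb.loc[qtl["marker"], "lg"], mb.loc[qtl["marker"], "bin"])),
            index=qtl.index,
        )


def build_bins(map_df: pd.DataFrame, width: float = 10.0) -> BinIndex:
    """Assign every marker to its 10 cM (by default) map bin."""
    if width <= 0:
        raise ValueError("bin width must be > 0")
    mb = map_df.set_index("marker")[["lg", "cm"]].copy()
    mb["bin"] = np.floor(mb["cm"] / width).astype(int)
    n_bins = int(sum(int(sub["bin"].max()) + 1 for _, sub in mb.groupby("lg")))
    return BinIndex(marker_bins=mb[["lg", "bin"]], n_bins=n_bins, width_cm=width)


def collocation_fraction(
    eqtl_bins: Sequence[tuple], pqtl_bins: set[tuple]
) -> float:
    """Fraction of a transcript's eQTLs whose bin holds a pQTL of the trait."""
    eqtl_bins = list(eqtl_bins)
    if not eqtl_bins:
        raise ValueError("transcript has no eQTLs; collocation undefined")
    hits = sum(1 for b in eqtl_bins if b in pqtl_bins)
    return hits / len(eqtl_bins)


def permutation_pvalue(
    n_eqtls: int,
    trait_pqtl_bins: set[tuple],
    bins: BinIndex,
    f_obs: float,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Randomization p-value for an observed collocation fraction.

    Null: the transcript's ``n_eqtls`` eQTLs land independently and
    uniformly over all map bins (with replacement); the null fraction is
    recomputed each time and compared with ``f_obs``.  With a +1 finite-
    sampling correction, p = (1 + #{f* >= f_obs}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    k = len(trait_pqtl_bins)
    # uniform iid placement over bins: the hit count is Binomial(n, k/B)
    hits = rng.binomial(n_eqtls, k / bins.n_bins, size=n_perm)
    f_null = hits / n_eqtls
    exceed = int(np.sum(f_null >= f_obs - 1e-12))
    return (1 + exceed) / (n_perm + 1)


def candidate_table(
    eqtl: pd.DataFrame,
    pqtl: pd.DataFrame,
    bins: BinIndex,
    min_frac: float = 0.4,
    alpha: float = 0.05,
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Collocation fraction and permutation p for every (transcript, trait).

    A record is flagged ``candidate`` when f >= ``min_frac`` and
    p <= ``alpha``.  Null draws are shared across transcripts with the
    same eQTL count for a trait, which leaves the p-values unchanged and
    makes 10,000 randomizations cheap.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if eqtl.empty:
        return pd.DataFrame(
            columns=["transcript", "trait", "n_eqtls", "frac", "pvalue", "candidate"]
        )
    e_bins = bins.bins_of(eqtl)
    eqtl_by_transcript: dict[str, list[tuple]] = {}
    for t, b in zip(eqtl["trait"], e_bins):
        eqtl_by_transcript.setdefault(t, []).append(b)

    rows = []
    for trait, sub in pqtl.groupby("trait"):
        tb = set(bins.bins_of(sub))
        k = len(tb)
        null_cache: dict[int, np.ndarray] = {}
        for transcript, tbins in eqtl_by_transcript.items():
            n = len(tbins)
            f = collocation_fraction(tbins, tb)
            if n not in null_cache:
                null_cache[n] = np.sort(rng.binomial(n, k / bins.n_bins, size=n_perm))
            hits_null = null_cache[n]
            need = int(np.ceil(f * n - 1e-9))
            exceed = n_perm - int(np.searchsorted(hits_null, need, side="left"))
            p = (1 + exceed) / (n_perm + 1)
            rows.append((transcript, trait, n, f, p, (f >= min_frac) and (p <= alpha)))
    out = pd.DataFrame(
        rows, columns=["transcript", "trait", "n_eqtls", "frac", "pvalue", "candidate"]
    )
    return out.sort_values(["trait", "transcript"]).reset_index(drop=True)


@dataclass
class CompositeResult:
    group_candidates: dict[str, list[str]]
    per_trait_candidates: dict[str, list[str]]
    overlap_pct: dict[tuple[str, str], float]


def composite_candidates(
    candidates: pd.DataFrame,
    trait_groups: Mapping[str, Sequence[str]] | None = None,
    alpha_each: float = 0.1,
) -> CompositeResult:
    """Transcripts significant for every trait of a group.

    A transcript is a composite candidate for a group when its collocation
    p-value is <= ``alpha_each`` for each of the group's traits.  Per-trait
    candidate lists use the table's own ``candidate`` flag, and the
    cross-group overlap percentages report how many of one group's
    per-trait candidates are also candidates for the other group's traits.
    """
    groups = dict(trait_groups) if trait_groups is not None else dict(TRAIT_GROUPS)
    known = set(candidates["trait"]) if not candidates.empty else set()
    per_trait: dict[str, list[str]] = {}
    if not candidates.empty:
        for trait, sub in candidates.groupby("trait"):
            per_trait[trait] = sorted(sub.loc[sub["candidate"], "transcript"])
    group_cands: dict[str, list[str]] = {}
    for gname, members in groups.items():
        unknown = [t for t in members if known and t not in known]
        if unknown:
            raise ValueError(f"trait group {gname!r} names unknown traits: {unknown}")
        if candidates.empty:
            group_cands[gname] = []
            continue
        ok = None
        for trait in members:
            sub = candidates[candidates["trait"] == trait]
            sig = set(sub.loc[sub["pvalue"] <= alpha_each, "transcript"])
            ok = sig if ok is None else (ok & sig)
        group_cands[gname] = sorted(ok or [])
    overlap: dict[tuple[str, str], float] = {}
    gnames = list(groups)
    for a in gnames:
        for b in gnames:
            if a == b:
                continue
            set_a = set().union(*[set(per_trait.get(t, [])) for t in groups[a]])
            set_b = set().union(*[set(per_trait.get(t, [])) for t in groups[b]])
            overlap[(a, b)] = 100.0 * len(set_a & set_b) / len(set_a) if set_a else float("nan")
    return CompositeResult(group_cands, per_trait, overlap)


def collocation_profile(candidates: pd.DataFrame) -> pd.DataFrame:
    """Transcripts x traits matrix of collocation fractions."""
    return candidates.pivot(index="transcript", columns="trait", values="frac")


def qtl_correlation_matrix(
    candidates: pd.DataFrame,
    trait_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Pearson correlations between traits' collocation profiles.

    For each trait, the vector over transcripts of collocation fractions
    is the trait's "QTL profile"; the matrix holds pairwise Pearson
    correlations of these profiles (NA where a profile has zero variance).
    When ``trait_groups`` is given, the aggregate group-vs-group
    correlation (mean profile per group, e.g. growth vs resistance) is
    also returned.
    """
    prof = collocation_profile(candidates)
    if len(prof) < 3:
        raise ValueError("need >= 3 transcripts with defined collocation fractions")
    corr = prof.corr(method="pearson", min_periods=3)
    aggregates: dict[str, float] = {}
    if trait_groups:
        gnames = list(trait_groups)
        for i, a in enumerate(gnames):
            for b in gnames[i + 1 :]:
                va = prof[[t for t in trait_groups[a] if t in prof.columns]].mean(axis=1)
                vb = prof[[t for t in trait_groups[b] if t in prof.columns]].mean(axis=1)
                if va.std() == 0 or vb.std() == 0:
                    aggregates[f"{a}_vs_{b}"] = float("nan")
                else:
                    aggregates[f"{a}_vs_{b}"] = float(stats.pearsonr(va, vb)[0])
    return corr, aggregates


def phenotypic_correlation_matrix(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations between phenotypic traits."""
    return phenotypes.corr(method="pearson", min_periods=3)
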