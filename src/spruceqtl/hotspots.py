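"""Trans-eQTL hotspot detection and hub identification.

The per-marker eQTL density is tested against uniformity (chi-square
goodness of fit), a randomization procedure places all detected eQTLs
uniformly over the marker loci to calibrate the largest cluster expected
by chance, hotspots are declared where the count exceeds the expected
average by a configurable factor, and hubs are hotspots that additionally
carry several phenotypic-trait QTLs in the same 10 cM bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def count_per_marker(eqtl: pd.DataFrame, map_df: pd.DataFrame) -> pd.Series:
    """Count eQTL records at each marker; markers without any get 0."""
    markers = map_df["marker"]
    if not eqtl.empty:
        unknown = set(eqtl["marker"]) - set(markers)
        if unknown:
            raise ValueError(f"eQTL records at unknown markers: {sorted(unknown)}")
    counts = eqtl["marker"].value_counts() if not eqtl.empty else pd.Series(dtype=int)
    out = counts.reindex(markers, fill_value=0).astype(int)
    out.index.name = "marker"
    out.name = "n_eqtl"
    return out


def uniform_gof(counts: pd.Series | np.ndarray) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of per-marker counts against uniformity.

    Returns (chi2, df, p) with df = number of markers - 1.
    """
    o = np.asarray(counts, dtype=float)
    if o.size < 2:
        raise ValueError("need at least two markers")
    total = o.sum()
    if total <= 0:
        raise ValueError("no eQTLs to test")
    e = total / o.size
    chi2 = float(np.sum((o - e) ** 2 / e))
    df = o.size - 1
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


@dataclass
class RandomizationResult:
    """Null distribution of the largest eQTL cluster under uniform placement."""

    overall_max: int
    q95: float
    maxima: np.ndarray = field(repr=False)

    @property
    def mean_max(self) -> float:
        return float(self.maxima.mean())


def randomization_max(
    n_eqtl: int,
    n_markers: int,
    replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> RandomizationResult:
    """Largest per-marker count when all eQTLs are placed uniformly at random.

    Each replicate drops ``n_eqtl`` items independently and uniformly over
    ``n_markers`` loci (a multinomial draw) and records the maximum cell
    count.  Both the overall maximum across replicates and the 95th
    percentile of per-replicate maxima are reported.
    """
    if n_eqtl < 1 or n_markers < 1 or replicates < 1:
        raise ValueError("n_eqtl, n_markers and replicates must all be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.full(n_markers, 1.0 / n_markers)
    maxima = np.empty(replicates, dtype=np.int64)
    chunk = max(1, min(replicates, int(5e7 // max(1, n_markers))))
    done = 0
    while done < replicates:
        k = min(chunk, replicates - done)
        draws = rng.multinomial(n_eqtl, p, size=k)
        maxima[done : done + k] = draws.max(axis=1)
        done += k
    return RandomizationResult(
        overall_max=int(maxima.max()),
        q95=float(np.percentile(maxima, 95)),
        maxima=maxima,
    )


def declare_hotspots(counts: pd.Series, factor: float = 1.5) -> tuple[int, pd.Series]:
    """Flag markers whose eQTL count strictly exceeds ``factor`` x average.

    The cutoff is the expected (uniform) per-marker count times ``factor``,
    rounded to the nearest integer; a marker is a hotspot when its count
    exceeds the cutoff.
    """
    total = int(np.asarray(counts).sum())
    expected = total / len(counts)
    cutoff = int(round(factor * expected))
    flags = counts > cutoff
    flags.name = "hotspot"
    return cutoff, flags


def find_hubs(
    hotspot_flags: pd.Series,
    pqtl: pd.DataFrame,
    map_df: pd.DataFrame,
    counts: pd.Series | None = None,
    bin_cm: float = 10.0,
    min_pqtl: int = 3,
    trait_groups: Mapping[str, Sequence[str]] | None = None,
) -> pd.DataFrame:
    """Hotspot markers carrying at least ``min_pqtl`` pQTLs in their bin.

    For each hub the supporting pQTL traits are listed and allele-effect
    sign concordance is reported: within each parent, whether all pQTL
    allele effects at the hub bin share one sign (and, when ``trait_groups``
    defines growth/resistance sets, whether those two groups share sign).
    Per-parent assessment matters because the labeling of a parent's two
    alleles is arbitrary, so signs are only comparable within a parent.
    """
    info = map_df.set_index("marker")
    hubs = []
    pq = pqtl.copy()
    if not pq.empty:
        pq["bin"] = np.floor(pq["cm"] / bin_cm).astype(int)
    for marker in hotspot_flags.index[hotspot_flags.astype(bool)]:
        lg = info.loc[marker, "lg"]
        b = int(np.floor(info.loc[marker, "cm"] / bin_cm))
        here = pq[(pq["lg"] == lg) & (pq["bin"] == b)] if not pq.empty else pq
        if len(here) < min_pqtl:
            continue
        concordant = True
        for _, sub in here.groupby("parent"):
            eff = sub["allele_effect"].to_numpy()
            eff = eff[eff != 0.0]
            if eff.size and not (np.all(eff > 0) or np.all(eff < 0)):
                concordant = False
        group_concordant = None
        if trait_groups is not None:
            group_concordant = True
            for _, sub in here.groupby("parent"):
                signs = {}
                for gname, members in trait_groups.items():
                    eff = sub.loc[sub["trait"].isin(members), "allele_effect"].to_numpy()
                    eff = eff[eff != 0.0]
                    if eff.size:
                        if not (np.all(eff > 0) or np.all(eff < 0)):
                            group_concordant = False
                        signs[gname] = float(np.sign(eff.sum()))
                if len(set(signs.values())) > 1:
                    group_concordant = False
        hubs.append(
            {
                "marker": marker,
                "lg": int(lg),
                "cm": float(info.loc[marker, "cm"]),
                "n_eqtl": int(counts.loc[marker]) if counts is not None else pd.NA,
                "n_pqtl": int(len(here)),
                "pqtl_traits": ",".join(sorted(here["trait"].unique())),
                "sign_concordant": bool(concordant),
                "group_sign_concordant": group_concordant,
            }
        )
    return pd.DataFrame(
        hubs,
        columns=[
            "marker", "lg", "cm", "n_eqtl", "n_pqtl", "pqtl_traits",
            "sign_concordant", "group_sign_concordant",
        ],
    )


def plot_density(
    counts: pd.Series,
    map_df: pd.DataFrame,
    pqtl: pd.DataFrame | None = None,
    cutoff: int | None = None,
    path=None,
):
    """eQTL density along the genome with pQTL positions overlaid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    info = map_df.reset_index(drop=True)
    offsets = {}
    offset = 0.0
    for lg, sub in info.groupby("lg"):
        offsets[lg] = offset
        offset += sub["cm"].max() + 10.0
    x = info.apply(lambda r: offsets[r["lg"]] + r["cm"], axis=1)
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.bar(x, counts.reindex(info["marker"]).to_numpy(), width=2.0, color="0.3")
    if cutoff is not None:
        ax.axhline(cutoff, color="red", lw=0.8, label=f"hotspot cutoff {cutoff}")
    if pqtl is not None and not pqtl.empty:
        px = [offsets[r.lg] + r.cm for r in pqtl.itertuples()]
        ax.plot(px, [0] * len(px), marker="^", linestyle="none", color="tab:blue",
                markersize=4, label="pQTL")
    for lg, off in offsets.items():
        ax.text(off, ax.get_ylim()[1] * 0.95, f"LG{lg}", fontsize=7)
    ax.set_xlabel("map position (cM, linkage groups concatenated)")
    ax.set_ylabel("eQTL count per marker")
    ax.legend(loc="upper right", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
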