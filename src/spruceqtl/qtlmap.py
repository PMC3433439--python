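"""Per-parent single-marker LOD mapping for phenotypic and expression traits.

Each heterozygous parent of the factorial is scanned separately: progeny
are split by which of the parent's two alleles they inherited at a marker,
and a Gaussian two-class likelihood compares class means against the
no-association model, giving LOD = (n/2) * log10(RSS0 / RSS1).  Significant
records are thinned to one QTL per 10 cM bin so two adjacent markers linked
to one QTL are not both reported.
"""

from __future__ import annotations

import logging
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

QTL_COLUMNS = [
    "trait",
    "marker",
    "lg",
    "cm",
    "parent",
    "lod",
    "allele_effect",
    "pct_var",
    "n_used",
]

#: LOD assigned when the two-class model fits perfectly (RSS1 = 0)
LOD_CAP = 300.0


class ScanResult(NamedTuple):
    lod: float
    allele_effect: float
    pct_var: float
    n_used: int


def single_marker_scan(
    trait: np.ndarray, codes: np.ndarray, lod_cap: float = LOD_CAP
) -> ScanResult:
    """Gaussian two-class single-marker test at one marker for one parent.

    ``codes`` holds transmission classes 1/2 (NaN = missing); missing
    values are dropped pairwise.  LOD = (n/2) log10(RSS0/RSS1) with RSS0
    about the grand mean and RSS1 about the two class means; the allele
    effect is half the difference of class means and pct_var the percent
    of trait variance explained.
    """
    y = np.asarray(trait, dtype=float)
    c = np.asarray(codes, dtype=float)
    keep = ~(np.isnan(y) | np.isnan(c))
    y, c = y[keep], c[keep]
    in1 = c == 1.0
    in2 = c == 2.0
    n1, n2 = int(in1.sum()), int(in2.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"need >=2 progeny per transmission class (got {n1} and {n2})"
        )
    n = n1 + n2
    m1 = y[in1].mean()
    m2 = y[in2].mean()
    rss0 = float(np.sum((y - y.mean()) ** 2))
    rss1 = float(np.sum((y[in1] - m1) ** 2) + np.sum((y[in2] - m2) ** 2))
    if rss0 <= 0.0:
        return ScanResult(0.0, 0.0, 0.0, n)
    if rss1 <= 0.0:
        return ScanResult(float(lod_cap), (m1 - m2) / 2.0, 100.0, n)
    lod = min(float(lod_cap), (n / 2.0) * np.log10(rss0 / rss1))
    pct = 100.0 * (1.0 - rss1 / rss0)
    return ScanResult(lod, (m1 - m2) / 2.0, pct, n)


def _scan_block(
    Y: np.ndarray, codes: np.ndarray, lod_cap: float = LOD_CAP
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int] | None:
    """Vectorized scan of one marker against a traits matrix (no NaNs in Y).

    Returns (lod, allele_effect, pct_var, n_used) arrays over traits, or
    None if a transmission class has fewer than two progeny.
    """
    in1 = codes == 1.0
    in2 = codes == 2.0
    n1, n2 = int(in1.sum()), int(in2.sum())
    if n1 < 2 or n2 < 2:
        return None
    keep = in1 | in2
    Yk = Y[keep]
    n = n1 + n2
    m1 = Y[in1].mean(axis=0)
    m2 = Y[in2].mean(axis=0)
    grand = Yk.mean(axis=0)
    rss0 = np.sum((Yk - grand) ** 2, axis=0)
    rss1 = np.sum((Y[in1] - m1) ** 2, axis=0) + np.sum((Y[in2] - m2) ** 2, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lod = (n / 2.0) * np.log10(rss0 / rss1)
        pct = 100.0 * (1.0 - rss1 / rss0)
    lod = np.where(rss1 <= 0.0, lod_cap, lod)
    pct = np.where(rss1 <= 0.0, 100.0, pct)
    lod = np.where(rss0 <= 0.0, 0.0, np.minimum(lod, lod_cap))
    pct = np.clip(np.where(rss0 <= 0.0, 0.0, pct), 0.0, 100.0)
    return lod, (m1 - m2) / 2.0, pct, n


def center_within_cross(traits: pd.DataFrame | pd.Series, cross_of: pd.Series):
    """Remove the cross (family) main effect by centering within cross."""
    aligned = cross_of.reindex(traits.index)
    if isinstance(traits, pd.Series):
        return traits - traits.groupby(aligned).transform("mean")
    return traits - traits.groupby(aligned).transform("mean")


def _bin_filter(records: pd.DataFrame, bin_cm: float) -> pd.DataFrame:
    """Keep the max-LOD marker per (trait, parent, lg, bin); ties -> smaller cM."""
    if records.empty:
        return records
    out = records.copy()
    out["bin"] = np.floor(out["cm"] / bin_cm).astype(int)
    out = out.sort_values(
        ["trait", "parent", "lg", "bin", "lod", "cm"],
        ascending=[True, True, True, True, False, True],
    )
    out = out.drop_duplicates(["trait", "parent", "lg", "bin"], keep="first")
    return out.drop(columns="bin").reset_index(drop=True)


def _map_matrix(
    traits: pd.DataFrame,
    transmissions: Mapping[str, pd.DataFrame],
    map_df: pd.DataFrame,
    threshold: float,
    bin_cm: float,
    cross_of: pd.Series | None,
    lod_cap: float,
    min_progeny: int,
    log_label: str,
) -> pd.DataFrame:
    if map_df.empty:
        raise ValueError("empty genetic map")
    if cross_of is not None:
        traits = center_within_cross(traits, cross_of)
    marker_info = map_df.set_index("marker")
    frames = []
    for parent, tm in transmissions.items():
        common = traits.index.intersection(tm.index)
        if len(common) < min_progeny:
            raise ValueError(
                f"parent {parent!r}: only {len(common)} progeny with trait data "
                f"(need >= {min_progeny})"
            )
        Y = traits.loc[common].to_numpy(dtype=float)
        col_ok = ~np.isnan(Y).any(axis=0)
        markers = [m for m in tm.columns if m in marker_info.index]
        codes_all = tm.loc[common, markers].to_numpy(dtype=float)
        rows = []
        for j, marker in enumerate(markers):
            res = _scan_block(Y[:, col_ok], codes_all[:, j], lod_cap)
            if res is None:
                logger.debug("%s: marker %s skipped for parent %s (empty class)",
                             log_label, marker, parent)
                continue
            lod, eff, pct, n = res
            hit = np.flatnonzero(lod >= threshold)
            if hit.size == 0:
                continue
            names = traits.columns[col_ok][hit]
            info = marker_info.loc[marker]
            for t, l, e, p in zip(names, lod[hit], eff[hit], pct[hit]):
                rows.append((t, marker, int(info["lg"]), float(info["cm"]),
                             parent, float(l), float(e), float(p), n))
        if rows:
            frames.append(pd.DataFrame(rows, columns=QTL_COLUMNS))
        logger.info("%s: parent %s scanned (%d traits x %d markers)",
                    log_label, parent, int(col_ok.sum()), len(markers))
    if not frames:
        return pd.DataFrame(columns=QTL_COLUMNS)
    records = pd.concat(frames, ignore_index=True)
    return _bin_filter(records, bin_cm)


def map_trait(
    trait: pd.Series,
    transmissions: Mapping[str, pd.DataFrame],
    map_df: pd.DataFrame,
    threshold: float = 3.84,
    bin_cm: float = 10.0,
    cross_of: pd.Series | None = None,
    lod_cap: float = LOD_CAP,
    min_progeny: int = 20,
) -> pd.DataFrame:
    """Scan one trait at every informative marker for every parent.

    Records with LOD >= ``threshold`` are kept and thinned to the best
    marker per (parent, linkage group, ``bin_cm`` bin).  When ``cross_of``
    is given the trait is first centered within cross, so crosses sharing
    a parent pool into that parent's scan without a family main effect.
    """
    name = trait.name or "trait"
    df = trait.dropna().to_frame(name)
    return _map_matrix(
        df, transmissions, map_df, threshold, bin_cm, cross_of, lod_cap,
        min_progeny, log_label=str(name),
    )


def map_phenotypes(
    phenotypes: pd.DataFrame,
    transmissions: Mapping[str, pd.DataFrame],
    map_df: pd.DataFrame,
    threshold: float = 3.84,
    bin_cm: float = 10.0,
    cross_of: pd.Series | None = None,
    lod_cap: float = LOD_CAP,
) -> pd.DataFrame:
    """Map every phenotype column; ordinal traits enter as numeric codes."""
    frames = [
        map_trait(phenotypes[c], transmissions, map_df, threshold, bin_cm,
                  cross_of, lod_cap)
        for c in phenotypes.columns
    ]
    frames = [f for f in frames if not f.empty]
    if not frames:
        return pd.DataFrame(columns=QTL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def map_all_expression(
    expression: pd.DataFrame,
    transmissions: Mapping[str, pd.DataFrame],
    map_df: pd.DataFrame,
    threshold: float = 3.84,
    bin_cm: float = 10.0,
    cross_of: pd.Series | None = None,
    lod_cap: float = LOD_CAP,
) -> pd.DataFrame:
    """Map every transcript in one vectorized pass, returning one eQTL table."""
    if expression.shape[1] == 0:
        return pd.DataFrame(columns=QTL_COLUMNS)
    return _map_matrix(
        expression, transmissions, map_df, threshold, bin_cm, cross_of,
        lod_cap, min_progeny=20, log_label="expression",
    )


def classify_cis_trans(
    eqtl: pd.DataFrame,
    transcript_locations: pd.DataFrame | None,
    window_cm: float = 10.0,
) -> pd.DataFrame:
    """Label each eQTL cis or trans against the transcript's own position.

    cis: the eQTL marker lies on the transcript's linkage group within
    ``window_cm``; trans otherwise; 'unknown' when no location is given.
    """
    out = eqtl.copy()
    if transcript_locations is None or out.empty:
        out["regulation"] = "unknown"
        return out
    loc = transcript_locations
    out = out.merge(
        loc.rename(columns={"lg": "t_lg", "cm": "t_cm"}),
        how="left", left_on="trait", right_index=True,
    )
    known = out["t_lg"].notna()
    same_lg = known & (out["lg"] == out["t_lg"])
    near = same_lg & ((out["cm"] - out["t_cm"]).abs() <= window_cm)
    out["regulation"] = np.where(~known, "unknown", np.where(near, "cis", "trans"))
    return out.drop(columns=["t_lg", "t_cm"])
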