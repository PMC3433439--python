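"""Distant-pair design for two-color hybridizations.

Within each full-sib cross, progeny are paired on the same array so that
the genetic distance between co-hybridized samples — the proportion of
segregating loci at which the two trees inherited different parental
allele combinations — is maximized by an exact maximum-weight perfect
matching.  Dyes are then balanced across replicate blocks and fabrication
batches.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import networkx as nx

logger = logging.getLogger(__name__)


def genetic_distance_matrix(
    transmissions: dict[str, pd.DataFrame],
    individuals: pd.Index | list | None = None,
) -> pd.DataFrame:
    """Pairwise mismatch proportion over shared segregating loci.

    For each pair of progeny, the distance is the proportion of loci --
    stacked over all parents' transmission matrices -- at which both have
    calls and the transmitted-allele codes differ.  Pairs with no shared
    genotyped locus get NaN (and are excluded from pairing).
    """
    mats = []
    if individuals is None:
        individuals = pd.Index(
            sorted(set().union(*[set(tm.index) for tm in transmissions.values()]))
        )
    individuals = pd.Index(individuals)
    for parent in sorted(transmissions):
        tm = transmissions[parent].reindex(individuals)
        mats.append(tm.to_numpy(dtype=float))
    G = np.concatenate(mats, axis=1)  # individuals x (parents * markers)
    valid = ~np.isnan(G)
    Gz = np.nan_to_num(G)
    n = len(individuals)
    shared = valid.astype(float) @ valid.astype(float).T
    # agreement count over shared loci: loci where both valid and codes equal
    eq1 = (valid & (Gz == 1.0)).astype(float)
    eq2 = (valid & (Gz == 2.0)).astype(float)
    agree = eq1 @ eq1.T + eq2 @ eq2.T
    with np.errstate(invalid="ignore", divide="ignore"):
        d = 1.0 - agree / shared
    d[shared == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=individuals, columns=individuals)


def optimal_pairing(
    distance: pd.DataFrame, cross_of: pd.Series
) -> pd.DataFrame:
    """Maximum-weight perfect matching of progeny within each cross.

    Solved exactly (blossom algorithm); with an odd cross size one
    individual is left unpaired with a logged warning.  Returns one row
    per array with columns ``cross``, ``ind_a``, ``ind_b``, ``distance``.
    """
    rows = []
    for cross, members in cross_of.groupby(cross_of):
        ids = [i for i in members.index if i in distance.index]
        if not ids:
            logger.warning("cross %s empty; skipped", cross)
            continue
        if len(ids) % 2:
            logger.warning("cross %s has odd size %d; one individual left unpaired",
                           cross, len(ids))
        g = nx.Graph()
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                w = distance.loc[a, b]
                if not np.isnan(w):
                    g.add_edge(a, b, weight=float(w))
        matching = nx.max_weight_matching(g, maxcardinality=True)
        for a, b in sorted(tuple(sorted(p)) for p in matching):
            rows.append((cross, a, b, float(distance.loc[a, b])))
    plan = pd.DataFrame(rows, columns=["cross", "ind_a", "ind_b", "distance"])
    return plan.sort_values(["cross", "ind_a"]).reset_index(drop=True)


def _random_matching_weight(
    ids: list, distance: pd.DataFrame, rng: np.random.Generator
) -> float:
    perm = rng.permutation(len(ids))
    total = 0.0
    for i in range(0, len(ids) - 1, 2):
        total += float(distance.loc[ids[perm[i]], ids[perm[i + 1]]])
    return total


def improvement_over_random(
    plan: pd.DataFrame,
    distance: pd.DataFrame,
    cross_of: pd.Series,
    n_random: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Percent gain of the optimal pairing over random within-cross pairing.

    improvement = 100 * (W_opt - mean W_random) / mean W_random, with the
    random matchings drawn uniformly within each cross.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w_opt = float(plan["distance"].sum())
    paired = set(plan["ind_a"]) | set(plan["ind_b"])
    randoms = np.zeros(n_random)
    for cross, members in cross_of.groupby(cross_of):
        ids = [i for i in members.index if i in paired]
        if len(ids) < 2:
            continue
        for r in range(n_random):
            randoms[r] += _random_matching_weight(ids, distance, rng)
    mean_random = float(randoms.mean())
    if mean_random == 0.0:
        return 0.0
    return 100.0 * (w_opt - mean_random) / mean_random


def assign_strata(
    pairs: pd.DataFrame,
    n_blocks: int = 3,
    n_batches: int = 2,
    persons: tuple[str, ...] = ("person1", "person2"),
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign replicate block, fabrication batch and experimenter per array."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = pairs.copy().reset_index(drop=True)
    n = len(out)
    order = rng.permutation(n)
    out.loc[order, "block"] = [f"block{(i % n_blocks) + 1}" for i in range(n)]
    order = rng.permutation(n)
    out.loc[order, "batch"] = [f"batch{(i % n_batches) + 1}" for i in range(n)]
    order = rng.permutation(n)
    out.loc[order, "person"] = [persons[i % len(persons)] for i in range(n)]
    return out


def assign_dyes(
    pairs: pd.DataFrame,
    seed: int | np.random.Generator | None = None,
    max_tries: int = 10000,
) -> pd.DataFrame:
    """Randomize dye orientation with block and batch balance.

    Each pair is assigned an orientation (which member is labeled Cy3 vs
    Cy5); orientations are randomized subject to the Cy3-first/Cy5-first
    counts differing by at most one within every block and every batch.
    Returns the plan with ``array``, ``ind_cy3`` and ``ind_cy5`` columns.
    """
    required = {"block", "batch"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"pairs lack stratum columns: {sorted(missing)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(pairs)
    out = pairs.copy().reset_index(drop=True)

    for _ in range(max_tries):
        orient = np.zeros(n, dtype=int)
        # balance within blocks by alternating after a random shuffle
        for _, idx in out.groupby("block").groups.items():
            idx = np.asarray(list(idx))
            idx = idx[rng.permutation(len(idx))]
            start = int(rng.integers(0, 2))
            orient[idx] = (np.arange(len(idx)) + start) % 2
        ok = True
        for _, idx in out.groupby("batch").groups.items():
            o = orient[np.asarray(list(idx))]
            if abs(int(o.sum()) * 2 - len(o)) > 1:
                ok = False
                break
        if ok:
            break
    else:
        raise ValueError("could not balance dyes within stratum 'batch'")

    out["array"] = [f"A{i + 1:03d}" for i in range(n)]
    a = out["ind_a"].to_numpy()
    b = out["ind_b"].to_numpy()
    out["ind_cy3"] = np.where(orient == 0, a, b)
    out["ind_cy5"] = np.where(orient == 0, b, a)
    return out


def dye_balance(plan: pd.DataFrame, stratum: str) -> pd.DataFrame:
    """Cy3-first / Cy5-first orientation counts per stratum level."""
    first_is_a = plan["ind_cy3"] == plan["ind_a"]
    tab = plan.assign(orientation=np.where(first_is_a, "a_cy3", "a_cy5"))
    return tab.pivot_table(index=stratum, columns="orientation", values="array",
                           aggfunc="count", fill_value=0)
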