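"""Synthetic genetical-genomics data with known ground truth.

Emulates an outbred conifer full-sib factorial: four parents crossed in a
2x2 design, a consensus SNP linkage map, per-parent transmission genotypes,
quantitative growth traits (heights in cm), ordinal pest-resistance traits
(attack outcome classes, oviposition classes), expression traits with
planted cis/trans eQTLs and hotspot regulators, and two-channel array
intensities carrying dye/block/batch/person technical effects.

Every random draw flows through one :class:`numpy.random.Generator`, so a
fixed seed reproduces all outputs exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

GROWTH_TRAITS = ("ldr_99", "hgt_1995", "hgt_1997", "hgt_1999")
ATTACK_TRAITS = ("atk_2000", "atk_2001")
EGG_TRAITS = ("egg_2000", "egg_2001")
SUM_TRAITS = ("sum_atk", "sum_egg")
RESISTANCE_TRAITS = ATTACK_TRAITS + SUM_TRAITS[:1] + EGG_TRAITS + SUM_TRAITS[1:]
#: individual (non-sum) ordinal traits, each with its own latent liability
ORDINAL_TRAITS = ATTACK_TRAITS + EGG_TRAITS
ALL_TRAITS = GROWTH_TRAITS + ATTACK_TRAITS + EGG_TRAITS + SUM_TRAITS

#: growth/resistance trait groups used for composite candidates and hubs
TRAIT_GROUPS = {
    "growth": list(GROWTH_TRAITS),
    "resistance": ["atk_2000", "atk_2001", "sum_atk", "egg_2000", "egg_2001", "sum_egg"],
}

# baseline means (cm) so simulated heights look like field measurements;
# QTL mapping is affine-invariant so these only affect presentation
_TRAIT_BASELINE = {
    "hgt_1995": 30.0,
    "hgt_1997": 120.0,
    "hgt_1999": 250.0,
    "ldr_99": 40.0,
}


@dataclass(frozen=True)
class Cross:
    """One full-sib family: dam x sire with a progeny count."""

    dam: str
    sire: str
    n_progeny: int


def _default_markers_per_lg() -> tuple[int, ...]:
    # 13 groups, 252 markers total: five groups of 20, eight of 19
    return (20,) * 5 + (19,) * 8


def _default_crosses() -> tuple[Cross, ...]:
    # 2x2 factorial, 188 profiled progeny in family sizes 48/36/50/54
    return (
        Cross("dam1", "sire1", 48),
        Cross("dam1", "sire2", 36),
        Cross("dam2", "sire1", 50),
        Cross("dam2", "sire2", 54),
    )


@dataclass
class SimConfig:
    """Parameters of the simulated study.

    Defaults mirror the emulated design: 13 linkage groups carrying 252
    mapped SNPs over ~97 cM each (~1,260 cM map, ~2 markers per 10 cM bin),
    a 2x2 factorial with 188 profiled progeny, and expression scaled down
    to hundreds of transcripts.
    """

    n_linkage_groups: int = 13
    markers_per_lg: int | Sequence[int] = field(default_factory=_default_markers_per_lg)
    lg_length_cm: float = 97.0
    crosses: Sequence[Cross] = field(default_factory=_default_crosses)
    n_transcripts: int = 300
    architecture: "TruthTable | None" = None
    tech_effects: Mapping[str, float] = field(
        default_factory=lambda: {"dye": 0.3, "block": 0.2, "batch": 0.2, "person": 0.1}
    )
    noise_sd: float = 1.0
    array_noise_sd: float = 0.1
    array_background: float = 20.0
    ordinal_cutpoints: Mapping[str, Sequence[float]] = field(
        default_factory=lambda: {
            # attack: no attack / failed attack / top kill
            "atk": (-0.45, 0.45),
            # oviposition: class 0 (none) plus five egg-puncture classes
            "egg": (-1.0, -0.4, 0.1, 0.6, 1.1),
        }
    )
    #: fraction of markers masked as uninformative per parent (no transmission calls)
    uninformative_fraction: float = 0.0
    #: optional explicit marker positions per linkage group (otherwise evenly spaced)
    marker_positions_cm: Sequence[Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_linkage_groups < 1:
            raise ValueError("n_linkage_groups must be >= 1")
        if self.lg_length_cm <= 0:
            raise ValueError("lg_length_cm must be > 0")
        if np.isscalar(self.markers_per_lg):
            self.markers_per_lg = (int(self.markers_per_lg),) * self.n_linkage_groups
        else:
            self.markers_per_lg = tuple(int(k) for k in self.markers_per_lg)
        if len(self.markers_per_lg) != self.n_linkage_groups:
            raise ValueError("markers_per_lg length must equal n_linkage_groups")
        if any(k < 1 for k in self.markers_per_lg):
            raise ValueError("each linkage group needs >= 1 marker")
        if not self.crosses:
            raise ValueError("at least one cross is required")
        self.crosses = tuple(
            c if isinstance(c, Cross) else Cross(*c) for c in self.crosses
        )
        if any(c.n_progeny < 1 for c in self.crosses):
            raise ValueError("each cross needs >= 1 progeny")
        if self.n_transcripts < 0:
            raise ValueError("n_transcripts must be >= 0")
        if not 0.0 <= self.uninformative_fraction < 1.0:
            raise ValueError("uninformative_fraction must be in [0, 1)")
        for name, cuts in self.ordinal_cutpoints.items():
            arr = np.asarray(cuts, dtype=float)
            if arr.ndim != 1 or arr.size < 1 or np.any(np.diff(arr) <= 0):
                raise ValueError(f"cutpoints for {name!r} must be strictly increasing")
        if self.marker_positions_cm is not None:
            if len(self.marker_positions_cm) != self.n_linkage_groups:
                raise ValueError("marker_positions_cm must list one array per linkage group")
            for lg, pos in enumerate(self.marker_positions_cm, start=1):
                arr = np.asarray(pos, dtype=float)
                if np.any(np.diff(arr) < 0):
                    raise ValueError(f"non-increasing cM positions on linkage group {lg}")

    @property
    def parents(self) -> tuple[str, ...]:
        dams = [c.dam for c in self.crosses]
        sires = [c.sire for c in self.crosses]
        seen: dict[str, None] = {}
        for p in dams + sires:
            seen.setdefault(p)
        return tuple(seen)


@dataclass
class TruthRecord:
    """One planted additive effect: a marker allele of one parent shifting a trait."""

    target: str  # transcript or trait id
    marker: str
    parent: str
    effect: float


@dataclass
class TruthTable:
    """Ground truth of the planted genetic architecture.

    ``records`` lists every additive effect; ``hotspot_regulators`` maps a
    regulator marker to the transcripts it drives in trans;
    ``pleiotropic_loci`` maps a marker to the phenotypic traits it affects
    (signed effects); ``transcript_locations`` gives each transcript's own
    map position for cis/trans truth labels.
    """

    records: list[TruthRecord] = field(default_factory=list)
    hotspot_regulators: dict[str, list[str]] = field(default_factory=dict)
    pleiotropic_loci: dict[str, dict[str, float]] = field(default_factory=dict)
    transcript_locations: pd.DataFrame | None = None  # index transcript; lg, cm

    def validate(self, map_df: pd.DataFrame) -> None:
        known = set(map_df["marker"])
        for rec in self.records:
            if rec.marker not in known:
                raise ValueError(f"causal marker {rec.marker!r} not in map")
            if not np.isfinite(rec.effect):
                raise ValueError(f"non-finite effect for {rec.target!r}")

    def effects_for(self, target: str) -> list[TruthRecord]:
        return [r for r in self.records if r.target == target]

    def to_json(self, path) -> None:
        payload = {
            "records": [asdict(r) for r in self.records],
            "hotspot_regulators": self.hotspot_regulators,
            "pleiotropic_loci": self.pleiotropic_loci,
            "transcript_locations": (
                None
                if self.transcript_locations is None
                else self.transcript_locations.reset_index()
                .rename(columns={"index": "transcript"})
                .to_dict(orient="list")
            ),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        locs = payload.get("transcript_locations")
        loc_df = None
        if locs is not None:
            loc_df = pd.DataFrame(locs).set_index("transcript")
        return cls(
            records=[TruthRecord(**r) for r in payload["records"]],
            hotspot_regulators={k: list(v) for k, v in payload["hotspot_regulators"].items()},
            pleiotropic_loci={
                k: {t: float(e) for t, e in v.items()}
                for k, v in payload["pleiotropic_loci"].items()
            },
            transcript_locations=loc_df,
        )


def haldane_recombination(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Recombination fraction for a map distance in cM under no interference."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


def transcript_ids(n: int) -> list[str]:
    return [f"T{i:04d}" for i in range(1, n + 1)]


def _progeny_ids(crosses: Sequence[Cross]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for c in crosses:
        cid = f"{c.dam}x{c.sire}"
        out[cid] = [f"{cid}_{i:03d}" for i in range(1, c.n_progeny + 1)]
    return out


def simulate_pedigree(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate the linkage map and per-parent transmission genotypes.

    Transmissions follow a Markov walk along each linkage group: the allele
    transmitted at the first marker is uniform on the parent's two alleles
    and switches between adjacent markers with the Haldane recombination
    fraction of their cM distance.  The two parents of a cross segregate
    independently.

    Returns
    -------
    map_df : DataFrame with columns ``marker``, ``lg``, ``cm``.
    transmissions : dict parent -> DataFrame (progeny x markers) with codes
        1/2 for the parent's two alleles; NaN at uninformative markers.
    cross_df : DataFrame indexed by progeny with ``cross``, ``dam``, ``sire``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)

    # --- map ---
    rows = []
    idx = 0
    for lg in range(1, config.n_linkage_groups + 1):
        k = config.markers_per_lg[lg - 1]
        if config.marker_positions_cm is not None:
            pos = np.asarray(config.marker_positions_cm[lg - 1], dtype=float)
            if pos.size != k:
                raise ValueError(f"marker_positions_cm[{lg - 1}] must have {k} entries")
        else:
            pos = np.linspace(0.0, config.lg_length_cm, k) if k > 1 else np.array([0.0])
        for cm in pos:
            idx += 1
            rows.append((f"SNP{idx:03d}", lg, float(cm)))
    map_df = pd.DataFrame(rows, columns=["marker", "lg", "cm"])

    # --- progeny / crosses ---
    fam = _progeny_ids(config.crosses)
    cross_rows = []
    for c in config.crosses:
        cid = f"{c.dam}x{c.sire}"
        for pid in fam[cid]:
            cross_rows.append((pid, cid, c.dam, c.sire))
    cross_df = pd.DataFrame(
        cross_rows, columns=["progeny", "cross", "dam", "sire"]
    ).set_index("progeny")

    # --- transmissions: one Markov walk per (parent, progeny, linkage group) ---
    transmissions: dict[str, pd.DataFrame] = {}
    for parent in config.parents:
        children = [
            pid
            for c in config.crosses
            if parent in (c.dam, c.sire)
            for pid in fam[f"{c.dam}x{c.sire}"]
        ]
        n = len(children)
        cols: list[np.ndarray] = []
        for lg in range(1, config.n_linkage_groups + 1):
            sub = map_df[map_df["lg"] == lg]
            k = len(sub)
            r = haldane_recombination(np.diff(sub["cm"].to_numpy()))
            state = np.empty((n, k), dtype=np.int8)
            state[:, 0] = rng.integers(0, 2, size=n)
            if k > 1:
                switches = rng.random((n, k - 1)) < r[None, :]
                state[:, 1:] = (state[:, [0]] + np.cumsum(switches, axis=1)) % 2
            cols.append(state)
        codes = np.concatenate(cols, axis=1).astype(float) + 1.0  # alleles 1/2
        tm = pd.DataFrame(codes, index=children, columns=map_df["marker"].tolist())
        tm.index.name = "progeny"
        if config.uninformative_fraction > 0:
            mask = rng.random(tm.shape[1]) < config.uninformative_fraction
            tm.loc[:, mask] = np.nan
        transmissions[parent] = tm
    return map_df, transmissions, cross_df


def default_architecture(
    map_df: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator,
    n_cis: int = 30,
    n_trans: int = 30,
    n_hotspot: int = 60,
    effect_sd_units: float = 1.0,
) -> TruthTable:
    """Plant a default architecture: cis and trans eQTLs, one trans-eQTL
    hotspot regulator that is also pleiotropic for growth and resistance
    (a hub), a second pleiotropic growth/resistance locus, and pQTLs for
    every phenotypic trait.

    Effects default to one residual SD (``effect_sd_units * noise_sd``),
    the regime in which single-marker mapping at n~200 has essentially
    full power.
    """
    planted = n_cis + n_trans + n_hotspot
    if planted > 0.4 * config.n_transcripts:
        # keep the planted fraction at the default ~40% for small studies
        scale = 0.4 * config.n_transcripts / planted
        n_cis = int(n_cis * scale)
        n_trans = int(n_trans * scale)
        n_hotspot = max(int(n_hotspot * scale), 1 if config.n_transcripts else 0)
    if n_cis + n_trans + n_hotspot > config.n_transcripts:
        raise ValueError("architecture plants more transcripts than simulated")
    markers = map_df["marker"].to_numpy()
    parents = config.parents
    eff = effect_sd_units * config.noise_sd
    t_ids = transcript_ids(config.n_transcripts)
    truth = TruthTable()

    # transcript locations: uniform over marker positions
    loc_idx = rng.integers(0, len(markers), size=config.n_transcripts)
    loc = map_df.iloc[loc_idx][["lg", "cm"]].reset_index(drop=True)
    loc.index = pd.Index(t_ids, name="transcript")

    cursor = 0
    for _ in range(n_cis):
        t = t_ids[cursor]
        m = markers[loc_idx[cursor]]  # eQTL at the transcript's own position
        truth.records.append(TruthRecord(t, m, parents[rng.integers(len(parents))], eff))
        cursor += 1
    for _ in range(n_trans):
        t = t_ids[cursor]
        own = loc_idx[cursor]
        other = int(rng.integers(len(markers) - 1))
        if other >= own:
            other += 1
        truth.records.append(
            TruthRecord(t, markers[other], parents[rng.integers(len(parents))], eff)
        )
        cursor += 1

    # hotspot regulator: one marker drives many transcripts in trans
    hub_marker = markers[int(rng.integers(len(markers)))]
    hub_parent = parents[int(rng.integers(len(parents)))]
    regulated = []
    for _ in range(n_hotspot):
        t = t_ids[cursor]
        truth.records.append(TruthRecord(t, hub_marker, hub_parent, eff))
        regulated.append(t)
        cursor += 1
    truth.hotspot_regulators[hub_marker] = regulated

    # the hub is pleiotropic: same-sign effects on growth and resistance traits
    hub_traits = {"hgt_1999": eff, "ldr_99": eff, "atk_2000": eff, "egg_2000": eff}
    truth.pleiotropic_loci[hub_marker] = dict(hub_traits)
    for trait, e in hub_traits.items():
        truth.records.append(TruthRecord(trait, hub_marker, hub_parent, e))

    # a second pleiotropic locus on a different linkage group
    hub_lg = map_df.loc[map_df["marker"] == hub_marker, "lg"].iloc[0]
    candidates = map_df[map_df["lg"] != hub_lg]
    m2 = candidates["marker"].iloc[int(rng.integers(len(candidates)))]
    p2 = parents[int(rng.integers(len(parents)))]
    pleio2 = {"hgt_1997": eff, "atk_2001": eff, "egg_2001": eff}
    truth.pleiotropic_loci[m2] = dict(pleio2)
    for trait, e in pleio2.items():
        truth.records.append(TruthRecord(trait, m2, p2, e))

    # remaining traits get one private QTL each so every trait maps somewhere
    covered = {r.target for r in truth.records}
    for trait in GROWTH_TRAITS + ORDINAL_TRAITS:
        if trait in covered:
            continue
        m = markers[int(rng.integers(len(markers)))]
        truth.records.append(TruthRecord(trait, m, parents[int(rng.integers(len(parents)))], eff))

    truth.transcript_locations = loc
    truth.validate(map_df)
    return truth


def _signed_codes(transmissions: Mapping[str, pd.DataFrame], individuals: pd.Index) -> dict[str, pd.DataFrame]:
    out = {}
    for parent, tm in transmissions.items():
        sub = tm.reindex(individuals)
        out[parent] = (sub == 1.0).astype(float) - (sub == 2.0).astype(float)
    return out


def simulate_traits(
    map_df: pd.DataFrame,
    transmissions: Mapping[str, pd.DataFrame],
    truth: TruthTable,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Simulate expression and phenotype tables from the planted truth.

    Each trait (transcript latent value, growth trait, or ordinal liability)
    is the sum of its planted effects times the signed transmission code
    (+1/-1 for the causal parent's two alleles) plus Gaussian noise.
    Ordinal traits are produced by cutting the liability at the configured
    cutpoints: attack into three classes (0 = no attack, 1 = failed attack,
    2 = top kill) and oviposition into class 0 plus five egg-count classes.
    ``sum_atk``/``sum_egg`` are sums of the two yearly class codes.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    truth.validate(map_df)
    individuals = next(iter(transmissions.values())).index
    individuals = pd.Index(
        sorted(set().union(*[set(tm.index) for tm in transmissions.values()]))
    )
    signed = _signed_codes(transmissions, individuals)
    n = len(individuals)

    def latent(target: str) -> np.ndarray:
        total = np.zeros(n)
        for rec in truth.effects_for(target):
            s = signed[rec.parent][rec.marker].to_numpy()
            s = np.nan_to_num(s)  # progeny outside the cross or uninformative: no contribution
            total += rec.effect * s
        return total

    t_ids = transcript_ids(config.n_transcripts)
    expr = np.empty((n, len(t_ids)))
    for j, t in enumerate(t_ids):
        expr[:, j] = latent(t) + rng.normal(0.0, config.noise_sd, size=n)
    expr_df = pd.DataFrame(expr, index=individuals, columns=t_ids)
    expr_df.index.name = "individual"

    pheno = {}
    for trait in GROWTH_TRAITS:
        pheno[trait] = (
            _TRAIT_BASELINE.get(trait, 0.0)
            + latent(trait)
            + rng.normal(0.0, config.noise_sd, size=n)
        )
    for trait in ORDINAL_TRAITS:
        liab = latent(trait) + rng.normal(0.0, config.noise_sd, size=n)
        cuts = np.asarray(
            config.ordinal_cutpoints["atk" if trait.startswith("atk") else "egg"], dtype=float
        )
        classes = np.digitize(liab, cuts)
        degenerate = n > 1 and liab.max() > liab.min()
        if degenerate and classes.min() == classes.max():
            raise ValueError(
                f"cutpoints for {trait!r} do not cover the latent range: "
                "all individuals fall in one class"
            )
        pheno[trait] = classes.astype(float)
    pheno_df = pd.DataFrame(pheno, index=individuals)
    pheno_df["sum_atk"] = pheno_df["atk_2000"] + pheno_df["atk_2001"]
    pheno_df["sum_egg"] = pheno_df["egg_2000"] + pheno_df["egg_2001"]
    pheno_df = pheno_df[list(ALL_TRAITS)]
    pheno_df.index.name = "individual"
    return expr_df, pheno_df, truth


@dataclass
class TechTruth:
    """Planted per-gene technical effects (for recovery tests)."""

    dye: pd.Series  # per gene, added to the Cy5 channel
    block: pd.DataFrame  # genes x levels
    batch: pd.DataFrame
    person: pd.DataFrame
    baseline: pd.Series  # per-gene log-intensity baseline


def simulate_arrays(
    expression_true: pd.DataFrame,
    pairing: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, TechTruth]:
    """Turn true expression into two-channel array intensities.

    ``pairing`` is a hybridization plan with one row per array and columns
    ``array``, ``ind_cy3``, ``ind_cy5``, ``block``, ``batch``, ``person``
    (as produced by :mod:`spruceqtl.pairdesign`).  Channel intensity is
    ``exp(baseline + signal + dye + block + batch + person + noise)`` plus
    a small additive background, so technical effects are additive on the
    log scale and the glog + fixed-effect model downstream can recover the
    true signal up to an affine transform.

    Returns the intensity table (genes x channels), the sample sheet (one
    row per channel), and the planted technical effects for tests.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    required = {"array", "ind_cy3", "ind_cy5", "block", "batch", "person"}
    missing = required - set(pairing.columns)
    if missing:
        raise ValueError(f"pairing plan lacks columns: {sorted(missing)}")
    used = pd.concat([pairing["ind_cy3"], pairing["ind_cy5"]])
    dup = used[used.duplicated()]
    if not dup.empty:
        raise ValueError(f"individual(s) appear in more than one pair: {sorted(set(dup))}")
    unknown = set(used) - set(expression_true.index)
    if unknown:
        raise ValueError(f"pairing references unprofiled individuals: {sorted(unknown)}")

    genes = expression_true.columns
    g = len(genes)
    mag = dict(config.tech_effects)
    baseline = pd.Series(rng.normal(7.0, 0.5, size=g), index=genes)
    dye = pd.Series(rng.normal(0.0, mag.get("dye", 0.0), size=g), index=genes)

    def level_effects(name: str, levels: Sequence) -> pd.DataFrame:
        sd = mag.get(name, 0.0)
        return pd.DataFrame(
            rng.normal(0.0, sd, size=(g, len(levels))), index=genes, columns=list(levels)
        )

    blocks = list(pd.unique(pairing["block"]))
    batches = list(pd.unique(pairing["batch"]))
    persons = list(pd.unique(pairing["person"]))
    blk = level_effects("block", blocks)
    bat = level_effects("batch", batches)
    per = level_effects("person", persons)

    sheet_rows = []
    columns = {}
    for row in pairing.itertuples(index=False):
        for dye_name, ind in (("Cy3", row.ind_cy3), ("Cy5", row.ind_cy5)):
            channel = f"{row.array}_{dye_name}"
            log_i = (
                baseline.to_numpy()
                + expression_true.loc[ind].to_numpy()
                + (dye.to_numpy() if dye_name == "Cy5" else 0.0)
                + blk[row.block].to_numpy()
                + bat[row.batch].to_numpy()
                + per[row.person].to_numpy()
                + rng.normal(0.0, config.array_noise_sd, size=g)
            )
            columns[channel] = np.exp(log_i) + config.array_background
            sheet_rows.append(
                (channel, row.array, ind, dye_name, row.block, row.batch, row.person)
            )
    intensities = pd.DataFrame(columns, index=genes)
    intensities.index.name = "transcript"
    samplesheet = pd.DataFrame(
        sheet_rows,
        columns=["channel", "array", "individual", "dye", "block", "batch", "person"],
    ).set_index("channel")
    truth = TechTruth(dye=dye, block=blk, batch=bat, person=per, baseline=baseline)
    return intensities, samplesheet, truth
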