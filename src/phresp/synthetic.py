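"""Seeded synthetic inputs with known ground truth for every pipeline stage.

Three generators emulate the study's input contracts without any sequencing
data:

* :func:`simulate_growth` — exponential fluorescence trajectories per
  well/strain/pH with multiplicative lognormal measurement noise, covering
  acidophile, generalist and acid-intolerant growth archetypes;
* :func:`simulate_de` — per-contrast differential-expression tables over a
  gene universe, with gene sets of several types and *planted* enriched or
  depleted sets whose DEGs run in one direction;
* :func:`simulate_ontology` — a rooted random DAG of terms plus toy gene
  annotations for ancestor propagation.

Every generator takes a seed and is byte-reproducible; a
:class:`SyntheticTruth` records the planted labels so recovery can be scored.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genesets import GeneSetCollection, OntologyDAG, SET_TYPES
from .growth import GrowthSeries
from .scoring import DETable

logger = logging.getLogger(__name__)

__all__ = [
    "GrowthSimConfig",
    "DESimConfig",
    "SyntheticTruth",
    "default_mu_true",
    "simulate_growth",
    "simulate_gene_sets",
    "simulate_de",
    "plant_de_table",
    "simulate_ontology",
    "simulate_cpm",
    "write_growth_tsv",
    "write_de_tsv",
    "write_edges_tsv",
]

PH_CONDITIONS = ("4.7", "7.0", "8.2")

# per-day growth-rate archetypes across (acidic, neutral, alkaline) conditions
_ARCHETYPES = {
    "acidophile": (0.60, 0.20, 0.20),
    "generalist": (0.35, 0.45, 0.40),
    "acid_intolerant_neutral": (-0.30, 0.45, 0.35),
    "acid_intolerant_alkaline": (-0.30, 0.35, 0.45),
}


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"invalid configuration field {name!r}: {msg}")


def default_mu_true(
    strains: Sequence[str], ph_conditions: Sequence[str] = PH_CONDITIONS
) -> dict[tuple[str, str], float]:
    """Study-like growth-rate map: 2 acidophiles, 2 generalists, rest acid-intolerant."""
    if len(ph_conditions) != 3:
        raise ValueError("archetype rates are defined for exactly 3 pH conditions")
    out: dict[tuple[str, str], float] = {}
    kinds = list(_ARCHETYPES)
    for i, strain in enumerate(strains):
        if i < 2:
            kind = "acidophile"
        elif i < 4:
            kind = "generalist"
        else:
            kind = kinds[2 + (i % 2)]
        for ph, mu in zip(ph_conditions, _ARCHETYPES[kind]):
            out[(strain, ph)] = mu
    return out


@dataclass
class SyntheticTruth:
    """Ground-truth labels recorded by the generators."""

    planted_sets: dict[str, str] = field(default_factory=dict)  # set_id -> enriched/depleted/null
    deg_labels: dict[str, str] = field(default_factory=dict)  # gene_id -> up/down/none
    mu_true: dict[tuple[str, str], float] = field(default_factory=dict)


@dataclass
class GrowthSimConfig:
    """Fluorescence growth-series generator settings.

    Defaults mirror the study design: 12 strains x 3 pH conditions in 12-well
    plates, 3-day growth periods between culture renewals.
    """

    n_strains: int = 12
    ph_conditions: tuple[str, ...] = PH_CONDITIONS
    n_wells: int = 12
    n_periods: int = 4
    period_length: float = 3.0
    mu_true: dict[tuple[str, str], float] | None = None
    noise_cv: float = 0.05
    rfu0: float = 100.0
    seed: int | None = None

    def __post_init__(self) -> None:
        _require(self.n_strains >= 1, "n_strains", "must be >= 1")
        _require(self.n_wells >= 1, "n_wells", "must be >= 1")
        _require(self.n_periods >= 1, "n_periods", "must be >= 1")
        _require(self.period_length > 0, "period_length", "must be > 0")
        _require(self.noise_cv >= 0, "noise_cv", "must be >= 0")
        _require(self.rfu0 > 0, "rfu0", "must be > 0")
        _require(len(self.ph_conditions) >= 1, "ph_conditions", "must be non-empty")

    @property
    def strains(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]


def simulate_growth(config: GrowthSimConfig) -> tuple[list[GrowthSeries], SyntheticTruth]:
    """Generate exponential RFU series with multiplicative lognormal noise.

    Each reading is ``rfu0 * exp(mu t) * exp(eps)`` with
    ``eps ~ N(0, sqrt(ln(1 + cv^2)))``, so noise never produces negative RFU
    and the expected log-increment per period is exactly ``mu * period_length``.
    """
    strains = config.strains
    mu_true = config.mu_true
    if mu_true is None:
        mu_true = default_mu_true(strains, config.ph_conditions)
    missing = [
        (s, ph) for s in strains for ph in config.ph_conditions if (s, ph) not in mu_true
    ]
    _require(not missing, "mu_true", f"missing rates for {missing[:4]}")

    rng = np.random.default_rng(config.seed)
    sigma = math.sqrt(math.log(1.0 + config.noise_cv**2))
    times = np.arange(config.n_periods + 1) * config.period_length
    series: list[GrowthSeries] = []
    for strain in strains:
        for ph in config.ph_conditions:
            mu = mu_true[(strain, ph)]
            for well in range(config.n_wells):
                clean = config.rfu0 * np.exp(mu * times)
                noise = np.exp(rng.normal(0.0, sigma, size=times.size)) if sigma > 0 else 1.0
                series.append(
                    GrowthSeries(
                        well_id=f"{strain}_{ph}_w{well + 1:02d}",
                        strain=strain,
                        ph=ph,
                        times=tuple(times),
                        rfu=tuple(clean * noise),
                    )
                )
    return series, SyntheticTruth(mu_true=dict(mu_true))


@dataclass
class DESimConfig:
    """Differential-expression table generator with planted set-level signals."""

    n_genes: int = 5000
    n_sets: int = 100
    set_size_range: tuple[int, int] = (10, 40)
    frac_enriched_sets: float = 0.1
    frac_depleted_sets: float = 0.1
    deg_rate_null: float = 0.02
    effect_deg_rate: float = 0.8
    effect_unidirectional: bool = True
    fdr_alpha_shape: float | None = None
    deg_alpha: float = 0.01
    strain: str = "S01"
    contrast: tuple[str, str] = ("4.7", "8.2")
    seed: int | None = None

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        _require(2 <= lo <= hi <= self.n_genes, "set_size_range",
                 f"must satisfy 2 <= min <= max <= n_genes, got ({lo}, {hi})")
        _require(0 <= self.frac_enriched_sets <= 1, "frac_enriched_sets", "must be in [0, 1]")
        _require(0 <= self.frac_depleted_sets <= 1, "frac_depleted_sets", "must be in [0, 1]")
        _require(self.frac_enriched_sets + self.frac_depleted_sets <= 1,
                 "frac_enriched_sets", "enriched + depleted fractions must be <= 1")
        _require(0 <= self.deg_rate_null <= 1, "deg_rate_null", "must be in [0, 1]")
        _require(0 <= self.effect_deg_rate <= 1, "effect_deg_rate", "must be in [0, 1]")
        _require(0 < self.deg_alpha < 1, "deg_alpha", "must be in (0, 1)")
        if self.fdr_alpha_shape is not None:
            _require(self.fdr_alpha_shape > 0, "fdr_alpha_shape", "must be > 0")

    @property
    def null_shape(self) -> float:
        """Shape a of the Beta(a, 1) null FDR law; P(FDR < deg_alpha) = deg_alpha**a.

        Derived from ``deg_rate_null`` unless ``fdr_alpha_shape`` overrides it.
        """
        if self.fdr_alpha_shape is not None:
            return self.fdr_alpha_shape
        if self.deg_rate_null <= 0:
            return math.inf  # degenerate: no null gene ever crosses the threshold
        return math.log(self.deg_rate_null) / math.log(self.deg_alpha)


def simulate_de(
    config: DESimConfig,
) -> tuple[DETable, GeneSetCollection, SyntheticTruth]:
    """Generate a DE table, a multi-type gene-set collection, and the truth.

    Planted signal sets are sampled over disjoint gene pools (null sets may
    overlap anything).  Member genes of a planted set become DEGs of the
    planted direction with probability ``effect_deg_rate``; background genes
    draw their FDR from Beta(a, 1) with ``P(FDR < deg_alpha) = deg_rate_null``.
    With ``effect_unidirectional``, chance background DEGs inside a planted
    set take the planted sign too, so all of a planted set's DEGs agree.
    """
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"g{i + 1:05d}" for i in range(config.n_genes)])
    set_ids = [f"SET{i + 1:04d}" for i in range(config.n_sets)]
    lo, hi = config.set_size_range

    n_en = int(round(config.frac_enriched_sets * config.n_sets))
    n_dp = int(round(config.frac_depleted_sets * config.n_sets))
    status = np.array(["enriched"] * n_en + ["depleted"] * n_dp
                      + ["null"] * (config.n_sets - n_en - n_dp))
    status = status[rng.permutation(config.n_sets)]

    sizes = rng.integers(lo, hi + 1, size=config.n_sets)
    planted_total = int(sizes[status != "null"].sum())
    if planted_total > config.n_genes:
        raise ValueError(
            "invalid configuration field 'set_size_range': planted sets need "
            f"{planted_total} distinct genes but n_genes={config.n_genes}"
        )

    sets: dict[str, frozenset[str]] = {}
    pool = rng.permutation(config.n_genes)  # disjoint slices for planted sets
    cursor = 0
    planted_dir: dict[str, int] = {}  # gene index -> +1/-1 forced sign
    effect_gene: dict[int, bool] = {}
    for sid, st, size in zip(set_ids, status, sizes):
        if st == "null":
            members = rng.choice(config.n_genes, size=size, replace=False)
        else:
            members = pool[cursor : cursor + size]
            cursor += size
            sign = 1 if st == "enriched" else -1
            is_effect = rng.random(size) < config.effect_deg_rate
            for g, eff in zip(members, is_effect):
                if config.effect_unidirectional or eff:
                    planted_dir[int(g)] = sign
                if eff:
                    effect_gene[int(g)] = True
        sets[sid] = frozenset(genes[members])

    table, deg_labels = _emit_de(
        rng, genes, planted_dir, sorted(effect_gene),
        null_shape=config.null_shape, deg_alpha=config.deg_alpha,
        strain=config.strain, contrast=config.contrast,
    )
    set_type = {sid: SET_TYPES[i % len(SET_TYPES)] for i, sid in enumerate(set_ids)}
    collection = GeneSetCollection(sets=sets, set_type=set_type, universe=frozenset(genes))
    truth = SyntheticTruth(
        planted_sets=dict(zip(set_ids, status)),
        deg_labels=deg_labels,
    )
    return table, collection, truth


def _emit_de(
    rng: np.random.Generator,
    genes: np.ndarray,
    planted_sign: dict[int, int],
    effect_idx: Sequence[int],
    *,
    null_shape: float,
    deg_alpha: float,
    strain: str,
    contrast: tuple[str, str],
) -> tuple[DETable, dict[str, str]]:
    """Draw FDR and log2FC columns given per-gene forced signs and effect flags."""
    n_genes = genes.size
    if math.isinf(null_shape):
        fdr = np.ones(n_genes)
    else:
        fdr = rng.random(n_genes) ** (1.0 / null_shape)  # Beta(shape, 1)
    effect_idx = np.asarray(sorted(effect_idx), dtype=int)
    if effect_idx.size:
        # effect DEGs: FDR log-uniform well below the threshold
        fdr[effect_idx] = 10.0 ** rng.uniform(
            -6.0, math.log10(deg_alpha), size=effect_idx.size
        )

    is_deg = fdr < deg_alpha
    signs = rng.choice([-1.0, 1.0], size=n_genes)
    for g, s in planted_sign.items():
        signs[g] = s

    mag = np.where(
        is_deg,
        rng.lognormal(0.7, 0.5, size=n_genes),
        rng.lognormal(-1.5, 0.6, size=n_genes),
    )
    log2fc = signs * np.maximum(mag, 1e-6)

    frame = pd.DataFrame({"gene_id": genes, "log2fc": log2fc, "fdr": fdr})
    table = DETable(frame=frame, strain=strain, contrast=tuple(contrast))
    deg_labels = {
        g: ("up" if d and f > 0 else "down" if d and f < 0 else "none")
        for g, d, f in zip(genes, is_deg, log2fc)
    }
    return table, deg_labels


def simulate_gene_sets(
    n_genes: int,
    n_sets: int,
    set_size_range: tuple[int, int] = (10, 40),
    seed: int | None = None,
    set_types: Sequence[str] = SET_TYPES,
) -> GeneSetCollection:
    """Overlapping gene sets of cycling types over a fresh gene universe."""
    lo, hi = set_size_range
    _require(2 <= lo <= hi <= n_genes, "set_size_range",
             f"must satisfy 2 <= min <= max <= n_genes, got ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    genes = np.array([f"g{i + 1:05d}" for i in range(n_genes)])
    sets = {}
    types = {}
    for i in range(n_sets):
        sid = f"SET{i + 1:04d}"
        size = int(rng.integers(lo, hi + 1))
        sets[sid] = frozenset(genes[rng.choice(n_genes, size=size, replace=False)])
        types[sid] = set_types[i % len(set_types)]
    return GeneSetCollection(sets=sets, set_type=types, universe=frozenset(genes))


def plant_de_table(
    collection: GeneSetCollection,
    planted: dict[str, str],
    *,
    effect_deg_rate: float = 0.8,
    effect_unidirectional: bool = True,
    deg_rate_null: float = 0.02,
    deg_alpha: float = 0.01,
    strain: str = "S01",
    contrast: tuple[str, str] = ("4.7", "8.2"),
    seed: int | None = None,
) -> tuple[DETable, SyntheticTruth]:
    """Generate a DE table over an *existing* collection with chosen planted sets.

    ``planted`` maps set ids (of ``collection``) to "enriched"/"depleted".
    Used by the pipeline so several strain x contrast tables share one set
    collection; a gene reached by planted sets of both directions keeps the
    sign of the alphabetically first set (with a warning).
    """
    unknown = sorted(set(planted) - set(collection.sets))
    if unknown:
        raise ValueError(f"planted set ids absent from the collection: {unknown}")
    rng = np.random.default_rng(seed)
    genes = np.array(sorted(collection.universe))
    index = {g: i for i, g in enumerate(genes)}
    if deg_rate_null <= 0:
        null_shape = math.inf
    else:
        null_shape = math.log(deg_rate_null) / math.log(deg_alpha)

    planted_sign: dict[int, int] = {}
    effect: set[int] = set()
    conflicts = 0
    for sid in sorted(planted):
        sign = 1 if planted[sid] == "enriched" else -1
        for g in sorted(collection.sets[sid]):
            gi = index[g]
            if gi in planted_sign and planted_sign[gi] != sign:
                conflicts += 1
                continue
            if effect_unidirectional:
                planted_sign[gi] = sign
                if rng.random() < effect_deg_rate:
                    effect.add(gi)
            elif rng.random() < effect_deg_rate:
                planted_sign[gi] = sign
                effect.add(gi)
    if conflicts:
        logger.warning("%d genes hit by planted sets of both directions; "
                       "first direction kept", conflicts)

    table, deg_labels = _emit_de(
        rng, genes, planted_sign, sorted(effect),
        null_shape=null_shape, deg_alpha=deg_alpha, strain=strain, contrast=contrast,
    )
    statuses = {sid: planted.get(sid, "null") for sid in collection.sets}
    return table, SyntheticTruth(planted_sets=statuses, deg_labels=deg_labels)


def simulate_ontology(
    n_terms: int,
    max_depth: int = 4,
    seed: int | None = None,
    genes: Sequence[str] | None = None,
    annotation_rate: float = 2.0,
) -> tuple[OntologyDAG, dict[str, frozenset[str]]]:
    """Random rooted DAG of terms plus toy gene-to-term annotations.

    Every non-root term gets 1-2 parents of strictly smaller depth, so the
    graph is acyclic with all root-to-leaf paths of length <= ``max_depth``.
    ``annotation_rate`` is the mean number of (Poisson) direct terms per gene.
    """
    if n_terms < 1:
        raise ValueError("invalid configuration field 'n_terms': must be >= 1")
    if max_depth < 1:
        raise ValueError("invalid configuration field 'max_depth': must be >= 1")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:04d}" for i in range(n_terms)]
    depth = np.zeros(n_terms, dtype=int)
    parents: dict[str, frozenset[str]] = {terms[0]: frozenset()}
    for i in range(1, n_terms):
        depth[i] = rng.integers(1, max_depth + 1)
        shallower = [j for j in range(i) if depth[j] < depth[i]]
        if not shallower:  # at least the root qualifies once depths settle
            shallower = [0]
        k = min(int(rng.integers(1, 3)), len(shallower))
        chosen = rng.choice(shallower, size=k, replace=False)
        parents[terms[i]] = frozenset(terms[j] for j in chosen)
    dag = OntologyDAG(parents=parents)

    annotations: dict[str, frozenset[str]] = {}
    if genes is None:
        genes = [f"g{i + 1:05d}" for i in range(50)]
    for gene in genes:
        k = min(int(rng.poisson(annotation_rate)), n_terms)
        if k == 0:
            annotations[gene] = frozenset()
        else:
            annotations[gene] = frozenset(rng.choice(terms, size=k, replace=False))
    return dag, annotations


def simulate_cpm(
    genes: Sequence[str],
    conditions: Sequence[str] = PH_CONDITIONS,
    n_reps: int = 3,
    seed: int | None = None,
    frac_condition_genes: float = 0.2,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.2,
    base_mean: float = 50.0,
) -> pd.DataFrame:
    """Replicate-level CPM matrix with planted condition effects.

    Counts are negative-binomial around condition means; a fraction of genes
    get a per-condition multiplier of up to ``effect_log2fc`` log2 units so
    replicates of one condition resemble each other more than cross-condition
    pairs.  Columns are ``<condition>_r<rep>``.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    n_genes = len(genes)
    base = base_mean * rng.lognormal(0.0, 1.0, size=n_genes)
    affected = rng.random(n_genes) < frac_condition_genes
    effects = np.ones((n_genes, len(conditions)))
    effects[affected] = 2.0 ** rng.uniform(
        -effect_log2fc, effect_log2fc, size=(int(affected.sum()), len(conditions))
    )
    cols = {}
    r = 1.0 / dispersion  # NB shape: var = m + dispersion * m^2
    for ci, cond in enumerate(conditions):
        mean = base * effects[:, ci]
        for rep in range(n_reps):
            p = r / (r + mean)
            counts = rng.negative_binomial(r, p)
            cols[f"{cond}_r{rep + 1}"] = counts
    frame = pd.DataFrame(cols, index=genes)
    cpm = frame / frame.sum(axis=0) * 1e6
    return cpm


def write_growth_tsv(series: Sequence[GrowthSeries], path: str | Path) -> None:
    rows = [
        (s.well_id, s.strain, s.ph, t, x)
        for s in series
        for t, x in zip(s.times, s.rfu)
    ]
    pd.DataFrame(rows, columns=["well_id", "strain", "ph", "time_days", "rfu"]).to_csv(
        path, sep="\t", index=False
    )


def write_de_tsv(table: DETable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def write_edges_tsv(dag: OntologyDAG, path: str | Path) -> None:
    rows = [
        (child, parent)
        for child in sorted(dag.parents)
        for parent in sorted(dag.parents[child])
    ]
    pd.DataFrame(rows, columns=["child_id", "parent_id"]).to_csv(path, sep="\t", index=False)
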