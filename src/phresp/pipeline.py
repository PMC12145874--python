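"""End-to-end orchestration: simulate -> growth -> score -> enrich -> cluster.

A single YAML-configurable run generates (or ingests) all stage inputs,
executes every analysis stage, and writes reproducible TSV outputs plus a
manifest recording the configuration hash, seed, per-stage row counts and
per-file checksums.  One top-level seed is fanned out to stage- and
table-specific derived seeds so each stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import clustering, enrichment, genesets, growth, scoring, synthetic

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]

# stage indices used to derive per-stage seeds from the run seed
_STAGES = ("growth", "genesets", "de", "enrich", "cluster")


@dataclass
class RunConfig:
    """Pipeline settings; defaults give a small but complete demonstration run."""

    seed: int = 0
    out_dir: str = "phresp_run"
    # growth simulation
    n_strains: int = 4
    n_wells: int = 6
    n_periods: int = 4
    period_length: float = 3.0
    noise_cv: float = 0.05
    # expression simulation
    n_genes: int = 1200
    n_sets: int = 60
    set_size_range: tuple[int, int] = (8, 25)
    frac_enriched_sets: float = 0.08
    frac_depleted_sets: float = 0.08
    deg_rate_null: float = 0.02
    effect_deg_rate: float = 0.8
    effect_unidirectional: bool = True
    share_frac: float = 0.8  # planted-set overlap between the first two strains
    n_ontology_terms: int = 30
    ontology_max_depth: int = 4
    contrasts: tuple[tuple[str, str], ...] = (
        ("4.7", "8.2"), ("4.7", "7.0"), ("7.0", "8.2"),
    )
    # thresholds
    deg_alpha: float = 0.01
    growth_alpha: float = 0.05
    enrich_alpha: float = 0.01
    min_cpm: float = 1.0
    min_reps: int = 2
    ugs_min_degs: int = 2
    n_perm: int = 1000
    render_png: bool = True

    def __post_init__(self) -> None:
        self.contrasts = tuple((str(a), str(b)) for a, b in self.contrasts)
        self.set_size_range = tuple(self.set_size_range)
        for name, value, low in (
            ("deg_alpha", self.deg_alpha, 0), ("growth_alpha", self.growth_alpha, 0),
            ("enrich_alpha", self.enrich_alpha, 0),
        ):
            if not 0 < value < 1:
                raise ValueError(f"threshold {name} must be in (0, 1), got {value}")
        if self.n_perm < 1 or self.ugs_min_degs < 1:
            raise ValueError("n_perm and ugs_min_degs must be >= 1")
        known_ph = set(synthetic.PH_CONDITIONS)
        for low, high in self.contrasts:
            if low not in known_ph or high not in known_ph:
                raise ValueError(f"contrast ({low}, {high}) uses undeclared pH labels")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seed(seed: int, stage: str, *extra: int) -> list[int]:
    return [seed, _STAGES.index(stage), *extra]


def _derive_seed(*parts: Any) -> int:
    """Stable sub-2^31 seed from arbitrary labelled parts (process-independent)."""
    digest = hashlib.sha256("|".join(map(str, parts)).encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, path: Path, manifest: dict, **counts: Any) -> None:
    frame.to_csv(path, sep="\t", index=False)
    manifest["files"][path.name] = {"sha256": _sha256(path), "rows": len(frame), **counts}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return the manifest (also written to manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
        "files": {},
    }
    stage = "simulate+growth"
    try:
        _stage_growth(config, out, manifest)
        stage = "genesets"
        collection, go_annotations = _stage_genesets(config, out, manifest)
        stage = "score"
        scored_tables, truths = _stage_score(config, collection, out, manifest)
        stage = "enrich"
        composites = _stage_enrich(config, collection, scored_tables, out, manifest)
        stage = "cluster"
        _stage_cluster(config, collection, composites, out, manifest)
    except Exception:
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        logger.error("pipeline aborted in stage %r", stage)
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_growth(config: RunConfig, out: Path, manifest: dict) -> None:
    sim = synthetic.GrowthSimConfig(
        n_strains=config.n_strains, n_wells=config.n_wells,
        n_periods=config.n_periods, period_length=config.period_length,
        noise_cv=config.noise_cv,
        seed=_derive_seed(config.seed, "growth"),
    )
    series, truth = synthetic.simulate_growth(sim)
    synthetic.write_growth_tsv(series, out / "growth_series.tsv")
    manifest["files"]["growth_series.tsv"] = {"sha256": _sha256(out / "growth_series.tsv")}

    records = [r for s in series for r in growth.period_rates(s)]
    rates = growth.records_to_frame(records)
    _write(rates, out / "growth_rates.tsv", manifest)

    test_rows, class_rows = [], []
    acidic = sim.ph_conditions[0]
    for strain in sim.strains:
        res = growth.test_ph_effect(rates, strain, alpha=config.growth_alpha)
        for (a, b), q in sorted(res.dunn_fdr.items()):
            test_rows.append((strain, res.kw_p, a, b, q, res.letters[a], res.letters[b]))
        pattern = growth.classify_growth_pattern(res.medians, res.letters, acidic)
        class_rows.append((strain, pattern, *[res.medians[ph] for ph in sim.ph_conditions]))
    tests = pd.DataFrame(
        test_rows,
        columns=["strain", "kw_p", "ph_a", "ph_b", "dunn_fdr", "letters_a", "letters_b"],
    )
    classes = pd.DataFrame(
        class_rows,
        columns=["strain", "pattern", *[f"median_mu_{ph}" for ph in sim.ph_conditions]],
    )
    _write(tests, out / "growth_tests.tsv", manifest)
    _write(classes, out / "growth_patterns.tsv", manifest)
    manifest["stages"]["growth"] = {
        "n_series": len(series), "n_rate_records": len(records),
        "n_strains": sim.n_strains,
    }


def _stage_genesets(config: RunConfig, out: Path, manifest: dict):
    seed = _derive_seed(config.seed, "genesets")
    collection = synthetic.simulate_gene_sets(
        config.n_genes, config.n_sets, config.set_size_range, seed=seed,
    )
    dag, annotations = synthetic.simulate_ontology(
        config.n_ontology_terms, config.ontology_max_depth, seed=seed + 1,
        genes=sorted(collection.universe), annotation_rate=0.15,
    )
    propagated = genesets.propagate_ancestors(annotations, dag)
    # GO-style sets: one set per term holding the genes annotated to it (after
    # closure); small terms are dropped by the collection invariant on size >= 1
    term_sets: dict[str, set[str]] = {}
    for gene, terms in propagated.items():
        for t in terms:
            term_sets.setdefault(t, set()).add(gene)
    go_sets = {f"GO:{t}": frozenset(g) for t, g in term_sets.items() if len(g) >= 2}
    merged = genesets.GeneSetCollection(
        sets={**collection.sets, **go_sets},
        set_type={**collection.set_type, **{sid: "GO" for sid in go_sets}},
        universe=collection.universe,
    )
    genesets.write_gmt(merged, out / "gene_sets.gmt")
    synthetic.write_edges_tsv(dag, out / "ontology_edges.tsv")
    manifest["files"]["gene_sets.gmt"] = {"sha256": _sha256(out / "gene_sets.gmt")}
    manifest["files"]["ontology_edges.tsv"] = {"sha256": _sha256(out / "ontology_edges.tsv")}
    manifest["stages"]["genesets"] = {
        "n_sets": len(merged), "n_go_sets": len(go_sets),
        "n_terms": config.n_ontology_terms, "universe": len(merged.universe),
    }
    return merged, propagated


def _planted_assignments(config: RunConfig, collection) -> dict[tuple[str, tuple[str, str]], dict[str, str]]:
    """Choose planted set statuses per strain x contrast.

    Only the simulated (non-GO) sets are planted.  The first two strains share
    ``share_frac`` of their planted sets per contrast, giving the clustering
    stage a known similar-response pair.
    """
    import numpy as np

    candidates = sorted(sid for sid in collection.sets if collection.set_type[sid] != "GO")
    strains = [f"S{i + 1:02d}" for i in range(config.n_strains)]
    n_en = max(1, int(round(config.frac_enriched_sets * len(candidates))))
    n_dp = max(1, int(round(config.frac_depleted_sets * len(candidates))))
    out: dict[tuple[str, tuple[str, str]], dict[str, str]] = {}
    for ci, contrast in enumerate(config.contrasts):
        base_rng = np.random.default_rng([config.seed, _STAGES.index("de"), ci])
        base_pick = list(base_rng.choice(candidates, size=n_en + n_dp, replace=False))
        for si, strain in enumerate(strains):
            rng = np.random.default_rng([config.seed, _STAGES.index("de"), ci, si])
            if si == 0:
                pick = base_pick
            elif si == 1:
                n_shared = int(round(config.share_frac * len(base_pick)))
                rest = [c for c in candidates if c not in base_pick]
                pick = base_pick[:n_shared] + list(
                    rng.choice(rest, size=len(base_pick) - n_shared, replace=False)
                )
            else:
                pick = list(rng.choice(candidates, size=n_en + n_dp, replace=False))
            out[(strain, contrast)] = {
                **{sid: "enriched" for sid in pick[:n_en]},
                **{sid: "depleted" for sid in pick[n_en:]},
            }
    return out


def _stage_score(config: RunConfig, collection, out: Path, manifest: dict):
    planted = _planted_assignments(config, collection)
    scored_tables: dict[tuple[str, tuple[str, str]], pd.DataFrame] = {}
    truths = {}
    n_deg_total = 0
    for i, ((strain, contrast), statuses) in enumerate(sorted(planted.items())):
        table, truth = synthetic.plant_de_table(
            collection, statuses,
            effect_deg_rate=config.effect_deg_rate,
            effect_unidirectional=config.effect_unidirectional,
            deg_rate_null=config.deg_rate_null,
            deg_alpha=config.deg_alpha,
            strain=strain, contrast=contrast,
            seed=_derive_seed(config.seed, "de", strain, contrast),
        )
        name = f"de_{strain}_{contrast[0]}v{contrast[1]}.tsv"
        synthetic.write_de_tsv(table, out / name)
        manifest["files"][name] = {"sha256": _sha256(out / name), "rows": len(table.frame)}
        scored = scoring.call_degs(table, alpha=config.deg_alpha)
        scored_tables[(strain, contrast)] = scored
        truths[(strain, contrast)] = truth
        n_deg_total += int((scored["deg_label"] != "none").sum())
    manifest["stages"]["score"] = {
        "n_tables": len(scored_tables), "n_degs_total": n_deg_total,
    }
    return scored_tables, truths


def _stage_enrich(config: RunConfig, collection, scored_tables, out: Path, manifest: dict):
    all_calls, all_comps = [], []
    set_types = sorted(set(collection.set_type.values()))
    composites: dict[tuple[str, tuple[str, str]], pd.DataFrame] = {}
    for i, ((strain, contrast), scored) in enumerate(sorted(scored_tables.items())):
        per_type_comps = []
        for ti, stype in enumerate(set_types):
            slice_sets = {
                sid: members for sid, members in collection.sets.items()
                if collection.set_type[sid] == stype
            }
            if not slice_sets:
                continue
            calls_df, comp_df = enrichment.run_enrichment(
                scored, slice_sets,
                alpha=config.enrich_alpha, n_perm=config.n_perm,
                seed=_derive_seed(config.seed, "enrich", strain, contrast, stype),
                ugs_min_degs=config.ugs_min_degs,
            )
            for df in (calls_df, comp_df):
                df.insert(0, "set_type", stype)
                df.insert(0, "contrast", f"{contrast[0]}v{contrast[1]}")
                df.insert(0, "strain", strain)
            all_calls.append(calls_df)
            all_comps.append(comp_df)
            per_type_comps.append(comp_df)
        composites[(strain, contrast)] = pd.concat(per_type_comps, ignore_index=True)
    calls = pd.concat(all_calls, ignore_index=True)
    comps = pd.concat(all_comps, ignore_index=True)
    _write(calls, out / "enrichment_calls.tsv", manifest)
    _write(comps, out / "composite_calls.tsv", manifest)
    manifest["stages"]["enrich"] = {
        "n_families": len(all_comps),
        "n_composite_enriched": int(comps["enriched"].sum()),
        "n_composite_depleted": int(comps["depleted"].sum()),
    }
    return composites


def _stage_cluster(config: RunConfig, collection, composites, out: Path, manifest: dict):
    groups = []
    for (strain, contrast), comp in sorted(composites.items()):
        en, dp = clustering.build_groups(comp, strain, contrast)
        groups.extend([en, dp])
    rows = [
        (g.label, g.strain, f"{g.contrast[0]}v{g.contrast[1]}", g.direction,
         len(g.members), ",".join(sorted(g.members)))
        for g in groups
    ]
    groups_df = pd.DataFrame(
        rows, columns=["label", "strain", "contrast", "direction", "n_sets", "members"]
    )
    _write(groups_df, out / "enrichment_groups.tsv", manifest)

    og_ids = {sid for sid in collection.sets if collection.set_type[sid] == "OG"}
    slices = {
        "orthogroups": og_ids,
        "functional": set(collection.sets) - og_ids,
    }
    cluster_info = {}
    for name, keep in slices.items():
        sliced = {g.label: g.members & keep for g in groups}
        matrix = clustering.jaccard_sqrt_distance(sliced)
        order, _link = clustering.order_groups(matrix)
        outputs = clustering.export_heatmap(
            matrix, order, out / f"response_distance_{name}",
            render_png=config.render_png,
        )
        for p in outputs.values():
            manifest["files"][p.name] = {"sha256": _sha256(p)}
        cluster_info[name] = {"n_groups": len(sliced), "leaf_order": order}
    manifest["stages"]["cluster"] = cluster_info
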