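"""End-to-end pipeline: ingest -> project -> bicluster -> bias filter ->
components -> Monte Carlo -> significant modules, with reproducible outputs.

Outputs written to the run directory:

* ``modules.tsv`` / ``modules.json`` — the significant phenotype-biased
  functional modules with density, bias and Monte Carlo p-values.
* ``modules/<id>.edges.tsv`` — per-module COG edge list (SIF-like).
* ``biclusters.json`` — every maximal bicluster enumerated.
* ``scored_biclusters.json`` — per-bicluster conservation counts and bias.
* ``config.yaml`` and ``run.log`` — the exact configuration (including the
  seed) and per-stage cardinalities.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import bias as bias_mod
from .biclusters import Bicluster, enumerate_maximal_biclusters
from .bipartite import BipartiteMatrix, build_matrix
from .io import (
    CogMapping,
    CogNetwork,
    PanelEntry,
    project_to_cogs,
    read_manifest,
    read_mapping,
    read_network,
)
from .modules import (
    BackgroundGraph,
    FunctionalModule,
    connected_components,
    density,
    filter_significant,
    merge_duplicate_modules,
    monte_carlo_p,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline parameters; defaults follow the published protocol
    (score cutoff 700, organism floor 2, bias cutoff 0.05, W = 1000 Monte
    Carlo draws, significance cutoff 0.05)."""

    manifest: Path
    mapping: Path
    out_dir: Path
    score_cutoff: int = 700
    min_orgs: int = 2
    min_pairs: int = 1
    max_biclusters: int = 100_000
    bias_alpha: float = 0.05
    bias_mode: str = "point"
    bias_correction: str = "none"
    mc_samples: int = 1000
    mc_alpha: float = 0.05
    mc_subset_size_rule: str = "nodes"
    mc_background: str = "expressing"  # edge source: expressing union | all union
    mc_universe: str = "mapping"  # M: mapping COG universe | incident COGs only
    seed: int = 0

    def __post_init__(self) -> None:
        self.manifest = Path(self.manifest)
        self.mapping = Path(self.mapping)
        self.out_dir = Path(self.out_dir)
        if not 0 <= self.score_cutoff <= 1000:
            raise ValueError("score_cutoff must be in [0, 1000]")
        if self.min_orgs < 2:
            raise ValueError("min_orgs must be >= 2")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")
        for name in ("bias_alpha", "mc_alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.bias_mode not in bias_mod.MODES:
            raise ValueError(f"bias_mode must be one of {bias_mod.MODES}")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.mc_subset_size_rule not in ("nodes", "edges"):
            raise ValueError("mc_subset_size_rule must be 'nodes' or 'edges'")
        if self.mc_background not in ("expressing", "all"):
            raise ValueError("mc_background must be 'expressing' or 'all'")
        if self.mc_universe not in ("mapping", "incident"):
            raise ValueError("mc_universe must be 'mapping' or 'incident'")

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("manifest", "mapping", "out_dir"):
            d[k] = str(d[k])
        return d


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    config: RunConfig
    counts: dict[str, int]
    biclusters: list[Bicluster]
    scored: list[tuple[Bicluster, bias_mod.BiasResult]]
    modules: list[FunctionalModule]
    background: BackgroundGraph
    modules_tsv: Path
    modules_json: Path


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage '{name}' failed: {exc}") from exc

    return wrap


def _fmt(x: float) -> str:
    return f"{x:.10g}"


def build_background(
    nets: list[CogNetwork],
    mapping: CogMapping | None,
    universe: str = "mapping",
) -> BackgroundGraph:
    """Null-model universe: edges are the union of the given COG networks;
    M is the mapping's full COG universe (default) or only the COGs
    incident to the union graph."""
    edges = frozenset().union(*(n.edges for n in nets)) if nets else frozenset()
    incident = frozenset(n for e in edges for n in e)
    if universe == "incident" or mapping is None:
        cogs = incident
    else:
        cogs = mapping.cogs | incident
    return BackgroundGraph(cogs=cogs, edges=edges)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full discovery pipeline and write all outputs.

    Raises :class:`StageError` naming the failing stage on any error.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phenomod")
    root.addHandler(handler)
    prior_level = root.level
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(prior_level)


def _run(config: RunConfig, out: Path) -> PipelineResult:
    counts: dict[str, int] = {}
    logger.info("run config: %s", json.dumps(config.to_dict(), sort_keys=True))
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    panel: list[PanelEntry] = _stage("ingest")(read_manifest, config.manifest)
    mapping = _stage("ingest")(read_mapping, config.mapping)
    expressing = [e for e in panel if e.is_expressing]
    non_expressing = [e for e in panel if not e.is_expressing]
    if len(expressing) < config.min_orgs:
        raise StageError(
            f"stage 'ingest' failed: need >= {config.min_orgs} expressing organisms, "
            f"got {len(expressing)}"
        )
    counts["organisms"] = len(panel)
    counts["expressing_organisms"] = len(expressing)
    counts["non_expressing_organisms"] = len(non_expressing)

    def _project(entries: list[PanelEntry]) -> list[CogNetwork]:
        nets = []
        for e in entries:
            pn = read_network(e.path, score_cutoff=config.score_cutoff, organism_id=e.organism_id)
            nets.append(project_to_cogs(pn, mapping))
        return nets

    expr_nets = _stage("project")(_project, expressing)
    nonx_nets = _stage("project")(_project, non_expressing)

    expr_matrix: BipartiteMatrix = _stage("build_matrix")(build_matrix, expr_nets)
    nonx_matrix = (
        _stage("build_matrix")(build_matrix, nonx_nets) if nonx_nets else None
    )
    counts["cog_pairs_expressing"] = len(expr_matrix.cog_pairs)
    counts["cog_pairs_non_expressing"] = (
        len(nonx_matrix.cog_pairs) if nonx_matrix is not None else 0
    )
    logger.info(
        "matrices: expressing %dx%d, non-expressing %s",
        *expr_matrix.shape,
        "x".join(map(str, nonx_matrix.shape)) if nonx_matrix is not None else "absent",
    )

    biclusters = _stage("biclusters")(
        enumerate_maximal_biclusters,
        expr_matrix,
        min_orgs=config.min_orgs,
        min_pairs=config.min_pairs,
        max_output=config.max_biclusters,
    )
    counts["biclusters"] = len(biclusters)
    logger.info("enumerated %d maximal biclusters", len(biclusters))
    bc_ids = {bc: f"B{i:05d}" for i, bc in enumerate(biclusters, start=1)}
    _dump_json(out / "biclusters.json", [
        {
            "id": bc_ids[bc],
            "organisms": sorted(bc.organisms),
            "cog_pairs": [list(p) for p in sorted(bc.cog_pairs)],
        }
        for bc in biclusters
    ])

    panel_labels = {e.organism_id: e.label for e in panel}
    all_results = _stage("bias_test")(
        bias_mod.bias_results, biclusters, nonx_matrix, panel_labels, config.bias_mode
    )
    scored = _stage("bias_test")(
        bias_mod.score_biclusters,
        biclusters,
        nonx_matrix,
        panel_labels,
        config.bias_alpha,
        config.bias_mode,
        config.bias_correction,
    )
    counts["biased_biclusters"] = len(scored)
    _dump_json(out / "scored_biclusters.json", [
        {
            "id": bc_ids[bc],
            "P": r.P, "S": r.S, "X": r.X, "Y": r.Y,
            "p_value": r.p_value, "mode": r.mode,
            "retained": r.p_value <= config.bias_alpha
            if config.bias_correction == "none"
            else bc in {b for b, _ in scored},
        }
        for bc, r in zip(biclusters, all_results)
    ])

    candidates: list[FunctionalModule] = []
    n_components = 0
    for bc, res in scored:
        comps = _stage("components")(connected_components, bc.cog_pairs)
        n_components += len(comps)
        for nodes, edges in comps:
            candidates.append(
                FunctionalModule(
                    cogs=nodes,
                    edges=edges,
                    density=density(nodes, edges),
                    bias_p=res.p_value,
                    source_bicluster_ids=frozenset({bc_ids[bc]}),
                    organisms=bc.organisms,
                )
            )
    counts["components"] = n_components
    candidates = merge_duplicate_modules(candidates)
    counts["candidate_modules"] = len(candidates)

    bg_nets = expr_nets if config.mc_background == "expressing" else expr_nets + nonx_nets
    background = _stage("monte_carlo")(
        build_background, bg_nets, mapping, config.mc_universe
    )
    logger.info(
        "background universe: |M|=%d COGs, %d edges (%s edges, %s universe)",
        len(background.cogs), len(background.edges),
        config.mc_background, config.mc_universe,
    )
    scored_modules = []
    for idx, mod in enumerate(candidates):
        seed = np.random.SeedSequence([config.seed, idx])
        p = _stage("monte_carlo")(
            monte_carlo_p,
            mod,
            background,
            W=config.mc_samples,
            seed=seed,
            subset_size_rule=config.mc_subset_size_rule,
        )
        mod.mc_p = p
        scored_modules.append(mod)

    significant = _stage("significance_filter")(
        filter_significant, scored_modules, config.mc_alpha
    )
    counts["significant_modules"] = len(significant)
    logger.info("stage counts: %s", json.dumps(counts, sort_keys=True))

    modules_tsv, modules_json = _stage("write_output")(
        _write_modules, out, significant, config
    )
    return PipelineResult(
        config=config,
        counts=counts,
        biclusters=biclusters,
        scored=scored,
        modules=significant,
        background=background,
        modules_tsv=modules_tsv,
        modules_json=modules_json,
    )


def _dump_json(path: Path, obj) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def _write_modules(
    out: Path, modules: list[FunctionalModule], config: RunConfig
) -> tuple[Path, Path]:
    tsv = out / "modules.tsv"
    edge_dir = out / "modules"
    edge_dir.mkdir(exist_ok=True)
    records = []
    with open(tsv, "w", encoding="utf-8") as fh:
        fh.write(
            "module_id\tcogs\tn_cogs\tn_edges\tdensity\tbias_p\tmc_p\tmc_p_note\t"
            "organisms\tsource_biclusters\n"
        )
        for i, mod in enumerate(modules, start=1):
            mid = f"M{i:04d}"
            note = f"<{_fmt(1.0 / config.mc_samples)}" if mod.mc_p == 0.0 else ""
            fh.write(
                "\t".join([
                    mid,
                    ";".join(sorted(mod.cogs)),
                    str(len(mod.cogs)),
                    str(len(mod.edges)),
                    _fmt(mod.density),
                    _fmt(mod.bias_p) if mod.bias_p is not None else "",
                    _fmt(mod.mc_p),
                    note,
                    ";".join(sorted(mod.organisms)),
                    ";".join(sorted(mod.source_bicluster_ids)),
                ]) + "\n"
            )
            with open(edge_dir / f"{mid}.edges.tsv", "w", encoding="utf-8") as ef:
                ef.write("cog_a\tcog_b\n")
                for u, v in sorted(mod.edges):
                    ef.write(f"{u}\t{v}\n")
            records.append({
                "module_id": mid,
                "cogs": sorted(mod.cogs),
                "edges": [list(e) for e in sorted(mod.edges)],
                "density": mod.density,
                "bias_p": mod.bias_p,
                "mc_p": mod.mc_p,
                "mc_p_note": note,
                "organisms": sorted(mod.organisms),
                "source_biclusters": sorted(mod.source_bicluster_ids),
            })
    mjson = out / "modules.json"
    _dump_json(mjson, records)
    return tsv, mjson
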