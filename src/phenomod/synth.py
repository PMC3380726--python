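"""Synthetic organism panels with planted conserved modules.

Generates the three pipeline inputs (per-organism STRING-dialect network
files, a protein-to-COG mapping, a panel manifest) for a panel of
phenotype-expressing and non-expressing organisms over a shared COG
universe.  Each "planted" module is a fixed COG edge set inserted into a
chosen number of carrier organisms from each class; every organism
additionally receives independent background COG edges at a fixed
probability.  Planted edges are written with scores >= 900 and background
edges with scores in [701, 1000], so both survive the default score cutoff
of 700; everything is deterministic given the seed.

The defaults describe a panel of 10 expressing and 10 non-expressing
organisms over 30 COGs with background edge probability 0.02 and a single
planted 5-COG, 6-edge module carried by 8 expressing and 1 non-expressing
organism — a conserved subsystem strongly biased toward the expressing
class, with conservation counts (P, S, X, Y) = (20, 10, 9, 8).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import numpy as np
import yaml

from .io import CogPair, canonical_pair


@dataclass(frozen=True)
class PlantedModule:
    """A fixed COG edge set inserted into carrier organisms."""

    edges: tuple[CogPair, ...]
    n_expr_carriers: int
    n_nonexpr_carriers: int

    @property
    def cogs(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    @property
    def edge_set(self) -> frozenset[CogPair]:
        return frozenset(canonical_pair(u, v) for u, v in self.edges)


def default_planted_module() -> PlantedModule:
    """5 COGs, 6 edges (a 5-cycle plus one chord, density 0.6), carried by
    8 of the expressing and 1 of the non-expressing organisms."""
    c = [f"COG{i:04d}" for i in range(1, 6)]
    edges = (
        (c[0], c[1]), (c[1], c[2]), (c[2], c[3]), (c[3], c[4]),
        (c[0], c[4]), (c[0], c[2]),
    )
    return PlantedModule(edges=edges, n_expr_carriers=8, n_nonexpr_carriers=1)


@dataclass
class SynthSpec:
    """Parameters of a synthetic panel (defaults are the standard benchmark
    panel described in the module docstring)."""

    n_expressing: int = 10
    n_non_expressing: int = 10
    n_cogs: int = 30
    background_edge_prob: float = 0.02
    planted_modules: list[PlantedModule] = field(
        default_factory=lambda: [default_planted_module()]
    )
    proteins_per_cog: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ValueError("background_edge_prob must be in [0, 1]")
        if self.proteins_per_cog < 1:
            raise ValueError("proteins_per_cog must be >= 1")
        universe = set(self.cogs)
        for pm in self.planted_modules:
            if pm.n_expr_carriers > self.n_expressing:
                raise ValueError("n_expr_carriers exceeds n_expressing")
            if pm.n_nonexpr_carriers > self.n_non_expressing:
                raise ValueError("n_nonexpr_carriers exceeds n_non_expressing")
            if not pm.cogs <= universe:
                raise ValueError(
                    f"planted COGs outside the universe: {sorted(pm.cogs - universe)}"
                )

    @property
    def cogs(self) -> list[str]:
        return [f"COG{i:04d}" for i in range(1, self.n_cogs + 1)]


@dataclass
class Panel:
    """Paths and ground truth of a generated panel."""

    directory: Path
    manifest: Path
    mapping: Path
    networks: dict[str, Path]
    labels: dict[str, str]
    intended_cog_edges: dict[str, frozenset[CogPair]]
    carriers: list[tuple[frozenset[str], frozenset[str]]]  # per planted module


def spec_to_yaml(spec: SynthSpec, path: str | Path) -> None:
    doc = asdict(spec)
    doc["planted_modules"] = [
        {
            "edges": [list(e) for e in pm.edges],
            "n_expr_carriers": pm.n_expr_carriers,
            "n_nonexpr_carriers": pm.n_nonexpr_carriers,
        }
        for pm in spec.planted_modules
    ]
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def spec_from_yaml(path: str | Path) -> SynthSpec:
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    planted = [
        PlantedModule(
            edges=tuple(tuple(e) for e in pm["edges"]),
            n_expr_carriers=int(pm["n_expr_carriers"]),
            n_nonexpr_carriers=int(pm["n_nonexpr_carriers"]),
        )
        for pm in doc.get("planted_modules", [])
    ]
    kwargs = {k: v for k, v in doc.items() if k != "planted_modules"}
    return SynthSpec(planted_modules=planted, **kwargs)


def _protein(cog: str, k: int) -> str:
    return f"{cog}.p{k + 1}"


def generate_panel(spec: SynthSpec, out_dir: str | Path) -> Panel:
    """Write a full synthetic panel into ``out_dir``.

    Carrier organisms receive every planted edge; every organism receives
    independent Bernoulli background edges over the COG universe.  Each COG
    edge is rendered as a single protein-level edge between randomly chosen
    member proteins (so the many-to-one projection is exercised).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    cogs = spec.cogs
    all_pairs = [canonical_pair(u, v) for u, v in combinations(cogs, 2)]
    expr_orgs = [f"expr{i:02d}" for i in range(1, spec.n_expressing + 1)]
    nonx_orgs = [f"nonx{i:02d}" for i in range(1, spec.n_non_expressing + 1)]

    carriers: list[tuple[frozenset[str], frozenset[str]]] = []
    planted_for: dict[str, set[CogPair]] = {o: set() for o in expr_orgs + nonx_orgs}
    for pm in spec.planted_modules:
        ec = rng.choice(len(expr_orgs), size=pm.n_expr_carriers, replace=False)
        nc = rng.choice(len(nonx_orgs), size=pm.n_nonexpr_carriers, replace=False)
        e_set = frozenset(expr_orgs[i] for i in sorted(ec))
        n_set = frozenset(nonx_orgs[i] for i in sorted(nc))
        carriers.append((e_set, n_set))
        for org in e_set | n_set:
            planted_for[org] |= pm.edge_set

    # mapping file: the full COG universe, proteins_per_cog proteins each
    mapping_path = out_dir / "cog_mapping.tsv"
    with open(mapping_path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tcog_id\n")
        for cog in cogs:
            for k in range(spec.proteins_per_cog):
                fh.write(f"{_protein(cog, k)}\t{cog}\n")

    labels: dict[str, str] = {}
    networks: dict[str, Path] = {}
    intended: dict[str, frozenset[CogPair]] = {}
    manifest_rows = []
    for org, label in [(o, "expressing") for o in expr_orgs] + [
        (o, "non_expressing") for o in nonx_orgs
    ]:
        planted = planted_for[org]
        bg_mask = rng.random(len(all_pairs)) < spec.background_edge_prob
        edges: dict[CogPair, str] = {}
        for pair, hit in zip(all_pairs, bg_mask):
            if hit:
                edges[pair] = "background"
        for pair in planted:
            edges[pair] = "planted"
        net_path = out_dir / f"{org}.links.txt"
        with open(net_path, "w", encoding="utf-8") as fh:
            fh.write("protein1 protein2 combined_score\n")
            for pair in sorted(edges):
                u, v = pair
                kind = edges[pair]
                score = (
                    int(rng.integers(900, 1001))
                    if kind == "planted"
                    else int(rng.integers(701, 1001))
                )
                pu = _protein(u, int(rng.integers(spec.proteins_per_cog)))
                pv = _protein(v, int(rng.integers(spec.proteins_per_cog)))
                fh.write(f"{pu} {pv} {score}\n")
        labels[org] = label
        networks[org] = net_path
        intended[org] = frozenset(edges)
        manifest_rows.append((org, net_path.name, label))

    manifest_path = out_dir / "panel.tsv"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        fh.write("organism_id\tpath\tlabel\n")
        for org, name, label in manifest_rows:
            fh.write(f"{org}\t{name}\t{label}\n")

    return Panel(
        directory=out_dir,
        manifest=manifest_path,
        mapping=mapping_path,
        networks=networks,
        labels=labels,
        intended_cog_edges=intended,
        carriers=carriers,
    )


def panel_digest(panel: Panel) -> str:
    """SHA-256 over all generated files (stability checks)."""
    h = hashlib.sha256()
    for path in sorted([panel.manifest, panel.mapping, *panel.networks.values()]):
        h.update(path.name.encode())
        h.update(path.read_bytes())
    return h.hexdigest()
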