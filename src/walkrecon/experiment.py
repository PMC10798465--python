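"""Sweep orchestration: walk -> reconstruct -> score, over full grids.

Two experiment designs are provided:

* :func:`run_sweep` — recovery versus walk length: for every combination of
  network, dynamics, walk length ``w`` and repetition, run an independent
  walk of ``w`` visited nodes, reconstruct, and record per-metric Pearson
  and Spearman correlations, the knowledge fraction (share of original
  nodes discovered) and, where a reference partition exists, the NMI/ARI
  of Leiden communities on the reconstruction against that reference.

* :func:`run_coverage_sweep` — recovery versus knowledge acquired: one long
  walk per (network, dynamics, repetition) evaluated at nested prefixes on
  the walk-length grid, so each row pairs a correlation with the coverage
  reached at that length.  ``fresh_walks=True`` switches to independent
  walks per length.

Every cell derives its own seed deterministically from the global seed and
the cell coordinates, so any record can be reproduced in isolation and
repeated runs are byte-identical.
"""

from __future__ import annotations

import json
import logging
import math
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from walkrecon._version import __version__ as _pkg_version
from walkrecon.communities import detect_leiden, partition_agreement
from walkrecon.netmodels import (
    LFRParams,
    generate_ba,
    generate_er,
    generate_lfr,
    generate_waxman,
    largest_component,
    load_edgelist,
    load_gml,
    relabel_to_range,
)
from walkrecon.nodemetrics import METRICS, compute_property, matched_correlation
from walkrecon.reconstruction import knowledge_fraction, reconstruct
from walkrecon.walkers import DEFAULT_LAMBDA, DYNAMICS, WalkSequence, run_walk, walk_until_unique

logger = logging.getLogger(__name__)

#: walk-length grid used throughout the recovery experiments
DEFAULT_WALK_LENGTHS = (100, 200, 400, 500, 600, 800, 1000, 2000, 5000, 20000, 50000)

RECORD_COLUMNS = [
    "record_type",
    "network_id",
    "dynamics",
    "w",
    "repetition",
    "metric",
    "pearson",
    "spearman",
    "knowledge",
    "nmi",
    "ari",
    "n_matched",
    "error",
]


def cell_seed(global_seed: int, *parts) -> int:
    """Deterministic per-cell seed (< 2**31) from the global seed and coordinates."""
    text = "|".join(str(p) for p in (global_seed, *parts))
    return zlib.crc32(text.encode()) & 0x7FFFFFFF


@dataclass
class SweepConfig:
    """Declarative description of a sweep.

    ``networks`` is a list of specs, each a dict with either a generator
    (``{"model": "er"|"ba"|"waxman"|"lfr", ...params}``) or a file
    (``{"path": ..., "format": "edgelist"|"gml"}``), plus an optional
    ``"id"``.  ``communities`` controls partition scoring: None means
    automatic (on for modular/LFR networks, off otherwise).
    """

    networks: list = field(default_factory=list)
    dynamics: tuple = DYNAMICS
    walk_lengths: tuple = DEFAULT_WALK_LENGTHS
    repetitions: int = 20
    metrics: tuple = METRICS
    seed: int = 0
    lam: float = DEFAULT_LAMBDA
    communities: bool | None = None
    fresh_walks: bool = False
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        if any(w < 1 for w in self.walk_lengths):
            raise ValueError("walk lengths must be >= 1")
        unknown = set(self.dynamics) - set(DYNAMICS)
        if unknown:
            raise ValueError(f"unknown dynamics: {sorted(unknown)}")
        unknown = set(self.metrics) - set(METRICS)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")

    @classmethod
    def from_file(cls, path) -> "SweepConfig":
        """Load from a JSON or YAML file mirroring the dataclass fields."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        for key in ("dynamics", "walk_lengths", "metrics"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class BuiltNetwork:
    graph: nx.Graph
    planted: dict | None
    network_id: str


def build_network(spec: dict, seed: int) -> BuiltNetwork:
    """Generate or load a network, reduce it to its largest component and
    relabel nodes to ``0..n-1``.  LFR specs also return the planted partition."""
    spec = dict(spec)
    planted = None
    if "path" in spec:
        fmt = spec.get("format", "edgelist")
        loader = load_gml if fmt == "gml" else load_edgelist
        g = loader(spec["path"])
        network_id = spec.get("id", Path(spec["path"]).stem)
        g, _ = relabel_to_range(largest_component(g))
        return BuiltNetwork(g, None, network_id)

    model = spec.get("model")
    n = int(spec.get("n", 5000))
    avg_degree = float(spec.get("avg_degree", 4.0))
    if model == "er":
        g = generate_er(n, avg_degree, seed=seed)
        g, _ = relabel_to_range(largest_component(g))
        default_id = f"er-n{n}-k{avg_degree:g}"
    elif model == "ba":
        m = int(spec.get("m", 2))
        g = generate_ba(n, m, seed=seed)
        g, _ = relabel_to_range(largest_component(g))
        default_id = f"ba-n{n}-m{m}"
    elif model == "waxman":
        g = generate_waxman(n, avg_degree, seed=seed, alpha=float(spec.get("alpha", 0.1)))
        default_id = f"waxman-n{n}-k{avg_degree:g}"
    elif model == "lfr":
        params = LFRParams(
            n_communities=int(spec.get("n_communities", 5)),
            degree_exponent=float(spec.get("t1", 3.0)),
            community_size_exponent=float(spec.get("t2", 0.0)),
            mu=float(spec.get("mu", 0.05)),
            n_nodes=n,
            avg_degree=avg_degree,
        )
        g, planted = generate_lfr(params, seed=seed)
        default_id = f"lfr-n{n}-mu{params.mu:g}"
    else:
        raise ValueError(f"network spec needs a 'model' or 'path' key: {spec}")
    return BuiltNetwork(g, planted, spec.get("id", default_id))


def _reference_partition(built: BuiltNetwork, config: SweepConfig) -> dict | None:
    """Planted labels when available, Leiden on the original otherwise."""
    use = config.communities
    if use is None:
        use = built.planted is not None
    if not use:
        return None
    if built.planted is not None:
        return built.planted
    return detect_leiden(built.graph, seed=cell_seed(config.seed, built.network_id, "leiden-ref"))


def _score_cell(
    built: BuiltNetwork,
    orig_props: dict,
    ref_partition: dict | None,
    seq: WalkSequence,
    config: SweepConfig,
    dynamics: str,
    w: int,
    rep: int,
    walk_seed: int,
) -> list[dict]:
    """Rows for one (dynamics, w, repetition) cell: one per metric."""
    recon = reconstruct(seq)
    kf = knowledge_fraction(seq, built.graph.number_of_nodes())
    nmi = ari = float("nan")
    if ref_partition is not None and recon.graph.number_of_nodes() >= 2:
        detected = detect_leiden(recon.graph, seed=walk_seed)
        nmi, ari = partition_agreement(ref_partition, detected, recon.graph.nodes())
    rows = []
    for metric in config.metrics:
        recon_vals = compute_property(recon.graph, metric)
        corr = matched_correlation(orig_props[metric], recon_vals)
        if not corr.defined:
            logger.warning(
                "undefined correlation: %s %s w=%d rep=%d metric=%s (n=%d)",
                built.network_id, dynamics, w, rep, metric, corr.n_matched,
            )
        rows.append(
            {
                "record_type": "cell",
                "network_id": built.network_id,
                "dynamics": dynamics,
                "w": w,
                "repetition": rep,
                "metric": metric,
                "pearson": corr.pearson,
                "spearman": corr.spearman,
                "knowledge": kf,
                "nmi": nmi,
                "ari": ari,
                "n_matched": corr.n_matched,
                "error": "",
            }
        )
    return rows


def _error_rows(built, config, dynamics, w, rep, exc) -> list[dict]:
    return [
        {
            "record_type": "cell",
            "network_id": built.network_id,
            "dynamics": dynamics,
            "w": w,
            "repetition": rep,
            "metric": metric,
            "pearson": float("nan"),
            "spearman": float("nan"),
            "knowledge": float("nan"),
            "nmi": float("nan"),
            "ari": float("nan"),
            "n_matched": 0,
            "error": f"{type(exc).__name__}: {exc}",
        }
        for metric in config.metrics
    ]


def _aggregate(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration mean/sd rows; undefined (NaN) correlations excluded."""
    if cells.empty:
        return cells
    grouped = cells.groupby(["network_id", "dynamics", "w", "metric"], sort=True)
    rows = []
    for (net_id, dyn, w, metric), sub in grouped:
        row = {
            "record_type": "aggregate",
            "network_id": net_id,
            "dynamics": dyn,
            "w": w,
            "repetition": -1,
            "metric": metric,
            "pearson": sub["pearson"].mean(),
            "spearman": sub["spearman"].mean(),
            "knowledge": sub["knowledge"].mean(),
            "nmi": sub["nmi"].mean(),
            "ari": sub["ari"].mean(),
            "n_matched": int(sub["n_matched"].mean()),
            "error": f"n_undefined={int(sub['pearson'].isna().sum())}",
        }
        rows.append(row)
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def run_sweep(config: SweepConfig) -> pd.DataFrame:
    """Recovery-versus-walk-length experiment over the full configuration grid.

    Returns a tidy table with one ``cell`` row per (network, dynamics, walk
    length, repetition, metric) and ``aggregate`` rows carrying
    per-configuration means.  When ``config.out_dir`` is set, one CSV per
    network plus a JSON run manifest are written there.
    """
    all_rows: list[dict] = []
    for spec in config.networks:
        built = build_network(spec, seed=cell_seed(config.seed, _spec_id(spec), "network"))
        t0 = time.time()
        orig_props = {m: compute_property(built.graph, m) for m in config.metrics}
        ref_partition = _reference_partition(built, config)
        logger.info(
            "%s: n=%d m=%d, original metrics in %.1fs",
            built.network_id, built.graph.number_of_nodes(),
            built.graph.number_of_edges(), time.time() - t0,
        )
        for dynamics in config.dynamics:
            t0 = time.time()
            for w in config.walk_lengths:
                for rep in range(config.repetitions):
                    s = cell_seed(config.seed, built.network_id, dynamics, w, rep)
                    try:
                        seq = run_walk(built.graph, dynamics, w, seed=s, lam=config.lam)
                        all_rows.extend(
                            _score_cell(
                                built, orig_props, ref_partition, seq,
                                config, dynamics, w, rep, s,
                            )
                        )
                    except Exception as exc:  # keep sweeping; the record carries the tag
                        logger.warning(
                            "cell failed: %s %s w=%d rep=%d: %s",
                            built.network_id, dynamics, w, rep, exc,
                        )
                        all_rows.extend(_error_rows(built, config, dynamics, w, rep, exc))
            logger.info("%s / %s: swept in %.1fs", built.network_id, dynamics, time.time() - t0)
    cells = pd.DataFrame(all_rows, columns=RECORD_COLUMNS)
    result = pd.concat([cells, _aggregate(cells)], ignore_index=True)
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def run_until_coverage(
    net: nx.Graph,
    dynamics: str,
    target_fraction: float,
    seed: int | None = None,
    max_steps: int | None = None,
    lam: float = DEFAULT_LAMBDA,
) -> tuple[WalkSequence, int, bool]:
    """Walk until the knowledge fraction first reaches ``target_fraction``.

    Returns (sequence truncated at the crossing, its length, reached-flag).
    The flag is False when the step cap was hit first.
    """
    if not 0 < target_fraction <= 1:
        raise ValueError("target_fraction must be in (0, 1]")
    target_unique = math.ceil(target_fraction * net.number_of_nodes())
    seq, reached = walk_until_unique(
        net, dynamics, target_unique, seed=seed, max_steps=max_steps, lam=lam
    )
    return seq, len(seq), reached


def run_coverage_sweep(config: SweepConfig) -> pd.DataFrame:
    """Recovery-versus-knowledge experiment.

    By default each (network, dynamics, repetition) runs one walk of
    ``max(walk_lengths)`` nodes whose nested prefixes are evaluated at every
    length on the grid; the knowledge fraction of each prefix supplies the
    x-coordinate.  ``config.fresh_walks`` switches to an independent walk
    per length (same seeds as :func:`run_sweep`).
    """
    if config.fresh_walks:
        return run_sweep(config)
    all_rows: list[dict] = []
    w_max = max(config.walk_lengths)
    for spec in config.networks:
        built = build_network(spec, seed=cell_seed(config.seed, _spec_id(spec), "network"))
        orig_props = {m: compute_property(built.graph, m) for m in config.metrics}
        ref_partition = _reference_partition(built, config)
        for dynamics in config.dynamics:
            for rep in range(config.repetitions):
                s = cell_seed(config.seed, built.network_id, dynamics, "coverage", rep)
                seq = run_walk(built.graph, dynamics, w_max, seed=s, lam=config.lam)
                for w in sorted(config.walk_lengths):
                    all_rows.extend(
                        _score_cell(
                            built, orig_props, ref_partition, seq.prefix(w),
                            config, dynamics, w, rep, s,
                        )
                    )
    cells = pd.DataFrame(all_rows, columns=RECORD_COLUMNS)
    result = pd.concat([cells, _aggregate(cells)], ignore_index=True)
    if config.out_dir is not None:
        _write_outputs(result, config)
    return result


def _spec_id(spec: dict) -> str:
    return spec.get("id") or spec.get("model") or str(spec.get("path"))


def _write_outputs(records: pd.DataFrame, config: SweepConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for net_id, sub in records.groupby("network_id", sort=True):
        sub.to_csv(out / f"records_{net_id}.csv", index=False)
    manifest = {
        "walkrecon_version": _pkg_version,
        "seed": config.seed,
        "dynamics": list(config.dynamics),
        "walk_lengths": list(config.walk_lengths),
        "repetitions": config.repetitions,
        "metrics": list(config.metrics),
        "lambda": config.lam,
        "networks": config.networks,
        "fresh_walks": config.fresh_walks,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
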