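"""End-to-end comparative analysis: load -> consensus -> decomposition ->
correlations -> phylogenetic mixed-model fits -> report.

The report mirrors the result set of a comparative telomere study: the
allometric lifespan decomposition, a phylogenetic-signal table for the five
analysis traits, and — for each of the six telomere-trait x lifespan-aspect
pairs — the unadjusted Pearson correlation next to the phylogeny-adjusted
posterior summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from telopace._version import __version__ as _version
from telopace.pmm import PMMConfig, fit_bivariate, fit_univariate
from telopace.traits_stats import (
    TraitTable,
    decompose_lifespan,
    pearson_with_inference,
)
from telopace.treeio import (
    majority_consensus,
    normalize_species_name,
    parse_newick_trees,
    tree_to_phylo_covariance,
)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisReport", "run_analysis", "analyze", "write_report"]

#: the six studied pairs: telomere traits x aspects of longevity
CORRELATION_PAIRS: list[tuple[str, str]] = [
    ("telomere_length", "log_lifespan"),
    ("telomere_length", "mass_predicted"),
    ("telomere_length", "mass_independent"),
    ("troc", "log_lifespan"),
    ("troc", "mass_predicted"),
    ("troc", "mass_independent"),
]

SIGNAL_TRAITS = [
    "log_lifespan",
    "log_mass",
    "mass_independent",
    "telomere_length",
    "troc",
]


@dataclass
class AnalysisReport:
    """Full result set of one pipeline run; JSON-serialisable throughout."""

    decomposition: dict
    signal_table: dict
    correlation_table: list
    provenance: dict
    decomposition_frame: pd.DataFrame | None = field(default=None, repr=False)
    consensus_newick: str | None = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "decomposition": self.decomposition,
            "signal_table": self.signal_table,
            "correlation_table": self.correlation_table,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisReport":
        return cls(
            decomposition=d["decomposition"],
            signal_table=d["signal_table"],
            correlation_table=d["correlation_table"],
            provenance=d["provenance"],
        )


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def _load_config(config) -> dict:
    if config is None:
        return {}
    if isinstance(config, dict):
        return config
    text = Path(config).read_text()
    return yaml.safe_load(text) or {}


def analyze(
    traits: TraitTable,
    trees: list[dendropy.Tree],
    config: dict | None = None,
    seed: int = 0,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run the full analysis on in-memory inputs.

    ``config`` may carry a ``pmm`` block (n_iter, burn_in, thin, priors).
    Per-fit seeds are spawned deterministically from ``seed``. Species
    present in only one of table/tree are dropped with a warning; fewer
    than 3 shared species is an error.
    """
    config = config or {}
    pmm_opts = dict(config.get("pmm", {}))

    tree = majority_consensus(trees) if len(trees) > 1 else trees[0]

    # match tree tips and table rows after name normalization
    tip_by_norm = {
        normalize_species_name(leaf.taxon.label): leaf.taxon.label
        for leaf in tree.leaf_node_iter()
    }
    shared, tip_labels = [], []
    for sp in traits.species:
        key = normalize_species_name(sp)
        if key in tip_by_norm:
            shared.append(sp)
            tip_labels.append(tip_by_norm[key])
    n_drop = (traits.n_species - len(shared)) + (len(tip_by_norm) - len(shared))
    if n_drop:
        logger.warning(
            "%d species dropped (present in only the table or only the tree)",
            n_drop,
        )
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} species shared between table and tree")

    traits = traits.subset(shared)
    A = tree_to_phylo_covariance(tree, tip_labels)

    decomp = decompose_lifespan(traits)
    columns = {
        "log_lifespan": traits["log_lifespan"],
        "log_mass": traits["log_mass"],
        "mass_predicted": decomp.mass_predicted,
        "mass_independent": decomp.mass_independent,
        "telomere_length": traits["telomere_length"],
        "troc": traits["troc"],
    }

    unadjusted = {
        f"{x}~{y}": pearson_with_inference(columns[x], columns[y]).as_dict()
        for x, y in CORRELATION_PAIRS + [("log_lifespan", "log_mass")]
    }

    seeds = _child_seeds(seed, len(SIGNAL_TRAITS) + len(CORRELATION_PAIRS))
    signal_table = {}
    for trait, s in zip(SIGNAL_TRAITS, seeds):
        cfg = PMMConfig.from_dict({**pmm_opts, "seed": s})
        res = fit_univariate(columns[trait], A, cfg)
        signal_table[trait] = res.summary_dict()

    correlation_table = []
    for (x, y), s in zip(CORRELATION_PAIRS, seeds[len(SIGNAL_TRAITS) :]):
        cfg = PMMConfig.from_dict({**pmm_opts, "seed": s})
        res = fit_bivariate(columns[x], columns[y], A, cfg)
        correlation_table.append(
            {
                "pair": f"{x}~{y}",
                "unadjusted": unadjusted[f"{x}~{y}"],
                "adjusted": res.summary_dict(),
            }
        )
    correlation_table.append(
        {
            "pair": "log_lifespan~log_mass",
            "unadjusted": unadjusted["log_lifespan~log_mass"],
            "adjusted": None,
        }
    )

    prov = {
        "seed": seed,
        "config": config,
        "version": _version,
        "n_species": traits.n_species,
        "n_trees": len(trees),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    prov.update(provenance or {})

    return AnalysisReport(
        decomposition=decomp.summary_dict(),
        signal_table=signal_table,
        correlation_table=correlation_table,
        provenance=prov,
        decomposition_frame=decomp.to_frame(traits),
        consensus_newick=tree.as_string(schema="newick", suppress_rooting=True),
    )


def run_analysis(
    traits_csv, trees_newick, config=None, seed: int = 0
) -> AnalysisReport:
    """File-based entry point: trait CSV + Newick tree sample -> report."""
    from telopace.traits_stats import load_traits

    traits = load_traits(traits_csv)
    trees = parse_newick_trees(trees_newick)
    cfg = _load_config(config)
    prov = {
        "traits_csv": str(traits_csv),
        "traits_sha256": _file_sha256(traits_csv),
        "trees_newick": str(trees_newick),
        "trees_sha256": _file_sha256(trees_newick),
    }
    return analyze(traits, trees, cfg, seed=seed, provenance=prov)


def _correlations_frame(report: AnalysisReport) -> pd.DataFrame:
    rows = []
    for entry in report.correlation_table:
        u = entry["unadjusted"]
        adj = entry["adjusted"] or {}
        rows.append(
            {
                "pair": entry["pair"],
                "r": u["r"],
                "t": u["t"],
                "df": u["df"],
                "p": u["p"],
                "ci_low": u["ci_low"],
                "ci_high": u["ci_high"],
                "effect": u["effect"],
                "adjusted_r": adj.get("adjusted_r"),
                "adjusted_hpd_low": (adj.get("adjusted_r_hpd") or [None, None])[0],
                "adjusted_hpd_high": (adj.get("adjusted_r_hpd") or [None, None])[1],
                "pmcmc": adj.get("pmcmc"),
                "r_phylo": adj.get("r_phylo_mode"),
                "r_total": adj.get("r_total_mode"),
            }
        )
    return pd.DataFrame(rows)


def write_report(report: AnalysisReport, out_dir) -> dict[str, Path]:
    """Write report.json plus tabular/plot-ready exports to ``out_dir``.

    Emits: ``report.json`` (full, round-trips to an equal report),
    ``correlations.csv`` (one row per pair plus the allometry itself),
    ``signal.csv``, ``figure_data.csv`` (pair, r, ci_low, ci_high,
    adjusted_r: the quantities a forest-style correlation figure plots),
    ``decomposition.csv``, ``consensus.nwk``, and ``run.log``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["report"] = out / "report.json"
    paths["report"].write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))

    corr = _correlations_frame(report)
    paths["correlations"] = out / "correlations.csv"
    corr.to_csv(paths["correlations"], index=False)

    sig = pd.DataFrame(
        [
            {
                "trait": t,
                "rho": s["rho"],
                "rho_mean": s["rho_mean"],
                "hpd_low": s["rho_hpd"][0],
                "hpd_high": s["rho_hpd"][1],
                "ess": s["ess"],
            }
            for t, s in report.signal_table.items()
        ]
    )
    paths["signal"] = out / "signal.csv"
    sig.to_csv(paths["signal"], index=False)

    fig = corr[corr["adjusted_r"].notna()][
        ["pair", "r", "ci_low", "ci_high", "adjusted_r"]
    ]
    paths["figure_data"] = out / "figure_data.csv"
    fig.to_csv(paths["figure_data"], index=False)

    if report.decomposition_frame is not None:
        paths["decomposition"] = out / "decomposition.csv"
        report.decomposition_frame.to_csv(paths["decomposition"], index=False)
    if report.consensus_newick is not None:
        paths["consensus"] = out / "consensus.nwk"
        paths["consensus"].write_text(report.consensus_newick)

    paths["log"] = out / "run.log"
    warn_lines = []
    for t, s in report.signal_table.items():
        for w in s.get("warnings", []):
            warn_lines.append(f"signal[{t}]: {w}")
    for entry in report.correlation_table:
        for w in (entry.get("adjusted") or {}).get("warnings", []):
            warn_lines.append(f"adjusted[{entry['pair']}]: {w}")
    paths["log"].write_text(
        "\n".join(
            [f"telopace {_version}", f"provenance: {json.dumps(report.provenance)}"]
            + warn_lines
        )
        + "\n"
    )
    return paths
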