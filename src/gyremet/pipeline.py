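"""End-to-end orchestration: rates → community → networks → linkage.

Seasons are analyzed as independent strata (one network, one PCA per
season); cross-season contrasts use the Wilcoxon rank-sum test.  Every
source of randomness flows from a named per-stage seed recorded in the run
manifest, and two runs with the same inputs and seeds produce byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import shutil
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from gyremet import community, conet, io, linkage, rates

__all__ = ["PipelineConfig", "PipelineError", "validate_inputs", "run_all"]

WILCOXON_VARS = ("temperature", "salinity", "chl_a", "ba", "bp", "br", "richness", "shannon")


class PipelineError(RuntimeError):
    """Stage-tagged pipeline failure."""


@dataclass
class PipelineConfig:
    metadata: str
    rates: str
    asv: str
    taxonomy: str
    out_dir: str
    rarefy_depth: int = 49_920
    min_prevalence: int = 5
    r_threshold: float = 0.75
    p_threshold: float = 0.001
    correlation_method: str = "spearman"
    n_permutations: int = 999
    rarefy_seed: int = 7
    network_seed: int = 7
    permanova_seed: int = 7
    banned_lineages: tuple = community.DEFAULT_BANNED

    def __post_init__(self) -> None:
        if self.rarefy_depth < 1:
            raise ValueError("rarefy_depth must be >= 1")
        if not (0 < self.r_threshold < 1 and 0 < self.p_threshold < 1):
            raise ValueError("correlation thresholds must lie in (0, 1)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["banned_lineages"] = list(self.banned_lineages)
        return d


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def validate_inputs(paths: dict) -> dict:
    """Schema checks per file plus cross-file sample-set agreement."""
    report: dict = {"files": {}, "cross_checks": [], "passed": True}
    readers = {
        "metadata": io.read_metadata,
        "rates": io.read_rate_inputs,
        "asv": io.read_asv_table,
        "taxonomy": io.read_taxonomy,
    }
    loaded: dict = {}
    for name, reader in readers.items():
        path = paths.get(name)
        entry: dict = {"path": str(path)}
        try:
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"missing input file: {path}")
            loaded[name] = reader(path)
            entry["status"] = "ok"
        except Exception as exc:  # noqa: BLE001 - reported, not swallowed silently
            entry["status"] = "fail"
            entry["error"] = str(exc)
            report["passed"] = False
        report["files"][name] = entry

    if report["passed"]:
        meta_ids = set(loaded["metadata"].index)
        rate_ids = loaded["rates"]["sample_id"]
        if rate_ids.duplicated().any():
            report["passed"] = False
            report["cross_checks"].append(
                f"duplicate sample_id in rates: {rate_ids[rate_ids.duplicated()].tolist()}"
            )
        asv_samples = set(loaded["asv"].index)
        orphans = sorted(asv_samples - meta_ids)
        if orphans:
            report["cross_checks"].append(
                f"warning: ASV-table samples missing from metadata: {orphans}"
            )
        missing_tax = sorted(set(loaded["asv"].columns) - set(loaded["taxonomy"].index))
        if missing_tax:
            report["cross_checks"].append(
                f"warning: ASVs without taxonomy: {missing_tax[:10]}"
            )
    return report


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk).

    Outputs land under ``config.out_dir``; a failing stage removes partial
    outputs and raises :class:`PipelineError` tagged with the stage name.
    """
    out_dir = Path(config.out_dir)
    tmp = out_dir.parent / (out_dir.name + ".partial")
    if tmp.exists():
        shutil.rmtree(tmp)
    tmp.mkdir(parents=True)
    # out_dir is implied by the manifest's own location; omitting it keeps
    # reruns into different directories byte-identical
    config_snapshot = {k: v for k, v in config.to_dict().items() if k != "out_dir"}
    manifest: dict = {
        "config": config_snapshot,
        "inputs": {},
        "stages": {},
        "versions": {"gyremet": _version(), "networkx": nx.__version__},
    }
    stage = "validate"
    try:
        paths = {k: getattr(config, k) for k in ("metadata", "rates", "asv", "taxonomy")}
        report = validate_inputs(paths)
        if not report["passed"]:
            failures = {k: v for k, v in report["files"].items() if v["status"] != "ok"}
            raise PipelineError(f"input validation failed: {failures}")
        manifest["inputs"] = {k: _sha256(v) for k, v in paths.items()}
        io.write_json(report, tmp / "validation.json")

        stage = "rates"
        panel = _stage_rates(config, tmp, manifest)

        stage = "community"
        metadata, rarefied, tax = _stage_community(config, tmp, manifest, panel)

        stage = "conet"
        season_nets = _stage_conet(config, tmp, manifest, metadata, rarefied)

        stage = "linkage"
        _stage_linkage(config, tmp, manifest, metadata, rarefied, tax, panel, season_nets)

        io.write_json(manifest, tmp / "manifest.json")
    except PipelineError:
        shutil.rmtree(tmp, ignore_errors=True)
        raise
    except Exception as exc:
        shutil.rmtree(tmp, ignore_errors=True)
        raise PipelineError(f"[{stage}] {exc}") from exc

    if out_dir.exists():
        shutil.rmtree(out_dir)
    tmp.rename(out_dir)
    return manifest


def _version() -> str:
    from gyremet import __version__

    return __version__


def _stage_rates(config: PipelineConfig, tmp: Path, manifest: dict) -> pd.DataFrame:
    inputs = io.read_rate_inputs(config.rates)
    panel, report = rates.compute_rate_panel(inputs)
    rates_dir = tmp / "rates"
    rates_dir.mkdir()
    io.write_rate_panel(panel, rates_dir / "panel.tsv")
    io.write_json(report, rates_dir / "validation.json")
    manifest["stages"]["rates"] = {
        "n_samples": int(len(panel)),
        "n_errors": len(report["errors"]),
        "n_warnings": len(report["warnings"]),
    }
    return panel.set_index("sample_id")


def _stage_community(
    config: PipelineConfig, tmp: Path, manifest: dict, panel: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    metadata = io.read_metadata(config.metadata)
    table = io.read_asv_table(config.asv)
    tax = io.read_taxonomy(config.taxonomy)

    filtered, filter_report = community.remove_lineages(table, tax, config.banned_lineages)
    rarefied, dropped = community.rarefy(filtered, config.rarefy_depth, config.rarefy_seed)

    out = tmp / "community"
    out.mkdir()
    diversity = community.diversity_table(rarefied)
    diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)

    dist = community.bray_curtis_matrix(rarefied)
    dist.to_csv(out / "bray_curtis.tsv", sep="\t", index_label="sample_id")

    ord_res = community.pcoa(dist)
    coords = ord_res.coordinates.copy()
    coords.to_csv(out / "pcoa.tsv", sep="\t", index_label="sample_id")

    seasons = metadata.loc[rarefied.index, "season"]
    stats: dict = {
        "pcoa_proportion_explained": ord_res.proportion_explained[:10],
        "pcoa_negative_eigenvalues": ord_res.negative_eigenvalues,
    }
    if seasons.nunique() >= 2 and seasons.value_counts().min() >= 2:
        f_obs, p = community.permanova(
            dist, seasons.to_numpy(), config.n_permutations, config.permanova_seed
        )
        stats["permanova"] = {
            "pseudo_F": f_obs,
            "p": p,
            "n_permutations": config.n_permutations,
        }
        stats["wilcoxon_season_contrasts"] = _season_contrasts(
            metadata, panel, diversity.set_index("sample_id"), seasons
        )
    io.write_json(stats, out / "stats.json")
    io.write_json(
        {
            "lineage_filter": filter_report,
            "rarefaction_dropped": list(dropped),
            "rarefy_depth": config.rarefy_depth,
        },
        out / "filter_report.json",
    )
    manifest["stages"]["community"] = {
        "asv_in": int(table.shape[1]),
        "asv_after_lineage_filter": int(filtered.shape[1]),
        "samples_after_rarefaction": int(rarefied.shape[0]),
        "samples_dropped": list(map(str, dropped)),
    }
    return metadata, rarefied, tax


def _season_contrasts(metadata, panel, diversity, seasons) -> dict:
    merged = metadata.join(panel, how="left").join(diversity, how="left")
    merged = merged.loc[seasons.index]
    labels = sorted(seasons.unique())
    a, b = labels[0], labels[1]
    results = {}
    for var in WILCOXON_VARS:
        if var not in merged.columns:
            continue
        x = merged.loc[seasons == a, var].dropna()
        y = merged.loc[seasons == b, var].dropna()
        if len(x) == 0 or len(y) == 0:
            continue
        w, p = community.wilcoxon_ranksum(x, y)
        results[var] = {"groups": [a, b], "W": w, "p": p}
    return results


def _stage_conet(
    config: PipelineConfig, tmp: Path, manifest: dict, metadata, rarefied
) -> dict:
    out = tmp / "conet"
    out.mkdir()
    seasons = metadata.loc[rarefied.index, "season"]
    season_nets: dict = {}
    stage_info: dict = {}
    for season in sorted(seasons.unique()):
        sub = rarefied.loc[seasons == season]
        net = conet.correlation_network(
            sub, config.r_threshold, config.p_threshold, config.min_prevalence
        )
        sdir = out / season
        sdir.mkdir()
        if net.number_of_edges() == 0:
            stage_info[season] = {"nodes": 0, "edges": 0, "note": "no edges at thresholds"}
            io.write_json(stage_info[season], sdir / "topology.json")
            continue
        partition = conet.detect_modules(net, seed=config.network_seed)
        nx.set_node_attributes(net, partition, "module")
        report = conet.topology_report(net, partition)
        abund = conet.module_abundance(sub, partition)

        edges = pd.DataFrame(
            [
                {"source": u, "target": v, "rho": d["weight"], "p_adj": d["p_adj"]}
                for u, v, d in sorted(net.edges(data=True))
            ]
        )
        edges.to_csv(sdir / "edges.tsv", sep="\t", index=False)
        nx.write_graphml(net, sdir / "network.graphml")
        io.write_json(report, sdir / "topology.json")
        pd.Series(partition, name="module").rename_axis("asv_id").sort_index().to_csv(
            sdir / "modules.tsv", sep="\t"
        )
        abund.to_csv(sdir / "module_abundance.tsv", sep="\t", index_label="sample_id")
        season_nets[season] = {"network": net, "partition": partition, "abundance": abund}
        stage_info[season] = {"nodes": report["nodes"], "edges": report["edges"]}
    manifest["stages"]["conet"] = stage_info
    return season_nets


def _stage_linkage(
    config: PipelineConfig,
    tmp: Path,
    manifest: dict,
    metadata,
    rarefied,
    tax,
    panel,
    season_nets: dict,
) -> None:
    out = tmp / "linkage"
    out.mkdir()
    vars_df = metadata.join(panel[["bp", "br"]], how="inner")
    seasons = vars_df["season"]

    module_cols = {}
    for season, bundle in season_nets.items():
        module_cols[season] = bundle["abundance"]

    if module_cols:
        abund_all = pd.concat(module_cols.values()).groupby(level=0).first()
    else:
        # no network had modules: the rate panel still supports the verdict
        abund_all = pd.DataFrame(index=vars_df.index)
    report = linkage.decoupling_report(
        vars_df, abund_all, seasons=seasons, method=config.correlation_method
    )
    report.correlations.to_records().to_csv(out / "correlations.tsv", sep="\t", index=False)
    report.regressions.to_csv(out / "regressions.tsv", sep="\t", index=False)
    io.write_json(
        {
            "alpha": report.alpha,
            "method": config.correlation_method,
            "coupled": [[a, b, p] for a, b, p in report.coupled],
            "decoupled": [[a, b, p] for a, b, p in report.decoupled],
            "note": "descriptive labels at the stated alpha; not causal claims",
        },
        out / "decoupling.json",
    )
    manifest["stages"]["linkage"] = {
        "coupled_pairs": [[a, b] for a, b, _ in report.coupled],
        "decoupled_pairs": [[a, b] for a, b, _ in report.decoupled],
        "n_regressions": int(len(report.regressions)),
    }

    # per-season PCA over BR, dominant classes, and module abundances
    class_rel = community.aggregate_taxa(rarefied, tax, "class")
    top_classes = class_rel.mean(axis=0).nlargest(6).index
    for season, bundle in season_nets.items():
        samples = bundle["abundance"].index
        mat = pd.concat(
            [
                panel.loc[panel.index.intersection(samples), ["br"]],
                class_rel.loc[samples, top_classes],
                bundle["abundance"],
            ],
            axis=1,
            join="inner",
        )
        if mat.shape[0] < 3:
            continue
        res = linkage.pca_panel(mat)
        res.loadings.to_csv(out / f"pca_{season}_loadings.tsv", sep="\t", index_label="variable")
        res.scores.to_csv(out / f"pca_{season}_scores.tsv", sep="\t", index_label="sample_id")
        io.write_json(
            {"pct_variance": res.pct_variance, "dropped": res.dropped},
            out / f"pca_{season}_variance.json",
        )
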