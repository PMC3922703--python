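"""End-to-end orchestration: simulate -> preprocess -> ... -> biomarker.

Every stage writes its artifacts under a stage subdirectory of the output
directory; a final ``manifest.json`` lists each artifact with a SHA-256
checksum, plus every threshold and derived per-stage seed, so a rerun with
the same root seed reproduces the TSV outputs byte for byte.  A short
``summary.md`` collects the headline numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .biomarker import enumerate_groupings, select_triplets
from .dataset import PATHWAY_GROUPS, DetectionProfile
from .diversity import (
    compare_groups_rowwise,
    core_variability_ranking,
    diversity_indices,
    permutation_t_test,
)
from .network import (
    build_core_network,
    build_noncore_subnetwork,
    detect_modules,
    summarize_network,
)
from .ordination import detrended_ca, mrpp
from .preprocessing import build_profile
from .sharing import group_core_fraction, pairwise_sharing_matrix, saturation_curve
from .simulate import SimulationConfig, config_to_dict, simulate_dataset, write_dataset

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed"]

STAGES = (
    "simulate",
    "preprocess",
    "diversity",
    "share",
    "network",
    "ordinate",
    "biomarker",
)


def stage_seed(root_seed: int, stage: str) -> int:
    """Per-stage seed derived deterministically from the root seed."""
    return (root_seed * 1_000_003 + STAGES.index(stage) + 1) % (2**31)


@dataclass
class PipelineConfig:
    """Everything a full run needs; loadable from a YAML mapping."""

    seed: int = 0
    input_dir: str | None = None  # when set, skip simulation and read TSVs
    simulation: dict = field(default_factory=dict)
    min_intensity: float = 1000.0
    min_snr: float = 2.0
    min_abs_corr: float = 0.8
    accuracy_threshold: float = 0.8
    n_perm: int = 999
    n_bootstrap: int = 50
    n_top_genes: int = 25
    saturation_iters: int = 100
    dca_segments: int = 26
    gene_level_tests: bool = True
    stages: dict = field(default_factory=dict)  # stage -> bool toggles

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = mio.read_yaml_config(path)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _write_tsv(frame: pd.DataFrame, path: Path, index_name: str | None = None):
    out = frame.copy()
    if index_name and out.index.name is None:
        out.index.name = index_name
    out.to_csv(path, sep="\t")
    return path


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every enabled stage; return the manifest dictionary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    summary: dict = {"seed": config.seed}

    # --- simulate / load ---------------------------------------------------
    if config.input_dir:
        dataset = mio.read_dataset(config.input_dir)
        truth = None
    else:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", stage_seed(config.seed, "simulate"))
        sim_config = SimulationConfig(**sim_kwargs)
        dataset, truth = simulate_dataset(sim_config)
        if config.enabled("simulate"):
            stage_dir = outdir / "simulate"
            for name, p in write_dataset(dataset, truth, stage_dir).items():
                paths[f"simulate/{name}"] = p
            (stage_dir / "config.json").write_text(
                json.dumps(config_to_dict(sim_config), indent=1)
            )
            paths["simulate/config"] = stage_dir / "config.json"

    groups = dataset.groups
    group_samples = {g: dataset.samples_in_group(g) for g in groups}

    # --- preprocess --------------------------------------------------------
    profile = build_profile(dataset, config.min_intensity, config.min_snr)
    if config.enabled("preprocess"):
        stage_dir = outdir / "preprocess"
        for name, p in mio.write_profile(profile, stage_dir).items():
            paths[f"preprocess/{name}"] = p
        from .preprocessing import aggregate_by_category

        abundance, rel_div = aggregate_by_category(profile)
        paths["preprocess/category_abundance"] = _write_tsv(
            abundance, stage_dir / "category_abundance.tsv"
        )
        paths["preprocess/category_diversity"] = _write_tsv(
            rel_div, stage_dir / "category_diversity.tsv"
        )
    summary["n_genes_detected"] = int(len(profile.genes))
    summary["n_core"] = int(len(profile.core_genes))
    summary["n_noncore"] = int(len(profile.noncore_genes))

    # --- diversity ---------------------------------------------------------
    if config.enabled("diversity"):
        stage_dir = outdir / "diversity"
        stage_dir.mkdir(parents=True, exist_ok=True)
        seed = stage_seed(config.seed, "diversity")
        indices = diversity_indices(profile.normalized)
        table = dataset.metadata.loc[list(profile.samples)].join(indices)
        paths["diversity/per_sample"] = _write_tsv(
            table, stage_dir / "per_sample.tsv", "sample"
        )
        labels = table["group"].to_numpy()
        comp_rows = {}
        for metric in ("richness", "shannon", "inverse_simpson"):
            res = permutation_t_test(
                table[metric].to_numpy(), labels, n_perm=config.n_perm, seed=seed
            )
            comp_rows[metric] = {
                "statistic": res.statistic,
                "p_value": res.p_value,
                "tier": res.tier,
            }
        comparisons = pd.DataFrame(comp_rows).T
        comparisons.index.name = "metric"
        paths["diversity/comparisons"] = _write_tsv(
            comparisons, stage_dir / "comparisons.tsv"
        )
        summary["diversity"] = {
            m: dict(comp_rows[m]) for m in comp_rows
        }
        summary["mean_shannon"] = float(indices["shannon"].mean())
        summary["mean_inverse_simpson"] = float(indices["inverse_simpson"].mean())
        summary["mean_richness"] = float(indices["richness"].mean())

        if len(profile.core_genes):
            ranking = core_variability_ranking(profile.normalized, profile.core_genes)
            paths["diversity/core_variability"] = _write_tsv(
                ranking, stage_dir / "core_variability.tsv"
            )

        from .preprocessing import aggregate_by_category

        abundance, _ = aggregate_by_category(profile)
        cat_tests = compare_groups_rowwise(
            abundance, labels, n_perm=config.n_perm, seed=seed
        )
        paths["diversity/category_comparisons"] = _write_tsv(
            cat_tests, stage_dir / "category_comparisons.tsv", "category"
        )
        if config.gene_level_tests:
            gene_tests = compare_groups_rowwise(
                profile.normalized, labels, n_perm=config.n_perm, seed=seed
            )
            paths["diversity/gene_comparisons"] = _write_tsv(
                gene_tests, stage_dir / "gene_comparisons.tsv", "gene"
            )
            summary["n_genes_significant_p05"] = int((gene_tests["p_value"] < 0.05).sum())

    # --- sharing -----------------------------------------------------------
    if config.enabled("share"):
        stage_dir = outdir / "share"
        stage_dir.mkdir(parents=True, exist_ok=True)
        seed = stage_seed(config.seed, "share")
        core_info = {}
        for grp in groups:
            members = group_samples[grp]
            mat = pairwise_sharing_matrix(profile.detected, members)
            paths[f"share/pairwise_{grp}"] = _write_tsv(
                mat, stage_dir / f"pairwise_{grp}.tsv", "sample"
            )
            off = mat.where(~pd.DataFrame(
                [[a == b for b in mat.columns] for a in mat.index],
                index=mat.index, columns=mat.columns,
            ))
            vals = off.stack()
            curve = saturation_curve(
                profile.detected, members, n_iter=config.saturation_iters, seed=seed
            )
            paths[f"share/saturation_{grp}"] = _write_tsv(
                curve.table.set_index("k"), stage_dir / f"saturation_{grp}.tsv"
            )
            frac = group_core_fraction(profile.detected, members)
            core_info[grp] = {
                "n_shared": frac.n_shared,
                "n_total": frac.n_total,
                "percentage": frac.percentage,
                "mean_pairwise_shared": float(vals.mean()),
                "min_pairwise_shared": float(vals.min()),
                "max_pairwise_shared": float(vals.max()),
            }
        (stage_dir / "group_core.json").write_text(json.dumps(core_info, indent=1))
        paths["share/group_core"] = stage_dir / "group_core.json"
        summary["sharing"] = core_info

    # --- network -----------------------------------------------------------
    if config.enabled("network"):
        stage_dir = outdir / "network"
        stage_dir.mkdir(parents=True, exist_ok=True)
        net_summaries = {}
        for grp in groups:
            members = group_samples[grp]
            net = build_core_network(
                profile.normalized,
                profile.core_genes,
                members,
                annotation=profile.annotation,
                min_abs_corr=config.min_abs_corr,
                group=grp,
            )
            detect_modules(net)
            s = summarize_network(net)
            net_summaries[f"core_{grp}"] = s.as_dict()
            paths[f"network/core_{grp}_edges"] = _write_tsv(
                net.edge_table().set_index("gene_a"),
                stage_dir / f"core_{grp}_edges.tsv",
            )
            paths[f"network/core_{grp}_nodes"] = _write_tsv(
                net.node_table().set_index("gene"),
                stage_dir / f"core_{grp}_nodes.tsv",
            )
            for pathway in PATHWAY_GROUPS:
                try:
                    sub = build_noncore_subnetwork(
                        profile.noncore_binary,
                        profile.annotation,
                        pathway,
                        members,
                        min_abs_corr=config.min_abs_corr,
                        group=grp,
                    )
                except ValueError:
                    continue
                detect_modules(sub)
                net_summaries[f"{pathway}_{grp}"] = summarize_network(sub).as_dict()
                paths[f"network/{pathway}_{grp}_edges"] = _write_tsv(
                    sub.edge_table().set_index("gene_a"),
                    stage_dir / f"{pathway}_{grp}_edges.tsv",
                )
        (stage_dir / "summaries.json").write_text(
            json.dumps(net_summaries, indent=1, sort_keys=True)
        )
        paths["network/summaries"] = stage_dir / "summaries.json"
        summary["networks"] = net_summaries

    # --- ordination --------------------------------------------------------
    if config.enabled("ordinate"):
        stage_dir = outdir / "ordinate"
        stage_dir.mkdir(parents=True, exist_ok=True)
        seed = stage_seed(config.seed, "ordinate")
        dca = detrended_ca(profile.normalized, n_segments=config.dca_segments)
        scores = dca.sample_scores.copy()
        scores["group"] = dataset.metadata.loc[list(scores.index), "group"]
        paths["ordinate/dca_scores"] = _write_tsv(
            scores, stage_dir / "dca_scores.tsv", "sample"
        )
        labels = dataset.metadata.loc[list(profile.samples), "group"].to_numpy()
        res = mrpp(
            profile.normalized, labels, metric="braycurtis",
            n_perm=config.n_perm, seed=seed,
        )
        mrpp_payload = {
            "delta": res.delta,
            "expected_delta": res.expected_delta,
            "A": res.A,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "metric": res.metric,
        }
        (stage_dir / "mrpp.json").write_text(json.dumps(mrpp_payload, indent=1))
        paths["ordinate/mrpp"] = stage_dir / "mrpp.json"
        summary["mrpp"] = mrpp_payload

    # --- biomarker ---------------------------------------------------------
    if config.enabled("biomarker"):
        stage_dir = outdir / "biomarker"
        stage_dir.mkdir(parents=True, exist_ok=True)
        seed = stage_seed(config.seed, "biomarker")
        report = select_triplets(
            profile.noncore_binary,
            {g: group_samples[g] for g in groups},
            accuracy_threshold=config.accuracy_threshold,
            n_bootstrap=config.n_bootstrap,
            n_top_genes=config.n_top_genes,
            seed=seed,
        )
        trip = report.triplets.copy()
        trip["genes"] = trip["genes"].map(lambda t: ";".join(map(str, t)))
        paths["biomarker/triplets"] = _write_tsv(
            trip.set_index("genes") if len(trip) else trip,
            stage_dir / "triplets.tsv",
        )
        paths["biomarker/gene_frequencies"] = _write_tsv(
            report.gene_frequencies.set_index("gene")
            if len(report.gene_frequencies)
            else report.gene_frequencies,
            stage_dir / "gene_frequencies.tsv",
        )
        (stage_dir / "exclusive_genes.json").write_text(
            json.dumps(report.exclusive_genes, indent=1, sort_keys=True)
        )
        paths["biomarker/exclusive_genes"] = stage_dir / "exclusive_genes.json"
        (stage_dir / "provenance.json").write_text(
            json.dumps(report.provenance, indent=1, sort_keys=True)
        )
        paths["biomarker/provenance"] = stage_dir / "provenance.json"
        summary["biomarker"] = {
            "n_selected_triplets": report.n_selected,
            "n_selected_per_group": {
                g: int(len(report.triplets_for(g))) for g in groups
            },
            "n_exclusive_genes": len(report.exclusive_genes),
            "exclusive_genes": report.exclusive_genes,
            "n_groupings_per_group": {
                g: len(enumerate_groupings(group_samples[g]))
                for g in groups
                if len(group_samples[g]) > 3
            },
        }

    # --- summary + manifest ------------------------------------------------
    summary_path = outdir / "summary.md"
    summary_path.write_text(_render_summary(summary))
    paths["summary"] = summary_path
    manifest_extra = {
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in STAGES},
        "thresholds": {
            "min_intensity": config.min_intensity,
            "min_snr": config.min_snr,
            "min_abs_corr": config.min_abs_corr,
            "accuracy_threshold": config.accuracy_threshold,
        },
    }
    mio.write_manifest(paths, outdir / "manifest.json", extra=manifest_extra)
    manifest = json.loads((outdir / "manifest.json").read_text())
    manifest["summary"] = summary
    return manifest


def _render_summary(summary: dict) -> str:
    lines = ["# Pipeline summary", ""]
    lines.append(f"- root seed: {summary.get('seed')}")
    for key in ("n_genes_detected", "n_core", "n_noncore",
                "mean_richness", "mean_shannon", "mean_inverse_simpson"):
        if key in summary:
            v = summary[key]
            lines.append(f"- {key}: {v:.4g}" if isinstance(v, float) else f"- {key}: {v}")
    if "sharing" in summary:
        for grp, info in summary["sharing"].items():
            lines.append(
                f"- group {grp} core: {info['n_shared']}/{info['n_total']} "
                f"({info['percentage']}%), mean pairwise sharing "
                f"{info['mean_pairwise_shared']:.2f}%"
            )
    if "mrpp" in summary:
        m = summary["mrpp"]
        lines.append(
            f"- MRPP: delta={m['delta']:.4f}, A={m['A']:.4f}, p={m['p_value']:.4g}"
        )
    if "biomarker" in summary:
        b = summary["biomarker"]
        lines.append(
            f"- biomarker: {b['n_selected_triplets']} selected triplets, "
            f"{b['n_exclusive_genes']} exclusive-pattern genes"
        )
    lines.append("")
    return "\n".join(lines)
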