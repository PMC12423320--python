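"""End-to-end orchestration of the study's comparisons from a config file.

A run reads a beta matrix, design and manifest, executes the requested
group comparisons through the DMR caller, clusters samples, and writes a
machine-readable report plus BED/TSV/newick artifacts.  The report carries,
per comparison, the probe and run counts, the hypermethylated fraction of
differential genes, the gene list, and the chrM-vs-nuclear methylation
contrast.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import clustering, dmr, io

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

_PRESET_ALIASES = {
    "methods": "methods", "methods_0.2": "methods",
    "fig3c-mutwt": "fig3c-mutwt", "fig3c_mutwt_0.4": "fig3c-mutwt",
    "fig3c-highlow": "fig3c-highlow", "fig3c_highlow_0.27": "fig3c-highlow",
}


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    beta: str
    design: str
    manifest: str
    outdir: str
    comparisons: list = field(default_factory=list)  # dicts: test/control/preset
    seed: int = 0
    cluster_axis: str = "samples"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def resolve_preset(self, name: str) -> dmr.DmrConfig:
        key = _PRESET_ALIASES.get(name)
        if key is None:
            raise PipelineError(f"[config] unknown preset {name!r}; "
                                f"choose from {sorted(set(_PRESET_ALIASES))}")
        return dmr.PRESETS[key]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured comparison plus clustering; return the report.

    Writes runs_<test>_vs_<control>.bed, genes_<test>_vs_<control>.tsv,
    tree.nwk, report.md and report.json into the output directory.  Any
    stage error aborts with a stage-tagged message and removes partial
    outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list = []
    try:
        report = _run(config, outdir, written)
    except PipelineError:
        _cleanup(written)
        raise
    except Exception as exc:  # tag unexpected failures with their stage too
        _cleanup(written)
        raise PipelineError(f"[pipeline] {exc}") from exc
    return report


def _cleanup(written):
    for p in written:
        try:
            Path(p).unlink()
        except OSError:
            pass


def _run(config: RunConfig, outdir: Path, written: list) -> dict:
    try:
        manifest = io.read_manifest(config.manifest)
        design = io.read_design(config.design)
        matrix = io.read_beta_matrix(config.beta, design)
    except Exception as exc:
        raise PipelineError(f"[read] {exc}") from exc

    report: dict = {"comparisons": [], "n_probes": len(matrix.probes),
                    "n_samples": len(matrix.samples)}

    # chrM vs nuclear methylation contrast (overall mean beta)
    chrm_probes = set(manifest.loc[manifest["chromosome"] == "chrM",
                                   "probe_id"])
    on_chrm = matrix.values.index.isin(chrm_probes)
    vals = matrix.values.to_numpy(dtype=float)
    report["chrM_mean_beta"] = (float(np.nanmean(vals[on_chrm]))
                                if on_chrm.any() else None)
    report["nuclear_mean_beta"] = float(np.nanmean(vals[~on_chrm]))

    for comp in config.comparisons:
        test, control = comp["test"], comp["control"]
        cfg = config.resolve_preset(comp.get("preset", "methods"))
        tag = f"{test}_vs_{control}"
        try:
            deltas = dmr.probe_deltas(matrix, test, control, cfg)
            runs = dmr.call_dmr_runs(deltas, manifest, cfg)
            genes = dmr.dmr_gene_list(runs)
        except Exception as exc:
            raise PipelineError(f"[dmr:{tag}] {exc}") from exc

        bed = outdir / f"runs_{tag}.bed"
        io.write_bed6_runs(runs, bed)
        written.append(bed)
        genes_path = outdir / f"genes_{tag}.tsv"
        genes.to_csv(genes_path, sep="\t", index=False)
        written.append(genes_path)

        n_hyper = int((genes["direction"] == "hyper").sum())
        n_dir = int((genes["direction"] != "mixed").sum())
        report["comparisons"].append({
            "test": test, "control": control,
            "preset": comp.get("preset", "methods"),
            "n_significant_probes": int((deltas["direction"] != "none").sum()),
            "n_excluded_probes": int(deltas["excluded"].sum()),
            "n_runs": len(runs),
            "n_genes": int(len(genes)),
            "hyper_fraction_genes": (n_hyper / n_dir if n_dir else None),
            "genes": genes.to_dict(orient="records"),
        })

    try:
        dist = clustering.manhattan_distance_matrix(matrix,
                                                    axis=config.cluster_axis)
        tree = clustering.average_linkage(dist)
    except Exception as exc:
        raise PipelineError(f"[cluster] {exc}") from exc
    tree_path = outdir / "tree.nwk"
    tree_path.write_text(clustering.to_newick(tree) + "\n")
    written.append(tree_path)

    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    written.append(json_path)
    md_path = outdir / "report.md"
    md_path.write_text(_render_markdown(report))
    written.append(md_path)
    logger.info("pipeline finished: %d comparisons, outputs in %s",
                len(report["comparisons"]), outdir)
    return report


def _render_markdown(report: dict) -> str:
    lines = ["# heteroshift run report", "",
             f"- probes: {report['n_probes']}",
             f"- samples: {report['n_samples']}",
             f"- nuclear mean beta: {report['nuclear_mean_beta']:.4f}"]
    if report["chrM_mean_beta"] is not None:
        lines.append(f"- chrM mean beta: {report['chrM_mean_beta']:.4f}")
    for c in report["comparisons"]:
        lines += ["",
                  f"## {c['test']} vs {c['control']} (preset {c['preset']})",
                  "",
                  f"- significant probes: {c['n_significant_probes']}",
                  f"- excluded probes: {c['n_excluded_probes']}",
                  f"- DMR runs: {c['n_runs']}",
                  f"- differential genes: {c['n_genes']}"]
        if c["hyper_fraction_genes"] is not None:
            lines.append("- hypermethylated fraction of differential genes: "
                         f"{100 * c['hyper_fraction_genes']:.1f}%")
        if c["genes"]:
            lines.append("- genes: " + ", ".join(
                f"{g['gene']} ({g['direction']})" for g in c["genes"][:20]))
    return "\n".join(lines) + "\n"
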