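"""End-to-end workflows: expectation chain and the full analysis pipeline.

Each run writes a JSON run manifest (config hash, seed, package version,
per-stage record counts) sufficient to reproduce it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .calling import process_ngs_sample, sanger_call_cells
from .expectation import (
    DEFAULT_DELETION_OBSERVATIONS,
    DeletionObservation,
    expectation_chain,
)
from .gating import GatingTree, join_index_data, rollup_frequency, tallies_from_cells
from .io import read_manifest, read_reads, read_template_fasta

__all__ = ["run_expectation_workflow", "run_analysis_workflow"]

logger = logging.getLogger(__name__)


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _write_manifest(outdir: Path, config: dict, counts: dict, seed=None) -> None:
    manifest = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "config": config,
        "seed": seed,
        "stage_counts": counts,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)


def run_expectation_workflow(q: float,
                             length: int = 393,
                             mu: float = 1e-3,
                             deletion_table: pd.DataFrame | None = None,
                             max_divisions: int = 2,
                             outdir=None) -> dict:
    """Run the analytic chain in both rounding modes.

    ``deletion_table`` needs columns ``mutation_load`` and
    ``deletion_fraction``; defaults to the bundled high/medium/low
    mutation-load observations.
    """
    if deletion_table is None:
        observations = DEFAULT_DELETION_OBSERVATIONS
    else:
        observations = tuple(
            DeletionObservation(row["mutation_load"], row["deletion_fraction"])
            for _, row in deletion_table.iterrows()
        )
    report = {
        mode: expectation_chain(q=q, length=length, mu=mu,
                                deletion_observations=observations,
                                max_divisions=max_divisions,
                                rounding=mode).to_dict()
        for mode in ("printed", "full")
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "expectation.json", "w") as fh:
            json.dump(report, fh, indent=2)
        _write_manifest(outdir, {"q": q, "length": length, "mu": mu,
                                 "max_divisions": max_divisions},
                        {"deletion_observations": len(observations)})
    return report


def run_analysis_workflow(template_fasta, manifest_csv, tree_yaml,
                          index_csv=None, outdir=None,
                          min_identity: float = 0.5,
                          populations: list[str] | None = None) -> dict:
    """Full pipeline: call stops -> (join index) -> tallies -> rollup.

    Sanger samples are called per cell; NGS samples are collapsed, abundance
    filtered and called per unique sequence, and contribute their sample
    frequency directly to the matching leaf gate's tally (as reads).
    Returns a dict with per-sample summaries and per-population estimates.
    """
    template = read_template_fasta(template_fasta)
    manifest = read_manifest(manifest_csv)
    tree = GatingTree.from_yaml(tree_yaml)
    counts: dict[str, int] = {"samples": len(manifest)}

    per_cell_frames = []
    sample_summaries = []
    ngs_tallies = []
    for _, row in manifest.iterrows():
        sample = read_reads(row["file"], row["mode"], row["sample_id"],
                            int(row["n_cells_sorted"]))
        if sample.mode == "sanger":
            calls = sanger_call_cells(sample, template, min_identity=min_identity)
            per_cell_frames.append(calls)
            aligned = calls[calls["aligned"]]
            freq = (100.0 * aligned["has_premature_stop"].astype(bool).mean()
                    if len(aligned) else float("nan"))
            sample_summaries.append({
                "sample_id": sample.sample_id, "mode": "sanger",
                "n_reads": len(sample.reads), "n_passing": len(aligned),
                "stop_frequency_percent": freq,
            })
        else:
            table, freq = process_ngs_sample(sample, template,
                                             min_identity=min_identity)
            passing = table[table["passes_threshold"]]
            sample_summaries.append({
                "sample_id": sample.sample_id, "mode": "ngs",
                "n_reads": len(sample.reads),
                "n_passing": int(passing["read_count"].sum()),
                "stop_frequency_percent": freq,
            })
            ngs_tallies.append({
                "gate": sample.sample_id,
                "n_sequenced": int(passing["read_count"].sum()),
                "n_stop": int(passing.loc[passing["has_premature_stop"],
                                          "read_count"].sum()),
            })
        logger.info("sample %s: %d reads", sample.sample_id, len(sample.reads))

    tallies_parts = []
    if per_cell_frames:
        per_cell = pd.concat(per_cell_frames, ignore_index=True)
        counts["cells_called"] = len(per_cell)
        if index_csv is not None:
            index_table = pd.read_csv(index_csv)
            joined, join_report = join_index_data(index_table, per_cell)
            counts["cells_joined"] = join_report["n_matched"]
            gate_source = joined
        else:
            gate_source = per_cell.rename(columns={"sample_id": "gate"})
        tallies_parts.append(tallies_from_cells(gate_source))
    if ngs_tallies:
        ngs_df = pd.DataFrame(ngs_tallies)
        if tallies_parts:
            # per-cell (sanger) tallies take precedence over bulk-read
            # tallies for the same gate — never mix cells with reads
            covered = set(tallies_parts[0]["gate"])
            dropped = ngs_df[ngs_df["gate"].isin(covered)]
            if len(dropped):
                logger.info("dropping NGS tallies for gates already covered "
                            "per-cell: %s", sorted(dropped["gate"]))
            ngs_df = ngs_df[~ngs_df["gate"].isin(covered)]
        if len(ngs_df):
            tallies_parts.append(ngs_df)
    if not tallies_parts:
        raise RuntimeError("join stage: no calls produced from any sample")
    tallies = pd.concat(tallies_parts, ignore_index=True)
    tallies = tallies.groupby("gate", as_index=False).sum()
    tree.set_tallies(tallies[tallies["gate"].isin(
        [g for g in tree.nodes if tree.is_leaf(g)])])

    if populations is None:
        populations = [tree.root] + tree.children(tree.root)
    estimates = {}
    for pop in populations:
        try:
            est = rollup_frequency(tree, pop)
        except ValueError as exc:
            logger.warning("rollup for %s skipped: %s", pop, exc)
            continue
        estimates[pop] = {
            "frequency_percent": est.frequency,
            "ci_low": est.ci_low, "ci_high": est.ci_high,
            "n_effective": est.n_effective,
            "leaves_used": list(est.leaves_used),
        }

    result = {
        "samples": sample_summaries,
        "tallies": tallies.to_dict(orient="records"),
        "populations": estimates,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(sample_summaries).to_csv(outdir / "sample_summary.tsv",
                                              sep="\t", index=False)
        tallies.to_csv(outdir / "tallies.tsv", sep="\t", index=False)
        with open(outdir / "populations.json", "w") as fh:
            json.dump(estimates, fh, indent=2)
        _write_manifest(outdir,
                        {"template": str(template_fasta),
                         "manifest": str(manifest_csv), "tree": str(tree_yaml),
                         "index": str(index_csv), "min_identity": min_identity},
                        counts)
    return result
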