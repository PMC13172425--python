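"""One configured, logged run of the whole analysis.

Stages (each optional, driven by which inputs the config names):
compete (reporter intensities -> competition profiles) ->
cluster (profiles -> t-SNE/k-means candidates) ->
score (AlphaFold metric table -> composite ranking) ->
contacts (structure + PAE [+ AF3 summary] -> interface contacts).
The run report is deterministic apart from its single timestamp field.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import chemoproteomics as cp
from . import clustering as cl
from . import contacts as ct
from . import scoring as sc
from .synthetic import ChannelDesign

log = logging.getLogger("chemoprofiler")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All stage inputs and parameters; defaults are the published analysis
    constants."""

    # inputs (any may be None -> stage skipped)
    intensities: str | None = None
    design: str | None = None
    annotation: str | None = None
    metrics: str | None = None
    structure: str | None = None
    pae: str | None = None
    af3_json: str | None = None
    out_dir: str = "run"
    # compete
    fc_cut: float = 0.6
    p_cut: float = 0.05
    # cluster
    alpha: float = 0.05
    n_clusters: int = 5
    max_perplexity: float = 30.0
    tsne_seed: int = 0
    kmeans_seed: int = 0
    sensitivity_log2fc_cut: float = -1.0
    # score
    lia_min: float = 1610.0
    lis_min: float = 0.073
    dockq_min: float = 0.175
    aggregate: str = "max"
    # contacts
    dist_cut: float = 8.0
    high_dist_cut: float = 6.0
    pae_cut: float = 25.7
    prob_cut: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "fc_cut", "alpha", "n_clusters", "max_perplexity", "lia_min",
            "lis_min", "dockq_min", "dist_cut", "high_dist_cut", "pae_cut", "prob_cut",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    """YAML config with a flat key namespace; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def read_design(path: str | Path) -> list[ChannelDesign]:
    df = pd.read_csv(path, sep="\t")
    return [
        ChannelDesign(str(r.channel_id), float(r.dose_uM), int(r.replicate), str(r.bead_type))
        for r in df.itertuples()
    ]


def read_annotation(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages; write stage TSVs and report.json under
    ``out_dir``.  Any stage failure removes partial outputs and re-raises
    with the stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "parameters": dataclasses.asdict(config),
        "inputs": {},
        "stages": {},
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    for key in ("intensities", "design", "annotation", "metrics", "structure", "pae", "af3_json"):
        p = getattr(config, key)
        if p:
            report["inputs"][key] = {"path": p, "sha256": _sha256(Path(p))}
    log.info("parameters: %s", report["parameters"])

    stage = "compete"
    try:
        if config.intensities and config.design:
            table = cp.ReporterIntensityTable(
                pd.read_csv(config.intensities, sep="\t", index_col=0),
                read_design(config.design),
            )
            prof = cp.competition_profiles(table, fc_cut=config.fc_cut, p_cut=config.p_cut)
            prof["log2fc"].to_csv(out / "profiles_log2fc.tsv", sep="\t")
            prof["p_values"].to_csv(out / "profiles_pvalues.tsv", sep="\t")
            prof["enrichment"].to_csv(out / "enrichment.tsv", sep="\t")
            pd.Series(prof["enriched"], name="protein_id").to_csv(
                out / "enriched.tsv", sep="\t", index=False
            )
            report["stages"]["compete"] = {
                "n_proteins": int(len(table.intensities)),
                "n_enriched": len(prof["enriched"]),
            }
        else:
            prof = None
            report["stages"]["compete"] = "skipped"

        stage = "cluster"
        if prof is not None:
            cfg = cl.ClusteringConfig(
                alpha=config.alpha,
                n_clusters=config.n_clusters,
                max_perplexity=config.max_perplexity,
                tsne_seed=config.tsne_seed,
                kmeans_seed=config.kmeans_seed,
                sensitivity_log2fc_cut=config.sensitivity_log2fc_cut,
            )
            annotation = read_annotation(config.annotation) if config.annotation else {}
            assignment, candidates = cl.run_clustering(
                prof["log2fc"], prof["p_values"], annotation, cfg
            )
            emb = pd.DataFrame(
                assignment.embedding, index=assignment.protein_ids, columns=["tsne1", "tsne2"]
            )
            emb["cluster"] = assignment.labels
            emb.to_csv(out / "embedding.tsv", sep="\t", index_label="protein_id")
            pd.Series(assignment.compactness, name="compactness").to_csv(
                out / "compactness.tsv", sep="\t", index_label="cluster"
            )
            candidates.candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
            candidates.known_members.to_csv(out / "known_members.tsv", sep="\t", index=False)
            _plot_embedding(emb, out / "embedding.png")
            report["stages"]["cluster"] = {
                "n_clustered": len(assignment.protein_ids),
                "sensitive_clusters": assignment.sensitive,
                "candidates": list(candidates.candidates["protein_id"]),
                "n_known_members": int(len(candidates.known_members)),
            }
        else:
            report["stages"]["cluster"] = "skipped"

        stage = "score"
        if config.metrics:
            thresholds = sc.ThresholdConfig(
                lia_min=config.lia_min,
                lis_min=config.lis_min,
                dockq_min=config.dockq_min,
                model_aggregation=config.aggregate,
            )
            models = pd.read_csv(config.metrics, sep="\t")
            ranking = sc.composite_score(sc.aggregate_models(models, thresholds), thresholds)
            ranking.to_csv(out / "ranking.tsv", sep="\t", index=False)
            report["stages"]["score"] = {
                "n_pairs": int(len(ranking)),
                "top": ranking.head(5)[["pair_id", "composite", "k"]].to_dict("records"),
            }
        else:
            report["stages"]["score"] = "skipped"

        stage = "contacts"
        if config.structure and config.pae:
            pair = ct.load_structure_pair(config.structure)
            pae = ct.load_pae(config.pae)
            probs = ct.load_contact_probs(config.af3_json) if config.af3_json else None
            table_df = ct.contact_table(
                pair, pae, probs,
                dist_cut=config.dist_cut,
                high_dist_cut=config.high_dist_cut,
                pae_cut=config.pae_cut,
                prob_cut=config.prob_cut,
            )
            table_df.to_csv(out / "contacts.tsv", sep="\t", index=False)
            cons = table_df[table_df["in_consensus"]]
            residues = sorted(
                {("A", int(r)) for r in cons["res_a"]} | {("B", int(r)) for r in cons["res_b"]}
            )
            pd.DataFrame(residues, columns=["chain", "residue"]).to_csv(
                out / "consensus_residues.tsv", sep="\t", index=False
            )
            report["stages"]["contacts"] = {
                "n_contacts": int(table_df["is_contact"].sum()),
                "n_high_confidence": int(table_df["is_high_confidence"].sum()),
                "n_consensus_pairs": int(table_df["in_consensus"].sum()),
            }
        else:
            report["stages"]["contacts"] = "skipped"
    except Exception as exc:
        shutil.rmtree(out, ignore_errors=True)
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=1, default=str))
    return report


def _plot_embedding(emb: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for c, sub in emb.groupby("cluster"):
        ax.scatter(sub["tsne1"], sub["tsne2"], s=8, label=f"cluster {c}")
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
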