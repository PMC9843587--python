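"""High-level orchestration: encode whole samples, batch tensors on disk,
score candidates and evaluate cohorts.

Stage artifacts live on disk (VCFs, ``.npz`` tensor archives with a TSV
sidecar, model checkpoints), so each stage can be re-run or reused across
cohorts — e.g. train on one cohort and predict on another. Tensor archives
record the pileup-configuration hash; the prediction stage refuses archives
whose hash does not match the checkpoint's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

from somaticnet.encoder import (
    PileupConfig,
    assemble_tensor,
    fetch_site_reads,
    reference_window,
)
from somaticnet.flanking import build_meta_vector, find_flanking
from somaticnet.metrics import SampleEvaluation, evaluate_samples, subset_view, summarize
from somaticnet.variants import CandidateVariant, PopulationDB, population_filter

LABEL_TO_BINARY = {"somatic": 1, "germline": 0, "artifact": 0, "unknown": 0}


@dataclass
class TensorBatch:
    """Encoded tensors plus their per-variant sidecar table."""

    tensors: np.ndarray  # (N, C, W, H) float32
    meta: np.ndarray  # (N, 10) float32
    table: pd.DataFrame  # sample_id, chrom, pos, ref, alt, truth_label, vaf, dp
    cfg_hash: str

    def __len__(self) -> int:
        return len(self.table)

    @property
    def binary_labels(self) -> np.ndarray:
        return self.table["truth_label"].map(LABEL_TO_BINARY).to_numpy(dtype=np.int64)

    def save(self, path: str) -> None:
        np.savez_compressed(
            path,
            tensors=self.tensors,
            meta=self.meta,
            cfg_hash=np.array(self.cfg_hash),
        )
        self.table.to_csv(_sidecar(path), sep="\t", index=False)

    @classmethod
    def load(cls, path: str) -> "TensorBatch":
        with np.load(path, allow_pickle=False) as data:
            tensors = data["tensors"]
            meta = data["meta"]
            cfg_hash = str(data["cfg_hash"])
        table = pd.read_csv(_sidecar(path), sep="\t", dtype={"sample_id": str, "chrom": str})
        return cls(tensors=tensors, meta=meta, table=table, cfg_hash=cfg_hash)

    @classmethod
    def concatenate(cls, batches: list["TensorBatch"]) -> "TensorBatch":
        hashes = {b.cfg_hash for b in batches}
        if len(hashes) != 1:
            raise ValueError("cannot concatenate batches with different pileup configurations")
        return cls(
            tensors=np.concatenate([b.tensors for b in batches]),
            meta=np.concatenate([b.meta for b in batches]),
            table=pd.concat([b.table for b in batches], ignore_index=True),
            cfg_hash=batches[0].cfg_hash,
        )


def _sidecar(path: str) -> str:
    return path[:-4] + ".tsv" if path.endswith(".npz") else path + ".tsv"


def encode_sample(
    bam_path: str,
    fasta_path: str,
    candidates_prefilter: list[CandidateVariant],
    db: PopulationDB,
    cfg: PileupConfig | None = None,
    max_af: float = 0.0,
    window_bp: int = 4_000_000,
    af_min: float = 0.10,
    zero_flanking: bool = False,
    sample_id: str = "",
) -> tuple[TensorBatch, list[CandidateVariant]]:
    """Filter, flank-annotate and encode one sample's candidates.

    Flanking annotation draws its germline pool from the *pre-filter*
    candidate list; tensors are built only for the retained candidates.
    Returns ``(batch, removed_candidates)``.
    """
    cfg = cfg or PileupConfig()
    retained, removed = population_filter(candidates_prefilter, db, max_af=max_af)
    rows = []
    tensors = np.zeros((len(retained), cfg.C, cfg.W, cfg.H), dtype=np.float32)
    metas = np.zeros((len(retained), 10), dtype=np.float32)
    stats_cache: dict = {}
    with pysam.AlignmentFile(bam_path) as bam, pysam.FastaFile(fasta_path) as fasta:
        for i, v in enumerate(retained):
            reads = fetch_site_reads(bam, v, cfg)
            vt = assemble_tensor(v, reads, reference_window(fasta, v, cfg), cfg)
            left, right = find_flanking(
                v,
                candidates_prefilter,
                db,
                bam,
                cfg,
                window_bp=window_bp,
                af_min=af_min,
                stats_cache=stats_cache,
            )
            vt.meta = build_meta_vector(
                vt.vaf_precrop, vt.dp_precrop, left, right, H=cfg.H, zero_flanking=zero_flanking
            )
            tensors[i] = vt.tensor
            metas[i] = vt.meta
            rows.append(
                {
                    "sample_id": sample_id or v.sample_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "variant_type": v.variant_type,
                    "truth_label": v.truth_label,
                    "vaf": vt.vaf_precrop,
                    "dp": vt.dp_precrop,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "variant_type", "truth_label", "vaf", "dp"],
    )
    return TensorBatch(tensors=tensors, meta=metas, table=table, cfg_hash=cfg.config_hash()), removed


def attach_truth_labels(candidates: list[CandidateVariant], truth_tsv: str) -> None:
    """Set ``truth_label`` on candidates from a simulator truth table (in place)."""
    truth = pd.read_csv(truth_tsv, sep="\t", dtype={"sample_id": str, "chrom": str})
    lookup = {
        (r.sample_id, r.chrom, int(r.pos), r.ref, r.alt): r.truth_label for r in truth.itertuples()
    }
    for v in candidates:
        label = lookup.get((v.sample_id, v.chrom, v.pos, v.ref, v.alt))
        if label is not None:
            v.truth_label = label


def prefilter_somatic_counts(truth_tsv: str) -> dict[str, int]:
    """Ground-truth somatic count per sample before population filtering."""
    truth = pd.read_csv(truth_tsv, sep="\t", dtype={"sample_id": str})
    som = truth[truth["truth_label"] == "somatic"]
    return som.groupby("sample_id").size().to_dict()


def evaluate_scores(
    scores_table: pd.DataFrame,
    prefilter_somatic: dict[str, int] | None = None,
    view: str = "somatic_vs_all",
    min_labels: int = 10,
) -> tuple[list[SampleEvaluation], float, dict[str, float]]:
    """Cohort evaluation from a scores table.

    ``scores_table`` needs columns sample_id, truth_label, score. Returns
    (per-sample evaluations, median threshold, summary). The f1 recall
    denominator is taken from ``prefilter_somatic`` when provided.
    """
    per_sample: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sid, grp in scores_table.groupby("sample_id"):
        s, y = subset_view(grp["score"].to_numpy(), grp["truth_label"].to_numpy(), view)
        per_sample[str(sid)] = (s, y)
    evals, t_median = evaluate_samples(per_sample, prefilter_somatic, min_labels=min_labels)
    return evals, t_median, summarize(evals)


def run_experiment(
    outdir: str,
    seed: int = 0,
    sim_cfg=None,
    train_cfg=None,
    n_test_samples: int = 2,
    pileup_cfg: PileupConfig | None = None,
    zero_flanking: bool = False,
) -> dict[str, float]:
    """Simulate a cohort, run the full pipeline and evaluate on held-out samples.

    The cohort is split at the sample level: the last ``n_test_samples``
    samples are held out, the rest train the classifier. Returns the headline
    metrics (per-sample mean test AUC, f1 at the median threshold, the
    class-view AUCs on the pooled test scores, and the somatic-vs-germline
    signature divergence). All stage artifacts are left under ``outdir``.
    """
    import os
    from dataclasses import replace

    from somaticnet.metrics import roc_auc
    from somaticnet.model import TrainConfig, predict_scores, save_checkpoint, train_classifier
    from somaticnet.signatures import compute_signature, js_divergence
    from somaticnet.simdata import SimConfig, simulate_cohort, write_fixtures
    from somaticnet.variants import load_population_db, read_candidate_vcf

    sim_cfg = replace(sim_cfg or SimConfig(), seed=seed)
    train_cfg = train_cfg or TrainConfig(seed=seed)
    cfg = pileup_cfg or PileupConfig()
    cohort = simulate_cohort(sim_cfg)
    paths = write_fixtures(cohort, outdir)
    db = load_population_db(paths["population"])

    batches = []
    for sample in cohort.samples:
        cands = read_candidate_vcf(paths["candidates"][sample.sample_id], sample_id=sample.sample_id)
        attach_truth_labels(cands, paths["truth"])
        batch, _removed = encode_sample(
            paths["bam"][sample.sample_id],
            paths["fasta"],
            cands,
            db,
            cfg=cfg,
            zero_flanking=zero_flanking,
            sample_id=sample.sample_id,
        )
        batches.append(batch)

    n_train = len(batches) - n_test_samples
    if n_train < 1 or n_test_samples < 1:
        raise ValueError("need at least one training and one test sample")
    train_batch = TensorBatch.concatenate(batches[:n_train])
    test_batch = TensorBatch.concatenate(batches[n_train:])

    clf, log = train_classifier(
        train_batch.tensors, train_batch.meta, train_batch.binary_labels, train_cfg
    )
    save_checkpoint(clf, os.path.join(outdir, "model.npz"), pileup_hash=cfg.config_hash(), train_cfg=train_cfg)
    scores = predict_scores(clf, test_batch.tensors, test_batch.meta)
    table = test_batch.table.copy()
    table["score"] = scores
    table.to_csv(os.path.join(outdir, "test_scores.tsv"), sep="\t", index=False)

    prefilter = prefilter_somatic_counts(paths["truth"])
    evals, t_median, summary = evaluate_scores(table, prefilter)
    write_evaluation_reports(evals, t_median, summary, os.path.join(outdir, "report"))

    results: dict[str, float] = {
        "n_train_tensors": float(len(train_batch)),
        "n_test_tensors": float(len(test_batch)),
        "test_auc_mean": summary["auc_mean"],
        "test_auc_sd": summary["auc_sd"],
        "f1_median_threshold": summary["f1_mean"],
        "median_threshold": t_median,
        "final_train_loss": float(log[-1]["loss"]),
    }
    for view in ("somatic_vs_germline", "somatic_vs_artifact"):
        s, y = subset_view(table["score"].to_numpy(), table["truth_label"].to_numpy(), view)
        if len(np.unique(y)) == 2:
            results[f"{view}_auc_pooled"], _, _ = roc_auc(s, y)

    with pysam.FastaFile(paths["fasta"]) as fasta:
        truth_variants = [t.variant for s in cohort.samples for t in s.truth]
        som = [v for v in truth_variants if v.truth_label == "somatic" and v.variant_type == "SNP"]
        germ = [v for v in truth_variants if v.truth_label == "germline" and v.variant_type == "SNP"]
        sig_s = compute_signature(som, fasta)
        sig_g = compute_signature(germ, fasta)
        results["signature_jsd_somatic_vs_germline"] = js_divergence(sig_s, sig_g)
    return results


def write_evaluation_reports(
    evals: list[SampleEvaluation], t_median: float, summary: dict, outdir: str
) -> None:
    """Per-sample TSV, ROC-point TSV and a mean +/- SD summary."""
    import os

    os.makedirs(outdir, exist_ok=True)
    rows = []
    for ev in evals:
        rows.append(
            {
                "sample_id": ev.sample_id,
                "n_variants": len(ev.scores),
                "n_somatic_prefilter": ev.n_somatic_prefilter,
                "excluded": ev.excluded,
                "exclusion_reason": ev.exclusion_reason,
                "auc": ev.auc,
                "optimal_threshold": ev.optimal_threshold,
                "threshold": ev.threshold,
                "f1": ev.f1,
                "precision": ev.precision,
                "recall": ev.recall,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(outdir, "per_sample.tsv"), sep="\t", index=False)
    roc_rows = []
    for ev in evals:
        for fpr, tpr in zip(ev.roc_fpr, ev.roc_tpr):
            roc_rows.append({"sample_id": ev.sample_id, "fpr": fpr, "tpr": tpr})
    pd.DataFrame(roc_rows).to_csv(os.path.join(outdir, "roc_points.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "summary.tsv"), "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"median_threshold\t{t_median:.6g}\n")
        for key, value in summary.items():
            fh.write(f"{key}\t{value:.6g}\n" if isinstance(value, float) else f"{key}\t{value}\n")
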