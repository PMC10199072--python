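"""End-to-end orchestration: prepare -> split -> augment -> train -> sample
-> curate -> score -> evaluate, with one seeded generator per stage."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict

from . import corpusprep, curator, evaluate, langmodel, nplikeness
from .chemio import read_smiles_file

log = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed by stage name (stable)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    corpus_path: str
    seed: int = 0
    augmentation_factor: int = 10
    n_samples: int = 5000
    sample_temperature: float = 1.0
    np_score_radius: int = 2
    np_score_bin_width: float = 0.1
    reference_corpus_path: str | None = None
    lm: langmodel.LMConfig = field(default_factory=langmodel.LMConfig)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        lm = langmodel.LMConfig(**d.pop("lm", {}))
        return cls(lm=lm, **d)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted in stage {stage!r}: {cause}")
        self.stage = stage


def run_pipeline(config: RunConfig, corpus: list[str] | None = None,
                 return_artifacts: bool = False):
    """Execute the full workflow and return a machine-readable report.

    ``corpus`` may be given directly (e.g. from the fixture generator);
    otherwise it is read from ``config.corpus_path``.  Deterministic for a
    fixed config: every stochastic stage draws its seed from the global one.
    """
    report: dict = {"seed": config.seed, "stages": {}}

    def _stage(name, fn):
        try:
            out = fn()
        except Exception as e:  # abort carries the stage name
            raise StageError(name, e) from e
        return out

    if corpus is None:
        corpus = _stage("prepare", lambda: [
            s for _, s in read_smiles_file(config.corpus_path)])

    filtered = _stage("prepare", lambda: corpusprep.prepare_corpus(corpus))
    report["stages"]["prepare"] = {"n_in": len(corpus), "n_out": len(filtered)}

    split = _stage("split", lambda: corpusprep.split_corpus(
        filtered, stage_seed(config.seed, "split")))
    report["stages"]["split"] = {
        "n_train": len(split.train), "n_validation": len(split.validation),
        "n_heldout": len(split.heldout)}

    train_aug, val_aug = _stage("augment", lambda: corpusprep.augment_corpus(
        split, config.augmentation_factor, stage_seed(config.seed, "augment")))
    report["stages"]["augment"] = {
        "factor": config.augmentation_factor,
        "n_train_aug": len(train_aug), "n_validation_aug": len(val_aug)}

    lm_cfg = langmodel.LMConfig(**{**asdict(config.lm),
                                   "seed": stage_seed(config.seed, "train")})
    state = _stage("train", lambda: langmodel.train(train_aug, val_aug, lm_cfg))
    report["stages"]["train"] = {
        "best_validation_loss": state.best_validation_loss,
        "n_minibatches": state.training_log[-1][0] if state.training_log else 0}

    sampled = _stage("sample", lambda: langmodel.sample(
        state, config.n_samples, stage_seed(config.seed, "sample"),
        config.sample_temperature))
    report["stages"]["sample"] = {"n_sampled": len(sampled)}

    kept, summary = _stage("curate", lambda: curator.curate(sampled))
    report["stages"]["curate"] = asdict_summary(summary)

    def _score():
        ref = (corpusprep.prepare_corpus(
            [s for _, s in read_smiles_file(config.reference_corpus_path)])
            if config.reference_corpus_path else None)
        if ref is None:
            from .fixturegen import generate_clean_corpus
            ref = generate_clean_corpus(
                min(500, max(50, len(filtered) // 4)),
                stage_seed(config.seed, "refpool"), pool="druglike")
        table = nplikeness.train_score_table(
            split.train, ref, radius=config.np_score_radius)
        train_scores = [nplikeness.np_score(s, table) for s in split.train]
        gen_scores = [nplikeness.np_score(r.canonical_smiles, table) for r in kept]
        for r, sc in zip(kept, gen_scores):
            r.np_score = sc
        return table, train_scores, gen_scores

    _table, train_scores, gen_scores = _stage("score", _score)

    def _evaluate():
        n_sampled = len(sampled)
        n_valid = n_sampled - summary.n_syntactic_invalid
        n_unique = n_valid - summary.n_duplicates
        out = {
            "n_sampled": n_sampled,
            "n_valid": n_valid,
            "n_unique": n_unique,
            "n_curated": summary.n_output,
            "validity_pct": 100.0 * n_valid / n_sampled if n_sampled else 0.0,
            "uniqueness_pct": 100.0 * n_unique / n_valid if n_valid else 0.0,
        }
        if gen_scores:
            pair = evaluate.make_distribution(
                train_scores, gen_scores, bin_width=config.np_score_bin_width)
            out["np_score_kl_nats"] = evaluate.kl_divergence(pair)
        gen_set = {r.canonical_smiles for r in kept}
        out["recovery_rate"] = evaluate.recovery_rate(gen_set, set(split.heldout))
        return out

    report["stages"]["evaluate"] = _stage("evaluate", _evaluate)
    report["records"] = len(kept)
    if return_artifacts:
        return report, {
            "split": split, "state": state, "sampled": sampled,
            "records": kept, "summary": summary,
            "train_scores": train_scores, "gen_scores": gen_scores,
        }
    return report


def asdict_summary(summary: curator.CurationSummary) -> dict:
    return {
        "n_input": summary.n_input,
        "n_syntactic_invalid": summary.n_syntactic_invalid,
        "n_duplicates": summary.n_duplicates,
        "n_checker_removed": summary.n_checker_removed,
        "n_output": summary.n_output,
    }


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
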