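"""End-to-end pipeline orchestration: config, stages, manifest, report.

Stage order: simulate (or ingest) -> enrichment selection -> labeling ->
featurization -> univariate screening -> knowledge veto ->
cross-validation -> full-data training -> apply-back scoring -> review
cohort selection -> report.  Every stage writes a text artifact into the
output directory; the run manifest records per-stage counts, metric
summaries and SHA-256 content hashes, so identical config and seed yield
an identical manifest.

A single global seed fans out to per-stage seeds by fixed offsets, giving
stage-level reproducibility without user-side seed bookkeeping.  All
thresholds of the procedure (screening alpha, minimum positive count,
per-type cap, kernel gamma, repetition counts, review cohort size) live
in one validated config object.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from raredetect import corpus as corpus_mod
from raredetect import features as features_mod
from raredetect import model as model_mod
from raredetect import review as review_mod
from raredetect import screening as screening_mod
from raredetect import simulate as simulate_mod
from raredetect import veto as veto_mod
from raredetect.corpus import Corpus, read_corpus, write_corpus
from raredetect.enrichment import (
    EnrichmentCriteria,
    LabelSet,
    build_labels,
    list_candidates,
    read_labels,
    select_enrichment,
    write_labels,
)
from raredetect.features import FeatureKey, FeatureMatrix, build_matrix, encode
from raredetect.model import DetectorConfig, TrainedDetector, cross_validate, score, train
from raredetect.review import (
    DEFAULT_LAB_PATTERNS,
    DEFAULT_RELATED_CODES,
    expected_cases,
    mention_flags,
    score_overlap,
    select_review_cohorts,
)
from raredetect.screening import ScreenParams, screen_features, write_screen_report
from raredetect.simulate import LeakageSpec, SignalSpec, SimConfig, describe_truth, simulate_corpus
from raredetect.veto import VetoRule, apply_veto, leakage_veto_rules, write_veto_report

__all__ = ["PipelineConfig", "ReviewSettings", "PipelineError", "run_pipeline", "report"]

logger = logging.getLogger("raredetect.pipeline")

# Fixed per-stage seed offsets fanned out from the global seed.
_SEED_SIM = 11
_SEED_MODEL = 23


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class ReviewSettings:
    term: str = "porph*"
    code_list: tuple[str, ...] = DEFAULT_RELATED_CODES
    lab_patterns: tuple[str, ...] = DEFAULT_LAB_PATTERNS
    top_n: int = 100
    prevalence: float = 1e-5


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run, in one auditable place."""

    sim: SimConfig = field(default_factory=SimConfig)
    enrichment: EnrichmentCriteria = field(default_factory=EnrichmentCriteria)
    screen: ScreenParams = field(default_factory=ScreenParams)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    review: ReviewSettings = field(default_factory=ReviewSettings)
    veto_rules: list[VetoRule] | None = None  # None -> derived from sim.leakage
    seed: int = 0

    def __post_init__(self) -> None:
        # Fan the global seed out to the stages.
        self.sim = dataclasses.replace(self.sim, seed=self.seed + _SEED_SIM)
        self.detector = dataclasses.replace(self.detector, seed=self.seed + _SEED_MODEL)

    def rules(self) -> list[VetoRule]:
        if self.veto_rules is not None:
            return self.veto_rules
        return leakage_veto_rules(self.sim.leakage)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sim": {
                "n_patients": self.sim.n_patients,
                "prevalence": self.sim.prevalence,
                "undiagnosed_fraction": self.sim.undiagnosed_fraction,
                "vocab_size": self.sim.vocab_size,
                "deceased_rate": self.sim.deceased_rate,
                "signal": dataclasses.asdict(self.sim.signal) | {
                    "symptom_tokens": list(self.sim.signal.symptom_tokens)
                },
                "leakage": dataclasses.asdict(self.sim.leakage),
            },
            "enrichment": dataclasses.asdict(self.enrichment),
            "screen": dataclasses.asdict(self.screen),
            "detector": dataclasses.asdict(self.detector),
            "review": dataclasses.asdict(self.review) | {
                "code_list": list(self.review.code_list),
                "lab_patterns": list(self.review.lab_patterns),
            },
            "veto_rules": None
            if self.veto_rules is None
            else [
                {"pattern": r.pattern, "scope": r.scope.value if r.scope else None, "reason": r.reason}
                for r in self.veto_rules
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sim_d = dict(d.get("sim", {}))
        signal = SignalSpec(**{**sim_d.pop("signal", {}),}) if "signal" in sim_d else SignalSpec()
        if isinstance(signal.symptom_tokens, list):
            signal.symptom_tokens = tuple(signal.symptom_tokens)
        leakage = LeakageSpec(**sim_d.pop("leakage", {}))
        sim_d.pop("seed", None)
        review_d = dict(d.get("review", {}))
        if "code_list" in review_d:
            review_d["code_list"] = tuple(review_d["code_list"])
        if "lab_patterns" in review_d:
            review_d["lab_patterns"] = tuple(review_d["lab_patterns"])
        rules_d = d.get("veto_rules")
        rules = None
        if rules_d is not None:
            rules = [
                VetoRule(
                    pattern=r["pattern"],
                    scope=corpus_mod.DocType(r["scope"]) if r.get("scope") else None,
                    reason=r["reason"],
                )
                for r in rules_d
            ]
        return cls(
            sim=SimConfig(signal=signal, leakage=leakage, **sim_d),
            enrichment=EnrichmentCriteria(**d.get("enrichment", {})),
            screen=ScreenParams(**d.get("screen", {})),
            detector=DetectorConfig(**{k: v for k, v in d.get("detector", {}).items() if k != "seed"}),
            review=ReviewSettings(**review_d),
            veto_rules=rules,
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _selected_features_from_records(records) -> list[FeatureKey]:
    return [r.feature for r in records if r.selected]


def read_feature_list(path: str | Path) -> list[FeatureKey]:
    """Read the retained-feature list of a veto report TSV."""
    out: list[FeatureKey] = []
    with open(path, encoding="utf-8") as fh:
        fh.readline()
        for line in fh:
            dt, fname, token, status, _ = line.rstrip("\n").split("\t")
            if status == "retained":
                out.append(FeatureKey(corpus_mod.DocType(dt), fname, token))
    return out


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages, write artifacts and return the run manifest.

    The manifest holds the config echo, the patient-count funnel, metric
    summaries and a content hash per text artifact.  On stage failure a
    :class:`PipelineError` names the stage; artifacts of completed stages
    are retained for debugging.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.to_dict(), "stages": {}, "hashes": {}}
    artifacts: dict[str, Path] = {}
    stage = "init"

    def _done(name: str, info: dict, *paths: Path) -> None:
        manifest["stages"][name] = info
        for p in paths:
            artifacts[p.name] = p
        logger.info("stage %s: %s", name, info)

    try:
        stage = "simulate"
        t0 = time.perf_counter()
        corpus, truth = simulate_corpus(config.sim)
        corpus_path = write_corpus(corpus, outdir / "corpus.jsonl")
        truth_path = simulate_mod.write_truth(truth, outdir / "truth.tsv")
        summary_path = corpus_mod.write_summary(
            corpus_mod.corpus_summary(corpus), outdir / "doc_summary.tsv"
        )
        _done(
            stage,
            {"n_patients": len(corpus), "truth": describe_truth(truth)},
            corpus_path,
            truth_path,
            summary_path,
        )
        logger.info("simulate took %.1fs", time.perf_counter() - t0)

        stage = "enrich"
        enriched = select_enrichment(corpus, config.enrichment)
        enrich_path = outdir / "enriched_ids.txt"
        enrich_path.write_text("\n".join(sorted(enriched)) + ("\n" if enriched else ""))
        _done(stage, {"n_enriched": len(enriched)}, enrich_path)

        stage = "label"
        candidates = list_candidates(corpus, config.sim.leakage.disease_code)
        # Chart-review analogue: a code-matched candidate is adjudicated
        # positive iff the ground truth marks it a diagnosed positive —
        # spuriously coded negatives stay unconfirmed, hence negative.
        adjudicated = {pid for pid in candidates if truth.get(pid) == "diagnosed_positive"}
        labels = build_labels(corpus, candidates, adjudicated)
        labels_path = write_labels(labels, outdir / "labels.tsv")
        _done(
            stage,
            {
                "n_candidates": len(candidates),
                "n_positive": len(labels.positives),
                "n_negative": len(labels.negatives),
            },
            labels_path,
        )

        stage = "featurize"
        t0 = time.perf_counter()
        matrix = build_matrix(corpus)
        feat_paths = features_mod.write_matrix(matrix, outdir / "features")
        _done(stage, {"n_features": len(matrix.vocabulary)}, *feat_paths.values())
        logger.info("featurize took %.1fs", time.perf_counter() - t0)

        stage = "screen"
        t0 = time.perf_counter()
        records = screen_features(matrix, labels, config.screen)
        screen_path = write_screen_report(records, outdir / "screen.tsv")
        selected = _selected_features_from_records(records)
        _done(stage, {"n_screened": len(records), "n_selected": len(selected)}, screen_path)
        logger.info("screen took %.1fs", time.perf_counter() - t0)

        stage = "veto"
        veto_report = apply_veto(selected, config.rules())
        veto_path = write_veto_report(veto_report, outdir / "veto.tsv")
        retained = veto_report.retained
        _done(stage, {"n_removed": len(veto_report.removed), "n_retained": len(retained)}, veto_path)

        stage = "cv"
        t0 = time.perf_counter()
        restricted = matrix.select(retained)
        encoded = encode(restricted, config.detector.encoding)
        cv = cross_validate(encoded, labels, config.detector)
        cv_path = model_mod.write_cv_result(cv, outdir / "cv.tsv")
        _done(
            stage,
            {
                "auc": cv.auc,
                "average_precision": cv.average_precision,
                "precision_at_100": cv.precision_at_100,
                "log_loss": cv.log_loss,
                "n_fold_evaluations": cv.n_fold_evaluations,
            },
            cv_path,
        )
        logger.info("cv took %.1fs", time.perf_counter() - t0)

        stage = "train"
        detector = train(encoded, labels, config.detector)
        _done(stage, {"model_state_hash": detector.state_hash()})

        stage = "score"
        rankings = score(detector, encoded)
        scores_path = model_mod.write_scores(rankings, outdir / "scores.tsv")
        overlap = score_overlap(rankings, labels)
        _done(stage, {"n_scored": len(rankings), "score_overlap": overlap}, scores_path)

        stage = "cohorts"
        flags = {
            p.patient_id: mention_flags(
                p, config.review.term, config.review.code_list, config.review.lab_patterns
            )
            for p in corpus
        }
        cohort_a, cohort_b = select_review_cohorts(
            rankings, flags, known_positives=labels.positives, top_n=config.review.top_n
        )
        cohorts_path = review_mod.write_cohorts(cohort_a, cohort_b, rankings, flags, outdir / "cohorts.tsv")
        n_reviewed = len(cohort_a) + len(cohort_b)
        _done(
            stage,
            {
                "cohort_a": len(cohort_a),
                "cohort_b": len(cohort_b),
                "expected_cases_by_chance": expected_cases(n_reviewed, config.review.prevalence),
            },
            cohorts_path,
        )
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["hashes"] = {name: _sha256(p) for name, p in sorted(artifacts.items())}
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    report_path = outdir / "report.txt"
    report_path.write_text(report(manifest))
    return manifest


def report(manifest: dict) -> str:
    """Human-readable run summary: counts funnel, CV metrics, cohorts.

    Regeneration from the same manifest is byte-identical.
    """
    required = ["simulate", "enrich", "label", "featurize", "screen", "veto", "cv", "train", "score", "cohorts"]
    stages = manifest.get("stages", {})
    missing = [s for s in required if s not in stages]
    if missing:
        raise ValueError(f"manifest incomplete; missing stages: {missing}")
    s = stages
    lines = [
        "rare-disease detection pipeline run",
        "===================================",
        "",
        "patient funnel",
        f"  patients simulated        {s['simulate']['n_patients']}",
        f"  wildcard-enriched         {s['enrich']['n_enriched']}",
        f"  code-matched candidates   {s['label']['n_candidates']}",
        f"  adjudicated positives     {s['label']['n_positive']}",
        f"  presumed negatives        {s['label']['n_negative']}",
        f"  features extracted        {s['featurize']['n_features']}",
        f"  features selected         {s['screen']['n_selected']}",
        f"  features after veto       {s['veto']['n_retained']}",
        f"  patients scored           {s['score']['n_scored']}",
        f"  review cohort A (no mention)    {s['cohorts']['cohort_a']}",
        f"  review cohort B (note mention)  {s['cohorts']['cohort_b']}",
        "",
        "cross-validation metrics (mean over fold-evaluations)",
        f"  AUC                 {s['cv']['auc']:.3f}",
        f"  average precision   {s['cv']['average_precision']:.3f}",
        f"  precision@100       {s['cv']['precision_at_100']:.3f}",
        f"  log loss            {s['cv']['log_loss']:.3f}",
        f"  fold-evaluations    {s['cv']['n_fold_evaluations']}",
        "",
        "apply-back ranking",
        f"  negatives overlapping positive score range  {s['score']['score_overlap']}",
        f"  expected cases among reviewed, by chance    {s['cohorts']['expected_cases_by_chance']:.6g}",
        "",
    ]
    return "\n".join(lines)
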