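"""End-to-end experiment runner: simulate -> cohort/split -> vocab -> 5-fold
training -> evaluation -> CMI scenario analyses, all under one run directory.

Every stage derives its own RNG stream from the global seed, records its
outputs in ``manifest.json`` and is skipped on re-invocation when its outputs
already exist for the same configuration (crash resume).  The vocabulary and
every model checkpoint are built from training-fold patients only; the
manifest records that provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import zlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cmi as cmi_mod
from . import metrics as metrics_mod
from .cohort import SplitPlan, build_cohort, make_cv_folds, make_test_population, split_train_test
from .model import DrgModel, ModelConfig, train
from .synthgen import GenConfig, make_drg_catalog, read_tables, simulate_cohort, write_tables
from .textprep import Vocab, build_vocab, clean_and_tokenize, assemble_document, encode_stay

log = logging.getLogger("drgcast")


def stage_seed(global_seed: int, stage: str) -> int:
    """Independent but reproducible per-stage seed stream."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass(frozen=True)
class RunConfig:
    """One reproducible experiment; sub-config seeds are derived from ``seed``."""

    seed: int
    gen: GenConfig
    model: ModelConfig
    test_frac: float = 0.10
    k_folds: int = 5
    max_len: int = 2000
    vocab_min_count: int = 3
    vocab_scope: str = "train"  # or "cohort": count tokens over the whole cohort
    eval_cutoff: float = 48.0
    hpa_grid: tuple[float, ...] = cmi_mod.DEFAULT_HPA_GRID
    sizes: tuple[int, ...] = (200, 400, 600, 800, 1000)
    n_subgroups: int = 20
    boot_reps: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        seed = int(raw["seed"])
        gen = GenConfig(seed=stage_seed(seed, "simulate"), **raw.get("gen", {}))
        model = ModelConfig(seed=stage_seed(seed, "train"), **raw.get("model", {}))
        extra = {k: v for k, v in raw.items() if k not in ("seed", "gen", "model")}
        if "sizes" in extra:
            extra["sizes"] = tuple(extra["sizes"])
        if "hpa_grid" in extra:
            extra["hpa_grid"] = tuple(extra["hpa_grid"])
        return cls(seed=seed, gen=gen, model=model, **extra)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True,
                                         default=str).encode()).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _Manifest:
    def __init__(self, path: Path, config_hash: str):
        self.path = path
        self.config_hash = config_hash
        self.data = {"config_hash": config_hash, "stages": {},
                     "versions": {"python": sys.version.split()[0],
                                  "numpy": np.__version__,
                                  "pandas": pd.__version__}}
        if path.exists():
            old = json.loads(path.read_text())
            if old.get("config_hash") == config_hash:
                self.data = old

    def done(self, stage: str, out_dir: Path) -> bool:
        entry = self.data["stages"].get(stage)
        if not entry:
            return False
        return all((out_dir / f).exists() for f in entry["files"])

    def record(self, stage: str, out_dir: Path, files: list[str],
               **extra) -> None:
        self.data["stages"][stage] = {
            "files": files,
            "hashes": {f: _sha256(out_dir / f) for f in files},
            **extra,
        }
        self.path.write_text(json.dumps(self.data, indent=1, sort_keys=True))


def _setup_logging(out_dir: Path) -> None:
    if not log.handlers:
        log.setLevel(logging.INFO)
        log.addHandler(logging.StreamHandler(sys.stderr))
    fh = logging.FileHandler(out_dir / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(fh)


def run_experiment(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute every stage under ``out_dir`` and return that directory.

    Re-running with the same config skips completed stages; any stage failure
    propagates after earlier stages have been persisted.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    manifest = _Manifest(out / "manifest.json", config.config_hash())

    # -- simulate ----------------------------------------------------------
    gen = replace(config.gen, seed=stage_seed(config.seed, "simulate"))
    if manifest.done("simulate", out):
        log.info("stage=simulate event=skip (resume)")
        stays, catalog = read_tables(out)
    else:
        log.info("stage=simulate event=start n_patients=%d", gen.n_patients)
        catalog = make_drg_catalog(gen)
        stays = simulate_cohort(catalog, gen)
        write_tables(stays, catalog, out)
        manifest.record("simulate", out,
                        ["notes.csv", "drg_assignments.csv", "catalog.csv"],
                        seed=gen.seed)
        log.info("stage=simulate event=done stays=%d", len(stays))

    # -- cohort + split ----------------------------------------------------
    cohort = build_cohort(stays, catalog)
    split_seed = stage_seed(config.seed, "split")
    split_path = out / "split.json"
    if manifest.done("split", out):
        raw = json.loads(split_path.read_text())
        split = SplitPlan(frozenset(raw["test_patient_ids"]),
                          tuple(frozenset(f) for f in raw["cv_folds"]), raw["seed"])
        log.info("stage=split event=skip (resume)")
    else:
        split = split_train_test(cohort, config.test_frac, seed=split_seed)
        train_patients = {s.patient_id for s in cohort.stays} - split.test_patient_ids
        folds = make_cv_folds(train_patients, config.k_folds, seed=split_seed)
        split = SplitPlan(split.test_patient_ids, folds, split_seed)
        split_path.write_text(json.dumps({
            "test_patient_ids": sorted(split.test_patient_ids),
            "cv_folds": [sorted(f) for f in split.cv_folds],
            "seed": split_seed}, indent=1))
        manifest.record("split", out, ["split.json"], seed=split_seed,
                        n_test_patients=len(split.test_patient_ids))
        log.info("stage=split event=done test_patients=%d", len(split.test_patient_ids))

    train_stays = [s for s in cohort.stays if s.patient_id not in split.test_patient_ids]
    test_stays = [s for s in cohort.stays if s.patient_id in split.test_patient_ids]

    # -- vocabulary --------------------------------------------------------
    vocab_path = out / "vocab.tsv"
    if manifest.done("vocab", out):
        vocab = Vocab.from_tsv(vocab_path, config.vocab_min_count)
        log.info("stage=vocab event=skip (resume)")
    else:
        source = cohort.stays if config.vocab_scope == "cohort" else train_stays
        corpus = (clean_and_tokenize(assemble_document(s, config.eval_cutoff))
                  for s in source)
        vocab = build_vocab(corpus, config.vocab_min_count)
        vocab.to_tsv(vocab_path)
        manifest.record("vocab", out, ["vocab.tsv"], scope=config.vocab_scope,
                        provenance="training-fold stays only" if config.vocab_scope == "train"
                        else "whole cohort", size=len(vocab))
        log.info("stage=vocab event=done size=%d", len(vocab))

    # -- fivefold training -------------------------------------------------
    models: list[DrgModel] = []
    ckpt_names = [f"model_{i}.npz" for i in range(config.k_folds)]
    if manifest.done("train", out):
        models = [DrgModel.load(out / n, vocab) for n in ckpt_names]
        log.info("stage=train event=skip (resume)")
    else:
        for i, fold in enumerate(split.cv_folds):
            tr = [s for s in train_stays if s.patient_id not in fold]
            va = [s for s in train_stays if s.patient_id in fold]
            tr_docs = [encode_stay(s, config.eval_cutoff, vocab, config.max_len) for s in tr]
            va_docs = [encode_stay(s, config.eval_cutoff, vocab, config.max_len) for s in va]
            mc = replace(config.model, seed=stage_seed(config.seed, f"train{i}"))
            log.info("stage=train fold=%d event=start n_train=%d n_val=%d",
                     i, len(tr), len(va))
            m = train(tr_docs, [s.drg_code for s in tr], mc,
                      label_space=cohort.label_space, vocab=vocab,
                      val_docs=va_docs, val_labels=[s.drg_code for s in va])
            m.save(out / ckpt_names[i])
            models.append(m)
        manifest.record("train", out,
                        ckpt_names + [n + ".json" for n in ckpt_names],
                        provenance="training-fold stays only")
        log.info("stage=train event=done folds=%d", len(models))

    # -- evaluation --------------------------------------------------------
    report_path = out / "report.json"
    if not manifest.done("evaluate", out):
        docs = [encode_stay(s, config.eval_cutoff, vocab, config.max_len)
                for s in test_stays]
        true_codes = [s.drg_code for s in test_stays]
        subsets = metrics_mod.make_subsets(test_stays, catalog)
        per_model = []
        for m in models:
            probs = m.predict_proba(docs)
            preds = [m.label_space[i] for i in probs.argmax(axis=1)]
            per_model.append(metrics_mod.evaluate_predictions(
                probs, preds, true_codes, m.label_space, subsets))
        common = set(per_model[0])
        for r in per_model[1:]:
            common &= set(r)
        agg = metrics_mod.aggregate_over_models(
            [{k: r[k] for k in common} for r in per_model])
        report_path.write_text(json.dumps(
            {"cutoff_hpa": config.eval_cutoff, "n_test_stays": len(test_stays),
             "subsets": agg}, indent=1, sort_keys=True))
        manifest.record("evaluate", out, ["report.json"])
        log.info("stage=evaluate event=done subsets=%d", len(agg))

    # -- CMI scenario analyses ----------------------------------------------
    if not manifest.done("cmi", out):
        population = make_test_population(cohort, split)
        _reports, summary = cmi_mod.hpa_sweep(models, population, catalog, vocab,
                                              grid=config.hpa_grid,
                                              max_len=config.max_len)
        pd.DataFrame(summary).to_csv(out / "sweep.csv", index=False)
        sizes = tuple(s for s in config.sizes if s <= 4 * len(population)) or (len(population),)
        rows = cmi_mod.population_size_analysis(
            models, population, catalog, vocab, sizes,
            n_subgroups=config.n_subgroups, boot_reps=config.boot_reps,
            seed=stage_seed(config.seed, "cmi"), max_len=config.max_len)
        pd.DataFrame(rows).to_csv(out / "size.csv", index=False)
        manifest.record("cmi", out, ["sweep.csv", "size.csv"],
                        population=len(population))
        log.info("stage=cmi event=done population=%d", len(population))

    return out
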