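"""End-to-end orchestration of the demand and content analyses.

A :class:`RunConfig` fully determines a run: the synthetic cohort (or an
epoch container on disk), the spectral-separation settings, the decoding
settings, the inference settings and a master seed from which every
stochastic stage derives its own stream.  Rerunning the same config
reproduces every numeric output bit-exactly.

All tables are tidy (one observation per row) TSVs so each stage is
independently re-analysable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from ._seeding import derive_int
from .containers import (
    CONTENTS,
    SIGNALS,
    TASKS,
    ConfigurationError,
    EpochSet,
    FeatureSet,
)
from .decode import DecodeConfig, decode_within, generalization_matrix
from .geometry import average_aligned, condition_means, embed_pca2, embedding_table
from .inference import bh_fdr, group_auc_test, permutation_corr_test
from .irasa import IrasaConfig, extract_features
from .patterns import activation_pattern, aggregate_patterns, percentile_mask
from .preprocess import RejectionThresholds, crop_window, reject_epochs, subtract_evoked
from .simulate import SimConfig, gen_epoch_set

logger = logging.getLogger(__name__)

SUBTASKS = [(t, c) for t in TASKS for c in CONTENTS]


@dataclass
class RunConfig:
    """Everything needed for one reproducible pipeline run."""

    sim: SimConfig | None = None
    input_path: str | None = None
    irasa: IrasaConfig = field(default_factory=IrasaConfig)
    decode: DecodeConfig = field(default_factory=DecodeConfig)
    thresholds: RejectionThresholds = field(default_factory=RejectionThresholds)
    window: tuple = (0.3, 1.5)
    signals: tuple = SIGNALS
    contrasts: tuple = ("demand", "content")
    content_easy_only: bool = False
    run_generalization: bool = True
    run_geometry: bool = True
    percentile: float = 60.0
    n_permutations: int = 1000
    alpha: float = 0.05
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sim is None and self.input_path is None:
            raise ConfigurationError("config needs either 'sim' or 'input_path'")
        unknown = set(self.signals) - set(SIGNALS)
        if unknown:
            raise ConfigurationError(f"unknown signals: {sorted(unknown)}")


_REQUIRED_FILE_KEYS = {"irasa": ["h_set"], "decode": [], "sim": []}


def run_config_from_dict(raw: dict) -> RunConfig:
    """Build a RunConfig from a parsed JSON/YAML mapping, naming any
    missing required key."""
    raw = dict(raw)
    kwargs: dict = {}
    if "sim" in raw:
        kwargs["sim"] = SimConfig(**raw.pop("sim"))
    if "irasa" in raw:
        section = raw.pop("irasa")
        for key in _REQUIRED_FILE_KEYS["irasa"]:
            if key not in section:
                raise ConfigurationError(f'missing configuration key "{key}" in irasa section')
        kwargs["irasa"] = IrasaConfig(**section)
    if "decode" in raw:
        kwargs["decode"] = DecodeConfig(**raw.pop("decode"))
    if "thresholds" in raw:
        kwargs["thresholds"] = RejectionThresholds(**raw.pop("thresholds"))
    for key in (
        "input_path", "window", "signals", "contrasts", "content_easy_only",
        "run_generalization", "run_geometry", "percentile", "n_permutations",
        "alpha", "out_dir", "seed",
    ):
        if key in raw:
            kwargs[key] = raw.pop(key)
    if raw:
        raise ConfigurationError(f"unknown configuration keys: {sorted(raw)}")
    if "window" in kwargs:
        kwargs["window"] = tuple(kwargs["window"])
    for key in ("signals", "contrasts"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return RunConfig(**kwargs)


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    return run_config_from_dict(raw)


# --------------------------------------------------------------------------
# feature table round trip
# --------------------------------------------------------------------------

def features_to_frame(features: FeatureSet) -> pd.DataFrame:
    return features.to_frame()


def features_from_frame(df: pd.DataFrame) -> FeatureSet:
    """Rebuild a FeatureSet from the tidy per-trial feature table."""
    label_cols = ["subject", "task", "content", "demand", "trial"]
    channels = list(pd.unique(df["channel"]))
    wide = df.pivot_table(
        index=label_cols, columns=["signal", "channel"], values="value", sort=False
    )
    labels = wide.index.to_frame(index=False)
    values = {}
    for sig in pd.unique(df["signal"]):
        values[sig] = wide[sig][channels].to_numpy()
    return FeatureSet(values=values, labels=labels, feature_ids=channels)


# --------------------------------------------------------------------------
# analysis stages on a FeatureSet
# --------------------------------------------------------------------------

def _contrast_units(contrast: str):
    """Decoding units: (unit-name-parts, label-column) per contrast.

    Demand is decoded within each of the six subtasks; content within each
    task (pooling demands unless easy-only is requested)."""
    if contrast == "demand":
        return [{"task": t, "content": c} for t, c in SUBTASKS], "demand"
    if contrast == "content":
        return [{"task": t} for t in TASKS], "content"
    raise ConfigurationError(f"unknown contrast {contrast!r}")


def _unit_mask(labels: pd.DataFrame, unit: dict, easy_only: bool) -> np.ndarray:
    mask = np.ones(len(labels), dtype=bool)
    for col, val in unit.items():
        mask &= (labels[col] == val).to_numpy()
    if easy_only:
        mask &= (labels["demand"] == "easy").to_numpy()
    return mask


def decoding_table(
    features: FeatureSet,
    contrast: str,
    config: DecodeConfig,
    signals=SIGNALS,
    easy_only: bool = False,
) -> pd.DataFrame:
    """Per-subject decoding AUCs for one contrast, all requested signals."""
    units, label_col = _contrast_units(contrast)
    easy_only = easy_only and contrast == "content"
    rows = []
    subjects = sorted(pd.unique(features.labels["subject"]))
    for subject in subjects:
        subj_mask = (features.labels["subject"] == subject).to_numpy()
        for unit in units:
            mask = subj_mask & _unit_mask(features.labels, unit, easy_only)
            for signal in signals:
                sf = features.signal(signal, mask)
                cfg = replace(
                    config,
                    seed=derive_int(config.seed, "decode", subject, signal, *unit.values()),
                )
                res = decode_within(sf, sf.labels[label_col].to_numpy(), cfg)
                rows.append(
                    {
                        "subject": subject,
                        "contrast": contrast,
                        **{k: unit.get(k, "all") for k in ("task", "content")},
                        "signal": signal,
                        "auc": res.auc,
                        "n_pseudotrials": res.n_pseudotrials,
                    }
                )
    return pd.DataFrame(rows)


def generalization_tables(
    features: FeatureSet, config: DecodeConfig, signals=SIGNALS
) -> dict[str, pd.DataFrame]:
    """Demand-contrast cross-subtask generalization matrix per signal,
    averaged across subjects."""
    subjects = sorted(pd.unique(features.labels["subject"]))
    out = {}
    for signal in signals:
        mats = []
        for subject in subjects:
            subj_mask = (features.labels["subject"] == subject).to_numpy()
            by_subtask = {}
            for task, content in SUBTASKS:
                mask = subj_mask & _unit_mask(
                    features.labels, {"task": task, "content": content}, False
                )
                sf = features.signal(signal, mask)
                by_subtask[f"{task}/{content}"] = (
                    sf.matrix,
                    sf.labels["demand"].to_numpy(),
                )
            cfg = replace(config, seed=derive_int(config.seed, "gen", subject, signal))
            mats.append(generalization_matrix(by_subtask, cfg))
        out[signal] = sum(mats) / len(mats)
    return out


def pattern_analysis(
    features: FeatureSet,
    contrast: str,
    config: DecodeConfig,
    signals=SIGNALS,
    percentile: float = 60.0,
):
    """Per-subject/subtask Haufe patterns, subject-level subtask averages,
    group aggregates and the percentile-masked group map.

    Returns ``(table, subject_patterns)`` where ``subject_patterns`` maps
    ``signal -> {subject -> ActivationPattern}`` (subtask-averaged, used by
    the pattern-correlation inference).
    """
    units, label_col = _contrast_units(contrast)
    subjects = sorted(pd.unique(features.labels["subject"]))
    rows = []
    subject_patterns: dict = {}
    for signal in signals:
        per_subject = {}
        all_patterns = []
        for subject in subjects:
            subj_mask = (features.labels["subject"] == subject).to_numpy()
            pats = []
            for unit in units:
                mask = subj_mask & _unit_mask(features.labels, unit, False)
                sf = features.signal(signal, mask)
                cfg = replace(
                    config,
                    seed=derive_int(config.seed, "pattern", subject, signal, *unit.values()),
                )
                pats.append(
                    activation_pattern(
                        sf,
                        sf.labels[label_col].to_numpy(),
                        cfg,
                        provenance={"subject": subject, "signal": signal, **unit},
                    )
                )
            per_subject[subject] = aggregate_patterns(pats)
            all_patterns.extend(pats)
        group = aggregate_patterns(all_patterns)
        mask, masked = percentile_mask(group, percentile)
        for fid, value, kept in zip(group.feature_ids, group.values, mask):
            rows.append(
                {
                    "feature_id": fid,
                    "signal": signal,
                    "contrast": contrast,
                    "value": value,
                    "retained": bool(kept),
                }
            )
        subject_patterns[signal] = per_subject
    return pd.DataFrame(rows), subject_patterns


def stats_table(
    decoding: pd.DataFrame,
    subject_patterns_by_contrast: dict,
    K: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Group inference: one-tailed t tests of AUC against chance with BH
    correction per contrast family, plus permutation tests of the mean
    within-subject correlation between band patterns."""
    rows = []
    for contrast, block in decoding.groupby("contrast", sort=True):
        tests = []
        for (task, content, signal), cell in block.groupby(
            ["task", "content", "signal"], sort=True
        ):
            t, p = group_auc_test(cell["auc"].to_numpy(), 0.5, tail="one")
            tests.append(
                {
                    "analysis": "decoding",
                    "signal": signal,
                    "contrast": f"{contrast}:{task}/{content}",
                    "statistic": t,
                    "p_raw": p,
                    "n": len(cell),
                    "tail": "one",
                    "K": "",
                }
            )
        p_adj = bh_fdr([r["p_raw"] for r in tests])
        for r, q in zip(tests, p_adj):
            r["p_fdr"] = q
            rows.append(r)
    band_pairs = [("theta", "alpha"), ("theta", "beta"), ("alpha", "beta")]
    for contrast, subject_patterns in subject_patterns_by_contrast.items():
        for sig_a, sig_b in band_pairs:
            if sig_a not in subject_patterns or sig_b not in subject_patterns:
                continue
            subjects = sorted(subject_patterns[sig_a])
            pairs = [
                (subject_patterns[sig_a][s], subject_patterns[sig_b][s])
                for s in subjects
            ]
            outcome = permutation_corr_test(
                pairs, K=K, seed=derive_int(seed, "permcorr", contrast, sig_a, sig_b)
            )
            rows.append(
                {
                    "analysis": "pattern_correlation",
                    "signal": f"{sig_a}~{sig_b}",
                    "contrast": contrast,
                    "statistic": outcome.observed_mean_r,
                    "p_raw": outcome.p,
                    "p_fdr": outcome.p,
                    "n": len(pairs),
                    "tail": "two",
                    "K": outcome.K,
                }
            )
    cols = ["analysis", "signal", "contrast", "statistic", "p_raw", "p_fdr", "n", "tail", "K"]
    return pd.DataFrame(rows)[cols]


def geometry_analysis(features: FeatureSet, signals=SIGNALS) -> pd.DataFrame:
    """Two-dimensional condition geometry per signal.

    Per subject: condition means per task (content x demand cells), PCA to
    two components per task, Procrustes alignment of tasks (no scaling) and
    averaging; then alignment and averaging across subjects (reference =
    first subject by sorted ID).
    """
    subjects = sorted(pd.unique(features.labels["subject"]))
    frames = []
    for signal in signals:
        per_subject = []
        for subject in subjects:
            subj_mask = (features.labels["subject"] == subject).to_numpy()
            task_embeddings = []
            for task in TASKS:
                mask = subj_mask & (features.labels["task"] == task).to_numpy()
                sf = features.signal(signal, mask)
                means, labels = condition_means(sf, by=("content", "demand"))
                task_embeddings.append(embed_pca2(means, labels))
            per_subject.append(average_aligned(task_embeddings))
        group = average_aligned(per_subject)
        frames.append(embedding_table({"all": group}, signal))
    return pd.concat(frames, ignore_index=True)


# --------------------------------------------------------------------------
# full run
# --------------------------------------------------------------------------

def _config_digest(config: RunConfig) -> str:
    def enc(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(config), default=enc, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute every configured stage and write all outputs under
    ``config.out_dir``.  Returns the in-memory results bundle."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    logger.info("stage: input")
    if config.sim is not None:
        sim = replace(config.sim, seed=derive_int(config.seed, "sim"))
        epochs, truth = gen_epoch_set(sim)
        truth.to_json(out / "ground_truth.json")
    else:
        epochs = EpochSet.load(config.input_path)

    logger.info("stage: preprocess")
    epochs, report = reject_epochs(epochs, config.thresholds)
    report.to_csv(out / "rejections.tsv", sep="\t", index=False)
    epochs = subtract_evoked(epochs)
    epochs = crop_window(epochs, *config.window)

    logger.info("stage: irasa features")
    features = extract_features(epochs, config.irasa)
    features.to_frame().to_csv(out / "features.tsv", sep="\t", index=False)
    results["features"] = features

    logger.info("stage: decoding")
    decode_cfg = replace(config.decode, seed=derive_int(config.seed, "decode"))
    decoding_frames = []
    for contrast in config.contrasts:
        decoding_frames.append(
            decoding_table(
                features, contrast, decode_cfg, config.signals,
                easy_only=config.content_easy_only,
            )
        )
    decoding = pd.concat(decoding_frames, ignore_index=True)
    decoding.to_csv(out / "decoding.tsv", sep="\t", index=False)
    results["decoding"] = decoding

    if config.run_generalization:
        logger.info("stage: generalization")
        gen = generalization_tables(features, decode_cfg, config.signals)
        for signal, mat in gen.items():
            mat.to_csv(out / f"generalization_{signal}.tsv", sep="\t")
        results["generalization"] = gen

    logger.info("stage: patterns")
    pattern_frames, subj_patterns = [], {}
    for contrast in config.contrasts:
        tbl, per_subject = pattern_analysis(
            features, contrast, decode_cfg, config.signals, config.percentile
        )
        pattern_frames.append(tbl)
        subj_patterns[contrast] = per_subject
    patterns = pd.concat(pattern_frames, ignore_index=True)
    patterns.to_csv(out / "patterns.tsv", sep="\t", index=False)
    results["patterns"] = patterns

    logger.info("stage: inference")
    stats = stats_table(
        decoding, subj_patterns, K=config.n_permutations,
        seed=derive_int(config.seed, "inference"),
    )
    stats.to_csv(out / "stats.tsv", sep="\t", index=False)
    results["stats"] = stats

    if config.run_geometry:
        logger.info("stage: geometry")
        embeddings = geometry_analysis(features, config.signals)
        embeddings.to_csv(out / "embeddings.tsv", sep="\t", index=False)
        results["embeddings"] = embeddings

    import importlib.metadata as _md

    manifest = {
        "config_digest": _config_digest(config),
        "seed": config.seed,
        "signals": list(config.signals),
        "contrasts": list(config.contrasts),
        "versions": {
            pkg: _md.version(pkg)
            for pkg in ("numpy", "scipy", "pandas", "scikit-learn", "statsmodels")
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    results["manifest"] = manifest
    return results
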